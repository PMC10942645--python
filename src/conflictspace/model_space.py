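"""Competing similarity models, BIC comparison, and dimensionality.

Three accounts of how the five conflict types relate: the cognitive-space
model (similarity = cosine of the axis-angle difference), the
domain-general model (types differ only in overall conflict strength, so
similarity is the sign-flipped z-scored absolute difference of their
behavioral congruency effects), and the domain-specific model (identity:
each type fully distinct).  Models are compared by swapping only the
conflict-similarity regressor in the RSA and comparing ML-fit BICs.  The
effective dimensionality of an averaged 5x5 similarity matrix is the
participation ratio of its eigenvalue spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedlm import MixedLM, RandomTerm
from .rsa_core import BASE_REGRESSORS, RegionFit, _random_terms
from .task_design import CONFLICT_TYPE_NAMES, conflict_similarity_matrix

MODEL_NAMES = ("cognitive-space", "domain-general", "domain-specific")


@dataclass
class SimilarityModel:
    name: str
    matrix: np.ndarray  # 5x5 conflict-type similarity

    def lookup(self, types_a, types_b) -> np.ndarray:
        """Expand to condition-level cells by conflict-type pair."""
        idx = {n: i for i, n in enumerate(CONFLICT_TYPE_NAMES)}
        ia = np.array([idx[t] for t in types_a])
        ib = np.array([idx[t] for t in types_b])
        return self.matrix[ia, ib]


def build_similarity_models(rt_congruency_effects) -> dict:
    """The three models; the domain-general one needs the five RT effects.

    `rt_congruency_effects` is a length-5 sequence (or Series indexed by
    conflict type) of group-averaged RT congruency effects in ms.
    """
    if isinstance(rt_congruency_effects, pd.Series):
        eff = rt_congruency_effects.reindex(CONFLICT_TYPE_NAMES).to_numpy(float)
    else:
        eff = np.asarray(rt_congruency_effects, float)
    if eff.shape != (5,):
        raise ValueError("need five congruency effects")
    dist = np.abs(eff[:, None] - eff[None, :])
    if np.allclose(dist, 0.0):
        raise ValueError(
            "all congruency effects are equal: the domain-general model is "
            "degenerate (zero-variance distance matrix)"
        )
    z = (dist - dist.mean()) / dist.std()
    models = {
        "cognitive-space": SimilarityModel(
            "cognitive-space", conflict_similarity_matrix()
        ),
        "domain-general": SimilarityModel("domain-general", -z),
        "domain-specific": SimilarityModel("domain-specific", np.eye(5)),
    }
    return models


@dataclass
class ModelComparisonResult:
    table: pd.DataFrame  # one row per model: beta, t, p, logLik, BIC
    winning_model: str
    variant: str

    def bic(self, name: str) -> float:
        return float(self.table.set_index("model").loc[name, "bic"])


def compare_models_bic(
    design: pd.DataFrame,
    models: dict,
    value_col: str = "z",
    variant: str = "full",
) -> ModelComparisonResult:
    """Refit the RSA once per model, swapping only the similarity regressor.

    All fits use ML (so BICs are comparable) on identical cells; the variant
    'incongruent' keeps only cells where both conditions are incongruent.
    """
    df = design
    if variant == "incongruent":
        df = df[
            (df["row_congruency"] == "I") & (df["col_congruency"] == "I")
        ].copy()
    elif variant != "full":
        raise ValueError(f"unknown variant {variant!r}")
    n_ref = len(df)
    rows = []
    for name, model in models.items():
        d = df.copy()
        d["conflict_similarity"] = model.lookup(
            d["row_conflict_type"].to_numpy(), d["col_conflict_type"].to_numpy()
        )
        if len(d) != n_ref:
            raise ValueError("row count changed across model fits")
        X = np.column_stack(
            [np.ones(len(d))] + [d[c].to_numpy(float) for c in BASE_REGRESSORS]
        )
        names = ["intercept"] + BASE_REGRESSORS
        res = MixedLM(
            d[value_col].to_numpy(float), X, _random_terms(d), names=names
        ).fit(reml=False)
        cs = res["conflict_similarity"]
        rows.append(
            dict(
                model=name,
                beta=cs["beta"],
                t=cs["t"],
                df=cs["df"],
                p_one_tailed=cs["p_one_tailed"],
                loglik=res.llf,
                bic=res.bic,
            )
        )
    table = pd.DataFrame(rows)
    winner = table.loc[table["bic"].idxmin(), "model"]
    return ModelComparisonResult(table, winner, variant)


def average_rsm_by_conflict_type(cells: pd.DataFrame, value_col: str = "r") -> np.ndarray:
    """Mean similarity per unordered conflict-type pair -> symmetric 5x5."""
    idx = {n: i for i, n in enumerate(CONFLICT_TYPE_NAMES)}
    ia = cells["row_conflict_type"].map(idx).to_numpy()
    ib = cells["col_conflict_type"].map(idx).to_numpy()
    v = cells[value_col].to_numpy(float)
    sums = np.zeros((5, 5))
    counts = np.zeros((5, 5))
    np.add.at(sums, (np.minimum(ia, ib), np.maximum(ia, ib)), v)
    np.add.at(counts, (np.minimum(ia, ib), np.maximum(ia, ib)), 1)
    if (counts[np.triu_indices(5)] == 0).any():
        raise ValueError("empty conflict-type pair bucket")
    out = sums / np.where(counts == 0, 1, counts)
    out = np.triu(out) + np.triu(out, 1).T
    return out


def participation_ratio(matrix: np.ndarray, clip_negative: bool = False) -> float:
    """(sum lambda)^2 / sum lambda^2 over the matrix's eigenvalues.

    For possibly indefinite empirical matrices the raw eigenvalues are used
    by default (squares handle signs); `clip_negative` zeroes them first.
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("need a square matrix")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    w = np.linalg.eigvalsh(m)
    if clip_negative:
        w = np.clip(w, 0.0, None)
    denom = float(np.sum(w**2))
    if denom == 0:
        raise ValueError("all-zero matrix has no dimensionality")
    return float(np.sum(w) ** 2 / denom)
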