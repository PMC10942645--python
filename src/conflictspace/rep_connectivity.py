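"""Representational connectivity between regions.

Regresses one region's within-subject representational similarity matrix
(RSM) on another's across subjects (random intercept and slope per
subject).  A candidate region is deemed connected to the target when its
slope exceeds the upper bound of the 95% confidence interval of the
best-connected control region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedlm import MixedLM, RandomTerm
from .neural_sim import PatternSet


def within_subject_rsm(ps: PatternSet) -> pd.DataFrame:
    """Per-subject Fisher-z RSM over all (run, condition) pattern pairs.

    Returns a long table with one row per subject and unordered off-diagonal
    cell (the diagonal is excluded).
    """
    s, r, c, v = ps.betas.shape
    iu = np.triu_indices(r * c, k=1)
    rows = []
    for si in range(s):
        flat = ps.betas[si].reshape(r * c, v)
        sd = flat.std(axis=1)
        with np.errstate(invalid="ignore"):
            mat = np.corrcoef(flat)
        if (sd == 0).any():
            warnings.warn("zero-variance pattern; cells set to NaN")
            mat[sd == 0, :] = np.nan
            mat[:, sd == 0] = np.nan
        z = np.arctanh(np.clip(mat[iu], -0.999999, 0.999999))
        # betas axis 0 follows ascending subject id (meta is sorted the same way)
        subj = np.sort(ps.meta["subject"].unique())[si]
        rows.append(
            pd.DataFrame(
                {"subject": subj, "cell": np.arange(len(z)), "z": z}
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class ConnectivityResult:
    target: str
    predictor: str
    slope: float
    se: float
    t: float
    df: float

    @property
    def ci95_upper(self) -> float:
        return self.slope + 1.96 * self.se


def representational_connectivity(
    target_rsms: pd.DataFrame,
    predictor_rsms: pd.DataFrame,
    target: str = "target",
    predictor: str = "predictor",
) -> ConnectivityResult:
    """Mixed-effects slope of target RSM cells on predictor RSM cells."""
    merged = target_rsms.merge(
        predictor_rsms, on=["subject", "cell"], suffixes=("_t", "_p")
    ).dropna()
    y = merged["z_t"].to_numpy(float)
    x = merged["z_p"].to_numpy(float)
    X = np.column_stack([np.ones(len(merged)), x])
    codes, _ = pd.factorize(merged["subject"])
    terms = [
        RandomTerm(
            "subject", codes, np.column_stack([np.ones(len(merged)), x]),
            ["icpt", "slope"],
        )
    ]
    res = MixedLM(y, X, terms, names=["intercept", "slope"]).fit()
    s = res["slope"]
    return ConnectivityResult(
        target, predictor, float(s["beta"]), float(s["se"]), float(s["t"]),
        float(s["df"]),
    )


def connectivity_screen(
    candidates: dict, controls: dict
) -> pd.DataFrame:
    """Flag candidates whose slope beats every control's 95% CI upper bound.

    `candidates` and `controls` map predictor-region names to
    ConnectivityResult.  The threshold is the largest control upper bound
    (mean + 1.96 SE); a candidate passes on strict inequality.
    """
    if not controls:
        raise ValueError("need at least one control region")
    threshold = max(c.ci95_upper for c in controls.values())
    rows = []
    for name, res in {**controls, **candidates}.items():
        rows.append(
            dict(
                predictor=name,
                slope=res.slope,
                se=res.se,
                is_control=name in controls,
                threshold=threshold,
                passes=(name in candidates) and (res.slope > threshold),
            )
        )
    return pd.DataFrame(rows)
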