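"""Cross-subject representational similarity analysis (RSA).

The similarity of condition-level multivoxel patterns is computed across
(subject, run, condition) entries, within-subject cells are discarded, and
the remaining Fisher-z similarities are regressed on model similarity
structures with crossed row/column random effects.  Working across the two
counterbalanced subject groups de-correlates the conflict-space regressor
(computed on quadrant-rotated axes) from the raw stimulus-orientation
regressor, which are perfectly confounded within a subject.

Region screening applies the three-criterion logic: (1) a significant
positive conflict-similarity effect (Bonferroni over regions, one-tailed);
(2) a stronger effect on incongruent than congruent trials (FDR among
criterion-1 survivors); (3) a positive across-subject correlation between
the neural effect and the behavioral similarity-modulation slope (FDR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .mixedlm import MixedLM, MixedLMResult, RandomTerm
from .neural_sim import PatternSet
from .task_design import fold_axial_difference

BASE_REGRESSORS = [
    "conflict_similarity",
    "orientation",
    "target_same",
    "response_same",
    "stroop_distractor",
    "simon_distractor",
    "same_group",
    "roi_mean_row",
    "roi_mean_col",
]
RANDOM_COVARIATES = ["intercept", "conflict_similarity", "orientation", "same_group"]


def noise_normalize(
    betas: np.ndarray, residual_cov: np.ndarray, shrinkage: float = 0.0
) -> np.ndarray:
    """Multivariate noise normalization: betas times cov^(-1/2).

    `residual_cov` is the voxel covariance of the GLM residuals for one run;
    a singular covariance forces shrinkage toward the scaled identity with a
    warning.
    """
    cov = np.asarray(residual_cov, float)
    v = cov.shape[0]
    if betas.shape[-1] != v:
        raise ValueError("voxel dimension mismatch")
    if shrinkage < 0 or shrinkage > 1:
        raise ValueError("shrinkage must be in [0, 1]")
    target = np.eye(v) * np.trace(cov) / v
    cov_s = (1 - shrinkage) * cov + shrinkage * target
    w, V = linalg.eigh(cov_s)
    if w.min() <= 1e-10 * max(w.max(), 1.0):
        warnings.warn("singular residual covariance; shrinkage forced to 0.1")
        cov_s = 0.9 * cov + 0.1 * target
        w, V = linalg.eigh(cov_s)
    inv_sqrt = (V / np.sqrt(w)) @ V.T
    return betas @ inv_sqrt


def normalize_patterns(ps: PatternSet, shrinkage: float = 0.0) -> PatternSet:
    """Apply per-run noise normalization to a PatternSet."""
    out = ps.betas.copy()
    for r in range(ps.betas.shape[1]):
        out[:, r] = noise_normalize(ps.betas[:, r], ps.residual_cov[r], shrinkage)
    return PatternSet(ps.region, out, ps.meta, ps.residual_cov)


@dataclass
class RSMLongTable:
    """Square cross-correlation matrix plus aligned row metadata."""

    matrix: np.ndarray  # (N, N) Pearson r
    meta: pd.DataFrame  # N rows: subject, run, condition metadata
    roi_mean: np.ndarray  # (N,) region-mean activation per row

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_rsm(ps: PatternSet) -> RSMLongTable:
    """Pearson correlations between all (subject, run, condition) patterns."""
    flat, meta = ps.flat()
    sd = flat.std(axis=1)
    bad = sd == 0
    with np.errstate(invalid="ignore"):
        mat = np.corrcoef(flat)
    if bad.any():
        warnings.warn(f"{bad.sum()} zero-variance patterns; cells set to NaN")
        mat[bad, :] = np.nan
        mat[:, bad] = np.nan
    np.fill_diagonal(mat, 1.0)
    roi_mean = flat.mean(axis=1)
    return RSMLongTable(mat, meta.reset_index(drop=True), roi_mean)


def select_cross_subject_cells(
    rsm: RSMLongTable, fisher: bool = True, standardize: bool = True
) -> pd.DataFrame:
    """All ordered cells whose row and column come from different subjects.

    Dropping same-subject cells also removes the within-run cells.  Values
    are Fisher r-to-z transformed and then standardized (both toggleable).
    """
    subj = rsm.meta["subject"].to_numpy()
    rows, cols = np.nonzero(subj[:, None] != subj[None, :])
    r = rsm.matrix[rows, cols]
    keep = np.isfinite(r)
    rows, cols, r = rows[keep], cols[keep], r[keep]
    value = np.arctanh(np.clip(r, -0.999999, 0.999999)) if fisher else r.copy()
    if standardize:
        value = (value - value.mean()) / value.std()
    df = pd.DataFrame({"row": rows, "col": cols, "r": r, "z": value})
    for side, idx in (("row", rows), ("col", cols)):
        m = rsm.meta.iloc[idx].reset_index(drop=True)
        for c in (
            "subject", "group", "run", "conflict_type", "congruency",
            "direction", "rotated_axis_deg", "axial_angle_deg", "x", "y",
            "response",
        ):
            df[f"{side}_{c}"] = m[c].to_numpy()
        df[f"{side}_roi_mean"] = rsm.roi_mean[idx]
    return df


def _zcol(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def build_rsa_design(cells: pd.DataFrame) -> pd.DataFrame:
    """Attach the model regressors to a cross-subject cell table.

    conflict_similarity uses quadrant-rotated axes (identical for the same
    conflict type in either group); orientation uses raw axial angles;
    the distractor similarities are sign-flipped absolute coordinate
    distances, z-scored.
    """
    df = cells.copy()
    d_rot = np.abs(df["row_rotated_axis_deg"] - df["col_rotated_axis_deg"])
    df["conflict_similarity"] = np.cos(np.radians(d_rot))
    d_raw = [
        fold_axial_difference(a - b)
        for a, b in zip(df["row_axial_angle_deg"], df["col_axial_angle_deg"])
    ]
    df["orientation"] = np.cos(np.radians(d_raw))
    df["target_same"] = (df["row_direction"] == df["col_direction"]).astype(float)
    df["response_same"] = (df["row_response"] == df["col_response"]).astype(float)
    df["stroop_distractor"] = _zcol(-np.abs(df["row_y"] - df["col_y"]).to_numpy())
    df["simon_distractor"] = _zcol(-np.abs(df["row_x"] - df["col_x"]).to_numpy())
    df["same_group"] = (df["row_group"] == df["col_group"]).astype(float)
    df["roi_mean_row"] = _zcol(df["row_roi_mean"].to_numpy())
    df["roi_mean_col"] = _zcol(df["col_roi_mean"].to_numpy())
    return df


def _random_terms(df: pd.DataFrame, extra_cols: list[str] | None = None):
    cov_cols = ["conflict_similarity", "orientation", "same_group"]
    if extra_cols:
        cov_cols = cov_cols + extra_cols
    design = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(float) for c in cov_cols]
    )
    names = ["intercept"] + cov_cols
    terms = []
    for side in ("row", "col"):
        codes, _ = pd.factorize(df[f"{side}_subject"])
        terms.append(RandomTerm(f"{side}_subject", codes, design, names))
    return terms


@dataclass
class RegionFit:
    """RSA result for one region."""

    region: str
    result: MixedLMResult
    per_subject_effect: pd.Series | None = None
    interaction: dict | None = None

    def regressor(self, name: str) -> dict:
        return self.result[name]


def _replicate_correct(res: MixedLMResult) -> MixedLMResult:
    """Inference correction for the twofold replication of ordered cells.

    The cell table keeps both (i, j) and (j, i) for every symmetric
    correlation, so each observation appears exactly twice; estimates are
    unchanged but the fixed-effect covariance must be doubled.
    """
    res.cov_params = res.cov_params * 2.0
    res.bse = res.bse * np.sqrt(2.0)
    res.tvalues = res.params / res.bse
    res.pvalues = 2.0 * stats.t.sf(np.abs(res.tvalues), res.df)
    return res


def fit_rsa(
    design: pd.DataFrame,
    value_col: str = "z",
    reml: bool = True,
    regressors: list[str] | None = None,
    region: str = "region",
    replicate_correction: bool = True,
) -> RegionFit:
    """Crossed-random-effects regression of similarity values on the models.

    Random intercept, conflict-similarity, orientation and group effects are
    included for both the row-side and column-side subject (crossed).  With
    `replicate_correction` (default) standard errors account for every
    unordered cell entering the ordered table twice.
    """
    regs = BASE_REGRESSORS if regressors is None else regressors
    X = np.column_stack(
        [np.ones(len(design))] + [design[c].to_numpy(float) for c in regs]
    )
    names = ["intercept"] + list(regs)
    y = design[value_col].to_numpy(float)
    terms = _random_terms(design)
    model = MixedLM(y, X, terms, names=names)
    res = model.fit(reml=reml)
    if not res.converged:
        simple = [
            RandomTerm(t.name, t.groups, t.design[:, :1], ["icpt"]) for t in terms
        ]
        model = MixedLM(y, X, simple, names=names)
        res = model.fit(reml=reml)
        res.simplified = True
    if replicate_correction:
        res = _replicate_correct(res)
    fit = RegionFit(region, res)
    if "conflict_similarity" in names and res.random_effects:
        i = names.index("conflict_similarity")
        subj_eff = {}
        for side in ("row", "col"):
            codes, levels = pd.factorize(design[f"{side}_subject"])
            re = res.random_effects.get(f"{side}_subject")
            if re is None:
                continue
            for lev, val in zip(levels, re[:, 1]):
                subj_eff.setdefault(lev, []).append(val)
        fit.per_subject_effect = pd.Series(
            {k: res.params[i] + float(np.mean(v)) for k, v in subj_eff.items()},
            name="conflict_similarity_effect",
        ).sort_index()
    return fit


def congruency_split_rsa(
    design: pd.DataFrame, value_col: str = "z", region: str = "region"
) -> RegionFit:
    """Congruent-only vs incongruent-only RSA and their interaction.

    Keeps only cells where both conditions share a congruency, fits each
    subset separately, and tests the conflict-similarity x congruency
    interaction in a combined model with the interaction as fixed and
    random effects.
    """
    both_c = (design["row_congruency"] == "C") & (design["col_congruency"] == "C")
    both_i = (design["row_congruency"] == "I") & (design["col_congruency"] == "I")
    sub = design[both_c | both_i].copy()
    if sub.empty:
        raise ValueError("no congruency-pure cells")
    sub["congruency_i"] = (sub["row_congruency"] == "I").astype(float)
    sub["conflict_similarity_x_congruency"] = (
        sub["conflict_similarity"] * sub["congruency_i"]
    )
    sub["orientation_x_congruency"] = sub["orientation"] * sub["congruency_i"]
    regs = BASE_REGRESSORS + [
        "congruency_i",
        "conflict_similarity_x_congruency",
        "orientation_x_congruency",
    ]
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(float) for c in regs]
    )
    names = ["intercept"] + regs
    terms = _random_terms(
        sub, extra_cols=["congruency_i", "conflict_similarity_x_congruency"]
    )
    model = MixedLM(sub[value_col].to_numpy(float), X, terms, names=names)
    res = model.fit()
    if not res.converged:
        simple = [
            RandomTerm(t.name, t.groups, t.design[:, :4], RANDOM_COVARIATES)
            for t in terms
        ]
        model = MixedLM(sub[value_col].to_numpy(float), X, simple, names=names)
        res = model.fit()
        res.simplified = True
    res = _replicate_correct(res)
    fits = {}
    for label, mask in (("C", both_c), (("I"), both_i)):
        part = design[mask]
        fits[label] = fit_rsa(part, value_col, region=f"{region}:{label}")
    inter = res["conflict_similarity_x_congruency"]
    out = RegionFit(region, res, interaction=inter)
    out.split_fits = fits
    return out


# ---------------------------------------------------------------------------
# region screening
# ---------------------------------------------------------------------------

def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    if len(pvals) == 0:
        return np.array([])
    return multipletests(pvals, method="fdr_bh")[1]


def screen_regions(
    region_results: dict,
    behavior_slopes: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Three-criterion screen over a cohort of region results.

    `region_results` maps region name -> dict with keys `p1` (one-tailed p
    of the conflict-similarity effect), `p_interaction` (one-tailed p of the
    incongruent > congruent interaction) and `per_subject_effect`
    (pd.Series).  Criterion 1 is Bonferroni-corrected across all regions;
    criteria 2 and 3 are BH-FDR-corrected among criterion-1 survivors.
    """
    n_regions = len(region_results)
    rows = []
    for name, rr in region_results.items():
        p1 = rr["p1"]
        rows.append(
            dict(
                region=name,
                p1=p1,
                p1_bonf=min(p1 * n_regions, 1.0),
                p_interaction=rr.get("p_interaction", np.nan),
            )
        )
    df = pd.DataFrame(rows).set_index("region")
    df["criterion1"] = df["p1_bonf"] < alpha
    surv = df.index[df["criterion1"]]
    # criterion 3: across-subject correlation with the behavioral slope
    r3, p3 = {}, {}
    for name in df.index:
        eff = region_results[name].get("per_subject_effect")
        if eff is None:
            r3[name], p3[name] = np.nan, np.nan
            continue
        joined = pd.concat([eff, behavior_slopes], axis=1, join="inner").dropna()
        if len(joined) < 3 or joined.std().min() == 0:
            r3[name], p3[name] = np.nan, 1.0
            continue
        r, _ = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
        n = len(joined)
        t = r * np.sqrt((n - 2) / max(1 - r**2, 1e-12))
        r3[name], p3[name] = r, float(stats.t.sf(t, n - 2))  # one-tailed
    df["r_behavior"] = pd.Series(r3)
    df["p3"] = pd.Series(p3)
    df["p2_fdr"] = np.nan
    df["p3_fdr"] = np.nan
    if len(surv):
        df.loc[surv, "p2_fdr"] = bh_fdr(df.loc[surv, "p_interaction"].to_numpy())
        df.loc[surv, "p3_fdr"] = bh_fdr(df.loc[surv, "p3"].to_numpy())
    df["criterion2"] = df["criterion1"] & (df["p2_fdr"] < alpha)
    df["criterion3"] = df["criterion1"] & (df["p3_fdr"] < alpha)
    df["pass_all"] = df["criterion1"] & df["criterion2"] & df["criterion3"]
    return df.reset_index()


def univariate_congruency_report(ps: PatternSet) -> dict:
    """Control checks: ROI-mean I-C t-test and a multivariate congruency test.

    The multivariate test contrasts between-congruency pattern correlations
    with within-congruency correlations (more negative means congruency is
    encoded in the pattern geometry).
    """
    inc = ps.meta["congruency"].to_numpy() == "I"
    roi = ps.roi_mean.reshape(-1)
    per_subj = (
        pd.DataFrame(
            {"subject": ps.meta["subject"], "inc": inc, "roi": roi}
        )
        .groupby(["subject", "inc"])["roi"]
        .mean()
        .unstack("inc")
    )
    diff = per_subj[True] - per_subj[False]
    t, p = stats.ttest_1samp(diff, 0.0)
    flat, meta = ps.flat()
    rsm = np.corrcoef(flat)
    inc_all = meta["congruency"].to_numpy() == "I"
    same = inc_all[:, None] == inc_all[None, :]
    off = ~np.eye(len(inc_all), dtype=bool)
    mv_contrast = float(rsm[same & off].mean() - rsm[~same].mean())
    return {
        "roi_mean_IC_t": float(t),
        "roi_mean_IC_p": float(p),
        "multivariate_congruency_contrast": mv_contrast,
    }
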