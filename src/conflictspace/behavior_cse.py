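"""Similarity-modulated congruency-sequence-effect (CSE) analysis.

Pipeline: trial filtering -> response-repetition centering -> per-subject
cell means of the 15 (previous x current conflict-type pair) x 4 (previous
x current congruency) factorial -> pooled z-scoring -> mixed-effects
estimation of the conflict-similarity modulation of the CSE, either in one
stage (cell means regressed on similarity x CSE-loading, with random
intercept and slope across both participants and the four CSE cells) or in
two stages (per-pair CSE contrasts regressed on similarity).  Includes the
leave-one-similarity-level-out prediction check, a physical-proximity
covariate, and a session-interaction test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior_sim import CSE_LOADING, type_similarity
from .mixedlm import MixedLM, MixedLMResult, RandomTerm
from .task_design import CONFLICT_TYPE_NAMES

log = logging.getLogger(__name__)

RT_MIN_MS = 200.0
RT_SD_CUTOFF = 3.0

_TYPE_ORDER = {n: i for i, n in enumerate(CONFLICT_TYPE_NAMES)}


@dataclass
class FilterReport:
    measure: str
    n_input: int
    n_kept: int
    removed: dict  # rule -> count (applied in order)

    @property
    def fractions(self) -> dict:
        return {k: v / max(self.n_input, 1) for k, v in self.removed.items()}


def _annotate_context(trials: pd.DataFrame) -> pd.DataFrame:
    df = trials.sort_values(["subject", "run", "trial"]).reset_index(drop=True)
    g = df.groupby(["subject", "run"], sort=False)
    if "prev_conflict_type" not in df:
        df["prev_conflict_type"] = g["conflict_type"].shift(1)
        df["prev_congruency"] = g["congruency"].shift(1)
    if "response_repetition" not in df:
        prev_resp = g["correct_response"].shift(1)
        df["response_repetition"] = (df["correct_response"] == prev_resp).astype(float)
        df.loc[prev_resp.isna(), "response_repetition"] = np.nan
    df["post_error"] = g["accuracy"].shift(1) == 0
    df["first_of_block"] = g.cumcount() == 0
    if "polar_angle_deg" in df:
        prev_ang = g["polar_angle_deg"].shift(1)
        d = np.radians(df["polar_angle_deg"] - prev_ang)
        df["proximity_dist"] = 2.0 * np.abs(np.sin(d / 2.0))
    return df


def filter_trials(
    trials: pd.DataFrame, measure: str = "RT", first_of_block: bool = True
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the measure-specific exclusion rules, in order.

    RT: first-of-block, errors, RT outliers (per-subject mean+3SD computed
    after error removal, or < 200 ms), post-error trials.  ER: first-of-block
    and post-error trials only (errors themselves are the signal).
    """
    if measure not in ("RT", "ER"):
        raise ValueError("measure must be 'RT' or 'ER'")
    df = _annotate_context(trials)
    n0 = len(df)
    removed = {}
    if first_of_block:
        m = df["first_of_block"]
        removed["first_of_block"] = int(m.sum())
        df = df[~m]
    if measure == "RT":
        m = df["accuracy"] == 0
        removed["error"] = int(m.sum())
        df = df[~m]
        stats = df.groupby("subject")["rt"].agg(["mean", "std"])
        hi = df["subject"].map(stats["mean"] + RT_SD_CUTOFF * stats["std"])
        m = (df["rt"] > hi) | (df["rt"] < RT_MIN_MS)
        removed["rt_outlier"] = int(m.sum())
        df = df[~m]
    m = df["post_error"]
    removed["post_error"] = int(m.sum())
    df = df[~m]
    if df.empty:
        raise ValueError(f"no trials survive the {measure} filtering rules")
    report = FilterReport(measure, n0, len(df), removed)
    return df.reset_index(drop=True), report


def center_response_repetition(
    trials: pd.DataFrame, measure: str = "RT"
) -> pd.DataFrame:
    """Per subject, recenter each repetition class on the subject's mean.

    Replaces the class-specific mean (response repetition vs alternation)
    with the subject's global mean, preserving that mean exactly.
    """
    col = "rt" if measure == "RT" else "error"
    df = trials.copy()
    if col == "error" and "error" not in df:
        df["error"] = 1.0 - df["accuracy"]
    out = df[col].astype(float).copy()
    for subj, sub in df.groupby("subject"):
        classes = sub["response_repetition"].dropna().unique()
        if len(classes) < 2:
            warnings.warn(
                f"subject {subj}: a response-repetition class is absent; "
                "values passed through unchanged"
            )
            continue
        grand = sub[col].mean()
        for cls, cls_sub in sub.groupby("response_repetition"):
            out.loc[cls_sub.index] = cls_sub[col] - cls_sub[col].mean() + grand
    df[col] = out
    return df


def _pair_key(a: str, b: str) -> str:
    return "|".join(sorted((a, b), key=_TYPE_ORDER.get))


def build_cse_cells(trials: pd.DataFrame, measure: str = "RT") -> pd.DataFrame:
    """Per-subject cell means of the 15 pairs x 4 CSE cells design."""
    df = trials[trials["prev_conflict_type"].notna()].copy()
    col = "rt" if measure == "RT" else "error"
    if col == "error" and "error" not in df:
        df["error"] = 1.0 - df["accuracy"]
    df["pair"] = [
        _pair_key(a, b)
        for a, b in zip(df["prev_conflict_type"], df["conflict_type"])
    ]
    df["cse_cell"] = df["prev_congruency"] + df["congruency"]
    agg = {"value": (col, "mean"), "n": (col, "size")}
    if "proximity_dist" in df:
        agg["proximity"] = ("proximity_dist", "mean")
    if "session" in df:
        cells = df.groupby(
            ["subject", "session", "pair", "cse_cell"], as_index=False
        ).agg(**agg)
    else:
        cells = df.groupby(["subject", "pair", "cse_cell"], as_index=False).agg(**agg)
    t1 = cells["pair"].str.split("|").str[0]
    t2 = cells["pair"].str.split("|").str[1]
    cells["similarity"] = [type_similarity(a, b) for a, b in zip(t1, t2)]
    cells["measure"] = measure
    return cells


def build_similarity_cse_design(cells: pd.DataFrame) -> pd.DataFrame:
    """Add the similarity x CSE-loading regressor (the Kronecker design)."""
    out = cells.copy()
    loading = {
        pc + cc: l for (pc, cc), l in CSE_LOADING.items()
    }
    out["loading"] = out["cse_cell"].map(loading)
    out["x"] = out["similarity"] * out["loading"]
    return out


def cse_cells(trials: pd.DataFrame, measure: str = "RT",
              keep_session: bool = False) -> pd.DataFrame:
    """Full preprocessing: filter, center, aggregate, design columns."""
    filt, _ = filter_trials(trials, measure)
    filt = center_response_repetition(filt, measure)
    if not keep_session and "session" in filt:
        filt = filt.drop(columns=["session"])
    return build_similarity_cse_design(build_cse_cells(filt, measure))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v)
    if sd == 0:
        raise ValueError("degenerate (constant) dependent variable")
    return (v - np.mean(v)) / sd


@dataclass
class CSEFitResult:
    """One-stage or two-stage similarity-modulation estimate."""

    model: MixedLMResult
    slope_name: str
    per_subject_slopes: pd.Series
    interaction_F: tuple | None = None  # (F, df1, df2, p)

    @property
    def slope(self) -> dict:
        return self.model[self.slope_name]


def fit_one_stage(
    cells: pd.DataFrame,
    proximity_control: bool = False,
    session_interaction: bool = False,
    reml: bool = True,
) -> CSEFitResult:
    """Mixed model: z(cell mean) ~ similarity x CSE loading.

    Random intercept and slope across participants and across the four CSE
    cells (crossed, independent variances).  One-tailed inference on the
    similarity regressor is directional (positive modulation).
    """
    df = cells.copy()
    y = _zscore(df["value"].to_numpy(float))
    names = ["intercept", "similarity_cse"]
    cols = [np.ones(len(df)), df["x"].to_numpy(float)]
    if proximity_control:
        names.append("proximity")
        cols.append(_zscore(df["proximity"].to_numpy(float)))
    if session_interaction:
        if "session" not in df:
            raise ValueError("cells lack a session column")
        sessions = np.sort(df["session"].unique())
        for s in sessions[1:]:
            names.append(f"session[{s}]")
            cols.append((df["session"] == s).to_numpy(float))
        for s in sessions[1:]:
            names.append(f"similarity_cse:session[{s}]")
            cols.append(df["x"].to_numpy(float) * (df["session"] == s))
    X = np.column_stack(cols)
    subj_codes, subj_levels = pd.factorize(df["subject"])
    re_design = np.column_stack([np.ones(len(df)), df["x"].to_numpy(float)])
    terms = [
        RandomTerm("subject", subj_codes, re_design, ["icpt", "x"]),
        RandomTerm(
            "cse_cell", pd.factorize(df["cse_cell"])[0], re_design, ["icpt", "x"]
        ),
    ]
    model = MixedLM(y, X, terms, names=names)
    res = model.fit(reml=reml)
    if not res.converged:  # refit with intercept-only random structure
        terms = [
            RandomTerm("subject", subj_codes, np.ones((len(df), 1)), ["icpt"]),
            RandomTerm(
                "cse_cell", pd.factorize(df["cse_cell"])[0],
                np.ones((len(df), 1)), ["icpt"],
            ),
        ]
        model = MixedLM(y, X, terms, names=names)
        res = model.fit(reml=reml)
        res.simplified = True
    i_slope = names.index("similarity_cse")
    subj_slopes = pd.Series(
        res.params[i_slope]
        + (res.random_effects.get("subject", np.zeros((len(subj_levels), 2)))[:, -1]),
        index=subj_levels,
        name="similarity_cse_slope",
    )
    fres = CSEFitResult(res, "similarity_cse", subj_slopes)
    if session_interaction:
        L = np.zeros((len(sessions) - 1, X.shape[1]))
        for j, s in enumerate(sessions[1:]):
            L[j, names.index(f"similarity_cse:session[{s}]")] = 1.0
        F, df1, df2, p = model.contrast_F(res, L)
        fres.interaction_F = (F, df1, df2, p)
    return fres


def stage_one_cse(cells: pd.DataFrame) -> pd.DataFrame:
    """Per subject x pair CSE contrast (CI - CC) - (II - IC)."""
    gcols = [c for c in ("subject", "session") if c in cells]
    wide = cells.pivot_table(
        index=gcols + ["pair", "similarity"], columns="cse_cell", values="value"
    )
    wide = wide.dropna(subset=["CC", "CI", "IC", "II"])
    cse = (wide["CI"] - wide["CC"]) - (wide["II"] - wide["IC"])
    return cse.rename("cse").reset_index()


def two_stage_cse(cells: pd.DataFrame, reml: bool = True):
    """Stage 1: per-pair CSE per subject; stage 2: CSE ~ similarity."""
    tab = stage_one_cse(cells)
    y = _zscore(tab["cse"].to_numpy(float))
    X = np.column_stack([np.ones(len(tab)), tab["similarity"].to_numpy(float)])
    subj_codes, subj_levels = pd.factorize(tab["subject"])
    terms = [
        RandomTerm(
            "subject", subj_codes,
            np.column_stack([np.ones(len(tab)), tab["similarity"].to_numpy(float)]),
            ["icpt", "sim"],
        )
    ]
    model = MixedLM(y, X, terms, names=["intercept", "similarity"])
    res = model.fit(reml=reml)
    subj_slopes = pd.Series(
        res.params[1] + res.random_effects["subject"][:, 1],
        index=subj_levels,
        name="similarity_slope",
    )
    return tab, CSEFitResult(res, "similarity", subj_slopes)


SIMILARITY_LEVELS = (0.0, 22.5, 45.0, 67.5, 90.0)


def loo_similarity_prediction(cells: pd.DataFrame):
    """Leave one similarity level out; predict it from the other four.

    Fits the two-stage model on the remaining levels, forms per-subject
    intercept+slope (fixed effect plus conditional mode) and predicts each
    subject's CSE at the held-out level; returns the per-point table and the
    Pearson correlation between predictions and observations.
    """
    tab = stage_one_cse(cells)
    sims = {d: float(np.cos(np.radians(d))) for d in SIMILARITY_LEVELS}
    rows = []
    for d, s_level in sims.items():
        held = np.isclose(tab["similarity"], s_level)
        if held.sum() == 0:
            warnings.warn(f"no data at similarity level {d} deg; skipped")
            continue
        train = tab[~held]
        test = tab[held]
        y = train["cse"].to_numpy(float)
        mu, sd = y.mean(), y.std()
        X = np.column_stack([np.ones(len(train)), train["similarity"].to_numpy(float)])
        subj_codes, subj_levels = pd.factorize(train["subject"])
        terms = [
            RandomTerm(
                "subject", subj_codes,
                np.column_stack(
                    [np.ones(len(train)), train["similarity"].to_numpy(float)]
                ),
                ["icpt", "sim"],
            )
        ]
        res = MixedLM((y - mu) / sd, X, terms, names=["intercept", "similarity"]).fit()
        re = res.random_effects["subject"]
        coef = pd.DataFrame(
            {
                "icpt": res.params[0] + re[:, 0],
                "slope": res.params[1] + re[:, 1],
            },
            index=subj_levels,
        )
        for _, r in test.iterrows():
            if r["subject"] not in coef.index:
                continue
            c = coef.loc[r["subject"]]
            pred = (c["icpt"] + c["slope"] * r["similarity"]) * sd + mu
            rows.append((d, r["subject"], r["pair"], pred, r["cse"]))
    out = pd.DataFrame(
        rows, columns=["delta_deg", "subject", "pair", "predicted", "observed"]
    )
    r = float(np.corrcoef(out["predicted"], out["observed"])[0, 1])
    return out, r


def congruency_effect_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-conflict-type congruency effects, per subject and group-averaged.

    RT effects use the RT rule set and ER effects the ER rule set, both
    without the CSE-specific first-trial exclusion.
    """
    out = []
    for measure in ("RT", "ER"):
        filt, _ = filter_trials(trials, measure, first_of_block=False)
        col = "rt" if measure == "RT" else "error"
        if col == "error":
            filt["error"] = 1.0 - filt["accuracy"]
        m = (
            filt.groupby(["subject", "conflict_type", "congruency"])[col]
            .mean()
            .unstack("congruency")
        )
        eff = (m["I"] - m["C"]).rename("effect").reset_index()
        eff["measure"] = measure
        out.append(eff)
    per_subject = pd.concat(out, ignore_index=True)
    group = (
        per_subject.groupby(["measure", "conflict_type"])["effect"]
        .mean()
        .rename("group_mean")
        .reset_index()
    )
    order = {n: i for i, n in enumerate(CONFLICT_TYPE_NAMES)}
    group = group.sort_values(
        ["measure", "conflict_type"], key=lambda s: s.map(order).fillna(-1)
    ).reset_index(drop=True)
    return per_subject, group
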