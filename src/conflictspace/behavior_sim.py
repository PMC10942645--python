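"""Trial-level RT/accuracy generator for the conflict-space task.

Produces behavior whose congruency sequence effect (CSE) scales linearly
with the cosine similarity between the previous and current trial's
conflict types.  The generator's cell-mean structure is fully analytic, so
the expected CSE per similarity level and the pooled-sample standard
deviation used by the one-stage analysis can be computed in closed form;
`calibrate_cse_gain` inverts that relation to hit a target standardized
slope.

Conventions: the CSE loading on the (previous, current) congruency cells
CI, CC, II, IC is +1, -1, -1, +1, and a trial-level CSE contribution of
``0.5 * cse_gain * similarity * loading`` makes the classic CSE contrast
(CI - CC) - (II - IC) equal ``2 * cse_gain * similarity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task_design import (
    CONFLICT_TYPE_ANGLES,
    CONFLICT_TYPE_NAMES,
    conflict_similarity,
    conflict_types,
)

#: CSE loading per (previous congruency, current congruency)
CSE_LOADING = {("C", "I"): 1.0, ("C", "C"): -1.0, ("I", "I"): -1.0, ("I", "C"): 1.0}

_TYPE_ANGLE = dict(zip(CONFLICT_TYPE_NAMES, CONFLICT_TYPE_ANGLES))

#: variance loss of a Gaussian truncated at +/- 3 sd (the RT outlier rule)
_TRUNC_FACTOR = 0.9734


def type_similarity(a: str, b: str) -> float:
    return float(np.cos(np.radians(abs(_TYPE_ANGLE[a] - _TYPE_ANGLE[b]))))


@dataclass
class BehaviorGenParams:
    """Generator settings; the defaults emulate the in-lab experiment.

    RT terms are in ms; error terms are probabilities.  `congruency_effect`
    is the per-conflict-type RT cost of incongruency, ordered Stroop,
    StHSmL, StMSmM, StLSmH, Simon (middle types carry the largest costs, as
    the blended conflicts do empirically).
    """

    base_rt: float = 520.0
    congruency_effect: tuple = (60.0, 95.0, 100.0, 95.0, 70.0)
    cse_gain: float = 10.0
    similarity_slope_target: float | None = None
    subject_sd: float = 40.0
    cse_condition_sd: float = 5.0
    trial_sd: float = 90.0
    response_repetition_effect: float = -15.0
    post_error_slowing: float = 30.0
    error_base_rate: float = 0.025
    error_congruency_increment: float = 0.03
    error_cse_gain: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.error_base_rate <= 1 and 0 <= self.error_congruency_increment <= 1):
            raise ValueError("error probabilities must lie in [0, 1]")
        for s in (self.subject_sd, self.cse_condition_sd, self.trial_sd):
            if s < 0:
                raise ValueError("standard deviations must be nonnegative")

    @property
    def congruency_effect_by_type(self) -> dict:
        return dict(zip(CONFLICT_TYPE_NAMES, self.congruency_effect))


def _error_prob(params: BehaviorGenParams, congr, cse_term):
    p = (
        params.error_base_rate
        + params.error_congruency_increment * (np.asarray(congr) == "I")
        + cse_term
    )
    return np.clip(p, 1e-4, 0.999)


def simulate_trials(
    params: BehaviorGenParams, schedule: pd.DataFrame, profiles=None
) -> pd.DataFrame:
    """Simulate RT (ms) and accuracy for every trial of a schedule.

    The schedule must carry subject/run/trial/conflict_type/congruency/
    correct_response columns (as produced by `task_design.build_experiment`).
    Identical params and schedule give identical output.
    """
    rng = np.random.default_rng(params.seed)
    df = schedule.sort_values(["subject", "run", "trial"]).reset_index(drop=True)
    g = df.groupby(["subject", "run"], sort=False)
    df["prev_conflict_type"] = g["conflict_type"].shift(1)
    df["prev_congruency"] = g["congruency"].shift(1)
    prev_resp = g["correct_response"].shift(1)
    df["response_repetition"] = (df["correct_response"] == prev_resp).astype(float)
    df.loc[prev_resp.isna(), "response_repetition"] = np.nan

    has_prev = df["prev_conflict_type"].notna().to_numpy()
    sim = np.zeros(len(df))
    load = np.zeros(len(df))
    prev_t = df["prev_conflict_type"].to_numpy()
    cur_t = df["conflict_type"].to_numpy()
    prev_c = df["prev_congruency"].to_numpy()
    cur_c = df["congruency"].to_numpy()
    sim_lut = {
        (a, b): type_similarity(a, b)
        for a in CONFLICT_TYPE_NAMES
        for b in CONFLICT_TYPE_NAMES
    }
    idx = np.where(has_prev)[0]
    sim[idx] = [sim_lut[(prev_t[i], cur_t[i])] for i in idx]
    load[idx] = [CSE_LOADING[(prev_c[i], cur_c[i])] for i in idx]
    cse_x = sim * load

    subjects = df["subject"].to_numpy()
    uniq_subj = np.unique(subjects)
    subj_eff = dict(zip(uniq_subj, rng.normal(0, params.subject_sd, len(uniq_subj))))

    # accuracy first (post-error slowing needs it)
    err_cse = 0.5 * params.error_cse_gain * cse_x
    p_err = _error_prob(params, cur_c, err_cse)
    accuracy = (rng.random(len(df)) >= p_err).astype(int)
    df["accuracy"] = accuracy
    prev_acc = (
        df.groupby(["subject", "run"], sort=False)["accuracy"].shift(1).to_numpy()
    )
    post_error = prev_acc == 0

    cong_eff = np.asarray(
        [params.congruency_effect_by_type[t] for t in cur_t]
    ) * (cur_c == "I")
    # per subject x CSE-condition offset
    cse_cell = np.where(has_prev, prev_c.astype(str) + cur_c.astype(str), "NA")
    csec_keys = sorted({(s, c) for s, c in zip(subjects, cse_cell) if c != "NA"})
    csec_eff = dict(
        zip(csec_keys, rng.normal(0, params.cse_condition_sd, len(csec_keys)))
    )
    csec = np.array(
        [csec_eff.get((s, c), 0.0) for s, c in zip(subjects, cse_cell)]
    )
    rep = np.nan_to_num(df["response_repetition"].to_numpy())
    rt = (
        params.base_rt
        + np.array([subj_eff[s] for s in subjects])
        + cong_eff
        + 0.5 * params.cse_gain * cse_x
        + csec
        + params.response_repetition_effect * rep
        + params.post_error_slowing * post_error
        + rng.normal(0, params.trial_sd, len(df))
    )
    df["rt"] = np.maximum(rt, 1.0)
    return df


def expected_cse_by_similarity(params: BehaviorGenParams) -> pd.DataFrame:
    """Analytic expected CSE contrast at each angular-difference level."""
    deltas = [0.0, 22.5, 45.0, 67.5, 90.0]
    rows = []
    for d in deltas:
        s = float(np.cos(np.radians(d)))
        rows.append((d, s, 2.0 * params.cse_gain * s))
    return pd.DataFrame(rows, columns=["delta_deg", "similarity", "expected_cse"])


# ---------------------------------------------------------------------------
# analytic calibration of the standardized one-stage slope
# ---------------------------------------------------------------------------

def _pair_table():
    """The 15 unordered conflict-type pairs and their similarities."""
    types = conflict_types()
    pairs = []
    for i in range(5):
        for j in range(i, 5):
            pairs.append(
                (types[i].name, types[j].name, conflict_similarity(types[i], types[j]))
            )
    return pairs


def _cell_structure(params: BehaviorGenParams, measure: str):
    """Deterministic per-cell means (without the CSE term) and x = sim*load."""
    eff = params.congruency_effect_by_type
    xs, det, keeps, errs = [], [], [], []
    for t1, t2, s in _pair_table():
        e_bar = 0.5 * (eff[t1] + eff[t2])
        p1c = params.error_base_rate
        p1i = params.error_base_rate + params.error_congruency_increment
        for (pc, cc), l in CSE_LOADING.items():
            xs.append(s * l)
            p_prev = p1i if pc == "I" else p1c
            p_cur = p1i if cc == "I" else p1c
            if measure == "RT":
                det.append(e_bar if cc == "I" else 0.0)
                keeps.append((1 - p_prev) * (1 - p_cur) * (1 - 0.003))
                errs.append(p_cur)
            else:
                det.append(p_cur)
                keeps.append(1 - p_prev)
                errs.append(p_cur)
    return (np.array(xs), np.array(det), np.array(keeps), np.array(errs))


def _cell_counts(schedule: pd.DataFrame) -> pd.Series:
    """Expected kept-trial count per (pair, CSE cell), averaged over subjects."""
    df = schedule.sort_values(["subject", "run", "trial"])
    g = df.groupby(["subject", "run"], sort=False)
    prev_t = g["conflict_type"].shift(1)
    prev_c = g["congruency"].shift(1)
    ok = prev_t.notna()
    a = np.minimum(prev_t[ok], df.loc[ok, "conflict_type"])
    b = np.maximum(prev_t[ok], df.loc[ok, "conflict_type"])
    cell = prev_c[ok] + df.loc[ok, "congruency"]
    key = a + "|" + b + "|" + cell
    counts = (
        pd.DataFrame({"subject": df.loc[ok, "subject"], "key": key})
        .groupby(["subject", "key"])
        .size()
    )
    return counts


def _expected_cell_profile(params: BehaviorGenParams, schedule: pd.DataFrame,
                           g: float, measure: str) -> pd.DataFrame:
    """Expected per-(subject, cell) mean after filtering and centering.

    Works on the deterministic trial schedule: every trial's keep
    probability and expected value are known in closed form, so the
    response-repetition centering (which mixes cell and repetition-class
    means) and the unequal filtering weights are reproduced exactly.
    Returns columns subject, pair, cse_cell, x, profile, w (expected kept
    count).
    """
    from . import behavior_cse as _bc  # late import to avoid a cycle

    df = schedule.copy()
    df["accuracy"] = 1  # placeholder so context annotation works
    df = _bc._annotate_context(df)
    df = df[df["prev_conflict_type"].notna()].copy()
    df["pair"] = [
        _bc._pair_key(a, b)
        for a, b in zip(df["prev_conflict_type"], df["conflict_type"])
    ]
    df["cse_cell"] = df["prev_congruency"] + df["congruency"]
    sim = np.array([type_similarity(*k.split("|")) for k in df["pair"]])
    load = np.where(df["cse_cell"].isin(["CI", "IC"]), 1.0, -1.0)
    df["x"] = sim * load
    eff = params.congruency_effect_by_type
    p_cur = np.clip(
        params.error_base_rate
        + params.error_congruency_increment * (df["congruency"] == "I")
        + 0.5 * params.error_cse_gain * df["x"],
        1e-4, 0.999,
    )
    p_prev = np.clip(
        params.error_base_rate
        + params.error_congruency_increment * (df["prev_congruency"] == "I"),
        1e-4, 0.999,
    )
    if measure == "RT":
        w = (1.0 - p_cur) * (1.0 - p_prev) * (1.0 - 0.003)
        m0 = (
            df["conflict_type"].map(eff).to_numpy()
            * (df["congruency"] == "I").to_numpy()
            + 0.5 * g * df["x"].to_numpy()
        )
    else:
        w = 1.0 - p_prev
        m0 = np.clip(
            params.error_base_rate
            + params.error_congruency_increment
            * (df["congruency"] == "I").to_numpy()
            + 0.5 * g * df["x"].to_numpy(),
            1e-4, 0.999,
        )
    df["w"] = w
    df["m0"] = m0
    rep = df["response_repetition"].to_numpy()
    # centering replaces each repetition class's mean with the subject mean
    out = []
    for subj, sub in df.groupby("subject"):
        ww = sub["w"].to_numpy()
        mm = sub["m0"].to_numpy()
        rr = sub["response_repetition"].to_numpy()
        M = np.average(mm, weights=ww)
        cls_mean = {}
        for c in (0.0, 1.0):
            sel = rr == c
            cls_mean[c] = np.average(mm[sel], weights=ww[sel]) if sel.any() else M
        centered = mm - np.where(rr == 1.0, cls_mean[1.0], cls_mean[0.0]) + M
        s = sub.copy()
        s["profile"] = centered
        out.append(s)
    allc = pd.concat(out)
    cells = (
        allc.groupby(["subject", "pair", "cse_cell"])
        .apply(
            lambda t: pd.Series(
                {
                    "x": t["x"].iloc[0],
                    "profile": np.average(t["profile"], weights=t["w"]),
                    "w": t["w"].sum(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return cells


def _noise_variance(params: BehaviorGenParams, schedule, measure: str) -> float:
    """Mean per-cell sampling variance of the cell means (E[sigma^2 / n])."""
    xs, det, keeps, errs = _cell_structure(params, measure)
    counts = _cell_counts(schedule)
    keep_lut, err_lut = {}, {}
    i = 0
    for t1, t2, s in _pair_table():
        pk = "|".join(sorted((t1, t2)))
        for (pc, cc), l in CSE_LOADING.items():
            keep_lut[(pk, pc + cc)] = keeps[i]
            err_lut[(pk, pc + cc)] = errs[i]
            i += 1
    keys = counts.index.get_level_values("key")
    cells = [k.rsplit("|", 1)[1] for k in keys]
    pairs = [k.rsplit("|", 1)[0] for k in keys]
    n_sched = counts.to_numpy(float)
    p_keep = np.array([keep_lut[(pairs[j], cells[j])] for j in range(len(counts))])
    mean_n = np.maximum(n_sched * p_keep, 1.0)
    inv_n = (1.0 + (1.0 - p_keep) / mean_n) / mean_n
    if measure == "RT":
        return float(np.mean(_TRUNC_FACTOR * params.trial_sd**2 * inv_n))
    p = np.array([err_lut[(pairs[j], cells[j])] for j in range(len(counts))])
    return float(np.mean(p * (1 - p) * inv_n))


def true_one_stage_slope(
    params: BehaviorGenParams, schedule: pd.DataFrame, measure: str = "RT",
    g: float | None = None,
) -> float:
    """Expected standardized one-stage slope for a given CSE gain."""
    if g is None:
        g = params.cse_gain if measure == "RT" else params.error_cse_gain
    prof = _expected_cell_profile(params, schedule, g, measure)
    x = prof["x"].to_numpy()
    p = prof["profile"].to_numpy()
    vx = float(np.var(x))
    coef = float(np.cov(p, x, ddof=0)[0, 1] / vx)
    var_struct = float(np.var(p))
    noise = _noise_variance(params, schedule, measure)
    if measure == "RT":
        extra = params.subject_sd**2 + params.cse_condition_sd**2
    else:
        extra = 0.0
    sd_pool = np.sqrt(var_struct + extra + noise)
    return coef / sd_pool


def calibrate_cse_gain(
    params: BehaviorGenParams,
    schedule: pd.DataFrame,
    measure: str = "RT",
    target: float | None = None,
) -> BehaviorGenParams:
    """Set the CSE gain so the true standardized one-stage slope hits `target`.

    The one-stage analysis z-scores per-subject cell means over the pooled
    subjects x cells sample and regresses them on x = similarity * loading.
    The expected slope at gain g is computed from the exact expected cell
    profile (filtering weights and repetition centering included) divided by
    the pooled standard deviation, and solved for g.  The expected profile
    is linear in g, so two evaluations determine the whole curve.
    """
    from scipy.optimize import brentq

    t = params.similarity_slope_target if target is None else target
    if t is None:
        raise ValueError("no slope target given")
    step = 1.0 if measure == "RT" else 0.01  # stay clear of probability clipping
    prof0 = _expected_cell_profile(params, schedule, 0.0, measure)
    prof1 = _expected_cell_profile(params, schedule, step, measure)
    x = prof0["x"].to_numpy()
    p0 = prof0["profile"].to_numpy()
    dp = (prof1["profile"].to_numpy() - p0) / step
    vx = float(np.var(x))
    noise = _noise_variance(params, schedule, measure)
    if measure == "RT":
        extra = params.subject_sd**2 + params.cse_condition_sd**2
    else:
        extra = 0.0

    def slope_at(g):
        p = p0 + g * dp
        coef = float(np.cov(p, x, ddof=0)[0, 1] / vx)
        sd_pool = np.sqrt(float(np.var(p)) + extra + noise)
        return coef / sd_pool

    lo, hi = 0.0, 1.0
    while slope_at(hi) < t:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(f"target slope {t} is unattainable")
    g = float(brentq(lambda gg: slope_at(gg) - t, lo, hi, xtol=1e-10))
    if measure == "RT":
        return replace(params, cse_gain=g, similarity_slope_target=t)
    return replace(params, error_cse_gain=g, similarity_slope_target=t)
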