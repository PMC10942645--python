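"""Condition x run x subject multivoxel pattern generator.

Stand-in for condition-level GLM beta maps: each pseudo-region mixes
weighted latent components (conflict-space geometry, stimulus orientation,
target, response, the two distractor coordinates, subject group, and a
congruency-dependent boost of the conflict-space component) through a
fixed voxel embedding shared by all subjects, plus per-(subject, run)
noise with a configurable residual covariance.  Because the embedding is
shared, cross-subject pattern correlations inherit each component's
similarity structure, which is what the cross-subject RSA consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task_design import (
    SubjectProfile,
    condition_location,
    conditions,
    fold_axial_difference,
    group_axis_angle,
    rotated_axis_angle,
)

COMPONENTS = (
    "conflict_space",
    "orientation",
    "target",
    "response",
    "stroop_distractor",
    "simon_distractor",
    "group",
    "congruency_interaction",
)


@dataclass
class NeuralGenParams:
    """Settings for one pseudo-region."""

    n_subjects: int = 35
    group_split: int = 17
    n_runs: int = 2
    n_voxels: int = 60
    weights: dict = field(default_factory=dict)  # component -> nonneg weight
    univariate_offsets: np.ndarray | None = None  # (20,) per-condition offset
    #: optional 5x5 conflict-type similarity matrix for the conflict
    #: component (default: the cosine cognitive-space geometry)
    conflict_space_matrix: np.ndarray | None = None
    #: optional per-subject multiplier on the conflict-space (and its
    #: congruency-boost) weight; couples neural effect strength to
    #: subject-level traits such as the behavioral similarity slope
    subject_conflict_scale: np.ndarray | None = None
    noise_sd: float = 1.0
    residual_cov_spec: str = "diagonal"  # "identity" | "diagonal" | "toeplitz"
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.weights) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("component weights must be nonnegative")


@dataclass
class PatternSet:
    """Beta patterns for one region: (subject, run, condition) -> voxels."""

    region: str
    betas: np.ndarray  # (n_subjects, n_runs, 20, n_voxels)
    meta: pd.DataFrame  # one row per (subject, run, condition)
    residual_cov: np.ndarray  # (n_runs, n_voxels, n_voxels)

    @property
    def n_subjects(self) -> int:
        return self.betas.shape[0]

    @property
    def roi_mean(self) -> np.ndarray:
        """(n_subjects, n_runs, 20) mean activation across voxels."""
        return self.betas.mean(axis=-1)

    def flat(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Stack to (n_subjects*n_runs*20, n_voxels) aligned with meta."""
        s, r, c, v = self.betas.shape
        return self.betas.reshape(s * r * c, v), self.meta


def embed_model_geometry(target: np.ndarray, n_latent: int | None = None,
                         tol: float = 1e-8,
                         diagonal_load: float | str = 0.0) -> np.ndarray:
    """Feature vectors whose Gram matrix equals the target (matrix sqrt).

    The target must be symmetric PSD up to `tol` after the diagonal load
    (``"auto"`` adds just enough to the diagonal to reach PSD, leaving all
    off-diagonal similarities untouched); otherwise the offending eigenvalue
    is reported.
    """
    target = np.asarray(target, float)
    if not np.allclose(target, target.T):
        raise ValueError("target similarity matrix is not symmetric")
    if diagonal_load == "auto":
        lo = float(np.linalg.eigvalsh(target).min())
        diagonal_load = max(0.0, -lo) + 1e-9
    if diagonal_load:
        target = target + diagonal_load * np.eye(target.shape[0])
    w, V = np.linalg.eigh(target)
    if w.min() < -tol * max(abs(w).max(), 1.0):
        raise ValueError(
            f"target matrix is not PSD (eigenvalue {w.min():.3e})"
        )
    w = np.clip(w, 0.0, None)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if n_latent is None:
        n_latent = int(np.sum(w > tol * max(w.max(), 1.0)))
    return V[:, :n_latent] * np.sqrt(w[:n_latent])


def _orientation_features() -> dict:
    """Shared embedding of the folded-angle cosine similarity over all axes."""
    angles = [i * 22.5 for i in range(8)]  # all axial angles across groups
    M = np.array(
        [
            [np.cos(np.radians(fold_axial_difference(a - b))) for b in angles]
            for a in angles
        ]
    )
    feats = embed_model_geometry(M, tol=1e-6, diagonal_load="auto")
    return dict(zip(angles, feats))


def condition_metadata(profile: SubjectProfile) -> pd.DataFrame:
    """The 20 conditions of one subject with geometry columns attached."""
    rows = []
    for i, cond in enumerate(conditions()):
        loc = condition_location(cond, profile)
        axis = group_axis_angle(cond.conflict_type, profile.group)
        rows.append(
            dict(
                cond_index=i,
                conflict_type=cond.conflict_type.name,
                congruency=cond.congruency,
                direction=cond.direction,
                polar_angle_deg=loc.polar_angle,
                axial_angle_deg=axis,
                rotated_axis_deg=rotated_axis_angle(axis),
                x=loc.x,
                y=loc.y,
                response=profile.response_for(cond.direction),
                group=profile.group,
                subject=profile.subject_id,
            )
        )
    return pd.DataFrame(rows)


def _component_features(
    meta: pd.DataFrame, orient_lut: dict, conflict_matrix: np.ndarray | None = None
) -> dict:
    """Per-condition latent features for every component (rows align meta)."""
    a_rot = np.radians(meta["rotated_axis_deg"].to_numpy())
    if conflict_matrix is None:
        cs = np.column_stack([np.cos(a_rot), np.sin(a_rot)])
    else:
        from .task_design import CONFLICT_TYPE_NAMES

        f = embed_model_geometry(
            np.asarray(conflict_matrix, float), diagonal_load="auto"
        )
        lut = dict(zip(CONFLICT_TYPE_NAMES, f))
        cs = np.vstack([lut[t] for t in meta["conflict_type"]])
    feats = {
        "conflict_space": cs,
        "orientation": np.vstack(
            [orient_lut[a % 180.0] for a in meta["axial_angle_deg"]]
        ),
        "target": np.where(meta["direction"] == "up", 1.0, -1.0)[:, None],
        "response": np.where(meta["response"] == "right", 1.0, -1.0)[:, None],
        "stroop_distractor": meta["y"].to_numpy()[:, None],
        "simon_distractor": meta["x"].to_numpy()[:, None],
        "group": np.where(meta["group"] == "TL-BR", 1.0, -1.0)[:, None],
    }
    inc = (meta["congruency"] == "I").to_numpy(float)[:, None]
    feats["congruency_interaction"] = feats["conflict_space"] * inc
    return feats


def _residual_cov(params: NeuralGenParams, rng) -> np.ndarray:
    v = params.n_voxels
    covs = np.empty((params.n_runs, v, v))
    for r in range(params.n_runs):
        if params.residual_cov_spec == "identity":
            covs[r] = np.eye(v)
        elif params.residual_cov_spec == "diagonal":
            covs[r] = np.diag(rng.uniform(0.5, 2.0, v))
        elif params.residual_cov_spec == "toeplitz":
            var = rng.uniform(0.5, 2.0, v)
            rho = 0.3 ** np.abs(np.subtract.outer(np.arange(v), np.arange(v)))
            covs[r] = np.sqrt(np.outer(var, var)) * rho
        else:
            raise ValueError(f"unknown residual_cov_spec {params.residual_cov_spec!r}")
    return covs


def simulate_patterns(
    params: NeuralGenParams,
    profiles: list[SubjectProfile] | None = None,
    region: str = "region",
) -> PatternSet:
    """Generate a complete PatternSet for one pseudo-region.

    beta(s, r, c) = sum_k w_k * f_k(c, s) @ P_k + offset(c) + noise, with
    the projections P_k drawn once per region and shared by all subjects so
    that cross-subject similarity carries the component structure.
    """
    if profiles is None:
        profiles = [
            SubjectProfile(i, "TL-BR" if i < params.group_split else "TR-BL")
            for i in range(params.n_subjects)
        ]
    rng = np.random.default_rng(params.seed)
    orient_lut = _orientation_features()
    v = params.n_voxels
    dims = {
        k: f.shape[1]
        for k, f in _component_features(
            condition_metadata(profiles[0]), orient_lut, params.conflict_space_matrix
        ).items()
    }
    # the congruency boost scales the conflict-space component, so it shares
    # that component's voxel directions
    own_basis = [k for k in COMPONENTS if k != "congruency_interaction"]
    total_latent = sum(dims[k] for k in own_basis)
    if total_latent > v:
        raise ValueError("n_voxels must be at least the number of latent dims")
    # one orthonormal voxel basis, sliced per component: cross-component
    # leakage is exactly zero and each component's signal Gram is exact
    basis, _ = np.linalg.qr(rng.standard_normal((v, total_latent)))
    proj = {}
    off = 0
    for k in own_basis:
        proj[k] = basis[:, off : off + dims[k]].T
        off += dims[k]
    proj["congruency_interaction"] = proj["conflict_space"]
    covs = _residual_cov(params, rng)
    chols = np.linalg.cholesky(covs) if params.noise_sd > 0 else None
    offsets = (
        np.zeros(20)
        if params.univariate_offsets is None
        else np.asarray(params.univariate_offsets, float)
    )
    betas = np.zeros((len(profiles), params.n_runs, 20, v))
    metas = []
    for si, profile in enumerate(profiles):
        meta = condition_metadata(profile)
        feats = _component_features(meta, orient_lut, params.conflict_space_matrix)
        scale_s = 1.0
        if params.subject_conflict_scale is not None:
            scale_s = float(params.subject_conflict_scale[si])
        signal = np.zeros((20, v))
        for k, w in params.weights.items():
            if w > 0:
                if k in ("conflict_space", "congruency_interaction"):
                    w = w * scale_s
                signal += w * (feats[k] @ proj[k])
        signal += offsets[:, None]
        for r in range(params.n_runs):
            noise = 0.0
            if chols is not None:
                noise = params.noise_sd * (
                    rng.standard_normal((20, v)) @ chols[r].T
                )
            betas[si, r] = signal + noise
            m = meta.copy()
            m["run"] = r
            metas.append(m)
    meta_all = pd.concat(metas, ignore_index=True)
    meta_all = meta_all.sort_values(["subject", "run", "cond_index"]).reset_index(
        drop=True
    )
    return PatternSet(region, betas, meta_all, covs)


def default_region_specs() -> dict:
    """A small cohort of pseudo-regions for pipeline demonstrations.

    One conflict-space region with a congruency boost (the dlPFC-like
    candidate), two orientation regions (visual-cortex-like), one
    orientation region without the boost, and null control regions.
    """
    return {
        "conflict_dlpfc": {
            "conflict_space": 2.0,
            "congruency_interaction": 1.0,
            "orientation": 2.0,
            "target": 1.0,
            "stroop_distractor": 0.8,
            "simon_distractor": 0.8,
        },
        "orient_v1": {
            "orientation": 3.0,
            "target": 1.2,
            "stroop_distractor": 1.2,
            "simon_distractor": 1.2,
        },
        "orient_v2": {
            "orientation": 2.5,
            "target": 1.0,
            "stroop_distractor": 1.0,
            "simon_distractor": 1.0,
        },
        "orient_no_boost": {"orientation": 2.0},
        "control_null_1": {},
        "control_null_2": {},
    }


def simulate_region_cohort(
    base: NeuralGenParams,
    profiles=None,
    region_specs: dict | None = None,
) -> dict:
    """Simulate several regions with distinct seeds and weight vectors."""
    specs = default_region_specs() if region_specs is None else region_specs
    out = {}
    for i, (name, weights) in enumerate(specs.items()):
        p = replace(base, weights=weights, seed=base.seed + 1000 * (i + 1))
        out[name] = simulate_patterns(p, profiles, region=name)
    return out
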