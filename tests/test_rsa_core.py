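import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from conflictspace import neural_sim as ns
from conflictspace import rsa_core as rc


def make_patterns(profiles, weights, seed, noise_sd=1.0, n_voxels=40,
                  scale=None):
    p = ns.NeuralGenParams(
        n_subjects=len(profiles), group_split=sum(
            1 for pr in profiles if pr.group == "TL-BR"
        ),
        n_voxels=n_voxels, weights=weights, noise_sd=noise_sd, seed=seed,
        subject_conflict_scale=scale,
    )
    return ns.simulate_patterns(p, profiles)


def chain(ps, **kw):
    return rc.build_rsa_design(
        rc.select_cross_subject_cells(rc.build_rsm(rc.normalize_patterns(ps)), **kw)
    )


class TestNoiseNormalize:
    def test_identity_covariance_is_noop(self):
        b = np.random.default_rng(0).standard_normal((5, 4))
        assert np.allclose(rc.noise_normalize(b, np.eye(4)), b)

    def test_scalar_diagonal_halves(self):
        b = np.random.default_rng(0).standard_normal((5, 4))
        assert np.allclose(rc.noise_normalize(b, 4.0 * np.eye(4)), b / 2.0)

    def test_general_covariance_matches_eigen_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((2, 2))
        cov = a @ a.T + 0.5 * np.eye(2)
        b = rng.standard_normal((6, 2))
        w, v = np.linalg.eigh(cov)
        oracle = b @ (v @ np.diag(w**-0.5) @ v.T)
        assert np.allclose(rc.noise_normalize(b, cov), oracle, atol=1e-10)

    def test_singular_covariance_forces_shrinkage(self):
        cov = np.array([[1.0, 1.0], [1.0, 1.0]])
        b = np.ones((3, 2))
        with pytest.warns(UserWarning, match="shrinkage"):
            out = rc.noise_normalize(b, cov)
        assert np.all(np.isfinite(out))


class TestBuildRSM:
    def test_brute_force_pearson_agreement(self, profiles8):
        ps = make_patterns(profiles8[:4], {"conflict_space": 1.0}, seed=2,
                           n_voxels=18)
        rsm = rc.build_rsm(ps)
        flat, _ = ps.flat()
        n = flat.shape[0]
        idx = np.random.default_rng(0).choice(n * n, size=200)
        for k in idx:
            i, j = divmod(int(k), n)
            expected = np.corrcoef(flat[i], flat[j])[0, 1]
            assert abs(rsm.matrix[i, j] - expected) < 1e-12

    def test_exp2_cohort_rsm_is_1400_square(self):
        profiles = [
            ns.SubjectProfile(i, "TL-BR" if i < 17 else "TR-BL") for i in range(35)
        ]
        ps = make_patterns(profiles, {}, seed=0, noise_sd=1.0, n_voxels=16)
        rsm = rc.build_rsm(ps)
        assert rsm.matrix.shape == (1400, 1400)

    def test_identical_and_orthogonal_patterns(self):
        meta = pd.DataFrame(
            {
                "subject": [0, 0], "group": ["TL-BR"] * 2, "run": [0, 0],
                "conflict_type": ["Stroop"] * 2, "congruency": ["C", "I"],
                "direction": ["up"] * 2, "rotated_axis_deg": [90.0] * 2,
                "axial_angle_deg": [90.0] * 2, "x": [0.0] * 2, "y": [1.0] * 2,
                "response": ["left"] * 2, "cond_index": [0, 1],
            }
        )
        betas = np.array([[[[1.0, 2, 3, 4], [1.0, 2, 3, 4]]]])
        ps = ns.PatternSet("toy", betas, meta, np.eye(4)[None])
        rsm = rc.build_rsm(ps)
        assert rsm.matrix[0, 1] == pytest.approx(1.0)
        betas2 = np.array([[[[1.0, -1, 1, -1], [1.0, 1, -1, -1]]]])
        ps2 = ns.PatternSet("toy", betas2, meta, np.eye(4)[None])
        assert rc.build_rsm(ps2).matrix[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestCellSelection:
    def test_cross_subject_cell_count(self, profiles8):
        ps = make_patterns(profiles8[:4], {}, seed=1, n_voxels=16)
        cells = rc.select_cross_subject_cells(rc.build_rsm(ps))
        assert len(cells) == 160**2 - 4 * 40**2  # 19200

    def test_within_subject_cells_absent(self, profiles8):
        ps = make_patterns(profiles8[:4], {}, seed=1, n_voxels=16)
        cells = rc.select_cross_subject_cells(rc.build_rsm(ps))
        assert (cells["row_subject"] != cells["col_subject"]).all()

    def test_fisher_and_standardization_toggles(self, profiles8):
        ps = make_patterns(profiles8[:4], {}, seed=1, n_voxels=16)
        rsm = rc.build_rsm(ps)
        raw = rc.select_cross_subject_cells(rsm, fisher=False, standardize=False)
        assert np.allclose(raw["z"], raw["r"])
        std = rc.select_cross_subject_cells(rsm)
        assert std["z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert std["z"].std(ddof=0) == pytest.approx(1.0, abs=1e-6)


class TestDesign:
    @pytest.fixture(scope="class")
    def design(self, profiles8):
        ps = make_patterns(profiles8, {}, seed=4, n_voxels=16)
        return chain(ps)

    def test_same_type_across_groups(self, design):
        m = design[
            (design["row_conflict_type"] == "StHSmL")
            & (design["col_conflict_type"] == "StHSmL")
            & (design["row_group"] != design["col_group"])
        ]
        assert np.allclose(m["conflict_similarity"], 1.0)
        assert np.allclose(m["orientation"], np.cos(np.radians(45.0)))

    def test_same_group_same_axis(self, design):
        m = design[
            (design["row_conflict_type"] == design["col_conflict_type"])
            & (design["row_group"] == design["col_group"])
        ]
        assert np.allclose(m["conflict_similarity"], 1.0)
        assert np.allclose(m["orientation"], 1.0)

    def test_stroop_vs_simon_zero(self, design):
        m = design[
            (design["row_conflict_type"] == "Stroop")
            & (design["col_conflict_type"] == "Simon")
            & (design["row_group"] != design["col_group"])
        ]
        assert np.allclose(m["conflict_similarity"], 0.0, atol=1e-12)

    def test_regressors_decorrelated_on_cross_group_cells(self, design):
        cross = design[design["same_group"] == 0.0]
        within = design[design["same_group"] == 1.0]
        r_cross = abs(np.corrcoef(cross["conflict_similarity"], cross["orientation"])[0, 1])
        r_within = abs(np.corrcoef(within["conflict_similarity"], within["orientation"])[0, 1])
        assert r_cross < 0.9
        assert r_within > 0.99  # fully confounded within a subject group


class TestFitRSA:
    def test_conflict_only_generator_specificity(self, profiles8):
        ps = make_patterns(profiles8, {"conflict_space": 1.0}, seed=1)
        fit = rc.fit_rsa(chain(ps))
        cs = fit.regressor("conflict_similarity")
        ori = fit.regressor("orientation")
        assert cs["beta"] > 0 and cs["p_one_tailed"] < 0.001
        assert abs(ori["beta"]) < 0.4 * cs["beta"]

    def test_orientation_only_generator_specificity(self, profiles8):
        ps = make_patterns(profiles8, {"orientation": 1.0}, seed=1)
        fit = rc.fit_rsa(chain(ps))
        cs = fit.regressor("conflict_similarity")
        ori = fit.regressor("orientation")
        assert ori["beta"] > 0 and ori["p_one_tailed"] < 0.001
        assert abs(cs["beta"]) < 0.4 * ori["beta"]

    def test_congruency_split_interaction(self, profiles8):
        ps = make_patterns(
            profiles8, {"conflict_space": 0.7, "congruency_interaction": 0.7},
            seed=2,
        )
        split = rc.congruency_split_rsa(chain(ps))
        assert split.interaction["beta"] > 0
        assert split.interaction["p_one_tailed"] < 0.05
        assert split.split_fits["I"].regressor("conflict_similarity")["beta"] > 0
        assert split.split_fits["C"].regressor("conflict_similarity")["beta"] > 0

    def test_congruency_split_null_interaction(self, profiles8):
        ps = make_patterns(profiles8, {"conflict_space": 0.7}, seed=3)
        split = rc.congruency_split_rsa(chain(ps))
        assert abs(split.interaction["t"]) < 3.0


class TestScreenRegions:
    @staticmethod
    def _cohort(profiles, seed=5):
        rng = np.random.default_rng(seed)
        behav = pd.Series(
            rng.normal(0.1, 0.05, len(profiles)),
            index=[p.subject_id for p in profiles],
        )
        z = (behav - behav.mean()) / behav.std()
        scale = np.clip(1.0 + 0.4 * z.to_numpy(), 0.1, None)
        results = {}
        specs = {
            "injected": (
                {"conflict_space": 2.5, "congruency_interaction": 1.7}, scale
            ),
            "effect_no_interaction": ({"conflict_space": 2.5}, None),
            "null_a": ({}, None),
            "null_b": ({}, None),
        }
        for i, (name, (w, sc)) in enumerate(specs.items()):
            ps = make_patterns(profiles, w, seed=seed + 10 * i, noise_sd=0.6,
                               scale=sc)
            design = chain(ps)
            fit = rc.fit_rsa(design)
            split = rc.congruency_split_rsa(design)
            results[name] = {
                "p1": fit.regressor("conflict_similarity")["p_one_tailed"],
                "p_interaction": split.interaction["p_one_tailed"],
                "per_subject_effect": fit.per_subject_effect,
            }
        return results, behav

    def test_injected_region_passes_all_criteria(self, profiles8):
        results, behav = self._cohort(profiles8)
        screen = rc.screen_regions(results, behav).set_index("region")
        assert screen.loc["injected", "pass_all"]
        assert not screen.loc["null_a", "criterion1"]
        assert not screen.loc["null_b", "criterion1"]

    def test_region_without_interaction_passes_criterion1_only(self, profiles8):
        results, behav = self._cohort(profiles8)
        screen = rc.screen_regions(results, behav).set_index("region")
        row = screen.loc["effect_no_interaction"]
        assert row["criterion1"]
        assert not row["pass_all"]


class TestUnivariateReport:
    def test_null_region_shows_no_congruency_effect(self, profiles8):
        ps = make_patterns(profiles8, {}, seed=9)
        rep = rc.univariate_congruency_report(ps)
        assert abs(rep["roi_mean_IC_t"]) < 3.5
        assert abs(rep["multivariate_congruency_contrast"]) < 0.05
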