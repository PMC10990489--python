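"""Dose-response scaling chain and rectangular-hyperbola fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lbkit import dose_response as dr
from lbkit import synthetic


def make_table(gels, response="R", ligand="L"):
    """gels: {gel_id: [(conc, intensity), ...]}"""
    rows = []
    for gel, points in gels.items():
        for conc, inten in points:
            rows.append(
                {
                    "response_name": response,
                    "ligand": ligand,
                    "gel_id": gel,
                    "concentration_M": conc,
                    "replicate": gel,
                    "intensity": inten,
                }
            )
    return pd.DataFrame(rows)


class TestScaleWithinGel:
    def test_basic_scaling(self):
        t = make_table({"g1": [(1e-9, 200), (1e-8, 500), (1e-7, 1000)]})
        out = dr.scale_within_gel(t)
        assert list(out["intensity"]) == [0.2, 0.5, 1.0]

    def test_idempotent(self):
        t = make_table({"g1": [(1e-9, 0.2), (1e-8, 1.0)]})
        once = dr.scale_within_gel(t)
        twice = dr.scale_within_gel(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_gels_scaled_independently(self):
        t = make_table({"g1": [(1e-9, 10), (1e-8, 20)], "g2": [(1e-9, 3), (1e-8, 6)]})
        out = dr.scale_within_gel(t)
        assert list(out["intensity"]) == [0.5, 1.0, 0.5, 1.0]

    def test_all_zero_gel_errors(self):
        t = make_table({"g1": [(1e-9, 0.0), (1e-8, 0.0)]})
        with pytest.raises(ValueError, match="no positive band"):
            dr.scale_within_gel(t)


class TestAverageReplicates:
    def test_mean_and_sem(self):
        t = make_table(
            {"g1": [(1e-9, 0.5), (1e-8, 1.0)], "g2": [(1e-9, 0.7), (1e-8, 1.0)]}
        )
        out = dr.average_replicates(t)
        assert list(out["mean"]) == [pytest.approx(0.6), pytest.approx(1.0)]
        assert out["sem"].iloc[0] == pytest.approx(0.1)
        assert out["sem"].iloc[1] == pytest.approx(0.0)

    def test_renormalizes_max_mean_to_one(self):
        t = make_table(
            {"g1": [(1e-9, 0.4), (1e-8, 0.8)], "g2": [(1e-9, 0.4), (1e-8, 0.8)]}
        )
        out = dr.average_replicates(t)
        assert list(out["mean"]) == [pytest.approx(0.5), pytest.approx(1.0)]

    def test_identical_gels_zero_sem(self):
        pts = [(1e-9, 0.3), (1e-8, 1.0)]
        t = make_table({g: pts for g in ("g1", "g2", "g3")})
        out = dr.average_replicates(t)
        assert (out["sem"] == 0).all()

    def test_single_gel_warns_nan_sem(self):
        t = make_table({"g1": [(1e-9, 0.5), (1e-8, 1.0)]})
        with pytest.warns(UserWarning, match="single gel"):
            out = dr.average_replicates(t)
        assert out["sem"].isna().all()

    def test_concentration_alignment(self):
        t = make_table(
            {"g1": [(1.000e-9, 0.5), (1e-8, 1.0)], "g2": [(1.005e-9, 0.7), (1e-8, 1.0)]}
        )
        out = dr.average_replicates(t, align_tol=0.01)
        assert len(out) == 2  # 1.000e-9 and 1.005e-9 merged


class TestGlue:
    def test_coefficients_rule(self):
        glue = pd.DataFrame(
            {
                "ligand": ["FGF4"] * 3 + ["FGF8"] * 3 + ["FGF9"] * 3,
                "replicate": list(range(3)) * 3,
                "intensity": [0.8] * 3 + [1.0] * 3 + [0.5] * 3,
            }
        )
        c = dr.glue_coefficients(glue)
        assert c["FGF4"] == pytest.approx(0.8)
        assert c["FGF8"] == pytest.approx(1.0)
        assert c["FGF9"] == pytest.approx(0.5)

    def test_equal_glue_means_leave_curves_unchanged(self):
        avg = pd.DataFrame(
            {
                "response_name": "R",
                "ligand": ["A", "A", "B", "B"],
                "concentration_M": [1e-9, 1e-8] * 2,
                "mean": [0.5, 1.0, 0.4, 1.0],
                "sem": [0.05] * 4,
                "n": 3,
            }
        )
        glue = pd.DataFrame(
            {"ligand": ["A", "B"], "replicate": [0, 0], "intensity": [2.0, 2.0]}
        )
        out = dr.glue_scale(avg, glue)
        assert list(out["mean"]) == list(avg["mean"])

    def test_missing_ligand_errors(self):
        avg = pd.DataFrame(
            {
                "response_name": "R",
                "ligand": ["A"],
                "concentration_M": [1e-9],
                "mean": [1.0],
                "sem": [0.1],
                "n": 3,
            }
        )
        glue = pd.DataFrame({"ligand": ["B"], "replicate": [0], "intensity": [1.0]})
        with pytest.raises(ValueError, match="missing from glue"):
            dr.glue_scale(avg, glue)

    def test_recovers_true_efficacy_ratio(self):
        # hidden gel scales + glue step recover relative efficacies 0.70/1.11
        truths = {("R", "strong"): (1.11, 2e-9), ("R", "weak"): (0.70, 2e-9)}
        bands, glue = synthetic.simulate_study(truths, seed=42, n_gels=4)
        avg = dr.average_replicates(dr.scale_within_gel(bands))
        scaled = dr.glue_scale(avg, glue["R"])
        fits = dr.fit_response_table(scaled).set_index("ligand")
        ratio = fits.loc["weak", "etop"] / fits.loc["strong", "etop"]
        assert ratio == pytest.approx(0.70 / 1.11, rel=0.10)


class TestLossTransform:
    def test_worked_example(self):
        t = make_table({"g1": [(0.0, 1.0), (1e-9, 0.8), (1e-8, 0.6)]})
        out = dr.loss_transform(t)
        assert list(out["intensity"]) == [
            pytest.approx(0.0),
            pytest.approx(0.2),
            pytest.approx(0.4),
        ]

    def test_flat_curve_gives_zero_loss(self):
        t = make_table({"g1": [(0.0, 5.0), (1e-9, 5.0), (1e-8, 5.0)]})
        assert (dr.loss_transform(t)["intensity"] == 0).all()

    def test_random_vector_oracle(self, rng):
        conc = np.concatenate([[0.0], np.logspace(-10, -7, 5)])
        v = rng.uniform(0.1, 2.0, size=6)
        t = make_table({"g1": list(zip(conc, v))})
        out = dr.loss_transform(t)
        np.testing.assert_allclose(out["intensity"], 1.0 - v / v[0])

    def test_missing_baseline_errors(self):
        t = make_table({"g1": [(1e-9, 0.8), (1e-8, 0.6)]})
        with pytest.raises(ValueError, match="zero-ligand baseline"):
            dr.loss_transform(t)


class TestTruncateForFit:
    @pytest.mark.parametrize(
        "y,expected_kept",
        [
            ([0.2, 0.6, 1.0, 0.95, 0.7], 4),  # 0.95 >= 0.9*max
            ([0.2, 1.0, 0.5], 2),
            ([0.1, 0.3, 0.6, 0.9, 1.0], 5),  # monotone: keep all
        ],
    )
    def test_worked_prefixes(self, y, expected_kept):
        conc = np.logspace(-10, -6, len(y))
        keep, trunc = dr.truncate_for_fit(conc, np.array(y))
        assert keep.sum() == expected_kept
        assert trunc == conc[expected_kept - 1]

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            dr.truncate_for_fit(np.array([]), np.array([]))

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=12).map(np.array)
    )
    def test_prefix_contains_argmax(self, y):
        conc = np.logspace(-11, -6, y.size)
        keep, _ = dr.truncate_for_fit(conc, y)
        assert keep.any()
        assert keep[np.argmax(y)]
        # everything kept is a prefix
        assert not np.any(np.diff(keep.astype(int)) > 0)


class TestFitHill:
    def test_noise_free_exact_recovery(self):
        conc = np.logspace(-11, -7, 7)
        y = dr.hill(conc, 1.0, 1e-9)
        fit = dr.fit_hill(conc, y)
        assert fit.etop == pytest.approx(1.0, rel=1e-8)
        assert fit.ec50 == pytest.approx(1e-9, rel=1e-8)
        assert fit.valid

    def test_half_maximum_at_ec50(self):
        conc = np.logspace(-11, -7, 7)
        fit = dr.fit_hill(conc, dr.hill(conc, 0.8, 2e-9))
        assert dr.hill(fit.ec50, fit.etop, fit.ec50) == pytest.approx(fit.etop / 2)

    def test_equal_sems_match_unweighted_per_point(self, rng):
        conc = np.logspace(-11, -7, 7)
        y = dr.hill(conc, 1.0, 1e-9) * (1 + rng.normal(0, 0.05, 7))
        sem = np.full(7, 0.04)
        f_w = dr.fit_hill(conc, y, sem, error_model="per_point")
        f_u = dr.fit_hill(conc, y)
        assert f_w.etop == pytest.approx(f_u.etop, rel=1e-7)
        assert f_w.ec50 == pytest.approx(f_u.ec50, rel=1e-7)

    def test_solution_is_stationary(self, rng):
        conc = np.logspace(-11, -7, 7)
        y = dr.hill(conc, 1.0, 1e-9) * (1 + rng.normal(0, 0.05, 7))
        fit = dr.fit_hill(conc, y)

        def sse(etop, ec50):
            return np.sum((y - dr.hill(conc, etop, ec50)) ** 2)

        s0 = sse(fit.etop, fit.ec50)
        g_e = (sse(fit.etop * (1 + 1e-7), fit.ec50) - s0) / (fit.etop * 1e-7)
        g_c = (sse(fit.etop, fit.ec50 * (1 + 1e-7)) - s0) / (fit.ec50 * 1e-7)
        assert abs(g_e) < 1e-6
        assert abs(g_c) * fit.ec50 < 1e-6  # scale-adjusted

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError, match=">= 3 distinct"):
            dr.fit_hill(np.array([0.0, 1e-9, 1e-8]), np.array([0, 0.5, 1.0]))


class TestPipelineInvariants:
    def test_scaling_preserves_within_gel_ratios(self):
        t = make_table(
            {
                "g1": [(1e-10, 120), (1e-9, 300), (1e-8, 600)],
                "g2": [(1e-10, 40), (1e-9, 110), (1e-8, 190)],
            }
        )
        scaled = dr.scale_within_gel(t)
        for gel in ("g1", "g2"):
            raw = t[t.gel_id == gel]["intensity"].to_numpy()
            sc = scaled[scaled.gel_id == gel]["intensity"].to_numpy()
            np.testing.assert_allclose(raw / raw[-1], sc / sc[-1])

    def test_full_agonist_unique_max_after_glue(self):
        truths = {("R", "full"): (1.0, 2e-9), ("R", "partial"): (0.6, 2e-9)}
        bands, glue = synthetic.simulate_study(truths, seed=7)
        scaled = dr.glue_scale(
            dr.average_replicates(dr.scale_within_gel(bands)), glue["R"]
        )
        peak = scaled.groupby("ligand")["mean"].max()
        assert peak.idxmax() == "full"
        assert peak["full"] == pytest.approx(1.0)
        assert peak["partial"] < 1.0
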