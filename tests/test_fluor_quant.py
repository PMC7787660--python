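"""Mode thresholding, soma-excluded measurement, normalization, decision tree."""

import numpy as np
import pandas as pd
import pytest

from metalloscope import fluor_quant as fq
from metalloscope import synthetic_scene as ss


class TestModeThreshold:
    def test_threshold_is_next_bin_above_mode(self):
        # integer-valued image spanning [0, 256) with unit-width bins:
        # value 5 dominates, so the threshold is the next bin edge, 6
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=4000).astype(float)
        img[:2000] = 5.0
        img = np.concatenate([img, [0.0, 256.0]])  # pin the range
        thr = fq.mode_threshold(img, n_bins=256)
        assert thr == pytest.approx(6.0, abs=1e-9)

    def test_constant_image_warns_and_returns_constant(self):
        with pytest.warns(UserWarning, match="constant"):
            thr = fq.mode_threshold(np.full((8, 8), 9.0))
        assert thr == 9.0

    def test_bimodal_foreground_fraction_close_to_truth(self):
        # background must be narrow relative to the bin width for the mode
        # threshold to separate it cleanly (the 8-bit acquisition regime)
        rng = np.random.default_rng(1)
        n = 40000
        truth_frac = 0.2
        bg = rng.normal(20.0, 0.01, size=int(n * (1 - truth_frac)))
        fg = rng.normal(120.0, 10.0, size=int(n * truth_frac))
        img = np.concatenate([bg, fg])
        thr = fq.mode_threshold(img)
        measured_frac = (img > thr).mean()
        assert abs(measured_frac - truth_frac) < 0.02


class TestMeasureImage:
    def test_uniform_foreground(self):
        img = np.full((10, 10), 50.0)
        img[0, :] = 1.0
        res = fq.measure_image(img, threshold=10.0)
        assert res.mean_intensity == 50.0
        assert res.n_pixels == 90

    def test_soma_covering_everything_excludes_image(self):
        img = np.full((6, 6), 50.0)
        res = fq.measure_image(img, threshold=10.0, soma_mask=np.ones((6, 6), dtype=bool))
        assert res.excluded
        assert np.isnan(res.mean_intensity)

    def test_noisy_estimate_within_three_standard_errors(self):
        rng = np.random.default_rng(2)
        mu, sd, n = 80.0, 5.0, 2500
        img = rng.normal(mu, sd, size=n)
        res = fq.measure_image(img, threshold=0.0)
        assert abs(res.mean_intensity - mu) < 3 * sd / np.sqrt(n)


class TestNormalization:
    def test_control_median_maps_to_one(self):
        df = pd.DataFrame(
            {"value": [80.0, 100.0, 120.0, 70.0], "group": ["control"] * 3 + ["treated"]}
        )
        norm = fq.normalize_to_control(df)
        assert sorted(norm[:3]) == pytest.approx([0.8, 1.0, 1.2])
        assert norm.iloc[3] == pytest.approx(0.7)

    def test_per_replicate_uses_own_control_median(self):
        df = pd.DataFrame(
            {
                "value": [100.0, 100.0, 50.0, 200.0, 200.0, 100.0],
                "group": ["control", "control", "treated"] * 2,
                "replicate": [1, 1, 1, 2, 2, 2],
            }
        )
        norm = fq.normalize_to_control(df, replicate_col="replicate")
        assert norm.tolist() == pytest.approx([1.0, 1.0, 0.5, 1.0, 1.0, 0.5])

    def test_scaling_invariance_within_replicate(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(50, 150, size=12)
        df = pd.DataFrame({"value": vals, "group": ["control", "treated"] * 6})
        n1 = fq.normalize_to_control(df)
        df2 = df.assign(value=vals * 7.3)
        n2 = fq.normalize_to_control(df2)
        assert np.allclose(n1, n2)

    def test_zero_or_missing_control_rejected(self):
        df = pd.DataFrame({"value": [0.0, 1.0], "group": ["control", "treated"]})
        with pytest.raises(ValueError):
            fq.normalize_to_control(df)
        df = pd.DataFrame({"value": [1.0], "group": ["treated"]})
        with pytest.raises(ValueError):
            fq.normalize_to_control(df)


class TestDunn:
    def test_hand_computed_no_tie_example(self):
        # ranks are 1..9 by construction: mean ranks 2, 5, 8; var term 7.5
        groups = {"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6]),
                  "c": np.array([7.0, 8, 9])}
        out = fq.dunn_test(groups)
        z = dict(zip(zip(out.group_a, out.group_b), out.z))
        assert z[("a", "b")] == pytest.approx(-3 / np.sqrt(5.0), abs=1e-12)
        assert z[("a", "c")] == pytest.approx(-6 / np.sqrt(5.0), abs=1e-12)
        from scipy import stats

        p = dict(zip(zip(out.group_a, out.group_b), out.p_raw))
        expected_p = 2 * stats.norm.sf(6 / np.sqrt(5.0))
        assert p[("a", "c")] == pytest.approx(expected_p, abs=1e-12)
        padj = dict(zip(zip(out.group_a, out.group_b), out.p_adjusted))
        assert padj[("a", "c")] == pytest.approx(3 * expected_p, rel=1e-9)

    def test_holm_adjustment_never_below_raw(self):
        rng = np.random.default_rng(4)
        groups = {g: rng.normal(i * 0.3, 1.0, 15) for i, g in enumerate("abc")}
        out = fq.dunn_test(groups)
        assert (out.p_adjusted >= out.p_raw - 1e-15).all()


class TestCompareGroups:
    def test_identical_groups_yield_null_omnibus_no_pairwise(self):
        base = np.array([0.9, 1.0, 1.1, 1.0, 0.95, 1.05] * 3)
        rep = fq.compare_groups({"control": base, "treated": base, "rescued": base})
        assert rep.omnibus_p > 0.9
        assert rep.pairwise is None or rep.omnibus_test == "anova"
        if rep.omnibus_test == "kruskal-wallis":
            assert rep.pairwise is None

    def test_normal_homoscedastic_data_takes_anova_tukey_path(self):
        rng = np.random.default_rng(5)
        groups = {g: rng.normal(1.0, 0.1, 30) for g in ("control", "treated", "rescued")}
        rep = fq.compare_groups(groups)
        assert rep.assumptions_met
        assert rep.omnibus_test == "anova"
        assert rep.pairwise is not None and (rep.pairwise.adjustment == "tukey").all()

    def test_skewed_data_takes_kruskal_dunn_path(self):
        rng = np.random.default_rng(6)
        groups = {
            "control": np.exp(rng.normal(0.0, 0.5, 60)),
            "treated": np.exp(rng.normal(np.log(0.6), 0.5, 60)),
            "rescued": np.exp(rng.normal(0.0, 0.5, 60)),
        }
        rep = fq.compare_groups(groups)
        assert rep.omnibus_test == "kruskal-wallis"
        assert rep.omnibus_p < 0.01
        assert rep.pairwise is not None and (rep.pairwise.adjustment == "holm").all()
        assert any("Dunn" in step for step in rep.decision_path)

    def test_two_group_paths(self):
        rng = np.random.default_rng(7)
        normal = {"control": rng.normal(1, 0.1, 25), "treated": rng.normal(0.8, 0.1, 25)}
        rep = fq.compare_groups(normal)
        assert rep.omnibus_test in ("t-test", "mann-whitney")
        if rep.assumptions_met:
            assert rep.omnibus_test == "t-test"
        skewed = {
            "control": np.exp(rng.normal(0, 0.8, 40)),
            "treated": np.exp(rng.normal(-0.5, 0.8, 40)),
        }
        rep2 = fq.compare_groups(skewed)
        if not rep2.assumptions_met:
            assert rep2.omnibus_test == "mann-whitney"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            fq.compare_groups({"control": np.ones(3), "treated": np.ones(2)})

    def test_type_one_error_controlled_under_null(self):
        # three exchangeable groups: omnibus p < 0.05 in about 5% of replicates
        rejections = 0
        n_rep = 200
        for rep_i in range(n_rep):
            g = ss.generate_group_intensities(
                30, {"control": 1.0, "treated": 1.0, "rescued": 1.0}, seed=31000 + rep_i
            )
            med = np.median(g["control"])
            report = fq.compare_groups({k: v / med for k, v in g.items()})
            if report.omnibus_p < 0.05:
                rejections += 1
        assert 0.005 <= rejections / n_rep <= 0.10
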