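"""Quantification arithmetic: Ct calling, efficiency, RE, normalization."""

import logging

import numpy as np
import pandas as pd
import pytest

from hervh_crc import qpcr_quant as qq
from hervh_crc.synthetic_cohort import generate_amplification_curve

from conftest import small_annotations


def dense_sdm(midpoint, slope, lo=1.0, hi=45.0):
    """Brute-force SDM of a noiseless logistic on a dense cycle grid."""
    c = np.linspace(lo, hi, 200_001)
    f = 1.0 / (1.0 + np.exp(-(c - midpoint) / slope))
    d2 = np.gradient(np.gradient(f, c), c)
    return c[np.argmax(d2)]


class TestSdmCt:
    def test_matches_closed_form_for_known_logistic(self):
        # midpoint 25, slope 1/ln2 -> SDM at 25 - ln(2+sqrt(3))/ln(2)
        s = 1.0 / np.log(2.0)
        c = np.arange(1, 46, dtype=float)
        f = 0.1 + 1.0 / (1.0 + np.exp(-(c - 25.0) / s))
        expected = 25.0 - s * np.log(2.0 + np.sqrt(3.0))
        assert expected == pytest.approx(23.100, abs=5e-4)
        assert qq.sdm_ct(f) == pytest.approx(expected, abs=1e-6)
        assert dense_sdm(25.0, s) == pytest.approx(expected, abs=1e-3)

    def test_constant_fluorescence_is_censored(self):
        assert np.isnan(qq.sdm_ct(np.full(45, 0.3)))

    def test_translation_equivariance_against_grid_oracle(self):
        s = 1.0 / np.log(1.8)
        c = np.arange(1, 46, dtype=float)
        for m in (20.0, 23.0):
            f = 1.0 / (1.0 + np.exp(-(c - m) / s))
            assert qq.sdm_ct(f) == pytest.approx(dense_sdm(m, s), abs=1e-3)
        f20 = 1.0 / (1.0 + np.exp(-(c - 20.0) / s))
        f23 = 1.0 / (1.0 + np.exp(-(c - 23.0) / s))
        assert qq.sdm_ct(f23) - qq.sdm_ct(f20) == pytest.approx(3.0, abs=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="short"):
            qq.sdm_ct(np.ones(5))
        with pytest.raises(ValueError, match="finite"):
            qq.sdm_ct(np.r_[np.ones(44), np.nan])


class TestEstimateEfficiency:
    @pytest.mark.parametrize("eff", [1.7, 2.0])
    def test_recovers_generator_efficiency(self, eff):
        curve = generate_amplification_curve("s", "x", 26.0, efficiency=eff)
        assert qq.estimate_efficiency(curve) == pytest.approx(eff, abs=0.1)

    def test_flat_curve_falls_back_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="hervh_crc.qpcr_quant"):
            eff = qq.estimate_efficiency(np.full(45, 0.2))
        assert eff == 2.0
        assert "fallback" in caplog.text

    def test_system_efficiencies_median_over_reactions(self):
        curves = [generate_amplification_curve("sysA", f"s{i}", ct,
                                               efficiency=1.9)
                  for i, ct in enumerate([20.0, 24.0, 28.0])]
        eff = qq.system_efficiencies(curves)
        assert eff["sysA"] == pytest.approx(1.9, abs=0.1)


class TestCtCeiling:
    def ann(self):
        return small_annotations(["a", "b", "c"],
                                 ["tumor", "tumor", "normal"],
                                 cohort="rostock")

    def test_above_ceiling_clamped_and_censored(self):
        ct = pd.DataFrame({"sys": [34.2, 31.9, 33.0]},
                          index=["a", "b", "c"])
        clamped, censored = qq.apply_ct_ceiling(ct, self.ann(),
                                                {"rostock": 33.0})
        assert clamped["sys"].tolist() == [33.0, 31.9, 33.0]
        # strictly-greater rule: exactly-at-ceiling values are not censored
        assert censored["sys"].tolist() == [True, False, False]

    def test_idempotent(self):
        ct = pd.DataFrame({"sys": [35.0, 20.0, 33.0]},
                          index=["a", "b", "c"])
        once, _ = qq.apply_ct_ceiling(ct, self.ann(), {"rostock": 33.0})
        twice, cens2 = qq.apply_ct_ceiling(once, self.ann(),
                                           {"rostock": 33.0})
        pd.testing.assert_frame_equal(once, twice)
        assert not cens2.any().any()

    def test_unknown_cohort_rejected(self):
        ct = pd.DataFrame({"sys": [20.0, 21.0, 22.0]},
                          index=["a", "b", "c"])
        with pytest.raises(KeyError, match="rostock"):
            qq.apply_ct_ceiling(ct, self.ann(), {"reims": 32.0})


class TestRelativeExpression:
    def test_minimum_ct_sample_gets_unit_re(self):
        ct = pd.DataFrame({"sys": [18.0, 21.0]}, index=["a", "b"])
        re = qq.relative_expression(ct, 2.0)
        assert re["sys"].tolist() == pytest.approx([1.0, 0.125])
        assert re.attrs["series_min_ct"]["sys"] == 18.0

    def test_five_cycles_at_eff_1_8(self):
        ct = pd.DataFrame({"sys": [20.0, 25.0]}, index=["a", "b"])
        re = qq.relative_expression(ct, 1.8)
        assert re.loc["b", "sys"] == pytest.approx(1.8 ** -5)
        assert re.loc["b", "sys"] == pytest.approx(0.0529, abs=2e-4)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            qq.relative_expression(pd.DataFrame(), 2.0)


class TestNormalizeAndScale:
    def test_geometric_mean_normalization(self):
        re = pd.DataFrame({"t": [4.0], "G6PD": [2.0], "GAPDH": [4.0],
                           "HPRT": [8.0]}, index=["a"])
        norm = qq.normalize_housekeeping(re, ["G6PD", "GAPDH", "HPRT"])
        assert norm.loc["a", "t"] == pytest.approx(1.0)

    def test_unit_housekeeping_is_identity(self):
        re = pd.DataFrame({"t": [2.5], "G6PD": [1.0], "GAPDH": [1.0],
                           "HPRT": [1.0]}, index=["a"])
        norm = qq.normalize_housekeeping(re, ["G6PD", "GAPDH", "HPRT"])
        assert norm.loc["a", "t"] == pytest.approx(2.5)

    def test_cube_root_geomean(self):
        re = pd.DataFrame({"t": [2.0], "h1": [1.0], "h2": [1.0],
                           "h3": [8.0]}, index=["a"])
        norm = qq.normalize_housekeeping(re, ["h1", "h2", "h3"])
        assert norm.loc["a", "t"] == pytest.approx(1.0)

    def test_censored_housekeeping_excludes_sample(self, caplog):
        re = pd.DataFrame({"t": [1.0, 2.0], "h1": [1.0, 1.0]},
                          index=["a", "b"])
        censored = pd.DataFrame({"t": [False, False], "h1": [False, True]},
                                index=["a", "b"])
        with caplog.at_level(logging.WARNING):
            norm = qq.normalize_housekeeping(re, ["h1"], censored=censored)
        assert list(norm.index) == ["a"]
        assert norm.attrs["excluded_samples"] == ["b"]

    def test_scale_to_min_examples(self):
        df = pd.DataFrame({"s": [0.5, 2.0, 13.0]})
        scaled = qq.scale_to_min(df)
        assert scaled["s"].tolist() == [1.0, 4.0, 26.0]
        assert qq.scale_to_min(pd.DataFrame({"s": [7.0]}))["s"].iloc[0] == 1.0
        pd.testing.assert_frame_equal(qq.scale_to_min(scaled), scaled)

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            qq.scale_to_min(pd.DataFrame({"s": [0.0, 0.0]}))


class TestPipeline:
    def test_matches_direct_evaluation_oracle(self):
        """Full pipeline equals one-shot formula evaluation to 1e-9."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            samples = [f"s{i}" for i in range(n)]
            ann = small_annotations(samples, ["tumor", "normal"] * (n // 2)
                                    + ["tumor"] * (n % 2))
            systems = ["t1", "t2", "h1", "h2", "h3"]
            ct = pd.DataFrame(rng.uniform(18, 34, (n, 5)), index=samples,
                              columns=systems)
            ct.iloc[0, 2:] = rng.uniform(18, 30, 3)  # one always-valid sample
            eff = pd.Series(rng.uniform(1.6, 2.0, 5), index=systems)
            expr = qq.quantify(ct, ann, {"reims": 32.0}, ["h1", "h2", "h3"],
                               efficiencies=eff)
            # independent direct evaluation (censored-housekeeping samples
            # are excluded before normalization, as in the pipeline)
            clipped = ct.clip(upper=32.0)
            re = eff.to_numpy() ** (clipped.min(axis=0) - clipped)
            kept = ~(ct[["h1", "h2", "h3"]] > 32.0).any(axis=1)
            gm = np.exp(np.log(re.loc[kept, ["h1", "h2", "h3"]]).mean(axis=1))
            direct = re.loc[kept, ["t1", "t2"]].div(gm, axis=0)
            direct /= direct.to_numpy().min()
            err = (expr.scaled_re - direct).abs() / direct
            assert err.to_numpy().max() < 1e-9

    def test_lower_ct_means_higher_scaled_expression(self, expression,
                                                     cohort):
        ct, _, _ = cohort
        for system in ["X00041_h_gag", "2000045_h"]:
            sub = pd.DataFrame({
                "ct": ct.loc[expression.scaled_re.index, system],
                "re": expression.re[system]}).sort_values("ct")
            assert (sub["re"].diff().dropna() <= 0).all()

    def test_scaled_minimum_is_exactly_one(self, expression):
        assert expression.scaled_re.to_numpy().min() == 1.0
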