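import math

import numpy as np
import pytest

from hccmeta.effect_extraction import (
    effect_from_source,
    load_km_curves,
    loghr_from_ci,
    loghr_from_km,
    logor_from_table,
    select_effect,
)
from hccmeta.errors import DomainError, EffectLookupError, ValidationError
from hccmeta.records import (
    Adjustment,
    ContingencyTable,
    EffectOrigin,
    EffectSource,
    KMCurve,
    Outcome,
    Z95,
)


def exp_curve(rate, label="arm", n=200, t_max=60):
    """Analytic exponential survival sampled monthly (noise-free digitization)."""
    t = np.arange(0.0, t_max + 1.0)
    return KMCurve(label, tuple(zip(t, np.exp(-rate * t))), n)


class TestLogHrFromCi:
    def test_hand_computed_example(self):
        e = loghr_from_ci(2.0, 1.0, 4.0)
        assert e.log_effect == pytest.approx(math.log(2), abs=1e-12)
        assert e.se == pytest.approx((math.log(4) - math.log(1)) / (2 * Z95), abs=1e-12)
        assert e.se == pytest.approx(0.3537, abs=2e-4)

    def test_headline_estimate_roundtrips_to_display_precision(self):
        # pooling a single reported HR must re-print the publication's numbers
        e = loghr_from_ci(1.82, 1.49, 2.22)
        lo, hi = e.ci()
        assert f"{e.ratio:.3g} ({lo:.3g}-{hi:.3g})" == "1.82 (1.49-2.22)"

    @pytest.mark.parametrize("triple", [(1.0, 1.0, 1.0), (2.0, 2.0, 2.0)])
    def test_degenerate_ci_rejected(self, triple):
        with pytest.raises(DomainError):
            loghr_from_ci(*triple)

    @pytest.mark.parametrize("triple", [(0.5, 1.0, 2.0), (2.0, 1.0, 1.5), (-1.0, 0.5, 2.0)])
    def test_disordered_or_nonpositive_rejected(self, triple):
        with pytest.raises(DomainError):
            loghr_from_ci(*triple)

    @pytest.mark.parametrize("hr, half_width", [(1.82, 0.2), (0.47, 0.38), (2.71, 0.67), (1.7, 0.003)])
    def test_ci_roundtrip_to_three_sig_digits(self, hr, half_width):
        # log-symmetric CI (the only kind the normal model can produce)
        lo, hi = hr * math.exp(-half_width), hr * math.exp(half_width)
        e = loghr_from_ci(hr, lo, hi)
        back_lo, back_hi = e.ci()
        assert float(f"{e.ratio:.3g}") == float(f"{hr:.3g}")
        assert float(f"{back_lo:.3g}") == float(f"{lo:.3g}")
        assert float(f"{back_hi:.3g}") == float(f"{hi:.3g}")


class TestLogOrFromTable:
    def test_symmetric_table(self):
        e = logor_from_table(ContingencyTable("s", "f", 10, 10, 10, 10))
        assert e.log_effect == 0.0
        assert e.se == pytest.approx(math.sqrt(0.4), abs=1e-12)

    def test_forced_arithmetic(self):
        e = logor_from_table(ContingencyTable("s", "f", 20, 10, 5, 15))
        assert e.log_effect == pytest.approx(math.log(6.0), abs=1e-12)

    def test_zero_cell_continuity_correction(self):
        e = logor_from_table(ContingencyTable("s", "f", 5, 0, 3, 7), correction=0.5)
        assert e.ratio == pytest.approx((5.5 * 7.5) / (0.5 * 3.5), rel=1e-12)
        assert e.ratio == pytest.approx(23.571, abs=1e-3)

    def test_correction_only_applied_when_needed(self):
        # no zero cell: cells used as-is
        e = logor_from_table(ContingencyTable("s", "f", 20, 10, 5, 15), correction=0.5)
        assert e.ratio == pytest.approx(6.0, rel=1e-12)

    def test_all_zero_table_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            ContingencyTable("s", "f", 0, 0, 0, 0)

    def test_empty_margin_rejected(self):
        with pytest.raises(DomainError):
            logor_from_table(ContingencyTable("s", "f", 0, 0, 3, 7))


class TestLogHrFromKm:
    def test_identical_curves_give_zero(self):
        e = loghr_from_km(exp_curve(0.1, "high"), exp_curve(0.1, "low"))
        assert e.log_effect == pytest.approx(0.0, abs=1e-12)
        assert e.source is EffectOrigin.KM_CURVE

    @pytest.mark.parametrize("true_hr", [0.5, 2.0, 3.0])
    def test_recovers_exponential_truth_within_5pct(self, true_hr):
        e = loghr_from_km(exp_curve(0.1 * true_hr, "high"), exp_curve(0.1, "low"))
        assert e.ratio == pytest.approx(true_hr, rel=0.05)

    @pytest.mark.parametrize("true_hr", [0.5, 2.0, 3.0])
    def test_matches_bruteforce_exponential_ml_fit(self, true_hr):
        # independent oracle: per-arm exponential rate ML-fitted to the same
        # sampled points (regression of -ln S on t through the origin)
        t = np.arange(0.0, 61.0)
        rate_high = np.sum(-np.log(np.exp(-0.1 * true_hr * t[1:])) * t[1:]) / np.sum(t[1:] ** 2)
        rate_low = np.sum(-np.log(np.exp(-0.1 * t[1:])) * t[1:]) / np.sum(t[1:] ** 2)
        oracle = math.log(rate_high / rate_low)
        e = loghr_from_km(exp_curve(0.1 * true_hr, "high"), exp_curve(0.1, "low"))
        assert e.log_effect == pytest.approx(oracle, rel=0.05, abs=1e-9)

    def test_antisymmetric_under_arm_swap(self, rng):
        # irregular, noisy-looking step curves
        for _ in range(10):
            t = np.arange(0.0, 61.0)
            s1 = np.concatenate([[1.0], np.cumprod(1 - rng.uniform(0, 0.05, 60))])
            s2 = np.concatenate([[1.0], np.cumprod(1 - rng.uniform(0, 0.08, 60))])
            c1 = KMCurve("a", tuple(zip(t, s1)), 150)
            c2 = KMCurve("b", tuple(zip(t, s2)), 120)
            fwd = loghr_from_km(c1, c2)
            rev = loghr_from_km(c2, c1)
            assert fwd.log_effect == pytest.approx(-rev.log_effect, abs=1e-9)
            assert fwd.se == pytest.approx(rev.se, abs=1e-9)

    def test_flat_curves_rejected(self):
        t = np.arange(0.0, 61.0)
        flat = KMCurve("f", tuple(zip(t, np.ones_like(t))), 100)
        with pytest.raises(DomainError, match="degenerate"):
            loghr_from_km(flat, flat)

    def test_nonoverlapping_spans_rejected(self):
        c1 = KMCurve("a", ((0.0, 1.0),), 100)
        c2 = exp_curve(0.1)
        with pytest.raises(DomainError):
            loghr_from_km(c1, c2)

    def test_uses_at_risk_numbers_when_given(self):
        base = exp_curve(0.2, "high")
        with_risk = KMCurve(
            "high", base.points, 200,
            at_risk_times=tuple((t, 200 * math.exp(-0.25 * t)) for t in range(0, 61, 12)),
        )
        e_plain = loghr_from_km(base, exp_curve(0.1, "low"))
        e_risk = loghr_from_km(with_risk, exp_curve(0.1, "low"))
        # point estimate unchanged (same drops), variance differs (fewer at risk)
        assert e_risk.log_effect == pytest.approx(e_plain.log_effect, abs=1e-9)
        assert e_risk.se > e_plain.se


class TestSelectEffect:
    def test_multivariate_beats_univariate(self):
        uni = EffectSource(Outcome.OS, Adjustment.UNIVARIATE, hr=2.0, ci_low=1.0, ci_high=4.0)
        multi = EffectSource(Outcome.OS, Adjustment.MULTIVARIATE, hr=1.5, ci_low=1.0, ci_high=2.2)
        assert select_effect([uni, multi], Outcome.OS) is multi

    def test_single_curve_source_selected(self):
        src = EffectSource(
            Outcome.OS, Adjustment.CURVE_DERIVED,
            km_curves=(exp_curve(0.2, "high"), exp_curve(0.1, "low")),
        )
        assert select_effect([src], Outcome.OS) is src
        e = effect_from_source(src, study_id="k1")
        assert e.ratio == pytest.approx(2.0, rel=0.05)

    def test_no_matching_source_raises(self):
        uni = EffectSource(Outcome.OS, Adjustment.UNIVARIATE, hr=2.0, ci_low=1.0, ci_high=4.0)
        with pytest.raises(EffectLookupError):
            select_effect([uni], Outcome.DFS)
        with pytest.raises(EffectLookupError):
            select_effect([], Outcome.OS)


class TestKmCsv:
    def test_load_km_curves_with_at_risk(self, tmp_path):
        p = tmp_path / "km.csv"
        p.write_text(
            "arm,time,survival,at_risk\n"
            "high,0,1.0,100\nhigh,12,0.8,75\nhigh,24,0.6,\n"
            "low,0,1.0,120\nlow,12,0.9,\nlow,24,0.8,\n"
        )
        curves = load_km_curves(p)
        assert set(curves) == {"high", "low"}
        assert curves["high"].n_at_risk_initial == 100
        assert curves["high"].at_risk_times == ((0.0, 100.0), (12.0, 75.0))
        assert curves["low"].survival == (1.0, 0.9, 0.8)
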