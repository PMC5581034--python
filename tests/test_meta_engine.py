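import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hccmeta.errors import DomainError, EmptyInputError
from hccmeta.meta_engine import (
    heterogeneity,
    leave_one_out,
    pool_fixed,
    pool_random_dl,
    subgroup_difference,
)
from hccmeta.records import Scale

from conftest import make_effect, make_effects


def oracle_fixed(pairs):
    """Spreadsheet-style inverse-variance pool, written independently."""
    w = [1.0 / s**2 for _, s in pairs]
    est = sum(wi * y for wi, (y, _) in zip(w, pairs)) / sum(w)
    se = math.sqrt(1.0 / sum(w))
    q = sum(wi * (y - est) ** 2 for wi, (y, _) in zip(w, pairs))
    return est, se, q


def oracle_dl_tau2(pairs):
    w = [1.0 / s**2 for _, s in pairs]
    _, _, q = oracle_fixed(pairs)
    df = len(pairs) - 1
    denom = sum(w) - sum(wi**2 for wi in w) / sum(w)
    return max(0.0, (q - df) / denom)


class TestPoolFixed:
    def test_single_effect_is_identity(self):
        r = pool_fixed([make_effect(0.6, 0.2)])
        assert (r.estimate, r.se, r.q, r.df) == (0.6, 0.2, 0.0, 0)
        assert r.weights == (1.0,)

    def test_two_identical_effects(self):
        r = pool_fixed(make_effects([(0.5, 0.1), (0.5, 0.1)]))
        assert r.estimate == pytest.approx(0.5, abs=1e-15)
        assert r.se == pytest.approx(0.1 / math.sqrt(2), abs=1e-15)
        assert r.q == pytest.approx(0.0, abs=1e-15)

    def test_matches_arithmetic_oracle(self):
        pairs = [(0.2, 0.1), (0.6, 0.2), (0.4, 0.15)]
        est, se, q = oracle_fixed(pairs)
        r = pool_fixed(make_effects(pairs))
        assert r.estimate == pytest.approx(est, abs=1e-9)
        assert r.se == pytest.approx(se, abs=1e-9)
        assert r.q == pytest.approx(q, abs=1e-9)

    def test_errors(self):
        with pytest.raises(EmptyInputError):
            pool_fixed([])
        mixed = [make_effect(0.2, 0.1), make_effect(0.3, 0.1, scale=Scale.LOG_OR)]
        with pytest.raises(DomainError, match="mixed"):
            pool_fixed(mixed)


class TestPoolRandomDL:
    def test_homogeneous_set_equals_fixed_bitwise(self):
        effects = make_effects([(0.5, 0.1), (0.52, 0.12), (0.49, 0.11)])
        f, r = pool_fixed(effects), pool_random_dl(effects)
        assert r.tau_squared == 0.0
        assert (r.estimate, r.se, r.ci_low, r.ci_high, r.z, r.p) == (
            f.estimate, f.se, f.ci_low, f.ci_high, f.z, f.p)
        assert r.weights == f.weights

    def test_single_study_pool_reprints_headline(self):
        # pooling one study is the identity: HR 1.82 (1.49-2.22) comes back
        from hccmeta.effect_extraction import loghr_from_ci

        r = pool_random_dl([loghr_from_ci(1.82, 1.49, 2.22)])
        lo, hi = r.ratio_ci
        assert f"{r.ratio:.3g} ({lo:.3g}-{hi:.3g})" == "1.82 (1.49-2.22)"

    def test_tau2_matches_dl_oracle(self):
        pairs = [(0.0, 0.1), (1.0, 0.1), (0.5, 0.1)]
        r = pool_random_dl(make_effects(pairs))
        assert r.tau_squared == pytest.approx(oracle_dl_tau2(pairs), abs=1e-9)
        assert r.tau_squared == pytest.approx(0.24, abs=1e-12)

    def test_matches_statsmodels_combine_effects(self, rng):
        # independent implementation cross-check on a heterogeneous set
        from statsmodels.stats.meta_analysis import combine_effects

        y = rng.normal(0.5, 0.4, 6)
        se = rng.uniform(0.1, 0.4, 6)
        ours = pool_random_dl(make_effects(zip(y, se)))
        ref = combine_effects(y, se**2, method_re="chi2")
        frame = ref.summary_frame()
        assert ours.tau_squared == pytest.approx(ref.tau2, rel=1e-8)
        assert ours.q == pytest.approx(ref.q, rel=1e-8)
        assert ours.i_squared == pytest.approx(ref.i2 * 100, rel=1e-8)
        assert ours.estimate == pytest.approx(frame.loc["random effect", "eff"], rel=1e-8)
        assert ours.se == pytest.approx(frame.loc["random effect", "sd_eff"], rel=1e-8)
        fixed = pool_fixed(make_effects(zip(y, se)))
        assert fixed.estimate == pytest.approx(frame.loc["fixed effect", "eff"], rel=1e-8)


class TestHeterogeneity:
    def test_identical_effects_are_homogeneous(self):
        h = heterogeneity(make_effects([(0.4, 0.1)] * 4))
        assert h.q == pytest.approx(0.0, abs=1e-15)
        assert h.i_squared == 0.0
        assert not h.significant

    def test_i_squared_floored_at_zero(self):
        h = heterogeneity(make_effects([(0.40, 0.2), (0.42, 0.2), (0.41, 0.2)]))
        assert h.q < h.df
        assert h.i_squared == 0.0

    def test_hand_computed_q(self):
        h = heterogeneity(make_effects([(0.0, 0.1), (1.0, 0.1)]))
        assert h.q == pytest.approx(50.0, abs=1e-9)
        assert h.df == 1
        assert h.i_squared == pytest.approx(98.0, abs=1e-9)
        assert h.significant  # I2 >= 50 and p_Q < 0.1

    def test_flag_requires_both_conditions(self):
        # k=2 with Q=2.5: I2=60% >= 50 but p_Q = 0.114 >= 0.1 -> not flagged
        delta = math.sqrt(0.05)
        h = heterogeneity(make_effects([(0.0, 0.1), (delta, 0.1)]))
        assert h.q == pytest.approx(2.5, abs=1e-9)
        assert h.i_squared >= 50.0
        assert h.p >= 0.1
        assert not h.significant

    def test_needs_two_studies(self):
        with pytest.raises(DomainError):
            heterogeneity([make_effect(0.2, 0.1)])


class TestSubgroupDifference:
    def test_identical_groups_show_no_difference(self):
        g = make_effects([(0.5, 0.1), (0.7, 0.2)])
        comp = subgroup_difference([g, list(g)])
        assert comp.q_between == pytest.approx(0.0, abs=1e-12)
        assert comp.p_between == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_between_group_q(self):
        # groups pooling to (0.5, se 0.1) and (0.9, se 0.1)
        g1 = [make_effect(0.5, 0.1)]
        g2 = [make_effect(0.9, 0.1)]
        comp = subgroup_difference([g1, g2], model="fixed")
        assert comp.q_between == pytest.approx(8.0, abs=1e-9)
        assert comp.p_between == pytest.approx(0.00468, abs=5e-5)

    def test_three_copies_of_one_study(self):
        g = [make_effect(0.3, 0.15)]
        comp = subgroup_difference([g, list(g), list(g)])
        assert comp.q_between == pytest.approx(0.0, abs=1e-12)
        assert comp.df_between == 2

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            subgroup_difference([[make_effect(0.2, 0.1)], []])


class TestLeaveOneOut:
    def test_identical_studies_are_uninfluential(self):
        effects = make_effects([(0.4, 0.1)] * 5)
        for _, r in leave_one_out(effects):
            assert r.estimate == pytest.approx(0.4, abs=1e-12)

    def test_k2_returns_each_remaining_study(self):
        effects = make_effects([(0.2, 0.1), (0.8, 0.3)])
        results = leave_one_out(effects)
        assert results[0][0] == "s0"
        assert results[0][1].estimate == pytest.approx(0.8, abs=1e-15)
        assert results[1][1].estimate == pytest.approx(0.2, abs=1e-15)

    def test_each_reduced_pool_matches_pairwise_oracle(self):
        pairs = [(0.2, 0.1), (0.6, 0.2), (0.4, 0.15)]
        results = leave_one_out(make_effects(pairs), model="fixed")
        for i, (_, r) in enumerate(results):
            rest = [p for j, p in enumerate(pairs) if j != i]
            est, se, q = oracle_fixed(rest)
            assert r.estimate == pytest.approx(est, abs=1e-9)
            assert r.se == pytest.approx(se, abs=1e-9)
            assert r.q == pytest.approx(q, abs=1e-9)

    def test_needs_two_studies(self):
        with pytest.raises(DomainError):
            leave_one_out([make_effect(0.2, 0.1)])


class TestInvariants:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.05, 0.8)), min_size=2, max_size=8
        ),
        seed=st.integers(0, 10_000),
    )
    def test_permutation_invariance(self, data, seed):
        effects = make_effects(data)
        perm = list(np.random.default_rng(seed).permutation(len(effects)))
        shuffled = [effects[i] for i in perm]
        for fn in (pool_fixed, pool_random_dl):
            a, b = fn(effects), fn(shuffled)
            assert a.estimate == pytest.approx(b.estimate, rel=1e-12, abs=1e-12)
            assert a.q == pytest.approx(b.q, rel=1e-12, abs=1e-9)
            assert a.tau_squared == pytest.approx(b.tau_squared, rel=1e-12, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.05, 0.8)), min_size=1, max_size=8
        )
    )
    def test_information_never_decreases_and_weights_normalized(self, data):
        effects = make_effects(data)
        r = pool_fixed(effects)
        assert r.se <= min(e.se for e in effects) + 1e-12
        assert sum(r.weights) == pytest.approx(1.0, abs=1e-9)
        assert r.ci_low <= r.estimate <= r.ci_high
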