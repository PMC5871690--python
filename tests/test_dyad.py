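"""Joint states, synchrony, BH-FDR, and the paired condition comparison."""

import itertools

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from dyadplay import scheme
from dyadplay.dyad import (
    JointStateSequence,
    StateFrequencyComparison,
    bh_fdr,
    cohens_dz,
    compare_conditions,
    joint_distribution,
    joint_states,
    synchrony,
)
from dyadplay.states import derive_states, state_frequencies
from dyadplay.timeline import DyadTimeline, ValidationError

from conftest import make_timeline, random_timeline


def make_dyad(rng, n=200):
    inf = random_timeline(rng, n, participant="infant")
    adu = random_timeline(rng, n, participant="adult")
    return DyadTimeline(infant=inf, adult=adu)


def jseq_from_states(inf, adu, fps=30.0):
    return JointStateSequence(fps=fps, infant_states=np.asarray(inf),
                              adult_states=np.asarray(adu))


class TestJointStates:
    def test_concurrent_pairing(self, rng):
        dyad = make_dyad(rng)
        js = joint_states(dyad)
        np.testing.assert_array_equal(js.infant_states,
                                      derive_states(dyad.infant).states)
        np.testing.assert_array_equal(js.adult_states,
                                      derive_states(dyad.adult).states)

    def test_didactic_teaching_example(self):
        # mother in [1 0 1] while infant in [0 1 1]: joint pair (3, 2)
        inf = make_timeline(np.tile((0, 1, 1), (5, 1)), participant="infant")
        adu = make_timeline(np.tile((1, 0, 1), (5, 1)), participant="adult")
        js = joint_states(DyadTimeline(infant=inf, adult=adu))
        assert js.pairs().tolist() == [[3, 2]] * 5

    def test_empty_dyad_is_an_error(self):
        inf = make_timeline(np.zeros((0, 3), dtype=np.int8), participant="infant")
        adu = make_timeline(np.zeros((0, 3), dtype=np.int8), participant="adult")
        with pytest.raises(ValidationError):
            joint_states(DyadTimeline(infant=inf, adult=adu))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            jseq_from_states([1, 2], [1])


class TestJointDistribution:
    def test_counting(self):
        jd = joint_distribution(jseq_from_states([1, 1, 2, 1], [1, 1, 1, 3]))
        assert jd.p[0, 0] == 0.5 and jd.p[1, 0] == 0.25 and jd.p[0, 2] == 0.25
        assert jd.p.sum() == pytest.approx(1.0)

    def test_identical_partners_mass_on_diagonal(self, rng):
        s = rng.integers(1, 9, 100)
        jd = joint_distribution(jseq_from_states(s, s))
        assert np.trace(jd.p) == pytest.approx(1.0)

    def test_marginals_equal_individual_frequencies(self, rng):
        """The joint matrix's marginals are the two partners' 8-state
        frequency vectors, exactly."""
        for _ in range(50):
            inf = rng.integers(1, 9, int(rng.integers(1, 300)))
            adu = rng.integers(1, 9, len(inf))
            jd = joint_distribution(jseq_from_states(inf, adu))
            np.testing.assert_allclose(
                jd.infant_marginal.freq,
                state_frequencies(derive_states(make_timeline(
                    scheme.code_array_from_states(inf)))).freq,
                rtol=0, atol=1e-15)
            np.testing.assert_allclose(jd.adult_marginal.freq,
                                       np.bincount(adu, minlength=9)[1:] / len(adu),
                                       rtol=0, atol=1e-15)


class TestSynchrony:
    def test_identical_streams(self, rng):
        s = np.repeat([1, 2, 1, 3, 1], 8)  # freq[1] = 0.6
        rep = synchrony(jseq_from_states(s, s))
        assert rep.p_same_state == 1.0
        assert rep.p_joint_play == pytest.approx(0.6)

    def test_disjoint_states_no_joint_play(self):
        rep = synchrony(jseq_from_states([1] * 10, [2] * 10))
        assert rep.p_joint_play == 0.0 and rep.p_same_state == 0.0

    def test_counting(self):
        inf = [1, 1, 1, 2, 2, 2, 2, 1, 3, 4]
        adu = [1, 1, 2, 2, 2, 2, 2, 1, 4, 3]
        rep = synchrony(jseq_from_states(inf, adu))
        assert rep.p_joint_play == pytest.approx(0.3)

    def test_bounds_and_partner_symmetry(self, rng):
        for _ in range(30):
            inf = rng.integers(1, 9, 150)
            adu = rng.integers(1, 9, 150)
            rep = synchrony(jseq_from_states(inf, adu))
            jd = joint_distribution(jseq_from_states(inf, adu))
            assert rep.p_joint_play <= min(jd.infant_marginal[1], jd.adult_marginal[1])
            assert rep.p_joint_play <= rep.p_same_state
            swapped = synchrony(jseq_from_states(adu, inf))
            assert swapped.p_joint_play == rep.p_joint_play
            assert swapped.p_same_state == rep.p_same_state

    def test_dimension_concordance_from_main_codes(self, rng):
        dyad = make_dyad(rng, 100)
        rep = synchrony(joint_states(dyad))
        for dim, j in scheme.DIM_INDEX.items():
            expected = (dyad.infant.main[:, j] == dyad.adult.main[:, j]).mean()
            assert rep.dimension_concordance[dim] == pytest.approx(expected)


def bh_oracle(p, alpha):
    """Exhaustive step-up oracle: reject the k smallest p-values for the
    largest k with p_(k) <= k * alpha / m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


class TestBhFdr:
    def test_hand_worked_stepup(self):
        adjusted, rejected = bh_fdr([0.001] + [0.2] * 7, alpha=0.05)
        assert adjusted[0] == pytest.approx(0.008)
        assert rejected[0] and not rejected[1:].any()

    def test_all_ones_no_rejections(self):
        adjusted, rejected = bh_fdr([1.0] * 8)
        assert (adjusted == 1.0).all() and not rejected.any()

    def test_single_p(self):
        adjusted, rejected = bh_fdr([0.04], alpha=0.05)
        assert adjusted[0] == pytest.approx(0.04) and rejected[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])

    def test_matches_statsmodels_and_exhaustive_oracle(self, rng):
        for m in range(1, 9):
            for _ in range(40):
                p = np.round(rng.random(m), 3)
                alpha = float(rng.choice([0.01, 0.05, 0.1, 0.25]))
                adjusted, rejected = bh_fdr(p, alpha=alpha)
                sm_rej, sm_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
                np.testing.assert_allclose(adjusted, sm_adj, atol=1e-12)
                np.testing.assert_array_equal(rejected, sm_rej)
                np.testing.assert_array_equal(rejected, bh_oracle(p, alpha))

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(8)
        adjusted, _ = bh_fdr(p)
        assert (adjusted >= p - 1e-15).all()


def paired_t_definition(x2, x1):
    """Definitional paired t: mean(d) / (sd(d)/sqrt(n)), sd with ddof=1."""
    d = np.asarray(x2, float) - np.asarray(x1, float)
    n = len(d)
    return d.mean() / (d.std(ddof=1) / np.sqrt(n))


def random_freq_rows(rng, n):
    raw = rng.random((n, 8))
    return raw / raw.sum(axis=1, keepdims=True)


class TestCompareConditions:
    def test_matches_definitional_paired_t(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            f1, f2 = random_freq_rows(rng, n), random_freq_rows(rng, n)
            res = StateFrequencyComparison(f1, f2).fit()
            for s in range(8):
                expected = paired_t_definition(f2[:, s], f1[:, s])
                assert res.t_statistics[s] == pytest.approx(expected, abs=1e-10)
                assert res.effect_sizes[s] == pytest.approx(
                    expected / np.sqrt(n), abs=1e-10)
            assert res.df == n - 1
            np.testing.assert_allclose(res.p_bh_fdr,
                                       multipletests(res.p_raw, method="fdr_bh")[1])

    def test_effect_size_convention_reproduces_printed_pairs(self):
        """d_z = t/sqrt(n) matches all five published (t, d) pairs at n=5."""
        pairs = [(8.97, 4.01), (2.90, 1.30), (-3.11, -1.39),
                 (-9.85, -4.41), (1.28, 0.57)]
        for t, d in pairs:
            assert round(float(cohens_dz(t, 5)), 2) == d

    def test_zero_difference_gives_zero_t_and_d(self):
        f = random_freq_rows(np.random.default_rng(1), 5)
        res = StateFrequencyComparison(f, f.copy()).fit()
        np.testing.assert_array_equal(res.t_statistics, np.zeros(8))
        np.testing.assert_array_equal(res.effect_sizes, np.zeros(8))
        assert (res.p_raw == 1.0).all() and not res.rejected.any()

    def test_missing_condition_names_the_dyad(self, rng):
        freqs = {
            "d1": {"c1": random_freq_rows(rng, 1)[0], "c2": random_freq_rows(rng, 1)[0]},
            "d2": {"c1": random_freq_rows(rng, 1)[0]},
        }
        with pytest.raises(ValidationError, match="d2"):
            compare_conditions(freqs)

    def test_fewer_than_two_dyads_rejected(self, rng):
        with pytest.raises(ValidationError, match="2 dyads"):
            StateFrequencyComparison(random_freq_rows(rng, 1),
                                     random_freq_rows(rng, 1))

    def test_invariants_and_summary(self, rng):
        f1, f2 = random_freq_rows(rng, 5), random_freq_rows(rng, 5)
        res = StateFrequencyComparison(f1, f2, group="infant").fit()
        assert (res.p_bh_fdr >= res.p_raw - 1e-15).all()
        np.testing.assert_array_equal(np.sign(res.effect_sizes),
                                      np.sign(res.t_statistics))
        text = res.summary()
        assert "infant" in text and "d_z = t/sqrt(n)" in text
        frame = res.to_frame()
        assert list(frame.state) == list(range(1, 9))

    def test_from_dataframe_long_format(self, rng):
        import pandas as pd
        rows = []
        nested = {}
        for dyad in ("d1", "d2", "d3"):
            nested[dyad] = {}
            for cond in ("c1", "c2"):
                f = random_freq_rows(rng, 1)[0]
                nested[dyad][cond] = f
                rows += [{"dyad": dyad, "condition": cond, "state": s + 1,
                          "frequency": f[s]} for s in range(8)]
        res_df = StateFrequencyComparison.from_dataframe(pd.DataFrame(rows)).fit()
        res_dict = compare_conditions(nested)
        np.testing.assert_allclose(res_df.t_statistics, res_dict.t_statistics)


def test_sixty_four_joint_states_enumerable():
    """The joint taxonomy is exactly the 8 x 8 product of individual states."""
    pairs = set(itertools.product(range(1, 9), range(1, 9)))
    assert len(pairs) == 64
    jd = joint_distribution(jseq_from_states(*zip(*sorted(pairs))))
    assert jd.p.shape == (8, 8) and (jd.p == 1 / 64).all()
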