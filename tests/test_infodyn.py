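"""Plug-in information dynamics against independent brute-force oracles."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tandemflow as tf
from tandemflow.infodyn import InfoDynError


# ---------------------------------------------------------------------------
# Independent dense-enumeration oracle (pure Python, Counter-based)


def oracle_counts(dest_trials, k, src_trials=None):
    joint = Counter()
    src_trials = src_trials or [None] * len(dest_trials)
    for d, s in zip(dest_trials, src_trials):
        for i in range(k - 1, len(d) - 1):
            hist = tuple(d[i - k + 1 : i + 1])
            key = (d[i + 1], hist) if s is None else (d[i + 1], hist, s[i])
            joint[key] += 1
    return joint


def oracle_conditional_entropy(dest_trials, k):
    joint = oracle_counts(dest_trials, k)
    n = sum(joint.values())
    hist = Counter()
    for (f, h), c in joint.items():
        hist[h] += c
    return -sum(
        (c / n) * math.log2(c / hist[h]) for (f, h), c in joint.items()
    )


def oracle_te(src_trials, dest_trials, k):
    """Direct summation of p(f,h,s) log2 [p(f|h,s)/p(f|h)] over observed blocks."""
    joint = oracle_counts(dest_trials, k, src_trials)
    n = sum(joint.values())
    c_hs, c_hf, c_h = Counter(), Counter(), Counter()
    for (f, h, s), c in joint.items():
        c_hs[(h, s)] += c
        c_hf[(h, f)] += c
        c_h[h] += c
    te = 0.0
    for (f, h, s), c in joint.items():
        p_f_hs = c / c_hs[(h, s)]
        p_f_h = c_hf[(h, f)] / c_h[h]
        te += (c / n) * math.log2(p_f_hs / p_f_h)
    return te


# ---------------------------------------------------------------------------


class TestEntropy:
    @pytest.mark.parametrize(
        "p,expected",
        [((0.5, 0.5), 1.0), ((1.0, 0.0), 0.0),
         ((0.25, 0.75), -(0.25 * math.log2(0.25) + 0.75 * math.log2(0.75)))],
    )
    def test_closed_form(self, p, expected):
        assert tf.entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_quarter_three_quarters_value(self):
        assert tf.entropy((0.25, 0.75)) == pytest.approx(0.8113, abs=5e-5)

    def test_invalid_mass_rejected(self):
        with pytest.raises(InfoDynError):
            tf.entropy((0.5, 0.6))
        with pytest.raises(InfoDynError):
            tf.entropy((-0.1, 1.1))


class TestCountBlocks:
    def test_enumeration_binary_k1(self):
        counts = tf.count_blocks([[0, 0, 1]], k=1)  # M,M,P
        assert counts.total == 2
        assert counts.as_dict() == {(0, (0,)): 1, (1, (0,)): 1}

    def test_pooling_is_additive(self):
        a, b = [0, 1, 0, 1], [1, 1, 0]
        pooled = tf.count_blocks([a, b], k=1)
        sep = tf.count_blocks([a], k=1).total + tf.count_blocks([b], k=1).total
        assert pooled.total == sep

    def test_history_block_frequency(self):
        # p of the 3-symbol history {CW, CW, CCW} = its consecutive-occurrence
        # count over the number of counted samples
        series = [0, 0, 1, 0, 0, 1, 1, 0, 0, 1]
        counts = tf.count_blocks([series], k=3)
        d = counts.as_dict()
        occurrences = sum(c for (f, h), c in d.items() if h == (0, 0, 1))
        brute = sum(
            1
            for i in range(2, len(series) - 1)
            if tuple(series[i - 2 : i + 1]) == (0, 0, 1)
        )
        assert occurrences == brute

    def test_short_trial_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            counts = tf.count_blocks([[0, 1], [0, 1, 0, 1]], k=2)
        assert counts.total == 2

    def test_all_short_is_error(self):
        with pytest.raises(InfoDynError), pytest.warns(UserWarning):
            tf.count_blocks([[0, 1]], k=3)

    def test_misaligned_source_rejected(self):
        with pytest.raises(InfoDynError, match="misaligned"):
            tf.count_blocks([[0, 1, 0]], k=1, src_trials=[[0, 1]])


class TestConditionalEntropy:
    def test_iid_fair_binary_approaches_one_bit(self):
        rng = np.random.default_rng(0)
        series = rng.integers(0, 2, 20000)
        assert tf.conditional_entropy([series], k=1) == pytest.approx(1.0, abs=0.01)

    def test_alternating_series_is_deterministic(self):
        assert tf.conditional_entropy([[0, 1] * 10], k=1) == pytest.approx(0.0)

    def test_three_transition_example(self):
        # dest M,M,P,M with k=1: only the M-context branch is uncertain
        assert tf.conditional_entropy([[0, 0, 1, 0]], k=1) == pytest.approx(
            2.0 / 3.0, abs=1e-12
        )

    def test_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            series = rng.integers(0, 3, 15).tolist()
            k = int(rng.integers(1, 4))
            assert tf.conditional_entropy([series], k) == pytest.approx(
                oracle_conditional_entropy([series], k), abs=1e-12
            )


class TestTransferEntropy:
    def test_perfect_copy_of_fair_source_is_one_bit(self):
        rng = np.random.default_rng(2)
        src = rng.integers(0, 2, 50000)
        dst = np.empty_like(src)
        dst[1:] = src[:-1]
        dst[0] = 0
        r = tf.transfer_entropy([src], [dst], k=1)
        assert r.te_bits == pytest.approx(1.0, abs=0.01)

    def test_independent_processes_near_zero(self):
        rng = np.random.default_rng(3)
        src = rng.integers(0, 2, 100000)
        dst = rng.integers(0, 2, 100000)
        r = tf.transfer_entropy([src], [dst], k=1)
        assert r.te_bits == pytest.approx(0.0, abs=0.005)

    def test_five_symbol_worked_example(self):
        src, dst = [0, 1, 0, 1, 1], [1, 0, 1, 0, 1]
        r = tf.transfer_entropy([src], [dst], k=1)
        assert r.te_bits == pytest.approx(oracle_te([src], [dst], 1), abs=1e-12)

    def test_exhaustive_binary_length5_k1(self):
        """Every binary source/destination pair of length 5 matches the oracle."""
        for d_bits in itertools.product((0, 1), repeat=5):
            if len(set(d_bits)) == 1:
                continue  # degenerate but still valid; covered below
            for s_bits in itertools.product((0, 1), repeat=5):
                r = tf.transfer_entropy([list(s_bits)], [list(d_bits)], k=1)
                assert r.te_bits == pytest.approx(
                    oracle_te([list(s_bits)], [list(d_bits)], 1), abs=1e-12
                )

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(
        data=st.data(),
        a=st.integers(2, 3),
        k=st.integers(1, 3),
        n=st.integers(5, 12),
        n_trials=st.integers(1, 3),
    )
    def test_oracle_equivalence_and_invariants(self, data, a, k, n, n_trials):
        """Plug-in TE equals the dense oracle; bounds and identities hold."""
        trials_d, trials_s = [], []
        for _ in range(n_trials):
            trials_d.append(
                data.draw(st.lists(st.integers(0, a - 1), min_size=n, max_size=n))
            )
            trials_s.append(
                data.draw(st.lists(st.integers(0, a - 1), min_size=n, max_size=n))
            )
        if all(len(t) < k + 1 for t in trials_d):
            return
        r = tf.transfer_entropy(trials_s, trials_d, k)
        expected = oracle_te(trials_s, trials_d, k)
        assert r.te_bits == pytest.approx(expected, abs=1e-12)
        # 0 <= TE <= H(F|F^k) <= log2(a)
        assert -1e-12 <= r.te_bits <= r.cond_entropy_bits + 1e-12
        assert r.cond_entropy_bits <= math.log2(a) + 1e-12
        # TE = H(F|F^k) - H(F|F^k, S): the source-conditioned entropy
        h = oracle_conditional_entropy(trials_d, k)
        assert r.cond_entropy_bits == pytest.approx(h, abs=1e-12)
        # mean local TE equals pooled TE exactly
        local = tf.local_transfer_entropy(trials_s, trials_d, k)
        assert local.mean_bits == pytest.approx(r.te_bits, abs=1e-12)

    def test_per_trial_mode_reports_vector(self):
        rng = np.random.default_rng(4)
        src = [rng.integers(0, 2, 50) for _ in range(4)]
        dst = [rng.integers(0, 2, 50) for _ in range(4)]
        r = tf.transfer_entropy(src, dst, k=1, mode="per_trial")
        assert len(r.per_trial_values) == 4
        assert r.te_bits == pytest.approx(np.mean(r.per_trial_values))
        singles = [
            tf.transfer_entropy([s], [d], k=1).te_bits for s, d in zip(src, dst)
        ]
        np.testing.assert_allclose(r.per_trial_values, singles, atol=1e-12)

    def test_plug_in_bias_shrinks_with_sample_size(self):
        """For independent iid pairs the TE bias decays as n grows."""
        rng = np.random.default_rng(5)
        means = []
        for n in (100, 1000, 10000):
            vals = [
                tf.transfer_entropy(
                    [rng.integers(0, 2, n)], [rng.integers(0, 2, n)], k=1
                ).te_bits
                for _ in range(200)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2] > 0


class TestLocalTransferEntropy:
    def test_perfect_copy_every_step_one_bit(self):
        rng = np.random.default_rng(6)
        src = rng.integers(0, 2, 5000)
        dst = np.empty_like(src)
        dst[1:] = src[:-1]
        dst[0] = 0
        local = tf.local_transfer_entropy([src], [dst], k=1)
        assert np.all(np.abs(local.values - 1.0) < 0.05)

    def test_misinformative_steps_are_negative(self):
        # a source that usually copies but sometimes anti-copies: the rare
        # anti-copy transitions must score negative local TE
        rng = np.random.default_rng(7)
        src = rng.integers(0, 2, 5000)
        dst = np.empty_like(src)
        flip = rng.random(5000) < 0.1
        dst[1:] = np.where(flip[1:], 1 - src[:-1], src[:-1])
        dst[0] = 0
        local = tf.local_transfer_entropy([src], [dst], k=1)
        assert local.values.min() < 0 < local.values.max()

    def test_per_trial_alignment(self):
        src = [[0, 1, 0, 1, 1], [1, 1, 0, 0]]
        dst = [[1, 0, 1, 0, 1], [0, 1, 1, 0]]
        local = tf.local_transfer_entropy(src, dst, k=2)
        assert [v.size for v in local.per_trial] == [3, 2]


class TestDerivedQuantities:
    def test_net_te_difference_and_antisymmetry(self):
        rng = np.random.default_rng(8)
        lead = [rng.integers(0, 2, 200) for _ in range(3)]
        foll = [rng.integers(0, 2, 200) for _ in range(3)]
        net = tf.net_transfer_entropy(lead, foll, 2)
        flipped = tf.net_transfer_entropy(foll, lead, 2)
        assert net == pytest.approx(-flipped, abs=1e-12)

    def test_net_te_identical_series_is_zero(self):
        series = [[0, 1, 1, 0, 1, 0, 0, 1]]
        assert tf.net_transfer_entropy(series, series, 1) == pytest.approx(0.0)

    def test_normalized_te(self):
        r = tf.TEResult(("leader", "follower"), 0.25, 1.0, k=1)
        assert tf.normalized_transfer_entropy(r) == pytest.approx(0.25)
        assert tf.normalized_transfer_entropy(r, correction=0.05) == pytest.approx(0.2)
        full = tf.TEResult(("leader", "follower"), 1.0, 1.0, k=1)
        assert tf.normalized_transfer_entropy(full) == pytest.approx(1.0)
        zero = tf.TEResult(("leader", "follower"), 0.0, 0.7, k=1)
        assert tf.normalized_transfer_entropy(zero) == pytest.approx(0.0)

    def test_normalized_te_zero_entropy_rejected(self):
        r = tf.TEResult(("leader", "follower"), 0.0, 0.0, k=1)
        with pytest.raises(InfoDynError, match="self-predictable"):
            tf.normalized_transfer_entropy(r)


def test_te_result_json_round_trip():
    r = tf.TEResult(
        ("follower", "leader"), 0.12345678901234, 0.9876, k=3, period_s=0.5005,
        mode="per_trial", per_trial_values=(0.1, 0.15), n_transitions=123,
    )
    back = tf.TEResult.from_json(r.to_json())
    assert back == r
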