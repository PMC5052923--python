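import io
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from motifnull import (
    ClassTable,
    CountVector,
    ParameterError,
    class_count_closed_form,
    class_entropy,
    class_weight,
    enumerate_classes,
    log_partition_column,
    tilted_moments,
)
from motifnull.count_classes import (
    class_probs,
    load_or_build,
    sample_column,
    sample_columns,
)


def brute_force_columns(N: int, alphabet_size: int = 4):
    """All alphabet_size^N columns with their entropies (independent oracle)."""
    total = alphabet_size**N
    cols = np.array(
        [[(i // alphabet_size**k) % alphabet_size for k in range(N)] for i in range(total)]
    )
    H = np.empty(total)
    for i, col in enumerate(cols):
        counts = np.bincount(col, minlength=alphabet_size)
        p = counts[counts > 0] / N
        H[i] = -(p * np.log2(p)).sum()
    return cols, H


class TestEnumeration:
    def test_single_site_single_class(self):
        t = enumerate_classes(1)
        assert t.class_count == 1
        assert tuple(t.counts[0]) == (1, 0, 0, 0)

    def test_n4_partitions(self):
        t = enumerate_classes(4)
        assert [tuple(map(int, r)) for r in t.counts] == [
            (4, 0, 0, 0),
            (3, 1, 0, 0),
            (2, 2, 0, 0),
            (2, 1, 1, 0),
            (1, 1, 1, 1),
        ]

    def test_n200_matches_closed_form(self):
        t = enumerate_classes(200)
        assert t.class_count == class_count_closed_form(200) == 59823
        assert t.class_count <= 60_000

    def test_closed_form_against_partition_dp(self):
        # independent oracle: DP count of partitions into parts of size <= 4,
        # which equals partitions into at most 4 parts by conjugation
        limit = 300
        dp = np.zeros(limit + 1, dtype=np.int64)
        dp[0] = 1
        for part in range(1, 5):
            for n in range(part, limit + 1):
                dp[n] += dp[n - part]
        for N in range(1, limit + 1):
            assert class_count_closed_form(N) == dp[N]

    def test_alphabet_size_guards(self):
        with pytest.raises(ParameterError):
            enumerate_classes(5, alphabet_size=1)
        with pytest.raises(ParameterError):
            enumerate_classes(5, alphabet_size=21)
        with pytest.warns(RuntimeWarning):
            enumerate_classes(3, alphabet_size=7)


class TestWeightsAndEntropy:
    @pytest.mark.parametrize(
        "counts,expected_weight",
        [((4, 0, 0, 0), 4), ((1, 1, 1, 1), 24), ((2, 1, 1, 0), 144), ((2, 2, 0, 0), 36)],
    )
    def test_exact_weights_match_brute_force(self, counts, expected_weight):
        # expected values verified by enumerating all 256 N=4 columns below
        exact, log_w = class_weight(CountVector(counts))
        assert exact == expected_weight
        assert log_w == pytest.approx(math.log(expected_weight), rel=1e-12)

    def test_weights_partition_the_column_space(self):
        cols, H = brute_force_columns(4)
        t = enumerate_classes(4)
        for k in range(t.class_count):
            match = 0
            rep = tuple(map(int, t.counts[k]))
            for col in cols:
                if tuple(sorted(np.bincount(col, minlength=4), reverse=True)) == rep:
                    match += 1
            assert t.exact_weight(k) == match
        assert t.total_weight_exact() == 256

    def test_completeness_exact_bigint(self):
        for N in range(1, 31):
            assert enumerate_classes(N).total_weight_exact() == 4**N

    def test_log_and_exact_weights_agree_large_n(self):
        t = enumerate_classes(150)
        for k in range(0, t.class_count, 997):
            assert t.log_weight[k] == pytest.approx(
                float(math.log(t.exact_weight(k))), rel=1e-9
            )

    @pytest.mark.parametrize(
        "counts,expected",
        [((5, 0, 0, 0), 0.0), ((1, 1, 1, 1), 2.0), ((2, 1, 1, 0), 1.5)],
    )
    def test_class_entropy(self, counts, expected):
        assert class_entropy(CountVector(counts)) == pytest.approx(expected)

    def test_entropies_within_bounds(self):
        t = enumerate_classes(17)
        assert (t.entropy >= 0).all() and (t.entropy <= 2.0).all()


class TestTiltedSums:
    def test_partition_function_at_lambda_zero(self):
        for N in (1, 3, 10, 60):
            t = enumerate_classes(N)
            assert log_partition_column(t, 0.0) == pytest.approx(
                N * math.log(4), rel=1e-12
            )

    def test_partition_function_n2_closed_form(self):
        t = enumerate_classes(2)
        assert log_partition_column(t, 1.0) == pytest.approx(
            math.log(4 + 12 * math.exp(-1)), rel=1e-12
        )

    @pytest.mark.parametrize("N,alphabet", [(2, 4), (4, 4), (5, 4), (8, 2), (12, 2)])
    @pytest.mark.parametrize("lam", [-2.0, 0.0, 1.0, 5.0])
    def test_oracle_equivalence(self, N, alphabet, lam):
        cols, H = brute_force_columns(N, alphabet)
        t = enumerate_classes(N, alphabet)
        w = np.exp(-lam * H)
        assert log_partition_column(t, lam) == pytest.approx(
            math.log(w.sum()), rel=1e-9
        )
        mean = (H * w).sum() / w.sum()
        var = (H**2 * w).sum() / w.sum() - mean**2
        got_mean, got_var = tilted_moments(t, lam)
        assert got_mean == pytest.approx(mean, abs=1e-9)
        assert got_var == pytest.approx(var, abs=1e-9)

    def test_mean_entropy_decreases_in_lambda(self):
        t = enumerate_classes(12)
        means = [tilted_moments(t, lam)[0] for lam in np.linspace(-5, 10, 16)]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_extreme_tilt_limits(self):
        t = enumerate_classes(6)
        mean, var = tilted_moments(t, 400.0)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert var == pytest.approx(0.0, abs=1e-9)

    def test_no_overflow_at_large_parameters(self):
        t = enumerate_classes(500)
        assert np.isfinite(log_partition_column(t, 500.0))
        assert np.isfinite(log_partition_column(t, -500.0))


class TestSerialization:
    def test_text_round_trip(self):
        t = enumerate_classes(9)
        buf = io.StringIO()
        t.to_text(buf)
        buf.seek(0)
        back = ClassTable.from_text(buf)
        assert back.N == 9 and back.alphabet_size == 4
        np.testing.assert_array_equal(back.counts, t.counts)
        np.testing.assert_allclose(back.entropy, t.entropy, rtol=1e-15)
        np.testing.assert_allclose(back.log_weight, t.log_weight, rtol=1e-15)

    def test_cache_round_trip(self, tmp_path):
        t1 = load_or_build(7, cache_dir=tmp_path)
        assert (tmp_path / "classes_N7_A4.tsv").exists()
        t2 = load_or_build(7, cache_dir=tmp_path)
        np.testing.assert_array_equal(t1.counts, t2.counts)


class TestColumnSampler:
    def test_single_site_uniform_over_bases(self, rng):
        t = enumerate_classes(1)
        draws = sample_columns(t, 3.0, 20_000, rng)[:, 0]
        _, p = chisquare(np.bincount(draws, minlength=4))
        assert p > 0.001

    def test_uniform_over_columns_at_lambda_zero(self, rng):
        t = enumerate_classes(3)
        cols = sample_columns(t, 0.0, 100_000, rng)
        codes = cols @ (4 ** np.arange(3))
        _, p = chisquare(np.bincount(codes, minlength=64))
        assert p > 0.001

    def test_class_frequencies_match_tilted_probabilities(self, rng):
        t = enumerate_classes(4)
        lam = 6.0
        cols = sample_columns(t, lam, 100_000, rng)
        reps = [
            tuple(sorted(np.bincount(col, minlength=4), reverse=True)) for col in cols
        ]
        lut = {tuple(map(int, t.counts[k])): k for k in range(t.class_count)}
        obs = np.bincount([lut[r] for r in reps], minlength=t.class_count)
        expected = class_probs(t, lam)
        n = obs.sum()
        for k in range(t.class_count):
            se = math.sqrt(expected[k] * (1 - expected[k]) * n)
            assert abs(obs[k] - expected[k] * n) <= max(3 * se, 5)

    def test_sample_column_returns_letters(self, rng):
        t = enumerate_classes(5)
        col = sample_column(t, 1.0, rng)
        assert len(col) == 5 and set(col) <= set("ACGT")
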