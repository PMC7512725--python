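"""Dispersion patterns, DispEn/FDispEn, forbidden-pattern analysis."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dispen.core import (
    EntropyParams,
    dispen,
    embed,
    fdispen,
    forbidden_census,
    forbidden_implication_check,
    pattern_distribution,
    shannon_entropy,
    to_fluctuation,
)
from dispen.signals import logistic_map


def naive_pattern_counts(u, m, c, d, flavor):
    """Nested-loop recount oracle, independent of the vectorized path."""
    counts = Counter()
    n = len(u)
    for i in range(n - (m - 1) * d):
        pat = tuple(int(u[i + k * d]) for k in range(m))
        if flavor == "fluctuation":
            pat = tuple(pat[k + 1] - pat[k] for k in range(m - 1))
        counts[pat] += 1
    return counts


class TestEmbed:
    def test_worked_pairs(self):
        u = [2, 2, 1, 1, 2, 1, 1, 2, 3, 3]
        v = embed(np.array(u), 2, 1)
        assert v.shape == (9, 2)
        assert v[0].tolist() == [2, 2] and v[1].tolist() == [2, 1]

    def test_boundary_single_vector(self):
        assert embed(np.arange(5), 3, 2).shape == (1, 3)

    def test_stride(self):
        v = embed(np.arange(1, 8), 3, 2)
        assert v.tolist() == [[1, 3, 5], [2, 4, 6], [3, 5, 7]]

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            embed(np.arange(4), 3, 2)


class TestFluctuationTransform:
    @pytest.mark.parametrize(
        "pattern,expected",
        [((1, 3, 4), (2, 1)), ((2, 4, 5), (2, 1)), ((3, 3, 3), (0, 0)),
         ((1, 1, 1), (0, 0)), ((1, 1, 2), (0, 1))],
    )
    def test_adjacent_differences(self, pattern, expected):
        assert to_fluctuation(pattern) == expected

    def test_requires_m_ge_2(self):
        with pytest.raises(ValueError):
            to_fluctuation((3,))


class TestWorkedExamples:
    def test_dispen_pattern_probabilities(self):
        """The ten-sample example yields three patterns of probability 2/9
        and three of 1/9."""
        x = [3.6, 4.2, 1.2, 3.1, 4.2, 2.1, 3.3, 4.6, 6.8, 8.4]
        r = dispen(x, m=2, c=3, mapping="linear")
        probs = sorted(r.distribution.probabilities.values(), reverse=True)
        assert probs == pytest.approx([2 / 9] * 3 + [1 / 9] * 3)

    def test_dispen_value(self):
        x = [3.6, 4.2, 1.2, 3.1, 4.2, 2.1, 3.3, 4.6, 6.8, 8.4]
        r = dispen(x, m=2, c=3, mapping="linear")
        assert r.raw == pytest.approx(1.7351, abs=5e-5)
        assert r.normalized == pytest.approx(1.7351264 / math.log(9), abs=1e-4)

    def test_fdispen_difference_sequence(self):
        """The two-class example produces the printed difference patterns."""
        x = [3, 4.5, 6.2, 5.1, 3.2, 1.2, 3.5, 5.6, 4.9, 8.4]
        params = EntropyParams(m=3, c=2, d=1, mapping="linear", flavor="fluctuation")
        u = np.array([1, 1, 2, 2, 1, 1, 1, 2, 2, 2])
        seq = [to_fluctuation(v) for v in embed(u, 3, 1)]
        assert seq == [(0, 1), (1, 0), (0, -1), (-1, 0), (0, 0), (0, 1), (1, 0), (0, 0)]
        dist = pattern_distribution(u, params)
        assert dist.counts == {(0, 1): 2, (1, 0): 2, (0, 0): 2, (0, -1): 1, (-1, 0): 1}
        assert dist.total == 8

    def test_fdispen_value(self):
        x = [3, 4.5, 6.2, 5.1, 3.2, 1.2, 3.5, 5.6, 4.9, 8.4]
        r = fdispen(x, m=3, c=2, mapping="linear")
        assert r.raw == pytest.approx(1.5596, abs=5e-5)
        assert r.normalized == pytest.approx(1.5595812 / math.log(9), abs=1e-4)

    def test_pattern_space_sizes(self):
        assert EntropyParams(m=2, c=3, flavor="dispersion").pattern_space_size == 9
        assert EntropyParams(m=3, c=2, flavor="fluctuation").pattern_space_size == 9


class TestEntropyProperties:
    def test_uniform_distribution_maximal(self):
        """A class series visiting every pattern equally often has entropy
        exactly ln(c^m)."""
        c, m = 2, 2
        # de Bruijn-style sequence covering all 4 patterns once per period
        u = np.array([1, 1, 2, 2] * 25 + [1])
        params = EntropyParams(m=m, c=c, d=1, mapping="linear")
        dist = pattern_distribution(u, params)
        assert len(dist.counts) == c**m
        assert shannon_entropy(dist) == pytest.approx(math.log(c**m), abs=1e-12)

    def test_constant_series_zero_entropy(self):
        u = np.full(50, 3)
        dist = pattern_distribution(u, EntropyParams(m=2, c=6))
        assert dist.counts == {(3, 3): 49}
        assert shannon_entropy(dist) == 0.0

    def test_monotone_class_staircase_gives_zero_fdispen(self):
        x = np.linspace(0, 1, 12)  # strictly increasing, constant step
        r = fdispen(x, m=3, c=12, mapping="sorting")
        assert r.raw == 0.0

    def test_white_noise_near_maximal(self):
        """NCDF classes of Gaussian noise are uniform, so normalized DispEn
        approaches 1; logsig occupancy is non-uniform and saturates lower."""
        x = np.random.default_rng(5).standard_normal(10000)
        assert abs(dispen(x, m=2, c=6, mapping="ncdf").normalized - 1.0) < 0.02
        assert dispen(x, m=2, c=6, mapping="logsig").normalized > 0.9

    def test_fdispen_class_shift_invariance(self):
        rng = np.random.default_rng(8)
        u = rng.integers(1, 5, 300)  # classes 1..4 within c=6 alphabet
        params = EntropyParams(m=3, c=6, flavor="fluctuation")
        d1 = pattern_distribution(u, params)
        d2 = pattern_distribution(u + 2, params)
        assert d1.counts == d2.counts

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(10, 200),
        m=st.integers(2, 4),
        c=st.integers(2, 4),
        d=st.integers(1, 2),
        flavor=st.sampled_from(["dispersion", "fluctuation"]),
        seed=st.integers(0, 2**16),
    )
    def test_oracle_equivalence_on_random_class_series(self, n, m, c, d, flavor, seed):
        """Vectorized counts equal a naive recount; entropy equals -sum p ln p;
        counts sum to N - (m-1)d; normalized entropy is in [0, 1]."""
        if n < (m - 1) * d + 1:
            n = (m - 1) * d + 1
        u = np.random.default_rng(seed).integers(1, c + 1, n)
        params = EntropyParams(m=m, c=c, d=d, flavor=flavor)
        dist = pattern_distribution(u, params)
        assert dist.counts == dict(naive_pattern_counts(u, m, c, d, flavor))
        assert sum(dist.counts.values()) == dist.total == n - (m - 1) * d
        h = shannon_entropy(dist)
        expected = -sum(
            (v / dist.total) * math.log(v / dist.total) for v in dist.counts.values()
        )
        assert h == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= h / math.log(dist.space_size) <= 1.0


class TestForbiddenPatterns:
    def test_full_coverage_has_no_forbidden(self):
        u = np.array([1, 1, 2, 2] * 25 + [1]).astype(float)
        observed, forbidden, frac = forbidden_census(
            u, m=2, c=2, mapping="sorting", flavor="dispersion"
        )
        assert forbidden == 0 and frac == 0.0

    def test_false_forbidden_permutations_short_series(self):
        """A six-sample series realizes only 4 of the 6 ordinal patterns."""
        from dispen.baselines import permutation_entropy

        r = permutation_entropy([1, 2, 3, 2.1, 1, 4], m=3)
        assert r.distribution.observed == 4
        assert r.distribution.forbidden == 2

    def test_chaotic_map_forbidden_majority(self):
        x = logistic_map(4.0, 10000, x0=0.23)
        for flavor in ("dispersion", "fluctuation"):
            _, _, frac = forbidden_census(x, m=3, c=6, mapping="logsig", flavor=flavor)
            assert frac > 0.5

    def test_implication_list_for_missing_231(self):
        """Missing ordinal pattern (2,3,1) with c=6 forbids exactly the 20
        strictly-ordered dispersion patterns and their difference images."""
        absent, fluct = forbidden_implication_check((2, 3, 1), 6)
        expected = {
            (2, 3, 1), (2, 4, 1), (2, 5, 1), (2, 6, 1), (3, 4, 1), (3, 5, 1),
            (3, 6, 1), (4, 5, 1), (4, 6, 1), (5, 6, 1), (3, 4, 2), (3, 5, 2),
            (3, 6, 2), (4, 5, 2), (4, 6, 2), (5, 6, 2), (4, 5, 3), (4, 6, 3),
            (5, 6, 3), (5, 6, 4),
        }
        assert set(absent) == expected
        assert len(absent) == 20
        expected_fluct = [
            (1, -2), (2, -3), (3, -4), (4, -5), (1, -3), (2, -4), (3, -5),
            (1, -4), (2, -5), (1, -5), (1, -2), (2, -3), (3, -4), (1, -3),
            (2, -4), (1, -4), (1, -2), (2, -3), (1, -3), (1, -2),
        ]
        assert Counter(fluct) == Counter(expected_fluct)

    @pytest.mark.parametrize("perm", list(itertools.permutations((1, 2, 3))))
    def test_implication_against_bruteforce_small_alphabet(self, perm):
        """With c=2..3 the implied-absent set matches exhaustive enumeration
        of tuples whose strict order realizes the permutation."""
        for c in (2, 3):
            absent, _ = forbidden_implication_check(perm, c)
            brute = []
            for tup in itertools.product(range(1, c + 1), repeat=3):
                # positions sorted by rank must hold strictly increasing values
                by_rank = sorted(range(3), key=lambda i: perm[i])
                vals = [tup[i] for i in by_rank]
                if all(vals[k] < vals[k + 1] for k in range(2)):
                    brute.append(tup)
            assert set(absent) == set(brute)

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            forbidden_implication_check((1, 1, 2), 6)
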