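"""Reference irregularity estimators: PerEn, SampEn, LZC, Hedges' g.

These are the comparators against which dispersion entropy is usually
benchmarked.  Permutation entropy follows the Bandt-Pompe construction
with equalities ranked by order of emergence (stable argsort, no noise
injection).  Sample entropy uses the Chebyshev distance with the tolerance
expressed as a multiple of the signal SD and self-matches excluded; on
short series it can be undefined (zero template matches), which is
reported as an explicit marker rather than a number.  Lempel-Ziv
complexity binarizes at the median and applies the LZ76 exhaustive-history
parse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike

from .core import EntropyParams, EntropyResult, PatternDistribution, embed

__all__ = [
    "MaybeEntropy",
    "permutation_entropy",
    "sample_entropy",
    "lempel_ziv_complexity",
    "hedges_g",
]


@dataclass(frozen=True)
class MaybeEntropy:
    """A sample-entropy value, or an explicit undefined marker with reason."""

    value: float | None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def __float__(self) -> float:
        return self.value if self.value is not None else math.nan


def permutation_entropy(x: ArrayLike, m: int = 3, d: int = 1) -> EntropyResult:
    """Permutation entropy: Shannon entropy of ordinal patterns.

    Each embedded vector is reduced to the permutation that sorts it; ties
    are broken by order of emergence, so ``(1, 2, 2)`` and ``(1, 2, 3)``
    produce the same ordinal pattern.  Normalized by ``ln(m!)``.
    """
    x = np.asarray(x, dtype=float)
    vectors = embed(x, m, d)
    # stable argsort: equal values keep left-to-right emergence order
    patterns = np.argsort(vectors, axis=1, kind="stable")
    keys = patterns @ (m ** np.arange(m - 1, -1, -1, dtype=np.int64))
    uniq, cnt = np.unique(keys, return_counts=True)
    total = vectors.shape[0]
    p = cnt / total
    raw = float(-np.sum(p * np.log(p)))

    def decode(key: int) -> tuple[int, ...]:
        digits = []
        for _ in range(m):
            key, r = divmod(key, m)
            digits.append(r)
        return tuple(reversed(digits))

    dist = PatternDistribution(
        flavor="dispersion",
        counts={decode(int(k)): int(n) for k, n in zip(uniq, cnt)},
        total=total,
        space_size=math.factorial(m),
    )
    params = EntropyParams(m=m, c=2, d=d, mapping="sorting")
    return EntropyResult(
        raw=raw, normalized=raw / math.log(math.factorial(m)), params=params,
        distribution=dist,
    )


def sample_entropy(x: ArrayLike, m: int = 2, r: float = 0.2) -> MaybeEntropy:
    """Sample entropy with Chebyshev distance and tolerance ``r * SD``.

    ``-ln(A / B)`` where B counts ordered template pairs (self-matches
    excluded) of length ``m`` within tolerance, and A the pairs that remain
    within tolerance at length ``m + 1``.  Returns an undefined marker when
    either count is zero (typical for short series) or when the signal SD
    is zero.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {n}")
    sd = x.std()
    if sd == 0.0:
        return MaybeEntropy(None, "zero standard deviation")
    tol = r * sd

    # Chebyshev template distances as running maxima over shifted diagonals
    # of the sample-wise |x_i - x_j| matrix; m-templates are truncated to
    # the n-m starting points shared with the (m+1)-templates.
    d0 = np.abs(x[:, None] - x[None, :])
    nt = n - m
    dist_m = d0[:nt, :nt].copy()
    for k in range(1, m):
        np.maximum(dist_m, d0[k : k + nt, k : k + nt], out=dist_m)
    b = int((np.count_nonzero(dist_m <= tol) - nt) // 2)
    np.maximum(dist_m, d0[m : m + nt, m : m + nt], out=dist_m)
    a = int((np.count_nonzero(dist_m <= tol) - nt) // 2)
    if b == 0:
        return MaybeEntropy(None, "no template matches at length m")
    if a == 0:
        return MaybeEntropy(None, "no template matches at length m+1")
    return MaybeEntropy(-math.log(a / b))


def _lz76_count(bits: np.ndarray) -> int:
    """LZ76 exhaustive-history phrase count of a binary sequence."""
    s = bits.tolist()
    n = len(s)
    count = 1
    i, k, l = 0, 1, 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                count += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                count += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return count


def lempel_ziv_complexity(x: ArrayLike) -> tuple[int, float]:
    """Median-binarized LZ76 complexity.

    The signal is symbolized as ``x_j >= median -> 1 else 0`` and parsed
    with the LZ76 exhaustive history.  Returns the raw phrase count
    ``c(n)`` and the normalized value ``c(n) log2(n) / n``, which tends to
    1 for an i.i.d. equiprobable binary source.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    bits = (x >= np.median(x)).astype(np.int8)
    raw = _lz76_count(bits)
    return raw, raw * math.log2(n) / n


def hedges_g(group_a: ArrayLike, group_b: ArrayLike) -> float:
    """Hedges' g: bias-corrected standardized mean difference.

    ``g = J (mean_a - mean_b) / s_pooled`` with the pooled SD from the two
    sample variances (n-1 weights) and small-sample correction
    ``J = 1 - 3 / (4 (n_a + n_b) - 9)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    s_pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if s_pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled standard deviation with unequal means")
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return j * (a.mean() - b.mean()) / s_pooled
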