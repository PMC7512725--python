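"""Dispersion patterns, DispEn / FDispEn, and forbidden-pattern analysis.

A class series ``u`` (alphabet ``1..c``) is embedded into overlapping
vectors ``(u_i, u_{i+d}, ..., u_{i+(m-1)d})``.  Each vector is a
*dispersion pattern*; its vector of adjacent differences is the
corresponding *fluctuation-based dispersion pattern*, which ranges over
``-(c-1)..(c-1)`` per element.  Dispersion entropy (DispEn) is the Shannon
entropy (natural log) of the empirical pattern distribution, normalized by
``ln(c^m)``; fluctuation-based dispersion entropy (FDispEn) is defined
analogously on difference patterns with pattern space ``(2c-1)^(m-1)``.

Patterns that never occur are *forbidden*.  An unconstrained stochastic
source eventually visits every pattern, whereas deterministic maps exclude
a persistent fraction of the pattern space, so the forbidden fraction is a
determinism marker.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .mapping import MappingSpec, map_to_classes

__all__ = [
    "EntropyParams",
    "PatternDistribution",
    "EntropyResult",
    "embed",
    "to_fluctuation",
    "pattern_distribution",
    "shannon_entropy",
    "dispen",
    "fdispen",
    "forbidden_census",
    "forbidden_implication_check",
]

Flavor = Literal["dispersion", "fluctuation"]


@dataclass(frozen=True)
class EntropyParams:
    """Embedding and coarse-graining parameters for DispEn / FDispEn.

    Defaults follow the recommendations that proved least noise-sensitive
    on benchmark signals: m=2 with c=6 for DispEn; FDispEn is typically run
    with m=3 (its patterns have length m-1) and c=5 or 6.
    """

    m: int = 2
    c: int = 6
    d: int = 1
    mapping: str = "logsig"
    flavor: Flavor = "dispersion"
    theoretical_range: bool = True

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.d < 1:
            raise ValueError("time delay d must be >= 1")
        if self.flavor not in ("dispersion", "fluctuation"):
            raise ValueError(f"unknown flavor: {self.flavor}")

    @property
    def mapping_spec(self) -> MappingSpec:
        return MappingSpec(self.mapping, self.c, self.theoretical_range)

    @property
    def pattern_space_size(self) -> int:
        if self.flavor == "dispersion":
            return self.c**self.m
        return (2 * self.c - 1) ** (self.m - 1)


@dataclass
class PatternDistribution:
    """Empirical distribution over dispersion or fluctuation patterns."""

    flavor: Flavor
    counts: dict[tuple[int, ...], int]
    total: int
    space_size: int

    @property
    def probabilities(self) -> dict[tuple[int, ...], float]:
        return {k: v / self.total for k, v in self.counts.items()}

    @property
    def observed(self) -> int:
        return len(self.counts)

    @property
    def forbidden(self) -> int:
        return self.space_size - len(self.counts)


@dataclass
class EntropyResult:
    """Raw and normalized entropy plus the pattern census behind them."""

    raw: float
    normalized: float
    params: EntropyParams
    distribution: PatternDistribution = field(repr=False)

    @property
    def observed_patterns(self) -> int:
        return self.distribution.observed

    @property
    def forbidden_patterns(self) -> int:
        return self.distribution.forbidden


def embed(u: ArrayLike, m: int, d: int = 1) -> NDArray[np.int64]:
    """Delay-embed a series into its ``N - (m-1)d`` overlapping m-vectors.

    Row ``i`` (0-based) is ``(u_i, u_{i+d}, ..., u_{i+(m-1)d})``.
    """
    u = np.asarray(u)
    n = u.shape[0]
    n_vec = n - (m - 1) * d
    if n_vec < 1:
        raise ValueError(
            f"series of length {n} too short for embedding (m={m}, d={d}): "
            f"need at least {(m - 1) * d + 1} samples"
        )
    idx = np.arange(n_vec)[:, None] + d * np.arange(m)[None, :]
    return u[idx]


def to_fluctuation(pattern: ArrayLike) -> tuple[int, ...]:
    """Adjacent differences of a dispersion pattern, e.g. (1,3,4) -> (2,1)."""
    p = np.asarray(pattern)
    if p.shape[-1] < 2:
        raise ValueError("fluctuation patterns require m >= 2")
    return tuple(int(v) for v in np.diff(p))


def _encode(vectors: NDArray[np.int64], c: int, flavor: Flavor) -> NDArray[np.int64]:
    """Mixed-radix integer key per pattern vector (O(N) counting)."""
    if flavor == "fluctuation":
        vectors = np.diff(vectors, axis=1) + (c - 1)  # shift to 0..2c-2
        base = 2 * c - 1
    else:
        vectors = vectors - 1  # shift to 0..c-1
        base = c
    width = vectors.shape[1]
    weights = base ** np.arange(width - 1, -1, -1, dtype=np.int64)
    return vectors @ weights


def _decode(key: int, base: int, width: int, offset: int) -> tuple[int, ...]:
    digits = []
    for _ in range(width):
        key, r = divmod(key, base)
        digits.append(r + offset)
    return tuple(reversed(digits))


def pattern_distribution(u: ArrayLike, params: EntropyParams) -> PatternDistribution:
    """Count dispersion or fluctuation patterns of a class series.

    Counts sum to ``N - (m-1)d``; probabilities are relative frequencies.
    """
    vectors = embed(u, params.m, params.d)
    keys = _encode(vectors, params.c, params.flavor)
    uniq, cnt = np.unique(keys, return_counts=True)
    if params.flavor == "fluctuation":
        base, width, offset = 2 * params.c - 1, params.m - 1, -(params.c - 1)
    else:
        base, width, offset = params.c, params.m, 1
    counts = {
        _decode(int(k), base, width, offset): int(n) for k, n in zip(uniq, cnt)
    }
    return PatternDistribution(
        flavor=params.flavor,
        counts=counts,
        total=int(vectors.shape[0]),
        space_size=params.pattern_space_size,
    )


def shannon_entropy(dist: PatternDistribution) -> float:
    """Shannon entropy (nats) of the pattern distribution, 0 ln 0 := 0."""
    p = np.fromiter(dist.counts.values(), dtype=float) / dist.total
    return float(-np.sum(p * np.log(p)))


def _entropy(x: ArrayLike, params: EntropyParams) -> EntropyResult:
    u = map_to_classes(x, params.mapping_spec)
    dist = pattern_distribution(u, params)
    raw = shannon_entropy(dist)
    return EntropyResult(
        raw=raw,
        normalized=raw / math.log(params.pattern_space_size),
        params=params,
        distribution=dist,
    )


def dispen(
    x: ArrayLike,
    m: int = 2,
    c: int = 6,
    d: int = 1,
    mapping: str = "logsig",
    **kwargs,
) -> EntropyResult:
    """Dispersion entropy of a signal.

    Pipeline: map to classes -> count m-length dispersion patterns ->
    Shannon entropy; ``normalized = raw / ln(c^m)``.

    Examples
    --------
    >>> r = dispen([3.6, 4.2, 1.2, 3.1, 4.2, 2.1, 3.3, 4.6, 6.8, 8.4],
    ...            m=2, c=3, mapping="linear")
    >>> round(r.raw, 4)
    1.7351
    """
    params = EntropyParams(m=m, c=c, d=d, mapping=mapping, flavor="dispersion", **kwargs)
    return _entropy(x, params)


def fdispen(
    x: ArrayLike,
    m: int = 3,
    c: int = 5,
    d: int = 1,
    mapping: str = "logsig",
    **kwargs,
) -> EntropyResult:
    """Fluctuation-based dispersion entropy of a signal.

    As :func:`dispen` but on adjacent-difference patterns; ``normalized =
    raw / ln((2c-1)^(m-1))``.  Shift-invariant in class space: class series
    differing by a constant integer offset give identical values.
    """
    params = EntropyParams(m=m, c=c, d=d, mapping=mapping, flavor="fluctuation", **kwargs)
    return _entropy(x, params)


def forbidden_census(
    x: ArrayLike,
    m: int = 3,
    c: int = 6,
    d: int = 1,
    mapping: str = "logsig",
    flavor: Flavor = "dispersion",
    **kwargs,
) -> tuple[int, int, float]:
    """Count observed and forbidden patterns of a signal.

    Returns ``(observed, forbidden, normalized_forbidden)`` where
    ``normalized_forbidden = forbidden / pattern_space_size``.
    """
    params = EntropyParams(m=m, c=c, d=d, mapping=mapping, flavor=flavor, **kwargs)
    u = map_to_classes(x, params.mapping_spec)
    dist = pattern_distribution(u, params)
    return dist.observed, dist.forbidden, dist.forbidden / dist.space_size


def forbidden_implication_check(
    missing_permutation: tuple[int, ...], c: int
) -> tuple[list[tuple[int, ...]], list[tuple[int, ...]]]:
    """Dispersion patterns forced absent by a missing ordinal pattern.

    If the ordinal (permutation) pattern given as a 1-based rank vector
    ``(r_1, ..., r_m)`` never occurs in a signal, then no embedded window
    whose class values realize exactly that strict ordering can occur
    either.  Only strictly-ordered class tuples are implied absent: a class
    tuple with ties can arise from underlying real values in more than one
    order, so it is not pinned to the missing permutation.

    Returns the ``C(c, m)`` implied-absent dispersion patterns and their
    fluctuation images (with repetitions, one per dispersion pattern).
    """
    ranks = tuple(missing_permutation)
    m = len(ranks)
    if sorted(ranks) != list(range(1, m + 1)):
        raise ValueError(f"not a 1-based permutation of 1..{m}: {ranks}")
    if c < 2:
        raise ValueError("alphabet size c must be >= 2")
    absent: list[tuple[int, ...]] = []
    for values in itertools.combinations(range(1, c + 1), m):
        # values are sorted ascending; place the k-th smallest at the
        # position holding rank k+1
        pattern = [0] * m
        for pos, r in enumerate(ranks):
            pattern[pos] = values[r - 1]
        absent.append(tuple(pattern))
    absent.sort()
    fluct = [to_fluctuation(p) for p in absent]
    return absent, fluct
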