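"""Signal-to-class coarse-graining.

Entropy estimators in this package operate on a *class series*: the raw
signal mapped to an integer alphabet ``1..c``.  Five mapping schemes are
provided.  ``linear`` stretches the empirical min-max range across the
classes; ``sorting`` assigns classes by rank so each class holds (nearly)
the same number of samples; ``logsig``, ``tansig`` and ``ncdf`` first push
the standardized signal through a sigmoid-shaped transfer function, which
compresses outliers so that extreme samples do not squeeze the bulk of the
data into a couple of classes.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.special import expit, ndtr

__all__ = [
    "MappingKind",
    "MappingSpec",
    "DegenerateSignalWarning",
    "map_logsig",
    "map_tansig",
    "map_ncdf",
    "map_sorting",
    "classify",
    "map_to_classes",
]


class MappingKind(str, enum.Enum):
    """Enumeration of the supported signal-to-class mappings."""

    LINEAR = "linear"
    SORTING = "sorting"
    LOGSIG = "logsig"
    TANSIG = "tansig"
    NCDF = "ncdf"


@dataclass(frozen=True)
class MappingSpec:
    """A mapping scheme together with the alphabet size ``c``.

    Parameters
    ----------
    kind:
        One of ``linear``, ``sorting``, ``logsig``, ``tansig``, ``ncdf``.
    c:
        Number of classes, at least 2.
    theoretical_range:
        For the sigmoid-family maps, use the codomain of the transfer
        function ((0, 1) or (-1, 1)) as the classification range.  Set to
        False to use the empirical (min, max) of the transformed values
        instead.  Ignored for ``linear`` and ``sorting``.
    """

    kind: MappingKind
    c: int
    theoretical_range: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", MappingKind(self.kind))
        if int(self.c) != self.c or self.c < 2:
            raise ValueError(f"number of classes must be an integer >= 2, got {self.c}")
        object.__setattr__(self, "c", int(self.c))


class DegenerateSignalWarning(UserWarning):
    """Raised (as a warning) when a constant signal is coarse-grained."""


def _validate_signal(x: ArrayLike) -> NDArray[np.float64]:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got shape {x.shape}")
    if x.size < 1:
        raise ValueError("signal must contain at least one sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return x


def _standardize(x: NDArray[np.float64]) -> NDArray[np.float64] | None:
    # Population moments (divide by N), matching MATLAB std(x, 1).
    mu = x.mean()
    sigma = x.std()
    if sigma == 0.0:
        return None
    return (x - mu) / sigma


def map_logsig(x: ArrayLike) -> NDArray[np.float64]:
    """Log-sigmoid transfer: ``y = 1 / (1 + exp(-(x - mu) / sigma))``.

    ``mu`` and ``sigma`` are the mean and (population) SD of ``x``; the
    output lies in (0, 1) with ``y(mu) = 0.5``.  Raises on constant input.
    """
    z = _standardize(_validate_signal(x))
    if z is None:
        raise ValueError("logsig mapping undefined for a constant signal (sigma = 0)")
    return expit(z)


def map_tansig(x: ArrayLike) -> NDArray[np.float64]:
    """Tan-sigmoid transfer: ``y = 2 / (1 + exp(-2 (x - mu) / sigma)) - 1``.

    Output in (-1, 1), odd-symmetric about the mean.  Raises on constant
    input.
    """
    z = _standardize(_validate_signal(x))
    if z is None:
        raise ValueError("tansig mapping undefined for a constant signal (sigma = 0)")
    return np.tanh(z)


def map_ncdf(x: ArrayLike) -> NDArray[np.float64]:
    """Normal-CDF transfer: ``y = Phi((x - mu) / sigma)``.

    For Gaussian data this is the probability integral transform, so the
    mapped values are approximately uniform on (0, 1).  Raises on constant
    input.
    """
    z = _standardize(_validate_signal(x))
    if z is None:
        raise ValueError("NCDF mapping undefined for a constant signal (sigma = 0)")
    return ndtr(z)


def classify(
    y: ArrayLike, rng: tuple[float, float], c: int
) -> NDArray[np.int64]:
    """Assign values in ``[alpha, beta]`` to integer classes ``1..c``.

    Each value is placed on the real line as ``z = 0.5 + c (y - alpha) /
    (beta - alpha)`` and rounded half-up, i.e. ``u = floor(z + 0.5)``
    clamped to ``[1, c]``.  The clamp only acts at the exact endpoints
    (``z = 0.5`` maps to class 1, ``z = c + 0.5`` to class ``c``).
    """
    y = np.asarray(y, dtype=float)
    alpha, beta = float(rng[0]), float(rng[1])
    if beta <= alpha:
        raise ValueError(f"invalid classification range: ({alpha}, {beta})")
    z = 0.5 + c * (y - alpha) / (beta - alpha)
    u = np.floor(z + 0.5).astype(np.int64)
    return np.clip(u, 1, c)


def map_sorting(x: ArrayLike, c: int) -> NDArray[np.int64]:
    """Rank-based (equal-occupancy) class assignment.

    Samples are ranked by value, ties broken by order of emergence, and the
    ranked sequence is cut into ``c`` classes of as-equal-as-possible size:
    ``u_j = ceil(r_j * c / n)`` with ``r_j`` the 1-based rank.  The result
    depends only on the ranks, so any strictly increasing transform of the
    signal yields the same class series.
    """
    x = _validate_signal(x)
    n = x.size
    if n < c:
        raise ValueError(f"sorting mapping needs at least c={c} samples, got {n}")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return -(-ranks * c // n)  # ceil division


_MIDDLE_CLASS_NOTE = (
    "constant signal: all samples assigned the middle class; "
    "downstream entropy will be 0"
)


def map_to_classes(x: ArrayLike, spec: MappingSpec) -> NDArray[np.int64]:
    """Coarse-grain a signal into the class series ``u`` with alphabet 1..c.

    Dispatches on ``spec.kind``.  A constant signal (zero SD, or equal min
    and max) cannot be standardized or range-normalized; it is assigned the
    middle class ``floor((c + 1) / 2)`` everywhere, with a
    :class:`DegenerateSignalWarning`, so that a perfectly regular epoch
    yields zero entropy rather than an error.
    """
    x = _validate_signal(x)
    if isinstance(spec, tuple):
        spec = MappingSpec(*spec)
    c = spec.c
    if np.ptp(x) == 0.0:
        warnings.warn(_MIDDLE_CLASS_NOTE, DegenerateSignalWarning, stacklevel=2)
        return np.full(x.size, (c + 1) // 2, dtype=np.int64)

    kind = spec.kind
    if kind is MappingKind.LINEAR:
        return classify(x, (x.min(), x.max()), c)
    if kind is MappingKind.SORTING:
        return map_sorting(x, c)
    if kind is MappingKind.LOGSIG:
        y = map_logsig(x)
        rng = (0.0, 1.0) if spec.theoretical_range else (y.min(), y.max())
    elif kind is MappingKind.TANSIG:
        y = map_tansig(x)
        rng = (-1.0, 1.0) if spec.theoretical_range else (y.min(), y.max())
    elif kind is MappingKind.NCDF:
        y = map_ncdf(x)
        rng = (0.0, 1.0) if spec.theoretical_range else (y.min(), y.max())
    else:  # pragma: no cover
        raise ValueError(f"unknown mapping kind: {kind}")
    if rng[1] == rng[0]:  # empirical range of a non-constant signal cannot collapse
        raise ValueError("degenerate classification range")
    return classify(y, rng, c)
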