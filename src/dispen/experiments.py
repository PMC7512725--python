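"""Benchmark drivers: sweeps, noise-sensitivity ratios, and group contrasts.

Each driver returns a long-format :class:`pandas.DataFrame` (one row per
condition x realization x estimator) so downstream summaries are a
``groupby`` away.  Every realization records the child seed it was
generated with; tables are pure functions of their configuration plus one
master seed.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike

from . import baselines, core, signals
from .baselines import MaybeEntropy

__all__ = [
    "make_estimator",
    "child_seeds",
    "nrm_ent_n",
    "coefficient_of_variation",
    "sliding_entropy_profile",
    "length_sweep",
    "forbidden_fraction_curve",
    "epoch_group_comparison",
]

#: An estimator maps a signal to a float, or None when undefined.
Estimator = Callable[[ArrayLike], float | None]


def make_estimator(name: str, *, normalized: bool = True, **params) -> Estimator:
    """Build an estimator callable by name.

    Names: ``dispen``, ``fdispen`` (keyword args ``m``, ``c``, ``d``,
    ``mapping``), ``peren`` (``m``, ``d``), ``sampen`` (``m``, ``r``),
    ``lzc`` (no parameters).  Entropy estimators report the normalized
    value by default (``normalized=False`` for raw nats); ``sampen``
    returns None where undefined.
    """
    if name == "dispen":
        return lambda x: getattr(core.dispen(x, **params), "normalized" if normalized else "raw")
    if name == "fdispen":
        return lambda x: getattr(core.fdispen(x, **params), "normalized" if normalized else "raw")
    if name == "peren":
        return lambda x: getattr(
            baselines.permutation_entropy(x, **params), "normalized" if normalized else "raw"
        )
    if name == "sampen":
        return lambda x: baselines.sample_entropy(x, **params).value
    if name == "lzc":
        return lambda x: baselines.lempel_ziv_complexity(x, **params)[1 if normalized else 0]
    raise ValueError(f"unknown estimator: {name!r}")


def child_seeds(master_seed: int, k: int) -> list[int]:
    """Derive ``k`` reproducible per-realization seeds from a master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(k, np.uint32)
    return [int(s) % 2**31 for s in state]


def _as_value(v: float | MaybeEntropy | None) -> float | None:
    if isinstance(v, MaybeEntropy):
        return v.value
    return v


def nrm_ent_n(clean: ArrayLike, noisy: ArrayLike, estimator: Estimator) -> float | None:
    """Noise-sensitivity ratio: entropy of the noisy series over the clean one.

    Values near 1 indicate robustness to the added noise.  Raises if the
    clean-series entropy is zero; returns None if either value is
    undefined.
    """
    e_clean = _as_value(estimator(clean))
    e_noisy = _as_value(estimator(noisy))
    if e_clean is None or e_noisy is None:
        return None
    if e_clean == 0.0:
        raise ValueError("clean-series entropy is zero; NrmEntN undefined")
    return e_noisy / e_clean


def coefficient_of_variation(values: ArrayLike) -> float:
    """SD divided by mean (sample SD, n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean == 0.0:
        raise ValueError("zero mean; CV undefined")
    return float(v.std(ddof=1) / mean)


def sliding_entropy_profile(
    x: ArrayLike,
    length: int,
    overlap: float,
    estimator: Estimator,
    estimator_id: str = "entropy",
) -> pd.DataFrame:
    """Entropy in a sliding window of ``length`` samples with given overlap.

    ``step = max(1, round(length * (1 - overlap)))``; the window count is
    ``floor((N - length) / step) + 1``.  Columns: window index, start,
    center (sample index of the window midpoint), estimator id, value.
    """
    x = np.asarray(x, dtype=float)
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    if length > x.size:
        raise ValueError(f"window length {length} exceeds signal length {x.size}")
    step = max(1, round(length * (1.0 - overlap)))
    starts = np.arange(0, x.size - length + 1, step)
    rows = []
    for w, s in enumerate(starts):
        rows.append(
            {
                "window": w,
                "start": int(s),
                "center": int(s) + length // 2,
                "estimator": estimator_id,
                "value": _as_value(estimator(x[s : s + length])),
            }
        )
    return pd.DataFrame(rows)


def length_sweep(
    generator: Callable[[int, int], np.ndarray],
    estimators: Mapping[str, Estimator],
    lengths: Sequence[int],
    n_realizations: int,
    master_seed: int,
) -> pd.DataFrame:
    """Evaluate estimators on seeded realizations across signal lengths.

    ``generator(n, seed)`` produces one realization.  One row per
    (length, realization, estimator); the seed of each realization is
    recorded.  Used for saturation-with-length and noise-color separation
    studies.
    """
    seeds = child_seeds(master_seed, n_realizations)
    rows = []
    for n in lengths:
        for i, seed in enumerate(seeds):
            x = generator(int(n), seed)
            for est_id, est in estimators.items():
                rows.append(
                    {
                        "n": int(n),
                        "realization": i,
                        "seed": seed,
                        "estimator": est_id,
                        "value": _as_value(est(x)),
                    }
                )
    return pd.DataFrame(rows)


def forbidden_fraction_curve(
    lengths: Sequence[int],
    alpha: float = 4.0,
    x0: float = 0.23,
    m: int = 3,
    c: int = 6,
    mapping: str = "logsig",
) -> pd.DataFrame:
    """Normalized forbidden-pattern fraction vs length on the logistic map.

    One fixed trajectory is generated at the longest requested length, and
    the census of dispersion, fluctuation-based dispersion, and
    permutation patterns is taken on its prefixes, so the fraction is
    non-increasing in ``n``.  For a chaotic (deterministic) map the
    fraction stabilizes well above zero; a stochastic full-support source
    would drive it to zero.
    """
    lengths = sorted(int(n) for n in lengths)
    x_full = signals.logistic_map(alpha, lengths[-1], x0=x0)
    rows = []
    for n in lengths:
        x = x_full[:n]
        for flavor in ("dispersion", "fluctuation"):
            if n >= m:  # need at least one embedded vector
                _, _, frac = core.forbidden_census(
                    x, m=m, c=c, mapping=mapping, flavor=flavor
                )
            else:
                frac = 1.0
            rows.append({"n": n, "flavor": flavor, "forbidden_fraction": frac})
        if n >= m:
            peren = baselines.permutation_entropy(x, m=m)
            frac = peren.distribution.forbidden / peren.distribution.space_size
        else:
            frac = 1.0
        rows.append({"n": n, "flavor": "permutation", "forbidden_fraction": frac})
    return pd.DataFrame(rows)


def _epoch_means(
    x: np.ndarray, epoch_length: int, estimators: Mapping[str, Estimator]
) -> tuple[dict[str, float], dict[str, int]]:
    n_epochs = x.size // epoch_length
    if n_epochs < 1:
        raise ValueError(
            f"signal of length {x.size} shorter than one epoch ({epoch_length})"
        )
    values: dict[str, list[float]] = {k: [] for k in estimators}
    undefined: dict[str, int] = {k: 0 for k in estimators}
    for e in range(n_epochs):
        epoch = x[e * epoch_length : (e + 1) * epoch_length]
        for est_id, est in estimators.items():
            v = _as_value(est(epoch))
            if v is None:
                undefined[est_id] += 1
            else:
                values[est_id].append(v)
    means = {
        k: (float(np.mean(v)) if v else float("nan")) for k, v in values.items()
    }
    return means, undefined


def epoch_group_comparison(
    group_a: Sequence[ArrayLike],
    group_b: Sequence[ArrayLike],
    epoch_length: int,
    estimators: Mapping[str, Estimator],
) -> pd.DataFrame:
    """Epoch-averaged entropy contrast between two groups of signals.

    Each signal is cut into non-overlapping epochs (last partial epoch
    dropped), the estimator is averaged over its epochs, and Hedges' g is
    computed between the per-signal means of the two groups.  Undefined
    epoch values (e.g. SampEn on short epochs) are excluded from the means
    and reported in an ``undefined`` count column.
    """
    per_signal: dict[str, dict[str, list[float]]] = {
        k: {"a": [], "b": []} for k in estimators
    }
    undefined_total = {k: 0 for k in estimators}
    for label, group in (("a", group_a), ("b", group_b)):
        for sig in group:
            means, undef = _epoch_means(
                np.asarray(sig, dtype=float), epoch_length, estimators
            )
            for k in estimators:
                per_signal[k][label].append(means[k])
                undefined_total[k] += undef[k]
    rows = []
    for k in estimators:
        rows.append(
            {
                "estimator": k,
                "hedges_g": baselines.hedges_g(per_signal[k]["a"], per_signal[k]["b"]),
                "n_a": len(per_signal[k]["a"]),
                "n_b": len(per_signal[k]["b"]),
                "undefined": undefined_total[k],
            }
        )
    return pd.DataFrame(rows)
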