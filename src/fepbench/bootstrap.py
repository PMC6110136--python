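"""Percentile-bootstrap confidence intervals and inter-source variability.

Resampling draws whole (TKI, mutation) rows with replacement, so paired
experimental/predicted structure is preserved; CIs are plain percentile
intervals (2.5th/97.5th for the default alpha = 0.05) with linear
interpolation between order statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class BootstrapSpec:
    """Number of resamples, interval level and RNG seed."""

    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError(f"n_boot must be >= 1, got {self.n_boot}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class MetricEstimate:
    """A point estimate with a bootstrap percentile interval."""

    name: str
    value: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int
    n_skipped: int = 0  # resamples on which the statistic was undefined

    def __post_init__(self) -> None:
        if self.n_boot > 0 and not (
            self.ci_low <= self.value + 1e-12 and self.value <= self.ci_high + 1e-12
        ):
            # Percentile intervals of a plug-in statistic bracket the point
            # estimate except in pathological cases; surface those loudly.
            raise ValueError(
                f"{self.name}: point {self.value} outside CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )

    def __str__(self) -> str:
        return f"{self.name} = {self.value:.2f} [{self.ci_low:.2f}, {self.ci_high:.2f}]"


def bootstrap_ci(
    statistic: Callable[[Sequence], float | None],
    records: Sequence,
    spec: BootstrapSpec | None = None,
    name: str = "statistic",
    stratify_by: Callable[[object], object] | None = None,
) -> MetricEstimate:
    """Percentile bootstrap of ``statistic`` over resampled records.

    The statistic may return None (not applicable, e.g. sensitivity with no
    resistant records in the resample); such resamples are skipped and
    counted rather than coerced to a number. ``stratify_by`` optionally
    resamples within groups (e.g. per TKI) instead of pooling all rows.
    """
    spec = spec or BootstrapSpec()
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    value = statistic(records)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"{name} is undefined on the full dataset")

    rng = np.random.default_rng(spec.seed)
    n = len(records)
    if stratify_by is not None:
        groups: dict[object, list[int]] = {}
        for i, rec in enumerate(records):
            groups.setdefault(stratify_by(rec), []).append(i)
        index_groups = [np.asarray(ix) for ix in groups.values()]
    stats: list[float] = []
    n_skipped = 0
    for _ in range(spec.n_boot):
        if stratify_by is None:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.concatenate(
                [ix[rng.integers(0, len(ix), size=len(ix))] for ix in index_groups]
            )
        resample = [records[i] for i in idx]
        try:
            s = statistic(resample)
        except (ValueError, ZeroDivisionError):
            s = None
        if s is None or (isinstance(s, float) and math.isnan(s)):
            n_skipped += 1
        else:
            stats.append(float(s))
    if not stats:
        raise ValueError(f"{name} undefined on every bootstrap resample")
    lo, hi = np.percentile(
        stats, [100 * spec.alpha / 2, 100 * (1 - spec.alpha / 2)]
    )
    return MetricEstimate(
        name, float(value), float(lo), float(hi), n, spec.n_boot, n_skipped
    )


def pairwise_rmse(pairs: Sequence[tuple[float, float]]) -> float:
    """RMSE between paired measurements of the same quantity by two sources."""
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("pairs must be non-empty")
    diffs = arr[:, 0] - arr[:, 1]
    return float(np.sqrt(np.mean(diffs**2)))


def sigma_from_pairwise_rmse(rmse: float) -> float:
    """Per-measurement s.d. implied by a between-source RMSE.

    If two measurements of the same quantity each carry independent noise of
    s.d. σ, their difference has s.d. σ√2, so σ = RMSE/√2 (0.81 -> 0.57).
    """
    if rmse < 0:
        raise ValueError(f"rmse must be non-negative, got {rmse}")
    return rmse / math.sqrt(2.0)
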