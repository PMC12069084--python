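"""Standard and stratified non-parametric bootstrap with percentile CIs.

The stratified variant resamples *within* each subcategory, holding every
stratum's resample size fixed at its observed size.  This is the mechanism
that lets sOIM/wsOIM respect an a-priori mixture structure in occurrence
data instead of treating the pooled sample as i.i.d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import OimError, ResamplingError, ValidationError

__all__ = [
    "ResamplePlan",
    "BootstrapDistribution",
    "resample_indices",
    "bootstrap_statistic",
    "percentile_ci",
]


@dataclass(frozen=True)
class ResamplePlan:
    """How to draw one bootstrap resample of ``n`` observations.

    ``mode`` is ``"standard"`` (n uniform draws with replacement) or
    ``"stratified"`` (per-stratum draws with replacement, sizes fixed at the
    observed stratum sizes).  ``strata`` maps stratum label → positional
    indices and must partition ``0..n-1`` in stratified mode.
    """

    mode: str
    strata: "Mapping[str, np.ndarray] | None" = None

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "stratified"):
            raise ValidationError(f"unknown resampling mode {self.mode!r}")
        if self.mode == "stratified" and not self.strata:
            raise ValidationError("stratified mode requires strata")

    def validate(self, n: int) -> None:
        if self.mode != "stratified":
            return
        sizes = [len(np.asarray(ix)) for ix in self.strata.values()]
        if any(s == 0 for s in sizes):
            empty = [k for k, ix in self.strata.items() if len(np.asarray(ix)) == 0]
            raise ResamplingError(f"empty stratum/strata {empty}")
        allix = np.concatenate([np.asarray(ix) for ix in self.strata.values()])
        if len(allix) != n or not np.array_equal(np.sort(allix), np.arange(n)):
            raise ResamplingError("strata must cover all indices exactly once")


@dataclass
class BootstrapDistribution:
    """``B`` replicates of a statistic, in the statistic's units."""

    values: np.ndarray
    statistic_label: str = ""
    seed: "int | None" = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValidationError("replicate vector must be 1-d and non-empty")

    @property
    def B(self) -> int:
        return int(self.values.size)


def resample_indices(n: int, plan: ResamplePlan, rng: np.random.Generator) -> np.ndarray:
    """Draw one resample of indices ``0..n-1`` according to ``plan``.

    Stratified draws are concatenated in the plan's stratum order, so
    positions within the output preserve stratum membership.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if plan.mode == "standard":
        return rng.integers(0, n, size=n)
    plan.validate(n)
    parts = []
    for ix in plan.strata.values():
        ix = np.asarray(ix)
        parts.append(ix[rng.integers(0, len(ix), size=len(ix))])
    return np.concatenate(parts)


def bootstrap_statistic(
    data: np.ndarray,
    stat: Callable[[np.ndarray], float],
    B: int,
    plan: "ResamplePlan | None" = None,
    seed: "int | None" = None,
    rng: "np.random.Generator | None" = None,
) -> BootstrapDistribution:
    """``B`` independent bootstrap replicates of ``stat`` over ``data``.

    Reproducible given ``seed`` (or an externally managed ``rng``).
    """
    data = np.asarray(data, dtype=float)
    if B < 1:
        raise ValidationError("B must be >= 1")
    if plan is None:
        plan = ResamplePlan("standard")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(data)
    plan.validate(n)
    out = np.empty(B, dtype=float)
    for b in range(B):
        idx = resample_indices(n, plan, rng)
        try:
            out[b] = stat(data[idx])
        except Exception as exc:  # pragma: no cover - propagation path
            raise OimError(f"statistic failed on replicate {b}: {exc}") from exc
    label = getattr(stat, "__name__", "statistic")
    return BootstrapDistribution(out, statistic_label=label, seed=seed)


def percentile_ci(
    dist: "BootstrapDistribution | np.ndarray", level: float
) -> tuple[float, float]:
    """Percentile-method confidence interval at confidence ``level``.

    Returns the ``(1-level)/2`` and ``1-(1-level)/2`` empirical quantiles of
    the replicates, with linear interpolation between order statistics.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    values = dist.values if isinstance(dist, BootstrapDistribution) else np.asarray(dist)
    if values.size < 2:
        raise ValidationError("need at least 2 replicates for a percentile CI")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)
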