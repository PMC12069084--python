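"""Chronic dietary exposure estimation: OIM, sOIM and wsOIM.

The Observed Individual Means (OIM) family estimates chronic exposure by
combining each individual's mean daily consumption and body weight with the
category mean contaminant occurrence:

    exposure_i = Σ_c  consumption_i(c) [g/day] · mean_occ(c) [μg/g] / bw_i [kg]

in μg/kg bw/day.  The three variants differ only in how the occurrence side
is summarized and resampled:

* **OIM** — pooled arithmetic mean occurrence; standard bootstrap.
* **sOIM** — pooled mean; *stratified* bootstrap by subcategory (resample
  sizes fixed at observed stratum sizes).
* **wsOIM** — weighted mean of subcategory means, Σ_s w_s·mean_s, with a
  stratified bootstrap; ``w`` is either consumption-derived (wsOIM*) or a
  hypothetical sensitivity scenario (wsOIM°).

Deterministic Estimates (DEs) come from the original data; Probabilistic
Estimates (PEs) are percentile-method bootstrap confidence intervals built
from B paired resamples of consumers (standard bootstrap over individuals)
and occurrence data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bootstrap import ResamplePlan, percentile_ci, resample_indices
from .errors import (
    DegenerateWeightsError,
    MatchError,
    MissingOccurrenceError,
    StrataError,
    ValidationError,
)
from .io import ConsumerRecord, ConsumerTable, OccurrenceTable, WeightScheme

__all__ = [
    "MethodSpec",
    "ExposureEstimate",
    "mean_occurrence",
    "consumption_aware_weights",
    "individual_exposure",
    "deterministic_estimate",
    "probabilistic_estimate",
]

UNITS = "ug/kg bw/day"
DEFAULT_PROBS = (0.5, 0.95)  # median and the 95th-percentile upper tail (UTP)


@dataclass(frozen=True)
class MethodSpec:
    """Which estimator to run.

    ``weights`` is required for wsOIM (a :class:`WeightScheme`, or a mapping
    category → scheme when several categories are assessed) and must be
    absent otherwise.  The occurrence resampling mode is derived: standard
    for OIM, stratified for sOIM and wsOIM.
    """

    name: str
    weights: "WeightScheme | Mapping[str, WeightScheme] | None" = None

    def __post_init__(self) -> None:
        if self.name not in ("OIM", "sOIM", "wsOIM"):
            raise ValidationError(f"unknown method {self.name!r}")
        if self.name == "wsOIM" and self.weights is None:
            raise ValidationError("wsOIM requires a WeightScheme")
        if self.name != "wsOIM" and self.weights is not None:
            raise ValidationError(f"{self.name} does not take weights")

    @property
    def resample_mode(self) -> str:
        return "standard" if self.name == "OIM" else "stratified"

    @property
    def scheme_label(self) -> str:
        if isinstance(self.weights, WeightScheme):
            return self.weights.label
        if self.weights:
            return "+".join(s.label for s in self.weights.values())
        return ""

    def scheme_for(self, category: str) -> WeightScheme:
        if isinstance(self.weights, WeightScheme):
            return self.weights
        if self.weights is None or category not in self.weights:
            raise StrataError(f"no weight scheme for category {category!r}")
        return self.weights[category]


@dataclass(eq=False)
class ExposureEstimate:
    """Deterministic percentiles of exposure, optionally with bootstrap CIs.

    ``de`` maps probability → exposure percentile (μg/kg bw/day) from the
    original data; ``ci`` maps probability → (lower, upper) percentile-method
    bounds, or is None for a deterministic-only estimate.  A percentile CI
    need not bracket the DE; only lower ≤ upper is guaranteed.
    """

    method: str
    scheme: str
    probs: tuple[float, ...]
    de: dict[float, float]
    ci: "dict[float, tuple[float, float]] | None" = None
    level: "float | None" = None
    B: int = 0
    seed_consumers: "int | None" = None
    seed_occurrence: "int | None" = None
    ecdf_x: "np.ndarray | None" = None
    ecdf_p: "np.ndarray | None" = None
    mean_occ_replicates: "dict[str, np.ndarray] | None" = None
    units: str = UNITS

    def __post_init__(self) -> None:
        ps = sorted(self.de)
        des = [self.de[p] for p in ps]
        if any(b < a for a, b in zip(des, des[1:])):
            raise ValidationError("DE percentiles must be non-decreasing in p")
        if self.ci is not None:
            for p, (lo, hi) in self.ci.items():
                if lo > hi:
                    raise ValidationError(f"CI lower > upper at p={p}")

    @property
    def utp(self) -> float:
        """The 95th-percentile DE (Upper Tail Percentile)."""
        return self.de[0.95]

    def ci_width(self, prob: float = 0.95) -> float:
        if self.ci is None:
            raise ValidationError("estimate has no confidence intervals")
        lo, hi = self.ci[prob]
        return hi - lo

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "scheme": self.scheme,
            "units": self.units,
            "B": self.B,
            "level": self.level,
            "seed_consumers": self.seed_consumers,
            "seed_occurrence": self.seed_occurrence,
            "probs": list(self.probs),
            "de": {repr(p): self.de[p] for p in self.probs},
            "ci": (
                None
                if self.ci is None
                else {repr(p): list(self.ci[p]) for p in self.probs}
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExposureEstimate":
        probs = tuple(float(p) for p in d["probs"])
        de = {float(p): float(v) for p, v in d["de"].items()}
        ci = None
        if d.get("ci") is not None:
            ci = {float(p): (float(v[0]), float(v[1])) for p, v in d["ci"].items()}
        return cls(
            method=d["method"],
            scheme=d.get("scheme", ""),
            probs=probs,
            de=de,
            ci=ci,
            level=d.get("level"),
            B=int(d.get("B") or 0),
            seed_consumers=d.get("seed_consumers"),
            seed_occurrence=d.get("seed_occurrence"),
            units=d.get("units", UNITS),
        )


# ---------------------------------------------------------------------------
# occurrence summaries


def _stratum_means(table: OccurrenceTable) -> "tuple[list[str], np.ndarray]":
    vals = table.values()
    labels, means = [], []
    for s, ix in table.strata.items():
        labels.append(s)
        means.append(vals[ix].mean())
    return labels, np.asarray(means)


def mean_occurrence(table: OccurrenceTable, method: MethodSpec) -> dict[str, float]:
    """Category-level mean occurrence (μg/g) under ``method``.

    OIM and sOIM use the pooled arithmetic mean of all values in the
    category; wsOIM uses Σ_s w_s · mean_s over subcategory means.  The
    weight scheme's key set must equal the category's strata.
    """
    out: dict[str, float] = {}
    for cat in table.categories:
        sub = table.subset(cat)
        if method.name in ("OIM", "sOIM"):
            out[cat] = float(sub.values().mean())
        else:
            scheme = method.scheme_for(cat)
            labels, means = _stratum_means(sub)
            w = scheme.as_vector(labels)
            out[cat] = float(w @ means)
    return out


def consumption_aware_weights(consumers: ConsumerTable, category: str) -> WeightScheme:
    """The wsOIM* weighting scheme: each subcategory's relative contribution
    to total mean daily consumption of the category.

    ``w_s`` = (across-subject total mean daily consumption of s) / (category
    total); weights sum to 1 by construction.
    """
    totals = consumers.subcategory_totals(category)
    grand = float(totals.sum())
    if grand <= 0:
        raise DegenerateWeightsError(f"zero total consumption for {category!r}")
    return WeightScheme({str(s): float(v) / grand for s, v in totals.items()},
                        label="w*")


def individual_exposure(
    consumer: ConsumerRecord, mean_occ: Mapping[str, float]
) -> float:
    """One individual's chronic exposure in μg/kg bw/day."""
    if consumer.body_weight <= 0:
        raise ValidationError("body weight must be positive")
    total = 0.0
    by_cat: dict[str, float] = {}
    for (cat, _), amount in consumer.intake.items():
        by_cat[cat] = by_cat.get(cat, 0.0) + amount
    for cat, amount in by_cat.items():
        if amount == 0.0:
            continue
        if cat not in mean_occ:
            raise MissingOccurrenceError(
                f"no mean occurrence for consumed category {cat!r}"
            )
        total += amount * mean_occ[cat]
    return total / consumer.body_weight


# ---------------------------------------------------------------------------
# estimates


def _check_match(consumers: ConsumerTable, occurrence: OccurrenceTable) -> list[str]:
    """Categories to assess; errors if consumption and occurrence don't match."""
    occ_cats = set(occurrence.categories)
    consumed = [
        c for c in consumers.categories if consumers.category_intake(c).sum() > 0
    ]
    if not set(consumed) & occ_cats:
        raise MatchError(
            f"no overlap between consumed categories {consumed} and occurrence "
            f"categories {sorted(occ_cats)}"
        )
    missing = [c for c in consumed if c not in occ_cats]
    if missing:
        raise MissingOccurrenceError(
            f"consumed categories without occurrence data: {missing}"
        )
    return consumed


def _exposure_vector(
    intake: np.ndarray, bw: np.ndarray, occ: np.ndarray
) -> np.ndarray:
    """intake (n×K, g/day) · occ (K, μg/g) / bw (n, kg) → μg/kg bw/day."""
    return (intake @ occ) / bw


def deterministic_estimate(
    consumers: ConsumerTable,
    occurrence: OccurrenceTable,
    method: MethodSpec,
    probs: Sequence[float] = DEFAULT_PROBS,
) -> ExposureEstimate:
    """Deterministic Estimate: exposure percentiles from the original data.

    Computes the method's mean occurrence, each individual's exposure, and
    the requested percentiles (linear-interpolation quantiles) plus the full
    eCDF.  Defaults include 0.95, the upper tail percentile used for risk
    characterization.
    """
    probs = tuple(float(p) for p in probs)
    if any(not 0 <= p <= 1 for p in probs):
        raise ValidationError("probabilities must lie in [0, 1]")
    cats = _check_match(consumers, occurrence)
    occ = mean_occurrence(occurrence, method)
    intake = np.column_stack([consumers.category_intake(c) for c in cats])
    occvec = np.array([occ[c] for c in cats])
    expo = _exposure_vector(intake, consumers.body_weights(), occvec)
    de = {p: float(np.quantile(expo, p, method="linear")) for p in probs}
    x = np.sort(expo)
    return ExposureEstimate(
        method=method.name,
        scheme=method.scheme_label,
        probs=probs,
        de=de,
        ecdf_x=x,
        ecdf_p=np.arange(1, len(x) + 1) / len(x),
    )


def _occurrence_replicate(
    values: np.ndarray,
    strata: "dict[str, np.ndarray]",
    method: MethodSpec,
    category: str,
    rng: np.random.Generator,
) -> float:
    """One bootstrap mean-occurrence replicate for one category."""
    n = len(values)
    if method.name == "OIM":
        idx = rng.integers(0, n, size=n)
        return float(values[idx].mean())
    labels = list(strata)
    means = np.empty(len(labels))
    sizes = np.empty(len(labels))
    for j, s in enumerate(labels):
        ix = strata[s]
        if len(ix) == 0:
            raise StrataError(f"empty stratum {s!r}")
        draw = ix[rng.integers(0, len(ix), size=len(ix))]
        means[j] = values[draw].mean()
        sizes[j] = len(ix)
    if method.name == "sOIM":
        return float((sizes * means).sum() / sizes.sum())
    w = method.scheme_for(category).as_vector(labels)
    return float(w @ means)


def probabilistic_estimate(
    consumers: ConsumerTable,
    occurrence: OccurrenceTable,
    method: MethodSpec,
    B: int = 1000,
    level: float = 0.95,
    probs: Sequence[float] = DEFAULT_PROBS,
    seeds: tuple[int, int] = (0, 1),
    keep_mean_occ: bool = False,
) -> ExposureEstimate:
    """Probabilistic Estimate: percentile-method bootstrap CIs for exposure
    percentiles.

    Consumers are resampled with the standard bootstrap (variability of
    daily consumption and body weight); occurrence values are resampled
    independently — standard for OIM, stratified by subcategory otherwise —
    and replicate ``b`` of consumers is combined with mean-occurrence
    replicate ``b``.  The two bootstrap streams are seeded separately by
    ``seeds = (consumer_seed, occurrence_seed)``.  The DE comes from the
    original data.
    """
    if B < 2:
        raise ValidationError("B must be >= 2 for probabilistic estimates")
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must be in (0, 1)")
    de_est = deterministic_estimate(consumers, occurrence, method, probs)
    probs = de_est.probs
    cats = _check_match(consumers, occurrence)
    intake = np.column_stack([consumers.category_intake(c) for c in cats])
    bw = consumers.body_weights()
    n = consumers.n_subjects

    per_cat = {}
    for c in cats:
        sub = occurrence.subset(c)
        per_cat[c] = (sub.values(), sub.strata)
        if method.name == "wsOIM":  # fail fast on a scheme/strata mismatch
            method.scheme_for(c).as_vector(list(sub.strata))

    crng = np.random.default_rng(seeds[0])
    orng = np.random.default_rng(seeds[1])
    reps = np.empty((B, len(probs)))
    occ_reps = {c: np.empty(B) for c in cats} if keep_mean_occ else None
    occvec = np.empty(len(cats))
    for b in range(B):
        cidx = crng.integers(0, n, size=n)
        for j, c in enumerate(cats):
            values, strata = per_cat[c]
            occvec[j] = _occurrence_replicate(values, strata, method, c, orng)
            if occ_reps is not None:
                occ_reps[c][b] = occvec[j]
        expo = _exposure_vector(intake[cidx], bw[cidx], occvec)
        reps[b] = np.quantile(expo, probs, method="linear")

    ci = {
        p: percentile_ci(reps[:, j], level) for j, p in enumerate(probs)
    }
    return ExposureEstimate(
        method=method.name,
        scheme=method.scheme_label,
        probs=probs,
        de=de_est.de,
        ci=ci,
        level=level,
        B=B,
        seed_consumers=seeds[0],
        seed_occurrence=seeds[1],
        ecdf_x=de_est.ecdf_x,
        ecdf_p=de_est.ecdf_p,
        mean_occ_replicates=occ_reps,
    )
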