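"""Synthetic occurrence and consumption data for the 3-MCPD case study.

Occurrence generation follows the case-study design for 3-monochloropropane-
1,2-diol (3-MCPD) in vegetable oils, with three subcategories:

* Seed Oils (SO):            C_SO   ~ lognormal(μ̂ = −1.48, sdlog 1)
* Olive Oil (OO):            C_OO   ~ lognormal(α, sdlog 1) with
  α = log(1.5 + exp(μ̂)), i.e. the OO median sits 1.5 μg/g above the SO
  median (refined pulp-fruit oils are expected to be more contaminated).
* Extra-Virgin Olive Oil:    C_EVOO ~ lognormal(log(LOD), sdlog 1) with
  LOD = 0.035 μg/g, so half the draws fall below LOD (EVOO is unrefined and
  essentially uncontaminated).

Values below LOD are flagged censored and, under the default middle-bound
scenario, substituted by LOD/2.  The σ̂ = 1.20 recorded in the config is the
*fitted* sdlog of the real seed-oil samples and is used by fitting tests; the
generating sdlog is 1 for all strata.

The consumption generator is a synthetic stand-in for an adult national
dietary survey (per-individual mean daily vegetable-oil consumption split
across the three subcategories, adult body weights); it does not emulate any
real survey's sampling design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ConsumerTable, OccurrenceTable, WeightScheme

__all__ = [
    "SimulationConfig",
    "ConsumptionProfile",
    "simulate_occurrence",
    "simulate_consumers",
    "seed_oil_fixture",
    "SEED_OIL_COUNTS",
    "SEED_OIL_STRATUM_MAP",
]

CATEGORY = "Vegetable oil"
STRATA = ("SO", "OO", "EVOO")

#: sample counts of the real seed-oil convenience sample the fixture emulates
SEED_OIL_COUNTS = {
    "corn oil": 3,
    "mixed seeds oil": 2,
    "peanut oil": 3,
    "rice oil": 1,
    "soybean oil": 1,
    "sunflower oil": 4,
}

#: collapses fine oil-type labels into the three resampling strata
SEED_OIL_STRATUM_MAP = {
    "corn oil": "SO",
    "flaxseed oil": "SO",
    "mixed seeds oil": "SO",
    "peanut oil": "SO",
    "rice oil": "SO",
    "soybean oil": "SO",
    "sunflower oil": "SO",
    "olive oil": "OO",
    "extra virgin olive oil": "EVOO",
}


def _default_weight_schemes() -> dict[str, WeightScheme]:
    return {
        "w_SO": WeightScheme({"SO": 0.8, "OO": 0.1, "EVOO": 0.1}, label="w_SO"),
        "w_OO": WeightScheme({"SO": 0.1, "OO": 0.8, "EVOO": 0.1}, label="w_OO"),
        "w_EVOO": WeightScheme({"SO": 0.1, "OO": 0.1, "EVOO": 0.8}, label="w_EVOO"),
        "w_star": WeightScheme({"SO": 0.07, "OO": 0.77, "EVOO": 0.16}, label="w*"),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All symbols of the simulation study in one place.

    ``mu_hat``/``sigma_hat`` are the fitted lognormal parameters of the
    seed-oil occurrence sample (meanlog scale); ``gen_sdlog`` is the sdlog
    actually used to *generate* occurrence values (1 for every stratum);
    ``alpha`` is derived, never stored.  ``tdi`` is the health-based
    guidance value (μg/kg bw/day) used for risk characterization.
    """

    mu_hat: float = -1.48
    sigma_hat: float = 1.20
    gen_sdlog: float = 1.0
    lod: float = 0.035
    n_per_stratum: int = 1000
    n_datasets: int = 1000
    B: int = 1000
    tdi: float = 2.0
    category: str = CATEGORY
    strata: tuple[str, ...] = STRATA
    weight_schemes: Mapping[str, WeightScheme] = field(
        default_factory=_default_weight_schemes
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lod <= 0 or self.gen_sdlog <= 0:
            raise ValidationError("lod and gen_sdlog must be positive")
        if min(self.n_per_stratum, self.n_datasets, self.B) < 1:
            raise ValidationError("counts must be positive")
        for scheme in self.weight_schemes.values():
            if set(scheme.weights) != set(self.strata):
                raise ValidationError(
                    f"scheme {scheme.label!r} keys do not match strata {self.strata}"
                )

    @property
    def alpha(self) -> float:
        """Meanlog of the OO stratum: log(1.5 + exp(mu_hat))."""
        return float(np.log(1.5 + np.exp(self.mu_hat)))

    @property
    def meanlogs(self) -> dict[str, float]:
        return {
            "SO": self.mu_hat,
            "OO": self.alpha,
            "EVOO": float(np.log(self.lod)),
        }


def _as_rng(seed: "int | np.random.Generator") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_occurrence(
    config: SimulationConfig,
    rng_seed: "int | np.random.Generator" = 0,
    substitute: bool = True,
) -> OccurrenceTable:
    """One simulated occurrence dataset (``n_per_stratum`` values per stratum).

    Draws below LOD are flagged censored; with ``substitute=True`` (the
    middle-bound default) their values are replaced by LOD/2.  The
    substitution rule is applied uniformly to all strata.
    """
    rng = _as_rng(rng_seed)
    frames = []
    for s in config.strata:
        raw = rng.lognormal(
            mean=config.meanlogs[s], sigma=config.gen_sdlog, size=config.n_per_stratum
        )
        censored = raw < config.lod
        value = np.where(censored, config.lod / 2.0, raw) if substitute else raw
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": [f"{s}-{i:06d}" for i in range(len(raw))],
                    "category": config.category,
                    "subcategory": s,
                    "value": value,
                    "lod": config.lod,
                    "censored": censored,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if substitute:
        df["scenario"] = "middle_bound"
    return OccurrenceTable(df)


@dataclass(frozen=True)
class ConsumptionProfile:
    """Parameters of the synthetic adult consumption survey.

    Per subcategory: probability of being a consumer and (meanlog, sdlog) of
    the lognormal mean daily amount in g/day among consumers.  Body weight
    is normal (kg) truncated at a positive floor; ages are uniform integers
    over ``age_range``.  Defaults put the expected subcategory shares of
    total category consumption at ≈ {SO: 0.07, OO: 0.77, EVOO: 0.16} with an
    expected total of ≈ 30 g/day.
    """

    category: str = CATEGORY
    subcategories: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            # label: (consumer probability, amount meanlog, amount sdlog)
            "SO": (0.30, 1.8209, 0.5),
            "OO": (0.90, 3.1202, 0.5),
            "EVOO": (0.50, 2.1368, 0.5),
        }
    )
    bw_mean: float = 70.0
    bw_sd: float = 12.0
    bw_floor: float = 35.0
    age_range: tuple[int, int] = (18, 80)

    def __post_init__(self) -> None:
        if not self.subcategories:
            raise ValidationError("profile needs at least one subcategory")
        for label, (p, _, sdlog) in self.subcategories.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"consumer probability for {label!r} not in [0,1]")
            if sdlog <= 0:
                raise ValidationError(f"amount sdlog for {label!r} must be positive")
        if self.bw_floor <= 0 or self.bw_sd <= 0:
            raise ValidationError("body-weight parameters must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ValidationError("age_range must be increasing")

    def expected_shares(self) -> dict[str, float]:
        """Expected subcategory share of total category consumption."""
        e = {
            s: p * np.exp(m + 0.5 * sd * sd)
            for s, (p, m, sd) in self.subcategories.items()
        }
        tot = sum(e.values())
        return {s: v / tot for s, v in e.items()}


def simulate_consumers(
    n_subjects: int,
    profile: "ConsumptionProfile | None" = None,
    rng_seed: "int | np.random.Generator" = 0,
) -> ConsumerTable:
    """Synthetic adult consumer table with the structure the estimators assume."""
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    profile = profile or ConsumptionProfile()
    rng = _as_rng(rng_seed)

    bw = rng.normal(profile.bw_mean, profile.bw_sd, size=n_subjects)
    while (bw < profile.bw_floor).any():  # truncation by redraw
        low = bw < profile.bw_floor
        bw[low] = rng.normal(profile.bw_mean, profile.bw_sd, size=int(low.sum()))
    age = rng.integers(profile.age_range[0], profile.age_range[1], size=n_subjects)

    ids = [f"S{i + 1:06d}" for i in range(n_subjects)]
    subjects = pd.DataFrame({"body_weight": bw, "age": age}, index=pd.Index(ids, name="subject_id"))
    cols, data = [], []
    for s, (p, meanlog, sdlog) in profile.subcategories.items():
        consumes = rng.random(n_subjects) < p
        amount = rng.lognormal(meanlog, sdlog, size=n_subjects) * consumes
        cols.append((profile.category, s))
        data.append(amount)
    intake = pd.DataFrame(
        np.column_stack(data),
        index=subjects.index,
        columns=pd.MultiIndex.from_tuples(cols, names=["category", "subcategory"]),
    )
    return ConsumerTable(subjects=subjects, intake=intake, survey_days=1)


def seed_oil_fixture(
    rng_seed: "int | np.random.Generator" = 0,
    meanlog: float = -1.48,
    sdlog: float = 1.20,
    lod: float = 0.035,
) -> OccurrenceTable:
    """Synthetic stand-in for the 14-sample seed-oil occurrence dataset.

    Reproduces the composition of the real convenience sample (corn 3, mixed
    seeds 2, peanut 3, rice 1, soybean 1, sunflower 4) with values drawn
    from the fitted lognormal(−1.48, 1.20); values below LOD are flagged
    censored (not substituted).  All records map to stratum SO.
    """
    rng = _as_rng(rng_seed)
    rows = []
    for oil, count in SEED_OIL_COUNTS.items():
        for i in range(count):
            value = float(rng.lognormal(meanlog, sdlog))
            rows.append(
                {
                    "sample_id": f"{oil.replace(' ', '_')}-{i + 1}",
                    "category": CATEGORY,
                    "subcategory": "SO",
                    "value": value,
                    "lod": lod,
                    "censored": value < lod,
                    "oil_type": oil,
                }
            )
    return OccurrenceTable(pd.DataFrame(rows))
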