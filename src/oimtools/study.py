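"""Simulation-study orchestration and TDI-based risk characterization.

:func:`run_study` runs the full method × weight-scheme grid — OIM, sOIM,
wsOIM* (consumption-aware weights) and the three wsOIM° sensitivity
scenarios — on simulated occurrence datasets combined with a consumer
table, producing per-cell Deterministic Estimates, percentile-method CIs
and the bootstrap mean-occurrence distributions.

Risk characterization compares the 95th-percentile exposure (UTP) CI with
the Tolerable Daily Intake.  "Not statistically different from the TDI at
0.05" is operationalized as the TDI lying inside the 95% percentile CI — a
documented heuristic, as is the mutual CI-exclusion rule used for pairwise
method comparisons.  Robustness follows a tipping-point logic: a primary
conclusion is robust unless some sensitivity scenario points to strictly
higher risk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .bootstrap import BootstrapDistribution, percentile_ci
from .errors import ValidationError
from .exposure import ExposureEstimate, MethodSpec, _exposure_vector, deterministic_estimate
from .io import ConsumerTable, WeightScheme, write_estimates
from .simulate import SimulationConfig, simulate_occurrence

__all__ = [
    "StudyCell",
    "StudyResult",
    "RiskVerdict",
    "run_study",
    "risk_characterization",
    "robustness_assessment",
    "characterize_study",
]

#: total ordering of verdicts by indicated risk
RISK_ORDER = {"below_tdi": 0, "not_different": 1, "above_tdi": 2}


@dataclass(frozen=True)
class RiskVerdict:
    """Outcome of comparing a UTP estimate with the TDI.

    ``verdict`` is ``below_tdi`` iff the CI upper bound is below the TDI,
    ``above_tdi`` iff the lower bound exceeds it, ``not_different``
    otherwise.  ``robust``/``tipping_schemes`` are filled by
    :func:`robustness_assessment`.
    """

    utp: float
    ci: tuple[float, float]
    tdi: float
    verdict: str
    robust: "bool | None" = None
    tipping_schemes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.verdict not in RISK_ORDER:
            raise ValidationError(f"unknown verdict {self.verdict!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyCell:
    """One (method, weight-scheme) cell of the study grid."""

    method: str
    scheme: str
    estimate: ExposureEstimate
    mean_occ: BootstrapDistribution


@dataclass
class StudyResult:
    """Per-cell estimates for the full grid plus pairwise comparisons."""

    cells: dict[str, StudyCell]
    config: SimulationConfig
    seed: int
    n_replicates: int
    comparisons: dict[str, str] = field(default_factory=dict)

    def utp_table(self) -> dict[str, dict]:
        out = {}
        for label, cell in self.cells.items():
            est = cell.estimate
            out[label] = {
                "utp_de": est.de[0.95],
                "ci": list(est.ci[0.95]) if est.ci else None,
            }
        return out

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_replicates": self.n_replicates,
            "config": {
                "mu_hat": self.config.mu_hat,
                "sigma_hat": self.config.sigma_hat,
                "gen_sdlog": self.config.gen_sdlog,
                "alpha": self.config.alpha,
                "lod": self.config.lod,
                "n_per_stratum": self.config.n_per_stratum,
                "n_datasets": self.config.n_datasets,
                "B": self.config.B,
                "tdi": self.config.tdi,
            },
            "cells": {k: c.estimate.to_dict() for k, c in self.cells.items()},
            "mean_occurrence": {
                k: {
                    "mean": float(np.mean(c.mean_occ.values)),
                    "sd": float(np.std(c.mean_occ.values, ddof=1)),
                }
                for k, c in self.cells.items()
            },
            "comparisons": dict(self.comparisons),
        }

    def save(self, outdir: "str | Path", force: bool = False) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "study.json").write_text(json.dumps(self.to_dict(), indent=2))
        for label, cell in self.cells.items():
            safe = label.replace("*", "star").replace("°", "o").replace("(", "_").replace(")", "")
            write_estimates(cell.estimate, outdir / f"estimate_{safe}.csv", force=force)


def _grid(config: SimulationConfig, w_star: WeightScheme) -> list[tuple[str, str, MethodSpec]]:
    """(label, scheme-key, MethodSpec) for the six study cells."""
    cells = [
        ("OIM", "", MethodSpec("OIM")),
        ("sOIM", "", MethodSpec("sOIM")),
        ("wsOIM*", "w_star", MethodSpec("wsOIM", weights=w_star)),
    ]
    for key in ("w_SO", "w_OO", "w_EVOO"):
        scheme = config.weight_schemes[key]
        cells.append((f"wsOIM°({key})", key, MethodSpec("wsOIM", weights=scheme)))
    return cells


def run_study(
    config: SimulationConfig,
    consumers: ConsumerTable,
    scale: float = 1.0,
    seed: int = 0,
    level: float = 0.95,
    probs: tuple[float, ...] = (0.5, 0.95),
) -> StudyResult:
    """Run the full simulation study grid.

    Each bootstrap replicate ``b`` uses one freshly simulated occurrence
    dataset: a standard resample of its pooled values feeds the OIM cell,
    and a single stratified resample (sizes fixed at the stratum sizes)
    feeds the sOIM and all wsOIM cells, whose mean occurrences differ only
    in the weighting.  One shared stream of consumer resamples is reused
    across all cells for comparability.  DEs come from a dedicated
    reference dataset simulated from its own child seed.  ``scale`` shrinks
    the replicate count (B and the number of simulated datasets together)
    for scaled-down runs; scaled counts must stay ≥ 10.
    """
    if not 0.0 < scale <= 1.0:
        raise ValidationError("scale must be in (0, 1]")
    n_rep = int(round(min(config.B, config.n_datasets) * scale))
    if n_rep < 10:
        raise ValidationError(f"scaled replicate count {n_rep} < 10")

    ss = np.random.SeedSequence(seed)
    consumer_ss, occurrence_ss, reference_ss = ss.spawn(3)
    crng = np.random.default_rng(consumer_ss)
    orng = np.random.default_rng(occurrence_ss)

    from .exposure import consumption_aware_weights

    w_star = consumption_aware_weights(consumers, config.category)
    cells = _grid(config, w_star)

    intake = np.column_stack([consumers.category_intake(config.category)])
    bw = consumers.body_weights()
    n = consumers.n_subjects
    labels = list(config.strata)

    reps = {label: np.empty((n_rep, len(probs))) for label, _, _ in cells}
    occ_reps = {label: np.empty(n_rep) for label, _, _ in cells}
    wvec = {
        label: spec.scheme_for(config.category).as_vector(labels)
        for label, _, spec in cells
        if spec.name == "wsOIM"
    }

    for b in range(n_rep):
        dataset = simulate_occurrence(config, rng_seed=orng)
        values = dataset.values()
        strata = dataset.strata
        # standard resample of the pooled values -> OIM
        m = len(values)
        occ_std = float(values[orng.integers(0, m, size=m)].mean())
        # one stratified resample shared by sOIM and all wsOIM cells
        means = np.empty(len(labels))
        sizes = np.empty(len(labels))
        for j, s in enumerate(labels):
            ix = strata[s]
            means[j] = values[ix[orng.integers(0, len(ix), size=len(ix))]].mean()
            sizes[j] = len(ix)
        occ_strat = float((sizes * means).sum() / sizes.sum())

        cidx = crng.integers(0, n, size=n)
        ratio = _exposure_vector(intake[cidx], bw[cidx], np.ones(1))
        q = np.quantile(ratio, probs, method="linear")  # exposure at unit occurrence
        for label, _, spec in cells:
            if spec.name == "OIM":
                occ_b = occ_std
            elif spec.name == "sOIM":
                occ_b = occ_strat
            else:
                occ_b = float(wvec[label] @ means)
            occ_reps[label][b] = occ_b
            reps[label][b] = q * occ_b

    reference = simulate_occurrence(config, rng_seed=np.random.default_rng(reference_ss))
    out_cells: dict[str, StudyCell] = {}
    for label, _, spec in cells:
        de_est = deterministic_estimate(consumers, reference, spec, probs)
        ci = {p: percentile_ci(reps[label][:, j], level) for j, p in enumerate(probs)}
        est = ExposureEstimate(
            method=spec.name,
            scheme=spec.scheme_label,
            probs=de_est.probs,
            de=de_est.de,
            ci=ci,
            level=level,
            B=n_rep,
            seed_consumers=seed,
            seed_occurrence=seed,
            ecdf_x=de_est.ecdf_x,
            ecdf_p=de_est.ecdf_p,
            mean_occ_replicates={config.category: occ_reps[label]},
        )
        out_cells[label] = StudyCell(
            method=spec.name,
            scheme=spec.scheme_label,
            estimate=est,
            mean_occ=BootstrapDistribution(
                occ_reps[label], statistic_label=f"mean occurrence [{label}]", seed=seed
            ),
        )

    comparisons = _pairwise_comparisons(out_cells)
    return StudyResult(
        cells=out_cells,
        config=config,
        seed=seed,
        n_replicates=n_rep,
        comparisons=comparisons,
    )


def _pairwise_comparisons(cells: dict[str, StudyCell]) -> dict[str, str]:
    """Heuristic pairwise verdicts on the UTP: two estimates 'differ' iff
    each DE lies outside the other's 95% CI (mutual CI exclusion)."""
    out = {}
    labels = list(cells)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ea, eb = cells[a].estimate, cells[b].estimate
            lo_a, hi_a = ea.ci[0.95]
            lo_b, hi_b = eb.ci[0.95]
            a_out = not lo_b <= ea.de[0.95] <= hi_b
            b_out = not lo_a <= eb.de[0.95] <= hi_a
            out[f"{a} vs {b}"] = (
                "different (heuristic)" if a_out and b_out else "not different (heuristic)"
            )
    return out


# ---------------------------------------------------------------------------
# risk characterization


def risk_characterization(estimate: ExposureEstimate, tdi: float) -> RiskVerdict:
    """Compare the UTP (95th-percentile exposure) CI against the TDI."""
    if tdi <= 0:
        raise ValidationError("TDI must be positive")
    if estimate.ci is None or 0.95 not in estimate.ci:
        raise ValidationError("estimate must carry a CI for the 0.95 percentile")
    lo, hi = estimate.ci[0.95]
    if hi < tdi:
        verdict = "below_tdi"
    elif lo > tdi:
        verdict = "above_tdi"
    else:
        verdict = "not_different"
    return RiskVerdict(utp=estimate.de[0.95], ci=(lo, hi), tdi=tdi, verdict=verdict)


def robustness_assessment(
    primary: RiskVerdict, scenarios: "dict[str, RiskVerdict]"
) -> RiskVerdict:
    """Tipping-point robustness of a primary conclusion.

    The primary verdict is robust unless some sensitivity scenario points to
    strictly higher risk (ordering below_tdi < not_different < above_tdi);
    the schemes that flip it are listed in ``tipping_schemes``.
    """
    if not scenarios:
        raise ValidationError("robustness assessment needs at least one scenario")
    rank = RISK_ORDER[primary.verdict]
    tipping = tuple(
        label for label, v in scenarios.items() if RISK_ORDER[v.verdict] > rank
    )
    return replace(primary, robust=not tipping, tipping_schemes=tipping)


def characterize_study(
    result: StudyResult,
    tdi: "float | None" = None,
    primaries: tuple[str, ...] = ("OIM", "sOIM", "wsOIM*"),
) -> dict[str, RiskVerdict]:
    """Risk verdicts for the primary cells, each assessed for robustness
    against the wsOIM° sensitivity scenarios."""
    tdi = result.config.tdi if tdi is None else tdi
    scenario_verdicts = {
        label: risk_characterization(cell.estimate, tdi)
        for label, cell in result.cells.items()
        if label.startswith("wsOIM°")
    }
    out = {}
    for label in primaries:
        primary = risk_characterization(result.cells[label].estimate, tdi)
        out[label] = robustness_assessment(primary, scenario_verdicts)
    return out
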