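"""Left-censored occurrence handling and censored distribution fitting.

Concentrations below the limit of detection (LOD) are *left-censored*: the
laboratory reports only that the value is below LOD.  Two distinct
treatments live here and are deliberately kept separate:

* **LOD substitution** (:func:`apply_lod_scenario`) replaces censored values
  by 0 (lower bound), LOD/2 (middle bound) or LOD (upper bound) for use in
  exposure computation.
* **Censored maximum likelihood** (:func:`fit_censored`) fits a parametric
  distribution using the exact censored likelihood — density for observed
  points, cumulative probability at LOD for censored points — which does not
  depend on any substitution rule.

Supported families are normal, lognormal, gamma and Weibull (two free
parameters each); model selection is by AIC.  The normal is fitted without
truncation at zero even though concentrations are non-negative; the support
mismatch is a known approximation (see the methods note).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ValidationError
from .io import OccurrenceTable

log = logging.getLogger("oimtools")

__all__ = [
    "LodScenario",
    "CensoredFit",
    "apply_lod_scenario",
    "fit_censored",
    "select_best_fit",
    "FAMILIES",
]


class LodScenario(enum.Enum):
    """Substitution rule for left-censored values."""

    LOWER_BOUND = "lower_bound"
    MIDDLE_BOUND = "middle_bound"
    UPPER_BOUND = "upper_bound"

    def substitute(self, lod: "float | np.ndarray") -> "float | np.ndarray":
        if self is LodScenario.LOWER_BOUND:
            return 0.0 * lod
        if self is LodScenario.MIDDLE_BOUND:
            return lod / 2.0
        return lod


def apply_lod_scenario(table: OccurrenceTable, scenario: LodScenario) -> OccurrenceTable:
    """Return a copy with censored values substituted under ``scenario``.

    Uncensored values are untouched; censored flags are retained and the
    applied scenario recorded in a ``scenario`` column.
    """
    df = table.data.copy()
    cens = df["censored"].to_numpy()
    df.loc[cens, "value"] = scenario.substitute(df.loc[cens, "lod"].to_numpy())
    df["scenario"] = scenario.value
    return OccurrenceTable(df)


# ---------------------------------------------------------------------------
# censored ML fitting


def _lognorm(meanlog: float, sdlog: float):
    return stats.lognorm(s=sdlog, scale=np.exp(meanlog))


# family name -> (param names, theta->dist, start from (possibly substituted)
# positive data, transform to/from the unconstrained optimizer scale)
def _start_normal(x):
    return np.array([np.mean(x), max(np.std(x, ddof=1), 1e-6)])


def _start_lognormal(x):
    lx = np.log(np.maximum(x, 1e-12))
    return np.array([np.mean(lx), max(np.std(lx, ddof=1), 1e-6)])


def _start_gamma(x):
    m, v = np.mean(x), max(np.var(x, ddof=1), 1e-12)
    shape = max(m * m / v, 1e-3)
    return np.array([shape, m / shape])


def _start_weibull(x):
    return np.array([1.2, max(np.mean(x), 1e-6)])


FAMILIES = {
    "normal": {
        "params": ("mean", "sd"),
        "dist": lambda th: stats.norm(loc=th[0], scale=th[1]),
        "start": _start_normal,
        "positive": (False, True),
    },
    "lognormal": {
        "params": ("meanlog", "sdlog"),
        "dist": lambda th: _lognorm(th[0], th[1]),
        "start": _start_lognormal,
        "positive": (False, True),
    },
    "gamma": {
        "params": ("shape", "scale"),
        "dist": lambda th: stats.gamma(a=th[0], scale=th[1]),
        "start": _start_gamma,
        "positive": (True, True),
    },
    "weibull": {
        "params": ("shape", "scale"),
        "dist": lambda th: stats.weibull_min(c=th[0], scale=th[1]),
        "start": _start_weibull,
        "positive": (True, True),
    },
}

#: canonical family order used for AIC tie-breaking
FAMILY_ORDER = ("normal", "lognormal", "gamma", "weibull")


@dataclass(frozen=True)
class CensoredFit:
    """A converged censored ML fit of one two-parameter family."""

    family: str
    params: dict[str, float]
    loglik: float
    aic: float
    n: int
    n_censored: int

    def __post_init__(self) -> None:
        k = len(self.params)
        if abs(self.aic - (2 * k - 2 * self.loglik)) > 1e-8 * max(1.0, abs(self.aic)):
            raise ValidationError("AIC does not satisfy 2k - 2*loglik")

    def dist(self):
        """The fitted scipy frozen distribution."""
        spec = FAMILIES[self.family]
        theta = np.array([self.params[p] for p in spec["params"]])
        return spec["dist"](theta)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "n_censored": self.n_censored,
        }


def censored_loglik(
    family: str,
    theta: np.ndarray,
    values: np.ndarray,
    censored: np.ndarray,
    lods: np.ndarray,
) -> float:
    """Censored log-likelihood: log-density at observed values plus log-CDF
    at LOD for censored points.  Reduces to the ordinary log-likelihood when
    nothing is censored."""
    dist = FAMILIES[family]["dist"](np.asarray(theta, dtype=float))
    ll = float(np.sum(dist.logpdf(values[~censored])))
    if censored.any():
        ll += float(np.sum(dist.logcdf(lods[censored])))
    return ll


def fit_censored(
    values: np.ndarray,
    censored: "np.ndarray | None" = None,
    lods: "np.ndarray | float | None" = None,
    family: str = "lognormal",
) -> CensoredFit:
    """Censored maximum-likelihood fit of one family.

    ``values`` for censored points are ignored by the likelihood (the
    information used is only that the observation lies below its LOD).
    Requires at least 3 uncensored values.  Optimization is Nelder-Mead on a
    log-transformed parameter scale from moment-based starting values, with
    three jittered restarts before giving up.
    """
    if family not in FAMILIES:
        raise ValidationError(
            f"unsupported family {family!r}; choose from {sorted(FAMILIES)}"
        )
    values = np.asarray(values, dtype=float)
    n = len(values)
    if censored is None:
        censored = np.zeros(n, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    if lods is None:
        lods = np.zeros(n)
    lods = np.broadcast_to(np.asarray(lods, dtype=float), (n,)).copy()
    if censored.any() and (lods[censored] <= 0).any():
        raise ValidationError("censored observations require a positive LOD")
    n_unc = int((~censored).sum())
    if n_unc < 3:
        raise FitError(
            f"need at least 3 uncensored values to fit {family!r}, got {n_unc}"
        )

    spec = FAMILIES[family]
    positive = np.array(spec["positive"])
    # moment starts computed on middle-bound substituted data
    x0_data = values.copy()
    x0_data[censored] = lods[censored] / 2.0
    theta0 = spec["start"](x0_data)

    def to_opt(theta):
        t = np.asarray(theta, dtype=float).copy()
        t[positive] = np.log(t[positive])
        return t

    def from_opt(z):
        t = np.asarray(z, dtype=float).copy()
        t[positive] = np.exp(t[positive])
        return t

    def nll(z):
        theta = from_opt(z)
        with np.errstate(all="ignore"):
            ll = censored_loglik(family, theta, values, censored, lods)
        return -ll if np.isfinite(ll) else 1e300

    rng = np.random.default_rng(0)
    starts = [to_opt(theta0)]
    starts += [to_opt(theta0) + rng.normal(0, 0.5, size=theta0.shape) for _ in range(3)]
    best = None
    diagnostics = []
    for z0 in starts:
        res = optimize.minimize(
            nll, z0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        diagnostics.append(res.message)
        if res.success and np.isfinite(res.fun) and res.fun < 1e299:
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise FitError(
            f"censored {family} fit did not converge: {diagnostics}"
        )
    theta = from_opt(best.x)
    loglik = -float(best.fun)
    params = dict(zip(spec["params"], map(float, theta)))
    return CensoredFit(
        family=family,
        params=params,
        loglik=loglik,
        aic=2 * len(params) - 2 * loglik,
        n=n,
        n_censored=int(censored.sum()),
    )


def fit_all_families(
    values, censored=None, lods=None, families=FAMILY_ORDER
) -> list[CensoredFit]:
    """Fit every requested family to the same censored sample."""
    return [fit_censored(values, censored, lods, family=f) for f in families]


def select_best_fit(fits: "list[CensoredFit]") -> CensoredFit:
    """The fit with the lowest AIC.

    Exact AIC ties are broken by the canonical family order (normal,
    lognormal, gamma, weibull) with a logged warning.  All fits must come
    from the same data (same n and censored count).
    """
    fits = list(fits)
    if not fits:
        raise ValidationError("no fits to select from")
    key = {(f.n, f.n_censored) for f in fits}
    if len(key) > 1:
        raise ValidationError(f"fits computed on different data: {sorted(key)}")
    min_aic = min(f.aic for f in fits)
    tied = [f for f in fits if f.aic == min_aic]
    if len(tied) > 1:
        tied.sort(key=lambda f: FAMILY_ORDER.index(f.family))
        log.warning(
            "AIC tie among %s; keeping %s by canonical order",
            [f.family for f in tied], tied[0].family,
        )
    return tied[0]
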