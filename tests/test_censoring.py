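"""LOD substitution scenarios and censored maximum-likelihood fitting."""

import logging

import numpy as np
import pytest
from scipy import stats

import oimtools as ot
from oimtools.censoring import FAMILIES, censored_loglik


class TestLodScenarios:
    @pytest.mark.parametrize(
        "scenario,expected",
        [
            (ot.LodScenario.LOWER_BOUND, 0.0),
            (ot.LodScenario.MIDDLE_BOUND, 0.0175),
            (ot.LodScenario.UPPER_BOUND, 0.035),
        ],
    )
    def test_censored_values_substituted(self, occ_factory, scenario, expected):
        table = occ_factory({"EVOO": [0.01, 0.5]}, lod=0.035)
        out = ot.apply_lod_scenario(table, scenario)
        assert out.data.loc[0, "value"] == pytest.approx(expected, abs=1e-12)
        # uncensored record untouched under every scenario
        assert out.data.loc[1, "value"] == 0.5
        assert out.data["censored"].tolist() == [True, False]
        assert (out.data["scenario"] == scenario.value).all()

    def test_substitution_never_exceeds_lod(self, occ_factory):
        rng = np.random.default_rng(0)
        table = occ_factory({"EVOO": rng.lognormal(np.log(0.035), 1, 200)})
        for scenario in ot.LodScenario:
            out = ot.apply_lod_scenario(table, scenario)
            cens = out.data["censored"]
            assert (out.data.loc[cens, "value"] <= 0.035).all()
            assert (out.data.loc[~cens, "value"] == table.data.loc[~cens, "value"]).all()


def _hessian_se(family, theta, values, censored, lods, eps=1e-4):
    """Wald standard errors from the observed information (central differences)."""
    theta = np.asarray(theta, dtype=float)
    k = len(theta)
    H = np.empty((k, k))

    def nll(t):
        return -censored_loglik(family, t, values, censored, lods)

    h = eps * np.maximum(np.abs(theta), 1.0)
    for i in range(k):
        for j in range(k):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            H[i, j] = (nll(tpp) - nll(tpm) - nll(tmp) + nll(tmm)) / (4 * h[i] * h[j])
    return np.sqrt(np.diag(np.linalg.inv(H)))


TRUE_PARAMS = {
    "normal": {"mean": 10.0, "sd": 2.0},
    "lognormal": {"meanlog": -1.48, "sdlog": 1.20},
    "gamma": {"shape": 2.0, "scale": 1.5},
    "weibull": {"shape": 1.5, "scale": 2.0},
}


def _draw(family, n, rng):
    spec = FAMILIES[family]
    theta = np.array([TRUE_PARAMS[family][p] for p in spec["params"]])
    return spec["dist"](theta).rvs(size=n, random_state=rng), theta


class TestCensoredFitting:
    def test_uncensored_lognormal_recovery(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(-1.48, 1.20, 5000)
        fit = ot.fit_censored(x, family="lognormal")
        assert fit.params["meanlog"] == pytest.approx(-1.48, abs=0.05)
        assert fit.params["sdlog"] == pytest.approx(1.20, abs=0.05)
        assert fit.n_censored == 0

    @pytest.mark.parametrize("family", list(FAMILIES))
    def test_recovery_with_20pct_censoring(self, family):
        """Each family's censored MLE recovers truth within 3 Wald SEs when a
        fifth of the sample is left-censored at a known LOD."""
        rng = np.random.default_rng(7)
        x, theta_true = _draw(family, 5000, rng)
        spec = FAMILIES[family]
        lod = float(spec["dist"](theta_true).ppf(0.2))
        censored = x < lod
        assert 0.15 < censored.mean() < 0.25
        fit = ot.fit_censored(x, censored, lod, family=family)
        theta_hat = np.array([fit.params[p] for p in spec["params"]])
        se = _hessian_se(family, theta_hat, x, censored, np.full_like(x, lod))
        assert np.all(np.abs(theta_hat - theta_true) < 3 * se), (
            family, theta_hat, theta_true, se,
        )

    @pytest.mark.parametrize("family", list(FAMILIES))
    def test_zero_censoring_likelihood_matches_plain(self, family):
        """With nothing censored the censored log-likelihood is the ordinary
        one, and the AIC identity holds exactly."""
        rng = np.random.default_rng(3)
        x, _ = _draw(family, 200, rng)
        fit = ot.fit_censored(x, family=family)
        plain = float(np.sum(fit.dist().logpdf(x)))
        assert fit.loglik == pytest.approx(plain, abs=1e-8)
        assert fit.aic == pytest.approx(4 - 2 * fit.loglik, abs=1e-10)

    def test_all_censored_raises(self):
        x = np.full(10, 0.01)
        with pytest.raises(ot.FitError, match="uncensored"):
            ot.fit_censored(x, np.ones(10, bool), 0.035, family="lognormal")

    def test_unsupported_family_raises(self):
        with pytest.raises(ot.ValidationError, match="family"):
            ot.fit_censored(np.ones(10), family="cauchy")

    def test_model_selection_consistency_gamma_vs_normal(self):
        """On a large gamma sample the gamma fit beats the normal by AIC."""
        rng = np.random.default_rng(21)
        x = rng.gamma(2.0, 3.0, 10000)
        gamma_fit = ot.fit_censored(x, family="gamma")
        normal_fit = ot.fit_censored(x, family="normal")
        assert gamma_fit.aic < normal_fit.aic
        assert gamma_fit.params["shape"] == pytest.approx(2.0, rel=0.1)


class TestSelectBestFit:
    def _fit(self, family, aic, n=100, n_censored=0):
        return ot.CensoredFit(
            family=family, params={"a": 1.0, "b": 1.0},
            loglik=(4 - aic) / 2, aic=aic, n=n, n_censored=n_censored,
        )

    def test_minimum_aic_wins(self):
        fits = [self._fit("normal", 12.0), self._fit("lognormal", 10.0),
                self._fit("gamma", 11.0)]
        assert ot.select_best_fit(fits).family == "lognormal"

    def test_single_fit_returned(self):
        fit = self._fit("weibull", 5.0)
        assert ot.select_best_fit([fit]) is fit

    def test_tie_broken_by_canonical_order_with_warning(self, caplog):
        fits = [self._fit("weibull", 10.0), self._fit("lognormal", 10.0)]
        with caplog.at_level(logging.WARNING, logger="oimtools"):
            best = ot.select_best_fit(fits)
        assert best.family == "lognormal"
        assert "tie" in caplog.text.lower()

    def test_inconsistent_data_rejected(self):
        fits = [self._fit("normal", 12.0, n=100), self._fit("gamma", 10.0, n=50)]
        with pytest.raises(ot.ValidationError, match="different data"):
            ot.select_best_fit(fits)

    def test_empty_collection_rejected(self):
        with pytest.raises(ot.ValidationError):
            ot.select_best_fit([])
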