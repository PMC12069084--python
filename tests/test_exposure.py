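"""Mean occurrence, weighting, and deterministic/probabilistic exposure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oimtools as ot

from conftest import CATEGORY, make_occurrence


class TestMethodSpec:
    def test_wsoim_requires_weights(self):
        with pytest.raises(ot.ValidationError):
            ot.MethodSpec("wsOIM")

    def test_plain_methods_refuse_weights(self):
        w = ot.WeightScheme({"SO": 1.0})
        with pytest.raises(ot.ValidationError):
            ot.MethodSpec("sOIM", weights=w)

    @pytest.mark.parametrize(
        "name,mode", [("OIM", "standard"), ("sOIM", "stratified"), ("wsOIM", "stratified")]
    )
    def test_resample_mode_derived(self, name, mode):
        w = ot.WeightScheme({"SO": 1.0}) if name == "wsOIM" else None
        assert ot.MethodSpec(name, weights=w).resample_mode == mode


class TestMeanOccurrence:
    def test_weighted_mean_of_stratum_means(self, three_strata_table):
        w = ot.WeightScheme({"SO": 0.8, "OO": 0.1, "EVOO": 0.1}, label="w_SO")
        occ = ot.mean_occurrence(three_strata_table, ot.MethodSpec("wsOIM", weights=w))
        assert occ[CATEGORY] == pytest.approx(0.8 * 1 + 0.1 * 2 + 0.1 * 3)

    def test_pooled_mean_for_oim_and_soim(self, three_strata_table):
        for name in ("OIM", "sOIM"):
            occ = ot.mean_occurrence(three_strata_table, ot.MethodSpec(name))
            assert occ[CATEGORY] == pytest.approx(2.0)

    def test_size_proportional_weights_equal_pooled_mean(self):
        rng = np.random.default_rng(2)
        sizes = {"SO": 7, "OO": 3, "EVOO": 5}
        table = make_occurrence(
            {s: rng.lognormal(0, 1, k) for s, k in sizes.items()}
        )
        n = sum(sizes.values())
        w = ot.WeightScheme({s: k / n for s, k in sizes.items()})
        weighted = ot.mean_occurrence(table, ot.MethodSpec("wsOIM", weights=w))
        pooled = ot.mean_occurrence(table, ot.MethodSpec("OIM"))
        assert weighted[CATEGORY] == pytest.approx(pooled[CATEGORY], rel=1e-12)

    def test_equal_sizes_and_uniform_weights_equal_pooled(self, three_strata_table):
        w = ot.WeightScheme({"SO": 1 / 3, "OO": 1 / 3, "EVOO": 1 / 3})
        weighted = ot.mean_occurrence(three_strata_table, ot.MethodSpec("wsOIM", weights=w))
        assert weighted[CATEGORY] == pytest.approx(2.0)

    def test_scheme_strata_mismatch_errors(self, three_strata_table):
        w = ot.WeightScheme({"SO": 0.5, "OO": 0.5})
        with pytest.raises(ot.StrataError):
            ot.mean_occurrence(three_strata_table, ot.MethodSpec("wsOIM", weights=w))

    @given(means=st.lists(st.floats(0.01, 100), min_size=2, max_size=5))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_weighted_mean_bounded_by_stratum_means(self, means):
        table = make_occurrence({f"s{i}": [m] for i, m in enumerate(means)})
        k = len(means)
        w = ot.WeightScheme({f"s{i}": 1 / k for i in range(k)})
        occ = ot.mean_occurrence(table, ot.MethodSpec("wsOIM", weights=w))[CATEGORY]
        assert min(means) - 1e-9 <= occ <= max(means) + 1e-9


class TestConsumptionAwareWeights:
    def test_relative_contributions(self, consumer_factory):
        consumers = consumer_factory(
            [70, 70], [[3.5, 38.5, 8.0], [3.5, 38.5, 8.0]],
            subcategories=("SO", "OO", "EVOO"),
        )
        w = ot.consumption_aware_weights(consumers, CATEGORY)
        assert w.weights == pytest.approx({"SO": 0.07, "OO": 0.77, "EVOO": 0.16})
        assert w.label == "w*"

    def test_single_subcategory_gets_weight_one(self, consumer_factory):
        consumers = consumer_factory([70], [[12.0]], subcategories=("OO",))
        assert ot.consumption_aware_weights(consumers, CATEGORY).weights == {"OO": 1.0}

    def test_equal_split_between_two_subcategories(self, consumer_factory):
        consumers = consumer_factory(
            [70, 80], [[10.0, 0.0], [0.0, 10.0]], subcategories=("SO", "OO")
        )
        w = ot.consumption_aware_weights(consumers, CATEGORY)
        assert w.weights == pytest.approx({"SO": 0.5, "OO": 0.5})

    def test_zero_total_consumption_errors(self, consumer_factory):
        consumers = consumer_factory([70], [[0.0]], subcategories=("OO",))
        with pytest.raises(ot.DegenerateWeightsError):
            ot.consumption_aware_weights(consumers, CATEGORY)


class TestIndividualExposure:
    def _record(self, bw=70.0, amount=20.0):
        return ot.ConsumerRecord("s1", bw, 40.0, {(CATEGORY, "OO"): amount})

    def test_direct_arithmetic(self):
        expo = ot.individual_exposure(self._record(), {CATEGORY: 0.5})
        assert expo == pytest.approx(20 * 0.5 / 70)

    def test_zero_consumption_zero_exposure(self):
        assert ot.individual_exposure(self._record(amount=0.0), {}) == 0.0

    def test_linearity_in_occurrence(self):
        rec = self._record()
        assert ot.individual_exposure(rec, {CATEGORY: 1.0}) == pytest.approx(
            2 * ot.individual_exposure(rec, {CATEGORY: 0.5})
        )

    def test_inverse_proportionality_to_body_weight(self):
        assert ot.individual_exposure(self._record(bw=35), {CATEGORY: 1}) == pytest.approx(
            2 * ot.individual_exposure(self._record(bw=70), {CATEGORY: 1})
        )

    def test_missing_occurrence_for_consumed_category(self):
        with pytest.raises(ot.MissingOccurrenceError):
            ot.individual_exposure(self._record(), {"Cereals": 0.5})


class TestDeterministicEstimate:
    def test_two_consumer_hand_computation(self, consumer_factory, occ_factory):
        consumers = consumer_factory([50, 100], [[10], [40]])
        table = occ_factory({"OO": [1.0, 1.0]})
        est = ot.deterministic_estimate(consumers, table, ot.MethodSpec("OIM"))
        np.testing.assert_allclose(np.sort(est.ecdf_x), [0.2, 0.4])
        assert est.de[0.5] == pytest.approx(0.3)  # interpolated median

    def test_identical_consumers_flat_percentiles(self, consumer_factory, occ_factory):
        consumers = consumer_factory([70] * 5, [[20]] * 5)
        table = occ_factory({"OO": [0.5]})
        est = ot.deterministic_estimate(
            consumers, table, ot.MethodSpec("OIM"), probs=(0.05, 0.5, 0.95)
        )
        expected = 20 * 0.5 / 70
        assert all(v == pytest.approx(expected) for v in est.de.values())

    def test_weight_placement_orders_estimates(self, consumer_factory,
                                               three_strata_table):
        consumers = consumer_factory([70, 60], [[10], [25]])
        most = ot.WeightScheme({"SO": 0.1, "OO": 0.1, "EVOO": 0.8})  # EVOO mean 3
        least = ot.WeightScheme({"SO": 0.8, "OO": 0.1, "EVOO": 0.1})  # SO mean 1
        de_most = ot.deterministic_estimate(
            consumers, three_strata_table, ot.MethodSpec("wsOIM", weights=most)
        )
        de_least = ot.deterministic_estimate(
            consumers, three_strata_table, ot.MethodSpec("wsOIM", weights=least)
        )
        assert de_most.de[0.95] >= de_least.de[0.95]

    def test_wsoim_de_monotone_along_weight_path(self, consumer_factory,
                                                 three_strata_table):
        consumers = consumer_factory([70], [[10]])
        utps = []
        for t in (0.0, 0.4, 0.8):  # shift weight from SO (mean 1) to EVOO (mean 3)
            w = ot.WeightScheme({"SO": 0.8 - t, "OO": 0.2, "EVOO": t})
            est = ot.deterministic_estimate(
                consumers, three_strata_table, ot.MethodSpec("wsOIM", weights=w)
            )
            utps.append(est.de[0.95])
        assert utps == sorted(utps)

    def test_ecdf_properties(self, consumer_factory, occ_factory):
        rng = np.random.default_rng(0)
        consumers = consumer_factory(
            rng.uniform(50, 90, 40), rng.lognormal(2, 1, 40).reshape(-1, 1)
        )
        table = occ_factory({"OO": [0.5, 1.5, 0.2]})
        est = ot.deterministic_estimate(consumers, table, ot.MethodSpec("OIM"))
        assert (np.diff(est.ecdf_x) >= 0).all()
        assert (np.diff(est.ecdf_p) >= 0).all()
        assert 0 < est.ecdf_p[0] <= 1 and est.ecdf_p[-1] == 1.0

    def test_no_category_overlap_errors(self, consumer_factory, occ_factory):
        consumers = consumer_factory([70], [[10]])
        table = occ_factory({"x": [0.5]}, category="Cereals")
        with pytest.raises(ot.MatchError):
            ot.deterministic_estimate(consumers, table, ot.MethodSpec("OIM"))


class TestProbabilisticEstimate:
    def test_degenerate_data_zero_width_ci(self, consumer_factory, occ_factory):
        consumers = consumer_factory([70], [[10]])
        table = occ_factory({"OO": [0.5]})
        est = ot.probabilistic_estimate(
            consumers, table, ot.MethodSpec("OIM"), B=25, seeds=(1, 2)
        )
        for lo, hi in est.ci.values():
            assert hi - lo == 0.0

    def test_same_seeds_bit_identical(self, consumer_factory, three_strata_table):
        consumers = consumer_factory([70, 60, 85], [[10], [25], [3]])
        kwargs = dict(B=60, seeds=(5, 6))
        a = ot.probabilistic_estimate(
            consumers, three_strata_table, ot.MethodSpec("sOIM"), **kwargs
        )
        b = ot.probabilistic_estimate(
            consumers, three_strata_table, ot.MethodSpec("sOIM"), **kwargs
        )
        assert a.to_dict() == b.to_dict()

    def test_single_stratum_methods_coincide(self, consumer_factory, occ_factory):
        """With one stratum, OIM, sOIM and wsOIM(weight 1) give identical DEs
        and, under shared seeds, identical PEs."""
        consumers = consumer_factory([70, 55, 90], [[12], [30], [7]])
        table = occ_factory({"OO": [0.3, 0.8, 1.4, 0.6]})
        w1 = ot.WeightScheme({"OO": 1.0})
        results = [
            ot.probabilistic_estimate(consumers, table, spec, B=80, seeds=(3, 4))
            for spec in (
                ot.MethodSpec("OIM"),
                ot.MethodSpec("sOIM"),
                ot.MethodSpec("wsOIM", weights=w1),
            )
        ]
        for other in results[1:]:
            assert other.de == results[0].de
            assert other.ci == results[0].ci

    def test_soim_narrows_ci_on_mixture_fixture(self, consumer_factory,
                                                contrasted_table):
        """Stratifying occurrence resampling narrows the UTP CI when stratum
        means are well separated (shared consumer stream)."""
        rng = np.random.default_rng(0)
        consumers = consumer_factory(
            rng.uniform(50, 90, 100), rng.lognormal(2.5, 0.8, 100).reshape(-1, 1)
        )
        wins = 0
        for rep in range(10):
            oim = ot.probabilistic_estimate(
                consumers, contrasted_table, ot.MethodSpec("OIM"),
                B=300, seeds=(rep, 1000 + rep),
            )
            soim = ot.probabilistic_estimate(
                consumers, contrasted_table, ot.MethodSpec("sOIM"),
                B=300, seeds=(rep, 1000 + rep),
            )
            assert soim.de[0.95] == pytest.approx(oim.de[0.95])  # same DE
            wins += soim.ci_width(0.95) < oim.ci_width(0.95)
        assert wins >= 8

    def test_invalid_arguments(self, consumer_factory, occ_factory):
        consumers = consumer_factory([70], [[10]])
        table = occ_factory({"OO": [0.5]})
        with pytest.raises(ot.ValidationError):
            ot.probabilistic_estimate(consumers, table, ot.MethodSpec("OIM"), B=1)
        with pytest.raises(ot.ValidationError):
            ot.probabilistic_estimate(
                consumers, table, ot.MethodSpec("OIM"), B=10, level=1.0
            )
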