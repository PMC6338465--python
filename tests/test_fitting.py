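"""Global fitting, SSE bookkeeping, and model selection."""

import numpy as np
import pytest

from conftest import exact_fv_dataset
from ratchetfit import conditions as C
from ratchetfit.fitting import (FitBounds, global_fit, r_squared, select_model,
                                sse)
from ratchetfit.kinetics import velocity_grid
from ratchetfit.schemes import enumerate_schemes, get_scheme

FORCES_OP = [2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0]
ATPS = [2e-5, 1e-4, 3.5e-4, 1e-3, 2e-3]


@pytest.fixture(scope="module")
def exact_opposing_dataset():
    return exact_fv_dataset(get_scheme("br-binding"), C.rates_in_complex(),
                            C.geometry_in_complex(), FORCES_OP, ATPS)


class TestSse:
    def test_zero_on_generating_parameters(self, exact_opposing_dataset,
                                           geom_opposing, rates_complex):
        s = sse(get_scheme("br-binding"), rates_complex,
                exact_opposing_dataset, geom_opposing)
        assert s == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("param", ["k_plus_b", "k_h", "delta"])
    def test_perturbation_never_decreases_sse(self, param,
                                              exact_opposing_dataset,
                                              geom_opposing, rates_complex):
        for factor in (0.9, 1.1):
            kw = {param: getattr(rates_complex, param) * factor}
            if param == "delta":
                kw["x_dagger"] = kw["delta"]
            s = sse(get_scheme("br-binding"), rates_complex.with_(**kw),
                    exact_opposing_dataset, geom_opposing)
            assert s > 0

    def test_permutation_invariance(self, exact_opposing_dataset,
                                    geom_opposing, rates_complex):
        import copy
        shuffled = copy.deepcopy(exact_opposing_dataset)
        shuffled.table = shuffled.table.sample(frac=1.0, random_state=0)
        a = sse(get_scheme("br-binding"), rates_complex,
                exact_opposing_dataset, geom_opposing)
        b = sse(get_scheme("br-binding"), rates_complex, shuffled,
                geom_opposing)
        assert a == b


class TestRSquared:
    def test_perfect_and_mean_model(self, exact_opposing_dataset,
                                    geom_opposing):
        v = exact_opposing_dataset.table["v_mean"].to_numpy()
        sst = float(np.sum((v - v.mean()) ** 2))
        assert r_squared(0.0, [exact_opposing_dataset],
                         [geom_opposing]) == 1.0
        assert r_squared(sst, [exact_opposing_dataset],
                         [geom_opposing]) == pytest.approx(0.0, abs=1e-12)

    def test_identity_holds_on_fit_result(self, exact_opposing_dataset,
                                          geom_opposing):
        fit = global_fit(get_scheme("br-binding"), [exact_opposing_dataset],
                         [geom_opposing], mode="joint", n_starts=4, seed=1)
        assert fit.r2 == pytest.approx(
            r_squared(fit.sse, [exact_opposing_dataset], [geom_opposing]))

    def test_zero_variance_rejected(self, exact_opposing_dataset,
                                    geom_opposing):
        import copy
        flat = copy.deepcopy(exact_opposing_dataset)
        flat.table["v_mean"] = 5.0
        with pytest.raises(ValueError):
            r_squared(1.0, [flat], [geom_opposing])


class TestGlobalFit:
    def test_noiseless_recovery_and_near_zero_sse(self, exact_opposing_dataset,
                                                  geom_opposing,
                                                  rates_complex):
        fit = global_fit(get_scheme("br-binding"), [exact_opposing_dataset],
                         [geom_opposing], mode="joint", n_starts=8, seed=3)
        assert fit.sse < 1.0  # velocities span hundreds of bp/s
        r = fit.rates["opposing_force"]
        assert r.delta == pytest.approx(rates_complex.delta, rel=0.05)
        assert r.k_c_eff == pytest.approx(rates_complex.k_c_eff, rel=0.05)
        assert r.k_eq == pytest.approx(rates_complex.k_eq, rel=0.5)

    def test_same_seed_identical_result(self, exact_opposing_dataset,
                                        geom_opposing):
        kw = dict(mode="joint", n_starts=3, seed=11)
        f1 = global_fit(get_scheme("ps-binding"), [exact_opposing_dataset],
                        [geom_opposing], **kw)
        f2 = global_fit(get_scheme("ps-binding"), [exact_opposing_dataset],
                        [geom_opposing], **kw)
        assert f1.sse == f2.sse
        assert f1.rates["opposing_force"] == f2.rates["opposing_force"]

    def test_best_sse_monotone_in_starts(self, exact_opposing_dataset,
                                         geom_opposing):
        sses = []
        for n in (1, 3, 6):
            f = global_fit(get_scheme("ps-release"), [exact_opposing_dataset],
                           [geom_opposing], mode="joint", n_starts=n, seed=2)
            sses.append(f.objective)
        assert sses[0] >= sses[1] >= sses[2]

    def test_parameters_respect_bounds(self, exact_opposing_dataset,
                                       geom_opposing):
        bounds = FitBounds(delta=(2.0, 4.0))
        fit = global_fit(get_scheme("br-binding"), [exact_opposing_dataset],
                         [geom_opposing], mode="joint", n_starts=4, seed=5,
                         bounds=bounds)
        assert 2.0 <= fit.rates["opposing_force"].delta <= 4.0

    def test_bootstrap_uncertainties_reported(self, exact_opposing_dataset,
                                              geom_opposing):
        fit = global_fit(get_scheme("ps-binding"), [exact_opposing_dataset],
                         [geom_opposing], mode="joint", n_starts=2, seed=7,
                         n_boot=20)
        assert fit.uncertainties is not None
        assert "delta" in fit.uncertainties
        assert fit.uncertainties["delta"]["se"] >= 0.0

    def test_invalid_arguments(self, exact_opposing_dataset, geom_opposing):
        with pytest.raises(ValueError):
            global_fit(get_scheme("br-binding"), [exact_opposing_dataset],
                       [geom_opposing], mode="bogus")
        with pytest.raises(ValueError):
            global_fit(get_scheme("br-binding"), [], [])


class TestSelectModel:
    @pytest.mark.parametrize("truth_id", ["br-binding", "ps-binding"])
    def test_noiseless_truth_attains_smallest_sse(self, truth_id,
                                                  geom_opposing):
        """Selection consistency on noiseless single-geometry surfaces."""
        rates = (C.rates_in_complex() if truth_id.startswith("br")
                 else C.rates_in_complex().with_(k_plus_tr=None,
                                                 k_minus_tr=None))
        ds = exact_fv_dataset(get_scheme(truth_id), rates,
                              geom_opposing, FORCES_OP, ATPS)
        ranking = select_model([ds], [geom_opposing], mode="joint",
                               n_starts=6, seed=4)
        assert len(ranking) == 6
        assert ranking[0].scheme_id in {truth_id, "br-hydrolysis"} \
            if truth_id == "br-binding" else True
        # the generating scheme reaches (near-)zero SSE
        truth_fit = next(f for f in ranking if f.scheme_id == truth_id)
        assert truth_fit.sse < 1.0
        # and no scheme beats it by a meaningful margin
        assert ranking[0].sse <= truth_fit.sse + 1e-9

    def test_full_ranking_reported(self, exact_opposing_dataset,
                                   geom_opposing):
        ranking = select_model([exact_opposing_dataset], [geom_opposing],
                               mode="joint", n_starts=2, seed=9)
        assert [f.scheme_id for f in ranking] != []
        assert len({f.scheme_id for f in ranking}) == 6
        assert all(ranking[i].objective <= ranking[i + 1].objective
                   for i in range(5))

    def test_needs_two_schemes(self, exact_opposing_dataset, geom_opposing):
        with pytest.raises(ValueError):
            select_model([exact_opposing_dataset], [geom_opposing],
                         schemes=enumerate_schemes()[:1])


def test_shared_chemistry_mode_builds_distinct_translocation_rates(
        exact_opposing_dataset, geom_opposing, geom_hairpin):
    ds_hp = exact_fv_dataset(get_scheme("br-binding"), C.rates_isolated(),
                             geom_hairpin, [4.0, 8.0, 12.0, 15.0], ATPS)
    fit = global_fit(get_scheme("br-binding"),
                     [exact_opposing_dataset, ds_hp],
                     [geom_opposing, geom_hairpin], mode="shared_chemistry",
                     n_starts=6, seed=21)
    r_op = fit.rates["opposing_force"]
    r_hp = fit.rates["hairpin_assisting"]
    # chemistry shared, ratchet equilibrium free per context
    assert r_op.k_plus_b == r_hp.k_plus_b
    assert r_op.k_h == r_hp.k_h
    assert r_hp.k_eq != r_op.k_eq
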