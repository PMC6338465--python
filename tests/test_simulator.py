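"""Stochastic trace generator: determinism, mechanics, oracle agreement."""

import numpy as np
import pytest

from ratchetfit import conditions as C
from ratchetfit.kinetics import steady_state_velocity
from ratchetfit.polymer import PolymerParams, ewlc_extension, fjc_extension_per_nt
from ratchetfit.schemes import get_scheme
from ratchetfit.simulate import (Dissociation, TrapModel, ensemble_velocities,
                                 generate_dataset, gillespie_run, render_trace,
                                 simulate_trace)


@pytest.fixture(scope="module")
def br_scheme():
    return get_scheme("br-binding")


class TestGillespie:
    def test_fixed_seed_is_bit_identical(self, br_scheme, rates_complex,
                                         geom_opposing):
        kw = dict(trap=C.trap_in_complex(), atp=1e-3, duration=0.5, seed=42)
        e1 = gillespie_run(br_scheme, rates_complex, geom_opposing, **kw)
        e2 = gillespie_run(br_scheme, rates_complex, geom_opposing, **kw)
        assert np.array_equal(e1["times"], e2["times"])
        assert np.array_equal(e1["positions"], e2["positions"])
        assert np.array_equal(e1["forces"], e2["forces"])

    def test_no_atp_gives_bounded_fluctuations(self, br_scheme, rates_complex,
                                               geom_opposing):
        ev = gillespie_run(br_scheme, rates_complex, geom_opposing,
                           C.trap_in_complex(), atp=0.0, duration=0.5, seed=3)
        # ratchet rattles but does not drift: net progress under one step
        assert abs(ev["positions"][-1]) <= rates_complex.delta
        assert np.max(np.abs(ev["positions"])) <= 3 * rates_complex.delta

    def test_passive_mode_force_balance(self, br_scheme, rates_complex,
                                        geom_opposing):
        """At every event |F - k_eff (sep - x_tether(F))| < 1e-6 pN."""
        trap = C.trap_in_complex()
        ev = gillespie_run(br_scheme, rates_complex, geom_opposing, trap,
                           atp=2e-3, duration=0.5, seed=11)
        poly = PolymerParams()
        L = (trap.handles_bp - ev["positions"]) * poly.nm_per_bp
        x = ewlc_extension(ev["forces"], poly, 1.0) * L
        resid = trap.k_eff * (ev["separation_nm"] - x) - ev["forces"]
        assert np.max(np.abs(resid)) < 1e-6

    def test_hairpin_force_balance_includes_released_ssdna(self, br_scheme,
                                                           rates_isolated,
                                                           geom_hairpin):
        trap = C.trap_isolated().__class__(k_eff=0.4, handles_bp=3400.0,
                                           hairpin_bp=500.0, f_start=14.0)
        ev = gillespie_run(br_scheme, rates_isolated, geom_hairpin, trap,
                           atp=2e-3, duration=0.5, seed=5)
        poly = PolymerParams()
        L_h = trap.handles_bp * poly.nm_per_bp
        x = (ewlc_extension(ev["forces"], poly, 1.0) * L_h
             + 2.0 * ev["positions"] * fjc_extension_per_nt(ev["forces"], poly))
        resid = trap.k_eff * (ev["separation_nm"] - x) - ev["forces"]
        assert np.max(np.abs(resid)) < 1e-6

    def test_opposing_force_rises_and_hairpin_force_falls(self, br_scheme,
                                                          rates_complex,
                                                          rates_isolated,
                                                          geom_opposing,
                                                          geom_hairpin):
        op = gillespie_run(br_scheme, rates_complex, geom_opposing,
                           C.trap_in_complex(), 2e-3, 1.5, seed=8)
        assert op["forces"][-1] > op["forces"][0]
        trap = TrapModel(k_eff=0.4, handles_bp=3400.0, hairpin_bp=500.0,
                         f_start=14.0)
        hp = gillespie_run(br_scheme, rates_isolated, geom_hairpin, trap,
                           2e-3, 1.5, seed=8)
        assert hp["forces"][-1] < hp["forces"][0]

    def test_dissociation_shortens_traces(self, br_scheme, rates_complex,
                                          geom_opposing):
        durations = {}
        for label, diss in [("off", None),
                            ("on", Dissociation(k0=2.0, f_scale=1e9))]:
            ts = [gillespie_run(br_scheme, rates_complex, geom_opposing,
                                C.trap_in_complex(), 2e-3, 3.0, seed=s,
                                dissociation=diss)["t_end"]
                  for s in range(20, 30)]
            durations[label] = np.mean(ts)
        assert durations["on"] < durations["off"]


class TestRenderTrace:
    def test_noiseless_channels_follow_force_balance(self, br_scheme,
                                                     rates_complex,
                                                     geom_opposing):
        trap = C.trap_in_complex()
        ev = gillespie_run(br_scheme, rates_complex, geom_opposing, trap,
                           2e-3, 0.5, seed=2)
        tr = render_trace(ev, sigma_nm=0.0)
        assert np.allclose(tr.extension_nm,
                           ev["separation_nm"] - tr.force_pN / trap.k_eff)
        # sampled forces are a subset of event forces
        assert set(np.round(tr.force_pN, 9)) <= set(np.round(ev["forces"], 9))

    def test_noise_magnitude_and_force_propagation(self, br_scheme,
                                                   rates_complex,
                                                   geom_opposing):
        trap = C.trap_in_complex()
        ev = gillespie_run(br_scheme, rates_complex, geom_opposing, trap,
                           2e-3, 1.0, seed=4)
        clean = render_trace(ev, sigma_nm=0.0)
        noisy = render_trace(ev, sigma_nm=2.0)
        n = min(clean.time.size, noisy.time.size)
        eps = noisy.extension_nm[:n] - clean.extension_nm[:n]
        assert np.std(eps) == pytest.approx(2.0, rel=0.1)
        # extension noise appears in force with gain -k_eff
        df = noisy.force_pN[:n] - clean.force_pN[:n]
        assert np.corrcoef(eps, df)[0, 1] < -0.99

    def test_uniform_grid_at_sampling_rate(self, br_scheme, rates_complex,
                                           geom_opposing):
        tr = simulate_trace(br_scheme, rates_complex, geom_opposing,
                            C.trap_in_complex(), 1e-3, 0.3, seed=9)
        assert tr.fs == 2500.0
        assert np.allclose(np.diff(tr.time), 1 / 2500.0)


class TestEnsembleOracle:
    @pytest.mark.parametrize("geom_name,F,atp", [
        ("opposing", 8.0, 2e-3),
        ("opposing", 20.0, 1e-4),
        ("hairpin", 10.0, 3.5e-4),
    ])
    def test_mean_velocity_matches_analytic(self, geom_name, F, atp,
                                            rates_complex, rates_isolated,
                                            geom_opposing, geom_hairpin,
                                            br_scheme):
        if geom_name == "opposing":
            geom, rates = geom_opposing, rates_complex
        else:
            geom, rates = geom_hairpin, rates_isolated
        v = ensemble_velocities(br_scheme, rates, F, atp, geom, n_runs=150,
                                duration=0.4, seed=17)
        va = steady_state_velocity(br_scheme, rates, F, atp, geom)
        sem = v.std(ddof=1) / np.sqrt(v.size)
        assert abs(v.mean() - va) <= 3 * max(sem, 1e-9)

    def test_agrees_with_clamped_single_runs(self, br_scheme, rates_complex,
                                             geom_opposing):
        """The vectorized ensemble and the event kernel sample the same chain."""
        F, atp = 10.0, 1e-3
        vv = ensemble_velocities(br_scheme, rates_complex, F, atp,
                                 geom_opposing, n_runs=120, duration=0.3,
                                 seed=23)
        singles = []
        for s in range(40):
            ev = gillespie_run(br_scheme, rates_complex, geom_opposing,
                               C.trap_in_complex(), atp, 0.3, seed=300 + s,
                               force_clamp=F)
            singles.append(ev["positions"][-1] / 0.3)
        se = np.sqrt(np.var(singles, ddof=1) / len(singles)
                     + np.var(vv, ddof=1) / len(vv))
        assert abs(np.mean(singles) - vv.mean()) <= 3.5 * se


class TestGenerateDataset:
    def test_condition_tags_and_reproducibility(self, br_scheme):
        plan = C.default_plan(n_traces=2, atp_grid=(1e-4, 1e-3))
        t1 = generate_dataset(plan, br_scheme, seed=5, duration=0.4)
        t2 = generate_dataset(plan, br_scheme, seed=5, duration=0.4)
        tags = {(tr.geometry, tr.atp) for tr in t1}
        assert len(tags) == 4  # 2 geometries x 2 [ATP]
        assert len(t1) == 8
        for a, b in zip(t1, t2):
            assert np.array_equal(a.extension_nm, b.extension_nm)

    def test_empty_plan_rejected(self, br_scheme):
        with pytest.raises(ValueError):
            generate_dataset([], br_scheme, seed=1)
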