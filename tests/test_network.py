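"""Topology structure, kinetic laws and the DDE integrator against oracles."""

import numpy as np
import pytest

from clockloops.network import (
    GENES,
    IntegrationError,
    NonRhythmicError,
    ParameterSet,
    Regulation,
    Topology,
    activation_factor,
    default_topology,
    extract_features,
    inhibition_factor,
    parameter_bounds,
    production_rate,
    simulate,
    Trajectory,
)


class TestTopology:
    def test_gene_and_edge_counts(self, topo):
        assert len(GENES) == 5
        assert len(topo.regulations) == 17
        assert len(topo.activations) == 7
        assert len(topo.inhibitions) == 10

    def test_parameter_vector_length(self, topo):
        assert topo.n_parameters == 34

    def test_regulator_wiring(self, topo):
        act_pairs = {(r.source, r.target) for r in topo.activations}
        assert act_pairs == {
            ("Bmal1", "Dbp"), ("Bmal1", "Per2"), ("Bmal1", "Cry1"),
            ("Bmal1", "RevErbA"), ("Dbp", "Per2"), ("Dbp", "Cry1"),
            ("Dbp", "RevErbA"),
        }
        inh_sources = {r.source for r in topo.inhibitions}
        assert inh_sources == {"Per2", "Cry1", "RevErbA"}
        rev_targets = {r.target for r in topo.inhibitions if r.source == "RevErbA"}
        assert rev_targets == {"Bmal1", "Cry1"}

    def test_duplicate_regulation_rejected(self, topo):
        regs = topo.regulations + (topo.regulations[0],)
        with pytest.raises(ValueError):
            Topology(genes=topo.genes, regulations=regs)

    def test_edge_list_round_trip(self, topo):
        assert Topology.from_edge_list(topo.to_edge_list()) == topo

    def test_exponent_override(self):
        t = default_topology(exponents={("Bmal1", "Dbp"): 2})
        exps = {(r.source, r.target): r.exponent for r in t.regulations}
        assert exps[("Bmal1", "Dbp")] == 2
        assert exps[("Bmal1", "Per2")] == 3

    def test_invalid_regulation_mode(self):
        with pytest.raises(ValueError):
            Regulation("Bmal1", "Dbp", "represses", "Ebox")


class TestParameterSet:
    def test_named_round_trip(self, topo, rng):
        v = rng.uniform(0.1, 5.0, topo.n_parameters)
        p = ParameterSet(topo, v)
        q = ParameterSet.from_dict(topo, p.to_dict())
        assert p == q

    def test_slices_cover_vector(self, topo):
        p = ParameterSet(topo, np.arange(34, dtype=float))
        stitched = np.concatenate(
            [p.act_fold, p.act_threshold, p.inh_strength, p.degradation, p.delay]
        )
        assert np.array_equal(stitched, p.vector)

    def test_set_get(self, topo):
        p = ParameterSet.neutral(topo)
        q = p.set("tau:Per2", 7.5)
        assert q.get("tau:Per2") == 7.5
        assert p.get("tau:Per2") == 0.0  # immutably copied

    def test_missing_parameter_rejected(self, topo):
        d = ParameterSet.neutral(topo).to_dict()
        d.pop("d:Cry1")
        with pytest.raises(ValueError, match="missing"):
            ParameterSet.from_dict(topo, d)

    def test_bounds_shape_and_bmal1_delay(self, topo, bounds):
        assert bounds.shape == (34, 2)
        names = ParameterSet.neutral(topo).names()
        i = names.index("tau:Bmal1")
        assert tuple(bounds[i]) == (0.0, 6.0)
        for g in ("Dbp", "Per2", "Cry1", "RevErbA"):
            assert tuple(bounds[names.index(f"tau:{g}")]) == (0.0, 12.0)


class TestKinetics:
    def test_activation_limits(self):
        assert activation_factor(0.0, 5.0, 1.0, 3) == 1.0
        assert activation_factor(1e6, 5.0, 1.0, 3) == pytest.approx(5.0, rel=1e-6)
        # at y = K the factor is the midpoint (1 + a)/2
        assert activation_factor(1.0, 5.0, 1.0, 3) == pytest.approx(3.0)

    def test_inhibition_limits(self):
        assert inhibition_factor(0.0, 2.0, 3) == 1.0
        assert inhibition_factor(0.5, 2.0, 3) == pytest.approx(0.5)  # (r*y)=1
        assert inhibition_factor(1e6, 2.0, 3) < 1e-10

    def test_monotonicity(self, rng):
        y = np.sort(rng.uniform(0, 4, 50))
        a = activation_factor(y, 10.0, 0.7, 3)
        assert np.all(np.diff(a) >= 0)
        i = inhibition_factor(y, 1.3, 3)
        assert np.all(np.diff(i) <= 0)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            activation_factor(-0.1, 2.0, 1.0, 3)
        with pytest.raises(ValueError):
            inhibition_factor(-0.1, 2.0, 3)

    def test_production_is_product_of_factors(self, topo, rng):
        v = rng.uniform(0.2, 3.0, topo.n_parameters)
        p = ParameterSet(topo, v)
        levels = {g: float(rng.uniform(0.1, 2.0)) for g in GENES}
        for gene in GENES:
            expected = 1.0
            for i, r in enumerate(topo.activations):
                if r.target == gene:
                    expected *= float(activation_factor(
                        levels[r.source], p.act_fold[i], p.act_threshold[i], r.exponent
                    ))
            for i, r in enumerate(topo.inhibitions):
                if r.target == gene:
                    expected *= float(inhibition_factor(
                        levels[r.source], p.inh_strength[i], r.exponent
                    ))
            assert production_rate(gene, levels, p, topo) == pytest.approx(expected)


class TestIntegrator:
    def test_pure_decay_closed_form(self, topo):
        """With all edges clamped at factor 0, dx/dt = -d x: x(t) = x0 e^{-dt}."""
        p = ParameterSet.neutral(topo, degradation=0.3)
        clamp = {i: 0.0 for i in range(len(topo.regulations))}
        traj = simulate(p, topo, history=np.full(5, 2.0), duration=20.0,
                        step=0.05, edge_clamp=clamp)
        expected = 2.0 * np.exp(-0.3 * traj.times)
        assert np.allclose(traj.values, expected[:, None], atol=1e-8)

    def test_fixed_point_under_total_clamping(self, topo):
        """Edges clamped at constants c: steady state prod(c)/d, reached exactly."""
        p = ParameterSet.neutral(topo, degradation=0.5)
        clamp = {i: 1.2 for i in range(len(topo.regulations))}
        traj = simulate(p, topo, duration=200.0, step=0.05, edge_clamp=clamp)
        incoming = {g: sum(1 for r in topo.regulations if r.target == g) for g in GENES}
        for j, g in enumerate(GENES):
            ss = 1.2 ** incoming[g] / 0.5
            assert traj.values[-1, j] == pytest.approx(ss, rel=1e-6)

    def test_step_halving_convergence(self, topo, rng):
        """RK4: halving the step shrinks the end-state error by ~2^4."""
        p = ParameterSet.neutral(topo, degradation=0.4)
        p = p.set("r:Per2-|Per2", 1.2).set("tau:Per2", 9.8)
        ends = {}
        for step in (0.1, 0.05, 0.025):
            traj = simulate(p, topo, duration=60.0, step=step)
            ends[step] = traj.values[-1].copy()
        e1 = np.abs(ends[0.1] - ends[0.025]).max()
        e2 = np.abs(ends[0.05] - ends[0.025]).max()
        assert e2 < e1 / 4  # well below the factor-16 asymptotic rate

    def test_zero_delay_matches_history_free_dynamics(self, topo):
        """tau = 0 dynamics must not depend on the pre-zero history values."""
        p = ParameterSet.neutral(topo, degradation=0.5).set("r:Per2-|Per2", 2.0)
        a = simulate(p, topo, history=np.ones(5), duration=50.0, step=0.05)
        b = simulate(p, topo, history=lambda t: np.ones(5), duration=50.0, step=0.05)
        assert np.allclose(a.values, b.values)

    def test_gene_clamp_freezes_gene(self, topo):
        p = ParameterSet.neutral(topo, degradation=0.4)
        p = p.set("r:Per2-|Per2", 1.2).set("tau:Per2", 9.8)
        traj = simulate(p, topo, duration=100.0, step=0.1, gene_clamp={"Cry1": 0.7})
        assert np.allclose(traj.gene("Cry1"), 0.7)

    def test_nonnegative_everywhere(self, topo, rng):
        lo, hi = parameter_bounds(topo).T
        for _ in range(3):
            p = ParameterSet(topo, rng.uniform(lo, hi))
            traj = simulate(p, topo, duration=120.0, step=0.1)
            assert np.all(traj.values >= 0)

    def test_too_large_step_rejected(self, topo):
        with pytest.raises(ValueError):
            simulate(ParameterSet.neutral(topo), topo, duration=10.0, step=0.2)

    def test_negative_history_rejected(self, topo):
        with pytest.raises(ValueError):
            simulate(ParameterSet.neutral(topo), topo,
                     history=np.array([1, 1, -1, 1, 1.0]), duration=10.0, step=0.1)


class TestFeatureExtraction:
    def _cosine_traj(self, period=24.0, phases=(0, 2, 4, 6, 8), amps=(0.5,) * 5):
        t = np.arange(0.0, 480.0, 0.1)
        vals = np.empty((len(t), 5))
        for j, (ph, am) in enumerate(zip(phases, amps)):
            vals[:, j] = 1.0 + am * np.cos(2 * np.pi * (t - ph) / period)
        return Trajectory(times=t, values=vals, step=0.1)

    def test_period_and_phases_on_cosines(self):
        traj = self._cosine_traj(period=23.5, phases=(0, 3, 6, 12, 18))
        f = extract_features(traj, transient=100.0)
        assert f.period == pytest.approx(23.5, abs=0.01)
        assert f.phase["Bmal1"] == 0.0
        for g, ph in zip(GENES, (0, 3, 6, 12, 18)):
            assert f.phase[g] == pytest.approx(ph % 23.5, abs=0.05)

    def test_fold_changes_on_cosines(self):
        traj = self._cosine_traj(amps=(0.5, 0.2, 0.8, 0.3, 0.6))
        f = extract_features(traj, transient=100.0)
        for g, am in zip(GENES, (0.5, 0.2, 0.8, 0.3, 0.6)):
            assert f.fold_change[g] == pytest.approx((1 + am) / (1 - am), rel=1e-3)

    def test_flat_trajectory_raises(self):
        t = np.arange(0.0, 300.0, 0.1)
        traj = Trajectory(times=t, values=np.ones((len(t), 5)), step=0.1)
        with pytest.raises(NonRhythmicError):
            extract_features(traj, transient=100.0)

    def test_damped_oscillation_period_still_measurable(self):
        """Feature extraction reports the period even for damped spirals;
        sustainedness is judged separately by the rhythmicity criterion."""
        t = np.arange(0.0, 480.0, 0.1)
        x = 1.0 + 0.5 * np.exp(-t / 100.0) * np.cos(2 * np.pi * t / 24.0)
        vals = np.tile(x[:, None], (1, 5))
        traj = Trajectory(times=t, values=vals, step=0.1)
        f = extract_features(traj, transient=240.0)
        assert f.period == pytest.approx(24.0, abs=0.05)
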