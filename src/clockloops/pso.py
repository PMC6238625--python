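"""Particle swarm optimization of the 34 kinetic parameters.

A swarm of candidate parameter vectors is initialized by Latin hypercube
sampling (optionally blended with a gradient-matching solution) and moved
through the box-bounded search space with inertia-weighted velocity
updates driven by each particle's own best position and the best position
in its ring neighborhood.  Positions are clipped to the bounds, with the
velocity zeroed in clipped dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .config import RunConfig, SwarmConfig
from .network import ParameterSet, Topology, default_topology, parameter_bounds
from .scoring import ExpressionProfile, Score, evaluate_params, profile_features
from .vfo import run_vfo, seed_swarm_positions


def latin_hypercube_init(n: int, bounds: np.ndarray, seed: int) -> np.ndarray:
    """n stratified samples: one per equal-width bin in every dimension."""
    if n < 1:
        raise ValueError("need at least one sample")
    sampler = qmc.LatinHypercube(d=bounds.shape[0], seed=seed)
    u = sampler.random(n)
    return qmc.scale(u, bounds[:, 0], bounds[:, 1])


@dataclass
class FitResult:
    params: ParameterSet
    score: Score
    trace: np.ndarray  # global-best score per iteration (non-increasing)
    tissue: str = ""
    seed: int = 0
    vfo_used: bool = False
    n_evaluations: int = 0
    fit_id: str = ""

    def __post_init__(self):
        if len(self.trace) and float(self.score) != float(self.trace[-1]):
            raise ValueError("best score must equal the last trace entry")


def run_pso(
    objective,
    bounds: np.ndarray,
    config: SwarmConfig | None = None,
    seed: int = 0,
    seeded_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray, int]:
    """Minimize ``objective`` over the box; returns (x_best, f_best, trace, n_evals).

    ``seeded_positions`` overrides the initial swarm positions (shape
    (n_particles, dim)); otherwise a Latin hypercube is drawn.  Non-finite
    objective values are treated as +infinity.
    """
    cfg = config or SwarmConfig()
    rng = np.random.default_rng(seed)
    dim = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    vmax = cfg.velocity_clamp * span

    if seeded_positions is not None:
        x = np.clip(np.asarray(seeded_positions, dtype=float), lo, hi)
        if x.shape != (cfg.n_particles, dim):
            raise ValueError("seeded positions shape mismatch")
    else:
        x = latin_hypercube_init(
            cfg.n_particles, bounds, seed=int(rng.integers(2**31))
        )
    v = np.zeros_like(x)

    def safe_eval(xi: np.ndarray) -> float:
        val = float(objective(xi))
        return val if np.isfinite(val) else np.inf

    n_evals = 0
    pbest = x.copy()
    pval = np.empty(cfg.n_particles)
    for i in range(cfg.n_particles):
        pval[i] = safe_eval(x[i])
        n_evals += 1

    half = cfg.neighborhood // 2
    neigh = [
        [(i + k) % cfg.n_particles for k in range(-half, half + 1)]
        for i in range(cfg.n_particles)
    ]

    gbest_i = int(np.argmin(pval))
    gx, gv = pbest[gbest_i].copy(), float(pval[gbest_i])
    trace = np.empty(cfg.n_iterations)
    for it in range(cfg.n_iterations):
        w = cfg.inertia_start + (cfg.inertia_end - cfg.inertia_start) * (
            it / max(1, cfg.n_iterations - 1)
        )
        lbest = np.empty_like(x)
        for i in range(cfg.n_particles):
            j = min(neigh[i], key=lambda k: pval[k])
            lbest[i] = pbest[j]
        r1 = rng.random(x.shape)
        r2 = rng.random(x.shape)
        v = w * v + cfg.cognitive * r1 * (pbest - x) + cfg.social * r2 * (lbest - x)
        v = np.clip(v, -vmax, vmax)
        x = x + v
        low = x < lo
        high = x > hi
        x = np.clip(x, lo, hi)
        v[low | high] = 0.0
        for i in range(cfg.n_particles):
            val = safe_eval(x[i])
            n_evals += 1
            if val < pval[i]:
                pval[i] = val
                pbest[i] = x[i].copy()
                if val < gv:
                    gv = val
                    gx = x[i].copy()
        trace[it] = gv
    return gx, gv, trace, n_evals


def fit_profile(
    profile: ExpressionProfile,
    config: RunConfig | None = None,
    seed: int = 0,
    use_vfo: bool = True,
    topo: Topology | None = None,
    bounds: np.ndarray | None = None,
) -> FitResult:
    """Full single-run fitting pipeline: (optional) VFO seeding, then PSO.

    The result is fully determined by (profile, config, seed, use_vfo).
    """
    cfg = config or RunConfig.default()
    topo = topo or default_topology()
    if bounds is None:
        bounds = parameter_bounds(topo)
    rng = np.random.default_rng(seed)
    vfo_seed = int(rng.integers(2**31))
    lhs_seed = int(rng.integers(2**31))
    pso_seed = int(rng.integers(2**31))

    feats = profile_features(profile, reference=cfg.sim.reference)

    def objective(x: np.ndarray) -> float:
        return float(
            evaluate_params(ParameterSet(topo, x), feats, cfg.sim, cfg.scoring)
        )

    seeded = None
    if use_vfo:
        vres = run_vfo(profile, bounds, cfg.vfo, seed=vfo_seed, topo=topo)
        positions = latin_hypercube_init(cfg.pso.n_particles, bounds, seed=lhs_seed)
        seeded = seed_swarm_positions(
            positions,
            vres.params,
            bounds,
            np.random.default_rng(vfo_seed ^ 0x5EED),
            rho=cfg.vfo.rho,
            jitter=cfg.vfo.jitter,
        )
    gx, gv, trace, n_evals = run_pso(
        objective, bounds, cfg.pso, seed=pso_seed, seeded_positions=seeded
    )
    best = ParameterSet(topo, gx)
    # deterministic simulation: re-evaluating the best position reproduces gv
    final = evaluate_params(best, feats, cfg.sim, cfg.scoring)
    return FitResult(
        params=best,
        score=final,
        trace=trace,
        tissue=profile.tissue,
        seed=seed,
        vfo_used=use_vfo,
        n_evaluations=n_evals,
        fit_id=f"{profile.tissue or 'profile'}-s{seed}-{'vfo' if use_vfo else 'raw'}",
    )
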