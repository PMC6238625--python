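"""Five-gene delayed gene-regulatory-network model of the mammalian core clock.

The network condenses the core circadian machinery to five representative
transcripts -- the activators *Bmal1* and *Dbp* and the inhibitors *Per2*,
*Cry1* and *Rev-erb-alpha* -- wired by 17 regulations acting through E-box,
D-box and RRE promoter elements.  Protein production, modification and
nuclear import are not modelled explicitly; each regulator acts on its
targets after an explicit transcriptional delay.  The resulting system is a
set of five delay differential equations

    dx_g/dt = prod_e F_e(x_src(e)(t - tau_src(e))) - d_g * x_g(t)

where the product runs over the incoming regulations of gene g, activating
edges contribute a saturating fold factor in [1, a] and inhibiting edges a
repression factor in (0, 1].
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from . import _kernel

GENES: tuple[str, ...] = ("Bmal1", "Dbp", "Per2", "Cry1", "RevErbA")
GENE_INDEX: dict[str, int] = {g: i for i, g in enumerate(GENES)}

ACTIVATION = "activation"
INHIBITION = "inhibition"

#: number of DDE integrations performed so far (used to assert that purely
#: algebraic code paths such as gradient matching never integrate)
SIMULATION_COUNTER = {"n": 0}


class NonRhythmicError(RuntimeError):
    """Raised when a trajectory has too few reference peaks to be a limit cycle."""


class IntegrationError(RuntimeError):
    def __init__(self, time: float):
        super().__init__(f"state became non-finite at t = {time:.3f} h")
        self.time = time


@dataclass(frozen=True)
class Gene:
    name: str
    index: int


@dataclass(frozen=True)
class Regulation:
    source: str
    target: str
    mode: str  # activation | inhibition
    element: str  # Ebox | Dbox | RRE
    exponent: int = 3

    def __post_init__(self):
        if self.exponent < 1:
            raise ValueError("regulation exponent must be >= 1")
        if self.mode not in (ACTIVATION, INHIBITION):
            raise ValueError(f"unknown regulation mode {self.mode!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.element)

    def __str__(self) -> str:  # e.g. "Per2 -| Cry1 (Ebox)"
        arrow = "->" if self.mode == ACTIVATION else "-|"
        return f"{self.source} {arrow} {self.target} ({self.element})"


# Edge list of the default network.  Activations first, then inhibitions;
# this order also fixes the flattening order of the kinetic parameters.
_DEFAULT_ACTIVATIONS = (
    ("Bmal1", "Dbp", "Ebox"),
    ("Bmal1", "Per2", "Ebox"),
    ("Bmal1", "Cry1", "Ebox"),
    ("Bmal1", "RevErbA", "Ebox"),
    ("Dbp", "Per2", "Dbox"),
    ("Dbp", "Cry1", "Dbox"),
    ("Dbp", "RevErbA", "Dbox"),
)
_DEFAULT_INHIBITIONS = (
    ("Per2", "Dbp", "Ebox"),
    ("Per2", "Per2", "Ebox"),
    ("Per2", "Cry1", "Ebox"),
    ("Per2", "RevErbA", "Ebox"),
    ("Cry1", "Dbp", "Ebox"),
    ("Cry1", "Per2", "Ebox"),
    ("Cry1", "Cry1", "Ebox"),
    ("Cry1", "RevErbA", "Ebox"),
    ("RevErbA", "Bmal1", "RRE"),
    ("RevErbA", "Cry1", "RRE"),
)


@dataclass(frozen=True)
class Topology:
    genes: tuple[Gene, ...]
    regulations: tuple[Regulation, ...]

    def __post_init__(self):
        keys = [r.key for r in self.regulations]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (source, target, element) regulation")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names")

    @property
    def activations(self) -> tuple[Regulation, ...]:
        return tuple(r for r in self.regulations if r.mode == ACTIVATION)

    @property
    def inhibitions(self) -> tuple[Regulation, ...]:
        return tuple(r for r in self.regulations if r.mode == INHIBITION)

    def incoming(self, gene: str) -> tuple[Regulation, ...]:
        return tuple(r for r in self.regulations if r.target == gene)

    def edge_index(self, reg: Regulation) -> int:
        return self.regulations.index(reg)

    @property
    def n_parameters(self) -> int:
        return 2 * len(self.activations) + len(self.inhibitions) + 2 * len(self.genes)

    # -- compiled-kernel edge arrays (cached lazily) -----------------------
    def _arrays(self):
        src = np.array([GENE_INDEX[r.source] for r in self.regulations], dtype=np.int64)
        tgt = np.array([GENE_INDEX[r.target] for r in self.regulations], dtype=np.int64)
        is_act = np.array([r.mode == ACTIVATION for r in self.regulations], dtype=np.bool_)
        nexp = np.array([r.exponent for r in self.regulations], dtype=np.int64)
        return src, tgt, is_act, nexp

    # -- plain-text edge list serialization --------------------------------
    def to_edge_list(self) -> str:
        lines = ["# source\ttarget\tmode\telement\texponent"]
        for r in self.regulations:
            lines.append(f"{r.source}\t{r.target}\t{r.mode}\t{r.element}\t{r.exponent}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edge_list(cls, text: str) -> "Topology":
        regs = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            s, t, mode, element, n = line.split("\t")
            regs.append(Regulation(s, t, mode, element, int(n)))
        genes = tuple(Gene(g, i) for i, g in enumerate(GENES))
        return cls(genes=genes, regulations=tuple(regs))


def default_topology(exponents: dict[tuple[str, str], int] | None = None) -> Topology:
    """The 17-regulation network: 7 activations and 10 inhibitions.

    Bmal1 activates Dbp, Per2, Cry1 and Rev-erb-alpha via E-boxes; Dbp
    activates Per2, Cry1 and Rev-erb-alpha via D-boxes; Per2 and Cry1 each
    inhibit Dbp, Per2, Cry1 and Rev-erb-alpha via E-boxes; Rev-erb-alpha
    inhibits Bmal1 and Cry1 via RREs.  ``exponents`` may override the
    default cooperativity (binding-site count) of 3 per (source, target).
    """
    exponents = exponents or {}
    regs = []
    for s, t, el in _DEFAULT_ACTIVATIONS:
        regs.append(Regulation(s, t, ACTIVATION, el, exponents.get((s, t), 3)))
    for s, t, el in _DEFAULT_INHIBITIONS:
        regs.append(Regulation(s, t, INHIBITION, el, exponents.get((s, t), 3)))
    genes = tuple(Gene(g, i) for i, g in enumerate(GENES))
    return Topology(genes=genes, regulations=tuple(regs))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

class ParameterSet:
    """Flat, named view of the model's kinetic parameters.

    Flattening order (stable, used for optimization and serialization):
    activation folds ``a`` (one per activation edge, topology order), then
    activation thresholds ``K``, then inhibition strengths ``r`` (one per
    inhibition edge), then degradation rates ``d`` (gene order), then
    delays ``tau`` (gene order).  For the default topology this gives
    7 + 7 + 10 + 5 + 5 = 34 scalars.
    """

    def __init__(self, topo: Topology, vector: np.ndarray):
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (topo.n_parameters,):
            raise ValueError(
                f"expected {topo.n_parameters} parameters, got {vector.shape}"
            )
        self.topo = topo
        self.vector = vector

    # -- slices -------------------------------------------------------------
    @property
    def _na(self) -> int:
        return len(self.topo.activations)

    @property
    def _ni(self) -> int:
        return len(self.topo.inhibitions)

    @property
    def act_fold(self) -> np.ndarray:
        return self.vector[0 : self._na]

    @property
    def act_threshold(self) -> np.ndarray:
        return self.vector[self._na : 2 * self._na]

    @property
    def inh_strength(self) -> np.ndarray:
        return self.vector[2 * self._na : 2 * self._na + self._ni]

    @property
    def degradation(self) -> np.ndarray:
        o = 2 * self._na + self._ni
        return self.vector[o : o + len(self.topo.genes)]

    @property
    def delay(self) -> np.ndarray:
        o = 2 * self._na + self._ni + len(self.topo.genes)
        return self.vector[o : o + len(self.topo.genes)]

    # -- named access ---------------------------------------------------------
    def names(self) -> list[str]:
        acts = self.topo.activations
        inhs = self.topo.inhibitions
        return (
            [f"a:{r.source}->{r.target}" for r in acts]
            + [f"K:{r.source}->{r.target}" for r in acts]
            + [f"r:{r.source}-|{r.target}" for r in inhs]
            + [f"d:{g}" for g in GENES]
            + [f"tau:{g}" for g in GENES]
        )

    def set(self, name: str, value: float) -> "ParameterSet":
        i = self.names().index(name)
        v = self.vector.copy()
        v[i] = value
        return ParameterSet(self.topo, v)

    def get(self, name: str) -> float:
        return float(self.vector[self.names().index(name)])

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names(), (float(x) for x in self.vector)))

    @classmethod
    def from_dict(cls, topo: Topology, d: dict[str, float]) -> "ParameterSet":
        probe = cls(topo, np.ones(topo.n_parameters))
        names = probe.names()
        missing = [n for n in names if n not in d]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        return cls(topo, np.array([d[n] for n in names], dtype=float))

    @classmethod
    def neutral(cls, topo: Topology, degradation: float = 0.5) -> "ParameterSet":
        """All regulations effectively inert: a = 1, weak inhibition, zero delay."""
        na, ni, ng = len(topo.activations), len(topo.inhibitions), len(topo.genes)
        v = np.concatenate(
            [
                np.ones(na),  # a = 1 -> activation factor identically 1
                np.ones(na),  # K
                np.full(ni, 0.1),  # weak repression near working point
                np.full(ng, degradation),
                np.zeros(ng),  # tau
            ]
        )
        return cls(topo, v)

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.topo, self.vector.copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and np.array_equal(
            self.vector, other.vector
        )


def parameter_bounds(
    topo: Topology,
    *,
    act_fold: tuple[float, float] = (1.0, 50.0),
    act_threshold: tuple[float, float] = (0.05, 5.0),
    inh_strength: tuple[float, float] = (0.1, 20.0),
    degradation: tuple[float, float] = (0.05, 1.0),
    delay: tuple[float, float] = (0.0, 12.0),
    bmal1_delay: tuple[float, float] = (0.0, 6.0),
) -> np.ndarray:
    """Box bounds per parameter, ordered as the flattened ParameterSet.

    Defaults reflect biologically plausible ranges: mRNA degradation rates
    0.05-1.0 / h (half-lives roughly 0.7-14 h), regulator delays up to 12 h
    with the Bmal1 delay searched on [0, 6] h, and regulation strengths
    spanning the working points around mean-normalized level 1.
    """
    na, ni, ng = len(topo.activations), len(topo.inhibitions), len(topo.genes)
    rows = (
        [act_fold] * na
        + [act_threshold] * na
        + [inh_strength] * ni
        + [degradation] * ng
    )
    for g in GENES[:ng]:
        rows.append(bmal1_delay if g == "Bmal1" else delay)
    return np.array(rows, dtype=float)


# ---------------------------------------------------------------------------
# Kinetics (reference NumPy implementations; the integrator reimplements
# these inside the compiled kernel)
# ---------------------------------------------------------------------------

def activation_factor(y, a, K, n):
    """Saturating activation fold (1 + a*(y/K)^n) / (1 + (y/K)^n) in [1, a]."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("regulator level must be non-negative")
    if np.any(np.asarray(K) <= 0):
        raise ValueError("activation threshold must be positive")
    u = (y / K) ** n
    return (1.0 + a * u) / (1.0 + u)


def inhibition_factor(y, r, n):
    """Repression fold 1 / (1 + (r*y)^n) in (0, 1]."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("regulator level must be non-negative")
    return 1.0 / (1.0 + (r * y) ** n)


def production_rate(
    gene: str,
    delayed_levels: dict[str, float],
    params: ParameterSet,
    topo: Topology,
) -> float:
    """Product of the incoming edges' fold factors for ``gene``.

    ``delayed_levels[s]`` must supply the regulator level x_s(t - tau_s)
    for every regulator s of the gene.  An empty product is 1 (basal rate).
    """
    acts = topo.activations
    inhs = topo.inhibitions
    out = 1.0
    for i, reg in enumerate(acts):
        if reg.target != gene:
            continue
        if reg.source not in delayed_levels:
            raise KeyError(f"missing delayed level for regulator {reg.source}")
        out *= float(
            activation_factor(
                delayed_levels[reg.source],
                params.act_fold[i],
                params.act_threshold[i],
                reg.exponent,
            )
        )
    for i, reg in enumerate(inhs):
        if reg.target != gene:
            continue
        if reg.source not in delayed_levels:
            raise KeyError(f"missing delayed level for regulator {reg.source}")
        out *= float(
            inhibition_factor(
                delayed_levels[reg.source], params.inh_strength[i], reg.exponent
            )
        )
    return out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Dense simulated time courses on a uniform grid starting at t = 0.

    ``values`` has shape (n_times, n_genes) in gene order.  The pre-zero
    history (needed for delayed lookups) is kept in ``history_values`` on
    the same grid extended to negative times.
    """

    times: np.ndarray
    values: np.ndarray
    step: float
    history_values: np.ndarray | None = None

    def gene(self, name: str) -> np.ndarray:
        return self.values[:, GENE_INDEX[name]]

    def at(self, t, gene: str) -> np.ndarray:
        return np.interp(t, self.times, self.gene(gene))

    def window(self, t0: float, t1: float | None = None) -> "Trajectory":
        m = self.times >= t0
        if t1 is not None:
            m &= self.times <= t1
        return Trajectory(self.times[m] - 0.0, self.values[m], self.step)


def simulate(
    params: ParameterSet,
    topo: Topology | None = None,
    history=None,
    duration: float = 720.0,
    step: float = 0.05,
    edge_clamp: dict[int, float] | None = None,
    gene_clamp: dict[str, float] | None = None,
) -> Trajectory:
    """Integrate the delayed system with the compiled RK4 kernel.

    ``history`` is either None (constant history at the normalized mean, 1),
    a length-5 vector of constant gene levels, or a callable t -> levels
    defined on [-max delay, 0].  ``edge_clamp`` maps edge indices (into
    ``topo.regulations``) to constant fold factors; ``gene_clamp`` maps gene
    names to frozen expression levels.
    """
    topo = topo or params.topo
    if step > 0.1:
        raise ValueError("integration step must be <= 0.1 h")
    src, tgt, is_act, nexp = topo._arrays()
    na = len(topo.activations)
    ne = len(topo.regulations)
    pa = np.zeros(ne)
    pK = np.ones(ne)
    pr = np.zeros(ne)
    pa[:na] = params.act_fold
    pK[:na] = params.act_threshold
    pr[na:] = params.inh_strength

    max_tau = float(np.max(params.delay))
    if duration <= max_tau:
        raise ValueError("duration must exceed the largest delay")
    n_hist = max(1, int(math.ceil(max_tau / step)) + 1)
    n_steps = int(round(duration / step))
    buf = np.empty((n_hist + n_steps + 1, len(GENES)))
    t_hist = (np.arange(n_hist + 1) - n_hist) * step
    if history is None:
        buf[: n_hist + 1] = 1.0
    elif callable(history):
        for i, t in enumerate(t_hist):
            buf[i] = np.asarray(history(t), dtype=float)
    else:
        buf[: n_hist + 1] = np.asarray(history, dtype=float)
    if np.any(buf[: n_hist + 1] < 0):
        raise ValueError("history must be non-negative")

    e_clamped = np.zeros(ne, dtype=np.bool_)
    e_clamp = np.zeros(ne)
    if edge_clamp:
        for idx, val in edge_clamp.items():
            e_clamped[idx] = True
            e_clamp[idx] = float(val)
    g_clamped = np.zeros(len(GENES), dtype=np.bool_)
    g_clamp = np.zeros(len(GENES))
    if gene_clamp:
        for name, val in gene_clamp.items():
            gi = GENE_INDEX[name]
            g_clamped[gi] = True
            g_clamp[gi] = float(val)
            buf[: n_hist + 1, gi] = float(val)

    SIMULATION_COUNTER["n"] += 1
    bad = _kernel.integrate_dde(
        buf, n_hist, n_steps, step, src, tgt, is_act, nexp, pa, pK, pr,
        np.asarray(params.degradation), np.asarray(params.delay),
        e_clamped, e_clamp, g_clamped, g_clamp,
    )
    if bad >= 0:
        raise IntegrationError(bad * step)
    times = np.arange(n_steps + 1) * step
    return Trajectory(
        times=times,
        values=buf[n_hist:],
        step=step,
        history_values=buf[: n_hist + 1],
    )


# ---------------------------------------------------------------------------
# Limit-cycle features
# ---------------------------------------------------------------------------

@dataclass
class ClockFeatures:
    """Period, per-gene peak phases relative to the reference, and fold changes."""

    period: float
    phase: dict[str, float]  # h in [0, period)
    fold_change: dict[str, float]  # >= 1
    reference: str = "Bmal1"

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")


def _refine_peak(t: np.ndarray, x: np.ndarray, i: int) -> tuple[float, float]:
    """Quadratic interpolation of a local maximum around grid index i."""
    if i <= 0 or i >= len(x) - 1:
        return t[i], x[i]
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    if denom >= 0 or abs(denom) < 1e-300:
        return t[i], x[i]
    off = 0.5 * (x[i - 1] - x[i + 1]) / denom
    h = t[1] - t[0]
    return t[i] + off * h, x[i] - 0.25 * (x[i - 1] - x[i + 1]) * off


def _gene_peaks(t: np.ndarray, x: np.ndarray) -> list[tuple[float, float]]:
    rng = x.max() - x.min()
    if rng <= 0:
        return []
    idx, _ = find_peaks(x, prominence=0.05 * rng)
    return [_refine_peak(t, x, i) for i in idx]


def extract_features(
    traj: Trajectory,
    reference: str = "Bmal1",
    transient: float = 480.0,
) -> ClockFeatures:
    """Measure period, relative peak phases and fold changes of a limit cycle.

    The initial ``transient`` is discarded; peaks are located per gene by
    local-maximum detection with quadratic refinement.  The period is the
    mean peak-to-peak interval of the reference gene; phases are peak times
    relative to the reference's last peak, modulo the period; fold changes
    are max/min over the last full cycle.  Raises :class:`NonRhythmicError`
    when fewer than two reference peaks remain.
    """
    m = traj.times >= transient
    t = traj.times[m]
    vals = traj.values[m]
    ref = vals[:, GENE_INDEX[reference]]
    ref_peaks = _gene_peaks(t, ref)
    if len(ref_peaks) < 2:
        raise NonRhythmicError(
            f"fewer than 2 {reference} peaks after t = {transient} h"
        )
    ptimes = np.array([p[0] for p in ref_peaks])
    period = float(np.mean(np.diff(ptimes)))
    if period <= 0:
        raise NonRhythmicError("non-positive inferred period")
    t_ref = ptimes[-1]

    phase: dict[str, float] = {}
    fc: dict[str, float] = {}
    t_end = t[-1]
    cyc = (t >= t_end - period)
    for g in GENES:
        x = vals[:, GENE_INDEX[g]]
        peaks = _gene_peaks(t, x)
        if peaks:
            # peak closest below/at the reference peak, in phase terms
            tg = peaks[-1][0]
            phase[g] = float((tg - t_ref) % period)
        else:
            phase[g] = 0.0
        lo = float(np.min(x[cyc]))
        hi = float(np.max(x[cyc]))
        fc[g] = hi / max(lo, 1e-12) if hi > 0 else 1.0
        fc[g] = max(fc[g], 1.0)
    phase[reference] = 0.0
    return ClockFeatures(period=period, phase=phase, fold_change=fc, reference=reference)
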