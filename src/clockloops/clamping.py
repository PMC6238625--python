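"""Feedback-loop identification by clamping genes and regulations.

Clamping fixes a gene's expression, or a single regulatory term of the
differential equations, at its unperturbed limit-cycle mean — the in-silico
analogue of constitutive expression experiments.  A negative feedback loop
is *essential* when clamping any single one of its links abolishes
self-sustained rhythms.  A set of loops is a *rhythm-generating oscillator*
when rhythms persist with every regulation outside the set clamped; minimal
such sets characterize which feedback structure actually drives the fitted
model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import RhythmCriterion, SimConfig
from .network import (
    GENES,
    GENE_INDEX,
    INHIBITION,
    NonRhythmicError,
    ParameterSet,
    Regulation,
    Topology,
    Trajectory,
    activation_factor,
    extract_features,
    inhibition_factor,
    simulate,
)

NEGATIVE = "negative"
POSITIVE = "positive"

FAMILIES = ("Per2_loop", "Cry1_loop", "Bmal1_RevErbA", "Repressilator")


@dataclass(frozen=True)
class Loop:
    """A simple directed cycle of regulations with its parity sign."""

    edges: tuple[Regulation, ...]
    sign: str
    family: str = "other"

    def __post_init__(self):
        for e1, e2 in zip(self.edges, self.edges[1:] + self.edges[:1]):
            if e1.target != e2.source:
                raise ValueError("edges do not form a closed cycle")
        n_inh = sum(1 for e in self.edges if e.mode == INHIBITION)
        expected = NEGATIVE if n_inh % 2 == 1 else POSITIVE
        if self.sign != expected:
            raise ValueError("sign inconsistent with inhibition parity")

    def __len__(self) -> int:
        return len(self.edges)

    def genes(self) -> tuple[str, ...]:
        return tuple(e.source for e in self.edges)

    def __str__(self) -> str:
        return " , ".join(str(e) for e in self.edges)


def _canonical(edges: list[Regulation]) -> tuple[Regulation, ...]:
    names = [GENE_INDEX[e.source] for e in edges]
    k = int(np.argmin(names))
    return tuple(edges[k:] + edges[:k])


def enumerate_loops(topo: Topology) -> list[Loop]:
    """All simple directed cycles of the regulation graph, with signs.

    Cycles are rotated so the lowest-index gene comes first and sorted by
    (length, gene tuple) for a deterministic ordering.
    """
    g = nx.DiGraph()
    for gene in GENES:
        g.add_node(gene)
    edge_of: dict[tuple[str, str], Regulation] = {}
    for r in topo.regulations:
        g.add_edge(r.source, r.target)
        edge_of[(r.source, r.target)] = r
    loops = []
    for cyc in nx.simple_cycles(g):
        edges = [
            edge_of[(cyc[i], cyc[(i + 1) % len(cyc)])] for i in range(len(cyc))
        ]
        edges = list(_canonical(edges))
        n_inh = sum(1 for e in edges if e.mode == INHIBITION)
        loops.append(
            Loop(
                edges=tuple(edges),
                sign=NEGATIVE if n_inh % 2 == 1 else POSITIVE,
            )
        )
    loops.sort(key=lambda L: (len(L), tuple(GENE_INDEX[s] for s in L.genes())))
    return loops


def core_loop_catalog(topo: Topology) -> dict[str, list[Loop]]:
    """The four loop families most discussed for the mammalian clock.

    Per2_loop / Cry1_loop: the direct auto-inhibition plus its extension via
    Dbp; Bmal1_RevErbA: the two-gene activation/repression loop;
    Repressilator: the three-inhibitor chain Per2 -| Rev-erb-alpha -| Cry1
    -| Per2.  Families whose edges are absent from the topology are omitted.
    """
    all_loops = enumerate_loops(topo)
    by_genes = {(L.genes(), tuple(e.mode for e in L.edges)): L for L in all_loops}

    def find(genes: tuple[str, ...], modes: tuple[str, ...]) -> Loop | None:
        key = (_rotate_min(genes, modes))
        return by_genes.get(key)

    def _rotate_min(genes, modes):
        k = int(np.argmin([GENE_INDEX[s] for s in genes]))
        return (genes[k:] + genes[:k], modes[k:] + modes[:k])

    wanted = {
        "Per2_loop": [
            (("Per2",), ("inhibition",)),
            (("Dbp", "Per2"), ("activation", "inhibition")),
        ],
        "Cry1_loop": [
            (("Cry1",), ("inhibition",)),
            (("Dbp", "Cry1"), ("activation", "inhibition")),
        ],
        "Bmal1_RevErbA": [
            (("Bmal1", "RevErbA"), ("activation", "inhibition")),
        ],
        "Repressilator": [
            (("Per2", "RevErbA", "Cry1"), ("inhibition", "inhibition", "inhibition")),
        ],
    }
    catalog: dict[str, list[Loop]] = {}
    for family, specs in wanted.items():
        members = []
        for genes, modes in specs:
            L = find(genes, modes)
            if L is not None:
                members.append(Loop(edges=L.edges, sign=L.sign, family=family))
        if members:
            catalog[family] = members
    return catalog


# ---------------------------------------------------------------------------
# Clamping
# ---------------------------------------------------------------------------

@dataclass
class ClampSpec:
    """Which genes/regulations are frozen, and at what constants."""

    gene_levels: dict[str, float] = field(default_factory=dict)
    edge_factors: dict[int, float] = field(default_factory=dict)  # edge index -> factor

    def describe(self, topo: Topology) -> dict:
        return {
            "genes": dict(self.gene_levels),
            "edges": {
                str(topo.regulations[i]): v for i, v in self.edge_factors.items()
            },
        }


def _limit_cycle_window(
    base: Trajectory, criterion: RhythmCriterion, reference: str
) -> tuple[np.ndarray, np.ndarray, float]:
    """Times/values over the last full period of the base trajectory."""
    try:
        feats = extract_features(base, reference=reference, transient=criterion.transient)
        period = feats.period
    except NonRhythmicError:
        period = min(criterion.window, base.times[-1] - criterion.transient)
    m = base.times >= base.times[-1] - period
    return base.times[m], base.values[m], period


def edge_clamp_constant(
    params: ParameterSet,
    topo: Topology,
    edge_index: int,
    base: Trajectory,
    criterion: RhythmCriterion | None = None,
    reference: str = "Bmal1",
) -> float:
    """Time-average of a regulation's fold factor over one base-cycle period.

    The delayed regulator level entering the factor is read from the base
    trajectory at t - tau (dense grid interpolation).
    """
    criterion = criterion or RhythmCriterion()
    t, vals, _ = _limit_cycle_window(base, criterion, reference)
    reg = topo.regulations[edge_index]
    s = GENE_INDEX[reg.source]
    tau = params.delay[s]
    y = np.interp(t - tau, base.times, base.values[:, s])
    y = np.clip(y, 0.0, None)
    if reg.mode == INHIBITION:
        i = topo.inhibitions.index(reg)
        fac = inhibition_factor(y, params.inh_strength[i], reg.exponent)
    else:
        i = topo.activations.index(reg)
        fac = activation_factor(
            y, params.act_fold[i], params.act_threshold[i], reg.exponent
        )
    return float(np.trapezoid(fac, t) / (t[-1] - t[0]))


def gene_clamp_level(
    base: Trajectory,
    gene: str,
    criterion: RhythmCriterion | None = None,
    reference: str = "Bmal1",
) -> float:
    """Mean expression of a gene over one period of the base limit cycle."""
    criterion = criterion or RhythmCriterion()
    t, vals, _ = _limit_cycle_window(base, criterion, reference)
    x = vals[:, GENE_INDEX[gene]]
    return float(np.trapezoid(x, t) / (t[-1] - t[0]))


def make_clamp_spec(
    params: ParameterSet,
    topo: Topology,
    base: Trajectory,
    genes: set[str] | None = None,
    edge_indices: set[int] | None = None,
    criterion: RhythmCriterion | None = None,
    reference: str = "Bmal1",
) -> ClampSpec:
    spec = ClampSpec()
    for g in genes or ():
        spec.gene_levels[g] = gene_clamp_level(base, g, criterion, reference)
    for i in edge_indices or ():
        spec.edge_factors[i] = edge_clamp_constant(
            params, topo, i, base, criterion, reference
        )
    return spec


def simulate_clamped(
    params: ParameterSet,
    topo: Topology,
    spec: ClampSpec,
    sim: SimConfig | None = None,
) -> Trajectory:
    sc = sim or SimConfig()
    return simulate(
        params,
        topo,
        duration=sc.duration,
        step=sc.step,
        edge_clamp=dict(spec.edge_factors),
        gene_clamp=dict(spec.gene_levels),
    )


# ---------------------------------------------------------------------------
# Rhythmicity
# ---------------------------------------------------------------------------

def _cycle_amplitudes(t: np.ndarray, x: np.ndarray) -> list[float]:
    """(max - min) within successive peak-to-peak windows of the signal."""
    from .network import _gene_peaks

    peaks = _gene_peaks(t, x)
    if len(peaks) < 3:
        return []
    times = [p[0] for p in peaks]
    amps = []
    for t0, t1 in zip(times[:-1], times[1:]):
        m = (t >= t0) & (t <= t1)
        if m.sum() >= 3:
            amps.append(float(x[m].max() - x[m].min()))
    return amps


def is_rhythmic(traj: Trajectory, criterion: RhythmCriterion | None = None) -> bool:
    """Sustained (non-damped) oscillation test on the post-transient window.

    A trajectory is rhythmic when some judged gene keeps a relative
    amplitude (max - min)/mean above ``epsilon`` AND the amplitude of its
    last cycle is at least ``decay_min`` times the previous one (ruling out
    slowly damped spirals).  ``criterion.gene`` selects a single gene or
    "any" (default): the system counts as rhythmic if any gene is.
    """
    c = criterion or RhythmCriterion()
    t0 = max(c.transient, traj.times[-1] - c.window)
    m = traj.times >= t0
    t = traj.times[m]
    genes = GENES if c.gene == "any" else (c.gene,)
    for g in genes:
        x = traj.values[m][:, GENE_INDEX[g]]
        mean = float(x.mean())
        if mean <= 0:
            continue
        rel_amp = float(x.max() - x.min()) / mean
        if rel_amp <= c.epsilon:
            continue
        amps = _cycle_amplitudes(t, x)
        if len(amps) < 2:
            continue
        if amps[-1] >= c.decay_min * amps[-2]:
            return True
    return False


# ---------------------------------------------------------------------------
# Essential loops and minimal oscillators
# ---------------------------------------------------------------------------

@dataclass
class LoopReport:
    fit_id: str
    essential_families: list[str]
    essential_members: list[str]  # string form of essential member cycles
    minimal_oscillators: list[tuple[str, ...]]  # sorted member-cycle keys
    minimal_oscillator_families: list[tuple[str, ...]]
    synergy: dict[str, str]  # oscillator key -> independent/dependent/mixed
    edge_clamp_rhythmic: dict[str, bool]  # per single-edge clamp
    clamp_constants: dict[str, float]
    criterion: RhythmCriterion = field(default_factory=RhythmCriterion)
    score: float | None = None

    def oscillator_family_union(self) -> tuple[str, ...]:
        fams: set[str] = set()
        for fs in self.minimal_oscillator_families:
            fams.update(fs)
        return tuple(sorted(fams))


def _member_key(loop: Loop) -> str:
    return f"{loop.family}:" + "/".join(loop.genes())


class ClampAnalysis:
    """Single-fit clamping analysis with cached single-edge verdicts."""

    def __init__(
        self,
        params: ParameterSet,
        topo: Topology | None = None,
        sim: SimConfig | None = None,
        criterion: RhythmCriterion | None = None,
    ):
        self.params = params
        self.topo = topo or params.topo
        self.sim = sim or SimConfig()
        self.criterion = criterion or RhythmCriterion(
            transient=self.sim.transient,
            window=min(240.0, self.sim.duration - self.sim.transient),
        )
        self.base = simulate(
            params, self.topo, duration=self.sim.duration, step=self.sim.step
        )
        if not is_rhythmic(self.base, self.criterion):
            raise NonRhythmicError("unclamped fit is not rhythmic")
        self._edge_verdict: dict[int, bool] = {}
        self._edge_constant: dict[int, float] = {}
        self._subset_cache: dict[frozenset, bool] = {}

    # -- single-edge clamps --------------------------------------------------
    def edge_constant(self, i: int) -> float:
        if i not in self._edge_constant:
            self._edge_constant[i] = edge_clamp_constant(
                self.params, self.topo, i, self.base, self.criterion,
                self.sim.reference,
            )
        return self._edge_constant[i]

    def single_edge_rhythmic(self, i: int) -> bool:
        if i not in self._edge_verdict:
            spec = ClampSpec(edge_factors={i: self.edge_constant(i)})
            traj = simulate_clamped(self.params, self.topo, spec, self.sim)
            self._edge_verdict[i] = is_rhythmic(traj, self.criterion)
        return self._edge_verdict[i]

    def essential_loops(self, catalog: dict[str, list[Loop]]) -> list[Loop]:
        """Member cycles all of whose single-edge clamps abolish rhythms."""
        out = []
        for family, members in catalog.items():
            for loop in members:
                idx = [self.topo.edge_index(e) for e in loop.edges]
                if all(not self.single_edge_rhythmic(i) for i in idx):
                    out.append(loop)
        return out

    # -- sufficiency ----------------------------------------------------------
    def subset_sufficient(self, members: frozenset[Loop]) -> bool:
        """Rhythmic with every regulation outside the member cycles clamped?"""
        key = frozenset(_member_key(m) for m in members)
        if key in self._subset_cache:
            return self._subset_cache[key]
        keep: set[int] = set()
        for loop in members:
            keep.update(self.topo.edge_index(e) for e in loop.edges)
        clamp_idx = set(range(len(self.topo.regulations))) - keep
        spec = ClampSpec(
            edge_factors={i: self.edge_constant(i) for i in clamp_idx}
        )
        traj = simulate_clamped(self.params, self.topo, spec, self.sim)
        verdict = is_rhythmic(traj, self.criterion)
        self._subset_cache[key] = verdict
        return verdict

    def minimal_oscillators(
        self, catalog: dict[str, list[Loop]], max_size: int = 4
    ) -> list[frozenset[Loop]]:
        members = [m for fam in catalog.values() for m in fam]
        sufficient: list[frozenset[Loop]] = []
        for size in range(1, max_size + 1):
            for combo in itertools.combinations(members, size):
                s = frozenset(combo)
                if any(prev <= s for prev in sufficient):
                    continue  # a proper subset already suffices: not minimal
                if self.subset_sufficient(s):
                    sufficient.append(s)
        return sufficient

    def classify_synergy(self, oscillator: frozenset[Loop]) -> str:
        """independent: >= 2 singleton subsets suffice; dependent: none proper does."""
        if len(oscillator) < 2:
            raise ValueError("synergy is undefined for a single loop")
        singles = sum(
            1 for m in oscillator if self.subset_sufficient(frozenset([m]))
        )
        if singles >= 2:
            return "independent"
        proper_sufficient = any(
            self.subset_sufficient(frozenset(c))
            for size in range(1, len(oscillator))
            for c in itertools.combinations(oscillator, size)
        )
        return "dependent" if not proper_sufficient else "mixed"

    # -- report ----------------------------------------------------------------
    def report(
        self,
        catalog: dict[str, list[Loop]] | None = None,
        fit_id: str = "",
        score: float | None = None,
    ) -> LoopReport:
        catalog = catalog or core_loop_catalog(self.topo)
        essential = self.essential_loops(catalog)
        minimal = self.minimal_oscillators(catalog)
        synergy = {}
        for osc in minimal:
            if len(osc) >= 2:
                key = "+".join(sorted(_member_key(m) for m in osc))
                synergy[key] = self.classify_synergy(osc)
        for i in range(len(self.topo.regulations)):
            self.single_edge_rhythmic(i)  # ensure the full verdict map exists
        return LoopReport(
            fit_id=fit_id,
            essential_families=sorted({L.family for L in essential}),
            essential_members=[_member_key(L) for L in essential],
            minimal_oscillators=[
                tuple(sorted(_member_key(m) for m in osc)) for osc in minimal
            ],
            minimal_oscillator_families=[
                tuple(sorted({m.family for m in osc})) for osc in minimal
            ],
            synergy=synergy,
            edge_clamp_rhythmic={
                str(self.topo.regulations[i]): v
                for i, v in sorted(self._edge_verdict.items())
            },
            clamp_constants={
                str(self.topo.regulations[i]): v
                for i, v in sorted(self._edge_constant.items())
            },
            criterion=self.criterion,
            score=score,
        )
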