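"""Synthetic circadian expression profiles and ground-truth model fixtures.

Two generators are provided.  The harmonic generator emulates the
statistical structure of published tissue atlases: five core-clock
transcripts sampled every 2 h over 48 h, mean-normalized, with
tissue-characteristic peak phases and fold changes and multiplicative
log-normal noise.  The model generator samples the limit cycle of a known
parameter set, providing ground truth for parameter- and loop-recovery
tests.  The shipped tissue presets encode the qualitative contrasts seen in
real atlases (the SCN's small amplitudes and early Cry1 peak; the large
Rev-erb-alpha amplitudes and late Cry1 of liver, adrenal gland and kidney);
their numeric values are fixture choices, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RhythmCriterion, SimConfig
from .network import (
    GENES,
    GENE_INDEX,
    NonRhythmicError,
    ParameterSet,
    Topology,
    default_topology,
    extract_features,
    simulate,
    _gene_peaks,
)
from .scoring import ExpressionProfile, normalize_profile

SAMPLING_TIMES = np.arange(0.0, 48.0, 2.0)  # 24 samples spanning 48 h


@dataclass(frozen=True)
class TissuePreset:
    name: str
    phase: dict[str, float]  # h on a 24-h cycle, relative to the Bmal1 peak
    fold_change: dict[str, float]
    noise: float = 0.1  # sd of log-normal multiplicative noise

    def __post_init__(self):
        for g, p in self.phase.items():
            if not 0.0 <= p < 24.0:
                raise ValueError(f"phase of {g} outside [0, 24)")
        for g, f in self.fold_change.items():
            if f < 1.0:
                raise ValueError(f"fold change of {g} below 1")


def _preset(name, phases, fcs, noise=0.1) -> TissuePreset:
    return TissuePreset(
        name=name,
        phase=dict(zip(GENES, phases)),
        fold_change=dict(zip(GENES, fcs)),
        noise=noise,
    )


# Gene order: Bmal1, Dbp, Per2, Cry1, RevErbA.  Phases relative to Bmal1.
_PRESETS = (
    _preset("liver",          (0, 11, 12.5, 18, 7), (3.0, 9.0, 4.5, 2.6, 14.0)),
    _preset("adrenal_gland",  (0, 11, 12.5, 17.5, 7), (2.6, 7.0, 4.0, 2.4, 11.0)),
    _preset("kidney",         (0, 11, 12.5, 17.5, 7), (2.8, 7.5, 4.0, 2.4, 11.5)),
    _preset("heart",          (0, 10.5, 12, 15, 6.5), (2.2, 4.5, 3.0, 2.0, 6.0)),
    _preset("skeletal_muscle",(0, 10.5, 12, 15, 6.5), (2.4, 5.0, 3.2, 2.0, 6.5)),
    _preset("lung",           (0, 11, 12, 16, 7), (2.4, 5.5, 3.4, 2.1, 7.5)),
    _preset("brown_adipose",  (0, 11, 12, 16.5, 7), (2.5, 6.0, 3.6, 2.2, 8.5)),
    _preset("white_adipose",  (0, 11, 12, 16.5, 7), (2.3, 5.5, 3.3, 2.1, 7.5)),
    _preset("SCN",            (0, 10, 11.5, 12.5, 6), (1.5, 2.2, 1.9, 1.5, 2.0)),
    _preset("cerebellum",     (0, 10.5, 11.5, 13.5, 6.5), (1.8, 3.0, 2.4, 1.8, 3.0)),
)


def tissue_presets() -> tuple[TissuePreset, ...]:
    """Ten tissue presets with the qualitative contrasts of real atlases."""
    return _PRESETS


def get_preset(name: str) -> TissuePreset:
    for p in _PRESETS:
        if p.name == name:
            return p
    raise KeyError(f"unknown tissue preset {name!r}")


def generate_harmonic_profile(
    preset: TissuePreset, seed: int = 0, noise: float | None = None
) -> ExpressionProfile:
    """Cosine profile x_g(t) = [1 + A_g cos(2 pi (t - phi_g)/24)] * exp(eta).

    The amplitude A_g = (FC - 1)/(FC + 1) reproduces the preset's fold
    change exactly at zero noise; eta ~ Normal(0, noise^2) i.i.d. per sample
    keeps expression positive.  The 24 samples are mean-normalized after
    the noise is applied.
    """
    rng = np.random.default_rng(seed)
    sd = preset.noise if noise is None else noise
    t = SAMPLING_TIMES
    vals = np.empty((len(GENES), len(t)))
    for i, g in enumerate(GENES):
        fc = preset.fold_change[g]
        amp = (fc - 1.0) / (fc + 1.0)
        vals[i] = 1.0 + amp * np.cos(2.0 * np.pi * (t - preset.phase[g]) / 24.0)
    if sd > 0:
        vals = vals * np.exp(rng.normal(0.0, sd, size=vals.shape))
    return normalize_profile(
        ExpressionProfile(genes=GENES, times=t, values=vals, tissue=preset.name)
    )


def generate_model_profile(
    params: ParameterSet,
    seed: int = 0,
    noise: float = 0.0,
    sim: SimConfig | None = None,
    tissue: str = "",
) -> ExpressionProfile:
    """Sample a model's limit cycle at 2-h spacing for 48 h from a reference peak."""
    sc = sim or SimConfig()
    traj = simulate(params, duration=sc.duration, step=sc.step)
    m = traj.times >= sc.transient
    t = traj.times[m]
    ref = traj.values[m][:, GENE_INDEX[sc.reference]]
    peaks = _gene_peaks(t, ref)
    if not peaks:
        raise NonRhythmicError("parameter set does not produce a rhythmic simulation")
    # start from a peak leaving >= 48 h of trajectory
    t0 = None
    for pt, _ in peaks:
        if pt + 46.0 <= t[-1]:
            t0 = pt
    if t0 is None:
        raise NonRhythmicError("trajectory too short to sample 48 h from a peak")
    sample_t = t0 + SAMPLING_TIMES
    vals = np.empty((len(GENES), len(sample_t)))
    for i, g in enumerate(GENES):
        vals[i] = np.interp(sample_t, traj.times, traj.values[:, GENE_INDEX[g]])
    vals = np.clip(vals, 0.0, None)
    if noise > 0:
        rng = np.random.default_rng(seed)
        vals = vals * np.exp(rng.normal(0.0, noise, size=vals.shape))
    return normalize_profile(
        ExpressionProfile(genes=GENES, times=SAMPLING_TIMES, values=vals, tissue=tissue)
    )


# ---------------------------------------------------------------------------
# Ground-truth fixtures for loop recovery
# ---------------------------------------------------------------------------

def _fixture_params(family: str, topo: Topology) -> ParameterSet:
    """Hand-tuned parameter sets whose dominant feedback loop is known.

    All start from the inert baseline (activation folds 1, inhibition
    strengths 0.1, degradation 0.4/h) and strengthen only the edges of the
    requested loop, plus a weak readout chain so every gene is driven.
    Delays were tuned so the free-running period is close to 24 h.
    """
    p = ParameterSet.neutral(topo, degradation=0.4)
    if family == "Repressilator":
        for e in ("r:Per2-|RevErbA", "r:RevErbA-|Cry1", "r:Cry1-|Per2"):
            p = p.set(e, 1.0)
        for g in ("Per2", "Cry1", "RevErbA"):
            p = p.set(f"tau:{g}", 1.85)
        # readouts: Bmal1 and Dbp follow the chain without feeding back
        p = p.set("r:RevErbA-|Bmal1", 0.3).set("r:Per2-|Dbp", 0.3)
    elif family == "Bmal1_RevErbA":
        p = p.set("a:Bmal1->RevErbA", 8.0).set("K:Bmal1->RevErbA", 1.2)
        p = p.set("r:RevErbA-|Bmal1", 0.3)
        p = p.set("tau:Bmal1", 4.2).set("tau:RevErbA", 3.2)
        # zero-gain readouts (downstream folds stay at 1)
        p = p.set("a:Bmal1->Dbp", 3.0).set("K:Bmal1->Dbp", 1.2)
        p = p.set("a:Bmal1->Per2", 3.0).set("K:Bmal1->Per2", 1.2)
    elif family == "Per2_loop":
        p = p.set("r:Per2-|Per2", 1.2).set("tau:Per2", 9.8)
        # readout chain Per2 -| RevErbA -| Bmal1 so all genes oscillate
        p = p.set("r:Per2-|RevErbA", 0.4).set("r:RevErbA-|Bmal1", 0.3)
        p = p.set("r:Per2-|Dbp", 0.3).set("r:Per2-|Cry1", 0.3)
    else:
        raise KeyError(f"no ground-truth fixture for family {family!r}")
    return p


FIXTURE_FAMILIES = ("Repressilator", "Bmal1_RevErbA", "Per2_loop")


@dataclass
class GroundTruthFixture:
    family: str
    params: ParameterSet
    profile: ExpressionProfile
    expected_essential_family: str
    expected_minimal_oscillator: tuple[str, ...]  # family names


def ground_truth_fixture(
    family: str,
    seed: int = 0,
    noise: float = 0.0,
    sim: SimConfig | None = None,
    verify: bool = True,
) -> GroundTruthFixture:
    """Parameter set + sampled profile with a known essential loop family.

    With ``verify=True`` (default) the construction is checked by direct
    simulation: the unclamped model must be rhythmic with a period within
    2 h of 24 h, and clamping any single edge of the target loop must
    abolish rhythms.  Verification failure raises instead of silently
    returning a bad fixture.
    """
    from .clamping import ClampAnalysis, core_loop_catalog, is_rhythmic

    topo = default_topology()
    sc = sim or SimConfig()
    params = _fixture_params(family, topo)
    profile = generate_model_profile(
        params, seed=seed, noise=noise, sim=sc, tissue=f"fixture:{family}"
    )
    if verify:
        analysis = ClampAnalysis(params, topo, sim=sc)
        feats = extract_features(
            analysis.base, reference=sc.reference, transient=sc.transient
        )
        if abs(feats.period - 24.0) > 2.0:
            raise RuntimeError(
                f"{family} fixture period {feats.period:.2f} h too far from 24 h"
            )
        catalog = core_loop_catalog(topo)
        target_edges = [
            topo.edge_index(e) for m in catalog[family] for e in m.edges
        ]
        # at least one member must have all its edges essential
        ok = any(
            all(not analysis.single_edge_rhythmic(topo.edge_index(e)) for e in m.edges)
            for m in catalog[family]
        )
        if not ok:
            raise RuntimeError(f"{family} fixture failed the essentiality check")
    return GroundTruthFixture(
        family=family,
        params=params,
        profile=profile,
        expected_essential_family=family,
        expected_minimal_oscillator=(family,),
    )
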