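"""Run configuration: integrator, scoring, VFO, swarm and clamping settings.

A :class:`RunConfig` collects every tunable of the pipeline in one strict,
YAML-serializable object.  ``RunConfig.default()`` is the full-scale setup
(720 h simulations at 0.05 h steps, 40 particles x 500 iterations);
``RunConfig.test_budget()`` is a reduced setup for quick runs (360 h at
0.1 h, 24 x 200) that keeps at least five scored cycles after the
transient.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class SimConfig:
    duration: float = 720.0  # h
    step: float = 0.05  # h
    transient: float = 480.0  # h discarded before feature extraction
    reference: str = "Bmal1"


@dataclass
class ScoringConfig:
    sigma_period: float = 0.5  # h
    sigma_phase: float = 1.0  # h
    sigma_fold_change: float = 0.5  # log2 units
    penalty_nonrhythmic: float = 1000.0
    threshold: float = 10.0  # strict upper bound for a "good" fit


@dataclass
class VfoConfig:
    n_starts: int = 20
    rho: float = 0.25  # swarm fraction with kinetic parameters re-centred on the VFO optimum
    jitter: float = 0.25  # relative half-width of the re-centring window
    maxiter: int = 200


@dataclass
class SwarmConfig:
    n_particles: int = 40
    n_iterations: int = 500
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    cognitive: float = 1.494
    social: float = 1.494
    neighborhood: int = 5  # ring neighborhood size (odd, includes self)
    velocity_clamp: float = 0.2  # fraction of each parameter range

    def __post_init__(self):
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.inertia_end > self.inertia_start:
            raise ValueError("inertia must not increase")
        if self.neighborhood > self.n_particles:
            raise ValueError("neighborhood larger than swarm")


@dataclass
class RhythmCriterion:
    transient: float = 480.0  # h
    epsilon: float = 0.01  # minimal relative amplitude (max-min)/mean
    decay_min: float = 0.95  # minimal ratio of last two cycle amplitudes
    window: float = 240.0  # h evaluated after the transient
    gene: str = "any"  # gene whose amplitude is judged, or "any" (max over genes)


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    vfo: VfoConfig = field(default_factory=VfoConfig)
    pso: SwarmConfig = field(default_factory=SwarmConfig)
    clamping: RhythmCriterion = field(default_factory=RhythmCriterion)

    @classmethod
    def default(cls) -> "RunConfig":
        return cls()

    @classmethod
    def test_budget(cls) -> "RunConfig":
        """Reduced problem sizes for fast runs (about 40 s per fit on one CPU).

        The shorter simulation still keeps four scored cycles after the
        transient; the 24 x 200 swarm reliably reaches good fits (score
        below the threshold) on noiseless and moderately noisy synthetic
        profiles of the two-gene feedback fixture.
        """
        return cls(
            sim=SimConfig(duration=240.0, step=0.1, transient=144.0),
            pso=SwarmConfig(n_particles=24, n_iterations=200),
            vfo=VfoConfig(n_starts=8, maxiter=120),
            clamping=RhythmCriterion(transient=144.0, window=96.0),
        )

    @classmethod
    def battery_budget(cls) -> "RunConfig":
        """Tiny per-fit budget for many-fit statistical comparisons.

        Used where dozens of independent fits are needed (e.g. comparing
        seeding strategies); each fit takes a few seconds, so differences
        between strategies are measured in distribution, not per run.
        """
        return cls(
            sim=SimConfig(duration=240.0, step=0.1, transient=144.0),
            pso=SwarmConfig(n_particles=12, n_iterations=40),
            vfo=VfoConfig(n_starts=4, maxiter=60),
            clamping=RhythmCriterion(transient=144.0, window=96.0),
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sections = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(sections)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, f in sections.items():
            sub = d.get(name, {})
            subcls = f.default_factory  # type: ignore[union-attr]
            valid = {sf.name for sf in dataclasses.fields(subcls)}
            bad = set(sub) - valid
            if bad:
                raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
            kwargs[name] = subcls(**sub)
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
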