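"""Feature-based goodness-of-fit between simulated limit cycles and data.

A fit is judged on the clock features that circadian experiments actually
constrain: the free-running period, the peak phases of the five transcripts
relative to Bmal1, and their peak-to-trough fold changes.  Each deviation is
normalized by a tolerance calibrated to day-to-day experimental variability
and squared; the total over the ten terms (1 period + 4 relative phases + 5
fold changes) is the score.  A score below 10 therefore means the
root-mean-square deviation is below one tolerance unit, i.e. the model is
within experimental uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScoringConfig, SimConfig
from .network import (
    GENES,
    GENE_INDEX,
    ClockFeatures,
    IntegrationError,
    NonRhythmicError,
    ParameterSet,
    extract_features,
    simulate,
)

DATA_PERIOD = 24.0  # entrained sampling: the data period is fixed


@dataclass
class ExpressionProfile:
    """Mean-normalized gene x time expression table for one tissue."""

    genes: tuple[str, ...]
    times: np.ndarray  # h
    values: np.ndarray  # shape (n_genes, n_times)
    tissue: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.times)):
            raise ValueError("values shape must be (n_genes, n_times)")
        if len(self.times) < 12:
            raise ValueError("need at least 12 time points")

    def gene(self, name: str) -> np.ndarray:
        return self.values[self.genes.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=self.times)


def normalize_profile(raw: ExpressionProfile) -> ExpressionProfile:
    """Divide each gene by its temporal mean (idempotent)."""
    means = raw.values.mean(axis=1, keepdims=True)
    if np.any(means <= 0):
        bad = [g for g, m in zip(raw.genes, means[:, 0]) if m <= 0]
        raise ValueError(f"non-positive mean expression for {bad}")
    return ExpressionProfile(
        genes=raw.genes, times=raw.times, values=raw.values / means, tissue=raw.tissue
    )


def _harmonic_design(t: np.ndarray) -> np.ndarray:
    w = 2.0 * np.pi / DATA_PERIOD
    return np.column_stack(
        [np.ones_like(t), np.cos(w * t), np.sin(w * t), np.cos(2 * w * t), np.sin(2 * w * t)]
    )


def profile_features(
    profile: ExpressionProfile, reference: str = "Bmal1"
) -> ClockFeatures:
    """Two-harmonic cosinor fit of each gene; phases and fold changes from the fit.

    Each gene is fitted by least squares with a 24-h fundamental plus second
    harmonic (to tolerate non-sinusoidal waveforms).  The phase is the
    fitted curve's global peak time relative to the reference gene's peak;
    the fold change is max/min of the fitted curve over one day.
    """
    if profile.times.max() - profile.times.min() < 24.0 - 1e-9:
        raise ValueError("profile must span at least 24 h")
    X = _harmonic_design(profile.times)
    tf = np.linspace(0.0, DATA_PERIOD, 2401)[:-1]
    Xf = _harmonic_design(tf)
    peak: dict[str, float] = {}
    fc: dict[str, float] = {}
    for g in profile.genes:
        y = profile.gene(g)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        curve = Xf @ beta
        lo, hi = float(curve.min()), float(curve.max())
        if lo <= 0:
            lo = max(lo, 1e-9)
        peak[g] = float(tf[np.argmax(curve)])
        fc[g] = max(hi / lo, 1.0)
    pref = peak[reference]
    phase = {g: float((peak[g] - pref) % DATA_PERIOD) for g in profile.genes}
    phase[reference] = 0.0
    return ClockFeatures(
        period=DATA_PERIOD, phase=phase, fold_change=fc, reference=reference
    )


def circular_distance(a: float, b: float, period: float) -> float:
    """Shorter-arc distance between two phases on a circle of given period."""
    d = abs(a - b) % period
    return min(d, period - d)


@dataclass
class Score:
    total: float
    breakdown: dict[str, float] = field(default_factory=dict)
    nonrhythmic: bool = False
    integration_failed: bool = False

    def __float__(self) -> float:
        return self.total


def score(
    sim: ClockFeatures, data: ClockFeatures, tol: ScoringConfig | None = None
) -> Score:
    """Sum of squared tolerance-normalized deviations over the ten features."""
    tol = tol or ScoringConfig()
    if sim.reference != data.reference:
        raise ValueError("features must share the reference gene")
    terms: dict[str, float] = {}
    terms["period"] = ((sim.period - data.period) / tol.sigma_period) ** 2
    for g in data.phase:
        if g == data.reference:
            continue
        d = circular_distance(sim.phase[g], data.phase[g], data.period)
        terms[f"phase:{g}"] = (d / tol.sigma_phase) ** 2
    for g in data.fold_change:
        d = np.log2(sim.fold_change[g]) - np.log2(data.fold_change[g])
        terms[f"fc:{g}"] = float((d / tol.sigma_fold_change) ** 2)
    return Score(total=float(sum(terms.values())), breakdown=terms)


def evaluate_params(
    params: ParameterSet,
    profile_feats: ClockFeatures,
    sim_config: SimConfig | None = None,
    tol: ScoringConfig | None = None,
) -> Score:
    """Simulate, extract limit-cycle features, and score against the data features.

    Non-rhythmic simulations (or integration failures) receive the flat
    non-rhythmic penalty.  ``profile_feats`` are typically obtained from
    :func:`profile_features`; passing features instead of the raw profile
    avoids refitting the cosinor model at every optimizer evaluation.
    """
    sc = sim_config or SimConfig()
    tol = tol or ScoringConfig()
    try:
        traj = simulate(params, duration=sc.duration, step=sc.step)
        feats = extract_features(traj, reference=sc.reference, transient=sc.transient)
    except NonRhythmicError:
        return Score(total=tol.penalty_nonrhythmic, nonrhythmic=True)
    except IntegrationError:
        return Score(
            total=tol.penalty_nonrhythmic, nonrhythmic=True, integration_failed=True
        )
    return score(feats, profile_feats, tol)


def is_good_fit(s: Score | float, threshold: float = 10.0) -> bool:
    """A fit is good iff its score is strictly below the threshold."""
    return float(s) < threshold
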