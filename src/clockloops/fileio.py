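"""File formats: expression tables, fit results, loop reports.

Expression tables are TSV/CSV with gene names in the first column and
sampling times (hours) in the header; common alias symbols (Nr1d1, Arntl,
...) are accepted.  Fit results and loop reports are versioned JSON with
full-precision parameters so that round-trips are lossless and stored clamp
specifications can be re-simulated for verification.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clamping import LoopReport
from .config import RhythmCriterion
from .network import GENES, ParameterSet, Topology, default_topology
from .pso import FitResult
from .scoring import ExpressionProfile, Score, normalize_profile

FORMAT_VERSION = 1

# case-insensitive gene symbol aliases -> canonical model names
GENE_ALIASES = {
    "bmal1": "Bmal1",
    "arntl": "Bmal1",
    "dbp": "Dbp",
    "per2": "Per2",
    "cry1": "Cry1",
    "reverba": "RevErbA",
    "rev-erba": "RevErbA",
    "rev-erb-a": "RevErbA",
    "rev-erb-alpha": "RevErbA",
    "rev-erbα": "RevErbA",
    "rev-erb-α": "RevErbA",
    "nr1d1": "RevErbA",
}


def _canonical_gene(name: str) -> str | None:
    return GENE_ALIASES.get(name.strip().lower())


def read_expression_table(path: str | Path, tissue: str | None = None) -> ExpressionProfile:
    """Read a gene x time TSV/CSV table and mean-normalize it.

    The header row holds sampling times in hours; the first column holds
    gene symbols (aliases accepted).  All five model genes must be present.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        times = df.columns.astype(float).to_numpy()
    except (TypeError, ValueError) as e:
        raise ValueError(f"{path}: header must be sampling times in hours") from e
    found: dict[str, np.ndarray] = {}
    for raw_name, row in df.iterrows():
        canon = _canonical_gene(str(raw_name))
        if canon is None:
            continue
        vals = pd.to_numeric(row, errors="coerce").to_numpy()
        if np.any(~np.isfinite(vals)):
            j = int(np.argmax(~np.isfinite(vals)))
            raise ValueError(
                f"{path}: non-numeric value for gene {raw_name!r} at column {df.columns[j]}"
            )
        found[canon] = vals
    missing = [g for g in GENES if g not in found]
    if missing:
        raise ValueError(
            f"{path}: missing genes {missing}; found {sorted(found)} "
            f"(expected {list(GENES)} or aliases)"
        )
    values = np.vstack([found[g] for g in GENES])
    return normalize_profile(
        ExpressionProfile(
            genes=GENES, times=times, values=values, tissue=tissue or path.stem
        )
    )


def write_expression_table(profile: ExpressionProfile, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(
        profile.values,
        index=list(profile.genes),
        columns=[f"{t:g}" for t in profile.times],
    )
    df.index.name = "gene"
    df.to_csv(path, sep=sep, float_format="%.10g")


# ---------------------------------------------------------------------------
# FitResult / LoopReport JSON
# ---------------------------------------------------------------------------

def save_fit_result(fit: FitResult, path: str | Path) -> None:
    doc = {
        "format": "clockloops.fit",
        "version": FORMAT_VERSION,
        "fit_id": fit.fit_id,
        "tissue": fit.tissue,
        "seed": fit.seed,
        "vfo_used": fit.vfo_used,
        "n_evaluations": fit.n_evaluations,
        "score": {
            "total": fit.score.total,
            "breakdown": fit.score.breakdown,
            "nonrhythmic": fit.score.nonrhythmic,
        },
        "trace": [float(v) for v in fit.trace],
        "parameters": fit.params.to_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_fit_result(path: str | Path, topo: Topology | None = None) -> FitResult:
    doc = _load_doc(path, "clockloops.fit")
    topo = topo or default_topology()
    params = ParameterSet.from_dict(topo, doc["parameters"])
    score = Score(
        total=doc["score"]["total"],
        breakdown=doc["score"]["breakdown"],
        nonrhythmic=doc["score"].get("nonrhythmic", False),
    )
    return FitResult(
        params=params,
        score=score,
        trace=np.array(doc["trace"]),
        tissue=doc["tissue"],
        seed=doc["seed"],
        vfo_used=doc["vfo_used"],
        n_evaluations=doc.get("n_evaluations", 0),
        fit_id=doc["fit_id"],
    )


def save_loop_report(report: LoopReport, path: str | Path) -> None:
    doc = {
        "format": "clockloops.loops",
        "version": FORMAT_VERSION,
        "fit_id": report.fit_id,
        "score": report.score,
        "essential_families": report.essential_families,
        "essential_members": report.essential_members,
        "minimal_oscillators": [list(o) for o in report.minimal_oscillators],
        "minimal_oscillator_families": [
            list(o) for o in report.minimal_oscillator_families
        ],
        "synergy": report.synergy,
        "edge_clamp_rhythmic": report.edge_clamp_rhythmic,
        "clamp_constants": report.clamp_constants,
        "criterion": dataclasses.asdict(report.criterion),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_loop_report(path: str | Path) -> LoopReport:
    doc = _load_doc(path, "clockloops.loops")
    return LoopReport(
        fit_id=doc["fit_id"],
        essential_families=doc["essential_families"],
        essential_members=doc["essential_members"],
        minimal_oscillators=[tuple(o) for o in doc["minimal_oscillators"]],
        minimal_oscillator_families=[
            tuple(o) for o in doc["minimal_oscillator_families"]
        ],
        synergy=doc["synergy"],
        edge_clamp_rhythmic=doc["edge_clamp_rhythmic"],
        clamp_constants=doc["clamp_constants"],
        criterion=RhythmCriterion(**doc["criterion"]),
        score=doc.get("score"),
    )


def _load_doc(path: str | Path, expected_format: str) -> dict:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: corrupted or not a JSON document") from e
    if not isinstance(doc, dict) or doc.get("format") != expected_format:
        raise ValueError(f"{path}: not a {expected_format} file")
    if doc.get("version") != FORMAT_VERSION:
        raise ValueError(
            f"{path}: incompatible version {doc.get('version')} "
            f"(this build reads version {FORMAT_VERSION})"
        )
    return doc
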