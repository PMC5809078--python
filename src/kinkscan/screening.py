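"""Batch screening of structure files for kinked protein-DNA complexes.

The screening workflow over one or many files: exclude entries whose
residue content is out of scope (RNA, modified DNA, no assemblable
duplex) or whose header reports a non-diffraction method, then curate
each duplex (trim dangling ends, flag flip-outs), compute roll profiles,
call kinks above the configured threshold, and look for intercalating
sidechains at every kinked step.  One report row per input file,
whatever happens to it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .duplex_builder import build_curated_duplexes
from .helix_geometry import roll_profile
from .kink_analysis import KINK_THRESHOLD, detect_intercalation, detect_kinks
from .structure_io import StructureEnsemble, read_structure
from .trajectory_stats import (
    classify_stability,
    fit_roll_histogram,
    roll_time_course,
    sample_snapshots,
)

logger = logging.getLogger("kinkscan")

__all__ = ["ScreenConfig", "ScreenReport", "screen_structures", "analyze_trajectory"]

NON_CRYSTAL_METHODS = ("NMR", "ELECTRON MICROSCOPY", "SOLUTION SCATTERING")


@dataclass
class ScreenConfig:
    kink_threshold: float = KINK_THRESHOLD  # degrees
    n_snapshots: int = 2000
    require_crystal: bool = True
    seed: int = 0


@dataclass
class ScreenReport:
    rows: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"rows": self.rows}, indent=2)

    def to_tsv(self) -> str:
        lines = ["identifier\toutcome\tn_duplexes\tkink_angle\tkinks\tintercalations\twarnings"]
        for r in self.rows:
            kinks = ";".join(
                f"{k['step_index']}:{k['dinucleotide']}:{k['roll']:.1f}"
                for d in r.get("duplexes", []) for k in d["kinks"]
            ) or "-"
            inter = ";".join(
                f"{c['residue'][0]}{c['residue'][1]}{c['residue'][2]}:{c['classification']}"
                for d in r.get("duplexes", [])
                for k in d["kinks"] for c in k["intercalating_residues"]
            ) or "-"
            lines.append(
                f"{r['identifier']}\t{r['outcome']}\t{r.get('n_duplexes', 0)}\t"
                f"{r.get('kink_angle') if r.get('kink_angle') is not None else '-'}\t"
                f"{kinks}\t{inter}\t{'; '.join(r.get('warnings', [])) or '-'}"
            )
        return "\n".join(lines) + "\n"


def _first_exclusion(ensemble: StructureEnsemble, duplexes, config: ScreenConfig) -> str | None:
    model = ensemble.models[0]
    kinds = [r.kind for r in model.iter_residues()]
    if "rna_nucleotide" in kinds:
        return "excluded_rna"
    if "modified_nucleotide" in kinds:
        return "excluded_modified"
    if not duplexes:
        return "excluded_single_stranded"
    method = (ensemble.metadata.get("experiment_method") or "").upper()
    if config.require_crystal and any(m in method for m in NON_CRYSTAL_METHODS):
        return "excluded_non_crystal"
    return None


def analyze_model(model, config: ScreenConfig | None = None) -> list[dict]:
    """Curate and analyze every duplex of one model; returns one dict
    per duplex with its profile, kink calls and intercalations."""
    config = config or ScreenConfig()
    results = []
    for d_idx, duplex in enumerate(build_curated_duplexes(model)):
        profile, steps = roll_profile(duplex, model)
        kinks = detect_kinks(profile, threshold=config.kink_threshold)
        warnings_ = []
        if duplex.trimmed_5p or duplex.trimmed_3p:
            warnings_.append(
                f"trimmed dangling ends: {duplex.trimmed_5p} nt (5'), "
                f"{duplex.trimmed_3p} nt (3')"
            )
            logger.warning("duplex %d: %s", d_idx, warnings_[-1])
        if duplex.flipped_positions:
            warnings_.append(f"flipped-out positions: {sorted(duplex.flipped_positions)}")
            logger.warning("duplex %d: %s", d_idx, warnings_[-1])
        kink_entries = []
        for k in kinks:
            calls = detect_intercalation(model, duplex, k.step_index)
            kink_entries.append({
                "step_index": k.step_index,
                "dinucleotide": k.dinucleotide,
                "roll": round(k.roll, 2),
                "flip_adjacent": k.flip_adjacent,
                "intercalating_residues": [
                    {"residue": list(c.residue),
                     "n_inserted_atoms": c.n_inserted_atoms,
                     "insertion_depth": round(c.insertion_depth, 2),
                     "classification": c.classification}
                    for c in calls
                ],
            })
        results.append({
            "duplex_index": d_idx,
            "length": len(duplex),
            "sequence_I": duplex.sequence_I,
            "rolls": [None if np.isnan(r) else round(float(r), 3) for r in profile.rolls],
            "kinks": kink_entries,
            "warnings": warnings_,
        })
    return results


def screen_structures(paths, config: ScreenConfig | None = None) -> ScreenReport:
    """Run the screening workflow over a batch of structure files.

    Exclusion reasons are evaluated in a fixed order and only the first
    matching one is reported; per-file failures become row-level errors
    and never abort the batch.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input files given")
    config = config or ScreenConfig()
    report = ScreenReport()
    for path in paths:
        row = {"identifier": path.stem, "path": str(path), "warnings": []}
        try:
            ensemble = read_structure(path)
            model = ensemble.models[0]
            duplexes = build_curated_duplexes(model)
            outcome = _first_exclusion(ensemble, duplexes, config)
            if outcome is not None:
                row["outcome"] = outcome
                row["n_duplexes"] = len(duplexes)
                logger.info("%s: %s", path.name, outcome)
            else:
                row["outcome"] = "analyzed"
                duplex_reports = analyze_model(model, config)
                row["n_duplexes"] = len(duplex_reports)
                row["duplexes"] = duplex_reports
                for d in duplex_reports:
                    row["warnings"].extend(d["warnings"])
                all_rolls = [r for d in duplex_reports for r in d["rolls"] if r is not None]
                row["kink_angle"] = max(all_rolls) if all_rolls else None
                logger.info("%s: analyzed, %d duplex(es), kink angle %s",
                            path.name, row["n_duplexes"], row["kink_angle"])
        except Exception as exc:  # keep the batch going
            row["outcome"] = "error"
            row["error"] = str(exc)
            logger.warning("%s: error: %s", path.name, exc)
        report.rows.append(row)
    return report


def analyze_trajectory(source, n_snapshots: int | None = None,
                       duplex_index: int = 0,
                       config: ScreenConfig | None = None) -> dict:
    """Trajectory analysis of a multi-model ensemble (file path or
    StructureEnsemble): equidistant snapshot sampling, roll time course,
    average profile, per-step histogram fit at the largest-mean-roll
    step, and stability classification there."""
    config = config or ScreenConfig()
    if n_snapshots is None:
        n_snapshots = config.n_snapshots
    ensemble = source if isinstance(source, StructureEnsemble) else read_structure(
        source, trajectory=True)
    if len(ensemble.models) < 2:
        raise ValueError(
            "single-model input: use screen_structures for static structures"
        )
    duplexes = build_curated_duplexes(ensemble.models[0])
    if not duplexes:
        raise ValueError("no duplex found in the first model")
    duplex = duplexes[duplex_index]
    snapshots = sample_snapshots(ensemble, n=n_snapshots)
    matrix, average = roll_time_course(snapshots, duplex)
    means = average.rolls
    ref_step = int(np.nanargmax(means)) + 1
    stability = classify_stability(matrix, ref_step)
    hist_fit = None
    try:
        hist_fit = fit_roll_histogram(matrix.values[:, ref_step - 1])
    except ValueError:
        pass
    return {
        "n_snapshots": matrix.n_snapshots,
        "n_steps": matrix.n_steps,
        "step_labels": matrix.step_labels,
        "average_profile": [round(float(v), 3) for v in means],
        "reference_step": ref_step,
        "mean_kink": round(float(means[ref_step - 1]), 3),
        "stability": asdict(stability),
        "histogram_fit": (None if hist_fit is None else
                          {"a": hist_fit.a, "b": hist_fit.b, "c": hist_fit.c,
                           "rss": hist_fit.rss, "sigma": hist_fit.sigma}),
        "matrix": matrix,
        "average": average,
    }
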