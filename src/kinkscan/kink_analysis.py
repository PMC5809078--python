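"""Kink calling and sidechain-intercalation detection.

A kink is a base-pair step whose roll exceeds a threshold (35 degrees by
default, the screening value); the kink angle of a complex is its
largest roll.  At a kinked step, protein sidechains whose heavy atoms
sit between the two base-pair planes are reported as intercalating,
classified full or partial from how much of the sidechain is inserted
and how deep it reaches past the C1'-C1' line.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .duplex_builder import Duplex
from .helix_geometry import (
    RollProfile,
    base_pair_frame,
    fit_base_frame,
    mid_step_frame,
)
from .structure_io import BACKBONE_ATOMS, ResidueRecord, StructureModel

__all__ = [
    "KinkCall",
    "IntercalationCall",
    "detect_kinks",
    "detect_intercalation",
    "classify_intercalation",
    "KINK_THRESHOLD",
]

KINK_THRESHOLD = 35.0       # degrees; screening threshold for a kink
SLAB_HALF_WIDTH = 4.5       # angstrom, max |distance| to either pair plane
SLAB_RADIUS = 7.0           # angstrom, max distance from the mid-step origin
FULL_FRACTION = 0.5         # fraction of sidechain atoms inside for "full"
FULL_DEPTH = 1.5            # angstrom past the C1'-C1' line for "full"


@dataclass
class KinkCall:
    step_index: int
    roll: float
    dinucleotide: str
    threshold_used: float = KINK_THRESHOLD
    flip_adjacent: bool = False


@dataclass
class IntercalationCall:
    residue: tuple[str, int, str]   # (chain_id, number, name)
    step_index: int
    n_inserted_atoms: int
    insertion_depth: float
    classification: str = "partial"
    inserted_fraction: float = 0.0


def detect_kinks(profile: RollProfile, threshold: float = KINK_THRESHOLD) -> list[KinkCall]:
    """All steps with roll strictly above the threshold, by descending
    roll; the first call's roll is the complex's kink angle.  Pure
    function of the profile."""
    calls = []
    for i, roll in enumerate(profile.rolls):
        if math.isnan(roll) or roll <= threshold:
            continue
        calls.append(KinkCall(
            step_index=i + 1,
            roll=float(roll),
            dinucleotide=profile.dinucleotides[i],
            threshold_used=threshold,
            flip_adjacent="flip_adjacent" in profile.flags[i],
        ))
    calls.sort(key=lambda c: -c.roll)
    return calls


def _sidechain_atoms(residue: ResidueRecord):
    return [a for a in residue.atoms
            if a.name not in BACKBONE_ATOMS and a.element != "H"]


def detect_intercalation(model: StructureModel, duplex: Duplex,
                         step_index: int) -> list[IntercalationCall]:
    """Protein sidechains inserted into one base-pair step.

    A sidechain heavy atom (CB and beyond) is inside the step slab when
    it lies between the two base-pair mean planes (signed distances of
    opposite sign, each below 4.5 A in magnitude) and within 7 A of the
    mid-step origin.  Residues with at least one inserted atom are
    returned with their insertion depth: how far the deepest atom
    reaches past the C1'-C1' line toward the helix axis.
    """
    if not (1 <= step_index <= len(duplex.pairs) - 1):
        raise IndexError(f"step {step_index} outside duplex")
    pair_a, pair_b = duplex.pairs[step_index - 1], duplex.pairs[step_index]

    def pf(pair):
        f1, _ = fit_base_frame(pair.res_I)
        f2, _ = fit_base_frame(pair.res_II)
        return base_pair_frame(f1, f2)

    frame_a, frame_b = pf(pair_a), pf(pair_b)
    mid = mid_step_frame(frame_a, frame_b)

    c1_positions = [p.atom("C1'").position
                    for p in (pair_a, pair_b) for p in (p.res_I, p.res_II)
                    if p.atom("C1'") is not None]
    x_line = float(np.mean([mid.to_local(p)[0] for p in c1_positions])) if c1_positions else -2.47

    def signed_dist(point, frame):
        return float((point - frame.origin) @ frame.z)

    calls = []
    for residue in model.iter_residues():
        if residue.kind != "amino_acid":
            continue
        side = _sidechain_atoms(residue)
        if not side:
            continue
        inserted = []
        for atom in side:
            da = signed_dist(atom.position, frame_a)
            db = signed_dist(atom.position, frame_b)
            if da * db >= 0:        # not between the planes
                continue
            if abs(da) > SLAB_HALF_WIDTH or abs(db) > SLAB_HALF_WIDTH:
                continue
            if np.linalg.norm(atom.position - mid.origin) > SLAB_RADIUS:
                continue
            inserted.append(atom)
        if not inserted:
            continue
        depth = max(mid.to_local(a.position)[0] for a in inserted) - x_line
        call = IntercalationCall(
            residue=(residue.chain_id, residue.number, residue.name),
            step_index=step_index,
            n_inserted_atoms=len(inserted),
            insertion_depth=float(depth),
            inserted_fraction=len(inserted) / len(side),
        )
        call.classification = classify_intercalation(call, residue)
        calls.append(call)
    calls.sort(key=lambda c: (-c.n_inserted_atoms, -c.insertion_depth))
    return calls


def classify_intercalation(call: IntercalationCall, residue: ResidueRecord) -> str:
    """'full' when at least half the sidechain heavy atoms sit inside
    the slab and the deepest one reaches 1.5 A past the C1'-C1' line;
    anything shallower or more grazing is 'partial'."""
    side = _sidechain_atoms(residue)
    if not side:
        return "partial"
    fraction = call.n_inserted_atoms / len(side)
    if fraction >= FULL_FRACTION and call.insertion_depth >= FULL_DEPTH:
        return "full"
    return "partial"


def kink_report(structure_id: str, duplex_index: int,
                kinks: list[KinkCall],
                intercalations: dict[int, list[IntercalationCall]]) -> dict:
    """JSON-ready catalogue entry: one record per kink step with its
    intercalating residues."""
    return {
        "structure": structure_id,
        "duplex": duplex_index,
        "kink_angle": kinks[0].roll if kinks else None,
        "kinks": [
            {
                "step_index": k.step_index,
                "roll": round(k.roll, 2),
                "dinucleotide": k.dinucleotide,
                "threshold": k.threshold_used,
                "flip_adjacent": k.flip_adjacent,
                "intercalating_residues": [
                    {
                        "residue": list(c.residue),
                        "n_inserted_atoms": c.n_inserted_atoms,
                        "insertion_depth": round(c.insertion_depth, 2),
                        "classification": c.classification,
                    }
                    for c in intercalations.get(k.step_index, [])
                ],
            }
            for k in kinks
        ],
    }


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2)
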