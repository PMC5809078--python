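#!/usr/bin/env python
"""Build the synthetic structure set the downstream analyses run on.

Generates, from prescribed step parameters, the complex types the
screening workflow must tell apart: a clean kinked protein-DNA complex
with an intercalated wedge, an RNA duplex, a single strand, a duplex
with dangling ends, one with a flipped-out base, a two-duplex model and
an NMR-flagged copy.  Structures go to scratch/fixtures/ (PDB); a
manifest of what was planted goes to results/fixture_manifest.json.
"""

import json
import warnings
from pathlib import Path

from kinkscan.structure_io import AtomRecord, classify_residue, write_structure
from kinkscan.synthetic_data import (
    StepParameterProfile,
    add_overhang,
    build_duplex,
    flip_base,
    plant_intercalator,
)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results"

SEQUENCE = "GCGTATACGCG"
KINK_STEP = 5
KINK_ROLL = 54.0   # the sharp Sac7d-scale kink


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    manifest = {}

    kinked = build_duplex(StepParameterProfile.ideal(SEQUENCE).with_roll(KINK_STEP, KINK_ROLL))
    complex_ = plant_intercalator(kinked, KINK_STEP, "MET", 2.0)
    complex_ = plant_intercalator(complex_, KINK_STEP, "VAL", 1.8, lateral_offset=2.5)
    write_structure(complex_, OUT / "kinked_complex.pdb")
    manifest["kinked_complex"] = {
        "sequence": SEQUENCE, "kink_step": KINK_STEP, "kink_roll": KINK_ROLL,
        "planted_residues": ["MET@2.0A", "VAL@1.8A"],
    }

    rna = build_duplex(StepParameterProfile.ideal("GCGCGC"))
    for res in rna.iter_residues():
        res.atoms.append(AtomRecord(name="O2'", element="O",
                                    position=res.atoms[0].position + 1.0))
        res.kind = classify_residue(res)
    write_structure(rna, OUT / "rna_duplex.pdb")
    manifest["rna_duplex"] = {"note": "ribose O2' on every residue"}

    single = build_duplex(StepParameterProfile.ideal("GCGCGCGC"))
    del single.chains["B"]
    write_structure(single, OUT / "single_strand.pdb")
    manifest["single_strand"] = {"note": "strand II removed"}

    overhung = add_overhang(kinked, 2, strand="I", end="5p")
    write_structure(overhung, OUT / "dangling_ends.pdb")
    manifest["dangling_ends"] = {"overhang_nt": 2, "end": "5p"}

    flipped = flip_base(build_duplex(StepParameterProfile.ideal(SEQUENCE)), "A", 6, 120.0)
    write_structure(flipped, OUT / "flipped_base.pdb")
    manifest["flipped_base"] = {"flipped_position": 6, "angle_deg": 120.0}

    import copy
    import numpy as np
    second = build_duplex(StepParameterProfile.ideal("ATTGCAAT").with_roll(4, 45.0),
                          chain_I="C", chain_II="D")
    for res in second.iter_residues():
        for atom in res.atoms:
            atom.position = atom.position + np.array([50.0, 0.0, 0.0])
    combined = copy.deepcopy(kinked)
    combined.chains.update(second.chains)
    write_structure(combined, OUT / "two_duplexes.pdb")
    manifest["two_duplexes"] = {"kinks": {"A/B": (KINK_STEP, KINK_ROLL), "C/D": (4, 45.0)}}

    nmr = OUT / "nmr_copy.pdb"
    nmr.write_text("EXPDTA    SOLUTION NMR\n" + (OUT / "kinked_complex.pdb").read_text())
    manifest["nmr_copy"] = {"note": "same coordinates, NMR header"}

    (RESULTS / "fixture_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print(f"wrote {len(manifest)} fixtures to {OUT}")
    print(f"manifest: {RESULTS / 'fixture_manifest.json'}")


if __name__ == "__main__":
    warnings.filterwarnings("ignore", message=".*experiment-method.*")
    main()
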