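#!/usr/bin/env python
"""In-silico alanine mutants of the intercalating sidechains.

Takes the kinked synthetic complex (MET + VAL wedges at the kinked
step), truncates each intercalating sidechain to alanine -- singly and
combined, the way mutant simulations are set up from a wildtype
structure -- and re-runs intercalation detection.  The static coordinates
keep their kink (relaxation needs dynamics, cf. 04), but the wedge
inventory changes: truncated residues stop being detected as
intercalating.  Output: results/mutant_truncation.json.
"""

import json
from pathlib import Path

from kinkscan.duplex_builder import build_curated_duplexes
from kinkscan.helix_geometry import roll_profile
from kinkscan.kink_analysis import detect_intercalation, detect_kinks
from kinkscan.structure_io import truncate_sidechain
from kinkscan.synthetic_data import (
    StepParameterProfile,
    build_duplex,
    plant_intercalator,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

SEQUENCE = "GCGTATACGCG"
KINK_STEP = 5


def inventory(model):
    dup = build_curated_duplexes(model)[0]
    prof, _ = roll_profile(dup, model)
    kinks = detect_kinks(prof)
    calls = detect_intercalation(model, dup, KINK_STEP)
    return {
        "kink_angle_deg": round(kinks[0].roll, 2) if kinks else None,
        "intercalating": [
            {"residue": f"{c.residue[0]}{c.residue[1]}{c.residue[2]}",
             "n_atoms": c.n_inserted_atoms, "class": c.classification}
            for c in calls
        ],
    }


def main():
    wildtype = build_duplex(
        StepParameterProfile.ideal(SEQUENCE).with_roll(KINK_STEP, 54.0))
    wildtype = plant_intercalator(wildtype, KINK_STEP, "MET", 2.0)
    wildtype = plant_intercalator(wildtype, KINK_STEP, "VAL", 1.8,
                                  lateral_offset=2.5)

    systems = {"wildtype": wildtype}
    systems["M1A"] = truncate_sidechain(wildtype, ("P", 1, ""), "ALA")
    systems["V2A"] = truncate_sidechain(wildtype, ("P", 2, ""), "ALA")
    systems["M1A_V2A"] = truncate_sidechain(systems["M1A"], ("P", 2, ""), "ALA")

    report = {name: inventory(model) for name, model in systems.items()}
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "mutant_truncation.json").write_text(json.dumps(report, indent=2) + "\n")

    for name, entry in report.items():
        wedges = ", ".join(f"{w['residue']}({w['class']})"
                           for w in entry["intercalating"]) or "none"
        print(f"{name:10s} kink {entry['kink_angle_deg']} deg   wedges: {wedges}")
    print(f"\nreport: {RESULTS / 'mutant_truncation.json'}")


if __name__ == "__main__":
    main()
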