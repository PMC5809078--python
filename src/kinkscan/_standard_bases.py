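"""Idealized base geometries in the standard nucleic-acid reference frame.

Each base is given in its own standard frame: the base plane is the
xy-plane, x points toward the major groove, y toward the strand-I
backbone (C1'), and z completes a right-handed system (along strand I
5'->3' in a regular helix).  Coordinates are in angstroms.

The tables carry the ring atoms, the Watson-Crick donor/acceptor
exocyclic atoms and C1' -- everything the pairing, frame-fitting and
coordinate-generation code needs.  The complementary (strand II) base is
obtained by negating y and z (a 180 degree flip about x).
"""

from __future__ import annotations

import numpy as np

# atom -> (x, y, z) in the standard base frame
STANDARD_BASE_COORDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, 0.000),
        "N3": (-2.342, 2.364, 0.000),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.000),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.000),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.000),
        "C6": (-0.024, 5.057, 0.000),
    },
}

PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": PURINE_RING,
    "G": PURINE_RING,
    "C": PYRIMIDINE_RING,
    "T": PYRIMIDINE_RING,
}

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# canonical Watson-Crick donor/acceptor contacts, (atom on purine, atom on
# pyrimidine); A:T has two, G:C three
WC_HBONDS: dict[tuple[str, str], tuple[tuple[str, str], ...]] = {
    ("A", "T"): (("N1", "N3"), ("N6", "O4")),
    ("G", "C"): (("O6", "N4"), ("N1", "N3"), ("N2", "O2")),
}


def wc_hbond_atoms(base_a: str, base_b: str) -> tuple[tuple[str, str], ...]:
    """Donor/acceptor atom-name pairs for a putative WC pair, ordered
    (atom of base_a, atom of base_b).  Empty tuple if not complementary."""
    if (base_a, base_b) in WC_HBONDS:
        return WC_HBONDS[(base_a, base_b)]
    if (base_b, base_a) in WC_HBONDS:
        return tuple((y, x) for x, y in WC_HBONDS[(base_b, base_a)])
    return ()


def standard_coords(base: str, atom_names=None) -> tuple[list[str], np.ndarray]:
    """Return (names, Nx3 array) of the standard geometry of one base."""
    table = STANDARD_BASE_COORDS[base]
    names = list(table) if atom_names is None else [n for n in atom_names if n in table]
    return names, np.array([table[n] for n in names], dtype=float)
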