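"""Synthetic B-DNA coordinate generator.

The exact inverse of the measurement scheme: a duplex is rebuilt from a
prescribed step-parameter profile by chaining :func:`apply_step` from an
identity pair frame and dropping ideal Watson-Crick pairs (standard base
geometries, zero intra-pair parameters) into each frame.  Because build
and measure share one convention, measure(build(profile)) reproduces the
profile to machine precision -- which makes the generator the oracle for
every analysis stage.

On top of plain duplexes the module plants the features the curation and
intercalation stages must handle: snapshot ensembles with normally
fluctuating per-step roll, dangling single-stranded overhangs, flipped
out bases, and protein sidechain wedges inserted at a step.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from ._standard_bases import COMPLEMENT, standard_coords
from .duplex_builder import build_curated_duplexes
from .helix_geometry import (
    ReferenceFrame,
    StepParameters,
    apply_step,
    base_pair_frame,
    fit_base_frame,
    mid_step_frame,
    previous_frame,
)
from .structure_io import (
    AtomRecord,
    ResidueRecord,
    StructureEnsemble,
    StructureModel,
    classify_residue,
)

__all__ = [
    "StepParameterProfile",
    "EnsembleSpec",
    "build_duplex",
    "simulate_roll_ensemble",
    "plant_intercalator",
    "duplex_from_build",
    "add_overhang",
    "flip_base",
]

# fiber B-DNA defaults: twist 36 deg, rise 3.38 A, everything else zero
DEFAULT_STEP = (0.0, 0.0, 3.38, 0.0, 0.0, 36.0)
PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")


@dataclass
class StepParameterProfile:
    """A strand-I sequence plus one (shift, slide, rise, tilt, roll,
    twist) sextuple per dinucleotide step."""

    sequence_I: str
    steps: np.ndarray  # (n_steps, 6)

    def __post_init__(self):
        self.sequence_I = self.sequence_I.upper()
        self.steps = np.atleast_2d(np.asarray(self.steps, dtype=float))
        if len(self.steps) != len(self.sequence_I) - 1:
            raise ValueError(
                f"profile has {len(self.steps)} steps for a "
                f"{len(self.sequence_I)}-nt sequence; need len(sequence)-1"
            )
        bad = set(self.sequence_I) - set("ACGT")
        if bad:
            raise ValueError(f"sequence contains non-ACGT letters: {sorted(bad)}")
        if np.any(self.steps[:, 2] <= 0):
            raise ValueError("rise must be positive")

    @classmethod
    def ideal(cls, sequence: str) -> "StepParameterProfile":
        n = len(sequence) - 1
        return cls(sequence_I=sequence, steps=np.tile(DEFAULT_STEP, (n, 1)))

    def with_roll(self, step_index: int, roll: float) -> "StepParameterProfile":
        """Copy with the roll of one step (1-based) replaced."""
        steps = self.steps.copy()
        steps[step_index - 1, 4] = roll
        return StepParameterProfile(sequence_I=self.sequence_I, steps=steps)

    @property
    def rolls(self) -> np.ndarray:
        return self.steps[:, 4]

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass
class EnsembleSpec:
    mean_profile: StepParameterProfile
    roll_sd_per_step: float | np.ndarray = 8.0
    n_snapshots: int = 2000
    seed: int = 0

    def __post_init__(self):
        sd = np.broadcast_to(np.asarray(self.roll_sd_per_step, dtype=float),
                             (self.mean_profile.n_steps,))
        if np.any(sd < 0):
            raise ValueError("roll SD must be non-negative")
        if self.n_snapshots < 1:
            raise ValueError("need at least one snapshot")
        self.roll_sd_per_step = np.array(sd)


def _element_of(atom_name: str) -> str:
    return atom_name[0]  # C1'/Nx/Ox/SD -> C/N/O/S


_FLIP = np.diag([1.0, -1.0, -1.0])


def _place_base(letter: str, frame: ReferenceFrame, flipped: bool) -> list[AtomRecord]:
    names, coords = standard_coords(letter)
    if flipped:
        coords = coords @ _FLIP.T
    placed = frame.to_global(coords)
    return [AtomRecord(name=n, element=_element_of(n), position=p)
            for n, p in zip(names, placed)]


def pair_frames_from_profile(profile: StepParameterProfile) -> list[ReferenceFrame]:
    frames = [ReferenceFrame(origin=np.zeros(3), axes=np.eye(3))]
    for row in profile.steps:
        frames.append(apply_step(frames[-1], StepParameters(*row)))
    return frames


def build_duplex(profile: StepParameterProfile,
                 chain_I: str = "A", chain_II: str = "B",
                 model_index: int = 0) -> StructureModel:
    """Build duplex coordinates from a step-parameter profile.

    Strand I goes into chain A (residues 1..N, 5'->3'), the complement
    into chain B (residues 1..N along its own 5'->3', antiparallel).
    Atoms per base: ring, WC donor/acceptor exocyclics, and C1'.
    """
    frames = pair_frames_from_profile(profile)
    n = len(profile.sequence_I)
    model = StructureModel(model_index=model_index)
    res_I: list[ResidueRecord] = []
    res_II: list[ResidueRecord] = []
    for i, letter in enumerate(profile.sequence_I):
        frame = frames[i]
        name_I = "D" + letter
        comp = COMPLEMENT[letter]
        res_I.append(ResidueRecord(
            chain_id=chain_I, number=i + 1, name=name_I,
            atoms=_place_base(letter, frame, flipped=False)))
        # partner occupies position n - i along strand II 5'->3'
        res_II.append(ResidueRecord(
            chain_id=chain_II, number=n - i, name="D" + comp,
            atoms=_place_base(comp, frame, flipped=True)))
    res_II.sort(key=lambda r: r.number)
    model.chains[chain_I] = res_I
    model.chains[chain_II] = res_II
    for r in model.iter_residues():
        r.kind = classify_residue(r)
    return model


def duplex_from_build(model: StructureModel, chain_I: str = "A",
                      chain_II: str = "B"):
    """The known pairing of a generator duplex, without geometric
    detection: chain-A residue i pairs chain-B residue N+1-i.

    Useful as the ground-truth duplex in round-trip checks, where the
    measurement must be tested independently of pair detection.
    """
    from .duplex_builder import BasePair, Duplex, count_wc_hbonds

    res_I = model.chains[chain_I]
    res_II = {r.number: r for r in model.chains[chain_II]}
    n = len(res_I)
    pairs = []
    for i, r1 in enumerate(res_I):
        r2 = res_II[n - i]
        d = float(np.linalg.norm(r1.atom("C1'").position - r2.atom("C1'").position))
        pairs.append(BasePair(res_I=r1, res_II=r2,
                              n_hbonds=count_wc_hbonds(r1, r2),
                              c1c1_distance=d))
    seq = "".join(r.name[-1] for r in res_I)
    return Duplex(pairs=pairs, sequence_I=seq)


def simulate_roll_ensemble(spec: EnsembleSpec) -> StructureEnsemble:
    """Snapshot ensemble with per-step roll drawn independently from a
    normal distribution about the mean profile (all other parameters
    fixed).  Fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    models = []
    base = spec.mean_profile
    for k in range(spec.n_snapshots):
        steps = base.steps.copy()
        steps[:, 4] = base.rolls + spec.roll_sd_per_step * rng.standard_normal(base.n_steps)
        profile = StepParameterProfile(sequence_I=base.sequence_I, steps=steps)
        models.append(build_duplex(profile, model_index=k))
    return StructureEnsemble(models=models, metadata={
        "identifier": "SYNTHETIC-ENSEMBLE",
        "source_format": "synthetic",
        "experiment_method": "SYNTHETIC MD STAND-IN",
        "seed": spec.seed,
    })


# sidechain heavy-atom templates in insertion coordinates: +x is the
# insertion direction (deepest atom at x = 0), y/z give modest spread
# templates are nearly planar (|z| <= 0.1): a wedge rides the middle of
# the step slab the way stacked sidechains do in minor-groove binders
SIDECHAIN_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "VAL": {"CB": (-1.3, 0.0, 0.0), "CG1": (0.0, 0.8, 0.1), "CG2": (0.0, -0.8, -0.1)},
    "LEU": {"CB": (-2.5, 0.0, -0.1), "CG": (-1.3, 0.0, 0.1),
            "CD1": (0.0, 0.8, 0.1), "CD2": (0.0, -0.8, -0.1)},
    "MET": {"CB": (-3.9, 0.0, 0.1), "CG": (-2.6, 0.0, -0.1),
            "SD": (-1.4, 0.0, 0.1), "CE": (0.0, 0.0, 0.0)},
    "PHE": {"CB": (-4.2, 0.0, 0.1), "CG": (-2.8, 0.0, 0.0),
            "CD1": (-2.1, 1.2, 0.1), "CD2": (-2.1, -1.2, -0.1),
            "CE1": (-0.7, 1.2, 0.1), "CE2": (-0.7, -1.2, -0.1),
            "CZ": (0.0, 0.0, 0.0)},
}

# backbone sits at a fixed distance outside the step slab, on the
# minor-groove side
_BACKBONE_LOCAL = {"CA": (-9.5, 0.0, 0.0), "N": (-10.3, 0.9, 0.5),
                   "C": (-10.2, -0.9, -0.4), "O": (-11.3, -1.1, -0.6)}

C1_LINE_X = -2.47  # mid-frame x of the C1'-C1' line in an ideal pair

CLASH_DIST = 1.5


def _step_mid_frame(model: StructureModel, step_index: int) -> tuple[ReferenceFrame, float]:
    """Mid-step frame of one step plus the mid-frame x of its C1'-C1'
    line (the insertion-depth reference)."""
    duplexes = build_curated_duplexes(model)
    if not duplexes:
        raise ValueError("model contains no duplex")
    duplex = duplexes[0]
    if not (1 <= step_index <= len(duplex.pairs) - 1):
        raise IndexError(f"step {step_index} outside duplex (1..{len(duplex.pairs) - 1})")
    def pf(pair):
        f1, _ = fit_base_frame(pair.res_I)
        f2, _ = fit_base_frame(pair.res_II)
        return base_pair_frame(f1, f2)
    pair_a = duplex.pairs[step_index - 1]
    pair_b = duplex.pairs[step_index]
    mid = mid_step_frame(pf(pair_a), pf(pair_b))
    c1s = [res.atom("C1'").position for pair in (pair_a, pair_b)
           for res in (pair.res_I, pair.res_II) if res.atom("C1'") is not None]
    x_line = float(np.mean([mid.to_local(p)[0] for p in c1s])) if c1s else C1_LINE_X
    return mid, x_line


def plant_intercalator(model: StructureModel, step_index: int,
                       residue_name: str, depth: float,
                       chain_id: str = "P",
                       lateral_offset: float = 0.0) -> StructureModel:
    """Insert a protein sidechain wedge into a base-pair step.

    The sidechain template is placed in the step's mid frame with its
    deepest atom ``depth`` angstroms past the C1'-C1' line toward the
    helix axis, approaching from the minor groove; backbone atoms stay
    outside the step slab.  Any placed atom closer than 1.5 A to a DNA
    atom raises a placement error.
    """
    residue_name = residue_name.upper()
    if residue_name not in SIDECHAIN_TEMPLATES:
        raise ValueError(f"no template for {residue_name!r}; "
                         f"available: {sorted(SIDECHAIN_TEMPLATES)}")
    mid, x_line = _step_mid_frame(model, step_index)
    local: dict[str, np.ndarray] = {}
    for name, off in SIDECHAIN_TEMPLATES[residue_name].items():
        local[name] = np.array([x_line + depth + off[0],
                                off[1] + lateral_offset, off[2]])
    for name, off in _BACKBONE_LOCAL.items():
        local[name] = np.array([off[0], off[1] + lateral_offset, off[2]])
    atoms = [AtomRecord(name=n, element=("S" if n == "SD" else _element_of(n)),
                        position=mid.to_global(p))
             for n, p in local.items()]

    dna_coords = np.array([a.position for r in model.iter_residues()
                           if r.kind == "dna_nucleotide" for a in r.atoms])
    for a in atoms:
        d = np.min(np.linalg.norm(dna_coords - a.position, axis=1))
        if d < CLASH_DIST:
            raise ValueError(
                f"placement clash: atom {a.name} only {d:.2f} A from DNA"
            )
    new_model = copy.deepcopy(model)
    number = 1 + max((r.number for r in new_model.chains.get(chain_id, [])), default=0)
    residue = ResidueRecord(chain_id=chain_id, number=number, name=residue_name,
                            atoms=atoms, kind="amino_acid")
    new_model.chains.setdefault(chain_id, []).append(residue)
    return new_model


def add_overhang(model: StructureModel, n: int, strand: str = "I",
                 end: str = "5p", sequence: str | None = None,
                 chain_I: str = "A", chain_II: str = "B") -> StructureModel:
    """Append n unpaired nucleotides continuing the helix beyond one
    terminus of a generator duplex (a dangling single-stranded end)."""
    if n < 1:
        raise IndexError("overhang length must be >= 1")
    if end not in ("5p", "3p") or strand not in ("I", "II"):
        raise IndexError(f"invalid strand/end {strand!r}/{end!r}")
    sequence = (sequence or "T" * n).upper()
    if len(sequence) != n:
        raise ValueError("sequence length must equal n")
    new_model = copy.deepcopy(model)
    duplexes = build_curated_duplexes(new_model)
    if not duplexes:
        raise ValueError("model contains no duplex")
    duplex = duplexes[0]

    def pf(pair):
        f1, _ = fit_base_frame(pair.res_I)
        f2, _ = fit_base_frame(pair.res_II)
        return base_pair_frame(f1, f2)

    ideal = StepParameters(*DEFAULT_STEP)
    chain_name = chain_I if strand == "I" else chain_II
    chain = new_model.chains[chain_name]
    flipped = strand == "II"
    # direction of helical continuation: strand I 5' end sits at the
    # first pair, strand II 5' end at the last pair (antiparallel)
    backward = (strand == "I") == (end == "5p")
    if backward:
        frame = pf(duplex.pairs[0])
        advance = previous_frame
    else:
        frame = pf(duplex.pairs[-1])
        advance = apply_step

    low = min(r.number for r in chain)
    high = max(r.number for r in chain)
    # the strand's own 5' terminus carries the lowest residue number
    prepend = end == "5p"
    new_residues = []
    for k, letter in enumerate(sequence):
        frame = advance(frame, ideal)
        number = (low - 1 - k) if prepend else (high + 1 + k)
        res = ResidueRecord(chain_id=chain_name, number=number,
                            name="D" + letter,
                            atoms=_place_base(letter, frame, flipped=flipped))
        res.kind = classify_residue(res)
        new_residues.append(res)
    chain.extend(new_residues)
    chain.sort(key=lambda r: (r.number, r.insertion_code))
    return new_model


def flip_base(model: StructureModel, chain_id: str, residue_number: int,
              angle: float = 120.0) -> StructureModel:
    """Rotate one base out of the helix about its glycosidic axis.

    The base atoms (everything but C1') are rotated by ``angle`` degrees
    about the C1'-N9 (purine) or C1'-N1 (pyrimidine) axis; angle 0
    returns an identical model.
    """
    new_model = copy.deepcopy(model)
    residue = new_model.find_residue(chain_id, residue_number)
    if residue is None:
        raise IndexError(f"no residue {residue_number} in chain {chain_id}")
    c1 = residue.atom("C1'")
    anchor = residue.atom("N9") or residue.atom("N1")
    if c1 is None or anchor is None:
        raise ValueError(f"residue {(chain_id, residue_number)} lacks glycosidic atoms")
    axis = anchor.position - c1.position
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle)
    K = np.array([[0.0, -axis[2], axis[1]],
                  [axis[2], 0.0, -axis[0]],
                  [-axis[1], axis[0], 0.0]])
    R = np.eye(3) + math.sin(t) * K + (1.0 - math.cos(t)) * (K @ K)
    pivot = c1.position
    for atom in residue.atoms:
        if atom.name == "C1'":
            continue
        atom.position = R @ (atom.position - pivot) + pivot
    return new_model
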