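"""Base reference frames and base-pair-step parameters.

The mid-step-frame (CEHS-style) scheme: a standard base geometry is
least-squares fitted onto each observed base to define its reference
frame; paired frames are averaged (after flipping the strand-II frame)
into a pair frame; consecutive pair frames yield the six rigid-body step
parameters shift, slide, rise (angstroms) and tilt, roll, twist
(degrees).  Roll is the central observable: positive roll opens the step
toward the minor groove (x points toward the major groove).

The scheme is exactly invertible -- :func:`apply_step` rebuilds the next
pair frame from the parameters, which is what the synthetic generator
uses, and measure(build(p)) == p to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from ._standard_bases import RING_ATOMS, standard_coords
from .structure_io import ResidueRecord, StructureModel, base_letter

__all__ = [
    "ReferenceFrame",
    "StepParameters",
    "RollProfile",
    "fit_base_frame",
    "base_pair_frame",
    "compute_step_parameters",
    "apply_step",
    "previous_frame",
    "roll_profile",
]


@dataclass
class ReferenceFrame:
    """A right-handed orthonormal frame: origin plus axis columns (x, y, z)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    def is_orthonormal(self, tol: float = 1e-9) -> bool:
        return (np.allclose(self.axes.T @ self.axes, np.eye(3), atol=tol)
                and abs(np.linalg.det(self.axes) - 1.0) < tol)

    def to_global(self, local: np.ndarray) -> np.ndarray:
        return (self.axes @ np.asarray(local, dtype=float).T).T + self.origin

    def to_local(self, global_xyz: np.ndarray) -> np.ndarray:
        return (self.axes.T @ (np.asarray(global_xyz, dtype=float) - self.origin).T).T


@dataclass
class StepParameters:
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float
    step_index: int = 0
    dinucleotide: str = ""
    flags: set = field(default_factory=set)

    def as_array(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise,
                         self.tilt, self.roll, self.twist])


@dataclass
class RollProfile:
    rolls: np.ndarray  # degrees; NaN marks a step that could not be measured
    dinucleotides: list[str]
    flags: list[set] = field(default_factory=list)

    def __post_init__(self):
        self.rolls = np.asarray(self.rolls, dtype=float)
        if not self.flags:
            self.flags = [set() for _ in self.rolls]

    @property
    def n_steps(self) -> int:
        return len(self.rolls)


def _rot_z(t: float) -> np.ndarray:
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(t: float) -> np.ndarray:
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_axis(axis: np.ndarray, t: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0.0, -axis[2], axis[1]],
                  [axis[2], 0.0, -axis[0]],
                  [-axis[1], axis[0], 0.0]])
    return np.eye(3) + math.sin(t) * K + (1.0 - math.cos(t)) * (K @ K)


def _kabsch(reference: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform: observed ~ R @ reference + t.

    Proper rotation enforced (det = +1).  Returns (R, t, rmsd).
    """
    ref_c = reference.mean(axis=0)
    obs_c = observed.mean(axis=0)
    H = (reference - ref_c).T @ (observed - obs_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = obs_c - R @ ref_c
    delta = (R @ reference.T).T + t - observed
    rmsd = math.sqrt((delta ** 2).sum() / len(observed))
    return R, t, rmsd


def fit_base_frame(residue: ResidueRecord) -> tuple[ReferenceFrame, float]:
    """Fit the standard base geometry onto an observed nucleotide.

    The rigid transform carrying the embedded standard base (defined in
    its own frame at the origin) onto the observed atoms defines the
    base frame; the superposition RMSD is returned with it.
    """
    letter = base_letter(residue)
    if letter is None:
        raise ValueError(f"residue {residue.id} ({residue.name}) is not a standard DNA base")
    present = [n for n in residue.atom_names()]
    names, ref = standard_coords(letter, present)
    n_ring = sum(1 for n in names if n in RING_ATOMS[letter])
    if n_ring < 6:
        raise ValueError(
            f"residue {residue.id}: only {n_ring} ring atoms present, need >= 6"
        )
    obs = np.array([residue.atom(n).position for n in names])
    R, t, rmsd = _kabsch(ref, obs)
    return ReferenceFrame(origin=t, axes=R), rmsd


_FLIP_X = np.diag([1.0, -1.0, -1.0])


def base_pair_frame(frame_I: ReferenceFrame, frame_II: ReferenceFrame) -> ReferenceFrame:
    """Average two paired base frames into the base-pair frame.

    The strand-II frame is first flipped 180 degrees about its x-axis
    (its y and z axes are negated), then each frame is rotated halfway
    along the relative rotation toward the other; the origin is the
    midpoint of the two origins.
    """
    R1 = frame_I.axes
    R2 = frame_II.axes @ _FLIP_X
    R_rel = R2 @ R1.T
    rotvec = Rotation.from_matrix(R_rel).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle > math.pi / 2:
        raise ValueError(
            f"relative base rotation {math.degrees(angle):.1f} deg > 90 deg: "
            "degenerate (non-Watson-Crick) pair geometry"
        )
    if angle < 1e-15:
        R_pair = R1
    else:
        R_pair = Rotation.from_rotvec(rotvec / 2.0).as_matrix() @ R1
    origin = (frame_I.origin + frame_II.origin) / 2.0
    return ReferenceFrame(origin=origin, axes=R_pair)


def compute_step_parameters(pair_i: ReferenceFrame, pair_j: ReferenceFrame,
                            step_index: int = 0,
                            dinucleotide: str = "") -> StepParameters:
    """Six rigid-body parameters between consecutive base-pair frames.

    Mid-step-frame scheme: the two triads are rotated by -/+ Gamma/2
    about the hinge (z_i x z_j) so their z-axes merge; twist is then the
    in-plane x-axis angle, the mid frame the half-twist interpolation,
    and (roll, tilt) the decomposition of Gamma along the hinge phase
    angle measured from the mid-frame y-axis.  Translations are the
    origin displacement in mid-frame coordinates.
    """
    R1, R2 = pair_i.axes, pair_j.axes
    z1, z2 = R1[:, 2], R2[:, 2]
    cross = np.cross(z1, z2)
    gamma = math.atan2(float(np.linalg.norm(cross)), float(z1 @ z2))
    if gamma >= math.pi / 2:
        raise ValueError(
            f"step {step_index}: bending angle {math.degrees(gamma):.1f} deg >= 90 deg "
            "(antiparallel frames)"
        )
    if gamma < 1e-12:
        R1p, R2p = R1, R2
        hinge = None
    else:
        hinge = cross / np.linalg.norm(cross)
        R1p = _rot_axis(hinge, +gamma / 2.0) @ R1
        R2p = _rot_axis(hinge, -gamma / 2.0) @ R2
    zm = R1p[:, 2]
    x1, x2 = R1p[:, 0], R2p[:, 0]
    twist = math.atan2(float(np.cross(x1, x2) @ zm), float(x1 @ x2))
    Rm = _rot_axis(zm, twist / 2.0) @ R1p if abs(twist) > 0 else R1p
    disp = Rm.T @ (pair_j.origin - pair_i.origin)
    if hinge is None:
        roll = tilt = 0.0
    else:
        ym = Rm[:, 1]
        phi = math.atan2(float(np.cross(ym, hinge) @ zm), float(ym @ hinge))
        roll = gamma * math.cos(phi)
        tilt = gamma * math.sin(phi)
    return StepParameters(
        shift=float(disp[0]), slide=float(disp[1]), rise=float(disp[2]),
        tilt=math.degrees(tilt), roll=math.degrees(roll), twist=math.degrees(twist),
        step_index=step_index, dinucleotide=dinucleotide,
    )


def mid_step_frame(pair_i: ReferenceFrame, pair_j: ReferenceFrame) -> ReferenceFrame:
    """The mid-step frame of two consecutive pair frames (same
    construction as :func:`compute_step_parameters`, origin at the
    midpoint)."""
    R1, R2 = pair_i.axes, pair_j.axes
    z1, z2 = R1[:, 2], R2[:, 2]
    cross = np.cross(z1, z2)
    gamma = math.atan2(float(np.linalg.norm(cross)), float(z1 @ z2))
    if gamma < 1e-12:
        R1p, R2p = R1, R2
    else:
        hinge = cross / np.linalg.norm(cross)
        R1p = _rot_axis(hinge, +gamma / 2.0) @ R1
        R2p = _rot_axis(hinge, -gamma / 2.0) @ R2
    zm = R1p[:, 2]
    twist = math.atan2(float(np.cross(R1p[:, 0], R2p[:, 0]) @ zm),
                       float(R1p[:, 0] @ R2p[:, 0]))
    Rm = _rot_axis(zm, twist / 2.0) @ R1p if abs(twist) > 0 else R1p
    return ReferenceFrame(origin=(pair_i.origin + pair_j.origin) / 2.0, axes=Rm)


def apply_step(frame: ReferenceFrame, params: StepParameters) -> ReferenceFrame:
    """Exact inverse of :func:`compute_step_parameters`: advance a pair
    frame by the given step parameters."""
    tilt = math.radians(params.tilt)
    roll = math.radians(params.roll)
    twist = math.radians(params.twist)
    gamma = math.hypot(roll, tilt)
    phi = math.atan2(tilt, roll)
    R1 = frame.axes
    R2 = R1 @ _rot_z(twist / 2.0 + phi) @ _rot_y(gamma) @ _rot_z(twist / 2.0 - phi)
    Rm = R1 @ _rot_z(twist / 2.0 + phi) @ _rot_y(gamma / 2.0) @ _rot_z(-phi)
    origin = frame.origin + Rm @ np.array([params.shift, params.slide, params.rise])
    return ReferenceFrame(origin=origin, axes=R2)


def previous_frame(frame: ReferenceFrame, params: StepParameters) -> ReferenceFrame:
    """Step a pair frame backward: the frame F with apply_step(F, p) == frame."""
    tilt = math.radians(params.tilt)
    roll = math.radians(params.roll)
    twist = math.radians(params.twist)
    gamma = math.hypot(roll, tilt)
    phi = math.atan2(tilt, roll)
    T = _rot_z(twist / 2.0 + phi) @ _rot_y(gamma) @ _rot_z(twist / 2.0 - phi)
    R1 = frame.axes @ T.T
    Rm = R1 @ _rot_z(twist / 2.0 + phi) @ _rot_y(gamma / 2.0) @ _rot_z(-phi)
    origin = frame.origin - Rm @ np.array([params.shift, params.slide, params.rise])
    return ReferenceFrame(origin=origin, axes=R1)


def pair_frames_for_duplex(duplex, model: StructureModel | None = None):
    """Fit a base-pair frame for every pair of a duplex.

    Returns a list parallel to ``duplex.pairs``; entries are None where
    frame fitting failed (e.g. missing ring atoms).  ``model`` is
    accepted for symmetry with the rest of the API but the residues
    referenced by the duplex already carry their coordinates.
    """
    frames = []
    for pair in duplex.pairs:
        try:
            f1, _ = fit_base_frame(pair.res_I)
            f2, _ = fit_base_frame(pair.res_II)
            frames.append(base_pair_frame(f1, f2))
        except ValueError:
            frames.append(None)
    return frames


def roll_profile(duplex, model: StructureModel | None = None
                 ) -> tuple[RollProfile, list[StepParameters]]:
    """Step-parameter table and roll profile of one duplex.

    Steps are indexed 1..N-1 on the paired core and labeled by the
    strand-I dinucleotide.  A step whose flanking frames cannot be fit
    is reported as missing (NaN roll, 'missing' flag) instead of
    aborting the profile; steps flanking a flipped-out position carry a
    'flip_adjacent' flag.
    """
    frames = pair_frames_for_duplex(duplex, model)
    seq = duplex.sequence_I
    steps: list[StepParameters] = []
    rolls: list[float] = []
    flags: list[set] = []
    for i in range(len(frames) - 1):
        dinuc = seq[i:i + 2]
        flag: set = set()
        if (i + 1) in duplex.flipped_positions or (i + 2) in duplex.flipped_positions:
            flag.add("flip_adjacent")
        if frames[i] is None or frames[i + 1] is None:
            flag.add("missing")
            steps.append(StepParameters(*([math.nan] * 6), step_index=i + 1,
                                        dinucleotide=dinuc, flags=flag))
            rolls.append(math.nan)
        else:
            try:
                sp = compute_step_parameters(frames[i], frames[i + 1],
                                             step_index=i + 1, dinucleotide=dinuc)
            except ValueError:
                flag.add("missing")
                steps.append(StepParameters(*([math.nan] * 6), step_index=i + 1,
                                            dinucleotide=dinuc, flags=flag))
                rolls.append(math.nan)
                flags.append(flag)
                continue
            sp.flags = flag
            steps.append(sp)
            rolls.append(sp.roll)
        flags.append(flag)
    profile = RollProfile(rolls=np.array(rolls), dinucleotides=[s.dinucleotide for s in steps],
                          flags=flags)
    return profile, steps


def steps_to_tsv(steps: list[StepParameters]) -> str:
    """Step-parameter table as TSV text."""
    lines = ["step_index\tdinucleotide\tshift\tslide\trise\ttilt\troll\ttwist\tflags"]
    for s in steps:
        lines.append(
            f"{s.step_index}\t{s.dinucleotide}\t{s.shift:.4f}\t{s.slide:.4f}\t"
            f"{s.rise:.4f}\t{s.tilt:.4f}\t{s.roll:.4f}\t{s.twist:.4f}\t"
            f"{','.join(sorted(s.flags)) if s.flags else '-'}"
        )
    return "\n".join(lines) + "\n"
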