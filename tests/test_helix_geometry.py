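"""Base-frame fitting and step-parameter measurement.

The central contract is exact invertibility against the synthetic
generator and the rigid-motion / strand-reversal symmetries of the six
step parameters.
"""

import math

import numpy as np
import pytest

from kinkscan.helix_geometry import (
    ReferenceFrame,
    StepParameters,
    apply_step,
    base_pair_frame,
    compute_step_parameters,
    fit_base_frame,
    roll_profile,
)
from kinkscan.structure_io import AtomRecord, ResidueRecord
from kinkscan.synthetic_data import (
    StepParameterProfile,
    build_duplex,
    duplex_from_build,
)
from kinkscan._standard_bases import standard_coords

from conftest import random_profile, random_rotation


def _base_residue(letter, R=np.eye(3), t=np.zeros(3), noise=0.0, rng=None):
    names, coords = standard_coords(letter)
    coords = (R @ coords.T).T + t
    if noise:
        coords = coords + rng.normal(0, noise, coords.shape)
    atoms = [AtomRecord(name=n, element=n[0], position=p) for n, p in zip(names, coords)]
    return ResidueRecord(chain_id="A", number=1, name="D" + letter, atoms=atoms,
                         kind="dna_nucleotide")


def _measure_model(profile):
    model = build_duplex(profile)
    _, steps = roll_profile(duplex_from_build(model), model)
    return np.array([s.as_array() for s in steps])


class TestFitBaseFrame:
    def test_recovers_planted_transform_exactly(self, rng):
        R = random_rotation(rng)
        t = rng.normal(size=3) * 10
        frame, rmsd = fit_base_frame(_base_residue("G", R, t))
        assert rmsd < 1e-12
        np.testing.assert_allclose(frame.axes, R, atol=1e-12)
        np.testing.assert_allclose(frame.origin, t, atol=1e-12)

    def test_noisy_coordinates_stay_close(self, rng):
        R = random_rotation(rng)
        t = rng.normal(size=3) * 5
        frame, rmsd = fit_base_frame(_base_residue("A", R, t, noise=0.1, rng=rng))
        assert rmsd <= 0.15
        # axis deviation: rotation angle between fitted and planted frames
        rel = frame.axes @ R.T
        angle = math.degrees(math.acos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
        assert angle <= 2.0

    def test_mirror_image_still_proper_rotation(self):
        res = _base_residue("C")
        for atom in res.atoms:
            atom.position = atom.position * np.array([1.0, 1.0, -1.0])
        frame, _ = fit_base_frame(res)
        assert np.linalg.det(frame.axes) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_ring_atoms_rejected(self):
        res = _base_residue("T")
        res.atoms = [a for a in res.atoms if a.name in ("N1", "C2", "N3", "C1'")]
        with pytest.raises(ValueError, match="ring atoms"):
            fit_base_frame(res)


class TestBasePairFrame:
    def test_exact_flip_returns_strand_I_frame(self, rng):
        R = random_rotation(rng)
        f1 = ReferenceFrame(origin=np.zeros(3), axes=R)
        f2 = ReferenceFrame(origin=np.ones(3), axes=R @ np.diag([1.0, -1.0, -1.0]))
        pair = base_pair_frame(f1, f2)
        np.testing.assert_allclose(pair.axes, R, atol=1e-12)
        np.testing.assert_allclose(pair.origin, 0.5 * np.ones(3), atol=1e-12)

    def test_planted_relative_rotation_is_bisected(self):
        from scipy.spatial.transform import Rotation

        f1 = ReferenceFrame(origin=np.zeros(3), axes=np.eye(3))
        rot10 = Rotation.from_euler("x", 10, degrees=True).as_matrix()
        f2 = ReferenceFrame(origin=np.zeros(3),
                            axes=(rot10 @ np.eye(3)) @ np.diag([1.0, -1.0, -1.0]))
        pair = base_pair_frame(f1, f2)
        rel = pair.axes @ f1.axes.T
        half = math.degrees(math.acos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
        assert half == pytest.approx(5.0, abs=1e-9)

    def test_degenerate_pair_rejected(self):
        from scipy.spatial.transform import Rotation

        f1 = ReferenceFrame(origin=np.zeros(3), axes=np.eye(3))
        bad = Rotation.from_euler("x", 120, degrees=True).as_matrix()
        f2 = ReferenceFrame(origin=np.zeros(3),
                            axes=bad @ np.diag([1.0, -1.0, -1.0]))
        with pytest.raises(ValueError, match="degenerate"):
            base_pair_frame(f1, f2)

    def test_generator_pair_origin_on_helix_axis(self, ideal_model):
        dup = duplex_from_build(ideal_model)
        f1, _ = fit_base_frame(dup.pairs[0].res_I)
        f2, _ = fit_base_frame(dup.pairs[0].res_II)
        pair = base_pair_frame(f1, f2)
        # pair frame 1 of the generator is the identity frame: origin 0
        np.testing.assert_allclose(pair.origin, np.zeros(3), atol=1e-6)


class TestStepParameters:
    def test_pure_twist_step(self):
        f1 = ReferenceFrame(origin=np.zeros(3), axes=np.eye(3))
        f2 = apply_step(f1, StepParameters(0, 0, 3.38, 0, 0, 36))
        p = compute_step_parameters(f1, f2)
        np.testing.assert_allclose(
            p.as_array(), [0, 0, 3.38, 0, 0, 36], atol=1e-12)

    def test_antiparallel_frames_rejected(self):
        f1 = ReferenceFrame(origin=np.zeros(3), axes=np.eye(3))
        f2 = ReferenceFrame(origin=np.array([0, 0, 3.4]),
                            axes=np.diag([1.0, -1.0, -1.0]))
        with pytest.raises(ValueError, match="90"):
            compute_step_parameters(f1, f2)

    def test_single_planted_roll_recovered(self, ideal_profile):
        profile = ideal_profile.with_roll(5, 54.0)
        measured = _measure_model(profile)
        assert np.max(np.abs(measured - profile.steps)) < 1e-6

    def test_round_trip_random_profiles(self, rng):
        worst = 0.0
        for _ in range(30):
            profile = random_profile(rng)
            measured = _measure_model(profile)
            worst = max(worst, np.max(np.abs(measured - profile.steps)))
        assert worst < 1e-6

    def test_rigid_motion_invariance(self, rng, kinked_profile):
        model = build_duplex(kinked_profile)
        ref = _measure_model(kinked_profile)
        for _ in range(10):
            R = random_rotation(rng)
            t = rng.normal(size=3) * 50
            import copy
            moved = copy.deepcopy(model)
            for res in moved.iter_residues():
                for atom in res.atoms:
                    atom.position = R @ atom.position + t
            _, steps = roll_profile(duplex_from_build(moved), moved)
            got = np.array([s.as_array() for s in steps])
            assert np.max(np.abs(got - ref)) < 1e-9

    def test_strand_reversal_symmetry(self, rng):
        """Reading the duplex along the other strand negates tilt and
        shift and keeps slide, rise, roll, twist."""
        from kinkscan.duplex_builder import Duplex, BasePair

        for _ in range(10):
            profile = random_profile(rng)
            model = build_duplex(profile)
            dup = duplex_from_build(model)
            flipped_pairs = [
                BasePair(res_I=p.res_II, res_II=p.res_I, n_hbonds=p.n_hbonds,
                         c1c1_distance=p.c1c1_distance)
                for p in reversed(dup.pairs)
            ]
            from kinkscan._standard_bases import COMPLEMENT
            rev = Duplex(pairs=flipped_pairs,
                         sequence_I="".join(COMPLEMENT[c] for c in reversed(dup.sequence_I)))
            _, fwd = roll_profile(dup, model)
            _, bwd = roll_profile(rev, model)
            a = np.array([s.as_array() for s in fwd])
            b = np.array([s.as_array() for s in bwd])[::-1]
            expected = a * np.array([-1, 1, 1, -1, 1, 1])
            assert np.max(np.abs(b - expected)) < 1e-9


class TestRollProfile:
    def test_ideal_duplex_all_zero_roll(self, ideal_model):
        profile, steps = roll_profile(duplex_from_build(ideal_model), ideal_model)
        assert profile.n_steps == 10
        assert np.max(np.abs(profile.rolls)) < 1e-6
        assert [s.twist for s in steps] == pytest.approx([36.0] * 10, abs=1e-6)

    def test_prescribed_kink_shape_recovered(self, ideal_profile):
        profile_in = ideal_profile.with_roll(4, 35.0).with_roll(5, 50.0).with_roll(6, 35.0)
        model = build_duplex(profile_in)
        profile, _ = roll_profile(duplex_from_build(model), model)
        np.testing.assert_allclose(profile.rolls, profile_in.rolls, atol=1e-6)

    def test_missing_ring_atoms_degrade_gracefully(self, ideal_model):
        # strip base ring atoms of residue 6 on strand I: steps 5 and 6
        # become missing, everything else is intact
        res = ideal_model.find_residue("A", 6)
        res.atoms = [a for a in res.atoms if a.name in ("C1'", "N1", "C2")]
        profile, steps = roll_profile(duplex_from_build(ideal_model), ideal_model)
        assert math.isnan(profile.rolls[4]) and math.isnan(profile.rolls[5])
        assert "missing" in steps[4].flags and "missing" in steps[5].flags
        ok = [r for i, r in enumerate(profile.rolls) if i not in (4, 5)]
        assert np.max(np.abs(ok)) < 1e-6
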