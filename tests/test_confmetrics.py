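"""Superposition, RMSD, helix-angle, contact and H-bond metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conforma import confmetrics as cm
from conforma.structio import CoordinateSet, ResidueRange, SelectionError, select_atoms
from conforma.toysystems import (
    make_core_and_helix,
    make_synthetic_helix,
    rotation_about_axis,
    transform_structure,
)

from conftest import build_structure

CORE = ResidueRange("A", 1, 30, "CA")
HELIX = ResidueRange("A", 50, 61, "CA")
REGION = ResidueRange("A", 50, 61, "backbone")


def brute_force_min_rmsd(mobile, reference, n_axes=400, angle_step=2.0):
    """Exhaustive proper-rotation search (Fibonacci axes x angle grid)."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    golden = np.pi * (3 - np.sqrt(5))
    i = np.arange(n_axes)
    z = 1 - 2 * (i + 0.5) / n_axes
    r = np.sqrt(1 - z * z)
    axes = np.stack([r * np.cos(golden * i), r * np.sin(golden * i), z], axis=1)
    best = np.inf
    for axis in axes:
        for ang in np.arange(0.0, 360.0, angle_step):
            R = rotation_about_axis(axis, ang)
            rmsd = np.sqrt(np.mean(np.sum((mob @ R.T - ref) ** 2, axis=1)))
            best = min(best, rmsd)
    return best


class TestKabsch:
    def test_self_superposition(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        res = cm.kabsch_superpose(pts, pts)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(res.translation, 0, atol=1e-9)
        assert res.rmsd == pytest.approx(0, abs=1e-9)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        R0 = rotation_about_axis((1, 2, 3), 37.0)
        shift = np.array([4.0, -1.0, 2.5])
        moved = pts @ R0.T + shift
        res = cm.kabsch_superpose(pts, moved)
        assert np.allclose(res.rotation, R0, atol=1e-6)
        assert res.rmsd == pytest.approx(0, abs=1e-8)

    def test_proper_rotation_invariants(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 8, 3))
        res = cm.kabsch_superpose(a, b)
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_mirror_image_not_matched_by_reflection(self):
        # Chiral 4-point set: its mirror image cannot be superposed to 0
        # by any proper rotation.
        chiral = np.array(
            [[0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0.3, 0.4, 2.5]], dtype=float
        )
        mirror = chiral * np.array([1, 1, -1])
        res = cm.kabsch_superpose(mirror, chiral)
        assert res.rmsd > 0.1
        brute = brute_force_min_rmsd(mirror, chiral)
        assert res.rmsd <= brute + 1e-9

    def test_rmsd_never_exceeds_unfitted(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a, b = rng.normal(size=(2, 6, 3))
            res = cm.kabsch_superpose(a, b)
            raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert res.rmsd <= raw + 1e-12

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cm.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRegionRmsd:
    def test_identical_structures(self):
        s = make_core_and_helix()
        assert cm.region_rmsd(s, s, CORE, REGION) == pytest.approx(0, abs=1e-9)

    def test_uniform_translation_gives_its_norm(self):
        s = make_core_and_helix()
        b = transform_structure(s, translation=(3, 4, 0), res_range=(50, 61))
        assert cm.region_rmsd(s, b, CORE, REGION) == pytest.approx(5.0, abs=1e-6)

    def test_symmetric_in_arguments(self):
        s = make_core_and_helix()
        b = transform_structure(
            s, rotation=rotation_about_axis((0, 1, 0), 25), res_range=(50, 61)
        )
        d_ab = cm.region_rmsd(s, b, CORE, REGION)
        d_ba = cm.region_rmsd(b, s, CORE, REGION)
        assert d_ab == pytest.approx(d_ba, abs=1e-6)

    def test_invariant_under_global_rigid_motion(self):
        s = make_core_and_helix()
        b = transform_structure(s, translation=(3, 4, 0), res_range=(50, 61))
        b_moved = transform_structure(
            b, rotation=rotation_about_axis((1, 1, 0), 73), translation=(5, -2, 9)
        )
        assert cm.region_rmsd(s, b_moved, CORE, REGION) == pytest.approx(
            5.0, abs=1e-6
        )


class TestHelixFrame:
    def test_ideal_helix_axis_along_z(self):
        # The PCA axis of a finite helix carries a small intrinsic tilt
        # that decays with length; at 10 turns it is well under 2 deg.
        helix = make_synthetic_helix(36)
        frame = cm.helix_frame(select_atoms(helix, ResidueRange("A", 1, 36, "CA")))
        angle = np.degrees(np.arccos(np.clip(frame.axis @ [0, 0, 1], -1, 1)))
        assert angle < 2.0

    def test_reversed_order_flips_axis(self):
        helix = make_synthetic_helix(12)
        cset = select_atoms(helix, ResidueRange("A", 1, 12, "CA"))
        rev = CoordinateSet(cset.labels[::-1], cset.points[::-1].copy())
        f_fwd = cm.helix_frame(cset)
        f_rev = cm.helix_frame(rev)
        assert np.allclose(f_fwd.axis, -f_rev.axis, atol=1e-9)

    def test_collinear_points_give_line_direction(self):
        pts = np.outer(np.arange(5, dtype=float), [1.0, 0, 0])
        frame = cm.helix_frame(pts)
        assert np.allclose(np.abs(frame.axis), [1, 0, 0], atol=1e-9)
        assert frame.axis[0] > 0  # oriented first -> last

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cm.helix_frame(np.zeros((3, 3)))


class TestDisplacementAngle:
    def test_zero_for_identical(self):
        s = make_core_and_helix()
        assert cm.helix_displacement_angle(s, s, CORE, HELIX) == pytest.approx(
            0, abs=1e-6
        )

    @pytest.mark.parametrize("angle", [30.0, 60.0, 150.0])
    def test_recovers_constructed_rotation(self, angle):
        s = make_core_and_helix()
        # Rotate the mobile helix about an axis perpendicular to its own
        # axis (~z), in place about its centroid.
        helix_pts = select_atoms(s, ResidueRange("A", 50, 61, "CA")).points
        centroid = helix_pts.mean(axis=0)
        R = rotation_about_axis((1, 0, 0), angle)
        b = transform_structure(
            s, rotation=R, translation=centroid - R @ centroid,
            res_range=(50, 61),
        )
        got = cm.helix_displacement_angle(s, b, CORE, HELIX)
        assert got == pytest.approx(angle, abs=1.0)

    def test_invariant_under_global_motion_of_either(self):
        s = make_core_and_helix()
        R = rotation_about_axis((1, 0, 0), 60)
        b = transform_structure(s, rotation=R, res_range=(50, 61))
        base = cm.helix_displacement_angle(s, b, CORE, HELIX)
        b2 = transform_structure(
            b, rotation=rotation_about_axis((0, 1, 1), 119), translation=(7, 7, -3)
        )
        assert cm.helix_displacement_angle(s, b2, CORE, HELIX) == pytest.approx(
            base, abs=1e-6
        )


class TestChargeClamp:
    def test_midpoint_distance(self):
        s = build_structure(
            [
                (314, "LYS", {"NZ": (0, 0, 0)}),
                (493, "GLU", {"OE1": (3, 0, 0), "OE2": (3, 2, 0)}),
            ]
        )
        d = cm.charge_clamp_distance(s, 314, 493, "A")
        assert d == pytest.approx(np.sqrt(10), abs=1e-9)

    def test_missing_sidechain_names_residue(self):
        s = build_structure([(314, "LYS", {"CA": (0, 0, 0)}),
                             (493, "GLU", {"OE1": (3, 0, 0), "OE2": (3, 2, 0)})])
        with pytest.raises(SelectionError, match="314"):
            cm.charge_clamp_distance(s, 314, 493, "A")

    def test_absent_residue_raises(self):
        s = build_structure([(1, "ALA", {"CA": (0, 0, 0)})])
        with pytest.raises(SelectionError):
            cm.charge_clamp_distance(s, 314, 493, "A")


class TestContactsAndHbonds:
    @pytest.fixture
    def two_residue_structure(self):
        return build_structure(
            [
                (10, "LEU", {"CA": (0, 0, 0), "CD1": (1.0, 0, 0)}),
                (20, "ILE", {"CA": (6.0, 0, 0), "CD1": (4.0, 0, 0)}),
            ]
        )

    def test_contact_within_cutoff(self, two_residue_structure):
        pairs = cm.contact_map(
            two_residue_structure,
            ResidueRange("A", 10, 10), ResidueRange("A", 20, 20), cutoff=4.5,
        )
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(3.0)

    def test_contact_outside_cutoff(self, two_residue_structure):
        pairs = cm.contact_map(
            two_residue_structure,
            ResidueRange("A", 10, 10), ResidueRange("A", 20, 20), cutoff=2.5,
        )
        assert pairs == []

    @given(c1=st.floats(0.5, 8.0), c2=st.floats(0.5, 8.0))
    @settings(max_examples=20, deadline=None)
    def test_contact_monotone_in_cutoff(self, c1, c2):
        s = build_structure(
            [
                (10, "LEU", {"CA": (0, 0, 0), "CD1": (1.0, 0.2, 0)}),
                (20, "ILE", {"CA": (6.0, 0, 0), "CD1": (3.5, 0, 0)}),
                (21, "VAL", {"CA": (0, 5.0, 0), "CG1": (0, 2.8, 0)}),
            ]
        )
        lo, hi = sorted((c1, c2))
        a = ResidueRange("A", 10, 10)
        b = ResidueRange("A", 20, 21)
        pairs_lo = {(p[0], p[1]) for p in cm.contact_map(s, a, b, lo)}
        pairs_hi = {(p[0], p[1]) for p in cm.contact_map(s, a, b, hi)}
        assert pairs_lo <= pairs_hi

    def test_hbond_detected_and_cutoff_respected(self):
        s = build_structure(
            [
                (12, "SER", {"CA": (3, 3, 0), "OG": (0, 0, 0)}),
                (40, "GLU", {"CA": (5.8, 0, 0), "OE1": (2.9, 0, 0),
                             "OE2": (4.0, 1.0, 0)}),
            ]
        )
        bonds = cm.hydrogen_bonds(s, d_cut=3.5)
        pairs = {(d[3], a[3]) for d, a, _ in bonds}
        assert ("OG", "OE1") in pairs
        far = build_structure(
            [
                (12, "SER", {"CA": (3, 3, 0), "OG": (0, 0, 0)}),
                (40, "GLU", {"CA": (7, 0, 0), "OE1": (4.0, 0, 0),
                             "OE2": (5.0, 1.0, 0)}),
            ]
        )
        assert cm.hydrogen_bonds(far, d_cut=3.5) == []


class TestProjectStructure:
    def _refs(self):
        ref_c = make_core_and_helix()
        R = rotation_about_axis((1, 0, 0), 90)
        ref_a = transform_structure(ref_c, rotation=R, translation=(14, 0, 0),
                                    res_range=(50, 61))
        return ref_c, ref_a

    def test_projection_of_the_references(self):
        ref_c, ref_a = self._refs()
        cv = ResidueRange("A", 50, 61, "CA")
        rc, ra = cm.project_structure(ref_a, ref_c, ref_a, cv)
        assert ra == pytest.approx(0, abs=1e-6)
        d = cm.region_rmsd(ref_c, ref_a, ResidueRange("A", 1, 30, "CA"),
                           ResidueRange("A", 50, 61, "CA"))
        assert rc == pytest.approx(d, abs=1e-6)
        rc2, ra2 = cm.project_structure(ref_c, ref_c, ref_a, cv)
        assert rc2 == pytest.approx(0, abs=1e-6)
        assert ra2 == pytest.approx(d, abs=1e-6)

    def test_midpoint_morph_closer_to_both(self):
        ref_c, ref_a = self._refs()
        cv = ResidueRange("A", 50, 61, "CA")
        # Linear coordinate interpolation of every shared atom.
        morph = transform_structure(ref_c)  # deep copy
        for (rkey, res) in morph.chains["A"].items():
            for name, atom in res.atoms.items():
                other = ref_a.chains["A"][rkey].atoms[name]
                atom.position[:] = 0.5 * (atom.position + other.position)
        d = cm.region_rmsd(ref_c, ref_a, ResidueRange("A", 1, 30, "CA"),
                           ResidueRange("A", 50, 61, "CA"))
        rc, ra = cm.project_structure(morph, ref_c, ref_a, cv)
        assert rc < d and ra < d
        assert abs(rc - ra) <= d + 1e-9


class TestRmsdDistribution:
    def test_identical_frames(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        counts, edges, rmsds = cm.rmsd_distribution([pts] * 5, n_bins=4)
        assert np.allclose(rmsds, 0, atol=1e-9)
        assert counts.sum() == 5

    def test_mirror_displaced_frames_have_equal_rmsd(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 3)) * 3
        delta = np.zeros((10, 3))
        delta[:, 0] = rng.normal(size=10)
        _, _, rmsds = cm.rmsd_distribution([base + delta, base - delta])
        assert rmsds[0] == pytest.approx(rmsds[1], abs=1e-6)

    def test_stiff_anchor_gives_narrower_distribution(self):
        # Boltzmann displacements about an anchor at two stiffnesses:
        # the stiffer anchor must give the lower-mean RMSD distribution.
        rng = np.random.default_rng(2)
        base = select_atoms(
            make_synthetic_helix(10), ResidueRange("A", 1, 10, "CA")
        ).points
        kt = 0.593
        trajs = {}
        for label, k in (("stiff", 10.0), ("loose", 0.5)):
            sigma = np.sqrt(kt / k)
            trajs[label] = [
                base + rng.normal(scale=sigma, size=base.shape)
                for _ in range(60)
            ]
        _, _, r_stiff = cm.rmsd_distribution(trajs["stiff"])
        _, _, r_loose = cm.rmsd_distribution(trajs["loose"])
        assert r_stiff.mean() < r_loose.mean()

    def test_frame_length_mismatch(self):
        with pytest.raises(ValueError):
            cm.rmsd_distribution([np.zeros((5, 3)), np.zeros((6, 3))])
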