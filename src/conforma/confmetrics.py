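"""Pairwise structural metrics between conformers of a ligand-binding domain.

The questions these metrics answer are the standard ones asked when a
nuclear-receptor helix 12 (H12) shows up somewhere unexpected: how far is
the helix from the canonical agonist position (region RMSD after a core
superposition), how is it oriented (displacement angle between helix
axes), is the coactivator charge clamp intact (Lys NZ to Glu carboxylate
distance), which hydrophobic contacts and hydrogen bonds hold the new
position in place, and where does a conformation sit on an
(RMSD_C, RMSD_A) free-energy landscape built from RMSDs to the canonical
and alternative reference structures.

All superpositions are least-squares rigid fits restricted to proper
rotations (no reflections).  Region RMSDs are computed after fitting on a
*core* that excludes the mobile region — fitting on the moving part would
absorb exactly the displacement being measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structio import (
    CoordinateSet,
    ResidueRange,
    SelectionError,
    Structure,
    pair_common_atoms,
    select_atoms,
)

__all__ = [
    "SuperpositionResult",
    "HelixFrame",
    "ConformerReport",
    "kabsch_superpose",
    "region_rmsd",
    "helix_frame",
    "helix_displacement_angle",
    "charge_clamp_distance",
    "contact_map",
    "hydrogen_bonds",
    "project_structure",
    "rmsd_distribution",
    "conformer_report",
    "DEFAULT_HBOND_CUTOFF",
    "DEFAULT_CONTACT_CUTOFF",
]

DEFAULT_HBOND_CUTOFF = 3.5  # Å, heavy-atom donor–acceptor
DEFAULT_CONTACT_CUTOFF = 4.5  # Å, heavy-atom hydrophobic contact


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper rigid transform mapping a mobile set onto a reference."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å after transform

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass(frozen=True)
class HelixFrame:
    """Helix axis (unit vector, N->C oriented) and centroid."""

    axis: np.ndarray
    centroid: np.ndarray


@dataclass
class ConformerReport:
    """All pairwise metrics between an alternative and a reference conformer."""

    region_rmsd: float
    displacement_angle: float
    charge_clamp_distance: float | None = None
    contacts: list[tuple] = field(default_factory=list)
    hbonds: list[tuple] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "region_rmsd": self.region_rmsd,
            "displacement_angle": self.displacement_angle,
            "charge_clamp_distance": self.charge_clamp_distance,
            "contacts": [
                {"residue_a": list(a), "residue_b": list(b), "distance": d}
                for a, b, d in self.contacts
            ],
            "hbonds": [
                {"donor": list(d), "acceptor": list(a), "distance": r}
                for d, a, r in self.hbonds
            ],
        }


def _as_points(x) -> np.ndarray:
    if isinstance(x, CoordinateSet):
        return x.points
    return np.asarray(x, dtype=float)


def kabsch_superpose(mobile, reference) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the proper rotation (det +1; mirror images are never matched
    by a reflection) and translation minimizing the RMSD between the
    transformed mobile points and the reference, plus that minimal RMSD.
    """
    mob = _as_points(mobile)
    ref = _as_points(reference)
    if mob.shape != ref.shape:
        raise ValueError(f"point sets differ in shape: {mob.shape} vs {ref.shape}")
    if len(mob) < 3:
        raise ValueError("need at least 3 points for a rigid superposition")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    r_mat = rot.as_matrix()
    if np.linalg.matrix_rank(mob - mob_c) < 2:
        raise ValueError("points are collinear; rotation is underdetermined")
    translation = ref_c - r_mat @ mob_c
    moved = mob @ r_mat.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=r_mat, translation=translation, rmsd=rmsd)


def _select_multi(s: Structure, ranges) -> CoordinateSet:
    """Select over one range or a sequence of ranges, concatenated in order."""
    if isinstance(ranges, ResidueRange):
        ranges = [ranges]
    parts = [select_atoms(s, r) for r in ranges]
    labels = [lab for p in parts for lab in p.labels]
    points = np.vstack([p.points for p in parts])
    return CoordinateSet(labels, points)


def _core_superposition(a: Structure, b: Structure, core) -> SuperpositionResult:
    core_a = _select_multi(a, core)
    core_b = _select_multi(b, core)
    pa, pb = pair_common_atoms(core_a, core_b)
    return kabsch_superpose(pb, pa)


def region_rmsd(
    a: Structure,
    b: Structure,
    core,
    region: ResidueRange,
) -> float:
    """RMSD of a region after superposing ``b`` onto ``a`` by the core.

    The core and region are paired across the two models on shared
    (residue, atom) labels; the fit uses core atoms only and the region
    RMSD is computed on the core-fitted coordinates with no further
    fitting.  This is the displacement measure used to compare H12
    positions between conformers.
    """
    fit = _core_superposition(a, b, core)
    reg_a = _select_multi(a, region)
    reg_b = _select_multi(b, region)
    pa, pb = pair_common_atoms(reg_a, reg_b)
    moved = fit.apply(pb.points)
    return float(np.sqrt(np.mean(np.sum((moved - pa.points) ** 2, axis=1))))


def helix_frame(helix_ca) -> HelixFrame:
    """Axis and centroid of a helix from its Cα trace.

    The axis is the first principal direction of the centered Cα cloud,
    with its sign fixed so the projection of (last − first) Cα onto the
    axis is positive, i.e. the axis points N-terminus -> C-terminus.
    """
    pts = _as_points(helix_ca)
    if len(pts) < 4:
        raise ValueError("need at least 4 CA points to define a helix axis")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(pts[-1] - pts[0], axis) < 0:
        axis = -axis
    return HelixFrame(axis=axis / np.linalg.norm(axis), centroid=centroid)


def helix_displacement_angle(
    a: Structure,
    b: Structure,
    core,
    helix: ResidueRange,
) -> float:
    """Angle in degrees between the helix axes of two conformers.

    ``b`` is superposed onto ``a`` by the core; each structure's helix
    axis comes from its own Cα trace (no cross-structure pairing needed),
    and the reported angle is arccos of the dot product of the two
    N->C-oriented axes, in [0, 180].  ~0° means the helices are parallel
    (same position/orientation class), ~180° anti-parallel.
    """
    fit = _core_superposition(a, b, core)
    helix_ca = ResidueRange(helix.chain_id, helix.start, helix.end, "CA")
    frame_a = helix_frame(select_atoms(a, helix_ca))
    helix_ca_b = ResidueRange(helix.chain_id, helix.start, helix.end, "CA")
    frame_b = helix_frame(select_atoms(b, helix_ca_b))
    axis_b_moved = fit.rotation @ frame_b.axis
    cosang = float(np.clip(np.dot(frame_a.axis, axis_b_moved), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def charge_clamp_distance(
    s: Structure, lys_res: int, glu_res: int, chain: str = "A"
) -> float:
    """Distance (Å) from the clamp Lys NZ to the clamp Glu carboxylate midpoint.

    The midpoint of OE1/OE2 is used rather than a single oxygen so the
    value is robust to crystallographic OE1/OE2 naming swaps.  An intact
    coactivator charge clamp sits at a short, peptide-gripping distance;
    a displaced H12 pulls the Glu away.
    """
    lys = s.residue(chain, lys_res)
    glu = s.residue(chain, glu_res)
    if "NZ" not in lys.atoms:
        raise SelectionError(f"residue {chain}:{lys_res} has no NZ atom (Lys side chain missing)")
    if "OE1" not in glu.atoms or "OE2" not in glu.atoms:
        raise SelectionError(f"residue {chain}:{glu_res} lacks OE1/OE2 (Glu carboxylate missing)")
    nz = lys.atoms["NZ"].position
    mid = 0.5 * (glu.atoms["OE1"].position + glu.atoms["OE2"].position)
    return float(np.linalg.norm(nz - mid))


def _range_residues(s: Structure, r: ResidueRange):
    chain = s.chains.get(r.chain_id, {})
    for res_seq in range(r.start, r.end + 1):
        res = chain.get((res_seq, ""))
        if res is not None and not res.is_water:
            yield res


def contact_map(
    s: Structure,
    a: ResidueRange,
    b: ResidueRange,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[tuple[tuple, tuple, float]]:
    """Residue pairs across two ranges in heavy-atom contact.

    Returns ``[((chain, seq, name), (chain, seq, name), min_distance), ...]``
    for every residue pair (one residue from each range, identical
    residues excluded) whose minimal heavy-atom distance is <= cutoff,
    sorted by that distance.  Symmetric in the two ranges.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res_a = list(_range_residues(s, a))
    res_b = list(_range_residues(s, b))
    out = []
    for ra in res_a:
        pts_a = np.array([at.position for at in ra.heavy_atoms()])
        if len(pts_a) == 0:
            continue
        tree_a = cKDTree(pts_a)
        for rb in res_b:
            if (a.chain_id, ra.res_seq) == (b.chain_id, rb.res_seq):
                continue
            pts_b = np.array([at.position for at in rb.heavy_atoms()])
            if len(pts_b) == 0:
                continue
            dmin = float(np.min(tree_a.query(pts_b)[0]))
            if dmin <= cutoff:
                out.append(
                    (
                        (a.chain_id, ra.res_seq, ra.res_name),
                        (b.chain_id, rb.res_seq, rb.res_name),
                        dmin,
                    )
                )
    out.sort(key=lambda t: (t[2], t[0][1], t[1][1]))
    return out


# Default donor/acceptor role table keyed on (res_name, atom_name).
# Backbone N/O handled generically; for unlisted HETATM residues any
# nitrogen or oxygen is treated as both donor and acceptor (crystal
# structures carry no hydrogens, so roles are necessarily approximate).
_SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",), "ASN": ("ND2",), "GLN": ("NE2",), "SER": ("OG",),
    "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
}
_SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}


def _atom_roles(res, atom) -> tuple[bool, bool]:
    """(is_donor, is_acceptor) for a heavy atom under the default table."""
    if atom.is_hydrogen:
        return False, False
    if res.is_hetero and res.res_name not in _SIDECHAIN_DONORS:
        elem = (atom.element or atom.name[:1]).upper()
        polar = elem in ("N", "O")
        return polar, polar
    if atom.name == "N":
        return True, False
    if atom.name in ("O", "OXT"):
        return False, True
    donor = atom.name in _SIDECHAIN_DONORS.get(res.res_name, ())
    acceptor = atom.name in _SIDECHAIN_ACCEPTORS.get(res.res_name, ())
    return donor, acceptor


def hydrogen_bonds(
    s: Structure,
    ranges: Sequence[ResidueRange] | None = None,
    d_cut: float = DEFAULT_HBOND_CUTOFF,
    role_table=None,
) -> list[tuple[tuple, tuple, float]]:
    """Geometric hydrogen bonds: donor–acceptor heavy atoms within ``d_cut``.

    No angle criterion is applied — the crystallographic models carry no
    hydrogens, so a pure heavy-atom distance cutoff (default 3.5 Å) is
    used, matching how dashed-line interactions are typically read off a
    deposited structure.  Waters are excluded; pass a custom
    ``role_table(res, atom) -> (is_donor, is_acceptor)`` to override the
    built-in role assignment.  Intra-residue pairs are not reported.

    Returns ``[((chain, seq, resname, atom), (chain, seq, resname, atom), d), ...]``
    sorted by distance.
    """
    if d_cut <= 0:
        raise ValueError("d_cut must be positive")
    roles = role_table or _atom_roles
    donors = []
    acceptors = []
    for chain_id, residues in s.chains.items():
        for res in residues.values():
            if res.is_water:
                continue
            if ranges is not None and not any(
                r.chain_id == chain_id and r.start <= res.res_seq <= r.end
                for r in ranges
            ):
                continue
            for atom in res.atoms.values():
                is_d, is_a = roles(res, atom)
                label = (chain_id, res.res_seq, res.res_name, atom.name)
                if is_d:
                    donors.append((label, atom.position))
                if is_a:
                    acceptors.append((label, atom.position))
    if not donors or not acceptors:
        return []
    d_pts = np.array([p for _, p in donors])
    a_pts = np.array([p for _, p in acceptors])
    tree = cKDTree(a_pts)
    out = []
    for i, (d_label, d_pos) in enumerate(donors):
        for j in tree.query_ball_point(d_pos, d_cut):
            a_label = acceptors[j][0]
            if d_label[:2] == a_label[:2]:  # same residue
                continue
            dist = float(np.linalg.norm(d_pos - a_pts[j]))
            out.append((d_label, a_label, dist))
    out.sort(key=lambda t: (t[2], t[0], t[1]))
    return out


def _chain_complement(s: Structure, region: ResidueRange) -> list[ResidueRange]:
    """CA ranges covering the region's chain outside the region itself."""
    chain = s.chains[region.chain_id]
    seqs = sorted(seq for (seq, icode), res in chain.items()
                  if icode == "" and not res.is_water and not res.is_hetero)
    lo, hi = seqs[0], seqs[-1]
    ranges = []
    if lo < region.start:
        ranges.append(ResidueRange(region.chain_id, lo, region.start - 1, "CA"))
    if hi > region.end:
        ranges.append(ResidueRange(region.chain_id, region.end + 1, hi, "CA"))
    if not ranges:
        raise SelectionError("region covers the whole chain; no core left to fit on")
    return ranges


def project_structure(
    s: Structure,
    ref_c: Structure,
    ref_a: Structure,
    cv_region: ResidueRange,
    core=None,
) -> tuple[float, float]:
    """Project a conformation onto landscape axes (RMSD_C, RMSD_A).

    Each coordinate is the Cα RMSD of the collective-variable region
    (e.g. residues 469–501: C-terminus of H11, the H11–H12 loop and H12)
    against one reference structure, computed after superposing on the
    core (by default the complement of the CV region on the same chain).
    The canonical reference gives RMSD_C, the alternative gives RMSD_A.
    """
    ca_region = ResidueRange(cv_region.chain_id, cv_region.start, cv_region.end, "CA")
    out = []
    for ref in (ref_c, ref_a):
        fit_core = core if core is not None else _chain_complement(ref, ca_region)
        out.append(region_rmsd(ref, s, fit_core, ca_region))
    return out[0], out[1]


def average_structure(
    frames: Sequence[CoordinateSet] | Sequence[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Iterative fit-average structure of a trajectory.

    Alternates superposing every frame onto the current average with
    recomputing the mean coordinates, until the average moves by less
    than ``tol`` Å RMS or ``max_iter`` iterations.
    """
    pts = [_as_points(f) for f in frames]
    n = {p.shape for p in pts}
    if len(n) != 1:
        raise ValueError("all frames must have the same number of atoms")
    avg = pts[0].copy()
    for _ in range(max_iter):
        fitted = [kabsch_superpose(p, avg).apply(p) for p in pts]
        new_avg = np.mean(fitted, axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_avg - avg) ** 2, axis=1))))
        avg = new_avg
        if shift < tol:
            break
    return avg


def rmsd_distribution(
    traj: Sequence[CoordinateSet] | Sequence[np.ndarray],
    n_bins: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram of per-frame RMSD to the trajectory's average structure.

    A narrow distribution at low RMSD means the region is rigid about a
    well-defined mean position; a broad or shifted one means mobility.
    Returns ``(counts, bin_edges, rmsds)``.
    """
    pts = [_as_points(f) for f in traj]
    if len(pts) < 2:
        raise ValueError("need at least 2 frames")
    avg = average_structure(pts)
    rmsds = np.array([kabsch_superpose(p, avg).rmsd for p in pts])
    lo, hi = float(rmsds.min()), float(rmsds.max())
    if hi - lo < 1e-9:  # (near-)rigid trajectory: pad a degenerate range
        counts, edges = np.histogram(
            rmsds, bins=np.linspace(lo - 0.5, hi + 0.5, n_bins + 1)
        )
    else:
        counts, edges = np.histogram(rmsds, bins=n_bins)
    return counts, edges, rmsds


def conformer_report(
    alt: Structure,
    ref: Structure,
    core,
    region: ResidueRange,
    helix: ResidueRange | None = None,
    clamp: tuple[int, int, str] | None = None,
    contact_partner: ResidueRange | None = None,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
) -> ConformerReport:
    """Assemble the full metric set comparing ``alt`` against ``ref``."""
    helix = helix or region
    report = ConformerReport(
        region_rmsd=region_rmsd(ref, alt, core, region),
        displacement_angle=helix_displacement_angle(ref, alt, core, helix),
    )
    if clamp is not None:
        lys, glu, chain = clamp
        report.charge_clamp_distance = charge_clamp_distance(alt, lys, glu, chain)
    if contact_partner is not None:
        report.contacts = contact_map(alt, helix, contact_partner, contact_cutoff)
    report.hbonds = hydrogen_bonds(alt, d_cut=hbond_cutoff)
    return report
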