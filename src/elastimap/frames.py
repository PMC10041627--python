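"""Crystallographic frames, plane slices and close-contact geometry.

Links the Cartesian frame of the elastic tensor to the crystal lattice:
2-D modulus slices in the ab/ac/bc planes, periodic hydrogen-bond /
close-contact detection, and the quantitative alignment of contact-network
directions with the directions of maximal Young's modulus.

Frame convention: lattice vector a lies along Cartesian x, b lies in the
xy-plane with positive y, and c completes a right-handed set.  The elastic
tensor is assumed to be expressed in this same frame.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np

from .core import ElasticityError
from . import maps

__all__ = [
    "CrystalCell",
    "AtomSite",
    "ContactRecord",
    "ContactCriteria",
    "PiStackRecord",
    "PlaneSliceResult",
    "AlignmentReport",
    "find_carbon_rings",
    "detect_pi_stacks",
    "cell_to_cartesian",
    "plane_slice",
    "detect_contacts",
    "alignment_report",
    "read_cif",
    "write_cif",
]

PLANES = ("ab", "ac", "bc")


@dataclasses.dataclass(frozen=True)
class CrystalCell:
    """Unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0.0:
            raise ElasticityError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ElasticityError("cell angles must lie in (0, 180) degrees")
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        if 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg <= 0.0:
            raise ElasticityError("degenerate cell metric")

    @property
    def basis(self) -> np.ndarray:
        return cell_to_cartesian(self)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.basis))


def cell_to_cartesian(cell: CrystalCell) -> np.ndarray:
    """Cartesian lattice basis, rows = lattice vectors a, b, c (Angstrom).

    a along x; b in the xy-plane with positive y; c completing a
    right-handed set (the standard crystallographic construction).
    """
    # exact zeros for right angles so orthogonal cells give exact frames
    ca, cb, cg = (0.0 if x == 90.0 else math.cos(math.radians(x))
                  for x in (cell.alpha, cell.beta, cell.gamma))
    sg = 1.0 if cell.gamma == 90.0 else math.sin(math.radians(cell.gamma))
    v = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    avec = np.array([cell.a, 0.0, 0.0])
    bvec = np.array([cell.b * cg, cell.b * sg, 0.0])
    cvec = np.array([cell.c * cb,
                     cell.c * (ca - cb * cg) / sg,
                     cell.c * math.sqrt(v) / sg])
    return np.array([avec, bvec, cvec])


@dataclasses.dataclass(frozen=True)
class AtomSite:
    """An atom in fractional coordinates, wrapped into [0, 1)."""

    element: str
    frac: np.ndarray
    label: str

    @classmethod
    def make(cls, element: str, frac, label: str) -> "AtomSite":
        f = np.asarray(frac, dtype=float) % 1.0
        return cls(element=element, frac=f, label=label)


@dataclasses.dataclass(frozen=True)
class ContactRecord:
    """A periodic D-H...A contact, direction taken donor -> acceptor."""

    donor_label: str
    hydrogen_label: str
    acceptor_label: str
    donor_element: str
    acceptor_element: str
    d_HA: float       # Angstrom
    d_DA: float       # Angstrom
    angle_DHA: float  # degrees
    direction: np.ndarray  # unit Cartesian vector, donor -> acceptor
    image_shift: tuple[int, int, int]

    @property
    def contact_class(self) -> str:
        return f"{self.donor_element}-H...{self.acceptor_element}"


@dataclasses.dataclass(frozen=True)
class ContactCriteria:
    """Geometric contact rules (common crystallographic practice)."""

    donor_elements: frozenset = frozenset({"N", "O", "C"})
    acceptor_elements: frozenset = frozenset({"N", "O"})
    max_d_HA: float = 2.7        # Angstrom
    min_angle_DHA: float = 120.0  # degrees
    max_covalent_DH: float = 1.25  # Angstrom, D-H bond assignment

    def to_dict(self) -> dict:
        return {"donor_elements": sorted(self.donor_elements),
                "acceptor_elements": sorted(self.acceptor_elements),
                "max_d_HA": self.max_d_HA,
                "min_angle_DHA": self.min_angle_DHA,
                "max_covalent_DH": self.max_covalent_DH}


def _image_range(cell: CrystalCell, cutoff: float) -> list[tuple[int, int, int]]:
    """Lattice image shifts whose cells can contain points within ``cutoff``
    of the home cell, from the perpendicular widths of the cell."""
    basis = cell.basis
    recip = np.linalg.inv(basis).T  # rows: reciprocal vectors (no 2 pi)
    widths = 1.0 / np.linalg.norm(recip, axis=1)
    nmax = [int(math.ceil(cutoff / w)) for w in widths]
    return [s for s in itertools.product(*(range(-n, n + 1) for n in nmax))]


def detect_contacts(sites: list[AtomSite], cell: CrystalCell,
                    criteria: ContactCriteria | None = None) -> list[ContactRecord]:
    """Find periodic D-H...A contacts.

    Hydrogens are assigned to the nearest donor-element atom within the
    covalent D-H cutoff (over periodic images); each H is then tested
    against acceptor atoms in all relevant lattice images.  A contact is
    reported once per (donor, acceptor, image) triple.
    """
    crit = criteria or ContactCriteria()
    basis = cell.basis
    carts = np.array([s.frac % 1.0 for s in sites]) @ basis
    hydrogens = [i for i, s in enumerate(sites) if s.element == "H"]
    if not hydrogens:
        raise ElasticityError(
            "no hydrogen atoms in the structure; contact detection needs "
            "explicit hydrogens (e.g. a neutron or DFT-optimized structure)")

    cutoff = crit.max_d_HA + crit.max_covalent_DH
    shifts = _image_range(cell, cutoff)
    shift_carts = np.array(shifts, dtype=float) @ basis

    # covalent donor assignment: nearest donor-element atom within cutoff
    donors_of_h: dict[int, tuple[int, np.ndarray]] = {}
    for ih in hydrogens:
        best = None
        for ia, s in enumerate(sites):
            if s.element not in crit.donor_elements:
                continue
            d2 = np.sum((carts[ia] + shift_carts - carts[ih]) ** 2, axis=1)
            k = int(np.argmin(d2))
            d = math.sqrt(d2[k])
            if d <= crit.max_covalent_DH and (best is None or d < best[0]):
                best = (d, ia, carts[ia] + shift_carts[k])
        if best is not None:
            donors_of_h[ih] = (best[1], best[2])

    records: list[ContactRecord] = []
    seen: set[tuple[str, str, tuple[int, int, int]]] = set()
    for ih, (idon, don_pos) in donors_of_h.items():
        h_pos = carts[ih]
        for ia, s in enumerate(sites):
            if s.element not in crit.acceptor_elements:
                continue
            for shift, sc in zip(shifts, shift_carts):
                a_pos = carts[ia] + sc
                if ia == idon and np.allclose(a_pos, don_pos, atol=1e-6):
                    continue  # the donor atom itself
                d_ha = float(np.linalg.norm(a_pos - h_pos))
                if d_ha <= crit.max_covalent_DH or d_ha > crit.max_d_HA:
                    continue
                hd = don_pos - h_pos
                ha = a_pos - h_pos
                cosang = float(np.dot(hd, ha) /
                               (np.linalg.norm(hd) * np.linalg.norm(ha)))
                angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if angle < crit.min_angle_DHA:
                    continue
                key = (sites[idon].label, s.label, shift)
                if key in seen:
                    continue
                seen.add(key)
                da = a_pos - don_pos
                records.append(ContactRecord(
                    donor_label=sites[idon].label,
                    hydrogen_label=sites[ih].label,
                    acceptor_label=s.label,
                    donor_element=sites[idon].element,
                    acceptor_element=s.element,
                    d_HA=d_ha,
                    d_DA=float(np.linalg.norm(da)),
                    angle_DHA=angle,
                    direction=da / np.linalg.norm(da),
                    image_shift=tuple(int(x) for x in shift)))
    records.sort(key=lambda r: (r.donor_label, r.acceptor_label, r.image_shift))
    return records


@dataclasses.dataclass(frozen=True)
class PiStackRecord:
    """A ring-centroid pi-stacking contact between six-membered carbon
    rings.  Heuristic: classified parallel-displaced vs T-shaped by the
    dihedral angle between ring planes (30 degree threshold)."""

    ring_a: tuple[str, ...]
    ring_b: tuple[str, ...]
    d_centroid: float       # Angstrom
    dihedral_deg: float     # ring-plane angle folded into [0, 90]
    geometry: str           # "parallel-displaced" or "T-shaped"
    direction: np.ndarray   # unit Cartesian vector, centroid a -> b
    image_shift: tuple[int, int, int]

    @property
    def contact_class(self) -> str:
        return "pi...pi"


def find_carbon_rings(sites: list[AtomSite], cell: CrystalCell,
                      bond_cutoff: float = 1.8) -> list[list[int]]:
    """Six-membered carbon rings from the minimum-image C-C bond graph."""
    import networkx as nx

    basis = cell.basis
    carbons = [i for i, s in enumerate(sites) if s.element == "C"]
    g = nx.Graph()
    g.add_nodes_from(carbons)
    for a_pos, ia in [(sites[i].frac % 1.0, i) for i in carbons]:
        for ib in carbons:
            if ib <= ia:
                continue
            d_frac = (sites[ib].frac % 1.0) - a_pos
            d_frac -= np.rint(d_frac)
            if np.linalg.norm(d_frac @ basis) <= bond_cutoff:
                g.add_edge(ia, ib)
    rings = [sorted(cyc) for cyc in nx.minimum_cycle_basis(g) if len(cyc) == 6]
    rings.sort()
    return rings


def _ring_geometry(sites, cell, ring) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit plane normal of a ring, unwrapped by minimum image
    relative to its first atom."""
    basis = cell.basis
    f0 = sites[ring[0]].frac % 1.0
    pts = []
    for i in ring:
        d = (sites[i].frac % 1.0) - f0
        d -= np.rint(d)
        pts.append((f0 + d) @ basis)
    pts = np.array(pts)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def detect_pi_stacks(sites: list[AtomSite], cell: CrystalCell,
                     max_centroid: float = 4.5,
                     t_shape_dihedral: float = 30.0) -> list[PiStackRecord]:
    """Detect pi-stacking contacts between six-membered carbon rings.

    Periodic search over centroid pairs within ``max_centroid`` Angstrom;
    each pair is reported once per (ring_a, ring_b, image) with ring_a
    lexicographically first.  The parallel-displaced vs T-shaped label is a
    geometric heuristic (ring-plane dihedral vs ``t_shape_dihedral``).
    """
    rings = find_carbon_rings(sites, cell)
    if not rings:
        return []
    geom = [_ring_geometry(sites, cell, r) for r in rings]
    labels = [tuple(sites[i].label for i in r) for r in rings]
    shifts = _image_range(cell, max_centroid)
    basis = cell.basis
    out: list[PiStackRecord] = []
    for ia, (ca, na) in enumerate(geom):
        for ib in range(ia, len(geom)):
            cb, nb = geom[ib]
            for shift in shifts:
                if ib == ia and tuple(shift) <= (0, 0, 0):
                    continue  # self / double-counted image pair
                d_vec = cb + np.asarray(shift, float) @ basis - ca
                d = float(np.linalg.norm(d_vec))
                if not 1e-6 < d <= max_centroid:
                    continue
                cosd = abs(float(np.dot(na, nb)))
                dihedral = math.degrees(math.acos(np.clip(cosd, 0.0, 1.0)))
                out.append(PiStackRecord(
                    ring_a=labels[ia], ring_b=labels[ib],
                    d_centroid=d, dihedral_deg=dihedral,
                    geometry=("parallel-displaced"
                              if dihedral <= t_shape_dihedral else "T-shaped"),
                    direction=d_vec / d,
                    image_shift=tuple(int(x) for x in shift)))
    out.sort(key=lambda r: (r.ring_a, r.ring_b, r.image_shift))
    return out


@dataclasses.dataclass(frozen=True)
class PlaneSliceResult:
    """A directional modulus sampled around a crystallographic plane."""

    plane: str             # "ab", "ac" or "bc"
    property: str          # "young" or "shear_min"
    angles: np.ndarray     # rad from the first in-plane axis, [0, 2 pi)
    values: np.ndarray     # GPa
    e1: np.ndarray         # in-plane orthonormal frame
    e2: np.ndarray

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.e1, self.e2)

    def direction(self, angle: float) -> np.ndarray:
        return math.cos(angle) * self.e1 + math.sin(angle) * self.e2

    @property
    def max_angle(self) -> float:
        return float(self.angles[int(np.argmax(self.values))])

    @property
    def max_direction(self) -> np.ndarray:
        return self.direction(self.max_angle)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"theta_rad": self.angles, "value_gpa": self.values})


def plane_slice(S, cell: CrystalCell, plane: str, property: str = "young",
                n_angles: int = 360, n_chi: int = 72) -> PlaneSliceResult:
    """2-D modulus slice in a crystallographic plane.

    The in-plane frame is e1 = first named axis normalized, e2 = second axis
    Gram-Schmidt-orthogonalized against e1; directions are
    u(theta) = cos(theta) e1 + sin(theta) e2 with theta in [0, 2 pi).
    """
    if plane not in PLANES:
        raise ElasticityError(f"plane must be one of {PLANES}, got {plane!r}")
    if property not in ("young", "shear_min"):
        raise ElasticityError("property must be 'young' or 'shear_min'")
    if n_angles < 36:
        raise ElasticityError("n_angles must be at least 36")
    basis = cell.basis
    idx = {"ab": (0, 1), "ac": (0, 2), "bc": (1, 2)}[plane]
    v1, v2 = basis[idx[0]], basis[idx[1]]
    e1 = v1 / np.linalg.norm(v1)
    w = v2 - np.dot(v2, e1) * e1
    if np.linalg.norm(w) < 1e-10 * np.linalg.norm(v2):
        raise ElasticityError("plane axes are parallel")
    e2 = w / np.linalg.norm(w)
    angles = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    U = np.outer(np.cos(angles), e1) + np.outer(np.sin(angles), e2)
    if property == "young":
        values = maps.young_modulus_batch(S, U)
    else:
        values = np.array([maps.shear_extrema_over_v(S, u, n_chi=n_chi).G_min
                           for u in U])
    return PlaneSliceResult(plane=plane, property=property, angles=angles,
                            values=values, e1=e1, e2=e2)


def _folded_angle_deg(d1, d2) -> float:
    """Angle between two directions folded by antipodal symmetry, [0, 90]."""
    c = abs(float(np.dot(d1, d2)) /
            (np.linalg.norm(d1) * np.linalg.norm(d2)))
    return math.degrees(math.acos(np.clip(c, 0.0, 1.0)))


@dataclasses.dataclass(frozen=True)
class ClassAlignment:
    """Alignment of one contact class with the E-max direction."""

    n_contacts: int
    mean_angle: float       # mean over contacts, degrees
    min_angle: float        # best-aligned contact, degrees
    principal_angle: float  # principal axis of the class vs E-max, degrees


@dataclasses.dataclass(frozen=True)
class AlignmentReport:
    """Quantitative contact-network vs modulus-maximum alignment.

    All angles are folded by antipodal symmetry into [0, 90] degrees.  Large
    angles are a legitimate outcome (stiffness need not trace any single
    contact class), so nothing here is an error condition.
    """

    e_max_direction: np.ndarray
    classes: dict[str, ClassAlignment]
    plane_angles: dict[str, float]  # slice-max vs nearest projected contact

    def to_dict(self) -> dict:
        return {
            "e_max_direction": [float(x) for x in self.e_max_direction],
            "classes": {k: dataclasses.asdict(v) for k, v in self.classes.items()},
            "plane_angles": {k: float(v) for k, v in self.plane_angles.items()},
        }


def principal_direction(directions: np.ndarray) -> np.ndarray:
    """Principal axis of a set of (possibly antipodally folded) directions:
    leading eigenvector of the second-moment matrix sum d d^T."""
    M = directions.T @ directions
    w, V = np.linalg.eigh(M)
    return V[:, -1]


def alignment_report(extrema: maps.ExtremumResult,
                     contacts: list[ContactRecord],
                     slices: list[PlaneSliceResult] | None = None) -> AlignmentReport:
    """Quantify how contact directions align with the modulus maximum.

    Per contact class: mean and minimum angle between individual contact
    directions and the global E-max direction, plus the angle between the
    class's principal direction and E-max.  Per plane slice (if given): the
    angle between the slice maximum and the in-plane projection of the
    nearest contact direction.
    """
    if not contacts:
        raise ElasticityError("empty contact list; run detect_contacts first "
                              "or relax the contact criteria")
    e_max = extrema.max_direction.vector
    classes: dict[str, ClassAlignment] = {}
    for cls in sorted({c.contact_class for c in contacts}):
        dirs = np.array([c.direction for c in contacts if c.contact_class == cls])
        # fold antipodes before the moment matrix (d and -d are equivalent)
        folded = dirs * np.where(dirs @ e_max < 0.0, -1.0, 1.0)[:, None]
        angles = [_folded_angle_deg(d, e_max) for d in dirs]
        classes[cls] = ClassAlignment(
            n_contacts=len(dirs),
            mean_angle=float(np.mean(angles)),
            min_angle=float(np.min(angles)),
            principal_angle=_folded_angle_deg(principal_direction(folded), e_max))

    plane_angles: dict[str, float] = {}
    for sl in slices or []:
        u_star = sl.max_direction
        n = sl.normal
        best = None
        for c in contacts:
            proj = c.direction - np.dot(c.direction, n) * n
            if np.linalg.norm(proj) < 1e-8:
                continue
            ang = _folded_angle_deg(proj, u_star)
            if best is None or ang < best:
                best = ang
        if best is not None:
            plane_angles[sl.plane] = best
    return AlignmentReport(e_max_direction=e_max, classes=classes,
                           plane_angles=plane_angles)


def read_cif(path) -> tuple[CrystalCell, list[AtomSite]]:
    """Read a small-molecule CIF (P1 or symmetry-listed) via gemmi.

    Symmetry operators are applied to produce the full unit-cell contents.
    Disorder is not handled: duplicate generated positions are merged.
    """
    import gemmi

    st = gemmi.read_small_structure(str(path))
    cell = CrystalCell(a=st.cell.a, b=st.cell.b, c=st.cell.c,
                       alpha=st.cell.alpha, beta=st.cell.beta,
                       gamma=st.cell.gamma)
    sites: list[AtomSite] = []
    seen: list[np.ndarray] = []
    counter: dict[str, int] = {}
    for site in st.get_all_unit_cell_sites():
        frac = np.array([site.fract.x, site.fract.y, site.fract.z]) % 1.0
        if any(np.linalg.norm((frac - f + 0.5) % 1.0 - 0.5) < 1e-4 for f in seen):
            continue
        seen.append(frac)
        el = site.element.name if site.element else site.type_symbol
        counter[el] = counter.get(el, 0) + 1
        label = site.label or f"{el}{counter[el]}"
        if any(s.label == label for s in sites):
            label = f"{label}_{counter[el]}"
        sites.append(AtomSite.make(el, frac, label))
    return cell, sites


def write_cif(path, cell: CrystalCell, sites: list[AtomSite],
              data_name: str = "elastimap") -> None:
    """Write a P1 CIF with fractional coordinates."""
    lines = [
        f"data_{data_name}",
        f"_cell_length_a {cell.a:.6f}",
        f"_cell_length_b {cell.b:.6f}",
        f"_cell_length_c {cell.c:.6f}",
        f"_cell_angle_alpha {cell.alpha:.6f}",
        f"_cell_angle_beta {cell.beta:.6f}",
        f"_cell_angle_gamma {cell.gamma:.6f}",
        "_space_group_name_H-M_alt 'P 1'",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for s in sites:
        lines.append(f"{s.label} {s.element} "
                     f"{s.frac[0]:.6f} {s.frac[1]:.6f} {s.frac[2]:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
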