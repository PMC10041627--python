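"""Synthetic inputs: stiffness tensors by Laue class and toy structures.

These generators stand in for the expensive stages of a first-principles
mechanics study — a stress engine and experimentally determined crystal
structures — so that every downstream operation can be exercised against
known ground truth.  Each generator is deterministic under a fixed seed.

The symmetry-class parameterization covers the Laue classes relevant to
molecular crystals (triclinic through cubic, plus hexagonal and the
isotropic limit).  A class is described by its independent coefficients,
its equal-by-symmetry ties, and any derived entries (e.g. the hexagonal
C66 = (C11 - C12)/2); every other entry is zero.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .core import ElasticityError, ElasticTensor, born_stability
from .frames import AtomSite, ContactRecord, CrystalCell

__all__ = [
    "LAUE_CLASSES",
    "SymmetryClassSpec",
    "symmetry_class",
    "isotropic_stiffness",
    "random_stable_stiffness",
    "urea_like_structure",
    "fibrous_stiffness",
]

LAUE_CLASSES = ("triclinic", "monoclinic", "orthorhombic", "tetragonal",
                "hexagonal", "cubic", "isotropic")


@dataclasses.dataclass(frozen=True)
class SymmetryClassSpec:
    """Independent coefficients, ties and derived entries of a Laue class.

    Positions are 0-based upper-triangle (i, j) pairs of the Voigt matrix.
    ``ties`` maps a position to the independent position it equals;
    ``derived`` maps a position to a function of the independent values.
    """

    laue_class: str
    independent: tuple[tuple[int, int], ...]
    ties: dict
    derived: dict

    def positions_of(self, rep: tuple[int, int]) -> list[tuple[int, int]]:
        """All upper-triangle positions whose value equals independent
        coefficient ``rep`` (itself plus its ties)."""
        return [rep] + [p for p, r in self.ties.items() if r == rep]

    def build(self, values: dict) -> np.ndarray:
        """Assemble the symmetric 6x6 matrix from independent values."""
        missing = [p for p in self.independent if p not in values]
        if missing:
            raise ElasticityError(f"missing independent coefficients: {missing}")
        m = np.zeros((6, 6))
        for p in self.independent:
            for i, j in self.positions_of(p):
                m[i, j] = m[j, i] = values[p]
        for (i, j), fn in self.derived.items():
            m[i, j] = m[j, i] = fn(values)
        return m


def _upper_triangle() -> tuple[tuple[int, int], ...]:
    return tuple((i, j) for i in range(6) for j in range(i, 6))


_DIAG = tuple((i, i) for i in range(6))

_CLASS_TABLE: dict[str, SymmetryClassSpec] = {
    "triclinic": SymmetryClassSpec(
        "triclinic", _upper_triangle(), {}, {}),
    # unique axis b: C15, C25, C35, C46 survive among the off-block entries
    "monoclinic": SymmetryClassSpec(
        "monoclinic",
        _DIAG + ((0, 1), (0, 2), (1, 2), (0, 4), (1, 4), (2, 4), (3, 5)),
        {}, {}),
    "orthorhombic": SymmetryClassSpec(
        "orthorhombic",
        _DIAG + ((0, 1), (0, 2), (1, 2)),
        {}, {}),
    "tetragonal": SymmetryClassSpec(
        "tetragonal",
        ((0, 0), (2, 2), (3, 3), (5, 5), (0, 1), (0, 2)),
        {(1, 1): (0, 0), (4, 4): (3, 3), (1, 2): (0, 2)}, {}),
    "hexagonal": SymmetryClassSpec(
        "hexagonal",
        ((0, 0), (2, 2), (3, 3), (0, 1), (0, 2)),
        {(1, 1): (0, 0), (4, 4): (3, 3), (1, 2): (0, 2)},
        {(5, 5): lambda v: (v[(0, 0)] - v[(0, 1)]) / 2.0}),
    "cubic": SymmetryClassSpec(
        "cubic",
        ((0, 0), (0, 1), (3, 3)),
        {(1, 1): (0, 0), (2, 2): (0, 0), (0, 2): (0, 1), (1, 2): (0, 1),
         (4, 4): (3, 3), (5, 5): (3, 3)}, {}),
    "isotropic": SymmetryClassSpec(
        "isotropic",
        ((0, 0), (0, 1)),
        {(1, 1): (0, 0), (2, 2): (0, 0), (0, 2): (0, 1), (1, 2): (0, 1)},
        {(3, 3): lambda v: (v[(0, 0)] - v[(0, 1)]) / 2.0,
         (4, 4): lambda v: (v[(0, 0)] - v[(0, 1)]) / 2.0,
         (5, 5): lambda v: (v[(0, 0)] - v[(0, 1)]) / 2.0}),
}


def symmetry_class(laue_class: str) -> SymmetryClassSpec:
    """Look up the :class:`SymmetryClassSpec` for a Laue class name."""
    try:
        return _CLASS_TABLE[laue_class]
    except KeyError:
        raise ElasticityError(
            f"unknown Laue class {laue_class!r}; choose from {LAUE_CLASSES}")


def isotropic_stiffness(E: float, nu: float) -> ElasticTensor:
    """Isotropic stiffness from Young's modulus E (GPa) and Poisson ratio nu.

    C11 = lambda + 2 mu, C12 = lambda, C44 = mu with the Lame constants
    lambda = E nu / ((1 + nu)(1 - 2 nu)), mu = E / (2 (1 + nu)).
    """
    if E <= 0.0:
        raise ElasticityError("E must be positive")
    if not -1.0 < nu < 0.5:
        raise ElasticityError("nu must lie in (-1, 0.5)")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    m = symmetry_class("isotropic").build({(0, 0): lam + 2.0 * mu, (0, 1): lam})
    return ElasticTensor(m, source_label=f"isotropic E={E} nu={nu}")


def random_stable_stiffness(laue_class: str | SymmetryClassSpec,
                            scale: float = 20.0,
                            seed: int = 0) -> ElasticTensor:
    """Random Born-stable stiffness tensor exactly in the given Laue class.

    Independent diagonal coefficients are drawn uniform(scale, 2*scale) —
    the diagonal bias makes stability rejection rare — and off-diagonal
    ones uniform(-scale/2, scale/2); draws are rejected until the matrix is
    positive definite.  Deterministic per seed.
    """
    if scale <= 0.0:
        raise ElasticityError("scale must be positive")
    spec = laue_class if isinstance(laue_class, SymmetryClassSpec) \
        else symmetry_class(laue_class)
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        values = {}
        for (i, j) in spec.independent:
            if i == j:
                values[(i, j)] = rng.uniform(scale, 2.0 * scale)
            else:
                values[(i, j)] = rng.uniform(-scale / 2.0, scale / 2.0)
        m = spec.build(values)
        if born_stability(m).stable:
            return ElasticTensor(
                m, source_label=f"synthetic {spec.laue_class} seed={seed}")
    raise ElasticityError(
        "could not draw a stable tensor in 1000 attempts; "
        "increase the diagonal bias (scale)")


def fibrous_stiffness(axis_modulus: float = 40.0,
                      transverse_modulus: float = 8.0,
                      shear_modulus: float = 3.0) -> ElasticTensor:
    """Tetragonal stiffness of a "fibrous" crystal, stiffest along c.

    Emulates a tape/chain motif running along the c axis (strong contacts
    along c, weak transverse packing): C33 >> C11 = C22.
    """
    m = symmetry_class("tetragonal").build({
        (0, 0): transverse_modulus * 1.5,
        (2, 2): axis_modulus,
        (3, 3): shear_modulus,
        (5, 5): shear_modulus * 1.2,
        (0, 1): transverse_modulus * 0.4,
        (0, 2): transverse_modulus * 0.5,
    })
    t = ElasticTensor(m, source_label="synthetic fibrous (stiff c axis)")
    if not t.stability().stable:  # pragma: no cover - defaults are stable
        raise ElasticityError("fibrous stiffness parameters are not stable")
    return t


def urea_like_structure() -> tuple[CrystalCell, list[AtomSite], list[ContactRecord]]:
    """Toy tetragonal structure with head-to-tail H-bonded tapes along c.

    Two planar 4-atom "molecules" (N, H, C, O) per cell, each donating one
    N-H...O hydrogen bond to its own translational image along +c, so every
    contact direction lies within 30 degrees of the c axis (d_HA = 1.9 A,
    angle_DHA = 165 degrees).  The second molecule is rotated 90 degrees
    about c, mimicking the orthogonal adjacent tapes of a urea-like packing.

    Returns (cell, sites, ground_truth_contacts); the ground-truth list is
    constructed analytically from the placement geometry, independent of
    :func:`elastimap.frames.detect_contacts`.
    """
    a = 5.6
    c = 4.7
    cell = CrystalCell(a=a, b=a, c=c)
    basis = cell.basis
    inv_basis = np.linalg.inv(basis)

    d_nh = 1.0     # N-H bond, A
    d_ha = 1.9     # H...O contact, A
    theta = math.radians(180.0 - 165.0)  # deviation of H->O from the N-H line
    d_co = 1.23    # C=O bond, A

    def molecule(base_xy: np.ndarray, offset_axis: int):
        """Cartesian atom positions; the acceptor O sits one cell below the
        contact position so that its +c image receives the N-H...O bond."""
        off = np.zeros(3)
        off[offset_axis] = d_ha * math.sin(theta)
        n = np.array([base_xy[0], base_xy[1], 0.0])
        h = n + np.array([0.0, 0.0, d_nh])
        o_contact = h + off + np.array([0.0, 0.0, d_ha * math.cos(theta)])
        o = o_contact - np.array([0.0, 0.0, c])
        cc = o + np.array([0.0, 0.0, d_co])
        return n, h, cc, o, o_contact

    sites: list[AtomSite] = []
    contacts: list[ContactRecord] = []
    for im, (base, axis) in enumerate(
            [(np.array([0.25 * a, 0.25 * a]), 0),
             (np.array([0.75 * a, 0.75 * a]), 1)], start=1):
        n, h, cc, o, o_contact = molecule(base, axis)
        labels = (f"N{im}", f"H{im}", f"C{im}", f"O{im}")
        for lab, pos, el in zip(labels, (n, h, cc, o), ("N", "H", "C", "O")):
            sites.append(AtomSite.make(el, pos @ inv_basis, lab))
        o_wrapped = ((o @ inv_basis) % 1.0) @ basis
        shift = np.rint((o_contact - o_wrapped) @ inv_basis).astype(int)
        da = o_contact - n
        contacts.append(ContactRecord(
            donor_label=f"N{im}", hydrogen_label=f"H{im}",
            acceptor_label=f"O{im}", donor_element="N", acceptor_element="O",
            d_HA=d_ha, d_DA=float(np.linalg.norm(da)),
            angle_DHA=165.0, direction=da / np.linalg.norm(da),
            image_shift=tuple(int(x) for x in shift)))
    contacts.sort(key=lambda r: (r.donor_label, r.acceptor_label, r.image_shift))
    return cell, sites, contacts
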