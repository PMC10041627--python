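"""Voigt-notation elastic tensor algebra.

The central object is :class:`ElasticTensor`, a validated symmetric 6x6
stiffness matrix ``C`` (GPa) in Voigt notation, the contracted form of the
fourth-order stiffness tensor of linear elasticity (generalized Hooke's law,
sigma = C : epsilon).  Everything else in the package — compliance, directional
moduli, Born stability, Voigt orientation averages — derives from it.

Voigt index convention: pairs (11, 22, 33, 23, 13, 12) -> (1..6).  The
stiffness matrix maps to the full rank-4 tensor with unit factors; the
compliance matrix carries the conventional 1/2/4 factors on shear rows and
columns so that the contracted and full forms of Hooke's law agree.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ElasticityError",
    "StabilityError",
    "StabilityReport",
    "VoigtAverages",
    "Compliance",
    "ElasticTensor",
    "validate_stiffness",
    "invert_to_compliance",
    "voigt_to_full",
    "full_to_voigt",
    "rotate_full",
    "born_stability",
    "voigt_averages",
]

#: Cartesian index pairs behind Voigt indices 1..6 (0-based).
VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))

#: Condition-number cutoff above which a stiffness matrix is treated as
#: numerically singular (near-unstable / degenerate tensor).
CONDITION_LIMIT = 1e12


class ElasticityError(ValueError):
    """Invalid input to an elasticity operation."""


class StabilityError(ElasticityError):
    """Operation requires a Born-stable tensor; carries the failing report."""

    def __init__(self, message: str, report: "StabilityReport"):
        super().__init__(message)
        self.report = report


@dataclasses.dataclass(frozen=True)
class StabilityReport:
    """Born mechanical stability of an unstressed crystal.

    ``stable`` is positive definiteness of the 6x6 Voigt stiffness matrix —
    the necessary and sufficient criterion, uniform across crystal systems.
    """

    stable: bool
    eigenvalues: np.ndarray  # six reals, GPa, ascending

    def to_dict(self) -> dict:
        return {"stable": bool(self.stable),
                "eigenvalues": [float(x) for x in self.eigenvalues]}


@dataclasses.dataclass(frozen=True)
class VoigtAverages:
    """Voigt (uniform-strain) orientation averages, all in GPa."""

    K_V: float
    G_V: float
    E_V: float

    def to_dict(self) -> dict:
        return {"K_V": self.K_V, "G_V": self.G_V, "E_V": self.E_V}


def validate_stiffness(raw, tolerance: float = 1e-3) -> np.ndarray:
    """Validate and symmetrize a raw 6x6 stiffness matrix (GPa).

    Returns ``(raw + raw.T) / 2`` when the largest asymmetry does not exceed
    ``tolerance`` (GPa); otherwise raises :class:`ElasticityError` naming the
    worst off-diagonal pair (1-based Voigt indices).
    """
    m = np.asarray(raw, dtype=float)
    if m.shape != (6, 6):
        raise ElasticityError(f"stiffness matrix must be 6x6, got {m.shape}")
    if not np.all(np.isfinite(m)):
        i, j = np.argwhere(~np.isfinite(m))[0]
        raise ElasticityError(f"non-finite entry at ({i + 1},{j + 1})")
    asym = np.abs(m - m.T)
    if asym.max() > tolerance:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        i, j = sorted((int(i), int(j)))
        raise ElasticityError(
            f"asymmetry {asym.max():.3g} GPa at ({i + 1},{j + 1}) exceeds "
            f"tolerance {tolerance:g} GPa")
    return (m + m.T) / 2.0


def voigt_to_full(matrix, kind: str = "stiffness") -> np.ndarray:
    """Expand a 6x6 Voigt matrix to the full 3x3x3x3 tensor.

    Stiffness entries map with factor 1; compliance entries are divided by 2
    for each shear (Voigt index > 3) row/column index, i.e. by 1, 2 or 4.
    """
    if kind not in ("stiffness", "compliance"):
        raise ElasticityError(f"unknown tensor kind {kind!r}")
    m = np.asarray(matrix, dtype=float)
    T = np.empty((3, 3, 3, 3))
    for a, (i, j) in enumerate(VOIGT_PAIRS):
        for b, (k, l) in enumerate(VOIGT_PAIRS):
            v = m[a, b]
            if kind == "compliance":
                v /= (2.0 if a > 2 else 1.0) * (2.0 if b > 2 else 1.0)
            T[i, j, k, l] = T[j, i, k, l] = T[i, j, l, k] = T[j, i, l, k] = v
    return T


def full_to_voigt(tensor, kind: str = "stiffness") -> np.ndarray:
    """Contract a full rank-4 tensor back to the 6x6 Voigt matrix (exact
    inverse of :func:`voigt_to_full`)."""
    if kind not in ("stiffness", "compliance"):
        raise ElasticityError(f"unknown tensor kind {kind!r}")
    T = np.asarray(tensor, dtype=float)
    m = np.empty((6, 6))
    for a, (i, j) in enumerate(VOIGT_PAIRS):
        for b, (k, l) in enumerate(VOIGT_PAIRS):
            v = T[i, j, k, l]
            if kind == "compliance":
                v *= (2.0 if a > 2 else 1.0) * (2.0 if b > 2 else 1.0)
            m[a, b] = v
    return m


def rotate_full(tensor, R) -> np.ndarray:
    """Rotate a full rank-4 tensor: T'_ijkl = R_ia R_jb R_kc R_ld T_abcd.

    ``R`` must be a proper rotation (orthogonal, det +1) within 1e-10.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-10 \
            or abs(np.linalg.det(R) - 1.0) > 1e-10:
        raise ElasticityError("R is not a proper rotation matrix")
    return np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R,
                     np.asarray(tensor, dtype=float), optimize=True)


def born_stability(matrix) -> StabilityReport:
    """Born stability report: eigenvalue spectrum of the 6x6 Voigt matrix,
    stable iff all eigenvalues are positive."""
    m = matrix.matrix if isinstance(matrix, ElasticTensor) else np.asarray(matrix, float)
    eig = np.linalg.eigvalsh(m)
    return StabilityReport(stable=bool(eig[0] > 0.0), eigenvalues=eig)


def invert_to_compliance(matrix) -> np.ndarray:
    """Invert a stiffness matrix to compliance (GPa^-1).

    Rejects singular or ill-conditioned input (condition number above
    ``CONDITION_LIMIT``), which signals an unstable or degenerate tensor.
    """
    m = matrix.matrix if isinstance(matrix, ElasticTensor) else np.asarray(matrix, float)
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise ElasticityError(
            f"stiffness matrix is singular or near-singular (cond={cond:.3g})")
    s = np.linalg.inv(m)
    return (s + s.T) / 2.0


def voigt_averages(matrix) -> VoigtAverages:
    """Voigt-averaged bulk, shear and Young's moduli K_V, G_V, E_V (GPa).

    K_V = (C11+C22+C33 + 2(C12+C13+C23)) / 9
    G_V = ((C11+C22+C33) - (C12+C13+C23)) / 15 + (C44+C55+C66) / 5
    E_V = 9 K_V G_V / (3 K_V + G_V)

    Requires a Born-stable tensor; raises :class:`StabilityError` (with the
    report attached) otherwise.
    """
    c = matrix.matrix if isinstance(matrix, ElasticTensor) else np.asarray(matrix, float)
    report = born_stability(c)
    if not report.stable:
        raise StabilityError("Voigt averages require a Born-stable tensor", report)
    diag = c[0, 0] + c[1, 1] + c[2, 2]
    off = c[0, 1] + c[0, 2] + c[1, 2]
    shear = c[3, 3] + c[4, 4] + c[5, 5]
    K = (diag + 2.0 * off) / 9.0
    G = (diag - off) / 15.0 + shear / 5.0
    E = 9.0 * K * G / (3.0 * K + G)
    return VoigtAverages(K_V=float(K), G_V=float(G), E_V=float(E))


class Compliance:
    """Voigt compliance matrix S (GPa^-1) with its full-tensor expansion.

    Obtained from :meth:`ElasticTensor.compliance`; the source of every
    directional modulus.
    """

    def __init__(self, matrix: np.ndarray):
        self.matrix = np.asarray(matrix, dtype=float)
        self._full: np.ndarray | None = None

    @property
    def full(self) -> np.ndarray:
        """Full rank-4 compliance tensor S_ijkl (cached)."""
        if self._full is None:
            self._full = voigt_to_full(self.matrix, kind="compliance")
        return self._full


class ElasticTensor:
    """A validated Voigt stiffness matrix with derived-property accessors.

    Parameters
    ----------
    matrix : (6, 6) array_like
        Stiffness constants in GPa.  Symmetrized on input; asymmetry above
        ``tolerance`` (default 1e-3 GPa) is rejected.
    source_label : str
        Free-text provenance, e.g. ``"benzene PBE+MBD"``.
    """

    def __init__(self, matrix, source_label: str = "", tolerance: float = 1e-3):
        self.matrix = validate_stiffness(matrix, tolerance=tolerance)
        self.source_label = source_label
        self._compliance: Compliance | None = None
        self._full: np.ndarray | None = None

    def __repr__(self) -> str:
        label = f" {self.source_label!r}" if self.source_label else ""
        return f"<ElasticTensor{label} C11={self.matrix[0, 0]:.4g} GPa>"

    @property
    def full(self) -> np.ndarray:
        """Full rank-4 stiffness tensor C_ijkl (cached)."""
        if self._full is None:
            self._full = voigt_to_full(self.matrix, kind="stiffness")
        return self._full

    def compliance(self) -> Compliance:
        """Inverse of the stiffness matrix (cached)."""
        if self._compliance is None:
            self._compliance = Compliance(invert_to_compliance(self.matrix))
        return self._compliance

    def stability(self) -> StabilityReport:
        return born_stability(self.matrix)

    def voigt_averages(self) -> VoigtAverages:
        return voigt_averages(self.matrix)

    def rotated(self, R) -> "ElasticTensor":
        """Stiffness expressed in a frame rotated by proper rotation ``R``."""
        m = full_to_voigt(rotate_full(self.full, R), kind="stiffness")
        return ElasticTensor(m, source_label=self.source_label, tolerance=1e-6)
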