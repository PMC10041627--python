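"""Directional elastic moduli and anisotropy maps.

Young's modulus along a unit direction ``u`` follows from the compliance
tensor by the quadruple contraction ``1/E(u) = u_i u_j u_k u_l S_ijkl``.
The shear modulus additionally depends on a second unit vector ``v``
perpendicular to ``u`` (shearing along u in the plane normal to v):
``1/G(u, v) = 4 u_i v_j u_k v_l S_ijkl``.

Sampling these over the sphere yields the "deformability map" of a crystal;
the ratio of the global maximum to the global minimum of a modulus is its
anisotropy index ``A_X = X_max / X_min`` (1 for an isotropic medium).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize

from .core import Compliance, ElasticityError, ElasticTensor

__all__ = [
    "Direction",
    "ShearExtrema",
    "ExtremumResult",
    "AnisotropySummary",
    "ModulusSurface",
    "young_modulus",
    "shear_modulus",
    "shear_plane_basis",
    "shear_extrema_over_v",
    "global_extrema",
    "anisotropy_index",
    "anisotropy_summary",
    "sphere_map",
    "icosphere_directions",
]

PROPERTIES = ("young", "shear_min", "shear_max", "shear_avg")


@dataclasses.dataclass(frozen=True)
class Direction:
    """A unit direction in the Cartesian crystal frame."""

    vector: np.ndarray
    theta: float  # polar angle from +z, rad
    phi: float    # azimuth from +x, rad

    @classmethod
    def from_vector(cls, u) -> "Direction":
        u = _unit_checked(u)
        theta = math.acos(np.clip(u[2], -1.0, 1.0))
        phi = math.atan2(u[1], u[0]) % (2.0 * math.pi)
        return cls(vector=u, theta=theta, phi=phi)

    @classmethod
    def from_angles(cls, theta: float, phi: float) -> "Direction":
        return cls(vector=_sph(theta, phi), theta=theta, phi=phi)


def _sph(theta, phi) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def _unit_checked(u, tol: float = 1e-8) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.shape != (3,) or abs(np.linalg.norm(u) - 1.0) > tol:
        raise ElasticityError("direction must be a unit 3-vector")
    return u


def _compliance_of(S) -> Compliance:
    if isinstance(S, ElasticTensor):
        return S.compliance()
    if isinstance(S, Compliance):
        return S
    return Compliance(np.asarray(S, dtype=float))


def young_modulus(S, u) -> float:
    """Young's modulus E(u) in GPa for unit direction ``u``."""
    S = _compliance_of(S)
    u = _unit_checked(u)
    inv = np.einsum("ijkl,i,j,k,l->", S.full, u, u, u, u)
    return float(1.0 / inv)


def young_modulus_batch(S, U: np.ndarray) -> np.ndarray:
    """Vectorized E(u) for an (n, 3) array of unit directions."""
    S = _compliance_of(S)
    inv = np.einsum("ijkl,ni,nj,nk,nl->n", S.full, U, U, U, U, optimize=True)
    return 1.0 / inv


def shear_modulus(S, u, v) -> float:
    """Shear modulus G(u, v) in GPa; ``v`` must be a unit vector
    perpendicular to unit ``u`` (within 1e-8).  Symmetric under u <-> v."""
    S = _compliance_of(S)
    u = _unit_checked(u)
    v = _unit_checked(v)
    if abs(float(np.dot(u, v))) > 1e-8:
        raise ElasticityError("u and v must be orthogonal")
    inv = 4.0 * np.einsum("ijkl,i,j,k,l->", S.full, u, v, u, v)
    return float(1.0 / inv)


def shear_plane_basis(u) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis (w1, w2) of the plane perpendicular
    to ``u``; w2 = u x w1.  Used to parameterize v(chi) = cos(chi) w1 +
    sin(chi) w2."""
    u = _unit_checked(u)
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(u)))] = 1.0
    w1 = ref - np.dot(ref, u) * u
    w1 /= np.linalg.norm(w1)
    w2 = np.cross(u, w1)
    return w1, w2


@dataclasses.dataclass(frozen=True)
class ShearExtrema:
    """Extrema of G(u, v) over v in the plane perpendicular to a fixed u."""

    G_min: float
    G_max: float
    G_avg: float
    chi_min: float  # angle of the minimizing v in the (w1, w2) basis, rad
    chi_max: float
    u: np.ndarray


def _shear_form(S: Compliance, u: np.ndarray) -> tuple[float, float, float]:
    """2x2 restriction of the shear quadratic form 1/G = v.M.v to the plane
    perpendicular to u, in the deterministic (w1, w2) basis."""
    w1, w2 = shear_plane_basis(u)
    M = 4.0 * np.einsum("ijkl,i,k->jl", S.full, u, u)
    M = (M + M.T) / 2.0
    return float(w1 @ M @ w1), float(w2 @ M @ w2), float(w1 @ M @ w2)


def shear_extrema_over_v(S, u, n_chi: int = 72) -> ShearExtrema:
    """Minimum, maximum and trapezoid-average shear modulus over all
    admissible v for fixed u.

    Scans chi in [0, pi) at ``n_chi`` points (1/G is pi-periodic in chi),
    then golden-section refines around the best bracket to 1e-6 rad.
    """
    if n_chi < 8:
        raise ElasticityError("n_chi must be at least 8")
    S = _compliance_of(S)
    u = _unit_checked(u)
    m11, m22, m12 = _shear_form(S, u)

    def inv_g(chi):
        c, s = np.cos(chi), np.sin(chi)
        return m11 * c * c + m22 * s * s + 2.0 * m12 * s * c

    chis = np.linspace(0.0, np.pi, n_chi, endpoint=False)
    vals = inv_g(chis)
    step = np.pi / n_chi

    def refine(sign: float) -> tuple[float, float]:
        # sign +1 locates the maximum of 1/G (minimum G), -1 the minimum
        k = int(np.argmax(sign * vals))
        a, b = chis[k] - step, chis[k] + step
        f = lambda x: -sign * inv_g(x)
        if not (f(chis[k]) < f(a) and f(chis[k]) < f(b)):
            # flat in chi (degenerate direction): the grid point is exact
            return float(chis[k]), float(vals[k])
        res = optimize.minimize_scalar(f, bracket=(a, chis[k], b),
                                       method="golden", options={"xtol": 1e-6})
        return float(res.x % np.pi), float(-sign * res.fun)

    chi_min, inv_max = refine(+1.0)
    chi_max, inv_min = refine(-1.0)
    # closed [0, pi] grid for the trapezoid mean (G is pi-periodic)
    chis_closed = np.linspace(0.0, np.pi, n_chi + 1)
    g_closed = 1.0 / inv_g(chis_closed)
    g_avg = float(np.trapezoid(g_closed, chis_closed) / np.pi)
    return ShearExtrema(G_min=1.0 / inv_max, G_max=1.0 / inv_min,
                        G_avg=g_avg, chi_min=chi_min, chi_max=chi_max, u=u)


def shear_extrema_batch(S, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-direction (G_min, G_max) for an (n, 3) batch of unit
    directions: eigenvalues of the 2x2 restriction of the shear form.

    Used to rank seed directions in the global search; the reported extrema
    are always re-evaluated through :func:`shear_extrema_over_v`.
    """
    S = _compliance_of(S)
    M = 4.0 * np.einsum("ijkl,ni,nk->njl", S.full, U, U, optimize=True)
    M = (M + np.swapaxes(M, 1, 2)) / 2.0
    # project out u: restrict to plane basis per direction
    g_min = np.empty(len(U))
    g_max = np.empty(len(U))
    for n, u in enumerate(U):
        w1, w2 = shear_plane_basis(u)
        m11 = w1 @ M[n] @ w1
        m22 = w2 @ M[n] @ w2
        m12 = w1 @ M[n] @ w2
        mean = (m11 + m22) / 2.0
        half = math.hypot((m11 - m22) / 2.0, m12)
        g_min[n] = 1.0 / (mean + half)
        g_max[n] = 1.0 / (mean - half)
    return g_min, g_max


def icosphere_directions(n_seed: int = 2562) -> np.ndarray:
    """Quasi-uniform unit directions from the smallest icosphere subdivision
    with at least ``n_seed`` vertices (10 * 4**s + 2).  Deterministic."""
    from trimesh.creation import icosphere

    s = 0
    while 10 * 4 ** s + 2 < n_seed:
        s += 1
    verts = np.asarray(icosphere(subdivisions=s, radius=1.0).vertices, float)
    return verts / np.linalg.norm(verts, axis=1, keepdims=True)


@dataclasses.dataclass(frozen=True)
class ExtremumResult:
    """Global extrema of a directional modulus over the sphere."""

    property: str
    min_value: float
    max_value: float
    min_direction: Direction
    max_direction: Direction
    min_secondary: Direction | None = None  # minimizing v (shear only)
    max_secondary: Direction | None = None

    def to_dict(self) -> dict:
        d = {"property": self.property,
             "min": self.min_value, "max": self.max_value,
             "min_dir": [float(x) for x in self.min_direction.vector],
             "max_dir": [float(x) for x in self.max_direction.vector]}
        if self.min_secondary is not None:
            d["min_dir_v"] = [float(x) for x in self.min_secondary.vector]
            d["max_dir_v"] = [float(x) for x in self.max_secondary.vector]
        return d


def _select_seeds(U: np.ndarray, vals: np.ndarray, want_max: bool,
                  k: int = 5, min_sep_deg: float = 10.0) -> list[np.ndarray]:
    """Best k seed directions, deduplicated by angular separation (folding
    antipodes together)."""
    order = np.argsort(-vals if want_max else vals)
    picked: list[np.ndarray] = []
    cos_sep = math.cos(math.radians(min_sep_deg))
    for idx in order:
        u = U[idx]
        if any(abs(float(np.dot(u, p))) > cos_sep for p in picked):
            continue
        picked.append(u)
        if len(picked) >= k:
            break
    return picked


def global_extrema(S, property: str = "young", n_seed: int = 2562,
                   n_chi: int = 72) -> ExtremumResult:
    """Global min and max of E(u) (property "young") or of G(u, v) over all
    admissible (u, v) pairs (property "shear").

    Seeds with a deterministic icosphere grid of ``n_seed`` directions, then
    refines the best few candidates with Nelder-Mead over (theta, phi) to
    1e-8 rad; shear refinement nests the chi scan of
    :func:`shear_extrema_over_v`.
    """
    if property not in ("young", "shear"):
        raise ElasticityError(f"property must be 'young' or 'shear', got {property!r}")
    S = _compliance_of(S)
    U = icosphere_directions(n_seed)

    if property == "young":
        def f_min(u):
            return young_modulus(S, u)

        f_max = f_min
        seed_min = seed_max = young_modulus_batch(S, U)
    else:
        def f_min(u):
            return shear_extrema_over_v(S, u, n_chi=n_chi).G_min

        def f_max(u):
            return shear_extrema_over_v(S, u, n_chi=n_chi).G_max

        seed_min, seed_max = shear_extrema_batch(S, U)

    def refine(f, seeds_vals, want_max: bool) -> tuple[float, np.ndarray]:
        sign = -1.0 if want_max else 1.0
        best_val, best_u = None, None
        for u0 in _select_seeds(U, seeds_vals, want_max):
            d0 = Direction.from_vector(u0)
            res = optimize.minimize(
                lambda x: sign * f(_sph(x[0], x[1])),
                x0=[d0.theta, d0.phi], method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 400})
            val = sign * res.fun
            if best_val is None or (val > best_val if want_max else val < best_val):
                best_val, best_u = float(val), _sph(res.x[0], res.x[1])
        return best_val, best_u

    min_value, u_min = refine(f_min, seed_min, want_max=False)
    max_value, u_max = refine(f_max, seed_max, want_max=True)

    min_sec = max_sec = None
    if property == "shear":
        ext = shear_extrema_over_v(S, u_min, n_chi=n_chi)
        w1, w2 = shear_plane_basis(u_min)
        min_sec = Direction.from_vector(
            np.cos(ext.chi_min) * w1 + np.sin(ext.chi_min) * w2)
        ext = shear_extrema_over_v(S, u_max, n_chi=n_chi)
        w1, w2 = shear_plane_basis(u_max)
        max_sec = Direction.from_vector(
            np.cos(ext.chi_max) * w1 + np.sin(ext.chi_max) * w2)

    return ExtremumResult(
        property=property, min_value=min_value, max_value=max_value,
        min_direction=Direction.from_vector(u_min),
        max_direction=Direction.from_vector(u_max),
        min_secondary=min_sec, max_secondary=max_sec)


@dataclasses.dataclass(frozen=True)
class AnisotropySummary:
    """Anisotropy indices A_E and A_G (dimensionless, >= 1)."""

    A_E: float
    A_G: float

    def to_dict(self) -> dict:
        return {"A_E": self.A_E, "A_G": self.A_G}


def anisotropy_index(ext: ExtremumResult) -> float:
    """A_X = X_max / X_min; rejects a non-positive minimum (marginally
    stable tensor)."""
    if ext.min_value <= 0.0:
        raise ElasticityError(
            "anisotropy index undefined: modulus minimum is non-positive")
    return ext.max_value / ext.min_value


def anisotropy_summary(S, n_seed: int = 2562, n_chi: int = 72) -> AnisotropySummary:
    """A_E and A_G from full-sphere global extrema."""
    A_E = anisotropy_index(global_extrema(S, "young", n_seed=n_seed))
    A_G = anisotropy_index(global_extrema(S, "shear", n_seed=n_seed, n_chi=n_chi))
    return AnisotropySummary(A_E=A_E, A_G=A_G)


@dataclasses.dataclass(frozen=True)
class ModulusSurface:
    """A directional modulus sampled on a regular (theta, phi) grid —
    the data behind a 3-D spherical "deformability map"."""

    property: str
    theta: np.ndarray  # (n_theta,), [0, pi]
    phi: np.ndarray    # (n_phi,), [0, 2 pi)
    values: np.ndarray  # (n_theta, n_phi), GPa
    resolution: int

    @property
    def samples(self):
        """Flat list of (theta, phi, value) triples."""
        T, P = np.meshgrid(self.theta, self.phi, indexing="ij")
        return np.column_stack([T.ravel(), P.ravel(), self.values.ravel()])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.samples,
                            columns=["theta_rad", "phi_rad", "value_gpa"])


def sphere_map(S, property: str = "young", resolution: int = 64,
               n_chi: int = 72) -> ModulusSurface:
    """Sample a modulus surface on a regular grid: ``resolution`` azimuth
    samples per ring, ``resolution // 2 + 1`` polar rings."""
    if property not in PROPERTIES:
        raise ElasticityError(f"unknown property {property!r}")
    if resolution < 16:
        raise ElasticityError("resolution must be at least 16")
    S = _compliance_of(S)
    theta = np.linspace(0.0, np.pi, resolution // 2 + 1)
    phi = np.linspace(0.0, 2.0 * np.pi, resolution, endpoint=False)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    U = np.column_stack([(np.sin(T) * np.cos(P)).ravel(),
                         (np.sin(T) * np.sin(P)).ravel(),
                         np.cos(T).ravel()])
    if property == "young":
        vals = young_modulus_batch(S, U)
    else:
        field = {"shear_min": "G_min", "shear_max": "G_max",
                 "shear_avg": "G_avg"}[property]
        vals = np.array([getattr(shear_extrema_over_v(S, u, n_chi=n_chi), field)
                         for u in U])
    return ModulusSurface(property=property, theta=theta, phi=phi,
                          values=vals.reshape(T.shape), resolution=resolution)
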