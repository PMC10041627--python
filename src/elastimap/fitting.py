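"""Elastic-constant extraction from stress-strain series.

The workflow mirrors the finite-deformation route to second-order elastic
constants: the unit cell is distorted along symmetry-dependent strain
patterns, a stress engine evaluates the stress tensor at a ladder of strain
amplitudes, and ordinary least squares on the stress-vs-strain slopes
assembles the stiffness matrix.

:class:`StressStrainModel` is the modelling object (data = a set of
:class:`DeformationSeries`, optionally a Laue class whose ties fill in the
columns a reduced pattern set does not excite); :meth:`StressStrainModel.fit`
returns a :class:`StressStrainResults` carrying the fitted
:class:`~elastimap.core.ElasticTensor`, per-coefficient standard errors,
residual diagnostics and a ``summary()`` table.

A real DFT stress engine is out of scope; :class:`SyntheticStressCalculator`
implements the same contract with linear elastic response, optional
quadratic anharmonicity and seeded Gaussian stress noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import ElasticityError, ElasticTensor, voigt_to_full
from .synthetic import LAUE_CLASSES, SymmetryClassSpec, symmetry_class

__all__ = [
    "StrainPattern",
    "DeformationSeries",
    "SyntheticStressCalculator",
    "StressStrainModel",
    "StressStrainResults",
    "generate_patterns",
    "apply_strain",
    "strain_tensor",
    "collect_series",
    "fit_constants",
    "synthetic_oracle",
]

#: Maximum admissible strain component; beyond this the linear (small
#: deformation) regime assumed throughout does not apply.
MAX_STRAIN = 0.2

#: Excited Voigt components per Laue class (1-based).  A single axial
#: pattern yields a full stress column (e.g. C11, C12, C13 from pattern 1),
#: so symmetry ties let reduced sets cover every independent coefficient.
_PATTERN_COMPONENTS = {
    "triclinic": (1, 2, 3, 4, 5, 6),
    "monoclinic": (1, 2, 3, 4, 5, 6),
    "orthorhombic": (1, 2, 3, 4, 5, 6),
    "tetragonal": (1, 3, 4, 6),
    "hexagonal": (1, 3, 4),
    "cubic": (1, 4),
    "isotropic": (1,),
}


@dataclasses.dataclass(frozen=True)
class StrainPattern:
    """A deformation pattern: signed weights on Voigt strain components."""

    voigt_components: tuple[int, ...]  # 1-based
    weights: tuple[float, ...]
    label: str

    def __post_init__(self):
        if not self.voigt_components or all(w == 0.0 for w in self.weights):
            raise ElasticityError("pattern must excite at least one component")
        if len(self.voigt_components) != len(self.weights):
            raise ElasticityError("components and weights differ in length")


def generate_patterns(laue_class: str) -> list[StrainPattern]:
    """Canonical minimal strain-pattern set for a Laue class.

    Six single-component patterns for triclinic/monoclinic/orthorhombic;
    reduced sets for the higher-symmetry classes whose equal-by-symmetry
    coefficients make some columns redundant.
    """
    if laue_class not in _PATTERN_COMPONENTS:
        raise ElasticityError(
            f"unknown Laue class {laue_class!r}; choose from {LAUE_CLASSES}")
    return [StrainPattern((k,), (1.0,), label=f"e{k}")
            for k in _PATTERN_COMPONENTS[laue_class]]


def strain_tensor(pattern: StrainPattern, amplitude: float) -> np.ndarray:
    """Symmetric 3x3 strain tensor for a pattern at a given amplitude.

    Voigt strain components use the engineering-shear convention: amplitude
    ``a`` on component 4 means gamma_23 = a, i.e. eps_23 = a / 2.
    """
    pairs = {1: (0, 0), 2: (1, 1), 3: (2, 2), 4: (1, 2), 5: (0, 2), 6: (0, 1)}
    eps = np.zeros((3, 3))
    for k, w in zip(pattern.voigt_components, pattern.weights):
        i, j = pairs[k]
        v = amplitude * w
        if i == j:
            eps[i, i] += v
        else:
            eps[i, j] += v / 2.0
            eps[j, i] += v / 2.0
    return eps


def apply_strain(cell_basis, strain) -> np.ndarray:
    """Deform a lattice basis (rows = lattice vectors) by (I + eps).

    Rejects strain components beyond +-0.2, far outside the linear regime.
    """
    basis = np.asarray(cell_basis, dtype=float)
    eps = np.asarray(strain, dtype=float)
    if np.linalg.matrix_rank(basis) < 3:
        raise ElasticityError("cell basis is singular")
    if np.abs(eps).max() > MAX_STRAIN:
        raise ElasticityError(
            f"strain component {np.abs(eps).max():.3g} exceeds {MAX_STRAIN}; "
            "outside the linear elastic regime")
    return basis @ (np.eye(3) + eps).T


@dataclasses.dataclass
class DeformationSeries:
    """Strain amplitudes paired with stress tensors for one pattern."""

    pattern: StrainPattern
    amplitudes: np.ndarray          # dimensionless, strictly increasing
    stresses: list[np.ndarray]      # symmetric 3x3, GPa

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.amplitudes) != len(self.stresses):
            raise ElasticityError("amplitudes and stresses differ in length")
        if not np.all(np.diff(self.amplitudes) > 0):
            raise ElasticityError("amplitudes must be strictly increasing")

    def stress_voigt(self) -> np.ndarray:
        """(n, 6) stress components in Voigt order (11,22,33,23,13,12)."""
        out = np.empty((len(self.stresses), 6))
        for m, s in enumerate(self.stresses):
            out[m] = [s[0, 0], s[1, 1], s[2, 2], s[1, 2], s[0, 2], s[0, 1]]
        return out


class SyntheticStressCalculator:
    """Stress engine contract implemented on a known stiffness tensor.

    evaluate(eps) = C_true : eps + gamma * ||eps|| * eps + noise, with
    per-component Gaussian noise of standard deviation ``noise_sd`` (GPa),
    drawn from a seeded generator — replaying a freshly constructed
    calculator reproduces the stress sequence bit for bit.
    """

    def __init__(self, C_true: ElasticTensor, noise_sd: float = 0.0,
                 anharmonic_gamma: float = 0.0, seed: int = 0):
        if noise_sd < 0.0:
            raise ElasticityError("noise_sd must be non-negative")
        if not C_true.stability().stable:
            raise ElasticityError("C_true must be Born-stable")
        self.C_true = C_true
        self.noise_sd = noise_sd
        self.anharmonic_gamma = anharmonic_gamma
        self.seed = seed
        self._full = voigt_to_full(C_true.matrix, kind="stiffness")
        self._rng = np.random.default_rng(seed)

    def evaluate(self, strain) -> np.ndarray:
        """Stress tensor (symmetric 3x3, GPa) for a symmetric 3x3 strain."""
        eps = np.asarray(strain, dtype=float)
        sigma = np.einsum("ijkl,kl->ij", self._full, eps)
        if self.anharmonic_gamma:
            sigma = sigma + self.anharmonic_gamma * np.linalg.norm(eps) * eps
        if self.noise_sd:
            # six independent components of a symmetric noise tensor, so
            # every Voigt stress component carries exactly noise_sd
            n = self._rng.normal(0.0, self.noise_sd, size=6)
            sigma = sigma + np.array([[n[0], n[5], n[4]],
                                      [n[5], n[1], n[3]],
                                      [n[4], n[3], n[2]]])
        return sigma


def synthetic_oracle(C_true: ElasticTensor, noise_sd: float = 0.0,
                     anharmonic_gamma: float = 0.0,
                     seed: int = 0) -> SyntheticStressCalculator:
    """Functional alias for :class:`SyntheticStressCalculator`."""
    return SyntheticStressCalculator(C_true, noise_sd=noise_sd,
                                     anharmonic_gamma=anharmonic_gamma,
                                     seed=seed)


def collect_series(oracle, pattern: StrainPattern,
                   max_amplitude: float = 0.003,
                   n_points: int = 12) -> DeformationSeries:
    """Evaluate the stress engine along one pattern.

    Amplitudes are ``n_points`` evenly spaced values spanning
    [-max_amplitude, +max_amplitude]; with even ``n_points`` the grid
    excludes zero (the midpoints +-(2k-1)/(n-1) * max_amplitude), so every
    call carries slope information and symmetric spacing cancels even-order
    anharmonicity in the slope estimate.
    """
    if n_points < 4 or n_points % 2:
        raise ElasticityError("n_points must be an even number >= 4")
    if max_amplitude <= 0.0:
        raise ElasticityError("max_amplitude must be positive")
    amplitudes = np.linspace(-max_amplitude, max_amplitude, n_points)
    stresses = []
    for a in amplitudes:
        try:
            stresses.append(np.asarray(oracle.evaluate(strain_tensor(pattern, a)),
                                       dtype=float))
        except ElasticityError:
            raise
        except Exception as exc:
            raise ElasticityError(
                f"stress engine failed at amplitude {a:+.6g} "
                f"(pattern {pattern.label}): {exc}") from exc
    return DeformationSeries(pattern=pattern, amplitudes=amplitudes,
                             stresses=stresses)


def _ols_slope(x: np.ndarray, y: np.ndarray,
               intercept: bool) -> tuple[float, float, np.ndarray]:
    """Slope, its standard error, and residuals of y ~ x (optionally + 1)."""
    if intercept:
        X = np.column_stack([x, np.ones_like(x)])
    else:
        X = x[:, None]
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(x) - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return float(beta[0]), float(np.sqrt(cov[0, 0])), resid


class StressStrainModel:
    """Least-squares model for elastic constants from deformation series.

    Parameters
    ----------
    series_set : list of DeformationSeries
        One series per strain pattern.
    laue_class : str, optional
        When given, equal-by-symmetry ties fill the Voigt columns a reduced
        pattern set does not excite, and class-forbidden entries are held
        at zero.  Without it, the series must excite all six components.
    fit_intercept : bool
        Fit an intercept per regression (detects residual stress at zero
        strain); default False, since the stress-engine contract fixes
        evaluate(0) = 0.
    """

    def __init__(self, series_set: list[DeformationSeries],
                 laue_class: str | None = None, fit_intercept: bool = False):
        if not series_set:
            raise ElasticityError("series_set is empty")
        self.series_set = list(series_set)
        self.laue_class = laue_class
        self.fit_intercept = fit_intercept
        self.spec: SymmetryClassSpec | None = (
            symmetry_class(laue_class) if laue_class is not None else None)

    @classmethod
    def from_oracle(cls, oracle, laue_class: str,
                    max_amplitude: float = 0.003, n_points: int = 12,
                    fit_intercept: bool = False) -> "StressStrainModel":
        """Collect one series per canonical pattern of ``laue_class``."""
        series = [collect_series(oracle, p, max_amplitude, n_points)
                  for p in generate_patterns(laue_class)]
        return cls(series, laue_class=laue_class, fit_intercept=fit_intercept)

    def fit(self) -> "StressStrainResults":
        """Per-pattern OLS slopes, assembled and symmetrized.

        For a series exciting Voigt component k, the slope of stress
        component i against the effective strain amplitude estimates
        C[i, k].  With a Laue class, each independent coefficient is the
        mean over all measured positions tied to it; the class pattern then
        rebuilds the full matrix.  Without one, the matrix of measured
        columns is symmetrized by (C + C^T)/2.
        """
        measured = np.full((6, 6), np.nan)
        stderr = np.full((6, 6), np.nan)
        resid_all: list[np.ndarray] = []
        for series in self.series_set:
            if len(series.pattern.voigt_components) != 1:
                raise ElasticityError(
                    "fit supports single-component patterns; "
                    f"got {series.pattern.label}")
            k = series.pattern.voigt_components[0] - 1
            w = series.pattern.weights[0]
            x = series.amplitudes * w
            sv = series.stress_voigt()
            for i in range(6):
                slope, se, resid = _ols_slope(x, sv[:, i], self.fit_intercept)
                measured[i, k] = slope
                stderr[i, k] = se
                resid_all.append(resid)
        covered = ~np.all(np.isnan(measured), axis=0)
        resid_rms = float(np.sqrt(np.mean(np.concatenate(resid_all) ** 2)))

        if self.spec is None:
            missing = [k + 1 for k in range(6) if not covered[k]]
            if missing:
                raise ElasticityError(
                    f"underdetermined: no series excites Voigt components "
                    f"{missing}; provide them or pass a laue_class")
            asym = float(np.nanmax(np.abs(measured - measured.T)))
            C = (measured + measured.T) / 2.0
            bse = np.sqrt((np.nan_to_num(stderr) ** 2 +
                           np.nan_to_num(stderr).T ** 2)) / 2.0
        else:
            C, bse, asym = self._assemble_by_class(measured, stderr)

        tensor = ElasticTensor(C, source_label="fitted"
                               + (f" ({self.laue_class})" if self.laue_class else ""),
                               tolerance=np.inf)
        return StressStrainResults(model=self, stiffness=tensor, bse=bse,
                                   resid_rms=resid_rms, asymmetry=asym,
                                   measured=measured, measured_stderr=stderr)

    def _assemble_by_class(self, measured, stderr):
        spec = self.spec
        values: dict = {}
        errors: dict = {}
        asym = 0.0
        missing = []
        for rep in spec.independent:
            obs, errs = [], []
            for (i, j) in spec.positions_of(rep):
                for (p, q) in {(i, j), (j, i)}:
                    if not np.isnan(measured[p, q]):
                        obs.append(measured[p, q])
                        errs.append(stderr[p, q])
            if not obs:
                missing.append((rep[0] + 1, rep[1] + 1))
                continue
            values[rep] = float(np.mean(obs))
            errors[rep] = float(np.sqrt(np.sum(np.square(errs))) / len(errs))
            if len(obs) > 1:
                asym = max(asym, float(np.ptp(obs)))
        if missing:
            raise ElasticityError(
                f"underdetermined: independent coefficients {missing} "
                "(1-based) are not excited by any series")
        C = spec.build(values)
        bse = np.zeros((6, 6))
        for rep in spec.independent:
            for (i, j) in spec.positions_of(rep):
                bse[i, j] = bse[j, i] = errors[rep]
        for (i, j), fn in spec.derived.items():
            bse[i, j] = bse[j, i] = fn(errors)  # linear in the same entries
        return C, np.abs(bse), asym


@dataclasses.dataclass
class StressStrainResults:
    """Fitted elastic constants with uncertainties and diagnostics."""

    model: StressStrainModel
    stiffness: ElasticTensor       # symmetrized fit, GPa
    bse: np.ndarray                # 6x6 standard errors, GPa
    resid_rms: float               # pooled regression residual RMS, GPa
    asymmetry: float               # pre-symmetrization spread, GPa
    measured: np.ndarray           # raw 6x6 slope matrix (NaN = not excited)
    measured_stderr: np.ndarray

    @property
    def params(self) -> np.ndarray:
        return self.stiffness.matrix

    def max_abs_error(self, C_true) -> float:
        """Largest absolute deviation from a reference stiffness (GPa)."""
        ref = C_true.matrix if isinstance(C_true, ElasticTensor) \
            else np.asarray(C_true, float)
        return float(np.abs(self.stiffness.matrix - ref).max())

    def summary(self) -> str:
        lines = ["Stress-strain elastic constant fit",
                 "=" * 50,
                 f"Laue class:       {self.model.laue_class or 'none (all 6 columns)'}",
                 f"Series:           {len(self.model.series_set)} patterns, "
                 f"{len(self.model.series_set[0].amplitudes)} points each",
                 f"Residual RMS:     {self.resid_rms:.3e} GPa",
                 f"Asymmetry (raw):  {self.asymmetry:.3e} GPa",
                 "",
                 "Stiffness matrix C (GPa), standard errors below:"]
        for i in range(6):
            lines.append("  " + " ".join(f"{self.stiffness.matrix[i, j]:9.4f}"
                                         for j in range(6)))
        lines.append("")
        for i in range(6):
            lines.append("  " + " ".join(f"{self.bse[i, j]:9.2e}"
                                         for j in range(6)))
        return "\n".join(lines)


def fit_constants(series_set: list[DeformationSeries],
                  laue_class: str | None = None,
                  fit_intercept: bool = False) -> StressStrainResults:
    """Functional wrapper: build a :class:`StressStrainModel` and fit it."""
    return StressStrainModel(series_set, laue_class=laue_class,
                             fit_intercept=fit_intercept).fit()
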