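"""File formats and the end-to-end deformability report.

Formats:

* stiffness matrix files — 6 lines of 6 whitespace-separated reals (GPa),
  optional ``#`` comment lines (the dialect the ELATE web tool accepts);
* deformation-series archives — CSV with columns pattern_label, amplitude,
  s11, s22, s33, s23, s13, s12 (GPa) at 12 significant digits;
* surface / slice exports — CSV with theta_rad[, phi_rad], value_gpa;
* the deformability report — a JSON document per system with stability,
  Voigt averages, anisotropy indices, extremal directions, plane slices and
  (when a structure is given) the contact-alignment analysis.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import frames, maps
from .core import ElasticityError, ElasticTensor
from .fitting import DeformationSeries, StrainPattern

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_series",
    "write_series",
    "write_surface_csv",
    "write_slice_csv",
    "stability_json",
    "analyze_tensor",
    "deformability_report",
]


def read_matrix(path, source_label: str | None = None,
                tolerance: float = 1e-3) -> ElasticTensor:
    """Read a 6x6 stiffness matrix file (GPa, '#' comments allowed)."""
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(tok) for tok in line.split()])
    if len(rows) != 6 or any(len(r) != 6 for r in rows):
        raise ElasticityError(
            f"{path}: expected 6 rows of 6 numbers, got "
            f"{[len(r) for r in rows]}")
    return ElasticTensor(np.array(rows), tolerance=tolerance,
                         source_label=source_label or path.stem)


def write_matrix(path, tensor, comment: str | None = None) -> None:
    """Write a stiffness matrix file with 6 significant digits."""
    m = tensor.matrix if isinstance(tensor, ElasticTensor) \
        else np.asarray(tensor, float)
    lines = []
    if comment:
        lines.append(f"# {comment}")
    elif isinstance(tensor, ElasticTensor) and tensor.source_label:
        lines.append(f"# {tensor.source_label}")
    for row in m:
        lines.append(" ".join(f"{v:.6g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


_SERIES_COLUMNS = ["pattern_label", "amplitude",
                   "s11", "s22", "s33", "s23", "s13", "s12"]


def write_series(path, series_set: list[DeformationSeries]) -> None:
    """Write a deformation-series archive (CSV, 12 significant digits)."""
    import pandas as pd

    rows = []
    for series in series_set:
        sv = series.stress_voigt()
        for a, s in zip(series.amplitudes, sv):
            rows.append([series.pattern.label, f"{a:.12g}"]
                        + [f"{x:.12g}" for x in s])
    pd.DataFrame(rows, columns=_SERIES_COLUMNS).to_csv(path, index=False)


def read_series(path) -> list[DeformationSeries]:
    """Read a deformation-series archive written by :func:`write_series`.

    Pattern labels of the form ``e<k>`` map back to single-component
    patterns; the write/read round trip is bit-equal at 12 digits.
    """
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ElasticityError(f"{path}: missing columns {missing}")
    out = []
    for label, group in df.groupby("pattern_label", sort=False):
        if not (label.startswith("e") and label[1:].isdigit()
                and 1 <= int(label[1:]) <= 6):
            raise ElasticityError(f"{path}: unrecognized pattern label {label!r}")
        pattern = StrainPattern((int(label[1:]),), (1.0,), label=label)
        group = group.sort_values("amplitude")
        stresses = []
        for _, r in group.iterrows():
            s = np.array([[r.s11, r.s12, r.s13],
                          [r.s12, r.s22, r.s23],
                          [r.s13, r.s23, r.s33]], dtype=float)
            stresses.append(s)
        out.append(DeformationSeries(pattern=pattern,
                                     amplitudes=group["amplitude"].to_numpy(),
                                     stresses=stresses))
    return out


def write_surface_csv(path, surface: maps.ModulusSurface) -> None:
    surface.to_dataframe().to_csv(path, index=False, float_format="%.9g")


def write_slice_csv(path, sl: frames.PlaneSliceResult) -> None:
    sl.to_dataframe().to_csv(path, index=False, float_format="%.9g")


def stability_json(tensor: ElasticTensor) -> dict:
    """The compact stability/averages record for one tensor."""
    report = tensor.stability()
    out = {"source_label": tensor.source_label,
           "stable": report.stable,
           "eigenvalues": [float(x) for x in report.eigenvalues]}
    if report.stable:
        out.update(tensor.voigt_averages().to_dict())
    else:
        out.update({"K_V": None, "G_V": None, "E_V": None})
    return out


def _round1(x: float) -> float:
    return float(np.round(x, 1))


def analyze_tensor(tensor: ElasticTensor,
                   cell: frames.CrystalCell | None = None,
                   sites: list | None = None,
                   planes: tuple[str, ...] = frames.PLANES,
                   properties: tuple[str, ...] = ("young", "shear_min"),
                   contact_criteria: frames.ContactCriteria | None = None,
                   n_seed: int = 2562, n_chi: int = 72,
                   n_angles: int = 360) -> dict:
    """Full single-tensor analysis: stability -> averages -> extrema ->
    anisotropy -> plane slices -> (contacts -> alignment).

    Returns a JSON-serializable dict.  For an unstable tensor the
    directional sections are omitted (there is no meaningful modulus
    surface to report).
    """
    out = stability_json(tensor)
    if not out["stable"]:
        return out

    ext_young = maps.global_extrema(tensor, "young", n_seed=n_seed)
    ext_shear = maps.global_extrema(tensor, "shear", n_seed=n_seed, n_chi=n_chi)
    out["extrema"] = {"young": ext_young.to_dict(),
                      "shear": ext_shear.to_dict()}
    out["A_E"] = maps.anisotropy_index(ext_young)
    out["A_G"] = maps.anisotropy_index(ext_shear)
    out["table"] = {"G_V": _round1(out["G_V"]), "E_V": _round1(out["E_V"]),
                    "A_G": _round1(out["A_G"]), "A_E": _round1(out["A_E"])}

    if cell is not None:
        out["cell"] = {"a": cell.a, "b": cell.b, "c": cell.c,
                       "alpha": cell.alpha, "beta": cell.beta,
                       "gamma": cell.gamma}
        slices = []
        out["slices"] = {}
        for plane in planes:
            for prop in properties:
                sl = frames.plane_slice(tensor, cell, plane, property=prop,
                                        n_angles=n_angles, n_chi=n_chi)
                slices.append(sl)
                out["slices"][f"{plane}:{prop}"] = {
                    "max_angle_rad": sl.max_angle,
                    "max_value_gpa": float(sl.values.max()),
                    "min_value_gpa": float(sl.values.min()),
                    "e1": [float(x) for x in sl.e1],
                    "e2": [float(x) for x in sl.e2],
                }
        if sites:
            crit = contact_criteria or frames.ContactCriteria()
            contacts = frames.detect_contacts(sites, cell, crit)
            out["contact_criteria"] = crit.to_dict()
            out["contacts"] = [{
                "donor": c.donor_label, "hydrogen": c.hydrogen_label,
                "acceptor": c.acceptor_label, "class": c.contact_class,
                "d_HA": c.d_HA, "d_DA": c.d_DA, "angle_DHA": c.angle_DHA,
                "direction": [float(x) for x in c.direction],
                "image_shift": list(c.image_shift)} for c in contacts]
            if contacts:
                young_slices = [s for s in slices if s.property == "young"]
                out["alignment"] = frames.alignment_report(
                    ext_young, contacts, young_slices).to_dict()
    return out


def _file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def deformability_report(matrix_paths: list, cif_path=None,
                         config: dict | None = None, **kwargs) -> dict:
    """Multi-system deformability report with provenance.

    Every number in the report is re-derivable from the named inputs plus
    the recorded configuration.
    """
    import importlib.metadata

    import scipy

    cell = sites = None
    if cif_path is not None:
        cell, sites = frames.read_cif(cif_path)
    systems = {}
    for p in matrix_paths:
        tensor = read_matrix(p)
        systems[tensor.source_label] = analyze_tensor(
            tensor, cell=cell, sites=sites, **kwargs)
    return {
        "systems": systems,
        "provenance": {
            "inputs": {str(p): _file_sha256(p) for p in matrix_paths}
            | ({str(cif_path): _file_sha256(cif_path)} if cif_path else {}),
            "config": config or {},
            "versions": {"numpy": np.__version__,
                         "scipy": scipy.__version__,
                         "click": importlib.metadata.version("click")},
        },
    }


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
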