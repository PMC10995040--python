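"""Readers and writers for all coroperf artifacts.

JSON for records and reports, YAML for run configurations, CSV for time
series and voxel fields (plus optional legacy-VTK structured points for
visualization).  Every artifact carries a metadata block — package
version, config hash, seed — as a ``_meta`` object in JSON or ``#``
comment lines in CSV.  Reads are schema-checked: a malformed header or a
missing field raises :class:`~coroperf.errors.SchemaError` naming the
field and the file, never a silent misparse.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .errors import SchemaError
from .hyperemia import QUANTITIES, PairedMeasureSet, StressMapCoefficients
from .patient import PatientRecord
from .perfusion import DarcyGrid, DarcyState
from .tree import CoronaryTree, Segment, Stenosis

__all__ = [
    "config_hash",
    "metadata",
    "read_patient",
    "write_patient",
    "read_pairs_csv",
    "write_pairs_csv",
    "write_series_csv",
    "read_series_csv",
    "read_tree_csv",
    "write_tree_csv",
    "read_stenoses_csv",
    "write_json",
    "read_json",
    "read_yaml",
    "write_darcy_csv",
    "write_vtk_structured_points",
]

_PATIENT_FIELDS = ("age", "sex", "height", "weight", "HR", "P_sys", "P_dia", "LV_mass", "state")


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def metadata(cfg_hash: str = "", seed: int | None = None) -> dict:
    return {"package": "coroperf", "version": __version__, "config_hash": cfg_hash, "seed": seed}


# -- JSON ---------------------------------------------------------------


def write_json(path, payload: dict, cfg_hash: str = "", seed: int | None = None) -> None:
    doc = dict(payload)
    doc["_meta"] = metadata(cfg_hash, seed)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    doc = json.loads(Path(path).read_text())
    doc.pop("_meta", None)
    return doc


def read_patient(path) -> PatientRecord:
    """Read one patient record from JSON; field names and units as declared."""
    doc = read_json(path)
    missing = [f for f in _PATIENT_FIELDS if f not in doc and f != "state"]
    if missing:
        raise SchemaError(f"{path}: missing patient field(s) {', '.join(missing)}")
    extra = [k for k in doc if k not in _PATIENT_FIELDS]
    if extra:
        raise SchemaError(f"{path}: unknown patient field(s) {', '.join(extra)}")
    return PatientRecord(**doc)


def write_patient(record: PatientRecord, path, cfg_hash: str = "", seed: int | None = None) -> None:
    write_json(path, asdict(record), cfg_hash, seed)


# -- CSV ----------------------------------------------------------------


def _write_csv(path, df: pd.DataFrame, cfg_hash: str, seed) -> None:
    meta = metadata(cfg_hash, seed)
    header = "".join(f"# {k}: {v}\n" for k, v in meta.items())
    with open(path, "w", newline="\n") as fh:
        fh.write(header)
        # %.17g round-trips every IEEE double exactly
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def write_series_csv(path, t, p, cfg_hash: str = "", seed=None) -> None:
    """Two-column waveform series ``time_s,pressure_mmHg`` at full precision."""
    df = pd.DataFrame({"time_s": np.asarray(t, float), "pressure_mmHg": np.asarray(p, float)})
    _write_csv(path, df, cfg_hash, seed)


def read_series_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv(path, ("time_s", "pressure_mmHg"))
    return df["time_s"].to_numpy(), df["pressure_mmHg"].to_numpy()


def write_pairs_csv(path, datasets: dict[str, PairedMeasureSet], cfg_hash: str = "", seed=None) -> None:
    frames = [
        pd.DataFrame({"quantity": ds.quantity, "x_rest": ds.rest, "x_stress": ds.stress})
        for ds in datasets.values()
    ]
    _write_csv(path, pd.concat(frames, ignore_index=True), cfg_hash, seed)


def read_pairs_csv(path) -> dict[str, PairedMeasureSet]:
    df = _read_csv(path, ("quantity", "x_rest", "x_stress"))
    out: dict[str, PairedMeasureSet] = {}
    for q, sub in df.groupby("quantity", sort=False):
        if q not in QUANTITIES:
            raise SchemaError(f"{path}: unknown quantity {q!r} (expected one of {QUANTITIES})")
        out[str(q)] = PairedMeasureSet(str(q), sub["x_rest"].to_numpy(), sub["x_stress"].to_numpy())
    return out


def write_coeffs_json(path, coeffs: StressMapCoefficients, cfg_hash: str = "", seed=None) -> None:
    write_json(path, coeffs.as_dict(), cfg_hash, seed)


def read_coeffs_json(path) -> StressMapCoefficients:
    doc = read_json(path)
    missing = [q for q in QUANTITIES if q not in doc]
    if missing:
        raise SchemaError(f"{path}: missing coefficient block(s) {', '.join(missing)}")
    return StressMapCoefficients.from_dict(doc)


def write_tree_csv(path, tree: CoronaryTree, cfg_hash: str = "", seed=None) -> None:
    df = pd.DataFrame(
        {
            "segment_id": [s.id for s in tree.segments],
            "parent_id": [s.parent if s.parent is not None else "" for s in tree.segments],
            "length_m": [s.length for s in tree.segments],
            "radius_m": [s.radius for s in tree.segments],
            "territory": [s.territory for s in tree.segments],
        }
    )
    _write_csv(path, df, cfg_hash, seed)


def read_tree_csv(path, stenoses: tuple[Stenosis, ...] = ()) -> CoronaryTree:
    df = _read_csv(path, ("segment_id", "parent_id", "length_m", "radius_m", "territory"))
    segments = tuple(
        Segment(
            id=str(row.segment_id),
            parent=None if (pd.isna(row.parent_id) or str(row.parent_id) == "") else str(row.parent_id),
            length=float(row.length_m),
            radius=float(row.radius_m),
            territory=str(row.territory),
        )
        for row in df.itertuples()
    )
    return CoronaryTree(segments=segments, stenoses=tuple(stenoses))


def read_stenoses_csv(path) -> tuple[Stenosis, ...]:
    df = _read_csv(path, ("segment_id", "radius_reduction_frac", "length_frac"))
    return tuple(
        Stenosis(str(r.segment_id), float(r.radius_reduction_frac), float(r.length_frac))
        for r in df.itertuples()
    )


def read_yaml(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: YAML config must be a mapping")
    return doc


# -- fields -------------------------------------------------------------


def write_darcy_csv(path, state: DarcyState, cfg_hash: str = "", seed=None) -> None:
    """Long-format voxel field ``i,j,k,p1_mmHg,p2_mmHg,p3_mmHg,mbf_ml_min_100g``."""
    grid = state.grid
    ii, jj, kk = np.meshgrid(
        np.arange(grid.nx), np.arange(grid.ny), np.arange(grid.nz), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "k": kk.ravel(),
            "p1_mmHg": state.p1.ravel(),
            "p2_mmHg": state.p2.ravel(),
            "p3_mmHg": state.p3.ravel(),
            "mbf_ml_min_100g": state.mbf.ravel(),
        }
    )
    _write_csv(path, df, cfg_hash, seed)


def write_vtk_structured_points(path, grid: DarcyGrid, fields: dict[str, np.ndarray]) -> None:
    """Legacy ASCII VTK structured-points file for quick visualization."""
    lines = [
        "# vtk DataFile Version 3.0",
        "coroperf darcy fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {grid.nx} {grid.ny} {grid.nz}",
        "ORIGIN 0 0 0",
        f"SPACING {grid.h} {grid.h} {grid.h}",
        f"POINT_DATA {grid.n_cells}",
    ]
    for name, field_ in fields.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK expects x fastest; our arrays are C-ordered (z fastest)
        lines.extend(format(v, ".10g") for v in np.transpose(field_, (2, 1, 0)).ravel())
    Path(path).write_text("\n".join(lines) + "\n")
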