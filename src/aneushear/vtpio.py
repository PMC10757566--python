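"""File I/O: VTK XML PolyData surfaces, waveform/cohort/trace CSV, JSON.

Surface fields travel as ASCII VTK XML PolyData (.vtp) with per-point
arrays ``region`` (0 excluded, 1 dome, 2 parent) and ``WSS_t<k>``
(3-component, one per time index), plus field-data arrays ``times`` and
``length_unit_cm`` (coordinate scale relative to cm).  A directory of
per-timestep .vtp files with a ``manifest.csv`` (columns time_s, file) is
accepted as an equivalent dialect, each file carrying a single ``WSS``
array.  Floats are written with 17 significant digits so a write/read
round trip is bitwise exact.
"""
from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InvalidParameterError, TriSurfaceField, Waveform
from .cohortstats import PairedCohort
from .meshconv import ConvergenceTrace

log = logging.getLogger("aneushear")


class FormatError(ValueError):
    """Malformed or unsupported surface-field file."""


def _fmt(a: np.ndarray) -> str:
    return " ".join(repr(float(x)) for x in np.asarray(a, dtype=float).ravel())


def _fmt_int(a: np.ndarray) -> str:
    return " ".join(str(int(x)) for x in np.asarray(a).ravel())


def _data_array(name: str, a: np.ndarray, n_comp: int | None = None) -> ET.Element:
    if np.issubdtype(np.asarray(a).dtype, np.integer):
        vtk_type, text = "Int64", _fmt_int(a)
    else:
        vtk_type, text = "Float64", _fmt(a)
    el = ET.Element("DataArray", {"type": vtk_type, "Name": name, "format": "ascii"})
    if n_comp is not None:
        el.set("NumberOfComponents", str(n_comp))
    el.text = text
    return el


def write_surface_field(field: TriSurfaceField, path: str | Path) -> Path:
    """Write a TriSurfaceField as ASCII VTK XML PolyData (.vtp)."""
    path = Path(path)
    root = ET.Element(
        "VTKFile", {"type": "PolyData", "version": "1.0", "byte_order": "LittleEndian"}
    )
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(
        poly,
        "Piece",
        {
            "NumberOfPoints": str(field.n_points),
            "NumberOfVerts": "0",
            "NumberOfLines": "0",
            "NumberOfStrips": "0",
            "NumberOfPolys": str(field.triangles.shape[0]),
        },
    )
    fd = ET.SubElement(piece, "FieldData")
    fd.append(_data_array("times", field.times))
    fd.append(_data_array("length_unit_cm", np.array([field.metadata.get("length_unit_cm", 1.0)])))
    pd_el = ET.SubElement(piece, "PointData")
    pd_el.append(_data_array("region", field.region.astype(np.int64)))
    for k in range(field.times.size):
        pd_el.append(_data_array(f"WSS_t{k}", field.wss[k], n_comp=3))
    pts = ET.SubElement(piece, "Points")
    pts.append(_data_array("Points", field.points, n_comp=3))
    polys = ET.SubElement(piece, "Polys")
    polys.append(_data_array("connectivity", field.triangles.astype(np.int64)))
    polys.append(
        _data_array("offsets", 3 * (np.arange(field.triangles.shape[0], dtype=np.int64) + 1))
    )
    ET.indent(root)
    path.parent.mkdir(parents=True, exist_ok=True)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
    return path


def _parse_array(el: ET.Element) -> np.ndarray:
    tokens = (el.text or "").split()
    dtype = np.int64 if el.get("type", "Float64").startswith("Int") else float
    a = np.array(tokens, dtype=dtype)
    n_comp = int(el.get("NumberOfComponents", "1"))
    return a.reshape(-1, n_comp) if n_comp > 1 else a


def _find_arrays(parent: ET.Element | None) -> dict[str, ET.Element]:
    if parent is None:
        return {}
    return {el.get("Name", ""): el for el in parent.findall("DataArray")}


def read_surface_field(path: str | Path) -> TriSurfaceField:
    """Read a .vtp surface field (or a per-timestep directory with manifest).

    Validates the presence of the ``region`` and time arrays and that all
    cells are triangles; a missing ``length_unit_cm`` declaration assumes
    cm with a logged warning.
    """
    path = Path(path)
    if path.is_dir():
        return _read_timestep_directory(path)
    if not path.exists():
        raise FileNotFoundError(path)
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise FormatError(f"{path}: no PolyData Piece element")
    points, triangles = _read_geometry(piece, path)
    point_arrays = _find_arrays(piece.find("PointData"))
    field_arrays = _find_arrays(piece.find("FieldData"))

    if "region" not in point_arrays:
        raise FormatError(f"{path}: missing point-data array 'region'")
    if "times" not in field_arrays:
        raise FormatError(f"{path}: missing field-data array 'times'")
    times = _parse_array(field_arrays["times"])
    wss_names = [f"WSS_t{k}" for k in range(times.size)]
    missing = [n for n in wss_names if n not in point_arrays]
    if missing:
        raise FormatError(f"{path}: missing WSS time-step arrays: {missing[:3]}...")
    wss = np.stack([_parse_array(point_arrays[n]) for n in wss_names])
    scale = _length_scale(field_arrays, str(path))
    return TriSurfaceField(
        points=points * scale,
        triangles=triangles,
        region=_parse_array(point_arrays["region"]).astype(np.int64),
        times=times,
        wss=wss,
        metadata={"source": str(path), "length_unit_cm": scale},
    )


def _length_scale(field_arrays: dict[str, ET.Element], origin: str) -> float:
    if "length_unit_cm" in field_arrays:
        return float(_parse_array(field_arrays["length_unit_cm"])[0])
    log.warning("%s: no length_unit_cm declaration; assuming coordinates in cm", origin)
    return 1.0


def _read_geometry(piece: ET.Element, path: Path) -> tuple[np.ndarray, np.ndarray]:
    pts_el = piece.find("Points/DataArray")
    if pts_el is None:
        raise FormatError(f"{path}: missing Points")
    points = _parse_array(pts_el)
    polys = piece.find("Polys")
    if polys is None:
        raise FormatError(f"{path}: missing Polys")
    arrays = _find_arrays(polys)
    conn = _parse_array(arrays["connectivity"]).astype(np.int64).ravel()
    offsets = _parse_array(arrays["offsets"]).astype(np.int64).ravel()
    sizes = np.diff(np.concatenate([[0], offsets]))
    if not np.all(sizes == 3):
        raise FormatError(f"{path}: non-triangle cells present; only triangles are supported")
    return points, conn.reshape(-1, 3)


def _read_timestep_directory(path: Path) -> TriSurfaceField:
    manifest = path / "manifest.csv"
    if not manifest.exists():
        raise FormatError(f"{path}: per-timestep directory requires manifest.csv")
    man = pd.read_csv(manifest, float_precision="round_trip")
    if not {"time_s", "file"} <= set(man.columns):
        raise FormatError(f"{manifest}: manifest needs columns time_s, file")
    man = man.sort_values("time_s")
    times = man["time_s"].to_numpy(float)
    wss_steps, points = [], None
    triangles = region = None
    scale = 1.0
    for _, row in man.iterrows():
        root = ET.parse(path / row["file"]).getroot()
        piece = root.find(".//Piece")
        if piece is None:
            raise FormatError(f"{row['file']}: no Piece element")
        pts, tris = _read_geometry(piece, path / row["file"])
        point_arrays = _find_arrays(piece.find("PointData"))
        if "WSS" not in point_arrays:
            raise FormatError(f"{row['file']}: missing point-data array 'WSS'")
        if points is None:
            points, triangles = pts, tris
            if "region" not in point_arrays:
                raise FormatError(f"{row['file']}: missing point-data array 'region'")
            region = _parse_array(point_arrays["region"]).astype(np.int64)
            scale = _length_scale(_find_arrays(piece.find("FieldData")), str(path / row["file"]))
        wss_steps.append(_parse_array(point_arrays["WSS"]))
    return TriSurfaceField(
        points=points * scale,
        triangles=triangles,
        region=region,
        times=times,
        wss=np.stack(wss_steps),
        metadata={"source": str(path), "length_unit_cm": scale},
    )


def write_timestep_directory(field: TriSurfaceField, out_dir: str | Path) -> Path:
    """Write the per-timestep directory dialect (one .vtp per time sample)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, t in enumerate(field.times):
        name = f"step_{k:04d}.vtp"
        _write_single_step(field, field.wss[k], out_dir / name)
        rows.append({"time_s": float(t), "file": name})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def _write_single_step(field: TriSurfaceField, wss_k: np.ndarray, path: Path) -> None:
    root = ET.Element(
        "VTKFile", {"type": "PolyData", "version": "1.0", "byte_order": "LittleEndian"}
    )
    piece = ET.SubElement(
        ET.SubElement(root, "PolyData"),
        "Piece",
        {
            "NumberOfPoints": str(field.n_points),
            "NumberOfVerts": "0",
            "NumberOfLines": "0",
            "NumberOfStrips": "0",
            "NumberOfPolys": str(field.triangles.shape[0]),
        },
    )
    fd = ET.SubElement(piece, "FieldData")
    fd.append(_data_array("length_unit_cm", np.array([field.metadata.get("length_unit_cm", 1.0)])))
    pd_el = ET.SubElement(piece, "PointData")
    pd_el.append(_data_array("region", field.region.astype(np.int64)))
    pd_el.append(_data_array("WSS", wss_k, n_comp=3))
    pts = ET.SubElement(piece, "Points")
    pts.append(_data_array("Points", field.points, n_comp=3))
    polys = ET.SubElement(piece, "Polys")
    polys.append(_data_array("connectivity", field.triangles.astype(np.int64)))
    polys.append(
        _data_array("offsets", 3 * (np.arange(field.triangles.shape[0], dtype=np.int64) + 1))
    )
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


# --- waveform / cohort / trace tables -------------------------------------

def write_waveform(waveform: Waveform, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": waveform.time, "flow_cm3_s": waveform.flow}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def read_waveform(path: str | Path) -> Waveform:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"time_s", "flow_cm3_s"} <= set(df.columns):
        raise FormatError(f"{path}: waveform CSV needs columns time_s, flow_cm3_s")
    t = df["time_s"].to_numpy(float)
    return Waveform(time=t, flow=df["flow_cm3_s"].to_numpy(float), period=float(t[-1]))


def write_cohort(cohort: PairedCohort, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_cohort(path: str | Path) -> PairedCohort:
    return PairedCohort(pd.read_csv(path, float_precision="round_trip"))


def read_outlet_areas(path: str | Path) -> np.ndarray:
    """Outlet areas from a one-column CSV (column area_cm2)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "area_cm2" not in df.columns:
        raise FormatError(f"{path}: outlet CSV needs column area_cm2")
    return df["area_cm2"].to_numpy(float)


def read_convergence_trace(path: str | Path) -> ConvergenceTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"edge_size_mm", "dome_mean_tawss"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: trace CSV needs columns {sorted(need)}")
    return ConvergenceTrace(
        edge_sizes=df["edge_size_mm"].to_numpy(float),
        dome_mean_tawss=df["dome_mean_tawss"].to_numpy(float),
    )


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
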