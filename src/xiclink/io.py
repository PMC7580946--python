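"""File I/O: mzML ingestion, point tables, XIC exports and annotation tables.

Canonical units: RT in seconds (minutes auto-converted on read), m/z in
Thomson, intensity in arbitrary ion counts.  Zero-intensity points (profile
padding) are dropped at read time so the baseline denominator is
reproducible.

Export formats
--------------
``points_csv``   one row per point:
    ``xic_id,point_id,mz,rt,intensity,is_root``
``summary_csv``  one row per XIC:
    ``xic_id,n_points,mz_min,mz_max,rt_min,rt_max,apex_mz,apex_rt,total_intensity``
``json``         ``{"xics": [{"xic_id": ..., "points": [...]}, ...]}``

Annotation tables are CSVs with columns ``(xic_id, mz, rt, intensity)`` or
``(xic_id, point_id)`` (or both); ``points_csv`` exports read back as
annotation tables unchanged.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
from lxml import etree

from xiclink.model import (
    AnnotatedXicSet,
    AnnotationPoint,
    EmptyRunError,
    FormatError,
    InvariantError,
    Point,
    Run,
    Scan,
    SchemaError,
    Xic,
)

PathLike = Union[str, Path]

POINTS_CSV_COLUMNS = ["xic_id", "point_id", "mz", "rt", "intensity", "is_root"]
SUMMARY_CSV_COLUMNS = [
    "xic_id",
    "n_points",
    "mz_min",
    "mz_max",
    "rt_min",
    "rt_max",
    "apex_mz",
    "apex_rt",
    "total_intensity",
]


# Controlled-vocabulary accessions used by the mzML reader.
_CV_MS_LEVEL = "MS:1000511"
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_SCAN_START = "MS:1000016"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NO_COMPRESSION = "MS:1000576"
_UNIT_MINUTE = "UO:0000031"


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _decode_binary_array(bda: etree._Element, spectrum_id: str) -> Optional[tuple[str, np.ndarray]]:
    """Decode one <binaryDataArray>; returns (kind, values) or None."""
    kind = None
    dtype = None
    compression = "none"
    binary_text = ""
    for child in bda.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _CV_MZ_ARRAY:
                kind = "mz"
            elif acc == _CV_INTENSITY_ARRAY:
                kind = "intensity"
            elif acc == _CV_FLOAT64:
                dtype = "<f8"
            elif acc == _CV_FLOAT32:
                dtype = "<f4"
            elif acc == _CV_ZLIB:
                compression = "zlib"
            elif acc == _CV_NO_COMPRESSION:
                compression = "none"
        elif name == "binary":
            binary_text = child.text or ""
    if kind is None:
        return None
    if dtype is None:
        raise FormatError(
            f"spectrum {spectrum_id}: binaryDataArray ({kind}) declares no "
            "float width cvParam"
        )
    data = base64.b64decode(binary_text) if binary_text.strip() else b""
    if compression == "zlib" and data:
        data = zlib.decompress(data)
    return kind, np.frombuffer(data, dtype=dtype).astype(float)


def _parse_spectrum(elem: etree._Element) -> dict:
    sid = elem.get("id", "?")
    out = {"id": sid, "ms_level": None, "mode": None, "rt": None, "mz": None, "intensity": None}
    for child in elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _CV_MS_LEVEL:
                out["ms_level"] = int(child.get("value", "0"))
            elif acc == _CV_CENTROID:
                out["mode"] = "centroid"
            elif acc == _CV_PROFILE:
                out["mode"] = "profile"
            elif acc == _CV_SCAN_START:
                rt = float(child.get("value"))
                unit = child.get("unitAccession", "") or child.get("unitName", "")
                if unit == _UNIT_MINUTE or "minute" in unit:
                    rt *= 60.0
                out["rt"] = rt
        elif name == "binaryDataArray":
            decoded = _decode_binary_array(child, sid)
            if decoded is not None:
                out[decoded[0]] = decoded[1]
    return out


def _iter_mzml_spectra(path: Path) -> Iterator[dict]:
    try:
        context = etree.iterparse(str(path), events=("end",))
        for _, elem in context:
            if _local(elem.tag) == "spectrum":
                yield _parse_spectrum(elem)
                elem.clear()
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"invalid mzML {path}: {exc}") from exc


def read_mzml(path: PathLike, ms_level_filter: int = 1) -> Run:
    """Read an mzML file into a Run, keeping only one MS level.

    The acquisition mode is taken from the spectrum-representation cvParams
    (``centroid spectrum`` / ``profile spectrum``) when present on every
    kept spectrum; mixed or absent metadata yields ``unknown``.  RT is
    converted to seconds regardless of the unit the file declares.  Handles
    64- and 32-bit float arrays, zlib-compressed or not, in plain or
    indexed mzML.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mzML file not found: {path}")
    raw: list[tuple[float, list[tuple[float, float]], Optional[str]]] = []
    for spectrum in _iter_mzml_spectra(path):
        if spectrum["ms_level"] != ms_level_filter:
            continue
        if spectrum["rt"] is None:
            raise FormatError(
                f"spectrum {spectrum['id']}: missing scan start time cvParam"
            )
        if spectrum["mz"] is None or spectrum["intensity"] is None:
            raise FormatError(
                f"spectrum {spectrum['id']}: missing m/z or intensity array"
            )
        if len(spectrum["mz"]) != len(spectrum["intensity"]):
            raise FormatError(
                f"spectrum {spectrum['id']}: m/z and intensity array lengths differ"
            )
        raw.append(
            (
                spectrum["rt"],
                list(zip(map(float, spectrum["mz"]), map(float, spectrum["intensity"]))),
                spectrum["mode"],
            )
        )
    if not raw:
        raise EmptyRunError(
            f"{path}: no spectra at MS level {ms_level_filter}"
        )
    raw.sort(key=lambda t: t[0])
    modes = {m for _, _, m in raw}
    run_mode = modes.pop() if len(modes) == 1 and None not in modes else None

    scans: list[Scan] = []
    pid = 0
    for si, (rt, pairs, _) in enumerate(raw):
        pts = []
        for mz, inten in sorted(pairs):
            if inten == 0:
                continue
            pts.append(Point(pid, mz, rt, inten, si))
            pid += 1
        scans.append(Scan(si, rt, tuple(pts)))
    return Run(
        scans=tuple(scans),
        mode=run_mode if run_mode else "unknown",
        source=str(path),
    )


def write_points_csv(run: Run, path: PathLike) -> None:
    """Write a run as a flat point table (point_id, mz, rt, intensity)."""
    rows = [
        {"point_id": p.point_id, "mz": p.mz, "rt": p.rt, "intensity": p.intensity}
        for p in run.iter_points()
    ]
    pd.DataFrame(rows, columns=["point_id", "mz", "rt", "intensity"]).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_points_csv(path: PathLike, mode: str = "unknown") -> Run:
    """Read a flat point table (mz, rt, intensity) into a Run.

    Points are regrouped into scans by exact RT; ids are reassigned in
    canonical (RT, m/z) order so the result is independent of row order.
    """
    df = pd.read_csv(path)
    missing = {"mz", "rt", "intensity"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    from xiclink.model import run_from_points

    triples = list(zip(df["mz"], df["rt"], df["intensity"]))
    return run_from_points(triples, mode=mode, source=str(path))


def write_xic_table(
    xics: Sequence[Xic], path: PathLike, format: str = "points_csv"
) -> None:
    """Write a collection of XICs in one of the documented formats."""
    path = Path(path)
    if format == "points_csv":
        rows = []
        for x in xics:
            for p in x.points:
                rows.append(
                    {
                        "xic_id": x.xic_id,
                        "point_id": p.point_id,
                        "mz": p.mz,
                        "rt": p.rt,
                        "intensity": p.intensity,
                        "is_root": int(p.point_id == x.root.point_id),
                    }
                )
        pd.DataFrame(rows, columns=POINTS_CSV_COLUMNS).to_csv(
            path, index=False, float_format="%.10g"
        )
    elif format == "summary_csv":
        rows = [
            {
                "xic_id": x.xic_id,
                "n_points": x.n_points,
                "mz_min": x.mz_min,
                "mz_max": x.mz_max,
                "rt_min": x.rt_min,
                "rt_max": x.rt_max,
                "apex_mz": x.apex.mz,
                "apex_rt": x.apex.rt,
                "total_intensity": x.total_intensity,
            }
            for x in xics
        ]
        pd.DataFrame(rows, columns=SUMMARY_CSV_COLUMNS).to_csv(
            path, index=False, float_format="%.10g"
        )
    elif format == "json":
        payload = {
            "xics": [
                {
                    "xic_id": x.xic_id,
                    "root_point_id": x.root.point_id,
                    "n_points": x.n_points,
                    "total_intensity": x.total_intensity,
                    "points": [
                        {
                            "point_id": p.point_id,
                            "mz": p.mz,
                            "rt": p.rt,
                            "intensity": p.intensity,
                        }
                        for p in x.points
                    ],
                }
                for x in xics
            ]
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_annotations(path: PathLike) -> AnnotatedXicSet:
    """Read an annotation / XIC-membership table into an AnnotatedXicSet.

    Accepts any CSV with an ``xic_id`` column plus either full coordinates
    (``mz, rt, intensity``) or ``point_id`` (or both, as written by
    ``write_xic_table(..., format="points_csv")``).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "xic_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'xic_id'")
    has_pid = "point_id" in df.columns
    has_coords = {"mz", "rt", "intensity"}.issubset(df.columns)
    if not has_pid and not has_coords:
        raise SchemaError(
            f"{path}: need either a point_id column or mz/rt/intensity columns"
        )
    xics: dict[str, list[AnnotationPoint]] = {}
    for row in df.itertuples(index=False):
        ap = AnnotationPoint(
            point_id=int(row.point_id) if has_pid else None,
            mz=float(row.mz) if has_coords else None,
            rt=float(row.rt) if has_coords else None,
            intensity=float(row.intensity) if has_coords else None,
        )
        xics.setdefault(str(row.xic_id), []).append(ap)
    return AnnotatedXicSet(
        xics={k: tuple(v) for k, v in xics.items()}, label=path.name
    )
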