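"""Reading and writing MS1 centroid data and sample manifests.

Two on-disk forms are supported for centroid clouds: a three-column CSV
dialect (``rt_s,mz,intensity``) and centroid-mode mzML.  mzML is handled by
a minimal standards-conformant serializer/parser (one spectrum per distinct
retention time, 64-bit uncompressed binary arrays); the test suite verifies
the writer's output against an independent mzML implementation.

The sample manifest ("assembly") maps sample_id to stage label, batch,
train/test split and the path of the sample's centroid file.
"""

from __future__ import annotations

import base64
import struct
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .containers import MSMap, SCAN_RANGE

__all__ = [
    "write_centroid_csv",
    "read_centroid_csv",
    "write_mzml",
    "read_mzml",
    "write_manifest",
    "read_manifest",
    "validate_manifest",
    "MANIFEST_COLUMNS",
]

CSV_HEADER = "rt_s,mz,intensity"
MANIFEST_COLUMNS = ["sample_id", "stage", "batch_id", "split", "path"]


class CentroidParseError(ValueError):
    """Raised for malformed centroid CSV input; carries the line number."""


def write_centroid_csv(msmap: MSMap, path) -> None:
    """Write a centroid cloud as CSV (rt to 2 decimals, mz to 6)."""
    with open(path, "w") as fh:
        fh.write(CSV_HEADER + "\n")
        for rt, mz, inten in zip(msmap.rt, msmap.mz, msmap.intensity):
            fh.write(f"{rt:.2f},{mz:.6f},{inten:.4f}\n")


def read_centroid_csv(path, sample_id: str | None = None) -> MSMap:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header != CSV_HEADER:
            raise CentroidParseError(
                f"{path}:1: expected header {CSV_HEADER!r}, got {header!r}"
            )
        rt, mz, inten = [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise CentroidParseError(f"{path}:{lineno}: expected 3 fields")
            try:
                r, m, i = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise CentroidParseError(f"{path}:{lineno}: {exc}") from exc
            if i < 0:
                raise CentroidParseError(f"{path}:{lineno}: negative intensity")
            if r < 0:
                raise CentroidParseError(f"{path}:{lineno}: negative retention time")
            rt.append(r)
            mz.append(m)
            inten.append(i)
    return MSMap(sample_id or path.stem, np.array(rt), np.array(mz), np.array(inten))


# --- mzML -------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr)).decode()


def _cv(parent, accession, name, value="", **extra):
    el = etree.SubElement(parent, "cvParam")
    el.set("cvRef", "MS")
    el.set("accession", accession)
    el.set("name", name)
    el.set("value", str(value))
    for k, v in extra.items():
        el.set(k, str(v))
    return el


def write_mzml(msmap: MSMap, path) -> None:
    """Write a centroid cloud as centroid-mode MS1 mzML.

    Centroids sharing a retention time are grouped into one spectrum; each
    spectrum stores uncompressed little-endian 64-bit m/z and intensity
    arrays.
    """
    ordered = msmap.sorted_by_rt()
    root = etree.Element("mzML", nsmap={None: _MZML_NS})
    root.set("version", "1.1.0")
    cvlist = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(
        cvlist,
        "cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = etree.SubElement(root, "run", id=msmap.sample_id)
    unique_rt, starts = np.unique(ordered.rt, return_index=True)
    speclist = etree.SubElement(run, "spectrumList", count=str(len(unique_rt)))
    bounds = list(starts) + [len(ordered)]
    for i, rt in enumerate(unique_rt):
        lo, hi = bounds[i], bounds[i + 1]
        mz = ordered.mz[lo:hi]
        inten = ordered.intensity[lo:hi]
        spec = etree.SubElement(
            speclist,
            "spectrum",
            index=str(i),
            id=f"scan={i + 1}",
            defaultArrayLength=str(mz.size),
        )
        _cv(spec, "MS:1000511", "ms level", 1)
        _cv(spec, "MS:1000127", "centroid spectrum")
        scanlist = etree.SubElement(spec, "scanList", count="1")
        scan = etree.SubElement(scanlist, "scan")
        _cv(
            scan,
            "MS:1000016",
            "scan start time",
            rt,
            unitCvRef="UO",
            unitAccession="UO:0000010",
            unitName="second",
        )
        balist = etree.SubElement(spec, "binaryDataArrayList", count="2")
        for accession, name, arr in (
            ("MS:1000514", "m/z array", mz),
            ("MS:1000515", "intensity array", inten),
        ):
            enc = _b64(arr)
            ba = etree.SubElement(balist, "binaryDataArray", encodedLength=str(len(enc)))
            _cv(ba, "MS:1000523", "64-bit float")
            _cv(ba, "MS:1000576", "no compression")
            _cv(ba, accession, name)
            etree.SubElement(ba, "binary").text = enc
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


def _decode_array(ba_el) -> tuple[str, np.ndarray]:
    """(array name, values) from one <binaryDataArray>; only the uncompressed
    64-bit layout our writer emits is supported."""
    name = None
    for cv in ba_el.findall(f"{{{_MZML_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc in ("MS:1000514", "MS:1000515"):
            name = cv.get("name")
        elif acc == "MS:1000521":
            raise ValueError("32-bit binary arrays are not supported")
        elif acc in ("MS:1000574", "MS:1000584"):
            raise ValueError("compressed binary arrays are not supported")
    binary = ba_el.find(f"{{{_MZML_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    return name, np.frombuffer(raw, dtype="<f8")


def read_mzml(path, sample_id: str | None = None) -> MSMap:
    """Read centroid MS1 spectra from mzML (uncompressed 64-bit arrays).

    Retention times are converted to seconds regardless of the file's unit.
    """
    tree = etree.parse(str(path))
    ns = {"m": _MZML_NS}
    rt, mz, inten = [], [], []
    for spec in tree.iterfind(".//m:spectrum", ns):
        level = spec.find("m:cvParam[@accession='MS:1000511']", ns)
        if level is not None and level.get("value") not in ("1", ""):
            continue
        start = spec.find(".//m:scan/m:cvParam[@accession='MS:1000016']", ns)
        if start is None:
            raise ValueError(f"spectrum {spec.get('id')!r} lacks a scan start time")
        t = float(start.get("value"))
        if start.get("unitName") == "minute":
            t *= 60.0
        arrays = dict(
            _decode_array(ba)
            for ba in spec.iterfind(".//m:binaryDataArray", ns)
        )
        m = arrays.get("m/z array", np.empty(0))
        i = arrays.get("intensity array", np.empty(0))
        rt.append(np.full(m.size, t))
        mz.append(m)
        inten.append(i)
    if rt:
        rt, mz, inten = np.concatenate(rt), np.concatenate(mz), np.concatenate(inten)
    else:
        rt = mz = inten = np.empty(0)
    return MSMap(sample_id or Path(path).stem, rt, mz, inten)


# --- manifest ---------------------------------------------------------------


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def validate_manifest(manifest: pd.DataFrame, check_files: bool = False) -> None:
    """Enforce the assembly invariants: unique ids, valid stages, both
    comparison groups represented in every batch."""
    if manifest["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in manifest")
    bad = set(manifest["stage"]) - {"early", "late"}
    if bad:
        raise ValueError(f"unknown stage labels: {sorted(bad)}")
    for batch, grp in manifest.groupby("batch_id"):
        if set(grp["stage"]) != {"early", "late"}:
            raise ValueError(f"batch {batch!r} lacks one of the comparison groups")
    if check_files:
        for p in manifest["path"]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
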