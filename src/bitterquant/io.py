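"""Reading and writing centroid runs (mzML, CSV dialect) and YAML configs.

The CSV dialect is four columns — ``scan, rt_min, mz, intensity`` — one row
per centroid, scans grouped and ordered by retention time.

mzML support is centroid-only and self-contained: writing emits a minimal
standards-conformant document (64-bit float binary arrays, base64, no
compression) that independent mzML readers parse, and reading handles
64/32-bit float arrays with or without zlib compression via the PSI-MS
controlled vocabulary.  Both writers are bit-stable for a fixed input, so
seeded synthetic runs round-trip exactly.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .synthgen import CentroidRun, Scan

__all__ = [
    "run_to_dataframe",
    "write_csv",
    "read_csv",
    "write_mzml",
    "read_mzml",
    "read_centroid_run",
    "load_config",
]


def run_to_dataframe(run: CentroidRun) -> pd.DataFrame:
    rows = []
    for i, scan in enumerate(run.scans):
        for mz, inten in zip(scan.mz, scan.intensity):
            rows.append((i, scan.rt_min, mz, inten))
    return pd.DataFrame(rows, columns=["scan", "rt_min", "mz", "intensity"])


def write_csv(run: CentroidRun, path: str | Path) -> None:
    run_to_dataframe(run).to_csv(path, index=False, float_format="%.10g")


def read_csv(path: str | Path) -> CentroidRun:
    df = pd.read_csv(path)
    required = {"scan", "rt_min", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    scans = []
    for _, grp in df.groupby("scan", sort=True):
        rt = float(grp["rt_min"].iloc[0])
        order = np.argsort(grp["mz"].to_numpy(), kind="stable")
        scans.append(
            Scan(rt, grp["mz"].to_numpy(float)[order], grp["intensity"].to_numpy(float)[order])
        )
    scans.sort(key=lambda s: s.rt_min)
    return CentroidRun(scans)


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="synthetic_run">
    <spectrumList count="{count}" defaultDataProcessingRef="dp">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={index}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.8f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{in_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{in_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(run: CentroidRun, path: str | Path) -> None:
    """Write a centroid run as minimal mzML (uncompressed 64-bit arrays)."""
    parts = [_MZML_HEADER.format(count=len(run))]
    for i, scan in enumerate(run.scans):
        mz_b64 = _b64(np.asarray(scan.mz, dtype=float))
        in_b64 = _b64(np.asarray(scan.intensity, dtype=float))
        parts.append(
            _MZML_SPECTRUM.format(
                index=i,
                n=len(scan.mz),
                rt=scan.rt_min,
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                in_len=len(in_b64),
                in_b64=in_b64,
            )
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_array(bda: ET.Element) -> np.ndarray:
    accessions = {cv.get("accession") for cv in bda.findall(f"{_NS}cvParam")}
    raw = base64.b64decode((bda.findtext(f"{_NS}binary") or "").encode("ascii"))
    if "MS:1000574" in accessions:  # zlib compression
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> CentroidRun:
    """Read centroid spectra from mzML (64/32-bit float arrays, zlib or none)."""
    tree = ET.parse(path)
    scans = []
    for spectrum in tree.getroot().iter(f"{_NS}spectrum"):
        rt = 0.0
        for scan in spectrum.iter(f"{_NS}scan"):
            for cv in scan.findall(f"{_NS}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if "second" in (cv.get("unitName") or "minute"):
                        rt /= 60.0
        mz = inten = None
        for bda in spectrum.iter(f"{_NS}binaryDataArray"):
            accessions = {cv.get("accession") for cv in bda.findall(f"{_NS}cvParam")}
            if "MS:1000514" in accessions:
                mz = _decode_array(bda)
            elif "MS:1000515" in accessions:
                inten = _decode_array(bda)
        if mz is None or inten is None:
            raise ValueError("spectrum without m/z or intensity array")
        scans.append(Scan(rt, mz, inten))
    scans.sort(key=lambda s: s.rt_min)
    return CentroidRun(scans)


def read_centroid_run(path: str | Path) -> CentroidRun:
    """Dispatch on extension: ``.mzML`` or the four-column ``.csv`` dialect."""
    p = Path(path)
    if p.suffix.lower() == ".mzml":
        return read_mzml(p)
    if p.suffix.lower() == ".csv":
        return read_csv(p)
    raise ValueError(f"unsupported run format: {p.suffix!r}")


def load_config(path: str | Path) -> dict[str, Any]:
    """Load the analysis config (analyte, standard, acquisition, prep) from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
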