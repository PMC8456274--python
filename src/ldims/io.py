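"""File I/O: spectra (two-column CSV and MS-level-1 profile mzML), feature
matrices, and run manifests.

mzML support is a minimal standards-conforming serializer/parser pair
(MS-level-1 profile spectra, 32/64-bit little-endian binary arrays, no or
zlib compression, standard CV accessions) built on lxml.
"""

from __future__ import annotations

import base64
import hashlib
import json
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .preprocessing import FeatureMatrix
from .simulate import Spectrum

__all__ = ["read_spectrum", "write_spectrum", "read_feature_matrix",
           "write_feature_matrix", "write_manifest"]


class SpectrumParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CSV


def _write_csv(spectrum: Spectrum, path: Path) -> Path:
    df = pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity})
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def _read_csv(path: Path) -> Spectrum:
    df = pd.read_csv(path)
    if not {"mz", "intensity"} <= set(df.columns):
        raise SpectrumParseError(f"{path}: expected 'mz,intensity' header")
    mz = df["mz"].to_numpy(float)
    inten = df["intensity"].to_numpy(float)
    if np.any(np.diff(mz) <= 0):
        bad = int(np.flatnonzero(np.diff(mz) <= 0)[0]) + 2
        raise SpectrumParseError(f"{path}: m/z not strictly increasing at line {bad}")
    return Spectrum(mz, inten)


# ---------------------------------------------------------------------------
# mzML

_MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, "<f8").tobytes()).decode()


def _write_mzml(spectrum: Spectrum, path: Path) -> Path:
    mz_b64, int_b64 = _b64(spectrum.mz), _b64(spectrum.intensity)
    path.write_text(_MZML_TEMPLATE.format(
        run_id=escape(spectrum.sample_id or "run"), n=len(spectrum),
        mz_len=len(mz_b64), mz_b64=mz_b64,
        int_len=len(int_b64), int_b64=int_b64))
    return path


def _decode_binary_array(node, ns: str) -> tuple[str, np.ndarray]:
    """Decode one <binaryDataArray>: returns (kind, values)."""
    import zlib

    accs = {cv.get("accession") for cv in node.findall(f"{ns}cvParam")}
    dtype = "<f8" if "MS:1000523" in accs else "<f4"
    kind = ("mz" if "MS:1000514" in accs
            else "intensity" if "MS:1000515" in accs else "other")
    binary = node.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").encode())
    if "MS:1000574" in accs:  # zlib compression
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> Spectrum:
    from lxml import etree

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc
    root = tree.getroot()
    ns = f"{{{root.nsmap.get(None, '')}}}" if root.nsmap.get(None) else ""
    spectrum = root.find(f".//{ns}spectrum")
    if spectrum is None:
        raise SpectrumParseError(f"{path}: no spectra found")
    arrays = dict(
        _decode_binary_array(node, ns)
        for node in spectrum.findall(f".//{ns}binaryDataArray"))
    if "mz" not in arrays or "intensity" not in arrays:
        raise SpectrumParseError(f"{path}: missing m/z or intensity array")
    mz, inten = arrays["mz"], arrays["intensity"]
    if np.any(np.diff(mz) <= 0):
        raise SpectrumParseError(f"{path}: m/z not strictly increasing")
    return Spectrum(mz, inten)


# ---------------------------------------------------------------------------
# public surface


def write_spectrum(spectrum: Spectrum, path: str | Path,
                   format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or ("mzml" if path.suffix.lower() == ".mzml" else "csv")
    if fmt == "csv":
        return _write_csv(spectrum, path)
    if fmt == "mzml":
        return _write_mzml(spectrum, path)
    raise ValueError(f"unknown spectrum format {fmt!r}")


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("mzml" if path.suffix.lower() == ".mzml" else "csv")
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown spectrum format {fmt!r}")


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    fm.to_frame().to_csv(path, index=False, float_format="%.10g")
    return path


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    meta_cols = [c for c in ("sample_id", "replicate_id", "label") if c in df.columns]
    feat_cols = [c for c in df.columns if c not in meta_cols]
    return FeatureMatrix(
        values=df[feat_cols].to_numpy(float),
        feature_mz=np.array([float(c) for c in feat_cols]),
        sample_ids=list(df.get("sample_id", pd.Series(["?"] * len(df)))),
        replicate_ids=list(df.get("replicate_id", pd.Series(["r0"] * len(df)))),
        labels=df["label"].to_numpy() if "label" in df.columns else None)


def write_manifest(path: str | Path, stage: str, config: dict,
                   seed: int | None = None, extra: dict | None = None) -> Path:
    """Append a stage record (config hash, seed, parameters) to a run manifest."""
    path = Path(path)
    record = {"stage": stage, "seed": seed, "config": config,
              "config_sha256": hashlib.sha256(
                  json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()}
    if extra:
        record.update(extra)
    records = []
    if path.exists():
        records = json.loads(path.read_text())
    records.append(record)
    path.write_text(json.dumps(records, indent=2, default=str))
    return path
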