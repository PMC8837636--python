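"""Scan-level peak-list I/O and per-sample scan averaging.

The native interchange format is a pair of CSV files: a peaks file with
columns (sample_id, scan, mz, intensity) and a manifest with columns
(sample_id, species, adulteration_fraction, source_id).  Centroided mzML
is supported read-only when pyteomics is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SPECIES = ("cow", "goat", "camel", "oat", "soya", "mixture")


class FormatError(ValueError):
    """Malformed peak list or manifest."""


class EmptySampleError(RuntimeError):
    """A sample lost all its scans (e.g. to intensity filtering)."""

    def __init__(self, sample_id: str, message: str | None = None):
        self.sample_id = sample_id
        super().__init__(message or f"sample {sample_id!r} has no surviving scans")


@dataclass
class PeakList:
    """One scan's sparse centroided spectrum."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise FormatError("mz and intensity must be matching 1-D arrays")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise FormatError("m/z values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise FormatError("intensities must be non-negative")

    @property
    def tic(self) -> float:
        """Total ion count of the scan."""
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class SampleRecord:
    """A sample's identity, metadata and replicate scans.

    ``adulteration_fraction`` is the volume fraction of cow milk: 0 for a
    pure non-cow sample, 1 for pure cow, strictly between for mixtures
    (in which case ``species`` must be ``"mixture"``).
    """

    sample_id: str
    species: str
    adulteration_fraction: float
    source_id: str
    scans: list[PeakList] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise FormatError(f"unknown species {self.species!r}")
        a = self.adulteration_fraction
        if not 0.0 <= a <= 1.0:
            raise FormatError(f"adulteration_fraction {a} outside [0, 1]")
        if (0.0 < a < 1.0) != (self.species == "mixture"):
            raise FormatError(
                f"species {self.species!r} inconsistent with adulteration_fraction {a}"
            )
        if not self.scans:
            raise EmptySampleError(self.sample_id, f"sample {self.sample_id!r} has no scans")


def _manifest_path(peaks_path: Path) -> Path:
    return peaks_path.with_name(peaks_path.stem + "_manifest" + peaks_path.suffix)


def write_peaklists(records: list[SampleRecord], path: str | Path) -> None:
    """Write records to the CSV dialect (peaks file + companion manifest).

    Lossless at 4 decimal places in m/z; intensities stored as written.
    Zero-intensity peaks are preserved.
    """
    path = Path(path)
    rows = []
    manifest = []
    for rec in records:
        manifest.append((rec.sample_id, rec.species, rec.adulteration_fraction, rec.source_id))
        for iscan, scan in enumerate(rec.scans):
            # peaks closer than the 4 dp written precision merge into one
            mz_r = np.round(scan.mz, 4)
            uniq, inverse = np.unique(mz_r, return_inverse=True)
            inten = np.bincount(inverse, weights=scan.intensity) \
                if len(uniq) < len(mz_r) else scan.intensity
            for mz, ivalue in zip(uniq, inten):
                rows.append((rec.sample_id, iscan, f"{mz:.4f}", f"{ivalue:.6g}"))
    pd.DataFrame(rows, columns=["sample_id", "scan", "mz", "intensity"]).to_csv(path, index=False)
    pd.DataFrame(
        manifest, columns=["sample_id", "species", "adulteration_fraction", "source_id"]
    ).to_csv(_manifest_path(path), index=False)


def read_peaklists(path: str | Path, dialect: str = "csv") -> list[SampleRecord]:
    """Read sample records from CSV (peaks + manifest) or centroided mzML.

    Ordering is deterministic: samples in manifest order, scans by index.
    """
    path = Path(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv(path: Path) -> list[SampleRecord]:
    mpath = _manifest_path(path)
    if not mpath.exists():
        raise FormatError(f"manifest file {mpath} not found")
    manifest = pd.read_csv(mpath, dtype={"sample_id": str, "source_id": str})
    required = {"sample_id", "species", "adulteration_fraction", "source_id"}
    if missing := required - set(manifest.columns):
        raise FormatError(f"manifest missing fields {sorted(missing)}")
    peaks = pd.read_csv(path, dtype={"sample_id": str})
    for col in ("mz", "intensity"):
        if not np.issubdtype(peaks[col].dtype, np.number):
            bad = peaks[pd.to_numeric(peaks[col], errors="coerce").isna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise FormatError(f"non-numeric {col} in {path} near line {line}")
    records = []
    grouped = peaks.groupby("sample_id", sort=False)
    for _, mrow in manifest.iterrows():
        sid = mrow["sample_id"]
        try:
            g = grouped.get_group(sid)
        except KeyError:
            raise FormatError(f"manifest sample {sid!r} has no peaks in {path}") from None
        scans = []
        for iscan in sorted(g["scan"].unique()):
            sub = g[g["scan"] == iscan].sort_values("mz", kind="stable")
            mz = sub["mz"].to_numpy(float)
            if np.any(np.diff(mz) <= 0):
                raise FormatError(f"descending/duplicate m/z in sample {sid!r} scan {iscan}")
            scans.append(PeakList(mz=mz, intensity=sub["intensity"].to_numpy(float)))
        records.append(SampleRecord(
            sample_id=str(sid),
            species=str(mrow["species"]),
            adulteration_fraction=float(mrow["adulteration_fraction"]),
            source_id=str(mrow["source_id"]),
            scans=scans,
        ))
    return records


_MZML_ACCESSIONS = {
    "MS:1000511": "ms_level",
    "MS:1000127": "centroid",
    "MS:1000128": "profile",
    "MS:1000514": "mz_array",
    "MS:1000515": "intensity_array",
    "MS:1000523": "f64",
    "MS:1000521": "f32",
    "MS:1000574": "zlib",
    "MS:1000576": "no_compression",
}


def _decode_binary_array(bda) -> np.ndarray:
    import base64
    import zlib as _zlib

    flags = {_MZML_ACCESSIONS.get(cv.get("accession"))
             for cv in bda.iter("{*}cvParam")}
    binary = bda.find("{*}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if "zlib" in flags:
        raw = _zlib.decompress(raw)
    dtype = np.float32 if "f32" in flags else np.float64
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[SampleRecord]:
    """Minimal centroided-MS1 mzML reader (zlib or uncompressed 32/64-bit
    float arrays).  One file holds one sample; metadata comes from a
    companion manifest."""
    from lxml import etree

    mpath = _manifest_path(path)
    if not mpath.exists():
        raise FormatError(f"manifest file {mpath} not found")
    manifest = pd.read_csv(mpath, dtype={"sample_id": str, "source_id": str})
    if len(manifest) != 1:
        raise FormatError("mzML manifest must describe exactly one sample")
    mrow = manifest.iloc[0]
    scans = []
    tree = etree.parse(str(path))
    for spec in tree.iter("{*}spectrum"):
        params = {_MZML_ACCESSIONS.get(cv.get("accession")): cv.get("value")
                  for cv in spec.findall("{*}cvParam")}
        if int(params.get("ms_level") or 1) != 1:
            continue
        if "profile" in params and "centroid" not in params:
            raise FormatError("profile-mode mzML spectra are not supported")
        mz = inten = None
        for bda in spec.iter("{*}binaryDataArray"):
            flags = {_MZML_ACCESSIONS.get(cv.get("accession"))
                     for cv in bda.findall("{*}cvParam")}
            if "mz_array" in flags:
                mz = _decode_binary_array(bda)
            elif "intensity_array" in flags:
                inten = _decode_binary_array(bda)
        if mz is None or inten is None:
            raise FormatError(f"spectrum {spec.get('id')!r} lacks m/z or intensity array")
        order = np.argsort(mz, kind="stable")
        scans.append(PeakList(mz=mz[order], intensity=inten[order]))
    return [SampleRecord(
        sample_id=str(mrow["sample_id"]),
        species=str(mrow["species"]),
        adulteration_fraction=float(mrow["adulteration_fraction"]),
        source_id=str(mrow["source_id"]),
        scans=scans,
    )]


def average_scans(sample: SampleRecord, grid) -> np.ndarray:
    """Mean of the per-scan binned vectors (bin first, then average).

    Binning each scan before averaging makes the result insensitive to
    centroid jitter between replicate scans.
    """
    from .preprocess import bin_peaks

    if not sample.scans:
        raise EmptySampleError(sample.sample_id)
    binned = np.stack([bin_peaks(s, grid) for s in sample.scans])
    return binned.mean(axis=0)
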