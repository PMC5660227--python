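"""Reading and writing spectra and tabular pipeline artifacts.

The on-disk formats are mzXML (one file per sample, one or more scans), plain
two-column CSV spectra, a sample manifest CSV, and the samples x peak-cluster
intensity matrix CSV that downstream modules exchange.

All m/z values are kept as continuous Daltons; no binning happens at I/O time.
Sample-to-group assignment is done through the manifest only, never by parsing
file names.
"""

from __future__ import annotations

import base64
import io
import logging
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from pyteomics import mzxml as _pyteomics_mzxml

from .exceptions import (
    EmptyInputError,
    ParameterError,
    SpectrumParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Canonical manifest column order.
MANIFEST_COLUMNS = [
    "sample_id",
    "group",
    "stage",
    "cea",
    "fobt",
    "surv_months",
    "surv_event",
]

GROUPS = ("HC", "CRC")
STAGES = ("I", "II", "III", "IV")


# ---------------------------------------------------------------------------
# Core data model
# ---------------------------------------------------------------------------


@dataclass
class RawSpectrum:
    """One sample's profile-mode mass spectrum.

    Parameters
    ----------
    sample_id:
        Opaque identifier; joins against the manifest.
    mz:
        m/z grid in Daltons, strictly increasing.
    intensity:
        Arbitrary-unit intensities, finite and non-negative.
    group:
        Optional cohort label, ``"HC"``, ``"CRC"`` or ``None`` (unknown).
    provenance:
        Free-form metadata (instrument, file of origin, ...).
    """

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    group: str | None = None
    provenance: dict = field(default_factory=dict)

    #: subclasses set this to allow intermediate negative intensities
    _allow_negative_intensity = False

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise ValidationError(
                f"mz ({len(self.mz)}) and intensity ({len(self.intensity)}) "
                "lengths differ"
            )
        if len(self.mz) < 2:
            raise ValidationError("spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.mz)):
            raise ValidationError("non-finite m/z values")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("non-finite intensity values")
        if np.any(np.diff(self.mz) <= 0):
            raise ValidationError("m/z must be strictly increasing")
        if not self._allow_negative_intensity and np.any(self.intensity < 0):
            raise ValidationError("negative intensity values")
        if self.group is not None and self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")

    def __len__(self) -> int:
        return len(self.mz)


def _sorted_arrays(mz, intensity):
    """Sort (mz, intensity) pairs by m/z, keeping pairs together."""
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if np.any(np.diff(mz) <= 0):
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
    return mz, intensity


# ---------------------------------------------------------------------------
# mzXML
# ---------------------------------------------------------------------------


def read_mzxml(path: str | Path) -> list[RawSpectrum]:
    """Read every MS1 scan of an mzXML file as a :class:`RawSpectrum`.

    Peak arrays may be 32- or 64-bit, plain or zlib-compressed base64
    (CompassXport emits both). Scans with unsorted m/z are sorted, permuting
    intensities consistently. The sample id is the file stem for a
    single-scan file, ``<stem>#<scan num>`` otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with _pyteomics_mzxml.read(str(path), use_index=False) as reader:
            scans = list(reader)
    except Exception as exc:  # lxml syntax errors carry a position
        offset = _byte_offset_of(exc, path)
        raise SpectrumParseError(f"malformed mzXML in {path.name}: {exc}", offset=offset) from exc
    if not scans:
        raise EmptyInputError(f"{path.name}: mzXML contains no scans")
    out = []
    multi = len(scans) > 1
    for scan in scans:
        mz, intensity = _sorted_arrays(scan["m/z array"], scan["intensity array"])
        sid = f"{path.stem}#{scan['num']}" if multi else path.stem
        out.append(
            RawSpectrum(
                sample_id=sid,
                mz=mz,
                intensity=np.clip(intensity, 0, None),
                provenance={"source_file": str(path), "scan_num": str(scan["num"])},
            )
        )
    return out


def _byte_offset_of(exc: Exception, path: Path) -> int | None:
    """Best-effort byte offset of an XML parse failure (from lxml's line/col)."""
    pos = getattr(exc, "position", None)
    if not pos:
        return None
    line, col = pos
    try:
        raw = path.read_bytes().splitlines(keepends=True)
        return sum(len(l) for l in raw[: max(line - 1, 0)]) + col
    except OSError:
        return None


def write_mzxml(spectra: Iterable[RawSpectrum], path: str | Path, *, precision: int = 64,
                compress: bool = True) -> Path:
    """Write spectra as a minimal mzXML 3.2 file (one scan per spectrum)."""
    path = Path(path)
    spectra = list(spectra)
    if not spectra:
        raise EmptyInputError("no spectra to write")
    if precision not in (32, 64):
        raise ParameterError("precision must be 32 or 64")
    fmt = ">f4" if precision == 32 else ">f8"
    buf = io.StringIO()
    buf.write('<?xml version="1.0" encoding="ISO-8859-1"?>\n')
    buf.write(
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">\n'
    )
    buf.write(f' <msRun scanCount="{len(spectra)}">\n')
    for i, s in enumerate(spectra, start=1):
        interleaved = np.empty(2 * len(s), dtype=float)
        interleaved[0::2] = s.mz
        interleaved[1::2] = s.intensity
        raw = interleaved.astype(fmt).tobytes()
        attrs = f'precision="{precision}" byteOrder="network" contentType="m/z-int"'
        if compress:
            raw_c = zlib.compress(raw)
            attrs = f'compressionType="zlib" compressedLen="{len(raw_c)}" ' + attrs
            raw = raw_c
        b64 = base64.b64encode(raw).decode("ascii")
        buf.write(f'  <scan num="{i}" msLevel="1" peaksCount="{len(s)}">\n')
        buf.write(f"   <peaks {attrs}>{b64}</peaks>\n")
        buf.write("  </scan>\n")
    buf.write(" </msRun>\n</mzXML>\n")
    path.write_text(buf.getvalue())
    return path


# ---------------------------------------------------------------------------
# CSV spectra
# ---------------------------------------------------------------------------


def read_csv_spectrum(path: str | Path, sample_id: str | None = None) -> RawSpectrum:
    """Read a two-column (mz, intensity) CSV; a non-numeric header row is allowed."""
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path.name}: empty spectrum file") from None
    if df.shape[1] < 2:
        raise SpectrumParseError(f"{path.name}: expected two columns, got {df.shape[1]}")
    df = df.iloc[:, :2]
    start = 0
    try:
        [float(v) for v in df.iloc[0]]
    except (TypeError, ValueError):
        start = 1  # header row
    df = df.iloc[start:]
    if df.empty:
        raise EmptyInputError(f"{path.name}: no data rows")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) & df.notna().all(axis=1)
    bad |= df.isna().any(axis=1)
    if bad.any():
        row = int(bad.idxmax()) + 1  # 1-based file row
        raise SpectrumParseError(f"{path.name}: non-numeric cell at row {row}")
    mz = numeric.iloc[:, 0].to_numpy()
    if len(np.unique(mz)) != len(mz):
        dup = mz[pd.Index(mz).duplicated()][0]
        raise ValidationError(f"{path.name}: duplicate m/z value {dup}")
    mz, intensity = _sorted_arrays(mz, numeric.iloc[:, 1].to_numpy())
    return RawSpectrum(
        sample_id=sample_id or path.stem,
        mz=mz,
        intensity=intensity,
        provenance={"source_file": str(path)},
    )


def write_csv_spectrum(s: RawSpectrum, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"mz": s.mz, "intensity": s.intensity}).to_csv(
        path, index=False, float_format="%.10g"
    )
    return path


# ---------------------------------------------------------------------------
# Sample manifest
# ---------------------------------------------------------------------------


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    """Check manifest invariants; returns the (unmodified) frame."""
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValidationError("manifest requires sample_id and group columns")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r} in manifest")
    if len(df) and not df["group"].isin(GROUPS).all():
        bad = df.loc[~df["group"].isin(GROUPS), "group"].iloc[0]
        raise ValidationError(f"manifest group must be HC or CRC, got {bad!r}")
    if "stage" in df.columns:
        staged = df["stage"].notna() & (df["stage"].astype(str).str.len() > 0)
        if (staged & (df["group"] == "HC")).any():
            raise ValidationError("stage present for an HC sample")
        bad_stage = staged & ~df["stage"].isin(STAGES)
        if bad_stage.any():
            raise ValidationError(
                f"unknown stage {df.loc[bad_stage, 'stage'].iloc[0]!r}"
            )
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the manifest CSV, preserving row order."""
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "stage": str})
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return validate_manifest(df[MANIFEST_COLUMNS])


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = df.copy()
    for col in MANIFEST_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    validate_manifest(out)
    out[MANIFEST_COLUMNS].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Peak matrix CSV
# ---------------------------------------------------------------------------


def cluster_labels(cluster_mz: np.ndarray) -> list[str]:
    """Display labels: integer-rounded Da, one decimal on collision."""
    rounded = [str(int(round(m))) for m in cluster_mz]
    labels = list(rounded)
    seen: dict[str, list[int]] = {}
    for i, lab in enumerate(rounded):
        seen.setdefault(lab, []).append(i)
    for lab, idxs in seen.items():
        if len(idxs) > 1:
            logger.warning(
                "cluster label collision at %s Da; disambiguating with one decimal", lab
            )
            for i in idxs:
                labels[i] = f"{cluster_mz[i]:.1f}"
    return labels


def write_peak_matrix(matrix, path: str | Path) -> Path:
    """Write a :class:`~serumpeaks.peakcall.PeakMatrix` as CSV.

    Columns are ``sample_id``, ``group`` and one column per cluster labelled
    by its integer-rounded m/z in Da. A leading ``#`` comment line stores the
    full-precision cluster centroids so that a read-back reproduces the
    matrix exactly.
    """
    path = Path(path)
    if len(matrix.samples) == 0 or len(matrix.cluster_mz) == 0:
        raise EmptyInputError("refusing to write an empty peak matrix")
    labels = cluster_labels(matrix.cluster_mz)
    df = pd.DataFrame(matrix.values, columns=labels)
    df.insert(0, "sample_id", matrix.samples)
    df.insert(1, "group", matrix.groups)
    with open(path, "w") as fh:
        fh.write("# cluster_mz: " + ",".join(f"{m:.10g}" for m in matrix.cluster_mz) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    return path


def read_peak_matrix(path: str | Path):
    """Read a peak-matrix CSV written by :func:`write_peak_matrix`."""
    from .peakcall import PeakMatrix  # local import: peakcall depends on this module

    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        cluster_mz = None
        if first.startswith("# cluster_mz:"):
            cluster_mz = np.array(
                [float(v) for v in first.split(":", 1)[1].split(",")], dtype=float
            )
        else:
            fh.seek(0)
        df = pd.read_csv(fh, dtype={"sample_id": str, "group": str})
    value_cols = [c for c in df.columns if c not in ("sample_id", "group")]
    if cluster_mz is None:
        cluster_mz = np.array([float(c) for c in value_cols])
    return PeakMatrix(
        cluster_mz=cluster_mz,
        samples=df["sample_id"].tolist(),
        groups=df["group"].tolist(),
        values=df[value_cols].to_numpy(dtype=float),
    )
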