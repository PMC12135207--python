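"""Reading, preprocessing and harmonizing cytometry samples.

A sample is one acquisition (one subject at one timepoint): an ``n_cells x
n_markers`` matrix of transformed intensities plus identifying metadata.
Samples arrive either as FCS 3.0/3.1 files or as delimited text with a
header row of marker names.  A study is a collection of samples that has
been harmonized to a shared, consistently ordered marker panel.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file could not be parsed under its declared format."""


class ValidationError(ValueError):
    """Input data violate a structural requirement."""


_TP_DIGITS = re.compile(r"(\d+)")


def timepoint_key(label: str) -> tuple:
    """Sort key giving natural order for labels like T1 < T2 < ... < T10."""
    parts = _TP_DIGITS.split(str(label))
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class CytometrySample:
    """One sample's cell-by-marker expression matrix with metadata.

    The matrix holds transformed (unitless) intensities, cells in rows and
    markers in columns; marker names must be unique and match the column
    count.
    """

    sample_id: str
    subject_id: str
    timepoint: str
    matrix: np.ndarray
    marker_names: tuple[str, ...]

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2:
            raise ValidationError(f"{self.sample_id}: matrix must be 2-D")
        n, m = mat.shape
        if n < 1 or m < 1:
            raise ValidationError(
                f"{self.sample_id}: need >=1 cell and >=1 marker, got {n}x{m}"
            )
        names = tuple(str(x) for x in self.marker_names)
        if len(names) != m:
            raise ValidationError(
                f"{self.sample_id}: {len(names)} marker names for {m} columns"
            )
        if len(set(names)) != len(names):
            dup = sorted({x for x in names if names.count(x) > 1})
            raise ValidationError(f"{self.sample_id}: duplicate marker names {dup}")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "marker_names", names)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_markers(self) -> int:
        return self.matrix.shape[1]

    def select_markers(self, markers) -> "CytometrySample":
        """Restrict to the given markers, in the given order."""
        markers = tuple(markers)
        missing = [m for m in markers if m not in self.marker_names]
        if missing:
            raise ValidationError(
                f"{self.sample_id}: markers not present: {missing}"
            )
        idx = [self.marker_names.index(m) for m in markers]
        return replace(self, matrix=self.matrix[:, idx], marker_names=markers)


@dataclass
class StudyCollection:
    """A harmonized set of samples sharing one marker panel.

    Every sample exposes ``shared_markers`` in identical column order, and
    each (subject, timepoint) pair occurs at most once.
    """

    samples: list[CytometrySample]
    shared_markers: tuple[str, ...]
    dropped_markers: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self.shared_markers = tuple(self.shared_markers)
        seen = set()
        for s in self.samples:
            if s.marker_names != self.shared_markers:
                raise ValidationError(
                    f"{s.sample_id}: markers differ from shared panel"
                )
            key = (s.subject_id, s.timepoint)
            if key in seen:
                raise ValidationError(f"duplicate (subject, timepoint) {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.samples]

    def subjects(self) -> list[str]:
        out = []
        for s in self.samples:
            if s.subject_id not in out:
                out.append(s.subject_id)
        return out

    def samples_for_subject(self, subject_id: str) -> list[CytometrySample]:
        sub = [s for s in self.samples if s.subject_id == subject_id]
        return sorted(sub, key=lambda s: timepoint_key(s.timepoint))


def _check_finite(mat: np.ndarray, sample_id: str) -> None:
    bad = ~np.isfinite(mat)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"{sample_id}: {int(bad.sum())} non-finite values "
            f"(first at cell {int(r)}, column {int(c)})"
        )


def preprocess(sample: CytometrySample, cofactor: float = 5.0,
               enabled: bool = True) -> CytometrySample:
    """Arcsinh-transform intensities: ``x -> asinh(x / cofactor)``.

    The transform is the standard variance-stabilizing step for cytometry;
    with ``enabled=False`` the sample is returned unchanged (already
    transformed data).  Non-finite entries are rejected, not imputed.
    """
    if cofactor <= 0:
        raise ValidationError(f"cofactor must be positive, got {cofactor}")
    _check_finite(sample.matrix, sample.sample_id)
    if not enabled:
        return sample
    return replace(sample, matrix=np.arcsinh(sample.matrix / cofactor))


def read_sample(path, format: str | None = None, *, sample_id: str | None = None,
                subject_id: str = "", timepoint: str = "") -> CytometrySample:
    """Read one sample from an FCS or delimited-text file.

    ``format`` is ``"fcs"`` or ``"delimited"``; if omitted it is inferred
    from the file suffix.  Delimited files carry marker names in the first
    row; FCS channel names prefer the stain ($PnS) over the short name
    ($PnN).  Cell order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "delimited"
    if sample_id is None:
        sample_id = path.stem
    if format == "fcs":
        matrix, names = _read_fcs(path)
    elif format == "delimited":
        matrix, names = _read_delimited(path)
    else:
        raise ValidationError(f"unknown format {format!r}")
    return CytometrySample(sample_id=sample_id, subject_id=subject_id,
                           timepoint=timepoint, matrix=matrix,
                           marker_names=names)


def _read_delimited(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep, header=0,
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap parser errors uniformly
        raise FormatError(f"{path}: cannot parse delimited text: {exc}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows or columns")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values present")
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.columns)


def write_sample(sample: CytometrySample, path, sep: str = ",") -> None:
    """Write a sample's matrix as delimited text with a marker-name header."""
    df = pd.DataFrame(sample.matrix, columns=list(sample.marker_names))
    # default float repr is the shortest exact round-trip representation
    df.to_csv(path, sep=sep, index=False)


# --- FCS 3.0 / 3.1 reader (list mode, datatypes F/D/I) ------------------

def _read_fcs(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    raw = path.read_bytes()
    if len(raw) < 58:
        raise FormatError(f"{path}: file too short for an FCS header")
    version = raw[:6].decode("ascii", "replace")
    if version not in {"FCS3.0", "FCS3.1"}:
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        try:
            return int(raw[lo:hi].decode("ascii").strip() or 0)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed header offsets") from exc

    text_beg, text_end = _offset(10, 18), _offset(18, 26)
    data_beg, data_end = _offset(26, 34), _offset(34, 42)
    if text_end <= text_beg:
        raise FormatError(f"{path}: invalid TEXT segment offsets")

    delim = raw[text_beg:text_beg + 1].decode("latin-1")
    body = raw[text_beg + 1:text_end + 1].decode("latin-1")
    parts = body.split(delim)
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        parts = parts[:-1]
    text = {parts[i].strip().upper(): parts[i + 1]
            for i in range(0, len(parts), 2)}

    def _kw(name: str, required: bool = True) -> str:
        val = text.get(name.upper())
        if val is None and required:
            raise FormatError(f"{path}: missing required keyword {name}")
        return val

    mode = (_kw("$MODE") or "L").strip().upper()
    if mode != "L":
        raise FormatError(f"{path}: only list mode supported, got $MODE={mode}")
    n_par = int(_kw("$PAR"))
    n_tot = int(_kw("$TOT"))
    dtype_code = _kw("$DATATYPE").strip().upper()
    byteord = _kw("$BYTEORD").strip()
    endian = "<" if byteord.startswith("1") else ">"

    bits = [int(_kw(f"$P{i}B")) for i in range(1, n_par + 1)]
    names = []
    for i in range(1, n_par + 1):
        stain = text.get(f"$P{i}S")
        short = text.get(f"$P{i}N")
        names.append((stain or short or f"P{i}").strip())
    if len(set(names)) != len(names):
        raise ValidationError(f"{path}: duplicate marker names in FCS channels")

    if data_beg == 0 or data_end == 0:
        data_beg = int(_kw("$BEGINDATA"))
        data_end = int(_kw("$ENDDATA"))
    payload = raw[data_beg:data_end + 1]

    if dtype_code == "F":
        if any(b != 32 for b in bits):
            raise FormatError(f"{path}: $DATATYPE=F requires 32-bit channels")
        arr = np.frombuffer(payload[: 4 * n_par * n_tot], dtype=endian + "f4")
    elif dtype_code == "D":
        if any(b != 64 for b in bits):
            raise FormatError(f"{path}: $DATATYPE=D requires 64-bit channels")
        arr = np.frombuffer(payload[: 8 * n_par * n_tot], dtype=endian + "f8")
    elif dtype_code == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32, 64):
            raise FormatError(
                f"{path}: integer data requires uniform 8/16/32/64-bit widths"
            )
        nbytes = bits[0] // 8
        arr = np.frombuffer(payload[: nbytes * n_par * n_tot],
                            dtype=f"{endian}u{nbytes}")
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE={dtype_code}")

    if arr.size < n_par * n_tot:
        raise FormatError(
            f"{path}: DATA segment holds {arr.size} values, "
            f"expected {n_par * n_tot}"
        )
    matrix = arr[: n_par * n_tot].astype(float).reshape(n_tot, n_par)
    return matrix, tuple(names)


# --- study-level helpers -------------------------------------------------

def harmonize(samples: list[CytometrySample]) -> StudyCollection:
    """Subset every sample to the sorted intersection of marker panels.

    The sorted intersection gives a deterministic shared column order
    independent of per-file channel order; dropped markers are recorded
    per sample on the returned collection.
    """
    if not samples:
        raise ValidationError("no samples to harmonize")
    shared = set(samples[0].marker_names)
    for s in samples[1:]:
        shared &= set(s.marker_names)
    if not shared:
        panels = {s.sample_id: s.marker_names for s in samples}
        raise ValidationError(f"no markers common to all samples: {panels}")
    shared_sorted = tuple(sorted(shared))
    dropped = {}
    out = []
    for s in samples:
        lost = tuple(m for m in s.marker_names if m not in shared)
        if lost:
            dropped[s.sample_id] = lost
        out.append(s.select_markers(shared_sorted))
    return StudyCollection(samples=out, shared_markers=shared_sorted,
                           dropped_markers=dropped)


def read_manifest(path, *, arcsinh_fcs: bool = True,
                  arcsinh_delimited: bool = False,
                  cofactor: float = 5.0) -> StudyCollection:
    """Load a study from a manifest of (sample_id, subject_id, timepoint, path).

    FCS inputs get the arcsinh transform by default (raw intensities);
    delimited inputs are assumed pre-transformed.  Both defaults are
    overridable.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "subject_id", "timepoint", "path"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: manifest must have columns {sorted(required)}"
        )
    samples = []
    for row in df.itertuples(index=False):
        fpath = Path(row.path)
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        fmt = "fcs" if fpath.suffix.lower() == ".fcs" else "delimited"
        s = read_sample(fpath, fmt, sample_id=str(row.sample_id),
                        subject_id=str(row.subject_id),
                        timepoint=str(row.timepoint))
        enabled = arcsinh_fcs if fmt == "fcs" else arcsinh_delimited
        samples.append(preprocess(s, cofactor=cofactor, enabled=enabled))
    return harmonize(samples)


def write_study(collection: StudyCollection, outdir) -> Path:
    """Write per-sample CSVs plus a manifest.tsv; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in collection.samples:
        fname = f"{s.sample_id}.csv"
        write_sample(s, outdir / fname)
        rows.append({"sample_id": s.sample_id, "subject_id": s.subject_id,
                     "timepoint": s.timepoint, "path": fname})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
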