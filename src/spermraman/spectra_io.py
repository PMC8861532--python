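"""Spectrum/label data model and plain-text readers and writers.

A single-cell Raman measurement is represented as a :class:`RamanSpectrum`
(one scan, or an already-averaged trace), a :class:`ScanSet` (the repeated
scans of one cell on a shared wavenumber grid), a :class:`LabelTable`
(cell_id -> chromosome call from an orthogonal assay such as FISH), and a
:class:`CellRecord` (the averaged, preprocessed spectrum of one cell plus
its label).

All file formats are plain UTF-8 CSV with "." decimal separator; vendor
binary formats are out of scope.  Two layouts are supported:

``two_column``
    header-optional ``wavenumber,intensity`` rows, one file per scan.
``long_table``
    ``cell_id,scan,wavenumber,intensity`` rows, any number of cells and
    scans in one file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RamanSpectrum",
    "ScanSet",
    "LabelTable",
    "CellRecord",
    "SpectrumFormatError",
    "VALID_LABELS",
    "FEATURE_COLUMNS",
    "read_spectrum",
    "write_long_table",
    "read_feature_table",
    "write_feature_table",
    "merge_labels",
]

#: labels a cell may carry; ``unknown`` marks cells excluded from group stats
VALID_LABELS = ("X", "Y", "unknown")

#: column order of the on-disk feature table
FEATURE_COLUMNS = ("cell_id", "label", "I785", "area_714_1162")


class SpectrumFormatError(ValueError):
    """A spectrum file violates the format contract (grid, values, labels)."""


@dataclass(frozen=True)
class RamanSpectrum:
    """One wavenumber-indexed intensity trace for one scan of one cell.

    Parameters
    ----------
    wavenumbers : ndarray
        Raman shift in cm^-1, strictly increasing.
    intensities : ndarray
        Detector counts (arbitrary units), same length as `wavenumbers`.
    cell_id : str
        Opaque identifier of the cell the scan belongs to.
    scan_index : int or None
        0-based scan number; ``None`` means the trace is already averaged.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    cell_id: str = ""
    scan_index: int | None = None

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)
        if wn.ndim != 1 or it.ndim != 1:
            raise SpectrumFormatError("wavenumbers and intensities must be 1-D")
        if wn.size != it.size:
            raise SpectrumFormatError(
                f"length mismatch: {wn.size} wavenumbers vs {it.size} intensities"
            )
        if wn.size == 0:
            raise SpectrumFormatError("empty spectrum")
        if not (np.isfinite(wn).all() and np.isfinite(it).all()):
            raise SpectrumFormatError("non-finite value in spectrum")
        if np.any(np.diff(wn) <= 0):
            bad = wn[1:][np.diff(wn) <= 0][0]
            raise SpectrumFormatError(
                f"wavenumber grid not strictly increasing near {bad:g} cm^-1"
            )
        if self.scan_index is not None and self.scan_index < 0:
            raise SpectrumFormatError("scan_index must be >= 0 or None")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        """Return a copy with new intensities on the same grid."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass(frozen=True)
class ScanSet:
    """All scans of one cell, sharing one wavenumber grid exactly.

    Grids must match bit-for-bit across scans; resampling onto a common
    grid is an explicit preprocessing step, never implicit.
    """

    cell_id: str
    scans: tuple[RamanSpectrum, ...]

    def __post_init__(self) -> None:
        scans = tuple(self.scans)
        object.__setattr__(self, "scans", scans)
        if len(scans) < 1:
            raise SpectrumFormatError(f"cell {self.cell_id!r}: a ScanSet needs >= 1 scan")
        grid = scans[0].wavenumbers
        for s in scans[1:]:
            if not np.array_equal(s.wavenumbers, grid):
                raise SpectrumFormatError(
                    f"cell {self.cell_id!r}: scans do not share one wavenumber grid"
                )

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.scans[0].wavenumbers

    @property
    def n_scans(self) -> int:
        return len(self.scans)


@dataclass(frozen=True)
class LabelTable:
    """Mapping from cell_id to chromosome label (``X``, ``Y`` or ``unknown``)."""

    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = dict(self.labels)
        for cid, lab in labels.items():
            if lab not in VALID_LABELS:
                raise SpectrumFormatError(
                    f"cell {cid!r}: label {lab!r} not in {VALID_LABELS}"
                )
        object.__setattr__(self, "labels", labels)

    def get(self, cell_id: str) -> str:
        return self.labels.get(cell_id, "unknown")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelTable":
        """Read a two-column ``cell_id,label`` CSV (header required)."""
        df = pd.read_csv(path, dtype=str)
        if list(df.columns[:2]) != ["cell_id", "label"]:
            raise SpectrumFormatError(
                f"{path}: expected header 'cell_id,label', got {list(df.columns)}"
            )
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise SpectrumFormatError(f"{path}: duplicate cell_id {dup!r}")
        return cls(dict(zip(df["cell_id"], df["label"])))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"cell_id": list(self.labels), "label": list(self.labels.values())}
        )
        _write_lf(df, path)


@dataclass(frozen=True)
class CellRecord:
    """A cell's averaged, preprocessed spectrum plus its chromosome label."""

    cell_id: str
    spectrum: RamanSpectrum
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise SpectrumFormatError(
                f"cell {self.cell_id!r}: label {self.label!r} not in {VALID_LABELS}"
            )

    @property
    def in_group_stats(self) -> bool:
        """Whether the cell enters X-vs-Y group statistics."""
        return self.label in ("X", "Y")


# ---------------------------------------------------------------------------
# readers / writers


def _write_lf(df: pd.DataFrame, path: str | Path) -> None:
    # LF endings regardless of platform
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")


def _check_numeric(df: pd.DataFrame, cols: Sequence[str], path: str | Path,
                   header_rows: int) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any() or coerced.isna().any():
            idx = int(np.flatnonzero(coerced.isna())[0])
            raise SpectrumFormatError(
                f"{path}: non-numeric value {out[col].iloc[idx]!r} in column "
                f"{col!r} at line {idx + 1 + header_rows}"
            )
        out[col] = coerced.astype(float)
    return out


def _grid_from_rows(wn: np.ndarray, it: np.ndarray, path: str | Path,
                    cell_id: str = "", scan_index: int | None = None) -> RamanSpectrum:
    order = np.argsort(wn, kind="stable")
    wn, it = wn[order], it[order]
    dup = np.flatnonzero(np.diff(wn) == 0)
    if dup.size:
        raise SpectrumFormatError(
            f"{path}: duplicated wavenumber {wn[dup[0]]:g} cm^-1"
            + (f" in cell {cell_id!r}" if cell_id else "")
        )
    return RamanSpectrum(wn, it, cell_id=cell_id, scan_index=scan_index)


def read_spectrum(path: str | Path, dialect: str = "two_column",
                  cell_id: str | None = None):
    """Read spectra from a CSV file.

    Parameters
    ----------
    path : path
        CSV file to read.
    dialect : {"two_column", "long_table"}
        ``two_column`` returns a single :class:`RamanSpectrum`;
        ``long_table`` returns a list of :class:`ScanSet`, one per cell,
        cells in order of first appearance, scans ordered by scan index.
    cell_id : str, optional
        Cell id to attach to a two-column spectrum (defaults to the file
        stem).

    Raises
    ------
    SpectrumFormatError
        On non-numeric cells (naming the line), duplicated wavenumbers
        within one scan (naming the wavenumber), or grid violations.
    """
    path = Path(path)
    if dialect == "two_column":
        text = path.read_text(encoding="utf-8")
        first = text.split("\n", 1)[0]
        header = 0 if _looks_like_header(first) else None
        df = pd.read_csv(io.StringIO(text), header=header, dtype=str)
        if df.shape[1] < 2:
            raise SpectrumFormatError(f"{path}: expected two columns")
        df.columns = ["wavenumber", "intensity"] + list(df.columns[2:])
        df = _check_numeric(df, ["wavenumber", "intensity"], path,
                            header_rows=1 if header == 0 else 0)
        return _grid_from_rows(
            df["wavenumber"].to_numpy(), df["intensity"].to_numpy(), path,
            cell_id=cell_id if cell_id is not None else path.stem,
            scan_index=None,
        )
    if dialect == "long_table":
        df = pd.read_csv(path, dtype=str)
        required = ["cell_id", "scan", "wavenumber", "intensity"]
        if list(df.columns[:4]) != required:
            raise SpectrumFormatError(
                f"{path}: expected header {','.join(required)}, got {list(df.columns)}"
            )
        df = _check_numeric(df, ["scan", "wavenumber", "intensity"], path, header_rows=1)
        sets: list[ScanSet] = []
        for cid in df["cell_id"].drop_duplicates():
            sub = df[df["cell_id"] == cid]
            scans = []
            for scan_idx in sorted(sub["scan"].unique()):
                rows = sub[sub["scan"] == scan_idx]
                scans.append(_grid_from_rows(
                    rows["wavenumber"].to_numpy(), rows["intensity"].to_numpy(),
                    path, cell_id=str(cid), scan_index=int(scan_idx),
                ))
            sets.append(ScanSet(cell_id=str(cid), scans=tuple(scans)))
        return sets
    raise ValueError(f"unknown dialect {dialect!r}")


def _looks_like_header(line: str) -> bool:
    first_field = line.split(",")[0].strip()
    try:
        float(first_field)
        return False
    except ValueError:
        return True


def write_long_table(scan_sets: Iterable[ScanSet], path: str | Path) -> None:
    """Write scan sets as a long-format ``cell_id,scan,wavenumber,intensity`` CSV."""
    frames = []
    for ss in scan_sets:
        for s in ss.scans:
            frames.append(pd.DataFrame({
                "cell_id": ss.cell_id,
                "scan": 0 if s.scan_index is None else s.scan_index,
                "wavenumber": s.wavenumbers,
                "intensity": s.intensities,
            }))
    if not frames:
        raise SpectrumFormatError("no scan sets to write")
    _write_lf(pd.concat(frames, ignore_index=True), path)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cell feature table as CSV.

    The header is ``cell_id,label,I785,area_714_1162``; float values
    round-trip through the file to full precision.
    """
    if len(table) == 0:
        raise SpectrumFormatError("refusing to write an empty feature table")
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise SpectrumFormatError(f"feature table missing columns {missing}")
    _write_lf(table.loc[:, list(FEATURE_COLUMNS)], path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, dtype={"cell_id": str, "label": str})
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumFormatError(f"{path}: feature table missing columns {missing}")
    bad = ~df["label"].isin(VALID_LABELS)
    if bad.any():
        raise SpectrumFormatError(
            f"{path}: invalid label {df.loc[bad, 'label'].iloc[0]!r}"
        )
    return df


def merge_labels(cells: Sequence[CellRecord], labels: LabelTable) -> list[CellRecord]:
    """Attach chromosome labels to cell records.

    Cells with no entry in `labels` are kept and labeled ``unknown`` (they
    are retained in the cohort but flagged out of group statistics), which
    mirrors the heavy cell loss between spectral acquisition and the
    orthogonal labeling assay.
    """
    seen: set[str] = set()
    out = []
    for cell in cells:
        if cell.cell_id in seen:
            raise SpectrumFormatError(f"duplicate cell_id {cell.cell_id!r} in cells")
        seen.add(cell.cell_id)
        out.append(replace(cell, label=labels.get(cell.cell_id)))
    return out
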