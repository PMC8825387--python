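"""Reading and writing the text formats the pipeline touches.

Two inputs come out of an MS-DIAL alignment export: an MGF file with one
entry per aligned MS1 feature, and a tab-separated peak-area table with
per-sample areas (leaf, root and blank columns). Both the generic Mascot
MGF dialect (``PEPMASS``) and the MS-DIAL export dialect (``PRECURSORMZ``)
are accepted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SpectrumRecord", "AlignmentTable", "read_mgf", "write_mgf", "read_alignment"]


class MGFError(ValueError):
    """Malformed MGF input."""


@dataclass
class SpectrumRecord:
    """One aligned MS1 feature with its MS/MS fragment list.

    Fragments are kept sorted by m/z; intensities are raw (relative
    intensity against the base peak is computed downstream, never at parse
    time). ``linked_to`` carries an MS-DIAL link to a higher-mass feature,
    ``adduct_label`` an adduct annotation; unrecognized headers survive in
    ``metadata``.
    """

    feature_id: str
    precursor_mz: float
    retention_time: float = 0.0
    fragments: list[tuple[float, float]] = field(default_factory=list)
    linked_to: str | None = None
    adduct_label: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fragments = sorted(self.fragments)
        for mz, inten in self.fragments:
            if inten < 0:
                raise ValueError(
                    f"negative intensity {inten} in feature {self.feature_id}"
                )

    @property
    def base_peak_intensity(self) -> float:
        return max((i for _, i in self.fragments), default=0.0)

    def relative_intensity(self, mz: float, tol: float) -> float:
        """Highest relative intensity among fragments within tol of mz."""
        base = self.base_peak_intensity
        if base <= 0:
            return 0.0
        best = 0.0
        for fmz, finten in self.fragments:
            if abs(fmz - mz) <= tol:
                best = max(best, finten / base)
        return best

    def has_fragment(self, mz: float, tol: float) -> bool:
        return any(abs(fmz - mz) <= tol for fmz, _ in self.fragments)


_PRECURSOR_KEYS = ("PEPMASS", "PRECURSORMZ")
_RT_KEYS = ("RTINMINUTES", "RTINSECONDS", "RETENTIONTIME")


def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Parse an MGF file into SpectrumRecords.

    One record per BEGIN IONS/END IONS block. ``TITLE`` (falling back to
    the scan index) supplies the feature id. Raises :class:`MGFError` with
    the offending line number for malformed peak lines or blocks lacking a
    precursor.
    """
    path = Path(path)
    text = path.read_text()
    records: list[SpectrumRecord] = []
    in_block = False
    headers: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            in_block, headers, peaks = True, {}, []
            continue
        if line == "END IONS":
            records.append(_finish_block(headers, peaks, len(records), lineno))
            in_block = False
            continue
        if not in_block:
            continue
        if "=" in line:
            key, _, value = line.partition("=")
            headers[key.strip().upper()] = value.strip()
        else:
            parts = line.split()
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except (IndexError, ValueError) as exc:
                raise MGFError(f"{path}:{lineno}: malformed ion line {line!r}") from exc
            peaks.append((mz, inten))
    if not records:
        warnings.warn(f"{path}: no spectra found", stacklevel=2)
    return records


def _finish_block(
    headers: dict[str, str], peaks: list[tuple[float, float]], index: int, lineno: int
) -> SpectrumRecord:
    feature_id = headers.pop("TITLE", None) or f"scan_{index}"
    precursor = None
    for key in _PRECURSOR_KEYS:
        if key in headers:
            # PEPMASS may carry "mz intensity"
            precursor = float(headers.pop(key).split()[0])
            break
    if precursor is None:
        raise MGFError(
            f"line {lineno}: spectrum {feature_id!r} has no precursor "
            f"(PEPMASS/PRECURSORMZ)"
        )
    rt = 0.0
    for key in _RT_KEYS:
        if key in headers:
            rt = float(headers.pop(key))
            if key == "RTINSECONDS":
                rt /= 60.0
            break
    linked = headers.pop("LINKEDTO", None) or None
    adduct = headers.pop("ION", None) or headers.pop("ADDUCT", None) or None
    return SpectrumRecord(
        feature_id=feature_id,
        precursor_mz=precursor,
        retention_time=rt,
        fragments=peaks,
        linked_to=linked,
        adduct_label=adduct,
        metadata=headers,
    )


def write_mgf(records: list[SpectrumRecord], path: str | Path) -> None:
    """Write records as MGF; round-trips m/z and intensity to 6 decimals."""
    lines: list[str] = []
    for rec in records:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={rec.feature_id}")
        lines.append(f"PRECURSORMZ={rec.precursor_mz:.6f}")
        lines.append(f"RTINMINUTES={rec.retention_time:.4f}")
        if rec.linked_to:
            lines.append(f"LINKEDTO={rec.linked_to}")
        if rec.adduct_label:
            lines.append(f"ION={rec.adduct_label}")
        for key, value in rec.metadata.items():
            lines.append(f"{key}={value}")
        for mz, inten in sorted(rec.fragments):
            lines.append(f"{mz:.6f} {inten:.6f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


@dataclass
class AlignmentTable:
    """Per-feature peak areas with a sample-to-role mapping.

    ``roles`` maps each used sample column to one of ``leaf``, ``root`` or
    ``blank``; multiple columns may share a role (their areas are summed by
    the accessors, matching how replicate injections are pooled).
    """

    areas: pd.DataFrame  # index: feature_id, columns: sample names
    roles: dict[str, str]
    missing_cells: int = 0

    def __post_init__(self) -> None:
        bad = {r for r in self.roles.values()} - {"leaf", "root", "blank"}
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        if "blank" not in self.roles.values():
            raise ValueError("no blank column configured; blank filter cannot run")

    def _role_total(self, feature_id: str, role: str) -> float:
        cols = [c for c, r in self.roles.items() if r == role]
        if feature_id not in self.areas.index:
            return 0.0
        return float(self.areas.loc[feature_id, cols].sum())

    def leaf_area(self, feature_id: str) -> float:
        return self._role_total(feature_id, "leaf")

    def root_area(self, feature_id: str) -> float:
        return self._role_total(feature_id, "root")

    def blank_area(self, feature_id: str) -> float:
        return self._role_total(feature_id, "blank")

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.areas.index


def read_alignment(
    path: str | Path,
    sample_roles: dict[str, str],
    feature_column: str = "feature_id",
) -> AlignmentTable:
    """Read a tab-separated peak-area table.

    Non-numeric or missing cells become 0 (counted in
    ``AlignmentTable.missing_cells``); columns not named in ``sample_roles``
    are ignored with a log entry; a duplicated feature id is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if feature_column not in df.columns:
        raise ValueError(f"{path}: missing feature column {feature_column!r}")
    missing_roles = set(sample_roles) - set(df.columns)
    if missing_roles:
        raise ValueError(f"{path}: role columns absent from table: {sorted(missing_roles)}")
    ignored = [c for c in df.columns if c != feature_column and c not in sample_roles]
    if ignored:
        logger.info("%s: ignoring unmapped columns %s", path, ignored)
    if df[feature_column].duplicated().any():
        dupes = df.loc[df[feature_column].duplicated(), feature_column].tolist()
        raise ValueError(f"{path}: duplicated feature ids {dupes}")
    sample_cols = list(sample_roles)
    numeric = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    missing = int(numeric.isna().sum().sum())
    if missing:
        warnings.warn(f"{path}: {missing} missing/non-numeric area cells set to 0",
                      stacklevel=2)
    numeric = numeric.fillna(0.0)
    if (numeric < 0).any().any():
        raise ValueError(f"{path}: negative peak areas")
    numeric.index = df[feature_column].values
    return AlignmentTable(areas=numeric, roles=dict(sample_roles), missing_cells=missing)


def write_alignment(table: AlignmentTable, path: str | Path,
                    feature_column: str = "feature_id") -> None:
    out = table.areas.copy()
    out.insert(0, feature_column, out.index)
    out.to_csv(path, sep="\t", index=False)
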