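"""Domain containers and delimited-text readers/writers.

The on-disk conventions are deliberately plain text:

* per-sample spectra: two columns ``(m/z, intensity)``, comma or tab
  separated, optional header;
* intensity matrices: first column ``mz``, one column per sample, with a
  configurable missing-value token (default ``"NA"``; empty fields also
  count as missing);
* validation reports: JSON with a fixed key layout.

All matrices are stored rows = m/z (or feature), columns = samples.
Internally, missing intensities are represented as ``NaN``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputFormatError, LabelError, UsageError

__all__ = [
    "RawSpectrum",
    "SpectrumSet",
    "RefinedMatrix",
    "read_label_table",
    "read_spectrum_file",
    "read_spectrum_dir",
    "read_matrix",
    "write_matrix",
    "write_features",
    "write_report",
    "read_report",
]

#: accepted label aliases (case-insensitive for the textual ones)
_LABEL_ALIASES = {"+1": 1, "1": 1, "-1": -1, "cancer": 1, "control": -1}


def _parse_label(raw: str, *, context: str = "") -> int:
    token = str(raw).strip().lower()
    if token in _LABEL_ALIASES:
        return _LABEL_ALIASES[token]
    raise LabelError(
        f"invalid label {raw!r}{context}; expected +1/-1 or 'cancer'/'control'"
    )


@dataclass
class RawSpectrum:
    """One sample's spectrum: sorted m/z values (Da) and intensities."""

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise UsageError(
                f"spectrum {self.sample_id!r}: mz and intensity must be "
                "1-D arrays of equal length"
            )
        if self.mz.size == 0:
            raise UsageError(f"spectrum {self.sample_id!r} is empty")
        if np.any(np.diff(self.mz) <= 0):
            raise UsageError(
                f"spectrum {self.sample_id!r}: m/z values must be strictly "
                "increasing with no duplicates"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise UsageError(
                f"spectrum {self.sample_id!r}: intensities must be finite"
            )

    def __len__(self) -> int:
        return self.mz.size


def _check_labels(labels: np.ndarray, n: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (n,):
        raise UsageError(f"expected {n} labels, got shape {labels.shape}")
    if not np.all(np.isin(labels, (-1, 1))):
        raise LabelError("labels must be +1 (cancer) or -1 (non-cancer)")
    return labels


@dataclass
class SpectrumSet:
    """Union-aligned intensity matrix with explicit missingness (NaN).

    ``intensities`` has shape ``(len(mz_axis), len(sample_ids))``; a NaN
    cell means the sample did not observe that m/z point.
    """

    mz_axis: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.mz_axis) <= 0):
            raise UsageError("mz_axis must be strictly increasing")
        n_mz, n_samples = self.intensities.shape
        if n_mz != self.mz_axis.size:
            raise UsageError("intensity rows must match mz_axis length")
        if n_samples != len(self.sample_ids):
            raise UsageError("intensity columns must match sample_ids")
        self.labels = _check_labels(self.labels, n_samples)

    @property
    def n_mz(self) -> int:
        return self.mz_axis.size

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.intensities)


@dataclass
class RefinedMatrix:
    """Complete intensity matrix: every sample observed every m/z row."""

    mz_axis: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.mz_axis) <= 0):
            raise UsageError("mz_axis must be strictly increasing")
        if np.any(np.isnan(self.intensities)):
            raise UsageError("RefinedMatrix must not contain missing values")
        n_mz, n_samples = self.intensities.shape
        if n_mz != self.mz_axis.size:
            raise UsageError("intensity rows must match mz_axis length")
        if n_samples != len(self.sample_ids):
            raise UsageError("intensity columns must match sample_ids")
        self.labels = _check_labels(self.labels, n_samples)

    @property
    def n_mz(self) -> int:
        return self.mz_axis.size

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def select_samples(self, idx: Sequence[int]) -> "RefinedMatrix":
        """Column subset (new object, views where possible)."""
        idx = np.asarray(idx, dtype=int)
        return RefinedMatrix(
            mz_axis=self.mz_axis,
            intensities=self.intensities[:, idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_label_table(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column (sample_id, label) delimited table.

    Accepts +1/-1 or 'cancer'/'control'; a header row is detected and
    skipped when its second field is not a recognisable label.
    """
    path = Path(path)
    out: dict[str, int] = {}
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 2:
            raise InputFormatError(
                f"{path.name}:{lineno}: expected two columns (sample_id, label)"
            )
        sid, raw = parts[0], parts[1]
        if lineno == 1 and raw.lower() not in _LABEL_ALIASES:
            try:
                float(raw)
            except ValueError:
                continue  # header row (non-numeric, non-alias second field)
        out[sid] = _parse_label(raw, context=f" ({path.name}:{lineno})")
    if not out:
        raise LabelError(f"label table {path} contains no entries")
    return out


def _detect_sep(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_spectrum_file(path: str | os.PathLike, sample_id: str | None = None) -> RawSpectrum:
    """Parse one two-column (m/z, intensity) file; rows are sorted by m/z."""
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    mzs: list[float] = []
    intens: list[float] = []
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(_detect_sep(line))]
        if len(parts) < 2:
            raise InputFormatError(
                f"{path.name}:{lineno}: expected two columns, got {len(parts)}"
            )
        try:
            mz, inten = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1 and not mzs:
                continue  # header row
            raise InputFormatError(
                f"{path.name}:{lineno}: non-numeric value in {parts[:2]!r}"
            ) from None
        mzs.append(mz)
        intens.append(inten)
    if not mzs:
        raise InputFormatError(f"{path.name}: no data rows found")
    mz_arr = np.asarray(mzs)
    if np.unique(mz_arr).size != mz_arr.size:
        raise InputFormatError(f"{path.name}: duplicate m/z values")
    order = np.argsort(mz_arr, kind="stable")
    return RawSpectrum(sample_id, mz_arr[order], np.asarray(intens)[order])


def read_spectrum_dir(
    path: str | os.PathLike, label_table: str | os.PathLike
) -> tuple[list[RawSpectrum], np.ndarray]:
    """Read every delimited spectrum file in a directory plus its labels.

    Returns spectra sorted by sample id and the matching +1/-1 label vector.
    Every file's stem must appear in the label table.
    """
    path = Path(path)
    label_path = Path(label_table).resolve()
    labels_map = read_label_table(label_table)
    files = sorted(
        p for p in path.iterdir()
        if p.is_file() and p.suffix.lower() in {".txt", ".csv", ".tsv"}
        and p.resolve() != label_path
    )
    if not files:
        raise InputFormatError(f"no spectrum files (*.txt/*.csv/*.tsv) in {path}")
    spectra: list[RawSpectrum] = []
    labels: list[int] = []
    for f in files:
        spec = read_spectrum_file(f)
        if spec.sample_id not in labels_map:
            raise LabelError(f"sample {spec.sample_id!r} missing from label table")
        spectra.append(spec)
        labels.append(labels_map[spec.sample_id])
    return spectra, np.asarray(labels, dtype=int)


def read_matrix(
    path: str | os.PathLike,
    *,
    orientation: str = "rows_mz",
    missing_token: str = "NA",
    labels: dict[str, int] | str | os.PathLike | None = None,
) -> SpectrumSet | RefinedMatrix:
    """Read a delimited intensity matrix.

    The first column holds m/z values and each remaining column one sample
    (``orientation="rows_samples"`` reads the transpose).  Returns a
    :class:`SpectrumSet` when any missing token is present, otherwise a
    :class:`RefinedMatrix`.  ``labels`` maps sample ids to +1/-1; when
    omitted, all-(+1) placeholder labels are attached.
    """
    path = Path(path)
    with path.open() as fh:
        sep = _detect_sep(fh.readline())
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0,
            na_values=[missing_token], keep_default_na=False,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise InputFormatError(f"{path.name}: {exc}") from None
    if orientation == "rows_samples":
        df = df.T
    elif orientation != "rows_mz":
        raise UsageError(f"unknown orientation {orientation!r}")
    try:
        mz_axis = df.index.to_numpy(dtype=float)
    except (TypeError, ValueError):
        # feature matrices carry names, not m/z values; use row positions
        mz_axis = np.arange(1.0, len(df.index) + 1.0)
    else:
        if np.unique(mz_axis).size != mz_axis.size:
            raise InputFormatError(f"{path.name}: duplicate m/z rows")
    order = np.argsort(mz_axis, kind="stable")
    mz_axis = mz_axis[order]
    try:
        values = df.to_numpy(dtype=float)[order]
    except ValueError as exc:
        raise InputFormatError(f"{path.name}: non-numeric intensity: {exc}") from None
    sample_ids = [str(c) for c in df.columns]

    if labels is None:
        label_vec = np.ones(len(sample_ids), dtype=int)
    else:
        if not isinstance(labels, dict):
            labels = read_label_table(labels)
        missing = [s for s in sample_ids if s not in labels]
        if missing:
            raise LabelError(f"samples missing from label table: {missing}")
        label_vec = np.asarray([labels[s] for s in sample_ids], dtype=int)

    if np.any(np.isnan(values)):
        return SpectrumSet(mz_axis, values, sample_ids, label_vec)
    return RefinedMatrix(mz_axis, values, sample_ids, label_vec)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_matrix(
    obj, path: str | os.PathLike, *, missing_token: str = "NA",
    index_label: str = "mz",
) -> None:
    """Write a SpectrumSet/RefinedMatrix (or feature matrix) as TSV.

    Full float precision (repr round-trip) so write-then-read is exact.
    """
    if hasattr(obj, "mz_axis"):
        index = np.asarray(obj.mz_axis)
        values, ids = obj.intensities, obj.sample_ids
    else:  # MomentFeatures duck-type: feature_names + features
        index = np.asarray(obj.feature_names, dtype=object)
        values, ids = obj.features, obj.sample_ids
        index_label = "feature"
    df = pd.DataFrame(values, index=pd.Index(index, name=index_label), columns=ids)
    df.to_csv(path, sep="\t", na_rep=missing_token, float_format=None)


#: alias matching the feature-matrix vocabulary used by the CLI
write_features = write_matrix

_METRIC_ORDER = ("Ac", "CC", "Sn", "Sp")


def write_report(report, path: str | os.PathLike) -> None:
    """Serialise a ValidationReport to JSON (mean and SD per metric).

    Raises ``UsageError`` for a report with no repeats rather than writing
    an empty file.
    """
    if not report.per_repeat:
        raise UsageError("refusing to write a report with zero repeats")
    payload = {
        "scheme": report.scheme,
        "n_repeats": report.n_repeats,
        "seed": report.seed,
        "mean": {m: report.mean[m] for m in _METRIC_ORDER},
        "sd": {m: report.sd[m] for m in _METRIC_ORDER},
        "per_repeat": [
            {m: getattr(ms, m) for m in _METRIC_ORDER} for ms in report.per_repeat
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_report(path: str | os.PathLike) -> dict:
    """Read back a JSON validation report as a plain dict."""
    return json.loads(Path(path).read_text())
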