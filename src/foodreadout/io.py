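"""Readers and writers for every on-disk artifact the pipeline touches.

Spectra travel as MGF (Mascot generic format, the dialect exported by
MZmine/GNPS-style tools: ``BEGIN IONS``/``END IONS`` blocks with ``PEPMASS``,
optional ``RTINSECONDS`` and a ``FEATURE_ID`` link into a feature table).
Feature tables are CSV/TSV, either the MZmine wide export (``row ID``,
``row m/z``, ``row retention time`` plus one peak-area column per sample) or a
long ``feature_id, sample_id, intensity`` layout. Sample metadata is a
delimited table whose first column is the sample id.

All text I/O is UTF-8 with the delimiter auto-detected among comma and tab.
Missing feature-table cells are imputed to zero (non-detection is treated as
absence, which is what the downstream fold-change filter assumes) and the
imputation count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "FeatureTable",
    "SampleMetadata",
    "read_mgf",
    "write_mgf",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "metadata_frame",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """One MS/MS scan: a precursor m/z plus its fragment peak list.

    A Spectrum represents the fragmentation of one *ion feature* — one
    chromatographic (m/z, RT) entity — not one molecule; a single compound
    can appear as several adducts or in-source fragments, each with its own
    spectrum.

    Parameters
    ----------
    spectrum_id : str
        Unique identifier of the scan.
    precursor_mz : float
        Precursor mass-to-charge in Da; must be positive.
    peaks : numpy.ndarray, shape (n_peaks, 2)
        Columns ``(fragment_mz, intensity)``. Stored sorted ascending by
        fragment m/z with non-negative intensities.
    retention_time : float, optional
        Retention time in seconds.
    source_file : str, optional
    feature_id : str, optional
        Link into a :class:`FeatureTable`.
    """

    spectrum_id: str
    precursor_mz: float
    peaks: np.ndarray
    retention_time: float | None = None
    source_file: str | None = None
    feature_id: str | None = None

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if peaks.size and np.any(peaks[:, 1] < 0):
            raise ValueError(f"spectrum {self.spectrum_id!r}: negative peak intensity")
        if self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.spectrum_id!r}: precursor_mz must be > 0")
        if self.retention_time is not None and self.retention_time < 0:
            raise ValueError(f"spectrum {self.spectrum_id!r}: negative retention time")
        order = np.argsort(peaks[:, 0], kind="stable")
        peaks = np.ascontiguousarray(peaks[order])
        peaks.setflags(write=False)
        object.__setattr__(self, "peaks", peaks)

    @property
    def n_peaks(self) -> int:
        return int(self.peaks.shape[0])

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensities(self) -> np.ndarray:
        return self.peaks[:, 1]

    def with_feature_id(self, feature_id: str) -> "Spectrum":
        return replace(self, feature_id=feature_id)


@dataclass
class FeatureTable:
    """MS1 peak areas of aligned ion features across samples.

    Attributes
    ----------
    feature_ids : list of str, unique
    mz, rt : numpy.ndarray
        Per-feature m/z (Da) and retention time (seconds; NaN if unknown).
    sample_ids : list of str, unique
    intensities : numpy.ndarray, shape (n_features, n_samples)
        Non-negative peak areas.
    """

    feature_ids: list[str]
    mz: np.ndarray
    rt: np.ndarray
    sample_ids: list[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n_f, n_s = len(self.feature_ids), len(self.sample_ids)
        if self.intensities.shape != (n_f, n_s):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} != ({n_f}, {n_s})"
            )
        if self.mz.shape != (n_f,) or self.rt.shape != (n_f,):
            raise ValueError("mz/rt must have one entry per feature")
        if len(set(self.feature_ids)) != n_f:
            raise ValueError("duplicate feature_id")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample_id")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities are not allowed")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature_id {feature_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample_id {sample_id!r}") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return FeatureTable(
            feature_ids=list(self.feature_ids),
            mz=self.mz.copy(),
            rt=self.rt.copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            intensities=self.intensities[:, idx].copy(),
        )

    def tic_normalized(self) -> "FeatureTable":
        """Divide each sample column by its total ion current.

        All-zero samples are left at zero (with a warning) rather than
        producing NaNs.
        """
        totals = self.intensities.sum(axis=0)
        zero = totals == 0
        if zero.any():
            logger.warning("TIC normalization: %d all-zero sample(s) left as zeros", zero.sum())
        safe = np.where(zero, 1.0, totals)
        return FeatureTable(
            feature_ids=list(self.feature_ids),
            mz=self.mz.copy(),
            rt=self.rt.copy(),
            sample_ids=list(self.sample_ids),
            intensities=self.intensities / safe,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample annotations: diet group, timepoint, clinical indices, ...

    ``attributes`` maps variable name to a numeric or categorical value.
    """

    sample_id: str
    attributes: dict[str, object] = field(default_factory=dict)


def metadata_frame(records: Iterable[SampleMetadata]) -> pd.DataFrame:
    """Assemble metadata records into a DataFrame indexed by sample id."""
    records = list(records)
    frame = pd.DataFrame([r.attributes for r in records], index=[r.sample_id for r in records])
    frame.index.name = "sample_id"
    return frame


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    The precursor is taken from ``PEPMASS`` (first number), retention time
    from ``RTINSECONDS`` (absent, not zero, when the key is missing) and the
    feature link from ``FEATURE_ID`` with ``SCANS`` / ``TITLE`` as fallback
    identifiers. Peaks are re-sorted ascending by fragment m/z regardless of
    file order.

    Raises
    ------
    FormatError
        On a malformed block (missing PEPMASS, non-numeric peak line); the
        message names the 0-based block index.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        index = 0
        while True:
            try:
                entry = next(reader)
            except StopIteration:
                break
            except Exception as exc:  # noqa: BLE001 - re-raise with block index
                raise FormatError(f"{path.name}: malformed MGF block {index}: {exc}") from exc
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise FormatError(f"{path.name}: malformed MGF block {index}: missing PEPMASS")
            rt = params.get("rtinseconds")
            feature_id = params.get("feature_id")
            spectrum_id = str(
                params.get("title") or params.get("scans") or feature_id or f"scan_{index}"
            )
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            spectra.append(
                Spectrum(
                    spectrum_id=spectrum_id,
                    precursor_mz=float(pepmass[0]),
                    peaks=peaks,
                    retention_time=None if rt is None else float(rt),
                    source_file=path.name,
                    feature_id=None if feature_id is None else str(feature_id),
                )
            )
            index += 1
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra to an MGF file readable by :func:`read_mgf`.

    Round-tripping preserves precursor m/z and peak m/z within 1e-6 Da and
    intensities within a relative 1e-6. An empty spectrum list produces a
    valid empty file; a spectrum without peaks is refused.
    """
    path = Path(path)
    entries = []
    for spec in spectra:
        if spec.n_peaks == 0:
            raise ValueError(f"spectrum {spec.spectrum_id!r} has no peaks; refusing to write")
        params: dict[str, object] = {
            "title": spec.spectrum_id,
            "pepmass": spec.precursor_mz,
        }
        if spec.retention_time is not None:
            params["rtinseconds"] = spec.retention_time
        if spec.feature_id is not None:
            params["feature_id"] = spec.feature_id
        entries.append(
            {
                "m/z array": spec.mz,
                "intensity array": spec.intensities,
                "params": params,
            }
        )
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        _mgf.write(entries, handle, fragment_format="{:.8f} {:.10g}", key_order=["title"])


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

_WIDE_ID, _WIDE_MZ, _WIDE_RT = "row ID", "row m/z", "row retention time"


def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", encoding="utf-8")


def read_feature_table(path: str | Path, dialect: str = "wide-mzmine") -> FeatureTable:
    """Read a feature table from CSV/TSV.

    ``dialect="wide-mzmine"`` expects the MZmine export layout: ``row ID``,
    ``row m/z``, ``row retention time`` columns followed by one peak-area
    column per sample (a trailing `` Peak area`` suffix is stripped from
    sample names). ``dialect="long"`` expects ``feature_id, sample_id,
    intensity`` triples with optional ``mz``/``rt`` columns.

    Missing cells are imputed to zero and the count logged; negative
    intensities are rejected.
    """
    frame = _read_delimited(path)
    if dialect == "wide-mzmine":
        missing = [c for c in (_WIDE_ID, _WIDE_MZ, _WIDE_RT) if c not in frame.columns]
        if missing:
            raise FormatError(f"{path}: wide-mzmine table lacks columns {missing}")
        sample_cols = [c for c in frame.columns if c not in (_WIDE_ID, _WIDE_MZ, _WIDE_RT)]
        if not sample_cols:
            raise FormatError(f"{path}: no sample columns found")
        feature_ids = frame[_WIDE_ID].astype(str).tolist()
        if len(set(feature_ids)) != len(feature_ids):
            raise FormatError(f"{path}: duplicate feature ids")
        values = frame[sample_cols].apply(pd.to_numeric, errors="raise")
        n_missing = int(values.isna().sum().sum())
        if n_missing:
            logger.warning("%s: %d missing cell(s) imputed to 0", path, n_missing)
            values = values.fillna(0.0)
        sample_ids = [c.removesuffix(" Peak area").strip() for c in sample_cols]
        return FeatureTable(
            feature_ids=feature_ids,
            mz=frame[_WIDE_MZ].to_numpy(float),
            rt=frame[_WIDE_RT].to_numpy(float),
            sample_ids=sample_ids,
            intensities=values.to_numpy(float),
        )
    if dialect == "long":
        required = {"feature_id", "sample_id", "intensity"}
        if not required.issubset(frame.columns):
            raise FormatError(f"{path}: long table needs columns {sorted(required)}")
        if frame.duplicated(["feature_id", "sample_id"]).any():
            raise FormatError(f"{path}: duplicate (feature_id, sample_id) pairs")
        n_missing = int(frame["intensity"].isna().sum())
        if n_missing:
            logger.warning("%s: %d missing cell(s) imputed to 0", path, n_missing)
        wide = (
            frame.pivot(index="feature_id", columns="sample_id", values="intensity")
            .fillna(0.0)
            .sort_index()
        )
        feature_ids = [str(f) for f in wide.index]
        meta = frame.drop_duplicates("feature_id").set_index("feature_id")
        mz = (
            meta.reindex(wide.index)["mz"].to_numpy(float)
            if "mz" in frame.columns
            else np.full(len(feature_ids), np.nan)
        )
        rt = (
            meta.reindex(wide.index)["rt"].to_numpy(float)
            if "rt" in frame.columns
            else np.full(len(feature_ids), np.nan)
        )
        return FeatureTable(
            feature_ids=feature_ids,
            mz=mz,
            rt=rt,
            sample_ids=[str(s) for s in wide.columns],
            intensities=wide.to_numpy(float),
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_feature_table(
    table: FeatureTable, path: str | Path, dialect: str = "wide-mzmine"
) -> None:
    """Write a feature table in either supported dialect (CSV or TSV by suffix)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    if dialect == "wide-mzmine":
        frame = pd.DataFrame(
            {
                _WIDE_ID: table.feature_ids,
                _WIDE_MZ: table.mz,
                _WIDE_RT: table.rt,
            }
        )
        for j, sample in enumerate(table.sample_ids):
            frame[sample] = table.intensities[:, j]
        frame.to_csv(path, sep=sep, index=False)
    elif dialect == "long":
        rows = []
        for i, fid in enumerate(table.feature_ids):
            for j, sid in enumerate(table.sample_ids):
                rows.append((fid, sid, table.intensities[i, j], table.mz[i], table.rt[i]))
        pd.DataFrame(rows, columns=["feature_id", "sample_id", "intensity", "mz", "rt"]).to_csv(
            path, sep=sep, index=False
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a delimited metadata table (first column = sample id).

    Columns whose every non-missing value parses as a number are typed
    numeric; anything mixed stays categorical (string).
    """
    frame = _read_delimited(path)
    if frame.shape[1] < 1:
        raise FormatError(f"{path}: empty metadata table")
    id_col = frame.columns[0]
    ids = frame[id_col].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated sample_id(s) {dupes}")
    records = []
    typed: dict[str, pd.Series] = {}
    for col in frame.columns[1:]:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.notna().eq(frame[col].notna()).all():
            typed[col] = numeric
        else:
            typed[col] = frame[col].astype("string")
    for i, sid in enumerate(ids):
        attrs: dict[str, object] = {}
        for col, series in typed.items():
            value = series.iloc[i]
            if pd.isna(value):
                continue
            attrs[col] = float(value) if series.dtype.kind in "ifu" else str(value)
        records.append(SampleMetadata(sample_id=sid, attributes=attrs))
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = metadata_frame(records)
    frame.to_csv(path, sep=sep)
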