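"""Dietary scores: from spectral matches + MS1 intensities to a readout matrix.

A sample's dietary score for a food category is the mean MS1 intensity of
that category's MS/MS biomarkers in the sample. Library matches identify
which biomarkers were detected; each detected biomarker contributes the
intensity of the query feature its matched spectrum links to. Two averaging
modes exist: ``fill="zeros"`` (default) averages over *all* of the
category's biomarkers with undetected ones contributing zero — rewarding
breadth of detection — while ``fill="detected_only"`` averages over the
detected biomarkers alone. Scores are relative readouts of intake, never
absolute amounts (ionization efficiency and matrix effects preclude
gram/calorie conversion).

Scores are computed per ontology level; proportion normalization divides
each sample's scores at one level by their sum, so cross-level mixtures of
granularity are never compared directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biomarker import BiomarkerLibrary
from .io import FeatureTable, Spectrum
from .spectral_match import SpectralMatch

logger = logging.getLogger(__name__)

__all__ = [
    "DietaryScoreMatrix",
    "link_matches_to_features",
    "dietary_scores",
    "normalize_scores",
]


@dataclass
class DietaryScoreMatrix:
    """Samples × food-categories dietary readout.

    ``category_levels`` records each category's ontology level so that
    proportion normalization (and any comparison) stays within one level.
    ``proportion`` is None for raw scores or the level the rows were
    normalized at.
    """

    values: np.ndarray  # samples × categories, >= 0
    sample_ids: list[str]
    category_ids: list[str]
    category_levels: dict[str, int]
    fill: str = "zeros"
    proportion: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.category_ids)):
            raise ValueError("score matrix shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("dietary scores must be non-negative")
        missing = [c for c in self.category_ids if c not in self.category_levels]
        if missing:
            raise ValueError(f"categories without a level: {missing}")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.sample_ids, columns=self.category_ids)
        frame.index.name = "sample_id"
        return frame

    def level_columns(self, level: int) -> list[int]:
        cols = [i for i, c in enumerate(self.category_ids) if self.category_levels[c] == level]
        if not cols:
            raise ValueError(f"no categories at ontology level {level}")
        return cols

    def save(self, path: str | Path, sidecar: Mapping[str, object] | None = None) -> None:
        """Write the TSV matrix plus a JSON sidecar with provenance."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t")
        meta = {
            "fill": self.fill,
            "proportion_level": self.proportion,
            "category_levels": dict(sorted(self.category_levels.items())),
        }
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "DietaryScoreMatrix":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text(encoding="utf-8")) if sidecar.is_file() else {}
        levels = {str(k): int(v) for k, v in meta.get("category_levels", {}).items()}
        for c in frame.columns:
            levels.setdefault(str(c), 0)
        prop = meta.get("proportion_level")
        return cls(
            values=frame.to_numpy(float),
            sample_ids=[str(i) for i in frame.index],
            category_ids=[str(c) for c in frame.columns],
            category_levels=levels,
            fill=meta.get("fill", "zeros"),
            proportion=None if prop is None else int(prop),
        )


def link_matches_to_features(
    matches: Sequence[SpectralMatch],
    query_table: FeatureTable,
    query_spectra: Sequence[Spectrum],
    mz_tol: float = 0.01,
    rt_tol: float = 30.0,
) -> tuple[dict[str, str], int]:
    """Map each matched query spectrum to a feature of the query table.

    An explicit ``feature_id`` on the spectrum wins regardless of m/z;
    otherwise the nearest feature within both the m/z and RT tolerances is
    used (features without RT are compared on m/z alone). Matches whose
    query spectrum cannot be linked are dropped with a logged count.

    Returns ``(query_spectrum_id → feature_id, n_dropped_matches)``.
    """
    spectra_by_id = {s.spectrum_id: s for s in query_spectra}
    feature_set = set(query_table.feature_ids)
    links: dict[str, str] = {}
    dropped = 0
    for qid in sorted({m.query_spectrum_id for m in matches}):
        spec = spectra_by_id.get(qid)
        if spec is None:
            continue
        if spec.feature_id is not None and spec.feature_id in feature_set:
            links[qid] = spec.feature_id
            continue
        d_mz = np.abs(query_table.mz - spec.precursor_mz)
        ok = d_mz <= mz_tol
        if spec.retention_time is not None:
            d_rt = np.abs(query_table.rt - spec.retention_time)
            ok &= np.isnan(query_table.rt) | (d_rt <= rt_tol)
        if not ok.any():
            continue
        candidates = np.flatnonzero(ok)
        best = candidates[np.argmin(d_mz[candidates])]
        links[qid] = query_table.feature_ids[int(best)]
    dropped = sum(1 for m in matches if m.query_spectrum_id not in links)
    if dropped:
        logger.warning("%d match(es) dropped: query spectrum not linkable to a feature", dropped)
    return links, dropped


def dietary_scores(
    query_table: FeatureTable,
    library: BiomarkerLibrary,
    matches: Sequence[SpectralMatch],
    links: Mapping[str, str],
    fill: str = "zeros",
    tic_normalize: bool = True,
) -> DietaryScoreMatrix:
    """Compute the samples × categories dietary score matrix.

    For each category the library's biomarkers are looked up; a biomarker is
    "detected" when some match hits its reference spectrum and that match's
    query spectrum links to a feature of the query table. When several query
    spectra match the same biomarker, the top-scoring match supplies the
    feature. ``fill="zeros"`` averages over all of the category's
    biomarkers; ``fill="detected_only"`` over the detected ones (0 if none).
    The matrix covers every library category; a category with no biomarkers
    yields a zero column with a warning.
    """
    if fill not in ("zeros", "detected_only"):
        raise ValueError(f"unknown fill mode {fill!r}")
    work = query_table.tic_normalized() if tic_normalize else query_table
    # best-scoring linked match per library spectrum
    best_match: dict[str, SpectralMatch] = {}
    for m in matches:
        if m.query_spectrum_id not in links:
            continue
        cur = best_match.get(m.library_spectrum_id)
        if cur is None or (m.score, m.query_spectrum_id) > (cur.score, cur.query_spectrum_id):
            best_match[m.library_spectrum_id] = m

    categories = library.categories
    values = np.zeros((work.n_samples, len(categories)))
    for c_idx, category in enumerate(categories):
        biomarkers = library.by_category(category)
        if not biomarkers:
            logger.warning("category %r has no biomarkers; zero column emitted", category)
            continue
        detected_rows = []
        for entry in biomarkers:
            if entry.reference_spectrum_id is None:
                continue
            m = best_match.get(entry.reference_spectrum_id)
            if m is None:
                continue
            feature_id = links[m.query_spectrum_id]
            detected_rows.append(work.intensities[work.feature_index(feature_id), :])
        if not detected_rows:
            continue
        detected = np.vstack(detected_rows)
        if fill == "zeros":
            values[:, c_idx] = detected.sum(axis=0) / len(biomarkers)
        else:
            values[:, c_idx] = detected.mean(axis=0)
    return DietaryScoreMatrix(
        values=values,
        sample_ids=list(work.sample_ids),
        category_ids=categories,
        category_levels=dict(library.category_levels),
        fill=fill,
        proportion=None,
    )


def normalize_scores(scores: DietaryScoreMatrix, level: int) -> DietaryScoreMatrix:
    """Proportion-normalize one ontology level of the score matrix.

    Returns the matrix restricted to the categories at ``level`` with each
    sample's row divided by its sum; all-zero rows stay zero. Rows of the
    result sum to 1 (or 0 when nothing of that level was detected).
    """
    cols = scores.level_columns(level)
    sub = scores.values[:, cols]
    totals = sub.sum(axis=1, keepdims=True)
    safe = np.where(totals == 0, 1.0, totals)
    category_ids = [scores.category_ids[i] for i in cols]
    return DietaryScoreMatrix(
        values=sub / safe,
        sample_ids=list(scores.sample_ids),
        category_ids=category_ids,
        category_levels={c: level for c in category_ids},
        fill=scores.fill,
        proportion=level,
    )
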