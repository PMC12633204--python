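"""Cosine and modified-cosine MS/MS spectral matching against the library.

Scores use square-root-transformed intensities (standard library-search
practice to damp base-peak dominance): candidate peak pairs are those within
the fragment tolerance — the modified cosine additionally allows pairs
offset by the precursor mass difference, which captures host/microbially
modified metabolites (methylation, glucuronidation, hydroxylation, ...) —
and a one-to-one pairing maximizing Σ √(Iₐ·I_b) is chosen. The score is that
sum divided by ‖√Iₐ‖·‖√I_b‖, so a spectrum against itself scores 1.

The pairing is solved exactly (Hungarian assignment) when both spectra have
at most 12 peaks and greedily — descending pair product, ties broken by
smaller |Δm/z| — beyond that; the greedy path is an approximation whose gap
to the exact optimum is exercised by the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .biomarker import BiomarkerLibrary
from .io import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralMatch",
    "cosine_score",
    "modified_cosine",
    "search_library",
    "write_matches",
    "read_matches",
]

EXACT_ASSIGNMENT_MAX_PEAKS = 12


@dataclass(frozen=True)
class SpectralMatch:
    """One accepted query↔library spectrum match."""

    query_spectrum_id: str
    library_spectrum_id: str
    score: float
    matched_peaks: int
    precursor_delta: float  # query − library, Da
    mode: str  # "cosine" | "modified_cosine"

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.matched_peaks < 0:
            raise ValueError("matched_peaks must be >= 0")
        if self.mode not in ("cosine", "modified_cosine"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _candidate_pairs(
    a: Spectrum, b: Spectrum, fragment_tol: float, shift: float | None
) -> list[tuple[int, int, float, float]]:
    """(i, j, √(Iₐᵢ·I_bⱼ), |Δm/z residual|) for every allowed peak pair."""
    sqrt_a = np.sqrt(a.intensities)
    sqrt_b = np.sqrt(b.intensities)
    delta = a.mz[:, None] - b.mz[None, :]
    allowed = np.abs(delta) <= fragment_tol
    residual = np.abs(delta)
    if shift is not None and abs(shift) > 0:
        shifted = np.abs(delta - shift)
        allowed |= shifted <= fragment_tol
        residual = np.minimum(residual, shifted)
    pairs = []
    for i, j in zip(*np.nonzero(allowed)):
        pairs.append((int(i), int(j), float(sqrt_a[i] * sqrt_b[j]), float(residual[i, j])))
    return pairs


def _solve_pairing(
    pairs: list[tuple[int, int, float, float]], n_a: int, n_b: int, exact: bool
) -> tuple[float, int]:
    """Maximize the summed pair product under one-to-one matching."""
    if not pairs:
        return 0.0, 0
    if exact:
        weight = np.zeros((n_a, n_b))
        allowed = np.zeros((n_a, n_b), dtype=bool)
        for i, j, product, _ in pairs:
            weight[i, j] = product
            allowed[i, j] = True
        rows, cols = linear_sum_assignment(weight, maximize=True)
        chosen = allowed[rows, cols]
        return float(weight[rows, cols].sum()), int(chosen.sum())
    total, used_a, used_b, count = 0.0, set(), set(), 0
    for i, j, product, _ in sorted(pairs, key=lambda p: (-p[2], p[3], p[0], p[1])):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += product
        count += 1
    return total, count


def _score(
    a: Spectrum, b: Spectrum, fragment_tol: float, shift: float | None
) -> tuple[float, int]:
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("cannot score an empty spectrum")
    if fragment_tol <= 0:
        raise ValueError("fragment_tol must be positive")
    pairs = _candidate_pairs(a, b, fragment_tol, shift)
    exact = max(a.n_peaks, b.n_peaks) <= EXACT_ASSIGNMENT_MAX_PEAKS
    total, matched = _solve_pairing(pairs, a.n_peaks, b.n_peaks, exact)
    norm = np.sqrt(a.intensities.sum()) * np.sqrt(b.intensities.sum())
    if norm == 0:
        return 0.0, matched
    return float(np.clip(total / norm, 0.0, 1.0)), matched


def cosine_score(a: Spectrum, b: Spectrum, fragment_tol: float = 0.02) -> tuple[float, int]:
    """Cosine similarity of two spectra on √-intensities.

    Returns ``(score in [0, 1], matched peak count)``.
    """
    return _score(a, b, fragment_tol, shift=None)


def modified_cosine(a: Spectrum, b: Spectrum, fragment_tol: float = 0.02) -> tuple[float, int]:
    """Modified cosine: peaks may also pair at the precursor mass difference.

    With identical precursors this reduces exactly to :func:`cosine_score`;
    a spectrum whose fragments and precursor are all shifted by the same
    mass modification scores 1 against the unmodified spectrum.
    """
    shift = a.precursor_mz - b.precursor_mz
    return _score(a, b, fragment_tol, shift=shift)


def search_library(
    queries: Sequence[Spectrum],
    library: BiomarkerLibrary,
    precursor_tol: float = 0.01,
    fragment_tol: float = 0.02,
    min_peaks: int = 4,
    min_score: float = 0.7,
    mode: str = "cosine",
    analog_max_delta: float = 200.0,
) -> list[SpectralMatch]:
    """Match query spectra against the library's reference spectra.

    ``mode="cosine"`` compares only pairs whose precursor m/z difference is
    within ``precursor_tol``; ``mode="modified_cosine"`` (analog search)
    allows differences up to ``analog_max_delta``. Matches are kept when
    score ≥ ``min_score`` and matched peaks ≥ ``min_peaks``; per query they
    are returned sorted by descending score.
    """
    if not library.spectra:
        raise ValueError("library has no reference spectra")
    if mode not in ("cosine", "modified_cosine"):
        raise ValueError(f"unknown mode {mode!r}")
    refs = [library.spectra[k] for k in sorted(library.spectra)]
    ref_prec = np.array([r.precursor_mz for r in refs])
    matches: list[SpectralMatch] = []
    for query in queries:
        deltas = query.precursor_mz - ref_prec
        window = precursor_tol if mode == "cosine" else analog_max_delta
        hits: list[SpectralMatch] = []
        for ref, delta in zip(refs, deltas):
            if abs(delta) > window:
                continue
            if mode == "cosine":
                score, matched = cosine_score(query, ref, fragment_tol)
            else:
                score, matched = modified_cosine(query, ref, fragment_tol)
            if score >= min_score and matched >= min_peaks:
                hits.append(
                    SpectralMatch(
                        query_spectrum_id=query.spectrum_id,
                        library_spectrum_id=ref.spectrum_id,
                        score=score,
                        matched_peaks=matched,
                        precursor_delta=float(delta),
                        mode=mode,
                    )
                )
        hits.sort(key=lambda m: (-m.score, m.library_spectrum_id))
        matches.extend(hits)
    logger.info("library search: %d quer(ies), %d match(es)", len(queries), len(matches))
    return matches


# ---------------------------------------------------------------------------
# match table I/O (the readout module's alternative input)
# ---------------------------------------------------------------------------

_MATCH_COLUMNS = [
    "query_id",
    "library_id",
    "category_id",
    "score",
    "matched_peaks",
    "precursor_delta",
    "mode",
]


def write_matches(
    matches: Sequence[SpectralMatch], library: BiomarkerLibrary, path: str | Path
) -> None:
    """Export matches as TSV, one row per (match, library category)."""
    rows = []
    for m in matches:
        categories = sorted(
            {e.category_id for e in library.entries_for_spectrum(m.library_spectrum_id)}
        ) or [""]
        for cat in categories:
            rows.append(
                (
                    m.query_spectrum_id,
                    m.library_spectrum_id,
                    cat,
                    m.score,
                    m.matched_peaks,
                    m.precursor_delta,
                    m.mode,
                )
            )
    pd.DataFrame(rows, columns=_MATCH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_matches(path: str | Path) -> list[SpectralMatch]:
    """Read a match TSV back into unique :class:`SpectralMatch` records."""
    frame = pd.read_csv(path, sep="\t", dtype={"query_id": str, "library_id": str})
    missing = [c for c in _MATCH_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: match table lacks columns {missing}")
    frame = frame.drop_duplicates(["query_id", "library_id", "mode"])
    return [
        SpectralMatch(
            query_spectrum_id=str(row.query_id),
            library_spectrum_id=str(row.library_id),
            score=float(row.score),
            matched_peaks=int(row.matched_peaks),
            precursor_delta=float(row.precursor_delta),
            mode=str(row.mode),
        )
        for row in frame.itertuples(index=False)
    ]
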