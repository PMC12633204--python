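"""VIP × fold-change biomarker selection and the MS/MS food-biomarker library.

A feature becomes a "MS/MS food biomarker" for a category when its OPLS-DA
VIP score exceeds the VIP threshold (strictly, default > 4.0) *and* its mean
intensity is enriched in that category by at least the fold threshold
(inclusive, default ≥ 6-fold) relative to all other foods. Fold-changes are
ratios of TIC-normalized but *unlogged* mean intensities with a scale-aware
pseudo-count (half the smallest nonzero normalized intensity) so absent
features never produce infinite ratios.

The resulting :class:`BiomarkerLibrary` couples the selected
(feature, category) entries with their reference MS/MS spectra and records
the exact parameters used; it serializes to JSON plus a companion MGF.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .discriminant import PreprocessSpec, fit_opls, preprocess, vip_scores
from .io import FeatureTable, Spectrum, read_mgf, write_mgf
from .ontology import ContrastSpec, FoodOntology, enumerate_contrasts

logger = logging.getLogger(__name__)

__all__ = [
    "BiomarkerEntry",
    "BiomarkerLibrary",
    "LibraryConfig",
    "fold_change",
    "select_biomarkers",
    "learn_library",
]


@dataclass(frozen=True)
class BiomarkerEntry:
    """One selected (feature, category) pair with its filter evidence."""

    feature_id: str
    category_id: str
    level: int
    vip: float
    fold_change: float
    mean_intensity_target: float
    mean_intensity_rest: float
    reference_spectrum_id: str | None = None
    annotation: str = ""  # empty for unannotated ("dark") features

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "category_id": self.category_id,
            "level": self.level,
            "vip": self.vip,
            "fold_change": self.fold_change,
            "mean_intensity_target": self.mean_intensity_target,
            "mean_intensity_rest": self.mean_intensity_rest,
            "reference_spectrum_id": self.reference_spectrum_id,
            "annotation": self.annotation,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "BiomarkerEntry":
        return cls(**doc)


@dataclass(frozen=True)
class LibraryConfig:
    """Thresholds and preprocessing used to learn a library."""

    vip_threshold: float = 4.0
    fold_threshold: float = 6.0
    preprocess: PreprocessSpec = PreprocessSpec()
    scope: str = "global"
    min_group_size: int = 3
    n_ortho: int = 1
    epsilon: float | None = None  # None → half the smallest nonzero normalized intensity

    def to_dict(self) -> dict:
        return {
            "vip_threshold": self.vip_threshold,
            "fold_threshold": self.fold_threshold,
            "preprocess": self.preprocess.to_dict(),
            "scope": self.scope,
            "min_group_size": self.min_group_size,
            "n_ortho": self.n_ortho,
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LibraryConfig":
        doc = dict(doc)
        doc["preprocess"] = PreprocessSpec.from_dict(doc["preprocess"])
        return cls(**doc)


@dataclass
class BiomarkerLibrary:
    """Selected biomarker entries plus their reference MS/MS spectra.

    A feature may legitimately appear under several categories and levels
    (hierarchical levels overlap by design). ``parameters`` records the
    configuration exactly as used; ``run_log`` summarizes the learning run.
    """

    entries: list[BiomarkerEntry]
    spectra: dict[str, Spectrum] = field(default_factory=dict)
    parameters: LibraryConfig = field(default_factory=LibraryConfig)
    category_levels: dict[str, int] = field(default_factory=dict)
    run_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for entry in self.entries:
            if (
                entry.reference_spectrum_id is not None
                and entry.reference_spectrum_id not in self.spectra
            ):
                raise ValueError(
                    f"entry {entry.feature_id}/{entry.category_id} references missing "
                    f"spectrum {entry.reference_spectrum_id!r}"
                )
            self.category_levels.setdefault(entry.category_id, entry.level)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def categories(self) -> list[str]:
        return sorted(self.category_levels)

    def by_category(self, category_id: str) -> list[BiomarkerEntry]:
        return [e for e in self.entries if e.category_id == category_id]

    def by_feature(self, feature_id: str) -> list[BiomarkerEntry]:
        return [e for e in self.entries if e.feature_id == feature_id]

    def entries_for_spectrum(self, spectrum_id: str) -> list[BiomarkerEntry]:
        return [e for e in self.entries if e.reference_spectrum_id == spectrum_id]

    def audit(self) -> None:
        """Verify every entry satisfies the thresholds it was selected under."""
        for e in self.entries:
            if not (e.vip > self.parameters.vip_threshold):
                raise ValueError(
                    f"entry {e.feature_id}/{e.category_id}: VIP {e.vip} fails "
                    f"threshold > {self.parameters.vip_threshold}"
                )
            if not (e.fold_change >= self.parameters.fold_threshold):
                raise ValueError(
                    f"entry {e.feature_id}/{e.category_id}: fold-change {e.fold_change} "
                    f"fails threshold >= {self.parameters.fold_threshold}"
                )

    # -- persistence -------------------------------------------------------

    def save(self, json_path: str | Path, mgf_path: str | Path | None = None) -> None:
        json_path = Path(json_path)
        if mgf_path is None:
            mgf_path = json_path.with_suffix(".mgf")
        doc = {
            "parameters": self.parameters.to_dict(),
            "category_levels": dict(sorted(self.category_levels.items())),
            "entries": [e.to_dict() for e in sorted(
                self.entries, key=lambda e: (e.level, e.category_id, e.feature_id)
            )],
            "spectra_file": Path(mgf_path).name,
            "run_log": self.run_log,
        }
        json_path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")
        ordered = [self.spectra[k] for k in sorted(self.spectra)]
        write_mgf(ordered, mgf_path)

    @classmethod
    def load(cls, json_path: str | Path, mgf_path: str | Path | None = None) -> "BiomarkerLibrary":
        json_path = Path(json_path)
        doc = json.loads(json_path.read_text(encoding="utf-8"))
        if mgf_path is None:
            mgf_path = json_path.parent / doc.get("spectra_file", json_path.stem + ".mgf")
        spectra: dict[str, Spectrum] = {}
        if Path(mgf_path).is_file():
            spectra = {s.spectrum_id: s for s in read_mgf(mgf_path)}
        library = cls(
            entries=[BiomarkerEntry.from_dict(d) for d in doc["entries"]],
            spectra=spectra,
            parameters=LibraryConfig.from_dict(doc["parameters"]),
            category_levels={k: int(v) for k, v in doc.get("category_levels", {}).items()},
            run_log=doc.get("run_log", {}),
        )
        library.audit()
        return library


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def fold_change(
    table: FeatureTable,
    positives: Iterable[str],
    negatives: Iterable[str],
    epsilon: float | None = None,
    tic_normalize: bool = True,
) -> np.ndarray:
    """Per-feature enrichment ratio of a target group over the rest.

    ``FC_j = (mean_j(positives) + ε) / (mean_j(negatives) + ε)`` computed on
    TIC-normalized, *unlogged* intensities ("≥ n-fold enrichment" is a ratio
    statement about abundances, not log-abundances). ``ε`` defaults to half
    the smallest nonzero normalized intensity in the table — a scale-aware
    pseudo-count keeping ratios finite when a feature is absent from the
    rest of the foods.
    """
    positives, negatives = list(positives), list(negatives)
    if not positives or not negatives:
        raise ValueError("positive and negative sample sets must be non-empty")
    if set(positives) & set(negatives):
        raise ValueError("positive and negative sample sets overlap")
    work = table.tic_normalized() if tic_normalize else table
    pos_idx = [work.sample_index(s) for s in positives]
    neg_idx = [work.sample_index(s) for s in negatives]
    if epsilon is None:
        nonzero = work.intensities[work.intensities > 0]
        epsilon = float(nonzero.min()) / 2.0 if nonzero.size else 1e-12
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    mean_pos = work.intensities[:, pos_idx].mean(axis=1)
    mean_neg = work.intensities[:, neg_idx].mean(axis=1)
    return (mean_pos + epsilon) / (mean_neg + epsilon)


def select_biomarkers(
    vip: np.ndarray,
    fc: np.ndarray,
    vip_threshold: float = 4.0,
    fold_threshold: float = 6.0,
) -> np.ndarray:
    """Boolean mask of features passing both filters.

    Selection requires VIP strictly above ``vip_threshold``, fold-change at
    or above ``fold_threshold``, and enrichment in the target direction
    (fold-change > 1).
    """
    vip = np.asarray(vip, dtype=float)
    fc = np.asarray(fc, dtype=float)
    if vip.shape != fc.shape:
        raise ValueError(f"VIP and fold-change lengths differ: {vip.shape} vs {fc.shape}")
    return (vip > vip_threshold) & (fc >= fold_threshold) & (fc > 1.0)


# ---------------------------------------------------------------------------
# library learning
# ---------------------------------------------------------------------------


def learn_library(
    table: FeatureTable,
    ontology: FoodOntology,
    spectra: Sequence[Spectrum] | Mapping[str, Spectrum] = (),
    config: LibraryConfig = LibraryConfig(),
) -> BiomarkerLibrary:
    """Learn the food-biomarker library from a reference food dataset.

    For every one-vs-rest contrast enumerated from the ontology:
    preprocess → OPLS-DA fit → VIP scores → fold-change → joint selection.
    Selected features keep their reference MS/MS spectrum when one is linked
    by ``feature_id``; features without a spectrum stay in the library
    flagged spectrum-less (usable only in feature-id matching mode).

    A dataset with no enriched features yields an empty library, not an
    error. Per-contrast failures are re-raised with the contrast identity
    attached.
    """
    if isinstance(spectra, Mapping):
        spectrum_by_feature = {
            s.feature_id: s for s in spectra.values() if s.feature_id is not None
        }
        all_spectra = dict(spectra)
    else:
        spectrum_by_feature = {s.feature_id: s for s in spectra if s.feature_id is not None}
        all_spectra = {s.spectrum_id: s for s in spectra}

    samples = [s for s in table.sample_ids if s in ontology.sample_assignments]
    if not samples:
        raise ValueError("no feature-table sample is assigned in the ontology")
    try:
        contrasts = enumerate_contrasts(
            ontology, samples, scope=config.scope, min_group_size=config.min_group_size
        )
    except ValueError as exc:
        if "no valid contrasts" in str(exc):
            raise
        raise

    # one preprocessing pass over all assigned samples (global scope uses
    # every contrast on the same matrix; per-contrast y just relabels rows)
    prep = preprocess(table, config.preprocess, samples=samples)
    sample_pos = {s: i for i, s in enumerate(prep.sample_ids)}
    norm_table = table.subset_samples(samples).tic_normalized()
    nonzero = norm_table.intensities[norm_table.intensities > 0]
    epsilon = (
        config.epsilon
        if config.epsilon is not None
        else (float(nonzero.min()) / 2.0 if nonzero.size else 1e-12)
    )

    entries: list[BiomarkerEntry] = []
    used_spectra: dict[str, Spectrum] = {}
    category_levels: dict[str, int] = {}
    per_contrast: dict[str, int] = {}
    n_spectrumless = 0
    for contrast in contrasts:
        try:
            y = np.full(len(prep.sample_ids), -1.0)
            for s in contrast.positive_samples:
                y[sample_pos[s]] = 1.0
            keep = np.array(
                [s in contrast.positive_samples or s in contrast.negative_samples
                 for s in prep.sample_ids]
            )
            X = prep.matrix[keep]
            X = X - X.mean(axis=0)  # re-center within the contrast's samples
            model = fit_opls(X, y[keep], n_ortho=config.n_ortho)
            vip = vip_scores(model)
            fc = fold_change(
                norm_table,
                sorted(contrast.positive_samples),
                sorted(contrast.negative_samples),
                epsilon=epsilon,
                tic_normalize=False,
            )
            mask = select_biomarkers(
                vip, fc, config.vip_threshold, config.fold_threshold
            )
        except Exception as exc:
            raise RuntimeError(
                f"contrast {contrast.target_category!r} (level {contrast.level}): {exc}"
            ) from exc
        pos_idx = [norm_table.sample_index(s) for s in sorted(contrast.positive_samples)]
        neg_idx = [norm_table.sample_index(s) for s in sorted(contrast.negative_samples)]
        mean_pos = norm_table.intensities[:, pos_idx].mean(axis=1)
        mean_neg = norm_table.intensities[:, neg_idx].mean(axis=1)
        selected = np.flatnonzero(mask)
        per_contrast[contrast.target_category] = int(selected.size)
        category_levels[contrast.target_category] = contrast.level
        for j in selected:
            fid = norm_table.feature_ids[j]
            spec = spectrum_by_feature.get(fid)
            if spec is None:
                n_spectrumless += 1
            else:
                used_spectra[spec.spectrum_id] = spec
            entries.append(
                BiomarkerEntry(
                    feature_id=fid,
                    category_id=contrast.target_category,
                    level=contrast.level,
                    vip=float(vip[j]),
                    fold_change=float(fc[j]),
                    mean_intensity_target=float(mean_pos[j]),
                    mean_intensity_rest=float(mean_neg[j]),
                    reference_spectrum_id=None if spec is None else spec.spectrum_id,
                )
            )
    run_log = {
        "n_contrasts": len(contrasts),
        "n_entries": len(entries),
        "n_spectrumless_entries": n_spectrumless,
        "selected_per_contrast": per_contrast,
        "epsilon": epsilon,
    }
    logger.info(
        "library learned: %d contrast(s), %d entries (%d without reference spectrum)",
        len(contrasts),
        len(entries),
        n_spectrumless,
    )
    library = BiomarkerLibrary(
        entries=entries,
        spectra=used_spectra,
        parameters=LibraryConfig(
            vip_threshold=config.vip_threshold,
            fold_threshold=config.fold_threshold,
            preprocess=config.preprocess,
            scope=config.scope,
            min_group_size=config.min_group_size,
            n_ortho=config.n_ortho,
            epsilon=epsilon,
        ),
        category_levels=category_levels,
        run_log=run_log,
    )
    return library
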