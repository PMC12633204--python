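"""Synthetic reference-food datasets, mixtures and cohorts with ground truth.

The generator emulates the statistical shape of a reference food
metabolomics experiment: a category-structured feature table in which most
features are shared background while a planted subset is enriched several
fold in its home food category; lognormal multiplicative noise (LC-MS
intensity error is multiplicative, not additive) and Bernoulli dropout
(per-run detection failure) corrupt the measurements; every feature carries
a small synthetic MS/MS spectrum — a random peak list, geometrically but
not chemically realistic — linked by feature id.

Mixtures combine leaf-category mean profiles at known fractions (the
ground-truth design), and cohorts draw per-subject mixtures from diet-group
weight profiles, so the full learn → match → score → statistics pipeline
can be validated end to end against planted truth. Every operation is
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FeatureTable, SampleMetadata, Spectrum
from .ontology import FoodOntology

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "simulate_reference",
    "simulate_mixture",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the reference-food generator.

    Defaults describe the standard validation conditions: 8 leaf food
    categories with 12 reference samples each, 40 planted biomarkers per
    category at 10-fold enrichment over 400 background features, 30%
    lognormal intensity CV and 10% dropout. ``ontology_depth`` 1 builds a
    flat root→leaves tree; depth 2 groups the leaves under ``n_branches``
    intermediate categories.
    """

    n_categories: int = 8
    ontology_depth: int = 1
    n_branches: int = 2
    samples_per_category: int = 12
    planted_biomarkers_per_category: int = 40
    background_features: int = 400
    planted_fold: float = 10.0
    intensity_cv: float = 0.3
    dropout_rate: float = 0.1
    peaks_per_spectrum: int = 8
    fragment_mz_range: tuple[float, float] = (50.0, 1000.0)
    base_abundance: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_fold <= 1:
            raise ValueError("planted_fold must be > 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_categories < 1 or self.samples_per_category < 1:
            raise ValueError("need at least one category with at least one sample")
        if self.ontology_depth not in (1, 2):
            raise ValueError("ontology_depth must be 1 or 2")
        if self.ontology_depth == 2 and self.n_branches < 1:
            raise ValueError("depth-2 trees need n_branches >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring downstream."""

    planted: dict[str, set[str]]  # category_id -> planted feature ids
    mixture_design: pd.DataFrame | None = None  # samples × component fractions
    cohort_labels: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        doc = {
            "planted": {k: sorted(v) for k, v in sorted(self.planted.items())},
            "mixture_design": (
                None
                if self.mixture_design is None
                else json.loads(self.mixture_design.to_json(orient="split"))
            ),
            "cohort_labels": dict(sorted(self.cohort_labels.items())),
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def _lognormal_sigma(cv: float) -> float:
    # CV of a lognormal: sqrt(exp(sigma^2) - 1)
    return float(np.sqrt(np.log(1.0 + cv**2)))


def _build_ontology(config: SynthConfig, samples_by_cat: Mapping[str, list[str]]) -> FoodOntology:
    edges: list[tuple[str, str | None, str]] = [("root", None, "food")]
    leaves = sorted(samples_by_cat)
    if config.ontology_depth == 1:
        edges += [(leaf, "root", leaf) for leaf in leaves]
    else:
        branches = [f"branch{b + 1}" for b in range(config.n_branches)]
        edges += [(b, "root", b) for b in branches]
        for i, leaf in enumerate(leaves):
            edges.append((leaf, branches[i % len(branches)], leaf))
    assignments = {s: cat for cat, ss in samples_by_cat.items() for s in ss}
    return FoodOntology.from_edges(edges, assignments)


def simulate_reference(
    config: SynthConfig = SynthConfig(),
) -> tuple[FeatureTable, FoodOntology, list[Spectrum], GroundTruth]:
    """Generate the reference-food dataset with planted category biomarkers.

    Background features share one lognormal baseline across all categories;
    each planted feature's baseline is multiplied by ``planted_fold`` in its
    home category only. Per-cell multiplicative lognormal noise (from
    ``intensity_cv``) and Bernoulli dropout are then applied. Each feature
    receives a reproducible synthetic spectrum (uniform fragment m/z,
    exponential intensities) keyed to the seed.
    """
    rng = np.random.default_rng(config.seed)
    cats = [f"food{c + 1:02d}" for c in range(config.n_categories)]
    samples_by_cat = {
        cat: [f"{cat}_s{r + 1:02d}" for r in range(config.samples_per_category)]
        for cat in cats
    }
    ontology = _build_ontology(config, samples_by_cat)
    sample_ids = [s for cat in cats for s in samples_by_cat[cat]]
    n_planted = config.n_categories * config.planted_biomarkers_per_category
    n_features = n_planted + config.background_features
    feature_ids = [f"F{i + 1:05d}" for i in range(n_features)]
    planted: dict[str, set[str]] = {}
    home = np.full(n_features, -1)
    k = 0
    for c_idx, cat in enumerate(cats):
        ids = feature_ids[k : k + config.planted_biomarkers_per_category]
        planted[cat] = set(ids)
        home[k : k + config.planted_biomarkers_per_category] = c_idx
        k += config.planted_biomarkers_per_category

    # per-feature baseline: lognormal spread of base abundances across features
    baseline = config.base_abundance * rng.lognormal(mean=0.0, sigma=1.0, size=n_features)
    fold = np.ones((n_features, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        c_idx = cats.index(ontology.sample_assignments[sid])
        fold[home == c_idx, j] = config.planted_fold
    sigma = _lognormal_sigma(config.intensity_cv)
    noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=(n_features, len(sample_ids)))
    intensities = baseline[:, None] * fold * noise
    if config.dropout_rate > 0:
        keep = rng.random((n_features, len(sample_ids))) >= config.dropout_rate
        intensities = intensities * keep

    mz = np.round(rng.uniform(100.0, 1000.0, size=n_features), 4)
    rt = np.round(rng.uniform(10.0, 600.0, size=n_features), 1)
    table = FeatureTable(
        feature_ids=feature_ids,
        mz=mz,
        rt=rt,
        sample_ids=sample_ids,
        intensities=intensities,
    )
    lo, hi = config.fragment_mz_range
    spectra = []
    for i, fid in enumerate(feature_ids):
        frag_mz = np.sort(rng.uniform(lo, hi, size=config.peaks_per_spectrum))
        frag_int = rng.exponential(scale=1.0, size=config.peaks_per_spectrum) + 1e-3
        spectra.append(
            Spectrum(
                spectrum_id=f"spec_{fid}",
                precursor_mz=float(mz[i]),
                peaks=np.column_stack([frag_mz, frag_int]),
                retention_time=float(rt[i]),
                feature_id=fid,
            )
        )
    truth = GroundTruth(planted=planted)
    return table, ontology, spectra, truth


def _category_profiles(
    table: FeatureTable, ontology: FoodOntology, categories: Sequence[str]
) -> np.ndarray:
    """features × categories matrix of mean raw reference profiles."""
    profiles = np.zeros((table.n_features, len(categories)))
    leaf_set = ontology.leaves()
    for c_idx, cat in enumerate(categories):
        if cat not in leaf_set:
            raise ValueError(f"mixture component {cat!r} is not a reference leaf category")
        samples = sorted(ontology.subtree_samples(cat))
        if not samples:
            raise ValueError(f"category {cat!r} has no reference samples")
        idx = [table.sample_index(s) for s in samples]
        profiles[:, c_idx] = table.intensities[:, idx].mean(axis=1)
    return profiles


def simulate_mixture(
    table: FeatureTable,
    ontology: FoodOntology,
    spectra: Sequence[Spectrum],
    design: pd.DataFrame,
    noise_cv: float = 0.2,
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> tuple[FeatureTable, list[Spectrum]]:
    """Mix leaf-category mean profiles at known fractions.

    ``design`` rows are mixture samples, columns are reference leaf
    categories, entries are fractions summing to 1 per row. Intensities are
    the fraction-weighted category profiles under multiplicative lognormal
    noise and optional dropout; spectra of features detected in at least one
    mixture sample are carried over (feature links preserved).
    """
    if not np.allclose(design.to_numpy(float).sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("design rows must sum to 1")
    if (design.to_numpy(float) < 0).any():
        raise ValueError("fractions must be non-negative")
    rng = np.random.default_rng(seed)
    categories = [str(c) for c in design.columns]
    profiles = _category_profiles(table, ontology, categories)
    mixed = profiles @ design.to_numpy(float).T  # features × mixture samples
    if noise_cv > 0:
        sigma = _lognormal_sigma(noise_cv)
        mixed = mixed * rng.lognormal(-0.5 * sigma**2, sigma, size=mixed.shape)
    if dropout_rate > 0:
        mixed = mixed * (rng.random(mixed.shape) >= dropout_rate)
    out = FeatureTable(
        feature_ids=list(table.feature_ids),
        mz=table.mz.copy(),
        rt=table.rt.copy(),
        sample_ids=[str(s) for s in design.index],
        intensities=mixed,
    )
    present = set(np.asarray(table.feature_ids)[(mixed > 0).any(axis=1)])
    carried = [s for s in spectra if s.feature_id in present]
    return out, carried


def simulate_cohort(
    table: FeatureTable,
    ontology: FoodOntology,
    spectra: Sequence[Spectrum],
    groups: Mapping[str, Mapping[str, float]],
    n_per_group: int = 10,
    between_subject_cv: float = 0.3,
    noise_cv: float = 0.2,
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> tuple[FeatureTable, list[Spectrum], list[SampleMetadata]]:
    """Simulate a diet-group cohort of subjects with individual variation.

    Each group maps leaf categories to diet weights; each subject's sample
    is a mixture draw whose fractions are the group weights perturbed by a
    subject-level lognormal effect (``between_subject_cv``) and
    renormalized. Metadata carries the diet-group label per subject.
    """
    if len(groups) < 2:
        raise ValueError("simulate_cohort needs at least 2 groups")
    for g, weights in groups.items():
        if not weights:
            raise ValueError(f"group {g!r} has an empty weight profile")
    rng = np.random.default_rng(seed)
    categories = sorted({c for w in groups.values() for c in w})
    rows, index, meta = [], [], []
    sigma = _lognormal_sigma(between_subject_cv) if between_subject_cv > 0 else 0.0
    for g in sorted(groups):
        base = np.array([float(groups[g].get(c, 0.0)) for c in categories])
        if base.sum() <= 0:
            raise ValueError(f"group {g!r} weights sum to zero")
        base = base / base.sum()
        for subject in range(n_per_group):
            effect = rng.lognormal(-0.5 * sigma**2, sigma, size=len(categories)) if sigma else 1.0
            fractions = base * effect
            fractions = fractions / fractions.sum()
            sid = f"{g}_subj{subject + 1:02d}"
            rows.append(fractions)
            index.append(sid)
            meta.append(
                SampleMetadata(sample_id=sid, attributes={"diet_group": g, "subject": sid})
            )
    design = pd.DataFrame(rows, index=index, columns=categories)
    mix_table, carried = simulate_mixture(
        table,
        ontology,
        spectra,
        design,
        noise_cv=noise_cv,
        dropout_rate=dropout_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return mix_table, carried, meta
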