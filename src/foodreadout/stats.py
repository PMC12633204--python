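"""Downstream statistics on dietary score matrices.

Three analyses mirror how diet readouts are interrogated in practice:
principal component analysis to visualize diet-group separation, PERMANOVA
to quantify how much score variance a grouping explains (pseudo-F, R²,
permutation p), and Pearson correlation of category scores against numeric
metadata (clinical indices, macronutrients) with Benjamini–Hochberg control
across the whole category × variable grid.

PERMANOVA follows the classical partitioning on a distance matrix d:

    SS_total   = (1/n) Σ_{i<j} d_ij²
    SS_within  = Σ_g (1/n_g) Σ_{i<j ∈ g} d_ij²
    SS_between = SS_total − SS_within
    F = (SS_between/(g−1)) / (SS_within/(n−g)),  R² = SS_between/SS_total
    p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations)

When the requested permutation count meets or exceeds the number of
distinct label arrangements, the test switches to exact enumeration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .readout import DietaryScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PcaResult",
    "PermanovaResult",
    "pca",
    "permanova",
    "correlate",
]


def _as_matrix(data) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(data, DietaryScoreMatrix):
        return data.values, list(data.sample_ids), list(data.category_ids)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(float), [str(i) for i in data.index], [str(c) for c in data.columns]
    arr = np.asarray(data, dtype=float)
    return (
        arr,
        [f"s{i}" for i in range(arr.shape[0])],
        [f"v{j}" for j in range(arr.shape[1])],
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    sample_scores: np.ndarray  # samples × components
    loadings: np.ndarray  # variables × components
    explained_variance_ratio: np.ndarray
    sample_ids: list[str]
    variable_ids: list[str]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.sample_scores.shape[1])]
        return pd.DataFrame(self.sample_scores, index=self.sample_ids, columns=cols)


def pca(data, n_components: int = 2, scale: bool = False) -> PcaResult:
    """Principal component analysis via SVD of the centered matrix.

    Columns are mean-centered (and optionally unit-scaled). The sign of
    each component is fixed so its largest-magnitude loading is positive,
    giving deterministic output across runs.
    """
    X, sample_ids, variable_ids = _as_matrix(data)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not np.any(X):
        raise ValueError("PCA on an all-zero matrix is undefined")
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds min matrix dimension")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd == 0, 1.0, sd)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((S**2).sum())
    if total_var == 0:
        raise ValueError("matrix has no variance")
    ratios = (S**2) / total_var
    scores = U * S
    loadings = Vt.T
    for k in range(min(n_components, loadings.shape[1])):
        pivot = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[pivot, k] < 0:
            loadings[:, k] = -loadings[:, k]
            scores[:, k] = -scores[:, k]
    return PcaResult(
        sample_scores=scores[:, :n_components],
        loadings=loadings[:, :n_components],
        explained_variance_ratio=ratios[:n_components],
        sample_ids=sample_ids,
        variable_ids=variable_ids,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None
    exact: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        how = "exact" if self.exact else f"{self.n_permutations} permutations"
        return (
            f"PERMANOVA: R²={self.r_squared:.3f}, pseudo-F={self.pseudo_f:.2f}, "
            f"p={self.p_value:.4g} ({how})"
        )


def _permanova_stats(D2: np.ndarray, groups: list[np.ndarray], n: int) -> tuple[float, float]:
    """(pseudo-F, R²) from squared distances and group index arrays."""
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for idx in groups:
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    g = len(groups)
    f = (ss_between / (g - 1)) / (ss_within / (n - g)) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _distinct_arrangements(counts: Sequence[int]) -> int:
    n = sum(counts)
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(c)
    return total


def permanova(
    data,
    labels: Sequence,
    distance: str = "euclidean",
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA of a score matrix against a grouping.

    ``distance`` is ``"euclidean"`` (recommended on proportion-normalized
    scores) or ``"braycurtis"`` (scores are composition-like). The p-value
    uses the ``(1 + more-extreme) / (1 + n_permutations)`` convention; when
    ``n_permutations`` is at least the number of distinct label
    arrangements, the permutation null is enumerated exactly instead.
    """
    X, sample_ids, _ = _as_matrix(data)
    labels = np.asarray([str(l) for l in labels])
    if labels.shape[0] != X.shape[0]:
        raise ValueError("one label per sample required")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    uniq, inverse = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(inverse)
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"every group needs >= 2 samples; too small: {small}")
    n, g = X.shape[0], uniq.size
    D2 = squareform(pdist(X, metric=distance)) ** 2
    groups = [np.flatnonzero(inverse == k) for k in range(g)]
    f_obs, r2 = _permanova_stats(D2, groups, n)

    n_distinct = _distinct_arrangements(counts.tolist())
    if n_permutations >= n_distinct:
        logger.info(
            "n_permutations=%d >= %d distinct arrangements; enumerating exactly",
            n_permutations,
            n_distinct,
        )
        from sympy.utilities.iterables import multiset_permutations

        hits, total = 0, 0
        for arrangement in multiset_permutations(inverse.tolist()):
            arr = np.asarray(arrangement)
            perm_groups = [np.flatnonzero(arr == k) for k in range(g)]
            f_perm, _ = _permanova_stats(D2, perm_groups, n)
            hits += f_perm >= f_obs - 1e-12
            total += 1
        return PermanovaResult(
            r_squared=float(r2),
            pseudo_f=float(f_obs),
            p_value=hits / total,
            n_permutations=total,
            seed=seed,
            exact=True,
        )

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(inverse)
        perm_groups = [np.flatnonzero(perm == k) for k in range(g)]
        f_perm, _ = _permanova_stats(D2, perm_groups, n)
        hits += f_perm >= f_obs - 1e-12
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        r_squared=float(r2),
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        exact=False,
    )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def correlate(
    data,
    metadata: pd.DataFrame | Mapping[str, Sequence[float]],
    variables: Sequence[str] | None = None,
    adjust: str = "benjamini_hochberg",
) -> pd.DataFrame:
    """Pearson correlation of every score column against numeric metadata.

    Missing values are handled pairwise-complete with the per-pair sample
    count recorded; two-sided p-values come from the t distribution with
    n − 2 degrees of freedom; ``q`` is the Benjamini–Hochberg adjusted p
    over the whole table. Pairs with fewer than 3 complete observations or
    a zero-variance vector are emitted flagged and excluded from the
    adjustment.

    Returns a DataFrame with columns
    ``category, variable, r, p, q, n, flag``.
    """
    X, sample_ids, categories = _as_matrix(data)
    if isinstance(metadata, Mapping) and not isinstance(metadata, pd.DataFrame):
        metadata = pd.DataFrame(metadata, index=sample_ids)
    meta = metadata.reindex(sample_ids)
    if variables is None:
        variables = [
            c for c in meta.columns if pd.api.types.is_numeric_dtype(pd.to_numeric(meta[c], errors="coerce"))
            and pd.to_numeric(meta[c], errors="coerce").notna().any()
        ]
    rows = []
    for j, category in enumerate(categories):
        x_all = X[:, j]
        for var in variables:
            y_all = pd.to_numeric(meta[var], errors="coerce").to_numpy(float)
            ok = ~np.isnan(x_all) & ~np.isnan(y_all)
            n_pair = int(ok.sum())
            flag = ""
            r = p = np.nan
            if n_pair < 3:
                flag = "insufficient_n"
            elif np.std(x_all[ok]) == 0 or np.std(y_all[ok]) == 0:
                flag = "zero_variance"
            else:
                r, p = sp_stats.pearsonr(x_all[ok], y_all[ok])
                r, p = float(r), float(p)
            rows.append((category, var, r, p, np.nan, n_pair, flag))
    table = pd.DataFrame(rows, columns=["category", "variable", "r", "p", "q", "n", "flag"])
    valid = table["flag"] == ""
    if adjust == "benjamini_hochberg" and valid.any():
        _, q, _, _ = multipletests(table.loc[valid, "p"].to_numpy(), method="fdr_bh")
        table.loc[valid, "q"] = q
    elif adjust not in ("benjamini_hochberg", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table
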