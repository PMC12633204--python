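"""One-vs-rest OPLS-DA and VIP scoring for food-biomarker discovery.

Orthogonal projections to latent structures (O-PLS) splits the predictive
variation (correlated with the ±1 class vector) from orthogonal variation.
The single-response algorithm iterates, for each orthogonal component on the
current (deflated) matrix X:

    w   = Xᵀy / (yᵀy),  w ← w/‖w‖
    t   = Xw
    p   = Xᵀt / (tᵀt)
    w_o = p − (wᵀp)·w,  w_o ← w_o/‖w_o‖
    t_o = X·w_o
    p_o = Xᵀt_o / (t_oᵀt_o)
    X  ← X − t_o·p_oᵀ

followed by one ordinary PLS component (w, t = Xw, p, q = yᵀt/(tᵀt)) on the
deflated matrix. With zero orthogonal components the model is exactly a
one-component PLS. Because the input matrix is column-centered, every
orthogonal score is uncorrelated with the class vector by construction.

Variable importance in projection (VIP) is computed over the predictive
component(s) only:

    VIP_j = sqrt( p · Σ_a SSY_a (w_{aj}/‖w_a‖)² / Σ_a SSY_a ),
    SSY_a = q_a² (t_aᵀ t_a)

so the squared VIPs average to one and the conventional "VIP > threshold"
selection is meaningful on the predictive axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessSpec",
    "PreprocessResult",
    "preprocess",
    "OplsModel",
    "fit_opls",
    "vip_scores",
]

_LOG_TRANSFORMS = ("none", "log10", "log2")
_SCALINGS = ("center", "uv", "pareto")


@dataclass(frozen=True)
class PreprocessSpec:
    """How a feature table is turned into a model matrix.

    ``tic_normalize`` divides each sample by its total ion current (row-wise,
    samples × features orientation); ``log_transform`` applies log10(x+1) or
    log2(x+1); ``scaling`` is per-feature (column-wise): plain centering,
    unit-variance ("uv") or Pareto (divide by sqrt of the standard
    deviation). Defaults — TIC on, log10(x+1), unit-variance — reflect that
    discriminant models are fit on relative abundances and that LC-MS
    intensities span decades.
    """

    tic_normalize: bool = True
    log_transform: str = "log10"
    scaling: str = "uv"

    def __post_init__(self) -> None:
        if self.log_transform not in _LOG_TRANSFORMS:
            raise ValueError(f"log_transform must be one of {_LOG_TRANSFORMS}")
        if self.scaling not in _SCALINGS:
            raise ValueError(f"scaling must be one of {_SCALINGS}")

    def to_dict(self) -> dict:
        return {
            "tic_normalize": self.tic_normalize,
            "log_transform": self.log_transform,
            "scaling": self.scaling,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PreprocessSpec":
        return cls(**doc)


@dataclass
class PreprocessResult:
    matrix: np.ndarray  # samples × features
    feature_means: np.ndarray
    feature_scales: np.ndarray
    zero_variance: np.ndarray  # boolean flags, scale forced to 1
    sample_ids: list[str]
    feature_ids: list[str]


def preprocess(
    table: FeatureTable,
    spec: PreprocessSpec = PreprocessSpec(),
    samples: Sequence[str] | None = None,
) -> PreprocessResult:
    """Build the samples × features model matrix from a feature table.

    Zero-variance features get scale 1 (leaving them centered at zero) and
    are flagged. All-zero samples survive TIC normalization as zeros.
    """
    if table.n_features == 0 or table.n_samples == 0:
        raise ValueError("empty feature table")
    if samples is not None:
        table = table.subset_samples(list(samples))
    if spec.tic_normalize:
        table = table.tic_normalized()
    X = table.intensities.T.astype(float)  # samples × features
    if spec.log_transform == "log10":
        X = np.log10(X + 1.0)
    elif spec.log_transform == "log2":
        X = np.log2(X + 1.0)
    means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    zero_var = sd <= 1e-15
    if zero_var.any():
        logger.debug("%d zero-variance feature(s); scale forced to 1", int(zero_var.sum()))
    if spec.scaling == "center":
        scales = np.ones_like(sd)
    elif spec.scaling == "uv":
        scales = np.where(zero_var, 1.0, sd)
    else:  # pareto
        scales = np.where(zero_var, 1.0, np.sqrt(sd))
    X = (X - means) / scales
    return PreprocessResult(
        matrix=X,
        feature_means=means,
        feature_scales=scales,
        zero_variance=zero_var,
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
    )


@dataclass
class OplsModel:
    """A fitted single-response OPLS model.

    ``w``/``t``/``p``/``q`` are the predictive weights (unit norm), scores,
    loadings and y-loading; ``ortho`` collects (w_o, t_o, p_o) per orthogonal
    component. ``n_ortho`` is the achieved orthogonal-component count, which
    can fall short of the request when the data are perfectly predictive
    (``truncated`` is then set).
    """

    w: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: float
    ortho: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=list)
    truncated: bool = False

    @property
    def n_ortho(self) -> int:
        return len(self.ortho)

    @property
    def n_features(self) -> int:
        return int(self.w.shape[0])

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "t": self.t.tolist(),
            "p": self.p.tolist(),
            "q": self.q,
            "n_ortho": self.n_ortho,
            "truncated": self.truncated,
        }


def _pls_weight(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    w = X.T @ y / (y @ y)
    norm = np.linalg.norm(w)
    if norm < 1e-15:
        raise ValueError("degenerate fit: X carries no covariance with y")
    return w / norm


def fit_opls(X: np.ndarray, y: np.ndarray, n_ortho: int = 1) -> OplsModel:
    """Fit an O-PLS model to a preprocessed (column-centered) matrix.

    Parameters
    ----------
    X : ndarray, samples × features
    y : ndarray of ±1 class labels (both classes present)
    n_ortho : requested number of orthogonal components (≥ 0)

    The sign of the predictive weight vector is fixed so its
    largest-magnitude element is positive, making output deterministic.
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be samples × features and y one label per sample")
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    if np.unique(np.sign(y)).size < 2:
        raise ValueError("y must contain both classes")
    if X.shape[0] < n_ortho + 2:
        raise ValueError(
            f"need at least n_ortho + 2 = {n_ortho + 2} samples, got {X.shape[0]}"
        )
    ortho: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    truncated = False
    for _ in range(n_ortho):
        w = _pls_weight(X, y)
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o < 1e-12:
            truncated = True
            logger.debug("orthogonal variation exhausted after %d component(s)", len(ortho))
            break
        w_o = w_o / norm_o
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        ortho.append((w_o, t_o, p_o))
    w = _pls_weight(X, y)
    t = X @ w
    tt = t @ t
    if tt < 1e-300:
        raise ValueError("degenerate model: predictive scores are all zero")
    p = X.T @ t / tt
    q = float(y @ t / tt)
    # deterministic sign: largest-|w| element positive
    pivot = int(np.argmax(np.abs(w)))
    if w[pivot] < 0:
        w, t, p, q = -w, -t, -p, -q
    signed_ortho = []
    for w_o, t_o, p_o in ortho:
        pivot_o = int(np.argmax(np.abs(w_o)))
        if w_o[pivot_o] < 0:
            w_o, t_o, p_o = -w_o, -t_o, -p_o
        signed_ortho.append((w_o, t_o, p_o))
    return OplsModel(w=w, t=t, p=p, q=q, ortho=signed_ortho, truncated=truncated)


def vip_scores(model: OplsModel) -> np.ndarray:
    """Per-feature VIP over the predictive component(s) of a fitted model.

    Returns a non-negative vector whose squared values sum to the number of
    features (mean squared VIP = 1).
    """
    tt = float(model.t @ model.t)
    if tt < 1e-300:
        raise ValueError("degenerate model: predictive scores are all zero")
    p_feat = model.n_features
    # single predictive component: the SSY weights cancel
    w_unit = model.w / np.linalg.norm(model.w)
    vip = np.sqrt(p_feat) * np.abs(w_unit)
    return vip
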