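"""Construction of the three connectivity layers and their multiplex assembly.

A subject's brain is represented by three node-aligned weighted networks over
the same parcellation:

* **MC** (morphological covariance): edge ``w_ij = exp(-(z_i - z_j)^2)``
  where ``z_i`` is the region's gray-matter volume standardized against the
  healthy-control norm after regressing out age, sex and total intracranial
  volume.  High weight means the two regions deviate from the norm together.
* **SC** (structural connectivity): streamline-weight matrices, compressed
  with ``log10(1 + w)`` so that edges spanning orders of magnitude become
  comparable with the other layers.
* **FC** (functional connectivity): Pearson correlations of regional BOLD
  signals, Fisher z-transformed and absolutized (``|atanh(r)|``), since
  anti-correlations carry information.

Before the layers are merged into a multiplex each one is divided by its
largest singular value, so that no layer dominates the combined node
strengths purely through its average weight scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

LAYER_KINDS = ("MC", "SC", "FC")

__all__ = [
    "ConnectivityLayer",
    "MultiplexNetwork",
    "VolumeZScores",
    "NuisanceZScorer",
    "zscore_volumes",
    "build_mc_layer",
    "transform_sc",
    "transform_fc",
    "svd_normalize",
    "assemble_multiplex",
]


def _check_square_symmetric(w: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{name}: expected a square matrix, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError(f"{name}: non-finite entries")
    asym = np.max(np.abs(w - w.T)) if w.size else 0.0
    if asym > tol:
        raise ValueError(f"{name}: matrix not symmetric (max asymmetry {asym:.3g})")
    return w


@dataclass
class ConnectivityLayer:
    """A single symmetric, nonnegative, zero-diagonal weighted layer."""

    kind: str
    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}; expected one of {LAYER_KINDS}")
        w = _check_square_symmetric(self.weights, f"{self.kind} layer")
        if np.any(w < 0):
            raise ValueError(f"{self.kind} layer: negative weights")
        if np.any(np.diag(w) != 0):
            raise ValueError(f"{self.kind} layer: nonzero diagonal")
        if not self.node_labels:
            self.node_labels = [f"node{i:03d}" for i in range(w.shape[0])]
        if len(self.node_labels) != w.shape[0]:
            raise ValueError(
                f"{self.kind} layer: {len(self.node_labels)} labels for {w.shape[0]} nodes"
            )
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class MultiplexNetwork:
    """Node-aligned (MC, SC, FC) triple with unit spectral norm per layer."""

    layers: tuple[ConnectivityLayer, ...]
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("multiplex needs at least one layer")
        ref = self.layers[0].node_labels
        for lay in self.layers[1:]:
            for a, b in zip(ref, lay.node_labels):
                if a != b:
                    raise ValueError(
                        f"node label mismatch across layers: {a!r} != {b!r}"
                    )
            if len(lay.node_labels) != len(ref):
                raise ValueError("layers differ in node count")
        if not self.node_labels:
            self.node_labels = list(ref)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def weight_arrays(self) -> list[np.ndarray]:
        return [lay.weights for lay in self.layers]


@dataclass
class VolumeZScores:
    """Standardized, covariate-adjusted regional volumes plus the HC model."""

    z: np.ndarray                 # subjects x nodes
    coef: np.ndarray              # (1 + n_covariates) x nodes, HC-fit OLS
    resid_sd: np.ndarray          # per-node SD of HC residuals
    covariate_names: list[str]


class NuisanceZScorer(BaseEstimator, TransformerMixin):
    """HC-anchored nuisance regression and z-scoring.

    Fits, per feature, an ordinary least-squares model of the feature on an
    intercept plus the given covariates **using only the reference (healthy
    control) rows**, so that disease-related variance is not removed.  The
    transform returns ``z = (x - prediction - mean_ref_resid) / sd_ref_resid``
    for every subject; over the reference sample each feature's z has mean 0
    and SD 1 by construction.

    Parameters
    ----------
    ddof : int, default 1
        Delta degrees of freedom for the reference-residual SD.
    min_reference : int, default 2
        Minimum number of reference rows beyond the parameter count.
    """

    def __init__(self, ddof: int = 1, min_reference: int = 2):
        self.ddof = ddof
        self.min_reference = min_reference

    def fit(self, X, y=None, *, covariates, reference_mask=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(C)):
            raise ValueError("non-finite values in features or covariates")
        n = X.shape[0]
        if C.shape[0] != n:
            raise ValueError("covariates and features disagree on sample count")
        if reference_mask is None:
            reference_mask = np.ones(n, dtype=bool)
        mask = np.asarray(reference_mask, dtype=bool)

        # Zero-variance covariates carry no information beyond the intercept:
        # drop them (with a warning) instead of failing on a singular design.
        ref_C = C[mask]
        keep = ref_C.std(axis=0) > 0
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} constant covariate column(s) "
                "from the nuisance design", stacklevel=2,
            )
        self._keep_cols_ = keep
        design = np.column_stack([np.ones(mask.sum()), ref_C[:, keep]])
        p = design.shape[1]
        if mask.sum() < p + self.min_reference:
            raise ValueError(
                f"too few reference subjects ({int(mask.sum())}) for {p} parameters"
            )
        if np.linalg.matrix_rank(design) < p:
            raise ValueError("singular nuisance design (collinear covariates)")

        coef, *_ = np.linalg.lstsq(design, X[mask], rcond=None)
        resid = X[mask] - design @ coef
        sd = resid.std(axis=0, ddof=self.ddof)
        # float tolerance: residuals of an exactly-fit feature are ~1e-16
        sd_floor = np.sqrt(np.finfo(float).eps) * np.maximum(
            1.0, np.abs(X[mask]).max(axis=0)
        )
        if np.any(sd <= sd_floor):
            bad = int(np.argmax(sd <= sd_floor))
            raise ValueError(f"zero residual SD in reference sample (feature {bad})")
        self.coef_ = coef
        self.resid_mean_ = resid.mean(axis=0)
        self.resid_sd_ = sd
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, *, covariates):
        if not hasattr(self, "coef_"):
            raise ValueError("NuisanceZScorer is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        design = np.column_stack([np.ones(X.shape[0]), C[:, self._keep_cols_]])
        resid = X - design @ self.coef_
        return (resid - self.resid_mean_) / self.resid_sd_

    def fit_transform(self, X, y=None, *, covariates, reference_mask=None):
        return self.fit(
            X, covariates=covariates, reference_mask=reference_mask
        ).transform(X, covariates=covariates)


def zscore_volumes(volumes, covariates, hc_mask, *, min_hc: int = 10) -> VolumeZScores:
    """Standardize regional volumes against the HC norm.

    ``covariates`` must hold age, sex (0/1) and TIV columns, in that order.
    The per-node OLS model is fit on HC subjects only; all subjects are then
    expressed as z-scores of their residual from that model, scaled by the
    SD (ddof=1) of the HC residuals.
    """
    hc_mask = np.asarray(hc_mask, dtype=bool)
    if hc_mask.sum() < min_hc:
        raise ValueError(f"need at least {min_hc} HC subjects, got {int(hc_mask.sum())}")
    scaler = NuisanceZScorer(ddof=1)
    scaler.fit(volumes, covariates=covariates, reference_mask=hc_mask)
    z = scaler.transform(volumes, covariates=covariates)
    names = ["age", "sex", "tiv"][: np.atleast_2d(np.asarray(covariates)).shape[1]]
    return VolumeZScores(
        z=z, coef=scaler.coef_, resid_sd=scaler.resid_sd_, covariate_names=names
    )


def build_mc_layer(z_row, node_labels: Sequence[str] | None = None) -> ConnectivityLayer:
    """Morphological-covariance layer from one subject's volume z-scores.

    ``w_ij = exp(-(z_i - z_j)^2)`` for ``i != j``; the diagonal (formally 1)
    is forced to 0 because self-edges never contribute to strength or
    coreness.  Weights lie in (0, 1].
    """
    z = np.asarray(z_row, dtype=float).ravel()
    if not np.all(np.isfinite(z)):
        bad = int(np.argmax(~np.isfinite(z)))
        label = node_labels[bad] if node_labels else f"node {bad}"
        raise ValueError(f"non-finite z-score at {label}")
    diff = z[:, None] - z[None, :]
    w = np.exp(-diff ** 2)
    np.fill_diagonal(w, 0.0)
    return ConnectivityLayer("MC", w, list(node_labels) if node_labels else [])


def transform_sc(raw_sc, node_labels: Sequence[str] | None = None) -> ConnectivityLayer:
    """``log10(1 + w)`` compression of a raw streamline-weight matrix.

    Preserves zeros and rank order while shrinking the dynamic range.
    """
    w = _check_square_symmetric(raw_sc, "raw SC")
    if np.any(w < 0):
        raise ValueError("raw SC has negative weights")
    out = np.log10(1.0 + w)
    np.fill_diagonal(out, 0.0)
    return ConnectivityLayer("SC", out, list(node_labels) if node_labels else [])


def transform_fc(corr_matrix, node_labels: Sequence[str] | None = None) -> ConnectivityLayer:
    """Absolutized Fisher z-transform ``|atanh(r)|`` of a correlation matrix."""
    r = _check_square_symmetric(corr_matrix, "FC correlations")
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        raise ValueError("off-diagonal correlation with |r| >= 1")
    with np.errstate(divide="ignore"):
        w = np.abs(np.arctanh(np.clip(r, -1.0, 1.0)))
    np.fill_diagonal(w, 0.0)
    return ConnectivityLayer("FC", w, list(node_labels) if node_labels else [])


def svd_normalize(layer: ConnectivityLayer | np.ndarray) -> ConnectivityLayer | np.ndarray:
    """Divide a layer by its largest singular value (spectral norm -> 1)."""
    if isinstance(layer, ConnectivityLayer):
        w = layer.weights
    else:
        w = _check_square_symmetric(layer, "layer")
    top = float(np.linalg.norm(w, 2))
    if top <= 0:
        raise ValueError("all-zero layer cannot be normalized (degenerate subject)")
    out = w / top
    if isinstance(layer, ConnectivityLayer):
        return ConnectivityLayer(layer.kind, out, list(layer.node_labels))
    return out


def assemble_multiplex(
    mc: ConnectivityLayer, sc: ConnectivityLayer, fc: ConnectivityLayer,
    *, check_normalized: bool = True,
) -> MultiplexNetwork:
    """Stack normalized (MC, SC, FC) layers into a multiplex network."""
    expected = ("MC", "SC", "FC")
    layers = (mc, sc, fc)
    for lay, kind in zip(layers, expected):
        if lay.kind != kind:
            raise ValueError(f"expected layer order {expected}, got {lay.kind!r}")
    ref = mc.node_labels
    for lay in (sc, fc):
        if lay.node_labels != ref:
            diff = next(
                (f"{a!r} != {b!r}" for a, b in zip(ref, lay.node_labels) if a != b),
                "different lengths",
            )
            raise ValueError(f"node label mismatch in {lay.kind} layer: {diff}")
    if check_normalized:
        for lay in layers:
            top = float(np.linalg.norm(lay.weights, 2))
            if abs(top - 1.0) > 1e-8:
                raise ValueError(
                    f"{lay.kind} layer not SVD-normalized (top singular value {top:.6g})"
                )
    return MultiplexNetwork(layers=layers, node_labels=list(ref))
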