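"""Single-response PLS (NIPALS) regression and discriminant models.

The algorithm is the classic sequential-deflation NIPALS for one
response: per component ``a``,

    w_a ∝ Xᵀy (normalized)     t_a = X w_a
    p_a = Xᵀt_a / (t_aᵀt_a)    q_a = yᵀt_a / (t_aᵀt_a)
    X ← X − t_a p_aᵀ           y ← y − q_a t_a

on column-centered X and centered y (no column autoscaling — spectra
share units). For a single response each component is closed-form; no
convergence loop is needed. Predictions use the equivalent regression
vector B = W (PᵀW)⁻¹ q, so ŷ = ȳ + (X_new − x̄)·B.

The two production models are:

* PLS-R — cocaine mass percentage regressed on the ``plsr`` chain
  features, 4 components;
* PLS-DA — a 0/1 cocaine-presence indicator regressed on the ``plsda``
  chain features, 2 components.  The continuous prediction is what the
  decision rule thresholds.

Cross-validation is grouped: replicate scans of one sample always share
a segment, with whole groups dealt round-robin into (default) 10
segments after a seeded shuffle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, RankError, UsageError, ValidationError
from .preprocess import PLSDA_CHAIN, PLSR_CHAIN, PreprocessChain, \
    apply_chain_matrix
from .spectra_io import SpectrumSet

_TINY = 1e-12


@dataclass
class PLSModel:
    """A fitted PLS model in both component and regression-vector form."""

    ncomp: int
    x_weights: np.ndarray      # p × a
    x_loadings: np.ndarray     # p × a
    y_loadings: np.ndarray     # a
    x_center: np.ndarray       # p
    y_center: float
    chain_id: str = "plsr"
    regression_vector: np.ndarray = field(default=None)  # p
    explained_x_variance: np.ndarray = field(default=None)  # a, fractions

    @property
    def cumulative_explained_x_variance(self) -> float:
        return float(np.sum(self.explained_x_variance))

    def to_json(self) -> str:
        payload = {
            "format_version": 1,
            "ncomp": self.ncomp,
            "chain_id": self.chain_id,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_center": self.x_center.tolist(),
            "y_center": self.y_center,
            "regression_vector": self.regression_vector.tolist(),
            "explained_x_variance": self.explained_x_variance.tolist(),
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        d = json.loads(text)
        return cls(ncomp=int(d["ncomp"]),
                   x_weights=np.array(d["x_weights"]),
                   x_loadings=np.array(d["x_loadings"]),
                   y_loadings=np.array(d["y_loadings"]),
                   x_center=np.array(d["x_center"]),
                   y_center=float(d["y_center"]),
                   chain_id=d["chain_id"],
                   regression_vector=np.array(d["regression_vector"]),
                   explained_x_variance=np.array(d["explained_x_variance"]))


def _nipals(Xc: np.ndarray, yc: np.ndarray, ncomp: int):
    """Core NIPALS loop on pre-centered data; returns W, P, q, ssx."""
    n, p = Xc.shape
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    ssx = np.zeros(ncomp)
    X = Xc.copy()
    y = yc.copy()
    total_ssx = float((Xc**2).sum())
    for a in range(ncomp):
        w = X.T @ y
        wn = float(np.linalg.norm(w))
        if wn < _TINY * max(1.0, float(np.abs(y).sum())):
            raise RankError(
                f"component {a + 1}: X carries no remaining y-covariance "
                "(ncomp exceeds the data's rank)")
        w /= wn
        t = X @ w
        tt = float(t @ t)
        if tt < _TINY:
            raise RankError(f"component {a + 1}: degenerate score vector")
        pvec = (X.T @ t) / tt
        q[a] = float(y @ t) / tt
        X -= np.outer(t, pvec)
        y = y - q[a] * t
        W[:, a], P[:, a] = w, pvec
        ssx[a] = tt * float(pvec @ pvec) / total_ssx if total_ssx > 0 else 0.0
    return W, P, q, ssx


def _regression_vectors(W, P, q) -> np.ndarray:
    """B_k for every component count k; returns p × ncomp matrix."""
    p, ncomp = W.shape
    B = np.zeros((p, ncomp))
    for k in range(1, ncomp + 1):
        R = np.linalg.solve(P[:, :k].T @ W[:, :k], q[:k])
        B[:, k - 1] = W[:, :k] @ R
    return B


def fit_pls(X, y, ncomp: int, chain_id: str = "plsr") -> PLSModel:
    """Fit a single-response NIPALS PLS model (centering only)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise UsageError("X row count and y length differ")
    if n < 2:
        raise UsageError("need at least two observations")
    if ncomp < 1:
        raise UsageError("ncomp must be >= 1")
    if y.std() == 0:
        raise DegenerateInputError("constant response cannot be fitted")
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    Xc = X - x_center
    rank = np.linalg.matrix_rank(Xc)
    if ncomp > rank:
        raise RankError(f"ncomp={ncomp} exceeds rank(X)={rank}")
    W, P, q, ssx = _nipals(Xc, y - y_center, ncomp)
    B = _regression_vectors(W, P, q)
    return PLSModel(ncomp=ncomp, x_weights=W, x_loadings=P, y_loadings=q,
                    x_center=x_center, y_center=y_center, chain_id=chain_id,
                    regression_vector=B[:, -1], explained_x_variance=ssx)


def predict_pls(model: PLSModel, X_new) -> np.ndarray:
    """ŷ = ȳ + (X_new − x̄)·B for one or many rows."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_center.size:
        raise UsageError(
            f"expected {model.x_center.size} columns, got {X_new.shape[1]}")
    return model.y_center + (X_new - model.x_center) @ model.regression_vector


@dataclass
class CVResult:
    """Grouped cross-validation errors per component count."""

    rmsep_cv: np.ndarray                  # max_ncomp
    segment_assignment: dict[str, int]    # group -> segment index
    nseg: int

    @property
    def best_ncomp(self) -> int:
        return int(np.argmin(self.rmsep_cv)) + 1


def cross_validate_grouped(X, y, groups, nseg: int = 10,
                           max_ncomp: int = 10, seed: int = 0) -> CVResult:
    """Grouped segment CV: every group's rows stay in one segment.

    Distinct groups are shuffled with a seeded RNG and dealt round-robin
    into ``nseg`` segments; each observation is predicted exactly once
    while its segment is held out. ``rmsep_cv[k-1]`` is the root mean
    squared held-out prediction error using k components.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    if not (len(groups) == len(y) == X.shape[0]):
        raise UsageError("X, y and groups must agree in length")
    uniq = list(dict.fromkeys(groups.tolist()))  # stable order
    if nseg < 2:
        raise UsageError("nseg must be >= 2")
    if len(uniq) < nseg:
        raise ValidationError(
            f"{len(uniq)} groups cannot fill {nseg} segments")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    assignment = {uniq[int(g)]: int(i % nseg) for i, g in enumerate(order)}
    seg_of_row = np.array([assignment[g] for g in groups.tolist()])

    preds = np.full((len(y), max_ncomp), np.nan)
    for seg in range(nseg):
        held = seg_of_row == seg
        Xtr, ytr = X[~held], y[~held]
        xc = Xtr.mean(axis=0)
        yc = float(ytr.mean())
        W, P, q, _ = _nipals(Xtr - xc, ytr - yc, max_ncomp)
        B = _regression_vectors(W, P, q)
        preds[held] = yc + (X[held] - xc) @ B
    rmsep = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return CVResult(rmsep_cv=rmsep, segment_assignment=assignment, nseg=nseg)


def _labels(sset: SpectrumSet):
    y_wt = np.array([m.cocaine_wt_pct for m in sset.metas])
    y_cls = (y_wt > 0).astype(float)
    groups = np.array([m.sample_id for m in sset.metas])
    return y_wt, y_cls, groups


def fit_plsr_cocaine(trainset: SpectrumSet, ncomp: int = 4,
                     chain: PreprocessChain = PLSR_CHAIN) -> PLSModel:
    """Cocaine wt% regression on the ``plsr`` chain features."""
    if len(trainset) < 2:
        raise UsageError("training set needs at least two spectra")
    y_wt, _, _ = _labels(trainset)
    if y_wt.min() == y_wt.max():
        raise DegenerateInputError(
            "training wt% labels must span more than one value")
    X = apply_chain_matrix(trainset, chain)
    return fit_pls(X, y_wt, ncomp=ncomp, chain_id=chain.chain_id)


def fit_plsda_cocaine(trainset: SpectrumSet, ncomp: int = 2,
                      chain: PreprocessChain = PLSDA_CHAIN) -> PLSModel:
    """Cocaine-presence (0/1, both salt forms = 1) PLS-DA on the
    ``plsda`` chain features."""
    if len(trainset) < 2:
        raise UsageError("training set needs at least two spectra")
    _, y_cls, _ = _labels(trainset)
    if len(np.unique(y_cls)) < 2:
        raise DegenerateInputError(
            "training set must contain both cocaine and non-cocaine spectra")
    X = apply_chain_matrix(trainset, chain)
    return fit_pls(X, y_cls, ncomp=ncomp, chain_id=chain.chain_id)
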