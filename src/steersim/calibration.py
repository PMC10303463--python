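"""Post hoc Dirichlet calibration of class probabilities.

A Dirichlet calibration map transforms a probability vector q by

    mu(q; W, b) = softmax(W ln q + b)

with a k x k matrix W and k-vector b. The identity map (W = I, b = 0)
reproduces its input exactly. The map is fitted on a held-out calibration
split by minimising the mean multinomial negative log-likelihood of the true
pixel classes, treating pixels as independent instances.

Calibration quality is summarised with per-class reliability tables
(equal-width probability bins; the last bin is right-closed so p = 1 falls in
bin m) and the classwise expected calibration error: the mean over classes of
the bin-weighted absolute gap between mean predicted probability and the
observed positive fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError, InvalidParameterError
from .segmentation import ProbabilityMap, softmax

_EPS = 1e-12


@dataclass
class CalibrationMap:
    W: np.ndarray                       # (k, k)
    b: np.ndarray                       # (k,)
    fit_info: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.W.shape[0]

    @classmethod
    def identity(cls, k: int = 4) -> "CalibrationMap":
        return cls(W=np.eye(k), b=np.zeros(k))


def _apply(W: np.ndarray, b: np.ndarray, q: np.ndarray) -> np.ndarray:
    logq = np.log(np.clip(q, _EPS, None))
    return softmax(logq @ W.T + b, axis=-1)


def apply_calibration(cal_map: CalibrationMap, prob_map) -> ProbabilityMap:
    """Apply ``softmax(W ln q + b)`` per pixel.

    Accepts a :class:`ProbabilityMap` or a bare (..., k) probability array;
    probabilities are clamped at 1e-12 before the logarithm.
    """
    if isinstance(prob_map, ProbabilityMap):
        q, pid = prob_map.probs, prob_map.phantom_id
    else:
        q, pid = np.asarray(prob_map, dtype=np.float64), None
    if q.shape[-1] != cal_map.k:
        raise ConfigurationError(
            f"map has k={cal_map.k} but probabilities have {q.shape[-1]}")
    return ProbabilityMap(probs=_apply(cal_map.W, cal_map.b, q),
                          phantom_id=pid, calibrated=True)


def _gather_pixels(prob_maps, targets, max_pixels, seed):
    qs, ys = [], []
    for pm, t in zip(prob_maps, targets):
        q = pm.probs if isinstance(pm, ProbabilityMap) else np.asarray(pm)
        qs.append(q.reshape(-1, q.shape[-1]))
        ys.append(np.asarray(t).reshape(-1))
    q = np.concatenate(qs)
    y = np.concatenate(ys).astype(int)
    if max_pixels is not None and y.size > max_pixels:
        # stratified subsample: preserve per-class proportions, keep rare
        # classes represented
        rng = np.random.default_rng(seed)
        keep = []
        frac = max_pixels / y.size
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            take = max(int(round(idx.size * frac)), min(idx.size, 100))
            keep.append(rng.choice(idx, size=take, replace=False))
        keep = np.concatenate(keep)
        q, y = q[keep], y[keep]
    return q, y


def fit_dirichlet(prob_maps, targets, max_pixels: int | None = 200_000,
                  seed: int = 0, odir_lambda: float = 0.0,
                  gtol: float = 1e-6, max_iter: int = 500) -> CalibrationMap:
    """Fit (W, b) by gradient optimisation of the multinomial NLL from (I, 0).

    ``prob_maps``/``targets`` are parallel sequences of probability maps and
    integer class maps from the calibration split; pixels are pooled and
    (optionally) subsampled with per-class stratification. If a class is
    absent from the split its targets are label-smoothed so the fit stays
    well-posed. The fitted map never has higher calibration-split NLL than
    the identity map.
    """
    q, y = _gather_pixels(prob_maps, targets, max_pixels, seed)
    k = q.shape[-1]
    n = y.size
    Y = np.eye(k)[y]
    present = np.unique(y)
    if present.size < k:
        warnings.warn(
            f"classes {sorted(set(range(k)) - set(present))} absent from the "
            "calibration split; applying label smoothing", stacklevel=2)
        Y = 0.99 * Y + 0.01 / k

    logq = np.log(np.clip(q, _EPS, None))

    def objective(theta):
        W = theta[:k * k].reshape(k, k)
        b = theta[k * k:]
        z = logq @ W.T + b
        z -= z.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        nll = -np.sum(Y * logp) / n
        p = np.exp(logp)
        d = (p - Y) / n                       # (n, k)
        gW = d.T @ logq
        gb = d.sum(axis=0)
        if odir_lambda > 0:
            off = W - np.diag(np.diag(W))
            nll += odir_lambda * (np.sum(off ** 2) + np.sum(b ** 2))
            gW += 2 * odir_lambda * off
            gb += 2 * odir_lambda * b
        return nll, np.concatenate([gW.ravel(), gb])

    theta0 = np.concatenate([np.eye(k).ravel(), np.zeros(k)])
    nll0 = objective(theta0)[0]
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"gtol": gtol, "maxiter": max_iter})
    theta = res.x if res.fun <= nll0 else theta0
    return CalibrationMap(
        W=theta[:k * k].reshape(k, k).copy(), b=theta[k * k:].copy(),
        fit_info={"nll_identity": float(nll0),
                  "nll_fitted": float(min(res.fun, nll0)),
                  "n_pixels": int(n), "converged": bool(res.success)})


@dataclass
class ReliabilityTable:
    """One-vs-rest reliability statistics for a single class.

    Equal-width bins over [0, 1]; the last bin is right-closed. Empty bins
    have size 0 and contribute nothing to the calibration error.
    """

    m: int
    bin_size: np.ndarray       # (m,) int, sums to n
    mean_pred: np.ndarray      # (m,) mean predicted probability per bin
    frac_pos: np.ndarray       # (m,) observed positive fraction per bin
    n: int


def reliability_binning(class_probs, one_vs_rest_labels,
                        m: int = 10) -> ReliabilityTable:
    """Bin one class's predicted probabilities against observed outcomes."""
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    p = np.asarray(class_probs, dtype=np.float64).ravel()
    y = np.asarray(one_vs_rest_labels).ravel().astype(np.float64)
    idx = np.minimum((p * m).astype(int), m - 1)   # p = 1.0 -> last bin
    size = np.bincount(idx, minlength=m)
    sum_p = np.bincount(idx, weights=p, minlength=m)
    sum_y = np.bincount(idx, weights=y, minlength=m)
    safe = np.maximum(size, 1)
    return ReliabilityTable(m=m, bin_size=size,
                            mean_pred=sum_p / safe, frac_pos=sum_y / safe,
                            n=int(p.size))


def classwise_ece(tables: list[ReliabilityTable]) -> float:
    """Mean over classes of the bin-weighted |observed - predicted| gap."""
    if not tables:
        raise InvalidParameterError("need at least one reliability table")
    n = tables[0].n
    m = tables[0].m
    for t in tables:
        if t.n != n or t.m != m:
            raise InvalidParameterError(
                "all per-class tables must share n and m")
    k = len(tables)
    total = 0.0
    for t in tables:
        total += np.sum(t.bin_size / n * np.abs(t.frac_pos - t.mean_pred))
    return float(total / k)


def classwise_ece_from(probs: np.ndarray, targets: np.ndarray,
                       m: int = 10) -> float:
    """classwise-ECE straight from pooled (..., k) probabilities and targets."""
    probs = np.asarray(probs, dtype=np.float64)
    k = probs.shape[-1]
    flat_p = probs.reshape(-1, k)
    flat_y = np.asarray(targets).reshape(-1)
    tables = [reliability_binning(flat_p[:, j], flat_y == j, m)
              for j in range(k)]
    return classwise_ece(tables)


def plot_reliability(tables, path, class_names=None):
    """Render per-class reliability diagrams to ``path`` (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(tables)
    fig, axes = plt.subplots(1, k, figsize=(3 * k, 3), squeeze=False)
    for j, (ax, t) in enumerate(zip(axes[0], tables)):
        centers = (np.arange(t.m) + 0.5) / t.m
        occ = t.bin_size > 0
        ax.bar(centers[occ], t.frac_pos[occ], width=0.9 / t.m,
               color="tab:blue", alpha=0.7)
        ax.plot([0, 1], [0, 1], "k--", lw=1)
        name = class_names[j] if class_names else f"class {j}"
        ax.set_title(name, fontsize=9)
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
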