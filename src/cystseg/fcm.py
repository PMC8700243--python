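"""Fuzzy C-Means quantization of image intensities.

Standard Bezdek alternating optimization in the 1-D intensity feature space.
Given data ``x_k`` (optionally with non-negative weights ``w_k``, used for
histogram-accelerated fitting where each distinct intensity carries its pixel
count), cluster count ``c`` and fuzzifier ``m > 1``, the updates are

    v_i  = sum_k w_k u_ik^m x_k / sum_k w_k u_ik^m
    d_ik = |x_k - v_i|
    u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))

iterated from a seeded random column-stochastic membership matrix ``U(0)``
until ``max |U(r+1) - U(r)| < tol`` or the iteration cap.  Pixels coinciding
with a centroid (zero distance) receive crisp membership on the coincident
cluster(s).  The fuzzified objective

    J_m = sum_i sum_k w_k u_ik^m d_ik^2

is non-increasing across iterations, which tests assert at every step.
Centroids are sorted ascending on return (membership rows permuted to match)
so that cluster index 0 is always the darkest cluster.

Weighted fitting on distinct intensities is mathematically identical to
per-pixel fitting because every update depends on pixels only through their
intensity value; it reduces the data size from W*H to at most 256.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError

__all__ = ["FcmConfig", "FcmState", "fcm_fit", "fcm_fit_image", "quantize", "fcm_objective"]

_ZERO = 1e-12


@dataclass(frozen=True)
class FcmConfig:
    """Parameters of one FCM fit.

    Parameters
    ----------
    c : int
        Cluster count, ``2 <= c < n``.
    m : float
        Fuzzifier, ``> 1``; 2 is the conventional default.
    tol : float
        Termination threshold on the max absolute membership change.
    max_iter : int
        Iteration cap; exceeding it flags the state ``converged=False``
        rather than raising.
    seed : int
        Seed for the random initial membership matrix.
    """

    c: int
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("c must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FcmState:
    """Converged (or capped) fit: sorted centroids plus diagnostics."""

    centroids: np.ndarray  # (c,) ascending
    membership: np.ndarray  # (c, n) columns sum to 1
    distances: np.ndarray  # (c, n)
    values: np.ndarray  # (n,) the fitted data
    weights: np.ndarray  # (n,)
    config: FcmConfig
    iterations: int
    converged: bool
    objective: np.ndarray = field(default_factory=lambda: np.empty(0))


def _memberships(x: np.ndarray, v: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix of data *x* against centroids *v* (zero-distance crisp)."""
    d = np.abs(x[None, :] - v[:, None])
    zero = d <= _ZERO
    safe = np.where(zero, 1.0, d)
    w = safe ** (-2.0 / (m - 1.0))
    u = w / w.sum(axis=0, keepdims=True)
    zcols = zero.any(axis=0)
    if zcols.any():
        z = zero[:, zcols].astype(np.float64)
        u[:, zcols] = z / z.sum(axis=0, keepdims=True)
    return u


def fcm_objective(u: np.ndarray, d: np.ndarray, w: np.ndarray, m: float) -> float:
    """Fuzzified within-cluster scatter J_m = sum w u^m d^2."""
    return float(((u**m) * d**2 * w[None, :]).sum())


def fcm_fit(values, cfg: FcmConfig, weights=None) -> FcmState:
    """Fit FCM to 1-D *values* (optionally weighted).

    Raises :class:`DegenerateDataError` when the data carry fewer than
    ``cfg.c`` distinct values.  Never raises on non-convergence: the returned
    state is flagged ``converged=False`` at the iteration cap.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=np.float64).ravel()
        if w.shape != x.shape:
            raise ValueError("weights must match values in shape")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
    if np.unique(x[w > 0] if weights is not None else x).size < cfg.c:
        raise DegenerateDataError(
            f"need at least c={cfg.c} distinct values to fit {cfg.c} clusters"
        )

    rng = np.random.default_rng(cfg.seed)
    c, n, m = cfg.c, x.size, cfg.m
    U = rng.random((c, n))
    U /= U.sum(axis=0, keepdims=True)
    v = np.empty(c)
    obj: list[float] = []
    converged = False
    it = 0
    d = np.abs(x[None, :] - v[:, None])
    for it in range(1, cfg.max_iter + 1):
        um = U**m
        den = um @ w
        num = um @ (w * x)
        ok = den > 0
        v[ok] = num[ok] / den[ok]  # rows with vanished membership keep old v
        d = np.abs(x[None, :] - v[:, None])
        U_new = _memberships(x, v, m)
        obj.append(fcm_objective(U_new, d, w, m))
        diff = float(np.max(np.abs(U_new - U)))
        U = U_new
        if diff < cfg.tol:
            converged = True
            break

    order = np.argsort(v, kind="stable")
    return FcmState(
        centroids=v[order],
        membership=U[order],
        distances=d[order],
        values=x,
        weights=w,
        config=cfg,
        iterations=it,
        converged=converged,
        objective=np.asarray(obj),
    )


def fcm_fit_image(img: np.ndarray, cfg: FcmConfig) -> tuple[FcmState, np.ndarray]:
    """Histogram-accelerated fit on an image; returns (state, label map)."""
    img = np.asarray(img)
    counts = np.bincount(img.ravel(), minlength=256)
    vals = np.flatnonzero(counts)
    state = fcm_fit(vals.astype(np.float64), cfg, weights=counts[vals])
    return state, quantize(img, state)


def quantize(img: np.ndarray, state: FcmState) -> np.ndarray:
    """Label each pixel with its argmax-membership cluster.

    Centroids are sorted ascending, and ``np.argmax`` returns the first
    maximum, so exact membership ties resolve toward the darker cluster.
    """
    lut_u = _memberships(np.arange(256, dtype=np.float64), state.centroids, state.config.m)
    lut = np.argmax(lut_u, axis=0).astype(np.uint8)
    return lut[np.asarray(img)]
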