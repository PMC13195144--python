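"""Distance and dependence primitives between organ SUV distributions.

The energy distance between two weighted scalar samples is the weighted
V-statistic

    E(P, Q) = 2 E|X - Y| - E|X - X'| - E|Y - Y'|

computed here in O((n+m) log(n+m)) from CDF differences: for step CDFs F
and G, E|X - Y| = integral of F + G - 2 F G over the merged support.

Mutual information between two organs of the same subject is estimated on
a position-paired sample (both organs resampled at common cranio-caudal
axis quantiles), rank-transformed, and binned into an equal-mass 2-D
histogram with Miller-Madow bias correction; the result is normalized to
[0, 1] by the smaller marginal entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrganDistribution",
    "energy_distance",
    "mutual_information",
    "normalized_mi_from_pairs",
    "corrected_distance",
    "similarity",
]

_MIN_MI_POINTS = 32


def _check_sample(values: np.ndarray, weights: np.ndarray | None, name: str):
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError(f"{name}: empty sample")
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float).ravel()
        if weights.shape != values.shape:
            raise ValueError(f"{name}: weights shape mismatch")
        if np.any(weights <= 0):
            raise ValueError(f"{name}: weights must be positive")
    return values, weights / weights.sum()


def _mean_abs_diff(x, px, y, py) -> float:
    """E|X - Y| for weighted step distributions, via CDF integration."""
    t = np.concatenate([x, y])
    order = np.argsort(t, kind="stable")
    t = t[order]
    # jumps of F and G at each merged point
    jf = np.concatenate([px, np.zeros_like(py)])[order]
    jg = np.concatenate([np.zeros_like(px), py])[order]
    F = np.cumsum(jf)
    G = np.cumsum(jg)
    dt = np.diff(t)
    integrand = F[:-1] + G[:-1] - 2.0 * F[:-1] * G[:-1]
    return float(np.sum(integrand * dt))


def energy_distance(
    x: np.ndarray,
    y: np.ndarray,
    x_weights: np.ndarray | None = None,
    y_weights: np.ndarray | None = None,
) -> float:
    """Weighted two-sample energy distance between 1-D samples.

    Weights are normalized to probabilities; unweighted samples get unit
    weights. Symmetric in its arguments and zero iff the two weighted
    distributions coincide.
    """
    x, px = _check_sample(x, x_weights, "x")
    y, py = _check_sample(y, y_weights, "y")
    return max(
        0.0,
        2.0 * _mean_abs_diff(x, px, y, py)
        - _mean_abs_diff(x, px, x, px)
        - _mean_abs_diff(y, py, y, py),
    )


@dataclass
class OrganDistribution:
    """Weighted scalar SUV sample of one organ plus its axial profile.

    ``axis_rank`` is the normalized cranio-caudal CDF position of each
    point in [0, 1]; it defines the subject-internal spatial
    correspondence used when pairing two organs for mutual information.
    """

    organ: str
    values: np.ndarray
    weights: np.ndarray
    axis_rank: np.ndarray

    def __post_init__(self) -> None:
        self.values, self.weights = _check_sample(self.values, self.weights, self.organ)
        self.axis_rank = np.asarray(self.axis_rank, dtype=float).ravel()
        if self.axis_rank.shape != self.values.shape:
            raise ValueError(f"{self.organ}: axis_rank shape mismatch")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.values.min()), float(self.values.max())

    @classmethod
    def from_points(
        cls, organ: str, values, z_positions, weights=None
    ) -> "OrganDistribution":
        """Build from raw points; axis rank is the weighted CDF of z."""
        values = np.asarray(values, dtype=float).ravel()
        z = np.asarray(z_positions, dtype=float).ravel()
        w = np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)
        order = np.argsort(z, kind="stable")
        cum = np.cumsum(w[order]) - w[order] / 2.0
        rank = np.empty(len(values), dtype=float)
        rank[order] = cum / w.sum()
        return cls(organ, values, w, rank)

    def resample_on_axis(self, n_quantiles: int) -> np.ndarray:
        """SUV profile sampled at `n_quantiles` equal axis quantiles."""
        order = np.argsort(self.axis_rank, kind="stable")
        cw = np.cumsum(self.weights[order])
        cw /= cw[-1]
        grid = (np.arange(n_quantiles) + 0.5) / n_quantiles
        idx = np.searchsorted(cw, grid, side="left")
        return self.values[order][np.clip(idx, 0, len(cw) - 1)]


def normalized_mi_from_pairs(u: np.ndarray, v: np.ndarray, bins: int = 16) -> float:
    """Normalized MI of a paired sample via equal-mass rank histograms.

    Both margins are rank-transformed and cut into `bins` equal-count
    bins, making the estimate invariant to strictly monotone rescaling of
    either variable. The plug-in entropy estimate gets a Miller-Madow
    correction; the result is divided by the smaller marginal entropy and
    clamped to [0, 1].
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    n = len(u)
    if len(v) != n:
        raise ValueError("paired samples must have equal length")
    if n < _MIN_MI_POINTS:
        raise ValueError(f"need at least {_MIN_MI_POINTS} paired points, got {n}")

    def equal_mass_bins(a: np.ndarray) -> np.ndarray:
        order = np.argsort(a, kind="stable")
        b = np.empty(n, dtype=np.int64)
        b[order] = (np.arange(n) * bins) // n
        return b

    bu, bv = equal_mass_bins(u), equal_mass_bins(v)
    joint = np.bincount(bu * bins + bv, minlength=bins * bins).astype(float)
    pj = joint / n
    pu = np.bincount(bu, minlength=bins).astype(float) / n
    pv = np.bincount(bv, minlength=bins).astype(float) / n

    nz = pj > 0
    outer = np.outer(pu, pv).ravel()
    mi = float(np.sum(pj[nz] * np.log(pj[nz] / outer[nz])))
    # Miller-Madow correction of the plug-in joint/marginal entropies
    k_joint = int(nz.sum())
    k_u = int((pu > 0).sum())
    k_v = int((pv > 0).sum())
    mi -= (k_joint - k_u - k_v + 1) / (2.0 * n)

    h_u = float(-np.sum(pu[pu > 0] * np.log(pu[pu > 0])))
    h_v = float(-np.sum(pv[pv > 0] * np.log(pv[pv > 0])))
    h_min = min(h_u, h_v)
    if h_min <= 0:
        return 0.0
    return float(np.clip(mi / h_min, 0.0, 1.0))


def mutual_information(
    p: OrganDistribution, q: OrganDistribution, n_quantiles: int = 1024, bins: int = 16
) -> float:
    """Normalized MI between two organs paired by matched axis quantiles."""
    for dist in (p, q):
        if len(dist.values) < _MIN_MI_POINTS:
            raise ValueError(
                f"{dist.organ}: {len(dist.values)} points < {_MIN_MI_POINTS}, "
                "MI estimate unreliable"
            )
    return normalized_mi_from_pairs(
        p.resample_on_axis(n_quantiles), q.resample_on_axis(n_quantiles), bins=bins
    )


def corrected_distance(
    d: float, mi: float, alpha: float, *, allow_alpha_one: bool = False
) -> float:
    """MI-corrected distance D* = D (1 - alpha * MI).

    ``alpha`` must lie in [0, 1); alpha = 1 is accepted only with
    ``allow_alpha_one``, in which case MI is clipped strictly below 1 so
    the corrected distance stays positive for distinct distributions.
    """
    if not 0.0 <= alpha < 1.0:
        if alpha == 1.0 and allow_alpha_one:
            mi = min(mi, 1.0 - 1e-6)
        else:
            raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if d < 0:
        raise ValueError("distance must be >= 0")
    if not 0.0 <= mi <= 1.0:
        raise ValueError(f"MI must be in [0, 1], got {mi}")
    return d * (1.0 - alpha * mi)


def similarity(d_star: float) -> float:
    """Exponential similarity exp(-D*), mapping [0, inf) onto (0, 1]."""
    if d_star < 0:
        raise ValueError("corrected distance must be >= 0")
    return float(np.exp(-d_star))
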