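"""Individual deviation from a control cohort: KDE residual networks.

For each connectome edge a Gaussian-kernel density is fitted on the
control cohort's values. A subject's edge value c gets an extremeness
probability from the KDE CDF and a signed residue

    r = sign(control_mean - c) * (1 - p^kappa),      0 < kappa <= 1,

where small kappa emphasizes rare values. By default p is the two-sided
extremeness 2 min(F(c), 1 - F(c)); the literal one-sided CDF is available
behind ``two_sided=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._rng import child_rng
from .connectome.build import Connectome

__all__ = [
    "EdgeDensityModel",
    "ResidualNetwork",
    "fit_control_model",
    "edge_extremeness",
    "residual",
    "residual_network",
    "sum_abs_residuals",
    "split_controls",
    "welch_compare",
    "group_residual_contrast",
]

_BANDWIDTH_FLOOR = 1e-6


@dataclass
class EdgeDensityModel:
    """Per-edge control KDE: values (E, n_controls), bandwidths, means."""

    roi_names: tuple[str, ...]
    edge_pairs: list[tuple[int, int]]
    values: np.ndarray
    bandwidths: np.ndarray
    means: np.ndarray
    two_sided: bool = True

    @property
    def n_controls(self) -> int:
        return self.values.shape[1]

    def edge_id(self, edge: tuple[int, int] | tuple[str, str]) -> int:
        i, j = edge
        if isinstance(i, str):
            try:
                i, j = self.roi_names.index(i), self.roi_names.index(j)
            except ValueError:
                raise KeyError(f"unknown edge {edge}") from None
        i, j = (i, j) if i < j else (j, i)
        try:
            return self.edge_pairs.index((i, j))
        except ValueError:
            raise KeyError(f"unknown edge {edge}") from None


def _silverman(values: np.ndarray) -> float:
    sd = float(np.std(values, ddof=1))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    sigma = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 1.06 * sigma * len(values) ** (-0.2)


def fit_control_model(controls: list[Connectome], two_sided: bool = True) -> EdgeDensityModel:
    """Fit the per-edge Gaussian-KDE control model (Silverman bandwidths)."""
    if len(controls) < 5:
        raise ValueError("need at least 5 control connectomes")
    names = controls[0].roi_names
    for c in controls[1:]:
        if c.roi_names != names:
            raise ValueError("control connectomes have mismatched ROI sets")
    iu, ju = np.triu_indices(len(names), k=1)
    pairs = list(zip(iu.tolist(), ju.tolist()))
    values = np.stack([c.C[iu, ju] for c in controls], axis=1)
    bw = np.array([_silverman(v) for v in values])
    degenerate = bw < _BANDWIDTH_FLOOR
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate edges; bandwidth floored at {_BANDWIDTH_FLOOR}",
            stacklevel=2,
        )
        bw = np.maximum(bw, _BANDWIDTH_FLOOR)
    return EdgeDensityModel(names, pairs, values, bw, values.mean(axis=1), two_sided)


def _kde_cdf(model: EdgeDensityModel, edge_id: int, c: float) -> float:
    return float(
        np.mean(stats.norm.cdf((c - model.values[edge_id]) / model.bandwidths[edge_id]))
    )


def edge_extremeness(model: EdgeDensityModel, edge, c: float) -> float:
    """Probability for `c` to be as extreme under the edge's control KDE."""
    eid = model.edge_id(edge) if not isinstance(edge, (int, np.integer)) else int(edge)
    if not 0 <= eid < len(model.edge_pairs):
        raise KeyError(f"unknown edge {edge}")
    f = _kde_cdf(model, eid, c)
    if model.two_sided:
        return float(np.clip(2.0 * min(f, 1.0 - f), 0.0, 1.0))
    return float(np.clip(f, 0.0, 1.0))


def residual(model: EdgeDensityModel, edge, c: float, kappa: float) -> float:
    """Signed extremeness residue r = sign(m - c) (1 - p^kappa) in [-1, 1]."""
    if not 0.0 < kappa <= 1.0:
        raise ValueError(f"kappa must be in (0, 1], got {kappa}")
    eid = model.edge_id(edge) if not isinstance(edge, (int, np.integer)) else int(edge)
    p = edge_extremeness(model, eid, c)
    return float(np.sign(model.means[eid] - c) * (1.0 - p**kappa))


@dataclass
class ResidualNetwork:
    """Signed edge extremeness of one subject vs the control model."""

    roi_names: tuple[str, ...]
    r: np.ndarray
    kappa: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("|r| must be <= 1")
        if not np.allclose(self.r, self.r.T):
            raise ValueError("residual matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 0.0):
            raise ValueError("residual diagonal must be 0")


def residual_network(
    subject: Connectome, model: EdgeDensityModel, kappa: float
) -> ResidualNetwork:
    """Residual network of one subject's connectome against the model."""
    if subject.roi_names != model.roi_names:
        missing = sorted(set(model.roi_names) ^ set(subject.roi_names))
        raise ValueError(f"ROI set mismatch, differing ROIs: {missing}")
    n = len(model.roi_names)
    r = np.zeros((n, n))
    for eid, (i, j) in enumerate(model.edge_pairs):
        r[i, j] = r[j, i] = residual(model, eid, float(subject.C[i, j]), kappa)
    return ResidualNetwork(model.roi_names, r, kappa, subject.subject_id)


def sum_abs_residuals(rn: ResidualNetwork) -> float:
    """Sum of |r| over unordered off-diagonal ROI pairs (each counted once)."""
    iu, ju = np.triu_indices(len(rn.roi_names), k=1)
    return float(np.abs(rn.r[iu, ju]).sum())


def split_controls(controls: list, n_holdout: int = 10, seed: int = 0) -> tuple[list, list]:
    """Seeded disjoint split into (fit controls, held-out controls)."""
    if n_holdout >= len(controls):
        raise ValueError(f"n_holdout={n_holdout} >= cohort size {len(controls)}")
    order = child_rng(seed, "split_controls").permutation(len(controls))
    holdout = set(order[:n_holdout].tolist())
    fit = [c for i, c in enumerate(controls) if i not in holdout]
    other = [c for i, c in enumerate(controls) if i in holdout]
    return fit, other


def welch_compare(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t-test; returns (t, two-tailed p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.inf if np.mean(a) > np.mean(b) else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def group_residual_contrast(
    group_a: list[ResidualNetwork], group_b: list[ResidualNetwork]
) -> np.ndarray:
    """Elementwise squared difference of the two groups' mean residuals."""
    names = group_a[0].roi_names
    for rn in [*group_a, *group_b]:
        if rn.roi_names != names:
            raise ValueError("mismatched ROI sets")
    mean_a = np.mean([rn.r for rn in group_a], axis=0)
    mean_b = np.mean([rn.r for rn in group_b], axis=0)
    return (mean_a - mean_b) ** 2
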