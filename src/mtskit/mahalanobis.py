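"""Mahalanobis reference space: fitting, distance scoring, and refinement.

The reference ("Mahalanobis") space is fitted from healthy subjects only:
per-variable sample mean and SD, plus the Pearson correlation matrix of the
standardized variables and its inverse.  A subject's squared Mahalanobis
distance is

    MD = z' C^{-1} z / k,        z_i = (x_i - mean_i) / sd_i,

scaled by the number of variables k so the healthy-group average sits near
one (exactly (n-1)/n when scored on the construction sample itself).  The
unscaled form (no /k) is available for callers who want the classical
quadratic form.

Refinement screens outlying healthy subjects with an individuals/moving-
range (XmR) control chart: subjects whose MD exceeds T = mu + 2.66 * Rbar
are removed and the space is refitted on the survivors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import ContractError, FitError, NumericError, RefinementError
from .io_config import FeatureTable

__all__ = [
    "MahalanobisSpace",
    "MDSeries",
    "RefinementResult",
    "XMR_CONSTANT",
    "fit_space",
    "compute_md",
    "refine_space",
    "xmr_limits",
]

#: Upper-control-limit constant of the individuals/moving-range chart
#: (3 / d2 with d2 = 1.128 for subgroups of size 2).
XMR_CONSTANT: float = 2.66


@dataclass
class MahalanobisSpace:
    """Fitted healthy reference space.

    ``correlation_inverse`` is a plain inverse unless the correlation
    matrix's condition number exceeded the configured bound (or n <= k), in
    which case it is a Moore-Penrose pseudo-inverse and ``pseudo_inverse``
    is set.
    """

    variable_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    correlation: np.ndarray
    correlation_inverse: np.ndarray
    n_construction: int
    pseudo_inverse: bool = False

    @property
    def k(self) -> int:
        return len(self.variable_names)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.correlation_inverse = np.asarray(self.correlation_inverse, dtype=float)
        k = self.k
        if self.correlation.shape != (k, k):
            raise ContractError("correlation matrix shape does not match variable count")
        if np.any(self.sds <= 0):
            raise FitError("all per-variable SDs must be strictly positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variable_names": self.variable_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "correlation": self.correlation.tolist(),
            "correlation_inverse": self.correlation_inverse.tolist(),
            "n_construction": self.n_construction,
            "pseudo_inverse": self.pseudo_inverse,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MahalanobisSpace":
        raw = json.loads(Path(path).read_text())
        return cls(
            variable_names=list(raw["variable_names"]),
            means=np.asarray(raw["means"], dtype=float),
            sds=np.asarray(raw["sds"], dtype=float),
            correlation=np.asarray(raw["correlation"], dtype=float),
            correlation_inverse=np.asarray(raw["correlation_inverse"], dtype=float),
            n_construction=int(raw["n_construction"]),
            pseudo_inverse=bool(raw["pseudo_inverse"]),
        )


@dataclass
class MDSeries:
    """Mahalanobis distances of a set of subjects against one space."""

    values: np.ndarray
    space: MahalanobisSpace
    scaled: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class RefinementResult:
    """Outcome of XmR-chart screening of the construction sample.

    ``threshold_T``, ``md_mean_mu`` and ``mean_moving_range_Rbar`` describe
    the final pass; ``removed_indices`` are positional indices into the
    original construction table, cumulative over passes.
    """

    threshold_T: float
    md_mean_mu: float
    mean_moving_range_Rbar: float
    removed_indices: list[int] = field(default_factory=list)
    passes: int = 1

    @property
    def n_removed(self) -> int:
        return len(self.removed_indices)

    def to_dict(self) -> dict:
        return {
            "threshold_T": self.threshold_T,
            "md_mean_mu": self.md_mean_mu,
            "mean_moving_range_Rbar": self.mean_moving_range_Rbar,
            "n_removed": self.n_removed,
            "removed_indices": list(self.removed_indices),
            "passes": self.passes,
        }


def fit_space(
    normal: FeatureTable,
    variables: Sequence[str] | None = None,
    condition_bound: float = 1e10,
) -> MahalanobisSpace:
    """Fit the reference space from healthy data on ``variables``.

    Means and SDs use the n-1 denominator; the correlation matrix is the
    Pearson correlation of the standardized columns.  A zero-variance
    variable raises :class:`FitError` naming it.  When n <= k or the
    correlation matrix is ill-conditioned, a pseudo-inverse is used and a
    warning emitted.
    """
    variables = list(variables) if variables is not None else normal.variable_names
    sub = normal.select(variables)
    if sub.has_missing():
        raise ContractError("fit_space requires complete rows")
    X = sub.values
    n, k = X.shape
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = [v for v, s in zip(variables, sds) if s == 0.0]
    if dead:
        raise FitError(f"zero-variance variable(s): {dead}")

    if k == 1:
        corr = np.array([[1.0]])
    else:
        corr = np.corrcoef(X, rowvar=False)

    pseudo = False
    if n <= k:
        warnings.warn(
            f"n={n} <= k={k}: correlation matrix is singular, using pseudo-inverse",
            stacklevel=2,
        )
        pseudo = True
    elif np.linalg.cond(corr) > condition_bound:
        warnings.warn(
            "near-singular correlation matrix; using pseudo-inverse",
            stacklevel=2,
        )
        pseudo = True
    inv = np.linalg.pinv(corr) if pseudo else np.linalg.inv(corr)

    return MahalanobisSpace(
        variable_names=list(variables),
        means=means,
        sds=sds,
        correlation=corr,
        correlation_inverse=inv,
        n_construction=n,
        pseudo_inverse=pseudo,
    )


def compute_md(space: MahalanobisSpace, table: FeatureTable, scaled: bool = True) -> MDSeries:
    """Score every subject in ``table`` against ``space``.

    Returns the (optionally k-scaled) quadratic form of the standardized
    subject vector under the inverse correlation matrix.  Tiny negative
    values from pseudo-inverse round-off are clipped to zero; genuinely
    non-finite output raises :class:`NumericError`.
    """
    missing = [v for v in space.variable_names if v not in table.data.columns]
    if missing:
        raise ContractError(f"table lacks space variables: {missing}")
    sub = table.select(space.variable_names)
    if sub.has_missing():
        raise ContractError("compute_md requires complete rows")
    Z = (sub.values - space.means) / space.sds
    md = np.einsum("ij,jk,ik->i", Z, space.correlation_inverse, Z)
    if scaled:
        md = md / space.k
    if not np.all(np.isfinite(md)):
        raise NumericError("non-finite Mahalanobis distance (degenerate inverse?)")
    if np.any(md < -1e-8):
        raise NumericError("substantially negative Mahalanobis distance")
    return MDSeries(np.clip(md, 0.0, None), space, scaled)


def xmr_limits(values: np.ndarray) -> tuple[float, float, float]:
    """Individuals/moving-range chart summary of a series, in order.

    Returns (mu, Rbar, T) where mu is the series mean, Rbar the mean of
    absolute successive differences, and T = mu + 2.66 * Rbar the upper
    control limit.  A single observation has Rbar = 0.
    """
    values = np.asarray(values, dtype=float)
    mu = float(values.mean())
    rbar = float(np.abs(np.diff(values)).mean()) if values.size > 1 else 0.0
    return mu, rbar, mu + XMR_CONSTANT * rbar


def refine_space(
    normal: FeatureTable,
    variables: Sequence[str] | None = None,
    max_passes: int = 1,
    condition_bound: float = 1e10,
    scaled: bool = True,
) -> tuple[MahalanobisSpace, RefinementResult]:
    """Fit, screen outliers with the XmR control limit, and refit.

    Each pass fits the space on the current construction set, scores those
    same subjects in input row order, and removes every subject with
    MD strictly above T = mu + 2.66 * Rbar.  Passes stop when nothing is
    removed or ``max_passes`` is reached.  The moving range is order-
    dependent (inherent to XmR charts); input row order is used.
    """
    if max_passes < 1:
        raise ContractError("max_passes must be at least 1")
    variables = list(variables) if variables is not None else normal.variable_names
    current = normal.select(variables)
    original_pos = np.arange(current.n_subjects)
    removed: list[int] = []
    mu = rbar = T = float("nan")
    passes = 0
    for _ in range(max_passes):
        passes += 1
        k = len(variables)
        if current.n_subjects < k + 2:
            raise RefinementError(
                f"only {current.n_subjects} subjects left for k={k} variables"
            )
        space = fit_space(current, variables, condition_bound)
        md = compute_md(space, current, scaled=scaled).values
        mu, rbar, T = xmr_limits(md)
        out = md > T
        if not out.any():
            break
        removed.extend(int(i) for i in original_pos[out])
        keep = ~out
        current = FeatureTable(current.data.loc[keep].copy(), current.group)
        original_pos = original_pos[keep]
    if current.n_subjects < len(variables) + 2:
        raise RefinementError(
            f"only {current.n_subjects} subjects left for k={len(variables)} variables"
        )
    space = fit_space(current, variables, condition_bound)
    result = RefinementResult(
        threshold_T=T,
        md_mean_mu=mu,
        mean_moving_range_Rbar=rbar,
        removed_indices=sorted(removed),
        passes=passes,
    )
    return space, result
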