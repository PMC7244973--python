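"""Two-level orthogonal-array screening of variables by SN-ratio gain.

Each candidate variable is assigned to one column of a two-level orthogonal
array.  Level 1 means the variable is INCLUDED in the reference space for
that run, level 2 EXCLUDED.  For every run the abnormal group is scored
against a space refitted on the included subset, and the run's quality is
summarized by the larger-the-better signal-to-noise ratio

    SN = -10 * log10( (1/n) * sum_i 1 / MD_i )   [decibels]

— higher when the included subset pushes abnormal subjects farther from
the healthy space.  A variable's gain is its level-1 mean SN minus its
level-2 mean SN across runs; variables with strictly positive gain are
selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, ContractError
from .io_config import FeatureTable
from .mahalanobis import compute_md, fit_space

__all__ = [
    "OrthogonalArray",
    "SNTable",
    "generate_oa",
    "sn_ratio_larger_better",
    "run_oa_experiment",
    "compute_gains",
    "select_variables",
]


@dataclass
class OrthogonalArray:
    """Balanced two-level design matrix with entries in {1, 2}."""

    levels: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.ndim != 2:
            raise ConfigError("design matrix must be 2-D")
        if not np.isin(self.levels, (1, 2)).all():
            raise ConfigError("design entries must be 1 or 2")

    @property
    def n_runs(self) -> int:
        return int(self.levels.shape[0])

    @property
    def n_columns(self) -> int:
        return int(self.levels.shape[1])

    def validate(self) -> None:
        """Check column balance and pairwise orthogonality exhaustively."""
        n = self.n_runs
        ones = (self.levels == 1).sum(axis=0)
        if not np.all(ones == n // 2):
            bad = np.nonzero(ones != n // 2)[0].tolist()
            raise ConfigError(f"unbalanced column(s): {bad}")
        for i in range(self.n_columns):
            for j in range(i + 1, self.n_columns):
                for a in (1, 2):
                    for b in (1, 2):
                        count = int(
                            ((self.levels[:, i] == a) & (self.levels[:, j] == b)).sum()
                        )
                        if count != n // 4:
                            raise ConfigError(
                                f"columns {i},{j} not orthogonal: "
                                f"pair ({a},{b}) occurs {count} times, expected {n // 4}"
                            )


def generate_oa(n_factors: int) -> OrthogonalArray:
    """Build a two-level orthogonal array holding at least ``n_factors``.

    Uses the Hadamard/parity construction: with n_runs the smallest power
    of two strictly greater than ``n_factors``, column c (c = 1..n_runs-1)
    has entry 1 + popcount(r AND c) mod 2 in row r.  Every column is
    balanced and every column pair orthogonal.  Column ordering differs
    from Taguchi's canonical tables, which matters only for reproducing a
    specific printed design (see :mod:`mtskit.datasets`).
    """
    if n_factors < 1:
        raise ConfigError("n_factors must be at least 1")
    n_runs = 1
    while n_runs <= n_factors:
        n_runs *= 2
    rows = np.arange(n_runs)
    cols = np.arange(1, n_runs)
    parity = np.zeros((n_runs, n_runs - 1), dtype=int)
    for ci, c in enumerate(cols):
        parity[:, ci] = [bin(int(r) & int(c)).count("1") % 2 for r in rows]
    return OrthogonalArray(1 + parity)


def sn_ratio_larger_better(mds: Sequence[float] | np.ndarray) -> float:
    """Larger-the-better SN ratio of a vector of positive distances, in dB."""
    mds = np.asarray(mds, dtype=float)
    if mds.size == 0:
        raise ContractError("SN ratio of an empty vector is undefined")
    if np.any(mds <= 0):
        raise ContractError("SN ratio requires strictly positive distances")
    return float(-10.0 * np.log10(np.mean(1.0 / mds)))


@dataclass
class SNTable:
    """Per-run SN ratios plus per-variable level means and gains.

    ``assignment`` maps each variable name to its (0-based) array column.
    Because every column is balanced, the average of a variable's two level
    means always equals the grand mean of ``run_sn``.
    """

    run_sn: np.ndarray
    assignment: dict[str, int]
    level1_mean: dict[str, float] = field(default_factory=dict)
    level2_mean: dict[str, float] = field(default_factory=dict)
    gain: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.run_sn = np.asarray(self.run_sn, dtype=float)

    def to_dict(self) -> dict:
        return {
            "run_sn": self.run_sn.tolist(),
            "assignment": dict(self.assignment),
            "level1_mean": {v: float(x) for v, x in self.level1_mean.items()},
            "level2_mean": {v: float(x) for v, x in self.level2_mean.items()},
            "gain": {v: float(x) for v, x in self.gain.items()},
        }


def compute_gains(
    run_sn: Sequence[float] | np.ndarray,
    oa: OrthogonalArray,
    assignment: dict[str, int],
) -> SNTable:
    """Level means and gains for every assigned variable (pure arithmetic).

    gain(v) = mean SN over runs at level 1 in v's column, minus the mean
    over runs at level 2.
    """
    run_sn = np.asarray(run_sn, dtype=float)
    if run_sn.size != oa.n_runs:
        raise ContractError(
            f"got {run_sn.size} SN values for a {oa.n_runs}-run design"
        )
    table = SNTable(run_sn=run_sn, assignment=dict(assignment))
    for var, col in assignment.items():
        column = oa.levels[:, col]
        m1 = float(run_sn[column == 1].mean())
        m2 = float(run_sn[column == 2].mean())
        table.level1_mean[var] = m1
        table.level2_mean[var] = m2
        table.gain[var] = m1 - m2
    return table


def run_oa_experiment(
    normal: FeatureTable,
    abnormal: FeatureTable,
    oa: OrthogonalArray,
    variables: Sequence[str],
    scaled: bool = True,
    condition_bound: float = 1e10,
) -> SNTable:
    """Run the full screening experiment over the array's rows.

    Variables are assigned to the first ``len(variables)`` columns in
    order.  For each run, the reference space is refitted on the healthy
    table restricted to the run's level-1 variables and the abnormal group
    is scored against it; the run's SN ratio summarizes those distances.
    """
    variables = list(variables)
    if len(variables) > oa.n_columns:
        raise ConfigError(
            f"{len(variables)} variables exceed the array's {oa.n_columns} columns"
        )
    assignment = {v: i for i, v in enumerate(variables)}
    run_sn = np.empty(oa.n_runs)
    for r in range(oa.n_runs):
        included = [v for v in variables if oa.levels[r, assignment[v]] == 1]
        if not included:
            raise ConfigError(f"run {r + 1} includes no variables; SN undefined")
        space = fit_space(normal, included, condition_bound)
        md = compute_md(space, abnormal, scaled=scaled).values
        run_sn[r] = sn_ratio_larger_better(md)
    return compute_gains(run_sn, oa, assignment)


def select_variables(sn_table: SNTable) -> list[str]:
    """Variables with strictly positive gain, ordered by descending gain."""
    import warnings

    chosen = [(v, g) for v, g in sn_table.gain.items() if g > 0]
    if not chosen:
        warnings.warn("no variable has positive gain; selection is empty", stacklevel=2)
    chosen.sort(key=lambda t: -t[1])
    return [v for v, _ in chosen]
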