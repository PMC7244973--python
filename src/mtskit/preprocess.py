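"""Subject and variable screening applied before any space is fitted.

Two steps: drop subjects with any missing cell, then prune one member of
every pair of variables whose Pearson correlation magnitude exceeds a
threshold.  Pruning is always decided on the healthy group and the same
column selection is then applied to every other table, so the abnormal
group cannot influence which variables survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ContractError, DegenerateDataError
from .io_config import FeatureTable

__all__ = [
    "CorrelationPruneReport",
    "drop_incomplete_rows",
    "pearson_prune",
    "pearson_r",
]


@dataclass
class CorrelationPruneReport:
    """Audit trail of a correlation-pruning decision.

    ``pairs`` lists every flagged (A, B, r) with r as a fraction in [-1, 1];
    ``reserved`` maps each flagged pair to the variable that was kept;
    ``dropped`` lists removed variables in removal order; ``zero_variance``
    lists degenerate (constant) variables, which are always removed.
    """

    threshold: float
    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    reserved: dict[tuple[str, str], str] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    zero_variance: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "pairs": [
                {"a": a, "b": b, "r": float(r)} for a, b, r in self.pairs
            ],
            "reserved": [
                {"pair": list(pair), "kept": kept}
                for pair, kept in self.reserved.items()
            ],
            "dropped": list(self.dropped),
            "zero_variance": list(self.zero_variance),
        }


def drop_incomplete_rows(table: FeatureTable) -> tuple[FeatureTable, int]:
    """Remove every subject with at least one missing cell.

    Returns the complete table (surviving row order preserved) and the
    number of removed subjects.  Raises :class:`DegenerateDataError` if no
    subject survives.
    """
    mask = table.data.notna().all(axis=1)
    removed = int((~mask).sum())
    if removed == table.n_subjects:
        raise DegenerateDataError("every row contains a missing value")
    if removed == 0:
        return table, 0
    return FeatureTable(table.data.loc[mask].copy(), table.group), removed


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Plain two-pass Pearson correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def pearson_prune(
    table: FeatureTable,
    threshold: float = 0.80,
    keep_policy: tuple[str, ...] | list[str] = (),
) -> tuple[FeatureTable, CorrelationPruneReport]:
    """Drop one variable of every pair correlated beyond ``threshold``.

    Flagged pairs are processed greedily in order of descending |r|; for
    each, the survivor is the member listed earlier in ``keep_policy``
    (falling back to the lower column index), unless both members are in
    the keep-list, in which case both are retained.  Constant (zero
    variance) variables have undefined correlation with every partner and
    are removed up front with a warning.
    """
    if table.has_missing():
        raise ContractError("prune requires a complete table; drop incomplete rows first")
    if table.n_subjects < 3:
        raise ContractError("Pearson correlation needs at least 3 subjects")
    if not 0.0 < threshold < 1.0:
        raise ContractError(f"threshold must be in (0, 1), got {threshold}")

    report = CorrelationPruneReport(threshold=float(threshold))
    names = table.variable_names
    keep_rank = {v: i for i, v in enumerate(keep_policy)}

    values = table.values
    sds = values.std(axis=0, ddof=1)
    alive = []
    for name, sd in zip(names, sds):
        if sd == 0.0:
            warnings.warn(f"variable {name!r} has zero variance; dropped", stacklevel=2)
            report.zero_variance.append(name)
            report.dropped.append(name)
        else:
            alive.append(name)

    col = {v: names.index(v) for v in names}
    corr = np.corrcoef(values[:, [col[v] for v in alive]], rowvar=False) if len(alive) > 1 else None

    flagged: list[tuple[str, str, float]] = []
    for i in range(len(alive)):
        for j in range(i + 1, len(alive)):
            r = float(corr[i, j])
            if abs(r) > threshold:
                flagged.append((alive[i], alive[j], r))
    flagged.sort(key=lambda t: (-abs(t[2]), col[t[0]], col[t[1]]))

    dropped_set = set(report.dropped)
    for a, b, r in flagged:
        if a in dropped_set or b in dropped_set:
            continue
        report.pairs.append((a, b, r))
        in_keep_a, in_keep_b = a in keep_rank, b in keep_rank
        if in_keep_a and in_keep_b:
            # Both reserved: keep both, report the pair for the audit trail.
            report.reserved[(a, b)] = f"{a},{b}"
            continue
        if in_keep_a:
            kept, lost = a, b
        elif in_keep_b:
            kept, lost = b, a
        else:
            kept, lost = (a, b) if col[a] < col[b] else (b, a)
        report.reserved[(a, b)] = kept
        report.dropped.append(lost)
        dropped_set.add(lost)

    survivors = [v for v in names if v not in dropped_set]
    if not survivors:
        raise DegenerateDataError("pruning removed every variable")
    return table.select(survivors), report
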