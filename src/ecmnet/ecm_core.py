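"""Per-subject eigenvector centrality over the ROI correlation network.

The adjacency matrix holds pairwise Pearson correlations shifted by +1 so
all entries are non-negative (diagonal = 2). Centrality is the leading
eigenvector of that positive matrix, computed by power iteration and
returned with unit Euclidean norm and all-positive entries; by
Perron-Frobenius this eigenvector is unique and positive, and it is
invariant to any positive rescaling of the adjacency (so the (1+r)/2
convention yields identical centralities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class ECMError(ValueError):
    pass


class ConvergenceError(ECMError):
    def __init__(self, iterations: int, trace: list[float]):
        self.iterations = iterations
        self.trace = trace
        super().__init__(
            f"power iteration did not converge in {iterations} iterations; "
            f"last successive differences: {trace[-5:]}"
        )


@dataclass
class ECVector:
    """Unit-norm leading eigenvector of one subject's adjacency matrix."""

    subject_id: str
    ec: np.ndarray
    eigenvalue: float
    iterations: int


def build_adjacency(cleaned: np.ndarray) -> np.ndarray:
    """Pairwise ROI correlation matrix shifted by +1 (entries in [0, 2])."""
    cleaned = np.asarray(cleaned, dtype=float)
    if cleaned.ndim != 2:
        raise ECMError("cleaned must be a 2-D ROI x time matrix")
    n_roi, T = cleaned.shape
    if T < 3:
        raise ECMError(f"need at least 3 time points, got {T}")
    if not np.isfinite(cleaned).all():
        raise ECMError("time series contain missing or non-finite values")
    sd = cleaned.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ECMError(
            f"constant time series for ROIs {constant.tolist()}; "
            "correlation undefined"
        )
    corr = np.corrcoef(cleaned)
    corr = 0.5 * (corr + corr.T)  # enforce exact symmetry
    adj = corr + 1.0
    np.fill_diagonal(adj, 2.0)
    return adj


def _validate_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ECMError("adjacency must be square")
    if not np.isfinite(adj).all():
        raise ECMError("adjacency contains non-finite values")
    asym = np.max(np.abs(adj - adj.T))
    if asym > 1e-12 * max(1.0, np.max(np.abs(adj))):
        raise ECMError(f"adjacency is asymmetric (max |A - A'| = {asym:g})")
    if adj.min() < 0:
        raise ECMError("adjacency has negative entries; expected corr + 1")
    return adj


def eigenvector_centrality(
    adj: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 10000,
    subject_id: str = "",
) -> ECVector:
    """Leading eigenvector of a non-negative adjacency by power iteration.

    Starts from the uniform vector 1/sqrt(n); converged when the successive
    iterates differ by less than ``tol`` in sup norm. The eigenvalue is the
    Rayleigh quotient at the converged vector.
    """
    adj = _validate_adjacency(adj)
    n = adj.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        w = adj @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ECMError("adjacency annihilated the iterate (zero matrix?)")
        w /= norm
        diff = float(np.max(np.abs(w - v)))
        trace.append(diff)
        v = w
        if diff < tol:
            break
    else:
        raise ConvergenceError(max_iter, trace)
    if v.sum() < 0:  # fix sign; positive matrix keeps iterates positive
        v = -v
    eigenvalue = float(v @ adj @ v)
    return ECVector(subject_id=subject_id, ec=v, eigenvalue=eigenvalue,
                    iterations=it)


def ec_table(
    subjects: Sequence[tuple[str, np.ndarray]],
    groups: pd.Series | dict | None = None,
    tol: float = 1e-12,
    max_iter: int = 10000,
) -> pd.DataFrame:
    """Eigenvector centrality for a list of ``(subject_id, cleaned)`` pairs.

    Returns a DataFrame with ``subject_id``, ``group`` (if provided) and one
    ``roi_<i>`` column per region. Per-subject failures are aggregated into
    a single error naming every failing subject.
    """
    rows = []
    failures: list[str] = []
    n_roi = None
    for subject_id, cleaned in subjects:
        try:
            adj = build_adjacency(cleaned)
            if n_roi is None:
                n_roi = adj.shape[0]
            elif adj.shape[0] != n_roi:
                raise ECMError(
                    f"ROI count {adj.shape[0]} differs from first subject "
                    f"({n_roi})"
                )
            ecv = eigenvector_centrality(adj, tol=tol, max_iter=max_iter,
                                         subject_id=subject_id)
            rows.append((subject_id, ecv.ec))
        except ECMError as exc:
            failures.append(f"{subject_id}: {exc}")
    if failures:
        raise ECMError(
            "eigenvector centrality failed for "
            f"{len(failures)} subject(s):\n" + "\n".join(failures)
        )
    table = pd.DataFrame(
        [ec for _, ec in rows],
        columns=[f"roi_{i}" for i in range(n_roi)],
    )
    table.insert(0, "subject_id", [sid for sid, _ in rows])
    if groups is not None:
        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series)
                           else groups)
        table.insert(1, "group", table["subject_id"].map(groups).to_numpy())
    return table


def roi_columns(table: pd.DataFrame) -> list[str]:
    """The ``roi_*`` columns of an EC table, in index order."""
    cols = [c for c in table.columns if c.startswith("roi_")]
    return sorted(cols, key=lambda c: tuple(
        int(p) if p.isdigit() else p for p in c[4:].split("+")
    ))


def group_mean_ec(table: pd.DataFrame) -> pd.DataFrame:
    """Mean EC per ROI within each group label."""
    cols = roi_columns(table)
    return table.groupby("group")[cols].mean()
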