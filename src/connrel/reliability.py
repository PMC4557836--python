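"""Intraclass-correlation reliability engine.

Each MRI scanning session is treated as a "rater" and each subject as a
"target": for every connectome link (and every nodal graph measure) the
n-subjects-by-k-sessions table of measurements feeds a two-way random-effects
ANOVA, and reliability is summarized by the single-measure absolute-agreement
intraclass correlation coefficient ICC(A,1):

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

where MSR, MSC and MSE are the row (subject), column (session) and residual
mean squares.  Absolute agreement penalizes systematic between-session
offsets (e.g. a scanner gain), not just loss of correlation.

Zero-variance tables have no defined ICC and are marked undefined (NaN) and
excluded from downstream distribution statistics; negative ICCs are retained
unclipped, since clipping would bias distribution comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builder import sparsity
from .core import ROITable, SessionStack, write_matrix
from .metrics import METRIC_NAMES, compute_metric

#: relative tolerance below which a table's total variance counts as zero
_VAR_TOL = 1e-12

#: mean off-diagonal sparsity below which degree ICC is not assessed
#: (near-fully-connected networks have no between-subject degree variance
#: left to measure — the "ceiling degree effect")
DEGREE_SPARSITY_FLOOR = 0.1


def icc_batch(data: np.ndarray) -> np.ndarray:
    """ICC(A,1) for a batch of complete rating tables.

    Parameters
    ----------
    data : array, shape (m, n, k)
        ``m`` independent tables of ``n`` subjects (rows) rated by ``k``
        sessions (columns).

    Returns
    -------
    array, shape (m,)
        ICC(A,1) per table; NaN where the table has (numerically) zero
        total variance.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a (m, n, k) batch of tables")
    m, n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 subjects and k >= 2 sessions, got {n}x{k}")
    if np.isnan(data).any():
        raise ValueError("missing cells are not allowed (no imputation)")

    gm = data.mean(axis=(1, 2))
    centered = data - gm[:, None, None]
    row_mean = centered.mean(axis=2)     # (m, n)
    col_mean = centered.mean(axis=1)     # (m, k)
    ssr = k * (row_mean ** 2).sum(axis=1)
    ssc = n * (col_mean ** 2).sum(axis=1)
    sst = (centered ** 2).sum(axis=(1, 2))
    sse = np.maximum(sst - ssr - ssc, 0.0)

    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    undefined = sst <= _VAR_TOL * np.maximum(1.0, (data ** 2).sum(axis=(1, 2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    return np.where(undefined | ~np.isfinite(icc), np.nan, icc)


def icc_absolute_agreement(ratings: np.ndarray) -> float:
    """ICC(A,1) — two-way, absolute agreement, single measures — for one
    complete n-subjects x k-sessions table.

    Returns NaN (undefined) for a table with zero total variance; raises on
    missing cells or degenerate dimensions.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x sessions table")
    return float(icc_batch(ratings[None])[0])


@dataclass
class ICCMatrix:
    """Link-wise ICC over all unordered ROI pairs for one session pair and
    method; undefined links are NaN, the diagonal is undefined by
    construction."""

    roi_table: ROITable
    session_pair: tuple[str, ...]
    method: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.roi_table)
        if v.shape != (n, n):
            raise ValueError(f"ICC matrix shape {v.shape} does not match {n} ROIs")
        np.fill_diagonal(v, np.nan)
        self.values = v

    @property
    def pair_label(self) -> str:
        return " vs ".join(self.session_pair)

    def defined_values(self) -> np.ndarray:
        """Defined ICCs over unordered off-diagonal pairs, as a flat array."""
        iu = np.triu_indices(len(self.roi_table), k=1)
        vals = self.values[iu]
        return vals[~np.isnan(vals)]

    def defined_mask(self) -> np.ndarray:
        """Boolean upper-triangle mask (flat) of defined links."""
        iu = np.triu_indices(len(self.roi_table), k=1)
        return ~np.isnan(self.values[iu])

    @property
    def n_undefined(self) -> int:
        iu = np.triu_indices(len(self.roi_table), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_tsv(self, path) -> None:
        write_matrix(self.values, path, roi_table=self.roi_table)


@dataclass
class MetricICCTable:
    """Per-node ICCs for one nodal graph measure, session pair and method.

    ``assessed`` is False when the measure was deliberately not evaluated
    (degree on near-fully-connected matrices)."""

    metric_name: str
    session_pair: tuple[str, ...]
    method: str
    values: np.ndarray
    roi_keys: list[str] = field(default_factory=list)
    assessed: bool = True

    def defined_values(self) -> np.ndarray:
        if not self.assessed:
            return np.array([])
        return self.values[~np.isnan(self.values)]


def _ratings_from_stack(stack: SessionStack, session_pair) -> np.ndarray:
    pair = tuple(session_pair)
    known = set(stack.session_ids)
    missing = [s for s in pair if s not in known]
    if missing:
        raise ValueError(f"sessions {missing} not present in stack {sorted(known)}")
    if len(pair) < 2:
        raise ValueError("need at least two sessions to compute an ICC")
    return stack.weight_array(pair)   # (n_subj, k, n, n)


def linkwise_icc(stack: SessionStack, session_pair) -> ICCMatrix:
    """ICC(A,1) per unordered ROI pair across a pair (or tuple) of sessions.

    For each link the n_subjects x k_sessions weight table is assembled and
    scored; links with zero variance across the whole table (e.g. absent in
    every subject) are undefined.
    """
    w = _ratings_from_stack(stack, session_pair)   # (n_subj, k, n, n)
    n_subj, k, n, _ = w.shape
    iu = np.triu_indices(n, k=1)
    tables = w[:, :, iu[0], iu[1]]                 # (n_subj, k, n_links)
    tables = np.moveaxis(tables, 2, 0)             # (n_links, n_subj, k)
    icc = icc_batch(tables)
    out = np.full((n, n), np.nan)
    out[iu] = icc
    out[(iu[1], iu[0])] = icc
    return ICCMatrix(stack.roi_table, tuple(session_pair), stack.method, out)


def nodewise_metric_icc(
    stack: SessionStack,
    metric_name: str,
    session_pair,
    degree_sparsity_floor: float = DEGREE_SPARSITY_FLOOR,
) -> MetricICCTable:
    """ICC(A,1) per node for one nodal graph measure across sessions.

    Degree is marked not-assessed when the stack's mean matrix sparsity
    falls below ``degree_sparsity_floor`` (ceiling degree effect in dense,
    probabilistic-like networks).
    """
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}; expected one of {METRIC_NAMES}")
    pair = tuple(session_pair)
    _ratings_from_stack(stack, pair)   # validates sessions
    if metric_name == "degree":
        mean_sparsity = float(
            np.mean([
                sparsity(stack.matrix(subj, sess))
                for subj in stack.subjects
                for sess in pair
            ])
        )
        if mean_sparsity < degree_sparsity_floor:
            return MetricICCTable(
                metric_name, pair, stack.method,
                np.full(len(stack.roi_table), np.nan),
                roi_keys=stack.roi_table.keys, assessed=False,
            )
    n = len(stack.roi_table)
    tables = np.empty((len(stack.subjects), len(pair), n))
    for i, subj in enumerate(stack.subjects):
        for j, sess in enumerate(pair):
            tables[i, j] = compute_metric(stack.matrix(subj, sess), metric_name).values
    per_node = np.moveaxis(tables, 2, 0)   # (n, n_subj, k)
    icc = icc_batch(per_node)
    return MetricICCTable(metric_name, pair, stack.method, icc,
                          roi_keys=stack.roi_table.keys, assessed=True)


def count_reproducible_links(icc: ICCMatrix, threshold: float = 0.75) -> int:
    """Number of defined unordered links with ICC strictly above threshold."""
    vals = icc.defined_values()
    return int((vals > threshold).sum())


def icc_summary(icc: ICCMatrix, threshold: float = 0.75) -> dict:
    """Machine-readable summary of an ICC matrix (counts, mean/median,
    reproducible-link count)."""
    vals = icc.defined_values()
    return {
        "method": icc.method,
        "session_pair": list(icc.session_pair),
        "n_links": int(len(vals) + icc.n_undefined),
        "n_defined": int(len(vals)),
        "n_undefined": int(icc.n_undefined),
        "mean_icc": float(np.mean(vals)) if len(vals) else None,
        "median_icc": float(np.median(vals)) if len(vals) else None,
        "threshold": threshold,
        "n_above_threshold": count_reproducible_links(icc, threshold),
    }
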