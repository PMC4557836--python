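"""Connectivity-matrix construction from streamline records.

Two weighting schemes are supported, mirroring the two tractography families:

* **deterministic** — whole-brain seeded single-path tracking; each fiber
  between ROIs i and j contributes 1/length, and the pair weight is the
  Hagmann surface-normalized sum ``w = (2/(Si+Sj)) * sum_f count_f/length_f``.
* **probabilistic** — each ROI of a pair is seeded in turn and the arriving
  streamline masses are counted; the pair weight is the mean of the two
  seeded masses divided by ``Si+Sj``.  With distance correction enabled the
  masses are already length-weighted upstream and are consumed as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core import ConnectivityMatrix, FiberRecord, FiberSet, ROITable


@dataclass(frozen=True)
class WeightingConfig:
    """Weighting scheme for a matrix build; ``distance_correction`` is only
    meaningful in the probabilistic regime and documents whether the seeded
    masses were length-weighted by the generator/tracker."""

    method: str = "deterministic"
    distance_correction: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("deterministic", "probabilistic"):
            raise ValueError(f"unknown method {self.method!r}")


def deterministic_weight(
    fibers: Iterable[FiberRecord], surface_i: float, surface_j: float
) -> float:
    """Hagmann-normalized deterministic weight for one ROI pair.

    ``(2/(Si+Sj)) * sum over fibers of count/length``; zero when no fibers.
    """
    if not (surface_i > 0 and surface_j > 0):
        raise ValueError("surface areas must be strictly positive")
    total = 0.0
    for f in fibers:
        if not f.length > 0:
            raise ValueError(f"fiber length must be > 0, got {f.length!r}")
        total += f.count / f.length
    return (2.0 / (surface_i + surface_j)) * total


def probabilistic_weight(
    corrected_count_i_seeded: float,
    corrected_count_j_seeded: float,
    surface_i: float,
    surface_j: float,
) -> float:
    """Bidirectional seeded-count weight: mean of the two seeded
    (distance-corrected) masses divided by the summed surface areas."""
    if corrected_count_i_seeded < 0 or corrected_count_j_seeded < 0:
        raise ValueError("seeded counts must be nonnegative")
    if not (surface_i > 0 and surface_j > 0):
        raise ValueError("surface areas must be strictly positive")
    return (
        0.5 * (corrected_count_i_seeded + corrected_count_j_seeded)
        / (surface_i + surface_j)
    )


def build_matrix(
    fiber_set: FiberSet, roi_table: ROITable, config: WeightingConfig | None = None
) -> ConnectivityMatrix:
    """Aggregate a :class:`FiberSet` into a symmetric weighted matrix.

    Records whose two endpoints resolve to the same ROI never form a link
    (tracking can produce such fibers; they are discarded).  Unresolvable
    endpoint labels raise a :class:`KeyError` naming the offending record.
    """
    if config is None:
        config = WeightingConfig(method=fiber_set.method)
    if fiber_set.method != config.method:
        raise ValueError(
            f"fiber set method {fiber_set.method!r} does not match config {config.method!r}"
        )
    n = len(roi_table)
    surf = roi_table.surface_areas
    weights = np.zeros((n, n))

    if not fiber_set.records:
        return ConnectivityMatrix(
            roi_table, weights, method=config.method,
            subject_id=fiber_set.subject_id, session_id=fiber_set.session_id,
            scanner_id=fiber_set.scanner_id,
        )

    df = fiber_set.to_frame()
    try:
        ia = df["roi_a"].map(roi_table.index_of).to_numpy()
        ib = df["roi_b"].map(roi_table.index_of).to_numpy()
    except KeyError:
        # re-resolve one by one so the error names the record
        fiber_set.validate_against(roi_table)
        raise

    keep = ia != ib   # same-ROI records never contribute to a link
    ia, ib = ia[keep], ib[keep]
    lo, hi = np.minimum(ia, ib), np.maximum(ia, ib)
    pair = lo * n + hi
    counts = df["count"].to_numpy(dtype=float)[keep]
    lengths = df["length"].to_numpy(dtype=float)[keep]
    if np.any(lengths <= 0):
        raise ValueError("fiber lengths must be > 0")

    if config.method == "deterministic":
        contrib = counts / lengths
        sums = np.zeros(n * n)
        np.add.at(sums, pair, contrib)
        flat = sums.reshape(n, n)
        denom = surf[:, None] + surf[None, :]
        weights = np.where(flat > 0, 2.0 * flat / denom, 0.0)
    else:
        # a_seeded mass accumulates to the seed ROI's direction slot; an
        # undirected record stands for the same mass observed from both
        # seedings, so it adds fully to both directions.
        direction = df["direction"].to_numpy()[keep]
        seed_lo = np.zeros(n * n)   # mass seeded from the lower-index ROI
        seed_hi = np.zeros(n * n)
        a_is_lo = ia == lo
        for dirname, arr_sel in (("a_seeded", True), ("b_seeded", False)):
            m = direction == dirname
            to_lo = m & (a_is_lo == arr_sel)
            to_hi = m & (a_is_lo != arr_sel)
            np.add.at(seed_lo, pair[to_lo], counts[to_lo])
            np.add.at(seed_hi, pair[to_hi], counts[to_hi])
        und = direction == "undirected"
        np.add.at(seed_lo, pair[und], counts[und])
        np.add.at(seed_hi, pair[und], counts[und])
        mean_mass = 0.5 * (seed_lo + seed_hi).reshape(n, n)
        denom = surf[:, None] + surf[None, :]
        weights = mean_mass / denom

    weights = weights + weights.T
    np.fill_diagonal(weights, 0.0)
    return ConnectivityMatrix(
        roi_table, weights, method=config.method,
        subject_id=fiber_set.subject_id, session_id=fiber_set.session_id,
        scanner_id=fiber_set.scanner_id,
    )


def sparsity(matrix: ConnectivityMatrix) -> float:
    """Fraction of off-diagonal unordered ROI pairs with weight exactly 0."""
    w = matrix.weights
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = w[iu]
    return float(np.count_nonzero(vals == 0) / vals.size)
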