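"""Correlate statistics on link-wise reliability.

Covers the secondary analyses of a test-retest connectome study: how
link-wise ICC relates to anatomy (inter-ROI distance, summed volume, volume
ratio), agreement of reliability across tractography methods, t-tests
between ICC distributions (method vs method, same vs different scanner),
proportion tests on reproducible-link counts, fiber-count and dispersion
(CV) relations, and the Bonferroni multiple-comparison plan that ties the
whole analysis together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SessionStack
from .reliability import ICCMatrix


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str = "pearson"

    @property
    def defined(self) -> bool:
        return math.isfinite(self.r)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n: int
    paired: bool = True


@dataclass(frozen=True)
class PlannedTest:
    family: str
    test_id: str


@dataclass
class AnalysisPlan:
    """Enumerated list of planned hypothesis tests with the family-wise
    Bonferroni level applied uniformly across all of them."""

    tests: list[PlannedTest]
    alpha: float = 0.05

    @property
    def total_comparisons(self) -> int:
        return len(self.tests)

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.tests:
            counts[t.family] = counts.get(t.family, 0) + 1
        return counts

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.total_comparisons)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display form of thresholds)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    if m < 1:
        raise ValueError(f"comparison count must be >= 1, got {m!r}")
    return alpha / m


def _paired_defined(icc_a: ICCMatrix, icc_b: ICCMatrix) -> tuple[np.ndarray, np.ndarray]:
    mask = icc_a.defined_mask() & icc_b.defined_mask()
    n = len(icc_a.roi_table)
    iu = np.triu_indices(n, k=1)
    return icc_a.values[iu][mask], icc_b.values[iu][mask]


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> CorrelationResult:
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if len(x) < 3:
        raise ValueError(f"need at least 3 paired values, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(x), method)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return CorrelationResult(float(r), float(p), len(x), method)


def correlate_icc_with_feature(
    icc: ICCMatrix, feature: np.ndarray, method: str = "pearson"
) -> CorrelationResult:
    """Correlate link-wise ICCs with a per-link anatomical feature.

    ``feature`` is a full square matrix or a flat upper-triangle vector;
    only links with a defined ICC enter the correlation.  A zero-variance
    feature yields an undefined (NaN) result rather than an error.
    """
    n = len(icc.roi_table)
    iu = np.triu_indices(n, k=1)
    feature = np.asarray(feature, dtype=float)
    if feature.shape == (n, n):
        feature = feature[iu]
    if feature.shape != iu[0].shape:
        raise ValueError(
            f"feature shape {feature.shape} matches neither the matrix nor its upper triangle"
        )
    mask = icc.defined_mask()
    if np.isnan(feature[mask]).any():
        raise ValueError("feature is undefined for some links with a defined ICC")
    return _correlate(icc.values[iu][mask], feature[mask], method)


def compare_icc_distributions(
    icc_a: ICCMatrix, icc_b: ICCMatrix, paired: bool = True
) -> TTestResult:
    """t-test between two link-wise ICC distributions.

    Paired mode (default) uses the intersection of links defined in both
    matrices; unpaired mode is Welch's t.  The t statistic is signed as
    mean(a) - mean(b).
    """
    if paired:
        a, b = _paired_defined(icc_a, icc_b)
        if len(a) == 0:
            raise ValueError("no links defined in both ICC matrices")
        diff = a - b
        if np.std(diff) == 0:
            # constant difference: t is 0 (identical) or infinite (pure shift)
            if diff[0] == 0:
                return TTestResult(0.0, 1.0, len(a), paired=True)
            return TTestResult(math.copysign(math.inf, diff[0]), 0.0, len(a), paired=True)
        t, p = stats.ttest_rel(a, b)
        return TTestResult(float(t), float(p), len(a), paired=True)
    a, b = icc_a.defined_values(), icc_b.defined_values()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one of the ICC matrices has no defined links")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(t), float(p), len(a) + len(b), paired=False)


def compare_reproducible_counts(
    count_a: int, count_b: int, n_links_a: int, n_links_b: int
) -> float:
    """Two-proportion chi-square p-value (1 df, no continuity correction)
    comparing reproducible-link fractions between two conditions."""
    if n_links_a <= 0 or n_links_b <= 0:
        raise ValueError("link totals must be positive")
    if count_a > n_links_a or count_b > n_links_b:
        raise ValueError("counts cannot exceed their link totals")
    table = np.array(
        [[count_a, n_links_a - count_a], [count_b, n_links_b - count_b]], dtype=float
    )
    if table.sum(axis=0).min() == 0:
        # both conditions all-success or all-failure: no difference testable
        return 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def link_weight_dispersion(stack: SessionStack, session_id: str) -> np.ndarray:
    """Across-subject coefficient of variation (sd/mean, sample sd) of each
    link's weight in one session; NaN where the mean weight is 0.

    Returns a flat vector over unordered upper-triangle pairs.
    """
    w = stack.weight_array([session_id])[:, 0]   # (n_subj, n, n)
    n = w.shape[1]
    iu = np.triu_indices(n, k=1)
    vals = w[:, iu[0], iu[1]]                    # (n_subj, n_links)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return cv


def mean_link_weight(stack: SessionStack, session_id: str) -> np.ndarray:
    """Across-subject mean link weight in one session (flat upper triangle);
    the fiber-count proxy for the count-vs-ICC correlation."""
    w = stack.weight_array([session_id])[:, 0]
    n = w.shape[1]
    iu = np.triu_indices(n, k=1)
    return w[:, iu[0], iu[1]].mean(axis=0)


def correlate_icc_across_methods(
    icc_det: ICCMatrix, icc_prob: ICCMatrix, method: str = "pearson"
) -> CorrelationResult:
    """Correlate link-wise ICCs between tractography methods over the links
    defined in both."""
    a, b = _paired_defined(icc_det, icc_prob)
    if len(a) < 3:
        raise ValueError(f"need at least 3 common defined links, got {len(a)}")
    return _correlate(a, b, method)


def correlate_icc_with_fibercount(
    icc: ICCMatrix, stack: SessionStack, session_id: str | None = None,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate link-wise ICC with the mean link weight across subjects
    (average tracked-fiber mass per link)."""
    sid = session_id if session_id is not None else icc.session_pair[0]
    return correlate_icc_with_feature(icc, _triu_to_square(mean_link_weight(stack, sid),
                                                           len(stack.roi_table)), method)


def correlate_icc_with_dispersion(
    icc: ICCMatrix, stack: SessionStack, session_id: str | None = None,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate link-wise ICC with the across-subject CV of link weight;
    links with undefined CV (mean weight 0) are dropped."""
    sid = session_id if session_id is not None else icc.session_pair[0]
    cv = link_weight_dispersion(stack, sid)
    n = len(stack.roi_table)
    iu = np.triu_indices(n, k=1)
    mask = icc.defined_mask() & ~np.isnan(cv)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 links with both a defined ICC and a defined CV")
    return _correlate(icc.values[iu][mask], cv[mask], method)


def _triu_to_square(flat: np.ndarray, n: int) -> np.ndarray:
    out = np.full((n, n), np.nan)
    iu = np.triu_indices(n, k=1)
    out[iu] = flat
    out[(iu[1], iu[0])] = flat
    return out


@dataclass(frozen=True)
class PlanConfig:
    """Study design knobs that determine the multiple-comparison plan."""

    methods: tuple[str, ...] = ("deterministic", "probabilistic")
    session_pairs: tuple[str, ...] = ("within_scanner", "between_scanner")
    anatomical_features: tuple[str, ...] = ("distance", "volume_sum", "volume_ratio")
    fibercount_features: tuple[str, ...] = ("mean_count", "cv")
    gt_metrics: tuple[str, ...] = ("degree", "strength", "clustering", "betweenness")
    alpha: float = 0.05
    #: degree ICC is not assessed for these methods (ceiling degree effect)
    degree_skipped_methods: tuple[str, ...] = ("probabilistic",)


def enumerate_analysis_plan(config: PlanConfig | None = None) -> AnalysisPlan:
    """Enumerate every planned test under a study design.

    Default design: 2 methods x 2 session pairs with 3 anatomical features
    (12 anatomical correlations), 2 cross-method correlations, 2 method
    t-tests, 2 fiber-count features per method and pair (8), and nodal
    graph-measure ICC analyses (4 measures x 2 pairs x 2 methods minus the
    probabilistic degree = 14) — 38 comparisons in total.
    """
    cfg = config or PlanConfig()
    tests: list[PlannedTest] = []
    for m in cfg.methods:
        for p in cfg.session_pairs:
            for f in cfg.anatomical_features:
                tests.append(PlannedTest("anatomical_correlation", f"icc~{f}|{m}|{p}"))
    if len(cfg.methods) >= 2:
        for p in cfg.session_pairs:
            tests.append(PlannedTest("cross_method_correlation", f"icc_det~icc_prob|{p}"))
        for p in cfg.session_pairs:
            tests.append(PlannedTest("method_ttest", f"det_vs_prob|{p}"))
    for m in cfg.methods:
        for p in cfg.session_pairs:
            for f in cfg.fibercount_features:
                tests.append(PlannedTest("fibercount_correlation", f"icc~{f}|{m}|{p}"))
    for m in cfg.methods:
        metrics = tuple(
            g for g in cfg.gt_metrics
            if not (g == "degree" and m in cfg.degree_skipped_methods)
        )
        for p in cfg.session_pairs:
            for g in metrics:
                tests.append(PlannedTest("gt_icc_analysis", f"{g}_icc|{m}|{p}"))
    return AnalysisPlan(tests, alpha=cfg.alpha)
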