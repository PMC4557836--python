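"""Synthetic multi-subject, multi-session tractography cohort generator.

Emulates the design of a scan-rescan connectome reliability study: a cohort
of subjects scanned twice on one scanner (sessions A1, A2) and once on a
second unit of the same model (B1), under a sparse low-count
"deterministic-like" regime and a dense high-count "probabilistic-like"
regime.  The generator owns a known variance structure so that pipeline
estimates can be checked against construction truth:

* base log-connectivity of a link falls off linearly with inter-ROI
  centroid distance and grows with the product of the two gray/white
  boundary areas (seed voxels of one ROI times the acceptance surface of
  the other): ``mu_ij = log(Si) + log(Sj) - distance_decay * d_ij`` plus an
  anatomy-fixed bundle-size spread ``link_sd``, rescaled so the expected
  total streamline count matches ``mean_total_fibers``;
* a per-subject-per-link random effect (sd ``subject_sd``) persists across
  sessions — this is the "true" biology the study tries to re-measure;
* a per-session-per-link effect (sd ``session_sd``) models measurement
  noise; scanner B adds an extra spread ``scanner_b_extra_sd`` and a
  multiplicative gain ``scanner_b_gain``;
* streamline counts are Poisson around the exponentiated mean, so weak
  (distant, small-surface) links are noisier — and in the sparse regime a
  link additionally fails to track with probability growing with distance.

All noise is multiplicative (log-normal) so weights stay nonnegative and
the closed-form log-scale ICC ``sigma_b^2 / (sigma_b^2 + sigma_w^2)``
(:func:`theoretical_link_icc`) is the recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import FiberRecord, FiberSet, ROIRecord, ROITable

REGIMES = ("sparse_deterministic", "dense_probabilistic")

_REGIME_METHOD = {
    "sparse_deterministic": "deterministic",
    "dense_probabilistic": "probabilistic",
}

#: desk-scale default streamline totals per subject; the study the design
#: emulates had ~4e5 deterministic and ~5e11 probabilistic streamlines —
#: only the relative order between regimes matters here.
_REGIME_TOTAL_FIBERS = {
    "sparse_deterministic": 1.0e4,
    "dense_probabilistic": 1.0e6,
}

#: Desikan-Killiany-derived cortical region names (34, bilateral)
DK_CORTICAL = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)

#: subcortical region names (7, bilateral)
DK_SUBCORTICAL = (
    "thalamus", "caudate", "putamen", "pallidum", "accumbens",
    "hippocampus", "amygdala",
)

#: 41 bilateral regions + unpaired brainstem = 83 ROIs, 42 distinct names
LAUSANNE83_REGIONS = DK_CORTICAL + DK_SUBCORTICAL + ("brainstem",)


@dataclass(frozen=True)
class CohortParams:
    """Study-design and variance parameters for one synthetic cohort.

    ``subject_sd`` and ``session_sd`` are standard deviations of log-weight
    effects (dimensionless); ``distance_decay`` is in 1/mm; ``dropout_scale``
    (mm) sets how fast deterministic tracking fails with distance.
    """

    seed: int
    n_subjects: int = 20
    sessions: tuple[tuple[str, str], ...] = (("A1", "A"), ("A2", "A"), ("B1", "B"))
    n_rois: int = 83
    subject_sd: float = 0.6
    session_sd: float = 0.25
    scanner_b_gain: float = 1.1
    scanner_b_extra_sd: float = 0.25
    #: scanner B's different head coil alters tracking success: its dropout
    #: exponent d/dropout_scale is multiplied by this factor (sparse regime)
    scanner_b_dropout_gain: float = 1.5
    distance_decay: float = 0.02
    dropout_scale: float = 150.0
    #: spread (log scale) of anatomy-fixed per-link bundle size around the
    #: surface/distance trend; real connectome weights span orders of
    #: magnitude, giving a strongly-tracked reliable core plus a weak tail
    link_sd: float = 1.2
    regime: str = "sparse_deterministic"
    mean_total_fibers: float | None = None
    #: Poisson counting noise on streamline counts; switch off to study the
    #: exact noise-free limit (counts become their continuous expectations)
    count_noise: bool = True

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_rois < 3:
            raise ValueError("need at least 3 ROIs")
        for name in ("subject_sd", "session_sd", "scanner_b_extra_sd", "link_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.distance_decay > 0:
            raise ValueError("distance_decay must be > 0")
        if not self.dropout_scale > 0:
            raise ValueError("dropout_scale must be > 0")
        if not self.scanner_b_gain > 0:
            raise ValueError("scanner_b_gain must be > 0")
        if not self.scanner_b_dropout_gain > 0:
            raise ValueError("scanner_b_dropout_gain must be > 0")
        if self.mean_total_fibers is not None and not self.mean_total_fibers > 0:
            raise ValueError("mean_total_fibers must be > 0")

    @property
    def method(self) -> str:
        return _REGIME_METHOD[self.regime]

    @property
    def total_fibers(self) -> float:
        if self.mean_total_fibers is not None:
            return float(self.mean_total_fibers)
        return _REGIME_TOTAL_FIBERS[self.regime]

    def with_(self, **kwargs) -> "CohortParams":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Construction truth for one generated cohort: what the pipeline's
    estimates should recover (up to count noise and dropout, which the
    closed forms deliberately ignore)."""

    roi_table: ROITable
    pairs: np.ndarray                 # (n_links, 2) upper-triangle indices
    base_weight: np.ndarray           # expected link weight scale (mass units)
    lengths: np.ndarray               # fixed per-link fiber length, mm
    icc_within_scanner: np.ndarray    # per-link closed-form log-scale ICC
    icc_between_scanner: np.ndarray
    dropout_prob: np.ndarray          # per-link tracking-failure probability


def theoretical_link_icc(subject_sd: float, session_sd_effective: float) -> float:
    """Closed-form log-scale link ICC ``sigma_b^2 / (sigma_b^2 + sigma_w^2)``.

    ``session_sd_effective`` is the within-subject spread of the session
    comparison at hand (for cross-scanner pairs, include the scanner-B
    extra spread in quadrature).
    """
    if subject_sd < 0 or session_sd_effective < 0:
        raise ValueError("spreads must be nonnegative")
    vb, vw = subject_sd ** 2, session_sd_effective ** 2
    if vb + vw == 0:
        raise ValueError("subject and session spreads cannot both be zero")
    return vb / (vb + vw)


def recovery_params(target_icc: float, seed: int, n_subjects: int = 20,
                    n_rois: int = 34) -> CohortParams:
    """Cohort parameters for a parameter-recovery run at a chosen
    theoretical link ICC.

    The recovery conditions keep the closed-form log-scale truth valid:
    dense regime with large streamline totals (counting noise negligible),
    no scanner effect, total log-weight spread 0.5 split between subject
    and session variance so ``subject_sd^2/(subject_sd^2+session_sd^2)``
    equals ``target_icc``, and a gentle distance decay so no link starves.
    """
    if not 0 < target_icc < 1:
        raise ValueError("target_icc must be in (0, 1)")
    total_sd = 0.5
    sb = total_sd * float(np.sqrt(target_icc))
    sw = total_sd * float(np.sqrt(1.0 - target_icc))
    return CohortParams(
        seed=seed, n_subjects=n_subjects, n_rois=n_rois,
        subject_sd=sb, session_sd=sw,
        scanner_b_gain=1.0, scanner_b_extra_sd=0.0,
        distance_decay=0.01, link_sd=0.8,
        regime="dense_probabilistic", mean_total_fibers=2.0e6,
    )


def _region_scheme(n_rois: int) -> list[tuple[str, str]]:
    """(label, hemisphere) pairs: bilateral pairs plus one unpaired midline
    node when ``n_rois`` is odd; the 83-node case uses the packaged names."""
    if n_rois == 83:
        out = []
        for name in DK_CORTICAL + DK_SUBCORTICAL:
            out.append((name, "left"))
            out.append((name, "right"))
        out.append(("brainstem", "none"))
        return out
    n_pairs = n_rois // 2
    out = []
    for i in range(n_pairs):
        out.append((f"region{i + 1:02d}", "left"))
        out.append((f"region{i + 1:02d}", "right"))
    if n_rois % 2:
        out.append(("midline", "none"))
    return out


def generate_roi_geometry(n_rois: int, seed: int) -> ROITable:
    """Synthetic ROI geometry: centroids on a jittered ellipsoidal shell
    (brain-sized semi-axes, mm) with exact left/right mirror symmetry for
    paired regions, log-normal volumes shared within a pair up to a small
    asymmetry, and surface area proportional to volume^(2/3)."""
    if n_rois < 3:
        raise ValueError("need at least 3 ROIs")
    rng = np.random.default_rng(seed)
    scheme = _region_scheme(n_rois)
    semi_axes = np.array([65.0, 85.0, 60.0])   # x (L-R), y (A-P), z (I-S)

    records: list[ROIRecord] = []
    pair_geom: dict[str, tuple[np.ndarray, float]] = {}
    for label, hemi in scheme:
        if hemi in ("left", "right"):
            if label not in pair_geom:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                u[0] = abs(u[0]) + 0.15          # keep off the midline
                u /= np.linalg.norm(u)
                radius = rng.uniform(0.45, 0.95)
                centroid = u * semi_axes * radius
                base_volume = float(np.exp(rng.normal(np.log(7000.0), 0.5)))
                pair_geom[label] = (centroid, base_volume)
            centroid, base_volume = pair_geom[label]
            sign = -1.0 if hemi == "left" else 1.0
            c = centroid * np.array([sign, 1.0, 1.0])
            volume = base_volume * float(np.exp(rng.normal(0.0, 0.08)))
        else:
            c = np.array([0.0, rng.uniform(-35.0, -15.0), rng.uniform(-45.0, -25.0)])
            volume = float(np.exp(rng.normal(np.log(20000.0), 0.2)))
        surface = 6.0 * volume ** (2.0 / 3.0)
        records.append(
            ROIRecord(label=label, hemisphere=hemi, centroid=tuple(c),
                      volume=volume, surface_area=surface)
        )
    return ROITable(records, atlas_name="lausanne83" if n_rois == 83 else f"synthetic{n_rois}")


def _link_structure(roi_table: ROITable, params: CohortParams, rng: np.random.Generator):
    """Fixed per-link quantities: expected mass, lengths, dropout prob.

    Expected streamline count scales with the product of the two
    gray/white boundary areas (seed voxels of one ROI times the acceptance
    surface of the other), decays exponentially with centroid distance, and
    carries an anatomy-fixed log-normal bundle-size spread.
    """
    n = len(roi_table)
    d = roi_table.distance_matrix()
    surf = roi_table.surface_areas
    log_surf = np.log(surf)
    iu = np.triu_indices(n, k=1)
    dist = d[iu]
    log_mu = (log_surf[iu[0]] + log_surf[iu[1]] - params.distance_decay * dist
              + rng.normal(0.0, params.link_sd, size=len(dist)))
    rel = np.exp(log_mu - log_mu.max())
    # scale so the expected per-session total streamline count matches
    lam = params.total_fibers * rel / rel.sum()
    surf_sum = (surf[:, None] + surf[None, :])[iu]
    if params.regime == "sparse_deterministic":
        dropout = 1.0 - np.exp(-dist / params.dropout_scale)
    else:
        dropout = np.zeros_like(dist)
    return iu, dist, surf_sum, lam, dropout


def generate_cohort(
    params: CohortParams, roi_table: ROITable | None = None
) -> tuple[list[FiberSet], GroundTruth]:
    """Generate one cohort of per-subject-per-session fiber sets plus the
    construction truth.

    Deterministic regime: one undirected record per tracked link, Poisson
    streamline count, fixed per-link length (centroid distance times a
    log-normal tortuosity >= 1 sampled once per link).  Probabilistic
    regime: two seeded records per link (one per seeding direction), each a
    Poisson streamline count converted to a distance-corrected mass
    (count x length).

    The seed governs three separate random streams: anatomy (geometry,
    per-link bundle sizes, fiber lengths) and subject biology (per-subject
    link effects) are shared between the two regimes at equal seed — both
    tractography methods observe the same brains — while measurement noise
    (session effects, tracking dropout, counting noise) is regime-specific.
    """
    rng_anat = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    rng_bio = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, 2, REGIMES.index(params.regime)])
    )
    if roi_table is None:
        roi_table = generate_roi_geometry(params.n_rois, int(rng_anat.integers(2 ** 31)))
    elif len(roi_table) != params.n_rois:
        raise ValueError(
            f"roi_table has {len(roi_table)} ROIs but params.n_rois={params.n_rois}"
        )
    iu, dist, surf_sum, lam, dropout = _link_structure(roi_table, params, rng_anat)
    n_links = len(lam)
    keys = roi_table.keys
    key_a = [keys[i] for i in iu[0]]
    key_b = [keys[j] for j in iu[1]]

    # anatomy-fixed fiber lengths: centroid distance x tortuosity >= 1
    tortuosity = np.maximum(np.exp(rng_anat.normal(0.15, 0.1, size=n_links)), 1.0)
    lengths = dist * tortuosity

    vw_a = params.session_sd ** 2
    vw_b = vw_a + params.scanner_b_extra_sd ** 2
    icc_within = np.full(n_links, theoretical_link_icc(params.subject_sd, params.session_sd))
    icc_between = np.full(
        n_links, theoretical_link_icc(params.subject_sd, float(np.sqrt(vw_b)))
    )
    truth = GroundTruth(
        roi_table=roi_table, pairs=np.stack(iu, axis=1), base_weight=lam,
        lengths=lengths, icc_within_scanner=icc_within,
        icc_between_scanner=icc_between, dropout_prob=dropout,
    )

    method = params.method
    fiber_sets: list[FiberSet] = []
    for s in range(params.n_subjects):
        subject_id = f"sub{s + 1:02d}"
        subj_effect = rng_bio.normal(0.0, params.subject_sd, size=n_links)
        for session_id, scanner_id in params.sessions:
            if scanner_id == "B":
                sd = float(np.sqrt(vw_b))
                gain = np.log(params.scanner_b_gain)
                # different head coil -> different tracking success profile
                session_dropout = 1.0 - (1.0 - dropout) ** params.scanner_b_dropout_gain
            else:
                sd = params.session_sd
                gain = 0.0
                session_dropout = dropout
            sess_effect = rng.normal(0.0, sd, size=n_links)
            lam_obs = lam * np.exp(subj_effect + sess_effect + gain)
            if params.regime == "sparse_deterministic":
                tracked = rng.random(n_links) >= session_dropout
                if params.count_noise:
                    counts = rng.poisson(lam_obs * tracked).astype(float)
                else:
                    counts = lam_obs * tracked
                nz = np.nonzero(counts)[0]
                records = [
                    FiberRecord(key_a[i], key_b[i], float(lengths[i]),
                                float(counts[i]), "undirected")
                    for i in nz
                ]
            else:
                if params.count_noise:
                    counts_a = rng.poisson(lam_obs).astype(float)
                    counts_b = rng.poisson(lam_obs).astype(float)
                else:
                    counts_a = counts_b = lam_obs
                records = []
                for i in range(n_links):
                    if counts_a[i]:
                        records.append(
                            FiberRecord(key_a[i], key_b[i], float(lengths[i]),
                                        float(counts_a[i] * lengths[i]), "a_seeded")
                        )
                    if counts_b[i]:
                        records.append(
                            FiberRecord(key_a[i], key_b[i], float(lengths[i]),
                                        float(counts_b[i] * lengths[i]), "b_seeded")
                        )
            fiber_sets.append(
                FiberSet(subject_id, session_id, scanner_id, method, records)
            )
    return fiber_sets, truth
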