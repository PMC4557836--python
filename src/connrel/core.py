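"""Domain containers and file I/O for structural connectome reliability studies.

The objects here model the substrate of a multi-session tractography study:
gray-matter parcels (:class:`ROIRecord` / :class:`ROITable`), streamline
evidence (:class:`FiberRecord` / :class:`FiberSet`), weighted adjacency
(:class:`ConnectivityMatrix`) and the full subject-by-session collection
(:class:`SessionStack`) that reliability statistics operate on.

All tabular formats are tab-separated UTF-8 text with "." decimals and "NA"
as the missing-value token; connectivity and ICC matrices carry ROI keys as
both a header row and a header column.  ROI ordering is always the order of
the ROI table, which is the single source of truth for matrix row/column
identity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right", "none")

#: hemisphere -> key prefix used in matrix headers and fiber tables
_HEMI_PREFIX = {"left": "lh.", "right": "rh.", "none": ""}
_PREFIX_HEMI = {"lh": "left", "rh": "right"}

MISSING_TOKEN = "NA"

ROI_COLUMNS = (
    "label",
    "hemisphere",
    "centroid_x",
    "centroid_y",
    "centroid_z",
    "volume_mm3",
    "surface_mm2",
)

FIBER_COLUMNS = (
    "subject",
    "session",
    "scanner",
    "method",
    "roi_a",
    "hemi_a",
    "roi_b",
    "hemi_b",
    "length_mm",
    "count",
    "direction",
)


def roi_key(label: str, hemisphere: str) -> str:
    """Qualified ROI name, e.g. ``lh.superiorfrontal`` or ``brainstem``."""
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    return _HEMI_PREFIX[hemisphere] + label


def split_roi_key(key: str) -> tuple[str, str]:
    """Inverse of :func:`roi_key`: ``lh.x`` -> (``x``, ``left``)."""
    head, _, tail = key.partition(".")
    if tail and head in _PREFIX_HEMI:
        return tail, _PREFIX_HEMI[head]
    return key, "none"


@dataclass(frozen=True)
class ROIRecord:
    """A gray-matter parcel: anatomical label plus the geometry used for
    edge-weight normalization (surface area) and anatomical correlates
    (centroid distance, volume)."""

    label: str
    hemisphere: str
    centroid: tuple[float, float, float]
    volume: float          # mm^3, > 0
    surface_area: float    # mm^2, gray/white boundary area, > 0

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        c = tuple(float(x) for x in self.centroid)
        if len(c) != 3 or not all(math.isfinite(x) for x in c):
            raise ValueError(f"centroid must be a finite 3-vector, got {self.centroid!r}")
        object.__setattr__(self, "centroid", c)
        if not (self.volume > 0 and math.isfinite(self.volume)):
            raise ValueError(f"volume must be strictly positive, got {self.volume!r}")
        if not (self.surface_area > 0 and math.isfinite(self.surface_area)):
            raise ValueError(f"surface_area must be strictly positive, got {self.surface_area!r}")

    @property
    def key(self) -> str:
        return roi_key(self.label, self.hemisphere)


class ROITable:
    """Ordered collection of :class:`ROIRecord` defining the node scheme.

    The record order fixes the row/column order of every matrix built
    against this table.
    """

    def __init__(self, records: Iterable[ROIRecord], atlas_name: str = "custom"):
        self.records: list[ROIRecord] = list(records)
        self.atlas_name = atlas_name
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate label+hemisphere entries: {dupes}")
        self._index: dict[str, int] = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ROIRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ROIRecord:
        return self.records[i]

    @property
    def keys(self) -> list[str]:
        return [r.key for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def index_of(self, key: str) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"ROI {key!r} not in table ({self.atlas_name})") from None

    @property
    def centroids(self) -> np.ndarray:
        return np.array([r.centroid for r in self.records], dtype=float)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([r.volume for r in self.records], dtype=float)

    @property
    def surface_areas(self) -> np.ndarray:
        return np.array([r.surface_area for r in self.records], dtype=float)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances (mm), shape (n, n)."""
        c = self.centroids
        d = c[:, None, :] - c[None, :, :]
        return np.sqrt((d ** 2).sum(axis=2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [r.label for r in self.records],
                "hemisphere": [r.hemisphere for r in self.records],
                "centroid_x": [r.centroid[0] for r in self.records],
                "centroid_y": [r.centroid[1] for r in self.records],
                "centroid_z": [r.centroid[2] for r in self.records],
                "volume_mm3": [r.volume for r in self.records],
                "surface_mm2": [r.surface_area for r in self.records],
            }
        )


@dataclass(frozen=True)
class FiberRecord:
    """One streamline bundle record.

    ``roi_a``/``roi_b`` are qualified ROI keys (see :func:`roi_key`).
    ``count`` is the number of streamlines, or the distance-corrected
    streamline mass in the probabilistic regime; a record with count > 1
    stands for that many identical fibers of the stated length.
    """

    roi_a: str
    roi_b: str
    length: float   # mm, > 0
    count: float    # >= 0
    direction: str = "undirected"   # {a_seeded, b_seeded, undirected}

    def __post_init__(self) -> None:
        if not (self.length > 0 and math.isfinite(self.length)):
            raise ValueError(f"fiber length must be > 0, got {self.length!r}")
        if not (self.count >= 0 and math.isfinite(self.count)):
            raise ValueError(f"fiber count must be >= 0, got {self.count!r}")
        if self.direction not in ("a_seeded", "b_seeded", "undirected"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class FiberSet:
    """All fiber records for one subject, session and tractography method."""

    subject_id: str
    session_id: str
    scanner_id: str
    method: str                       # {deterministic, probabilistic}
    records: list[FiberRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in ("deterministic", "probabilistic"):
            raise ValueError(f"unknown method {self.method!r}")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Vectorization surface: one row per record."""
        return pd.DataFrame(
            {
                "roi_a": [r.roi_a for r in self.records],
                "roi_b": [r.roi_b for r in self.records],
                "length": [r.length for r in self.records],
                "count": [r.count for r in self.records],
                "direction": [r.direction for r in self.records],
            }
        )

    def validate_against(self, roi_table: ROITable) -> None:
        """Check every endpoint label resolves against ``roi_table``."""
        known = set(roi_table.keys)
        for i, r in enumerate(self.records):
            for end in (r.roi_a, r.roi_b):
                if end not in known:
                    raise KeyError(
                        f"record {i} of {self.subject_id}/{self.session_id}: "
                        f"ROI {end!r} not in table"
                    )


class ConnectivityMatrix:
    """Symmetric nonnegative weighted adjacency over the ROIs of a table.

    Invariants (enforced at construction): square, symmetric, zero diagonal,
    finite, all entries >= 0.
    """

    def __init__(
        self,
        roi_table: ROITable,
        weights: np.ndarray,
        method: str = "deterministic",
        subject_id: str | None = None,
        session_id: str | None = None,
        scanner_id: str | None = None,
    ):
        w = np.asarray(weights, dtype=float)
        n = len(roi_table)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} does not match {n} ROIs")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(w, w.T, rtol=0, atol=1e-12 * max(1.0, float(np.abs(w).max()))):
            raise ValueError("weights must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.roi_table = roi_table
        self.weights = w
        self.method = method
        self.subject_id = subject_id
        self.session_id = session_id
        self.scanner_id = scanner_id

    @property
    def n_rois(self) -> int:
        return len(self.roi_table)


class SessionStack:
    """Complete subject-by-session grid of connectivity matrices.

    Each scanning session plays the role of a "rater" in the reliability
    analysis; the stack is the input to link-wise and node-wise ICC.
    """

    def __init__(
        self,
        subjects: Sequence[str],
        sessions: Sequence[tuple[str, str]],
        matrices: Mapping[tuple[str, str], ConnectivityMatrix],
        method: str | None = None,
    ):
        self.subjects = list(subjects)
        self.sessions = [(str(s), str(sc)) for s, sc in sessions]
        self.matrices = dict(matrices)
        missing = [
            (subj, sess)
            for subj in self.subjects
            for sess, _ in self.sessions
            if (subj, sess) not in self.matrices
        ]
        if missing:
            raise ValueError(f"incomplete stack, missing cells: {missing}")
        tables = {id(m.roi_table) for m in self.matrices.values()}
        if len(tables) > 1:
            keysets = {tuple(m.roi_table.keys) for m in self.matrices.values()}
            if len(keysets) > 1:
                raise ValueError("matrices do not share a single ROI table/ordering")
        first = next(iter(self.matrices.values()))
        self.roi_table = first.roi_table
        self.method = method if method is not None else first.method

    @property
    def session_ids(self) -> list[str]:
        return [s for s, _ in self.sessions]

    def scanner_of(self, session_id: str) -> str:
        for s, sc in self.sessions:
            if s == session_id:
                return sc
        raise KeyError(f"unknown session {session_id!r}")

    def matrix(self, subject: str, session: str) -> ConnectivityMatrix:
        return self.matrices[(subject, session)]

    def weight_array(self, session_ids: Sequence[str] | None = None) -> np.ndarray:
        """Dense view, shape (n_subjects, n_sessions, n_roi, n_roi)."""
        sids = list(session_ids) if session_ids is not None else self.session_ids
        n = len(self.roi_table)
        out = np.empty((len(self.subjects), len(sids), n, n))
        for i, subj in enumerate(self.subjects):
            for j, sess in enumerate(sids):
                out[i, j] = self.matrices[(subj, sess)].weights
        return out

    def mean_matrix(self, session_id: str) -> ConnectivityMatrix:
        """Across-subject average matrix for one session."""
        w = self.weight_array([session_id])[:, 0].mean(axis=0)
        return ConnectivityMatrix(
            self.roi_table, w, method=self.method, session_id=session_id,
            scanner_id=self.scanner_of(session_id),
        )


# ---------------------------------------------------------------------------
# geometry helpers

def euclidean_distance(roi_i: ROIRecord, roi_j: ROIRecord) -> float:
    """Euclidean distance between ROI centroids, in mm."""
    a, b = np.asarray(roi_i.centroid), np.asarray(roi_j.centroid)
    return float(np.linalg.norm(a - b))


def volume_features(roi_i: ROIRecord, roi_j: ROIRecord) -> tuple[float, float]:
    """(volume sum in mm^3, volume ratio max/min >= 1) for a ROI pair.

    The ratio is defined orientation-free (larger over smaller) so that
    correlations with it do not depend on pair ordering.
    """
    vi, vj = roi_i.volume, roi_j.volume
    return vi + vj, max(vi, vj) / min(vi, vj)


# ---------------------------------------------------------------------------
# readers / writers

def read_roi_table(path: str | Path, atlas_name: str | None = None) -> ROITable:
    """Read an ROI geometry TSV (columns: label, hemisphere, centroid_x/y/z,
    volume_mm3, surface_mm2); row order becomes the node order."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"label": str, "hemisphere": str},
                     float_precision="round_trip")
    missing = [c for c in ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = [
        ROIRecord(
            label=row.label,
            hemisphere=row.hemisphere,
            centroid=(row.centroid_x, row.centroid_y, row.centroid_z),
            volume=row.volume_mm3,
            surface_area=row.surface_mm2,
        )
        for row in df.itertuples()
    ]
    return ROITable(records, atlas_name=atlas_name or Path(path).stem)


def write_roi_table(table: ROITable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def lausanne_roi_table() -> ROITable:
    """The packaged 83-node parcellation fixture (41 bilateral regions plus
    an unpaired brainstem node; 42 distinct region names).

    Region names follow the Desikan-Killiany-derived cortical/subcortical
    scheme; the geometry (centroids, volumes, surfaces) is synthetic,
    generated once with :func:`connrel.cohort.generate_roi_geometry` and
    frozen into the packaged TSV.
    """
    ref = resources.files("connrel").joinpath("data/lausanne83.tsv")
    with resources.as_file(ref) as p:
        return read_roi_table(p, atlas_name="lausanne83")


def read_matrix(
    path: str | Path,
    roi_table: ROITable,
    max_asymmetry: float = 1e-8,
    **matrix_kwargs,
) -> ConnectivityMatrix:
    """Read a square matrix TSV against ``roi_table``.

    Accepts the canonical dialect (header row + header column of ROI keys)
    or a headerless square numeric block of matching dimension.  The matrix
    is symmetrized by averaging; asymmetries beyond ``max_asymmetry``
    (relative to the largest entry) are rejected, as are negative entries
    and dimension mismatches.
    """
    n = len(roi_table)
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = first.iloc[0].astype(str).str.match(r"^[\d\.\-+eE]+$").sum() < first.shape[1] - 1
    if has_header:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN],
                         float_precision="round_trip")
        if list(df.columns) != roi_table.keys or list(df.index) != roi_table.keys:
            if df.shape != (n, n):
                raise ValueError(
                    f"{path}: matrix is {df.shape}, expected {n}x{n} for this ROI table"
                )
            raise ValueError(f"{path}: header labels do not match the ROI table order")
        w = df.to_numpy(dtype=float)
    else:
        w = pd.read_csv(path, sep="\t", header=None, na_values=[MISSING_TOKEN],
                        float_precision="round_trip").to_numpy(dtype=float)
    if w.shape != (n, n):
        raise ValueError(f"{path}: matrix is {w.shape}, expected {n}x{n} for this ROI table")
    if np.isnan(w).any():
        raise ValueError(f"{path}: missing values are not allowed in a connectivity matrix")
    if (w < 0).any():
        raise ValueError(f"{path}: negative entries are not allowed")
    scale = max(1.0, float(np.abs(w).max()))
    if np.abs(w - w.T).max() > max_asymmetry * scale:
        raise ValueError(f"{path}: asymmetry exceeds tolerance {max_asymmetry}")
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(roi_table, w, **matrix_kwargs)


def write_matrix(matrix: ConnectivityMatrix | np.ndarray, path: str | Path,
                 roi_table: ROITable | None = None) -> None:
    """Write a matrix in the canonical dialect (ROI keys as header row and
    column, NA for missing entries, full float precision)."""
    if isinstance(matrix, ConnectivityMatrix):
        w, table = matrix.weights, matrix.roi_table
    else:
        if roi_table is None:
            raise ValueError("roi_table required when writing a bare array")
        w, table = np.asarray(matrix, dtype=float), roi_table
    df = pd.DataFrame(w, index=table.keys, columns=table.keys)
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def write_fibers(fiber_sets: Iterable[FiberSet], path: str | Path) -> None:
    """Write fiber records for one or more subject/session sets to one TSV."""
    frames = []
    for fs in fiber_sets:
        df = fs.to_frame()
        la, ha = zip(*(split_roi_key(k) for k in df["roi_a"])) if len(df) else ((), ())
        lb, hb = zip(*(split_roi_key(k) for k in df["roi_b"])) if len(df) else ((), ())
        frames.append(
            pd.DataFrame(
                {
                    "subject": fs.subject_id,
                    "session": fs.session_id,
                    "scanner": fs.scanner_id,
                    "method": fs.method,
                    "roi_a": la,
                    "hemi_a": ha,
                    "roi_b": lb,
                    "hemi_b": hb,
                    "length_mm": df["length"].to_numpy() if len(df) else [],
                    "count": df["count"].to_numpy() if len(df) else [],
                    "direction": df["direction"].to_numpy() if len(df) else [],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=FIBER_COLUMNS)
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_fibers(path: str | Path) -> list[FiberSet]:
    """Read a fiber TSV back into per-(subject, session, method) FiberSets."""
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "session": str, "scanner": str},
                     keep_default_na=False, na_values=[MISSING_TOKEN],
                     float_precision="round_trip")
    missing = [c for c in FIBER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sets = []
    for (subj, sess, scanner, method), grp in df.groupby(
        ["subject", "session", "scanner", "method"], sort=False
    ):
        records = [
            FiberRecord(
                roi_a=roi_key(row.roi_a, row.hemi_a),
                roi_b=roi_key(row.roi_b, row.hemi_b),
                length=row.length_mm,
                count=row.count,
                direction=row.direction,
            )
            for row in grp.itertuples()
        ]
        sets.append(FiberSet(subj, sess, scanner, method, records))
    return sets


def write_stack(stack: SessionStack, out_dir: str | Path, prefix: str = "matrix") -> Path:
    """Write every matrix of a stack plus a JSON manifest; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roi_path = out / "roi_table.tsv"
    write_roi_table(stack.roi_table, roi_path)
    entries = {}
    for subj in stack.subjects:
        for sess, _ in stack.sessions:
            rel = f"{prefix}_{stack.method}_{subj}_{sess}.tsv"
            write_matrix(stack.matrices[(subj, sess)], out / rel)
            entries[f"{subj}/{sess}"] = rel
    manifest = {
        "method": stack.method,
        "roi_table": roi_path.name,
        "subjects": stack.subjects,
        "sessions": [list(s) for s in stack.sessions],
        "matrices": entries,
    }
    mpath = out / f"stack_{stack.method}.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_stack(manifest_path: str | Path) -> SessionStack:
    """Load a stack from a manifest written by :func:`write_stack`."""
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    base = mpath.parent
    roi_table = read_roi_table(base / manifest["roi_table"])
    sessions = [tuple(s) for s in manifest["sessions"]]
    scanner = dict(sessions)
    matrices = {}
    for key, rel in manifest["matrices"].items():
        subj, sess = key.split("/")
        matrices[(subj, sess)] = read_matrix(
            base / rel, roi_table, method=manifest["method"],
            subject_id=subj, session_id=sess, scanner_id=scanner.get(sess),
        )
    return SessionStack(manifest["subjects"], sessions, matrices, method=manifest["method"])
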