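"""Connectome and cohort I/O.

Connectomes arrive as delimited-text square matrices (the format written by
MRtrix ``tck2connectome``): entry (i, j) is the number of streamlines joining
region i and region j. A valid connectome is square, symmetric, non-negative,
and has a zero diagonal. Cohort metadata is a TSV/CSV with columns
``subject_id``, ``age``, ``sex``, ``site``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: absolute tolerance for the symmetry invariant of a validated connectome
SYMMETRY_ATOL = 1e-9
#: relative asymmetry above which an input matrix is treated as corrupt
ASYMMETRY_RTOL = 1e-6

#: internal numeric encoding of sex (recorded in all outputs)
SEX_CODES = {"female": 1, "male": 0}

_SEX_TOKENS = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
}


class ConnectomeFormatError(ValueError):
    """The file or table does not have the expected shape/columns."""


class ConnectomeIntegrityError(ValueError):
    """The matrix violates a connectome invariant (asymmetry, negativity)."""


@dataclass(frozen=True)
class Connectome:
    """A weighted, undirected brain network.

    Parameters
    ----------
    weights
        ``n x n`` non-negative symmetric matrix of edge weights (streamline
        counts or derived weights); the diagonal is zero.
    node_labels
        Ordered region names, one per node.
    """

    weights: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        _validate_weights(w)
        if len(self.node_labels) != w.shape[0]:
            raise ConnectomeFormatError(
                f"{len(self.node_labels)} node labels for a {w.shape[0]}-node matrix"
            )

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def with_weights(self, weights: np.ndarray) -> "Connectome":
        return Connectome(weights=weights, node_labels=self.node_labels)


def default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"region_{i:03d}" for i in range(n))


def _validate_weights(w: np.ndarray) -> None:
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ConnectomeFormatError(f"weights must be square, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ConnectomeIntegrityError("non-finite entries in connectome")
    if np.any(w < 0):
        raise ConnectomeIntegrityError("negative entries in connectome")
    if np.max(np.abs(w - w.T), initial=0.0) > SYMMETRY_ATOL:
        raise ConnectomeIntegrityError("connectome is not symmetric")
    if np.any(np.diagonal(w) != 0):
        raise ConnectomeIntegrityError("connectome diagonal must be zero")


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: demographics plus their connectome."""

    subject_id: str
    age: float
    sex: str  # "female" | "male"
    site: str
    connectome: Connectome

    def __post_init__(self) -> None:
        if self.sex not in SEX_CODES:
            raise ConnectomeFormatError(
                f"sex must be one of {sorted(SEX_CODES)}, got {self.sex!r}"
            )
        if not (np.isfinite(self.age) and 0 < self.age < 120):
            raise ConnectomeFormatError(
                f"age must be finite and in (0, 120) years, got {self.age!r}"
            )

    @property
    def sex_code(self) -> int:
        return SEX_CODES[self.sex]


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of subject records sharing one node scheme."""

    records: tuple[SubjectRecord, ...]
    site_vocabulary: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        if not self.site_vocabulary:
            object.__setattr__(
                self, "site_vocabulary", tuple(sorted({r.site for r in records}))
            )
        else:
            object.__setattr__(self, "site_vocabulary", tuple(self.site_vocabulary))
        ids = [r.subject_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConnectomeFormatError(f"duplicate subject ids: {dupes}")
        unknown = sorted({r.site for r in records} - set(self.site_vocabulary))
        if unknown:
            raise ConnectomeFormatError(f"sites outside the vocabulary: {unknown}")
        if records:
            n0, labels0 = records[0].connectome.n, records[0].connectome.node_labels
            for r in records:
                if r.connectome.n != n0 or r.connectome.node_labels != labels0:
                    raise ConnectomeFormatError(
                        f"subject {r.subject_id} has a different node scheme"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    @property
    def n_nodes(self) -> int:
        if not self.records:
            raise ConnectomeFormatError("empty cohort has no node count")
        return self.records[0].connectome.n

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        keep = set(subject_ids)
        return Cohort(
            records=tuple(r for r in self.records if r.subject_id in keep),
            site_vocabulary=self.site_vocabulary,
        )

    def by_site(self, site: str) -> tuple[SubjectRecord, ...]:
        return tuple(r for r in self.records if r.site == site)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
                "site": [r.site for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str | None:
    """Return "," for comma-separated files, else None (any whitespace)."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "," if "," in line else None
    return None


def read_connectome(
    path: str | Path,
    delimiter: str = "auto",
    node_labels: Sequence[str] | None = None,
) -> Connectome:
    """Read a delimited-text square connectome matrix.

    Mild asymmetry (relative magnitude up to ``ASYMMETRY_RTOL``) is repaired
    by averaging ``(W + W.T) / 2``; anything larger is treated as corrupt
    data. The diagonal is zeroed.
    """
    path = Path(path)
    if delimiter == "auto":
        sep = _sniff_delimiter(path)
    elif delimiter == "comma":
        sep = ","
    elif delimiter == "whitespace":
        sep = None
    else:
        raise ValueError(f"delimiter must be auto|comma|whitespace, got {delimiter!r}")
    try:
        w = np.loadtxt(path, delimiter=sep, ndmin=2, dtype=float)
    except ValueError as exc:
        raise ConnectomeFormatError(f"{path}: not a numeric table ({exc})") from exc
    if w.shape[0] != w.shape[1]:
        raise ConnectomeFormatError(f"{path}: non-square table {w.shape}")
    if np.any(w < 0):
        raise ConnectomeIntegrityError(f"{path}: negative entries")
    scale = max(np.max(np.abs(w)), 1.0)
    asym = np.max(np.abs(w - w.T), initial=0.0)
    if asym > ASYMMETRY_RTOL * scale:
        raise ConnectomeIntegrityError(
            f"{path}: asymmetry {asym:.3g} exceeds tolerance "
            f"{ASYMMETRY_RTOL * scale:.3g}"
        )
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    labels = tuple(node_labels) if node_labels is not None else default_labels(w.shape[0])
    return Connectome(weights=w, node_labels=labels)


def write_connectome(path: str | Path, conn: Connectome, delimiter: str = ",") -> None:
    np.savetxt(path, conn.weights, delimiter=delimiter, fmt="%.10g")


def connectome_filename(subject_id: str) -> str:
    """Connectome file name for a subject id (``<id>.csv``)."""
    safe = re.sub(r"[^\w.-]", "_", subject_id)
    return f"{safe}.csv"


def read_cohort(metadata_path: str | Path, connectome_dir: str | Path) -> Cohort:
    """Load a cohort: metadata table plus one connectome file per subject.

    The metadata must contain columns ``subject_id``, ``age``, ``sex``,
    ``site``. For each subject a file ``<subject_id>.csv`` (or ``.tsv`` /
    ``.txt``) is looked up in ``connectome_dir``. The site vocabulary is the
    sorted set of observed site labels.
    """
    metadata_path = Path(metadata_path)
    connectome_dir = Path(connectome_dir)
    meta = pd.read_csv(metadata_path, sep=None, engine="python", dtype=str)
    required = ["subject_id", "age", "sex", "site"]
    missing_cols = [c for c in required if c not in meta.columns]
    if missing_cols:
        raise ConnectomeFormatError(
            f"{metadata_path}: missing metadata columns {missing_cols}"
        )

    missing_files: list[str] = []
    records: list[SubjectRecord] = []
    for row in meta.itertuples(index=False):
        sid = str(row.subject_id)
        token = str(row.sex).strip().lower()
        if token not in _SEX_TOKENS:
            raise ConnectomeFormatError(
                f"{metadata_path}: unknown sex token {row.sex!r} for subject {sid}"
            )
        conn_path = None
        stem = connectome_filename(sid)
        for candidate in (stem, stem.replace(".csv", ".tsv"), stem.replace(".csv", ".txt")):
            if (connectome_dir / candidate).exists():
                conn_path = connectome_dir / candidate
                break
        if conn_path is None:
            missing_files.append(sid)
            continue
        records.append(
            SubjectRecord(
                subject_id=sid,
                age=float(row.age),
                sex=_SEX_TOKENS[token],
                site=str(row.site),
                connectome=read_connectome(conn_path),
            )
        )
    if missing_files:
        raise LookupError(
            f"no connectome file in {connectome_dir} for subjects: {missing_files}"
        )
    return Cohort(records=tuple(records))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write ``metadata.tsv`` plus one connectome CSV per subject."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conn_dir = out_dir / "connectomes"
    conn_dir.mkdir(exist_ok=True)
    cohort.to_frame().to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    for rec in cohort:
        write_connectome(conn_dir / connectome_filename(rec.subject_id), rec.connectome)
    return out_dir


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def threshold_connectome(
    conn: Connectome,
    total_streamlines: int = 10_000_000,
    fraction: float = 1e-7,
) -> Connectome:
    """Remove edges lighter than ``fraction`` of the total streamline count.

    With the defaults (10 million streamlines, fraction ``1e-7`` i.e.
    0.00001%), the cutoff weight is 1.0: edges with weight strictly below 1
    streamline are zeroed, edges at or above the cutoff are kept unchanged.
    Idempotent; never increases any entry.
    """
    if total_streamlines <= 0:
        raise ValueError(f"total_streamlines must be positive, got {total_streamlines}")
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    cutoff = fraction * total_streamlines
    w = conn.weights.copy()
    w[w < cutoff] = 0.0
    return conn.with_weights(w)


def vectorize(conn: Connectome) -> np.ndarray:
    """Strict upper triangle in row-major order, length ``n(n-1)/2``."""
    iu = np.triu_indices(conn.n, k=1)
    return conn.weights[iu].copy()


def devectorize(
    vec: np.ndarray, n: int, node_labels: Sequence[str] | None = None
) -> Connectome:
    """Inverse of :func:`vectorize`: rebuild the symmetric zero-diagonal matrix."""
    vec = np.asarray(vec, dtype=float)
    expected = n * (n - 1) // 2
    if vec.shape != (expected,):
        raise ConnectomeFormatError(
            f"expected vector of length {expected} for n={n}, got shape {vec.shape}"
        )
    w = np.zeros((n, n), dtype=float)
    iu = np.triu_indices(n, k=1)
    w[iu] = vec
    w = w + w.T
    labels = tuple(node_labels) if node_labels is not None else default_labels(n)
    return Connectome(weights=w, node_labels=labels)
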