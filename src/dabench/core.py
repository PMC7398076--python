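"""Count-table data model, I/O, filtering, rarefaction and sparsity summaries.

The universal input of the framework is a features-by-samples table of
non-negative integer read counts (taxa in rows, samples in columns), together
with per-sample metadata (subject, group, sequencing center) and per-feature
annotations (taxonomy string, genus-level metabolism label).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "ValidationError",
    "EmptyResultError",
    "read_count_table",
    "write_count_table",
    "filter_counts",
    "rarefy",
    "zero_fraction",
]

#: sentinel used for any missing metadata value
ABSENT = "absent"

METABOLISM_LABELS = {"aerobic", "anaerobic", "facultative", "unassigned", ABSENT}

SAMPLE_META_COLUMNS = ["subject_id", "group", "center"]
FEATURE_META_COLUMNS = ["taxonomy", "metabolism"]


class ValidationError(ValueError):
    """Raised when an input violates the count-table contract."""


class EmptyResultError(ValueError):
    """Raised when a filter removes every sample or every feature."""


@dataclass
class CountTable:
    """Features x samples integer count matrix with aligned metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, features in rows (index =
        feature ids), samples in columns (columns = sample ids).
    sample_meta
        Optional per-sample records indexed by sample id with columns
        ``subject_id``, ``group``, ``center``.  Missing columns/values are
        filled with the sentinel ``"absent"``.  A ``library_size`` column is
        always (re)computed from the counts.
    feature_meta
        Optional per-feature records indexed by feature id with columns
        ``taxonomy`` and ``metabolism``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = pd.DataFrame(self.counts)
        values = counts.to_numpy()
        if values.size == 0 or counts.shape[0] < 1 or counts.shape[1] < 2:
            raise ValidationError(
                f"need at least 1 feature and 2 samples, got shape {counts.shape}"
            )
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(~np.isfinite(values.astype(float))):
            raise ValidationError("counts contain non-finite values")
        if np.any(values.astype(float) != np.floor(values.astype(float))):
            raise ValidationError("counts must be integers (non-integer cell found)")
        if np.any(values < 0):
            raise ValidationError("counts must be non-negative")
        counts = counts.astype(np.int64)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dupes}")
        if counts.columns.duplicated().any():
            dupes = counts.columns[counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        self.counts = counts
        self.sample_meta = _align_meta(
            self.sample_meta, counts.columns, SAMPLE_META_COLUMNS, "sample"
        )
        self.sample_meta["library_size"] = counts.sum(axis=0).to_numpy()
        self.feature_meta = _align_meta(
            self.feature_meta, counts.index, FEATURE_META_COLUMNS, "feature"
        )

    # -- convenience accessors -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample total read counts (recomputed, never stale)."""
        return self.counts.sum(axis=0)

    def matrix(self) -> np.ndarray:
        """Counts as a (features, samples) int64 array."""
        return self.counts.to_numpy()

    def copy(self) -> "CountTable":
        return CountTable(
            self.counts.copy(), self.sample_meta.copy(), self.feature_meta.copy()
        )

    def subset_samples(self, sample_ids) -> "CountTable":
        ids = [str(s) for s in sample_ids]
        return CountTable(
            self.counts.loc[:, ids],
            self.sample_meta.loc[ids],
            self.feature_meta,
        )

    def subset_features(self, feature_ids) -> "CountTable":
        ids = [str(f) for f in feature_ids]
        return CountTable(
            self.counts.loc[ids],
            self.sample_meta,
            self.feature_meta.loc[ids],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CountTable({self.n_features} features x {self.n_samples} samples, "
            f"zero fraction {zero_fraction(self)[0]:.2f})"
        )


def _align_meta(meta, index: pd.Index, columns, what: str) -> pd.DataFrame:
    if meta is None:
        meta = pd.DataFrame(index=index)
    else:
        meta = pd.DataFrame(meta).copy()
        meta.index = meta.index.astype(str)
        if meta.index.duplicated().any():
            raise ValidationError(f"duplicate {what} ids in metadata")
        missing = index.difference(meta.index)
        if len(missing):
            extra = pd.DataFrame(index=missing)
            meta = pd.concat([meta, extra])
        meta = meta.loc[index]
    for col in columns:
        if col not in meta.columns:
            meta[col] = ABSENT
        meta[col] = meta[col].fillna(ABSENT).astype(str)
    meta.index.name = f"{what}_id"
    return meta


# -- I/O ----------------------------------------------------------------------

def read_count_table(
    path,
    format: str = "tsv",
    sample_meta_path=None,
    feature_meta_path=None,
) -> CountTable:
    """Read a count table from TSV (or BIOM 2.1 HDF5) plus optional metadata.

    The TSV layout is: first column = feature ids (header ``feature_id``),
    remaining columns = one per sample.  Cells must be non-negative integers.
    """
    if format == "tsv":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        if counts.shape[1] == 0:
            raise ValidationError(f"{path}: no sample columns found (malformed header?)")
        for col in counts.columns:
            if not np.issubdtype(counts[col].dtype, np.number):
                raise ValidationError(f"{path}: non-numeric counts in column {col!r}")
    elif format == "biom":
        counts = _read_biom(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'biom')")

    sample_meta = None
    if sample_meta_path is not None:
        sample_meta = pd.read_csv(sample_meta_path, sep="\t", index_col=0, dtype=str)
    feature_meta = None
    if feature_meta_path is not None:
        feature_meta = pd.read_csv(feature_meta_path, sep="\t", index_col=0, dtype=str)
    return CountTable(counts, sample_meta, feature_meta)


def _read_biom(path) -> pd.DataFrame:
    # BIOM 2.1 stores a CSC sparse matrix under observation/matrix.
    import h5py  # optional dependency, only needed for biom input

    with h5py.File(path, "r") as fh:
        obs_ids = [x.decode() for x in fh["observation/ids"][:]]
        sample_ids = [x.decode() for x in fh["sample/ids"][:]]
        data = fh["observation/matrix/data"][:]
        indices = fh["observation/matrix/indices"][:]
        indptr = fh["observation/matrix/indptr"][:]
    from scipy.sparse import csr_matrix

    mat = csr_matrix(
        (data, indices, indptr), shape=(len(obs_ids), len(sample_ids))
    ).toarray()
    return pd.DataFrame(mat, index=obs_ids, columns=sample_ids)


def write_count_table(ct: CountTable, path, sample_meta_path=None, feature_meta_path=None):
    """Write the counts (and optionally metadata) as TSV, round-trip safe."""
    out = ct.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")
    if sample_meta_path is not None:
        meta = ct.sample_meta.drop(columns=["library_size"], errors="ignore")
        meta.to_csv(sample_meta_path, sep="\t")
    if feature_meta_path is not None:
        ct.feature_meta.to_csv(feature_meta_path, sep="\t")


# -- filtering ----------------------------------------------------------------

def filter_counts(
    ct: CountTable,
    min_libsize: int = 0,
    min_count: int = 10,
    min_samples: int = 1,
) -> CountTable:
    """Sample/feature prevalence filter with strict ("more than") thresholds.

    Keeps samples with library size strictly greater than ``min_libsize``,
    then keeps features observed with counts strictly greater than
    ``min_count`` in strictly more than ``min_samples`` samples.  Library
    sizes are recomputed on the result.  The operation is idempotent for
    fixed thresholds.
    """
    if min(min_libsize, min_count, min_samples) < 0:
        raise ValueError("filter thresholds must be >= 0")
    counts = ct.counts
    # iterate to a fixed point: dropping features can push a sample's
    # recomputed library size below the threshold, and vice versa
    while True:
        lib = counts.sum(axis=0)
        keep_samples = lib.index[lib.to_numpy() > min_libsize]
        if len(keep_samples) == 0:
            raise EmptyResultError(
                f"min_libsize={min_libsize} removed all samples "
                f"(max lib={lib.max()})"
            )
        trimmed = counts.loc[:, keep_samples]
        n_above = (trimmed.to_numpy() > min_count).sum(axis=1)
        keep_features = trimmed.index[n_above > min_samples]
        if len(keep_features) == 0:
            raise EmptyResultError(
                f"feature filter (count > {min_count} in > {min_samples} samples) "
                "removed all features"
            )
        new = trimmed.loc[keep_features]
        if new.shape == counts.shape:
            break
        counts = new
    if counts.shape[1] < 2:
        raise EmptyResultError("sample filter left fewer than 2 samples")
    return CountTable(
        counts,
        ct.sample_meta.loc[counts.columns],
        ct.feature_meta.loc[counts.index],
    )


# -- rarefaction --------------------------------------------------------------

def rarefy(ct: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Downsample every sample to ``depth`` reads without replacement.

    Each retained sample's column is replaced by a multivariate
    hypergeometric draw of ``depth`` reads from its observed reads, so the
    new library size is exactly ``depth`` and no cell can exceed its original
    count.  Samples with fewer than ``depth`` reads are dropped with a
    warning.
    """
    if depth <= 0:
        raise ValueError(f"depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    lib = ct.library_sizes
    keep = lib.index[lib.to_numpy() >= depth]
    dropped = lib.index.difference(keep)
    if len(dropped):
        warnings.warn(
            f"rarefy: dropped {len(dropped)} sample(s) with library size < {depth}: "
            f"{list(dropped)[:5]}...",
            stacklevel=2,
        )
    if len(keep) < 2:
        raise EmptyResultError(f"rarefaction depth {depth} left fewer than 2 samples")
    counts = ct.counts.loc[:, keep]
    out = np.empty(counts.shape, dtype=np.int64)
    mat = counts.to_numpy()
    for j in range(mat.shape[1]):
        col = mat[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(
        pd.DataFrame(out, index=counts.index, columns=counts.columns),
        ct.sample_meta.loc[keep],
        ct.feature_meta,
    )


# -- sparsity -----------------------------------------------------------------

def zero_fraction(ct: CountTable):
    """Overall fraction of zero cells and per-feature zero frequencies.

    Returns ``(overall, per_feature)`` where ``overall`` is
    ``#zeros / (F * n)`` and ``per_feature`` maps each feature to the
    fraction of samples in which it has a zero count.
    """
    zeros = ct.counts.to_numpy() == 0
    overall = float(zeros.mean())
    per_feature = pd.Series(zeros.mean(axis=1), index=ct.feature_ids, name="freq_zero")
    return overall, per_feature
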