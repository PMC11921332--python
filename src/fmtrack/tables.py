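"""Count tables, sample metadata, and metabolite tables.

The universal carrier between pipeline stages is :class:`FeatureTable`, an
integer matrix of amplicon sequence variants (ASVs) by samples, stored
features-as-rows (the common orientation of amplicon TSV exports).  Sample
metadata and the targeted-metabolomics panel get thin validated wrappers of
their own.  All on-disk formats are plain TSV, UTF-8, no quoting.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "TIMEPOINTS",
    "SAMPLE_TYPES",
    "FeatureTable",
    "SampleMetadata",
    "MetaboliteTable",
    "TableError",
    "read_feature_table",
    "write_feature_table",
    "filter_low_count_features",
    "relative_abundance",
    "read_sample_metadata",
    "read_metabolite_table",
    "write_metabolite_table",
]

#: Recipient group labels: untreated controls and the three inoculum arms
#: (sow-derived, wild-boar-derived, and the 1:1 mix of both).
GROUPS = ("Control", "Sow", "WB", "Mix")

#: Sampling days: post-natal day 21 (baseline, pre-inoculation), 27 (6 days
#: post-transplant) and 48 (28 days post-transplant / necropsy).
TIMEPOINTS = ("PND21", "PND27", "PND48")

SAMPLE_TYPES = ("fecal", "cecal", "inoculum")

METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "group",
    "timepoint",
    "sample_type",
    "pen",
    "litter",
    "sex",
)


class TableError(ValueError):
    """Raised for malformed or invariant-violating tables."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise TableError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclasses.dataclass(frozen=True)
class FeatureTable:
    """Integer ASV-by-sample count matrix.

    Parameters
    ----------
    feature_ids :
        Row labels (ASV identifiers), unique.
    sample_ids :
        Column labels, unique.
    counts :
        Non-negative integer matrix of shape
        ``(len(feature_ids), len(sample_ids))``.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise TableError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.feature_ids)} features, {len(self.sample_ids)} samples)"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise TableError(
                    f"non-integer count at feature {self.feature_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
        counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            bad = np.argwhere(counts < 0)[0]
            raise TableError(
                f"negative count at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        _check_unique(self.feature_ids, "feature_id")
        _check_unique(self.sample_ids, "sample_id")

    # -- basic accessors ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def sample_sums(self) -> np.ndarray:
        """Total counts (sequencing depth) per sample."""
        return self.counts.sum(axis=0)

    def feature_sums(self) -> np.ndarray:
        """Total counts per feature across all samples."""
        return self.counts.sum(axis=1)

    def features_present(self, sample_id: str) -> frozenset[str]:
        """Set of feature ids with count >= 1 in the given sample."""
        col = self.counts[:, self.sample_index(sample_id)]
        return frozenset(f for f, c in zip(self.feature_ids, col) if c > 0)

    # -- subsetting ---------------------------------------------------------

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = list(sample_ids)
        idx = [self.sample_index(s) for s in ids]
        return FeatureTable(self.feature_ids, tuple(ids), self.counts[:, idx])

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        ids = list(feature_ids)
        idx = [self.feature_index(f) for f in ids]
        return FeatureTable(tuple(ids), self.sample_ids, self.counts[idx, :])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.feature_ids), columns=list(self.sample_ids))
        df.index.name = "feature_id"
        return df


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a features-as-rows count TSV.

    First header cell must be ``feature_id``; remaining header cells are
    sample ids; cells are integers.  Errors name the offending row/column.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if not fields or fields[0] != "feature_id":
            raise TableError(
                f"{path}: first header cell must be 'feature_id', got {fields[0]!r}"
            )
        sample_ids = fields[1:]
        _check_unique(sample_ids, "sample_id")
        feature_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(sample_ids) + 1:
                raise TableError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, got {len(cells)}"
                )
            fid = cells[0]
            row = []
            for sid, cell in zip(sample_ids, cells[1:]):
                try:
                    value = int(cell)
                except ValueError:
                    raise TableError(
                        f"{path}:{lineno}: non-integer count {cell!r} "
                        f"(feature {fid!r}, sample {sid!r})"
                    ) from None
                if value < 0:
                    raise TableError(
                        f"{path}:{lineno}: negative count {value} "
                        f"(feature {fid!r}, sample {sid!r})"
                    )
                row.append(value)
            feature_ids.append(fid)
            rows.append(row)
    counts = np.asarray(rows, dtype=np.int64).reshape(len(feature_ids), len(sample_ids))
    return FeatureTable(tuple(feature_ids), tuple(sample_ids), counts)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table in the format read by :func:`read_feature_table`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(table.sample_ids) + "\n")
        for fid, row in zip(table.feature_ids, table.counts):
            fh.write(fid + "\t" + "\t".join(str(int(c)) for c in row) + "\n")


def filter_low_count_features(table: FeatureTable, min_total: int = 3) -> FeatureTable:
    """Drop features whose total count over all loaded samples is < ``min_total``.

    The default of 3 balances false-positive detections against falsely
    calling a microbe absent; the sum is taken over every sample in the
    table (inocula plus all piglet samples loaded for a run), so rare
    features backed up by multiple samples survive.  Idempotent.
    """
    if min_total < 1:
        raise ValueError(f"min_total must be >= 1, got {min_total}")
    keep = table.feature_sums() >= min_total
    ids = tuple(f for f, k in zip(table.feature_ids, keep) if k)
    return FeatureTable(ids, table.sample_ids, table.counts[keep, :])


def relative_abundance(table: FeatureTable) -> np.ndarray:
    """Column-normalized proportions; each sample column sums to 1."""
    sums = table.sample_sums()
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise TableError(f"sample {table.sample_ids[zero[0]]!r} has zero total count")
    return table.counts / sums[np.newaxis, :]


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SampleMetadata:
    """Per-sample study metadata, one row per sample.

    Wraps a DataFrame indexed by sample_id with columns subject_id, group,
    timepoint, sample_type, pen, litter, sex; the categorical columns are
    restricted to their enumerations.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in METADATA_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise TableError(f"metadata missing columns: {missing}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise TableError(f"duplicate sample_id {dup!r} in metadata")
        for col, allowed in (
            ("group", GROUPS),
            ("timepoint", TIMEPOINTS),
            ("sample_type", SAMPLE_TYPES),
        ):
            bad = set(df[col]) - set(allowed)
            if bad:
                raise TableError(f"invalid {col} value(s) {sorted(bad)}; allowed: {allowed}")
        object.__setattr__(self, "frame", df.copy())

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        """Check every given sample has exactly one metadata row."""
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise TableError(f"samples without metadata: {missing[:5]}")

    def select(
        self,
        group: str | None = None,
        timepoint: str | None = None,
        sample_type: str | None = None,
    ) -> tuple[str, ...]:
        """Sample ids matching the given group/timepoint/sample_type."""
        if group is not None and group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; allowed: {GROUPS}")
        if timepoint is not None and timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {timepoint!r}; allowed: {TIMEPOINTS}")
        if sample_type is not None and sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {sample_type!r}; allowed: {SAMPLE_TYPES}")
        mask = pd.Series(True, index=self.frame.index)
        if group is not None:
            mask &= self.frame["group"] == group
        if timepoint is not None:
            mask &= self.frame["timepoint"] == timepoint
        if sample_type is not None:
            mask &= self.frame["sample_type"] == sample_type
        return tuple(self.frame.index[mask])

    def group_of(self, sample_ids: Sequence[str]) -> list[str]:
        return list(self.frame.loc[list(sample_ids), "group"])

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise TableError(f"{path}: metadata must have a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# metabolite panel
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MetaboliteTable:
    """Targeted metabolite concentrations (metabolites x samples).

    Missing values (below the limit of detection, or not measured) are NaN.
    ``lod`` holds the per-metabolite limit of detection in the same units
    as the concentrations.
    """

    metabolite_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    concentrations: np.ndarray
    lod: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        conc = np.asarray(self.concentrations, dtype=float).copy()
        if conc.shape != (len(self.metabolite_ids), len(self.sample_ids)):
            raise TableError(
                f"concentration shape {conc.shape} does not match "
                f"({len(self.metabolite_ids)}, {len(self.sample_ids)})"
            )
        if np.any(conc[~np.isnan(conc)] < 0):
            raise TableError("negative concentration")
        lod = np.asarray(self.lod, dtype=float).copy()
        if lod.shape != (len(self.metabolite_ids),):
            raise TableError("lod must have one entry per metabolite")
        nonpos = ~np.isnan(lod) & ~(lod > 0)  # NaN = LOD undefined, allowed here
        if nonpos.any():
            bad = self.metabolite_ids[int(np.nonzero(nonpos)[0][0])]
            raise TableError(f"non-positive LOD for metabolite {bad!r}")
        conc.setflags(write=False)
        lod.setflags(write=False)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "lod", lod)
        _check_unique(self.metabolite_ids, "metabolite_id")
        _check_unique(self.sample_ids, "sample_id")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.concentrations, index=list(self.metabolite_ids), columns=list(self.sample_ids)
        )
        df.index.name = "metabolite_id"
        return df


def read_metabolite_table(path: str | Path, lod_path: str | Path) -> MetaboliteTable:
    """Read concentrations TSV plus its companion LOD TSV.

    Missing values are the literal token ``NA`` or an empty cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""], keep_default_na=False)
    lod_df = pd.read_csv(lod_path, sep="\t", index_col=0)
    if "lod" not in lod_df.columns:
        raise TableError(f"{lod_path}: expected a 'lod' column")
    missing = [m for m in df.index if m not in lod_df.index]
    if missing:
        raise TableError(f"metabolites without LOD entry: {missing[:5]}")
    lod = lod_df.loc[df.index, "lod"].to_numpy(dtype=float)
    return MetaboliteTable(
        tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float), lod
    )


def write_metabolite_table(
    table: MetaboliteTable, path: str | Path, lod_path: str | Path
) -> None:
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", na_rep="NA")
    lod_df = pd.DataFrame({"lod": table.lod}, index=list(table.metabolite_ids))
    lod_df.index.name = "metabolite_id"
    lod_df.to_csv(lod_path, sep="\t")
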