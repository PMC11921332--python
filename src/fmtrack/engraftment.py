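"""Donor-origin ASV classification and engraftment tracking.

The central question after a fecal-microbiota transplant: which members of a
donor inoculum actually established in the recipients?  Identity of the
transferred microbes is tracked at the ASV level.  An inoculum ASV is
*unique* to its donor if no recipient carried it at baseline (count 0 in
every pre-inoculation sample); its later appearance in a recipient is then
direct evidence of engraftment.  Inoculum ASVs already circulating in the
recipients at baseline are *common* and uninformative for source tracking.
Because the two donor inocula can themselves overlap, the unique ASVs split
further into source-specific and shared-unique strata, which are always
reported separately.

Detection counts between strata or groups are contrasted with a two-sided
Fisher exact test computed by exact hypergeometric enumeration (integer
arithmetic, minimum-likelihood two-sided rule).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping

import numpy as np

from .tables import FeatureTable, SampleMetadata

__all__ = [
    "ProvenanceClassification",
    "EngraftmentSummary",
    "ContingencyTable2x2",
    "ContrastCell",
    "classify_inoculum_asvs",
    "detect_engrafted_asvs",
    "summarize_engraftment_abundance",
    "fisher_exact_two_sided",
    "compare_engraftment_success",
]

STRATA = ("specific", "shared", "all")


@dataclasses.dataclass(frozen=True)
class ProvenanceClassification:
    """Partition of each donor's inoculum ASVs into unique vs common.

    ``unique[donor]`` holds the ASVs absent from every baseline sample,
    ``common[donor]`` those detected in at least one recipient before
    inoculation.  ``shared_unique`` is the intersection of all donors'
    unique sets (ASVs private to the inocula but carried by more than one
    donor).
    """

    donors: tuple[str, ...]
    unique: Mapping[str, frozenset[str]]
    common: Mapping[str, frozenset[str]]
    shared_unique: frozenset[str]

    def __post_init__(self) -> None:
        for donor in self.donors:
            u, c = self.unique[donor], self.common[donor]
            if u & c:
                raise ValueError(f"unique and common sets overlap for donor {donor!r}")
            if not self.shared_unique <= u:
                raise ValueError("shared_unique must be a subset of every donor's unique set")

    def stratum(self, donor: str, which: str) -> frozenset[str]:
        """Feature set of a reporting stratum for one donor.

        ``specific``: unique minus shared-unique; ``shared``: the
        shared-unique set; ``all``: the donor's full unique set.
        """
        if donor not in self.donors:
            raise KeyError(f"unknown donor {donor!r}; donors: {self.donors}")
        if which == "specific":
            return self.unique[donor] - self.shared_unique
        if which == "shared":
            return self.shared_unique
        if which == "all":
            return self.unique[donor]
        raise ValueError(f"unknown stratum {which!r}; allowed: {STRATA}")

    def counts_summary(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for donor in self.donors:
            out[donor] = {
                "unique": len(self.unique[donor]),
                "common": len(self.common[donor]),
                "total": len(self.unique[donor]) + len(self.common[donor]),
            }
        out["shared_unique"] = {"n": len(self.shared_unique)}
        return out


def classify_inoculum_asvs(
    inocula: FeatureTable, baseline: FeatureTable
) -> ProvenanceClassification:
    """Classify each donor's inoculum ASVs against pre-inoculation baselines.

    Each sample column of ``inocula`` is one donor inoculum (the column id is
    the donor label).  An inoculum ASV is *common* iff it has count >= 1 in
    at least one baseline sample, *unique* iff its count is 0 in every
    baseline sample.  Both tables should already have passed the global
    low-count filter.

    ``baseline`` must contain only pre-inoculation recipient samples; an
    empty baseline makes the classification undefined and raises.
    """
    if baseline.n_samples == 0:
        raise ValueError("baseline table has no samples; classification undefined")
    donors = inocula.sample_ids
    baseline_present = frozenset(
        f for f, s in zip(baseline.feature_ids, baseline.counts.sum(axis=1)) if s > 0
    )
    unique: dict[str, frozenset[str]] = {}
    common: dict[str, frozenset[str]] = {}
    for donor in donors:
        members = inocula.features_present(donor)
        common[donor] = frozenset(members & baseline_present)
        unique[donor] = frozenset(members - baseline_present)
    shared_unique = frozenset.intersection(*unique.values()) if donors else frozenset()
    return ProvenanceClassification(tuple(donors), unique, common, shared_unique)


def detect_engrafted_asvs(
    post: FeatureTable,
    metadata: SampleMetadata,
    classification: ProvenanceClassification,
    group: str,
    source: str,
    timepoint: str,
    stratum: str = "all",
    min_count: int = 1,
) -> frozenset[str]:
    """Source-unique ASVs detected in a recipient group at a timepoint.

    Returns the stratum members with count >= ``min_count`` in at least one
    sample of the group at the timepoint.  ``stratum`` selects
    source-specific-unique (``specific``), shared-unique (``shared``) or the
    full unique set (``all``).  The detection floor defaults to a single
    read, on top of the global low-count feature filter applied upstream.
    """
    samples = metadata.select(group=group, timepoint=timepoint)
    samples = tuple(s for s in samples if s in post.sample_ids)
    if not samples:
        raise ValueError(f"no samples for group {group!r} at timepoint {timepoint!r}")
    pool = classification.stratum(source, stratum)
    idx = [i for i, f in enumerate(post.feature_ids) if f in pool]
    cols = [post.sample_index(s) for s in samples]
    sub = post.counts[np.ix_(idx, cols)]
    hit = (sub >= min_count).any(axis=1)
    return frozenset(post.feature_ids[i] for i, h in zip(idx, hit) if h)


@dataclasses.dataclass(frozen=True)
class EngraftmentSummary:
    """Detection counts and relative-abundance summary for one stratum.

    ``per_sample_percent`` maps each sample of the group/timepoint to the
    percentage of its total reads carried by the detected ASVs; ``minimum``,
    ``mean`` and ``maximum`` summarize that vector.
    """

    group: str
    source: str
    timepoint: str
    stratum: str
    detected: frozenset[str]
    per_sample_percent: Mapping[str, float]
    minimum: float
    mean: float
    maximum: float

    @property
    def n_detected(self) -> int:
        return len(self.detected)

    def __post_init__(self) -> None:
        if not (0.0 <= self.minimum <= self.mean <= self.maximum <= 100.0 + 1e-9):
            raise ValueError("abundance summary must satisfy 0 <= min <= mean <= max <= 100")


def summarize_engraftment_abundance(
    post: FeatureTable,
    metadata: SampleMetadata,
    detected: Iterable[str],
    group: str,
    timepoint: str,
    source: str = "",
    stratum: str = "all",
) -> EngraftmentSummary:
    """Relative abundance (%) of a detected ASV set across a group's samples.

    Per sample, abundance% = 100 * (reads on detected ASVs) / (total reads);
    the summary reports min, mean and max over the group's samples at the
    timepoint.  An empty detected set gives (0, 0, 0); the full feature set
    gives (100, 100, 100).
    """
    detected = frozenset(detected)
    samples = metadata.select(group=group, timepoint=timepoint)
    samples = tuple(s for s in samples if s in post.sample_ids)
    if not samples:
        raise ValueError(f"no samples for group {group!r} at timepoint {timepoint!r}")
    cols = [post.sample_index(s) for s in samples]
    totals = post.counts[:, cols].sum(axis=0)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise ValueError(f"sample {samples[zero[0]]!r} has zero total count")
    idx = [i for i, f in enumerate(post.feature_ids) if f in detected]
    hit = post.counts[np.ix_(idx, cols)].sum(axis=0) if idx else np.zeros(len(cols))
    percent = 100.0 * hit / totals
    per_sample = {s: float(p) for s, p in zip(samples, percent)}
    return EngraftmentSummary(
        group=group,
        source=source,
        timepoint=timepoint,
        stratum=stratum,
        detected=detected,
        per_sample_percent=per_sample,
        minimum=float(percent.min()),
        mean=float(percent.mean()),
        maximum=float(percent.max()),
    )


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """A labelled 2x2 contingency table [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("all-zero contingency table")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def fisher_exact_two_sided(
    table: ContingencyTable2x2 | Iterable[Iterable[int]],
) -> tuple[float, float]:
    """Two-sided Fisher exact test by exact hypergeometric enumeration.

    Conditioning on the margins, the first cell ``a`` follows a
    hypergeometric distribution.  The two-sided p-value follows the
    minimum-likelihood rule: the sum of the probabilities of every table
    (same margins) whose point probability does not exceed that of the
    observed table.  Point probabilities are compared as exact integers
    (common-denominator hypergeometric numerators), so ties are resolved
    without floating-point ambiguity.

    Returns ``(odds_ratio, p)`` with the sample odds ratio a*d/(b*c)
    (``inf`` when b*c == 0 and a*d > 0, ``nan`` when both products vanish).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.cells
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    lo, hi = max(0, col1 - row2), min(row1, col1)
    # integer numerators over the common denominator C(n, col1)
    numerators = [math.comb(row1, k) * math.comb(row2, col1 - k) for k in range(lo, hi + 1)]
    observed = numerators[a - lo]
    p = sum(v for v in numerators if v <= observed) / math.comb(n, col1)
    ad, bc = a * d, b * c
    if bc == 0:
        odds_ratio = math.nan if ad == 0 else math.inf
    else:
        odds_ratio = ad / bc
    return odds_ratio, min(p, 1.0)


@dataclasses.dataclass(frozen=True)
class ContrastCell:
    """One cell of an engraftment contrast: a stratum observed in a group."""

    source: str
    stratum: str
    group: str
    timepoint: str


def compare_engraftment_success(
    classification: ProvenanceClassification,
    cell_a: ContrastCell,
    detected_a: Iterable[str],
    cell_b: ContrastCell,
    detected_b: Iterable[str],
) -> tuple[ContingencyTable2x2, float, float]:
    """Fisher contrast of engraftment success between two strata/groups.

    Builds the 2x2 table (engrafted vs not engrafted) x (cell A vs cell B)
    from the stratum sizes in ``classification`` and the detected sets, and
    applies :func:`fisher_exact_two_sided`.  The table is returned alongside
    the statistics so the exact contrast tested is auditable.

    The two cells must reference either identical or disjoint ASV strata;
    partially overlapping strata would double-count ASVs and raise.
    """
    pool_a = classification.stratum(cell_a.source, cell_a.stratum)
    pool_b = classification.stratum(cell_b.source, cell_b.stratum)
    if pool_a & pool_b and pool_a != pool_b:
        raise ValueError(
            "contrast cells reference partially overlapping ASV strata; "
            "use disjoint strata (e.g. 'specific' vs 'shared') or identical ones"
        )
    det_a = frozenset(detected_a)
    det_b = frozenset(detected_b)
    if not det_a <= pool_a or not det_b <= pool_b:
        raise ValueError("detected sets must be subsets of their contrast cell's stratum")
    table = ContingencyTable2x2(
        len(det_a),
        len(pool_a) - len(det_a),
        len(det_b),
        len(pool_b) - len(det_b),
        row_labels=(
            f"{cell_a.group}:{cell_a.source}/{cell_a.stratum}@{cell_a.timepoint}",
            f"{cell_b.group}:{cell_b.source}/{cell_b.stratum}@{cell_b.timepoint}",
        ),
        col_labels=("engrafted", "not_engrafted"),
    )
    odds_ratio, p = fisher_exact_two_sided(table)
    return table, odds_ratio, p
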