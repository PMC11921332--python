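"""Seeded synthetic datasets with the study's structure and known truth.

The generator emulates a two-donor microbiota-transplant trial in weanling
piglets: a wild-boar-derived (WB) inoculum of 439 ASVs and a sow-derived
(Sow) inoculum of 275 ASVs, of which 101 and 98 respectively already
circulate in the recipient cohort at baseline and 42 are private to the
inocula but shared between the two donors.  Forty-eight piglets (4 groups x
12) are sampled before inoculation (PND21) and twice after (PND27, PND48);
donor-unique ASVs engraft in recipients with per-(group, source)
probabilities, and a 70-metabolite cecal panel carries group effects plus
one taxon-coupled metabolite.

Compositions follow a standard latent model: log-normal relative abundances
renormalized per sample, then a multinomial read draw at Poisson-distributed
depth.  Every planted inoculum member is guaranteed at least 3 reads in its
inoculum (emulating deeply sequenced inocula and making the planted
membership recoverable after the global low-count filter), and every
donor-baseline overlap ASV is guaranteed at least one baseline read, so the
planted unique/common partition is exactly recoverable at the default
depths.  All randomness derives from the config seed; outputs are
bit-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (
    GROUPS,
    FeatureTable,
    MetaboliteTable,
    SampleMetadata,
    write_feature_table,
    write_metabolite_table,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_inocula",
    "generate_metadata",
    "generate_baseline_cohort",
    "generate_post_transplant",
    "generate_metabolome",
    "generate_dataset",
    "write_dataset",
]

# rng stream tags, one per stage, so stages are independent yet reproducible
_STAGE_INOCULA = 1
_STAGE_METADATA = 2
_STAGE_BASELINE = 3
_STAGE_POST = 4
_STAGE_METABOLOME = 5


def _default_engraftment_prob() -> dict[tuple[str, str], float]:
    # Detected fractions in the study were roughly 0.3 of the engrafting
    # source's unique pool in single-source recipients and about half that
    # for WB-origin ASVs in the mixed-inoculum group, with no sow-specific
    # engraftment in the mix and none at all in controls.
    return {
        ("Control", "WB"): 0.0,
        ("Control", "Sow"): 0.0,
        ("WB", "WB"): 0.3,
        ("WB", "Sow"): 0.0,
        ("Sow", "WB"): 0.0,
        ("Sow", "Sow"): 0.3,
        ("Mix", "WB"): 0.15,
        ("Mix", "Sow"): 0.0,
    }


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the trial's design: donor richness 439 (WB) and 275
    (Sow), 101/98 donor ASVs in common with the baseline cohort, 42
    shared-unique ASVs, 12 piglets per group in 4 groups, 3 timepoints, a
    70-metabolite cecal panel.  Sequencing depths and the latent log-normal
    spread are generator choices (the study does not publish per-sample
    depths): 50k mean reads per piglet sample, 300k per inoculum.
    """

    seed: int = 0
    donors: tuple[str, ...] = ("WB", "Sow")
    donor_richness: tuple[int, ...] = (439, 275)
    n_common_with_baseline: tuple[int, ...] = (101, 98)
    n_shared_unique: int = 42
    groups: tuple[str, ...] = GROUPS
    n_piglets_per_group: int = 12
    n_baseline_only: int = 300
    baseline_richness: int = 150
    engraftment_prob: Mapping[tuple[str, str], float] = dataclasses.field(
        default_factory=_default_engraftment_prob
    )
    engrafted_mass: float = 0.05
    depth: int = 50_000
    inoculum_depth: int = 300_000
    abundance_sigma: float = 1.0
    n_metabolites: int = 70
    metabolite_effect_size: float = 0.7
    n_affected_per_group: int = 5
    metabolite_sigma: float = 0.5
    lod_z: float = 2.0
    planted_rho: float = 0.8

    def __post_init__(self) -> None:
        if len(self.donors) != len(self.donor_richness) or len(self.donors) != len(
            self.n_common_with_baseline
        ):
            raise ValueError("donor_richness and n_common_with_baseline must match donors")
        for richness, common in zip(self.donor_richness, self.n_common_with_baseline):
            if common > richness:
                raise ValueError("n_common_with_baseline cannot exceed donor_richness")
            if self.n_shared_unique > richness - common:
                raise ValueError(
                    "n_shared_unique exceeds a donor's unique capacity "
                    f"({self.n_shared_unique} > {richness} - {common})"
                )
        if self.n_shared_unique < 0:
            raise ValueError("n_shared_unique must be non-negative")
        for key, p in self.engraftment_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"engraftment_prob[{key}] = {p} outside [0, 1]")
        if self.depth <= 0 or self.inoculum_depth <= 0:
            raise ValueError("sequencing depths must be positive")
        if self.n_piglets_per_group < 1:
            raise ValueError("n_piglets_per_group must be positive")
        if not (0.0 <= self.engrafted_mass < 1.0):
            raise ValueError("engrafted_mass must be in [0, 1)")
        pool = sum(self.n_common_with_baseline) + self.n_baseline_only
        if not (1 <= self.baseline_richness <= pool):
            raise ValueError(
                f"baseline_richness must be in [1, {pool}] (the baseline feature pool)"
            )
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be positive")
        if not (-1.0 <= self.planted_rho <= 1.0):
            raise ValueError("planted_rho must be in [-1, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclasses.dataclass
class GroundTruth:
    """The generator's planted parameters, the oracle for recovery tests."""

    donors: tuple[str, ...]
    unique: dict[str, frozenset[str]]
    common: dict[str, frozenset[str]]
    shared_unique: frozenset[str]
    baseline_only: frozenset[str] = frozenset()
    correlation_taxon: str = ""
    feature_ids: tuple[str, ...] = ()
    piglet_ids: tuple[str, ...] = ()
    piglet_group: dict[str, str] = dataclasses.field(default_factory=dict)
    baseline_features: dict[str, frozenset[str]] = dataclasses.field(default_factory=dict)
    engrafted: dict[tuple[str, str], frozenset[str]] = dataclasses.field(default_factory=dict)
    engrafted_mass: dict[str, float] = dataclasses.field(default_factory=dict)
    metabolite_effects: pd.DataFrame | None = None
    correlated_metabolite: str = ""
    planted_rho: float = 0.0

    def __post_init__(self) -> None:
        for donor in self.donors:
            if self.unique[donor] & self.common[donor]:
                raise ValueError(f"planted unique/common sets overlap for {donor!r}")

    def donor_features(self, donor: str) -> frozenset[str]:
        return self.unique[donor] | self.common[donor]

    def to_json_dict(self) -> dict:
        out: dict = {
            "donors": list(self.donors),
            "unique": {d: sorted(self.unique[d]) for d in self.donors},
            "common": {d: sorted(self.common[d]) for d in self.donors},
            "shared_unique": sorted(self.shared_unique),
            "correlation_taxon": self.correlation_taxon,
            "engrafted": {
                f"{g}:{s}": sorted(v) for (g, s), v in sorted(self.engrafted.items())
            },
            "engrafted_mass": dict(sorted(self.engrafted_mass.items())),
            "correlated_metabolite": self.correlated_metabolite,
            "planted_rho": self.planted_rho,
        }
        if self.metabolite_effects is not None:
            out["metabolite_effects"] = {
                g: {m: float(v) for m, v in row.items() if v != 0.0}
                for g, row in self.metabolite_effects.iterrows()
            }
        return out


def _lognormal_composition(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    w = np.exp(rng.normal(0.0, sigma, size=n))
    return w / w.sum()


def _multinomial_counts(
    rng: np.random.Generator, weights: np.ndarray, mean_depth: int
) -> np.ndarray:
    depth = int(rng.poisson(mean_depth))
    return rng.multinomial(max(depth, 1), weights)


# ---------------------------------------------------------------------------
# stage 1: inocula
# ---------------------------------------------------------------------------


def generate_inocula(cfg: SyntheticConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw the donor inoculum communities and fix the planted membership.

    Feature ids are allocated in blocks: per-donor specific-unique ASVs,
    the shared-unique block, per-donor baseline-common blocks, and a
    baseline-only block that never enters an inoculum.  Each inoculum
    column is a log-normal/multinomial draw over its donor's members, with
    a 3-read floor per planted member so the full membership survives the
    global low-count filter.
    """
    rng = cfg.rng(_STAGE_INOCULA)
    blocks: dict[str, list[str]] = {}
    counter = 0

    def take(n: int, tag: str) -> list[str]:
        nonlocal counter
        ids = [f"ASV{counter + i + 1:04d}" for i in range(n)]
        counter += n
        blocks[tag] = ids
        return ids

    shared = take(cfg.n_shared_unique, "shared_unique")
    specific: dict[str, list[str]] = {}
    common: dict[str, list[str]] = {}
    for donor, richness, n_common in zip(
        cfg.donors, cfg.donor_richness, cfg.n_common_with_baseline
    ):
        specific[donor] = take(richness - n_common - cfg.n_shared_unique, f"specific_{donor}")
        common[donor] = take(n_common, f"common_{donor}")
    baseline_only = take(cfg.n_baseline_only, "baseline_only")

    feature_ids = tuple(fid for tag in blocks for fid in blocks[tag])
    index = {f: i for i, f in enumerate(feature_ids)}
    counts = np.zeros((len(feature_ids), len(cfg.donors)), dtype=np.int64)
    for j, donor in enumerate(cfg.donors):
        members = specific[donor] + shared + common[donor]
        weights = _lognormal_composition(rng, len(members), cfg.abundance_sigma)
        col = _multinomial_counts(rng, weights, cfg.inoculum_depth)
        col = np.maximum(col, 3)  # floor: every planted member clears the >=3 filter
        for fid, c in zip(members, col):
            counts[index[fid], j] = c
    table = FeatureTable(feature_ids, tuple(cfg.donors), counts)
    truth = GroundTruth(
        donors=tuple(cfg.donors),
        unique={d: frozenset(specific[d]) | frozenset(shared) for d in cfg.donors},
        common={d: frozenset(common[d]) for d in cfg.donors},
        shared_unique=frozenset(shared),
        baseline_only=frozenset(baseline_only),
        correlation_taxon=baseline_only[0] if baseline_only else "",
        feature_ids=feature_ids,
        planted_rho=cfg.planted_rho,
    )
    return table, truth


# ---------------------------------------------------------------------------
# stage 2: cohort metadata
# ---------------------------------------------------------------------------


def generate_metadata(cfg: SyntheticConfig) -> SampleMetadata:
    """Sample sheet for the whole run: inocula plus piglets x timepoints.

    Piglets are split into two pens per group; litters cross-cut groups
    (littermates distributed across arms, as in a randomized design); sex
    alternates within group.  Fecal samples at PND21/PND27/PND48 plus a
    cecal sample at PND48 per piglet, and one inoculum sample per donor.
    """
    rng = cfg.rng(_STAGE_METADATA)
    n_litters = max(2, (len(cfg.groups) * cfg.n_piglets_per_group) // 6)
    litter_pool = [f"L{i + 1:02d}" for i in range(n_litters)]
    rows = []
    for donor in cfg.donors:
        rows.append(
            {
                "sample_id": donor,
                "subject_id": donor,
                "group": donor if donor in cfg.groups else cfg.groups[0],
                "timepoint": "PND21",
                "sample_type": "inoculum",
                "pen": "donor",
                "litter": "donor",
                "sex": "F",
            }
        )
    litters = rng.permutation(
        np.tile(litter_pool, int(np.ceil(len(cfg.groups) * cfg.n_piglets_per_group / n_litters)))
    )
    k = 0
    for group in cfg.groups:
        for i in range(cfg.n_piglets_per_group):
            pid = f"{group}{i + 1:02d}"
            pen = f"pen_{group}{1 if i < cfg.n_piglets_per_group / 2 else 2}"
            litter = str(litters[k])
            sex = "M" if i % 2 == 0 else "F"
            k += 1
            for tp in ("PND21", "PND27", "PND48"):
                rows.append(
                    {
                        "sample_id": f"{pid}_{tp}",
                        "subject_id": pid,
                        "group": group,
                        "timepoint": tp,
                        "sample_type": "fecal",
                        "pen": pen,
                        "litter": litter,
                        "sex": sex,
                    }
                )
            rows.append(
                {
                    "sample_id": f"{pid}_cecal",
                    "subject_id": pid,
                    "group": group,
                    "timepoint": "PND48",
                    "sample_type": "cecal",
                    "pen": pen,
                    "litter": litter,
                    "sex": sex,
                }
            )
    frame = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(frame)


# ---------------------------------------------------------------------------
# stage 3: baseline cohort
# ---------------------------------------------------------------------------


def generate_baseline_cohort(cfg: SyntheticConfig, truth: GroundTruth) -> FeatureTable:
    """Pre-inoculation (PND21) fecal communities for every piglet.

    Each piglet carries ``baseline_richness`` features drawn from the
    baseline pool (donor-common blocks plus baseline-only ASVs); donor
    *unique* ASVs never appear.  Every donor-common ASV is guaranteed to be
    carried, and observed with at least one read, in at least one piglet.
    The piglet membership sets persist to later timepoints and are recorded
    in the truth.
    """
    rng = cfg.rng(_STAGE_BASELINE)
    pool = sorted(
        frozenset().union(*(truth.common[d] for d in truth.donors)) | truth.baseline_only
    )
    piglet_ids = tuple(
        f"{group}{i + 1:02d}" for group in cfg.groups for i in range(cfg.n_piglets_per_group)
    )
    truth.piglet_ids = piglet_ids
    truth.piglet_group = {
        f"{group}{i + 1:02d}": group
        for group in cfg.groups
        for i in range(cfg.n_piglets_per_group)
    }
    ubiquitous = truth.correlation_taxon
    rest = [f for f in pool if f != ubiquitous]
    members: dict[str, set[str]] = {}
    for pid in piglet_ids:
        chosen = set(rng.choice(rest, size=cfg.baseline_richness - 1, replace=False))
        chosen.add(ubiquitous)
        members[pid] = chosen
    # guarantee every donor-common ASV is carried by someone
    carried = set().union(*members.values())
    for donor in truth.donors:
        for fid in sorted(truth.common[donor] - carried):
            members[str(rng.choice(piglet_ids))].add(fid)
    truth.baseline_features = {p: frozenset(m) for p, m in members.items()}

    index = {f: i for i, f in enumerate(truth.feature_ids)}
    sample_ids = tuple(f"{pid}_PND21" for pid in piglet_ids)
    counts = np.zeros((len(truth.feature_ids), len(sample_ids)), dtype=np.int64)
    for j, pid in enumerate(piglet_ids):
        mem = sorted(members[pid])
        weights = _lognormal_composition(rng, len(mem), cfg.abundance_sigma)
        col = _multinomial_counts(rng, weights, cfg.depth)
        for fid, c in zip(mem, col):
            counts[index[fid], j] = c
    # observation guarantee: each donor-common ASV has >=1 baseline read
    for donor in truth.donors:
        for fid in sorted(truth.common[donor]):
            row = index[fid]
            if counts[row].sum() == 0:
                carriers = [j for j, pid in enumerate(piglet_ids) if fid in members[pid]]
                counts[row, int(rng.choice(carriers))] = 1
    return FeatureTable(truth.feature_ids, sample_ids, counts)


# ---------------------------------------------------------------------------
# stage 4: post-transplant timepoints
# ---------------------------------------------------------------------------


def generate_post_transplant(cfg: SyntheticConfig, truth: GroundTruth) -> FeatureTable:
    """Fecal communities at PND27 and PND48 plus the PND48 cecal samples.

    Engraftment is decided once per (group, source): each source-unique ASV
    engrafts into the group with the configured probability, and engrafted
    ASVs are carried by every recipient of that group thereafter (no
    within-host dynamics between timepoints; abundances are redrawn
    independently).  Engrafted ASVs jointly receive a fixed share of each
    recipient's community (``engrafted_mass`` per engrafting source);
    controls receive nothing.
    """
    if not truth.baseline_features:
        raise ValueError("generate_baseline_cohort must run before generate_post_transplant")
    rng = cfg.rng(_STAGE_POST)
    for group in cfg.groups:
        for source in truth.donors:
            p = cfg.engraftment_prob.get((group, source), 0.0)
            unique = sorted(truth.unique[source])
            draws = rng.random(len(unique)) < p
            truth.engrafted[(group, source)] = frozenset(
                f for f, hit in zip(unique, draws) if hit
            )
    for group in cfg.groups:
        active = [s for s in truth.donors if truth.engrafted[(group, s)]]
        truth.engrafted_mass[group] = 100.0 * min(cfg.engrafted_mass * len(active), 0.9)

    index = {f: i for i, f in enumerate(truth.feature_ids)}
    sample_ids: list[str] = []
    cols: list[np.ndarray] = []
    for tp_suffix in ("PND27", "PND48", "cecal"):
        for pid in truth.piglet_ids:
            group = truth.piglet_group[pid]
            engrafted = sorted(
                frozenset().union(*(truth.engrafted[(group, s)] for s in truth.donors))
            )
            base = sorted(truth.baseline_features[pid])
            phi = truth.engrafted_mass[group] / 100.0 if engrafted else 0.0
            w_base = _lognormal_composition(rng, len(base), cfg.abundance_sigma) * (1.0 - phi)
            col = np.zeros(len(truth.feature_ids), dtype=np.int64)
            weights = np.zeros(len(base) + len(engrafted))
            weights[: len(base)] = w_base
            if engrafted:
                weights[len(base) :] = (
                    _lognormal_composition(rng, len(engrafted), cfg.abundance_sigma) * phi
                )
            draw = _multinomial_counts(rng, weights, cfg.depth)
            for fid, c in zip(base + engrafted, draw):
                col[index[fid]] = c
            sample_ids.append(f"{pid}_{tp_suffix}")
            cols.append(col)
    counts = np.column_stack(cols)
    return FeatureTable(truth.feature_ids, tuple(sample_ids), counts)


# ---------------------------------------------------------------------------
# stage 5: metabolome
# ---------------------------------------------------------------------------


def generate_metabolome(
    cfg: SyntheticConfig, truth: GroundTruth, post: FeatureTable
) -> MetaboliteTable:
    """Cecal metabolite panel with group effects and one taxon-coupled metabolite.

    Concentrations are log-normal around per-metabolite baselines with
    additive log-scale group shifts: each treated group is enriched in its
    own block of ``n_affected_per_group`` metabolites.  The first metabolite
    is coupled to the correlation taxon's relative abundance in the PND48
    cecal samples through a Gaussian copula targeting the configured
    Spearman rho.  Values below the per-metabolite limit of detection are
    emitted as missing.
    """
    rng = cfg.rng(_STAGE_METABOLOME)
    met_ids = tuple(f"metab{i + 1:02d}" for i in range(cfg.n_metabolites))
    n = len(truth.piglet_ids)
    mu = rng.normal(np.log(100.0), 1.0, size=cfg.n_metabolites)
    sigma = cfg.metabolite_sigma

    effects = pd.DataFrame(0.0, index=list(cfg.groups), columns=list(met_ids))
    block = 1  # metabolite 0 is reserved for the planted correlation
    for group in cfg.groups:
        if group == "Control":
            continue
        stop = min(block + cfg.n_affected_per_group, cfg.n_metabolites)
        effects.loc[group, list(met_ids[block:stop])] = cfg.metabolite_effect_size
        block = stop
    truth.metabolite_effects = effects
    truth.correlated_metabolite = met_ids[0]

    # taxon abundance driving the coupled metabolite (PND48 cecal samples)
    cecal_cols = [post.sample_index(f"{pid}_cecal") for pid in truth.piglet_ids]
    taxon_row = list(truth.feature_ids).index(truth.correlation_taxon)
    taxon_abund = post.counts[taxon_row, cecal_cols] / post.counts[:, cecal_cols].sum(axis=0)
    from scipy import stats as _st

    ranks = _st.rankdata(taxon_abund)
    z_taxon = _st.norm.ppf((ranks - 0.5) / n)
    # bivariate-normal Pearson rho achieving the target Spearman rho
    rho_p = 2.0 * np.sin(np.pi * cfg.planted_rho / 6.0)

    z = rng.standard_normal((cfg.n_metabolites, n))
    z[0] = rho_p * z_taxon + np.sqrt(max(0.0, 1.0 - rho_p**2)) * z[0]
    shift = np.zeros((cfg.n_metabolites, n))
    for j, pid in enumerate(truth.piglet_ids):
        shift[:, j] = effects.loc[truth.piglet_group[pid]].to_numpy()
    conc = np.exp(mu[:, None] + shift + sigma * z)
    lod = np.exp(mu - cfg.lod_z * sigma)
    censored = conc < lod[:, None]
    conc[censored] = np.nan
    return MetaboliteTable(met_ids, truth.piglet_ids, conc, lod)


# ---------------------------------------------------------------------------
# one-call assembly
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SyntheticDataset:
    """A complete synthetic study: counts, metadata, metabolites, truth."""

    table: FeatureTable
    metadata: SampleMetadata
    metabolites: MetaboliteTable
    truth: GroundTruth
    config: SyntheticConfig

    def inoculum_table(self) -> FeatureTable:
        return self.table.subset_samples(self.config.donors)

    def baseline_table(self) -> FeatureTable:
        ids = [s for s in self.table.sample_ids if s.endswith("_PND21")]
        return self.table.subset_samples(ids)


def generate_dataset(cfg: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Run all generator stages and assemble one combined feature table."""
    if cfg is None:
        cfg = SyntheticConfig(seed=seed if seed is not None else 0)
    elif seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    inocula, truth = generate_inocula(cfg)
    metadata = generate_metadata(cfg)
    baseline = generate_baseline_cohort(cfg, truth)
    post = generate_post_transplant(cfg, truth)
    metabolites = generate_metabolome(cfg, truth, post)
    counts = np.column_stack([inocula.counts, baseline.counts, post.counts])
    table = FeatureTable(
        truth.feature_ids,
        inocula.sample_ids + baseline.sample_ids + post.sample_ids,
        counts,
    )
    metadata.require_samples(table.sample_ids)
    return SyntheticDataset(table, metadata, metabolites, truth, cfg)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Emit feature_table.tsv, metadata.tsv, metabolites.tsv, lod.tsv, ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(dataset.table, outdir / "feature_table.tsv")
    dataset.metadata.to_tsv(outdir / "metadata.tsv")
    write_metabolite_table(
        dataset.metabolites, outdir / "metabolites.tsv", outdir / "lod.tsv"
    )
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(dataset.truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
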