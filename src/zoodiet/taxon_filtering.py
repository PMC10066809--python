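"""Taxon exclusion, rank aggregation, quality filtering and normalization.

The cleaning stages applied to a gut-content metabarcoding count table
before any diet statistic is computed:

1. **Exclusion** removes read classes that are not diet (the predator's own
   crustacean reads, heterotrophic bacteria, epibionts, lineages too vague
   to interpret), by exact label match at a chosen rank.
2. **Aggregation** collapses ASVs to a display rank (class for 16S; order
   for 18S with photoautotroph classes kept at class level), conserving
   per-sample read totals exactly.
3. **Prevalence/abundance filtering** keeps, per predator-station-campaign
   group, only prey present in at least 40% of the gut replicates and
   contributing at least 5% of the group's pooled reads.
4. **Normalization** converts counts to per-sample relative abundances.

The pipeline applies them in that order (exclusion -> aggregation ->
filter -> normalization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    RANKS,
    Dataset,
    DomainError,
    TaxonRecord,
    validate_composition,
)


class FilterError(ValueError):
    """Raised when a filtering stage cannot produce a meaningful result."""


@dataclass(frozen=True)
class ExclusionRule:
    """Remove every taxon whose lineage carries ``pattern`` at ``rank``.

    ``marker`` optionally restricts the rule to one marker gene, so a single
    rule list can serve mixed studies (e.g. crustacean removal applies to
    18S data only).
    """

    rank: str
    pattern: str
    marker: str | None = None

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise DomainError(f"unknown lineage rank {self.rank!r}; valid: {RANKS}")

    def matches(self, record: TaxonRecord) -> bool:
        if self.marker is not None and record.marker != self.marker:
            return False
        return record.rank_label(self.rank) == self.pattern


def default_exclusion_rules() -> list[ExclusionRule]:
    """The study's standard contaminant exclusions.

    Crustacean reads (the predator itself) for 18S; heterotrophic bacteria
    (here gammaproteobacterial reads) and the euglenozoan epibionts for 16S.
    """
    return [
        ExclusionRule(rank="class", pattern="Crustacea", marker="18S"),
        ExclusionRule(rank="class", pattern="Gammaproteobacteria", marker="16S"),
        ExclusionRule(rank="phylum", pattern="Euglenozoa", marker="16S"),
    ]


@dataclass(frozen=True)
class RankOverride:
    """Route taxa whose ``match_rank`` label is in ``labels`` to ``to_rank``."""

    match_rank: str
    labels: frozenset[str]
    to_rank: str

    def __post_init__(self) -> None:
        for r in (self.match_rank, self.to_rank):
            if r not in RANKS:
                raise DomainError(f"unknown lineage rank {r!r}")

    def matches(self, record: TaxonRecord) -> bool:
        return record.rank_label(self.match_rank) in self.labels


@dataclass(frozen=True)
class RankPolicy:
    """Aggregation policy: a default display rank plus routing overrides.

    The 16S convention is class level throughout; the 18S convention is
    order level except photoautotrophic classes, which stay at class level.
    A taxon matched by more than one override is a configuration error.
    """

    default_rank: str = "class"
    overrides: tuple[RankOverride, ...] = ()

    def __post_init__(self) -> None:
        if self.default_rank not in RANKS:
            raise DomainError(f"unknown lineage rank {self.default_rank!r}")

    def resolve(self, record: TaxonRecord) -> str:
        hits = [ov for ov in self.overrides if ov.matches(record)]
        if len(hits) > 1:
            raise FilterError(
                f"taxon {record.taxon_id!r} matched by {len(hits)} rank "
                f"overrides; policy is ambiguous"
            )
        return hits[0].to_rank if hits else self.default_rank


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the prevalence/pooled-abundance quality filter.

    Both are inclusive ("at least"): presence in >= ``min_prevalence`` of
    the group's replicates, and pooled reads >= ``min_pooled_abundance`` of
    the group's pooled total.
    """

    min_prevalence: float = 0.40
    min_pooled_abundance: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_prevalence", "min_pooled_abundance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def exclude_taxa(dataset: Dataset, rules: Sequence[ExclusionRule]) -> Dataset:
    """Drop every taxon matched by at least one rule; keep the rest intact.

    The removed taxa and their read totals are appended to the returned
    dataset's provenance log.  Removing everything raises ``FilterError``.
    """
    removed: list[str] = []
    kept: list[str] = []
    for taxon in dataset.counts.index:
        rec = dataset.taxonomy[taxon]
        if any(rule.matches(rec) for rule in rules):
            removed.append(taxon)
        else:
            kept.append(taxon)
    if not kept:
        raise FilterError("no taxa remain after applying exclusion rules")
    out = dataset.subset_taxa(kept)
    for taxon in removed:
        total = int(dataset.counts.loc[taxon].sum())
        out.log(f"excluded taxon {taxon} ({total} reads)")
    if not removed:
        out.log("exclusion rules matched no taxa")
    return out


def aggregate_taxa(dataset: Dataset, policy: RankPolicy) -> Dataset:
    """Sum counts within the display label each taxon resolves to.

    Labels come from the policy's output rank; an empty label at that rank
    becomes ``Unclassified_<nearest non-empty parent>``.  Column totals are
    conserved exactly (integer arithmetic).
    """
    labels: dict[str, str] = {}
    label_rank: dict[str, str] = {}
    label_lineage: dict[str, tuple[str, ...]] = {}
    for taxon in dataset.counts.index:
        rec = dataset.taxonomy[taxon]
        rank = policy.resolve(rec)
        lab = rec.rank_label(rank)
        if not lab:
            lab = f"Unclassified_{rec.parent_label(rank)}"
        labels[taxon] = lab
        label_rank.setdefault(lab, rank)
        if lab not in label_lineage:
            cut = RANKS.index(rank) + 1
            lineage = rec.lineage[:cut] + ("",) * (len(RANKS) - cut)
            if not rec.rank_label(rank):
                lineage = lineage[: cut - 1] + (lab,) + ("",) * (len(RANKS) - cut)
            label_lineage[lab] = lineage

    grouped = dataset.counts.groupby(
        dataset.counts.index.map(labels), sort=True
    ).sum()
    grouped.index.name = "taxon_id"
    marker = dataset.marker
    taxonomy = {
        lab: TaxonRecord(taxon_id=lab, lineage=label_lineage[lab], marker=marker)
        for lab in grouped.index
    }
    out = Dataset(
        counts=grouped.astype(np.int64),
        taxonomy=taxonomy,
        metadata=dict(dataset.metadata),
        provenance=list(dataset.provenance),
    )
    out.log(
        f"aggregated {len(dataset.counts)} taxa to {len(grouped)} labels "
        f"(default rank {policy.default_rank})"
    )
    return out.validate()


def prevalence_abundance_filter(
    dataset: Dataset,
    group: tuple[str, str, str],
    params: FilterParams = FilterParams(),
    mode: str = "pooled",
) -> set[str]:
    """Retained prey taxa for one (predator, station, campaign) group.

    A taxon passes if it is present (>= 1 read) in at least
    ``min_prevalence`` of the group's gut replicates AND its reads pooled
    across those replicates are at least ``min_pooled_abundance`` of the
    group's pooled total.  ``mode='per_replicate_mean'`` evaluates the
    abundance condition on the mean of per-replicate proportions instead of
    pooled reads (an alternative reading of the rule).
    """
    predator, station, campaign = group
    samples = dataset.sample_ids(
        sample_type="gut", predator=predator, station=station, campaign=campaign
    )
    if not samples:
        raise FilterError(
            f"no gut samples for predator={predator!r}, station={station!r}, "
            f"campaign={campaign!r}"
        )
    sub = dataset.counts[samples]
    total = sub.to_numpy().sum()
    if total == 0:
        raise FilterError(f"group {group} has zero total reads")
    prevalence = (sub > 0).sum(axis=1) / len(samples)
    if mode == "pooled":
        share = sub.sum(axis=1) / total
    elif mode == "per_replicate_mean":
        col_tot = sub.sum(axis=0)
        with np.errstate(invalid="ignore"):
            props = sub.div(col_tot.replace(0, np.nan), axis=1)
        share = props.mean(axis=1).fillna(0.0)
    else:
        raise DomainError(f"unknown filter mode {mode!r}")
    keep = (prevalence >= params.min_prevalence) & (
        share >= params.min_pooled_abundance
    )
    # a taxon with zero reads in the group is never "retained"
    keep &= sub.sum(axis=1) > 0
    return set(sub.index[keep])


def relative_abundance(
    counts: pd.DataFrame, taxon_subset: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1).

    ``taxon_subset`` restricts to those rows before renormalizing, so
    proportions are relative to the retained prey only.  A zero-total
    column raises, naming the sample.
    """
    if taxon_subset is not None:
        subset = set(taxon_subset)
        counts = counts.loc[[t for t in counts.index if t in subset]]
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise FilterError(
            f"sample {zero.index[0]!r} has zero total reads over the "
            f"selected taxa"
        )
    props = counts.div(totals, axis=1).astype(float)
    return validate_composition(props)
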