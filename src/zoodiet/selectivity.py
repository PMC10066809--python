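"""Standardized forage-ratio selectivity index (Chesson-type electivity).

For one gut sample j with prey read counts R_ij and ambient water read
abundances Rw_i over the same prey, the index is

    S_ij = (R_ij / Rw_i) / sum_k (R_kj / Rw_k)

S ranges over [0, 1] and sums to 1 across prey: S_i = 1/k for every prey
means no selection, larger values mean the prey is over-represented in the
gut relative to its availability in the water.  The index is invariant to
rescaling of either input, so counts and proportions are interchangeable.

Prey undetected in the water (Rw_i = 0) have an undefined ratio and are
excluded from the index (and reported), unless a pseudocount is requested.
Prey absent from the gut but present in the water are kept with S = 0 so
that replicate S vectors share a common index set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset, DomainError
from .taxon_filtering import relative_abundance


class SelectivityError(ValueError):
    """Raised when the index is undefined for the given inputs."""


@dataclass
class SelectivityResult:
    """Selectivity vector for one gut sample.

    ``S`` is aligned to ``prey_ids`` (the included prey); ``excluded_prey``
    maps dropped prey labels to the reason they were dropped.
    """

    prey_ids: list[str]
    S: np.ndarray
    excluded_prey: dict[str, str]

    def as_series(self) -> pd.Series:
        return pd.Series(self.S, index=self.prey_ids, name="S")


def selectivity_index(
    gut_counts: Sequence[float],
    water_abundance: Sequence[float],
    prey_ids: Sequence[str] | None = None,
    pseudocount: float = 0.0,
) -> SelectivityResult:
    """Compute the standardized forage ratio for one gut sample.

    Parameters
    ----------
    gut_counts
        Prey read abundances in the gut (counts or proportions).
    water_abundance
        The same prey's abundances in the water reference (counts or
        proportions); zeros make the ratio undefined for that prey.
    prey_ids
        Labels aligned to both vectors; defaults to ``p0..pN``.
    pseudocount
        Optional epsilon added to every water abundance before forming
        ratios, as an alternative to excluding water-absent prey.
    """
    R = np.asarray(gut_counts, dtype=float)
    Rw = np.asarray(water_abundance, dtype=float)
    if R.shape != Rw.shape or R.ndim != 1:
        raise DomainError(
            f"gut and water vectors must be 1-d and aligned, got shapes "
            f"{R.shape} and {Rw.shape}"
        )
    if prey_ids is None:
        prey_ids = [f"p{i}" for i in range(len(R))]
    elif len(prey_ids) != len(R):
        raise DomainError("prey_ids not aligned with abundance vectors")
    if np.any(R < 0) or np.any(Rw < 0):
        raise DomainError("negative read abundances")
    if pseudocount < 0:
        raise DomainError("pseudocount must be non-negative")
    if pseudocount > 0:
        Rw = Rw + pseudocount

    excluded: dict[str, str] = {}
    include = Rw > 0
    for i in np.flatnonzero(~include):
        reason = "water_absent_gut_present" if R[i] > 0 else "water_absent"
        excluded[prey_ids[i]] = reason

    ratios = np.zeros(int(include.sum()))
    ids = [prey_ids[i] for i in np.flatnonzero(include)]
    ratios = R[include] / Rw[include]
    denom = ratios.sum()
    if denom <= 0:
        raise SelectivityError(
            "selectivity undefined: no prey detected in both gut and water"
        )
    return SelectivityResult(prey_ids=ids, S=ratios / denom, excluded_prey=excluded)


def water_reference(
    dataset: Dataset,
    station: str,
    campaign: str,
    policy: str = "mean_proportions",
    taxon_subset: Sequence[str] | None = None,
) -> pd.Series:
    """Combine a station/campaign's water replicates into one reference.

    ``mean_proportions`` (default) averages per-replicate relative
    abundances, weighting replicates equally regardless of library size;
    ``pooled_counts`` sums raw reads first, weighting by sequencing depth.
    """
    samples = dataset.sample_ids(
        sample_type="water", station=station, campaign=campaign
    )
    if not samples:
        raise SelectivityError(
            f"no water samples for station={station!r}, campaign={campaign!r}"
        )
    counts = dataset.counts[samples]
    if taxon_subset is not None:
        subset = set(taxon_subset)
        counts = counts.loc[[t for t in counts.index if t in subset]]
    if policy == "mean_proportions":
        props = relative_abundance(counts)
        return props.mean(axis=1)
    if policy == "pooled_counts":
        pooled = counts.sum(axis=1)
        total = pooled.sum()
        if total == 0:
            raise SelectivityError(
                f"water samples for {station}/{campaign} have zero reads"
            )
        return pooled / total
    raise DomainError(f"unknown water policy {policy!r}")


def station_selectivity(
    dataset: Dataset,
    predator: str,
    station: str,
    campaign: str,
    water_policy: str = "mean_proportions",
    prey_subset: Sequence[str] | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-replicate selectivity for one predator at one station/campaign.

    Every gut replicate is scored against the same water reference.
    Returns a long table with one row per (replicate, prey) pair, columns
    ``predator, station, campaign, replicate, taxon, S, excluded_reason``
    (excluded prey get an empty S and a reason).
    """
    guts = dataset.sample_ids(
        sample_type="gut", predator=predator, station=station, campaign=campaign
    )
    if not guts:
        raise SelectivityError(
            f"no gut samples for predator={predator!r} at {station}/{campaign}"
        )
    ref = water_reference(
        dataset, station, campaign, policy=water_policy, taxon_subset=prey_subset
    )
    prey = list(ref.index)
    rows: list[dict] = []
    for sid in guts:
        rep = dataset.metadata[sid].replicate_id
        gut = dataset.counts.loc[prey, sid]
        res = selectivity_index(
            gut.to_numpy(), ref.to_numpy(), prey_ids=prey, pseudocount=pseudocount
        )
        s = res.as_series()
        for taxon in prey:
            if taxon in res.excluded_prey:
                rows.append(
                    dict(
                        predator=predator,
                        station=station,
                        campaign=campaign,
                        replicate=rep,
                        taxon=taxon,
                        S=np.nan,
                        excluded_reason=res.excluded_prey[taxon],
                    )
                )
            else:
                rows.append(
                    dict(
                        predator=predator,
                        station=station,
                        campaign=campaign,
                        replicate=rep,
                        taxon=taxon,
                        S=float(s[taxon]),
                        excluded_reason="",
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "predator",
            "station",
            "campaign",
            "replicate",
            "taxon",
            "S",
            "excluded_reason",
        ],
    )
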