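"""Bray-Curtis dissimilarity and diet-overlap summaries.

Diet overlap between two samples is quantified as the Bray-Curtis
similarity, 100 x (1 - BC), on relative-abundance vectors, where

    BC(p, q) = sum_i |p_i - q_i| / sum_i (p_i + q_i)

BC is 0 for identical compositions and 1 for disjoint prey supports; it is
a semimetric (the triangle inequality is not guaranteed).  Overlap is
computed between gut replicates of one predator, summarized overall,
within station/campaign groups and between groups — a selective feeder
keeps a similar diet everywhere (high between-group overlap) while an
opportunist tracks the local water community (low between-group overlap).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset, DomainError
from .taxon_filtering import relative_abundance


class OverlapError(ValueError):
    """Raised when an overlap summary cannot be formed."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with aligned sample ids."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise DomainError(
                f"distance matrix shape {self.d.shape} does not match "
                f"{n} sample ids"
            )
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise DomainError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise DomainError("distance matrix diagonal is not zero")

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)
        df.index.name = "sample_id"
        return df

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DistanceMatrix":
        return cls(sample_ids=list(frame.index), d=frame.to_numpy(dtype=float))


@dataclass
class OverlapSummary:
    """Mean Bray-Curtis similarities (percent) for one predator's diet."""

    predator: str
    mean_overall_pct: float
    mean_within_group_pct: float
    mean_between_group_pct: float
    n_pairs_overall: int
    n_pairs_within: int
    n_pairs_between: int
    pairs: pd.DataFrame  # sample_a, sample_b, group_a, group_b, similarity_pct

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("overall", self.mean_overall_pct, self.n_pairs_overall),
            ("within_station", self.mean_within_group_pct, self.n_pairs_within),
            ("between_station", self.mean_between_group_pct, self.n_pairs_between),
        ]
        return pd.DataFrame(
            [
                dict(predator=self.predator, level=lev, mean_pct=m, n_pairs=n)
                for lev, m, n in rows
            ]
        )


def bray_curtis(p: Sequence[float], q: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity between two aligned composition vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise DomainError(
            f"composition vectors must be 1-d and aligned, got {p.shape} "
            f"and {q.shape}"
        )
    if np.any(p < 0) or np.any(q < 0):
        raise DomainError("negative entries in composition vectors")
    denom = (p + q).sum()
    if denom <= 0:
        raise DomainError("both compositions are identically zero")
    return float(np.abs(p - q).sum() / denom)


def distance_matrix(compositions: pd.DataFrame) -> DistanceMatrix:
    """All pairwise Bray-Curtis distances between columns of a composition table."""
    ids = list(compositions.columns)
    arr = compositions.to_numpy(dtype=float).T  # samples x taxa
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = bray_curtis(arr[i], arr[j])
    return DistanceMatrix(sample_ids=ids, d=d)


def similarity_summary(
    dataset: Dataset,
    predator: str,
    prey_subset: Sequence[str] | None = None,
) -> tuple[OverlapSummary, DistanceMatrix]:
    """Diet-overlap summary for one predator across stations and campaigns.

    Pairwise similarity = (1 - Bray-Curtis) x 100 over every pair of the
    predator's gut replicates; pairs are labelled within-group when both
    replicates share (station, campaign), between-group otherwise.
    """
    samples = dataset.sample_ids(sample_type="gut", predator=predator)
    if len(samples) < 2:
        raise OverlapError(
            f"need at least 2 gut samples for predator {predator!r}, "
            f"got {len(samples)}"
        )
    comps = relative_abundance(dataset.counts[samples], prey_subset)
    dm = distance_matrix(comps)
    groups = {
        s: (dataset.metadata[s].station, dataset.metadata[s].campaign)
        for s in samples
    }
    rows = []
    for i, j in combinations(range(len(samples)), 2):
        a, b = samples[i], samples[j]
        rows.append(
            dict(
                sample_a=a,
                sample_b=b,
                group_a="/".join(groups[a]),
                group_b="/".join(groups[b]),
                within=groups[a] == groups[b],
                similarity_pct=(1.0 - dm.d[i, j]) * 100.0,
            )
        )
    pairs = pd.DataFrame(rows)
    within = pairs[pairs["within"]]
    between = pairs[~pairs["within"]]
    summary = OverlapSummary(
        predator=predator,
        mean_overall_pct=float(pairs["similarity_pct"].mean()),
        mean_within_group_pct=(
            float(within["similarity_pct"].mean()) if len(within) else float("nan")
        ),
        mean_between_group_pct=(
            float(between["similarity_pct"].mean()) if len(between) else float("nan")
        ),
        n_pairs_overall=len(pairs),
        n_pairs_within=len(within),
        n_pairs_between=len(between),
        pairs=pairs.drop(columns="within"),
    )
    return summary, dm
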