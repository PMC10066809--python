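"""Shared fixtures: small in-memory datasets and TSV writers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from zoodiet.data_model import Dataset, SampleRecord, TaxonRecord


def make_dataset(
    counts: dict[str, list[int]],
    lineages: dict[str, tuple[str, ...]],
    samples: dict[str, dict],
    marker: str = "16S",
) -> Dataset:
    """Build a validated Dataset from terse dict literals.

    ``counts`` maps taxon -> per-sample counts in ``samples`` order;
    ``lineages`` may give fewer than six ranks (padded with '').
    """
    taxa = list(counts)
    frame = pd.DataFrame(
        {s: [counts[t][i] for t in taxa] for i, s in enumerate(samples)},
        index=taxa,
        dtype=np.int64,
    )
    frame.index.name = "taxon_id"
    taxonomy = {
        t: TaxonRecord(
            taxon_id=t,
            lineage=tuple(lineages.get(t, ())) + ("",) * (6 - len(lineages.get(t, ()))),
            marker=marker,
        )
        for t in taxa
    }
    metadata = {
        s: SampleRecord(
            sample_id=s,
            sample_type=info.get("type", "gut"),
            predator_species=info.get(
                "predator", "" if info.get("type") == "water" else "Temora"
            ),
            station=info.get("station", "MS"),
            campaign=info.get("campaign", "2019-06"),
            replicate_id=info.get("replicate", "r1"),
        )
        for s, info in samples.items()
    }
    return Dataset(counts=frame, taxonomy=taxonomy, metadata=metadata).validate()


@pytest.fixture
def toy_dataset() -> Dataset:
    """3 taxa x 4 samples (2 gut replicates, 2 water replicates), one station."""
    return make_dataset(
        counts={
            "t1": [2, 20, 50, 55],
            "t2": [3, 30, 30, 25],
            "t3": [5, 50, 20, 20],
        },
        lineages={
            "t1": ("Bacteria", "Cyanobacteria", "Synechococcales"),
            "t2": ("Eukaryota", "Ochrophyta", "Bacillariophyceae"),
            "t3": ("Eukaryota", "Ochrophyta", "Coscinodiscophyceae"),
        },
        samples={
            "G1": {"type": "gut", "predator": "Temora", "replicate": "r1"},
            "G2": {"type": "gut", "predator": "Temora", "replicate": "r2"},
            "W1": {"type": "water", "replicate": "r1"},
            "W2": {"type": "water", "replicate": "r2"},
        },
    )


@pytest.fixture
def toy_tsv_paths(tmp_path: Path, toy_dataset: Dataset) -> dict[str, Path]:
    """The toy dataset written out as the three standard TSV files."""
    from zoodiet.data_model import write_dataset

    return write_dataset(toy_dataset, tmp_path)


def brute_force_bray(p, q) -> float:
    """Independent elementwise Bray-Curtis for oracle comparisons."""
    num = sum(abs(a - b) for a, b in zip(p, q))
    den = sum(a + b for a, b in zip(p, q))
    return num / den


def brute_force_ss(d: np.ndarray, labels: list) -> tuple[float, float, float]:
    """Independent total/within/among sums of squares from pair loops."""
    n = len(labels)
    ss_t = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_t += d[i, j] ** 2
    ss_t /= n
    ss_w = 0.0
    for g in set(labels):
        idx = [i for i, lab in enumerate(labels) if lab == g]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += d[idx[a], idx[b]] ** 2
        ss_w += acc / len(idx)
    return ss_t, ss_w, ss_t - ss_w


def brute_force_pseudo_F(d: np.ndarray, labels: list) -> float:
    ss_t, ss_w, ss_a = brute_force_ss(d, labels)
    a = len(set(labels))
    n = len(labels)
    return (ss_a / (a - 1)) / (ss_w / (n - a))
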