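"""Exclusion rules, rank aggregation, quality filter and normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from zoodiet.data_model import Dataset
from zoodiet.taxon_filtering import (
    ExclusionRule,
    FilterError,
    FilterParams,
    RankOverride,
    RankPolicy,
    aggregate_taxa,
    exclude_taxa,
    prevalence_abundance_filter,
    relative_abundance,
)

from conftest import make_dataset


@pytest.fixture
def mixed_dataset() -> Dataset:
    """4 taxa incl. one crustacean contaminant, 18S, one gut group of 5 reps."""
    return make_dataset(
        counts={
            "a1": [10, 0, 0, 0, 10],
            "a2": [3, 0, 0, 0, 0],
            "a3": [50, 40, 45, 30, 2],
            "cr": [100, 90, 80, 70, 60],
        },
        lineages={
            "a1": ("Eukaryota", "Ochrophyta", "Bacillariophyceae", "Naviculales"),
            "a2": ("Eukaryota", "Ochrophyta", "Bacillariophyceae", "Bacillariales"),
            "a3": ("Eukaryota", "Chlorophyta", "Trebouxiophyceae", "Chlorellales"),
            "cr": ("Eukaryota", "Arthropoda", "Crustacea", "Calanoida"),
        },
        samples={
            f"G{i}": {"type": "gut", "predator": "Acartia", "replicate": f"r{i}"}
            for i in range(1, 6)
        },
        marker="18S",
    )


# -- exclusion --------------------------------------------------------------


def test_exclusion_removes_matching_taxon_only(mixed_dataset):
    out = exclude_taxa(mixed_dataset, [ExclusionRule("class", "Crustacea")])
    assert out.taxa == ["a1", "a2", "a3"]
    pd.testing.assert_frame_equal(
        out.counts, mixed_dataset.counts.loc[["a1", "a2", "a3"]]
    )
    assert any("cr" in line for line in out.provenance)


def test_exclusion_with_empty_rules_is_identity(mixed_dataset):
    out = exclude_taxa(mixed_dataset, [])
    pd.testing.assert_frame_equal(out.counts, mixed_dataset.counts)


def test_exclusion_is_idempotent(mixed_dataset):
    rules = [ExclusionRule("class", "Crustacea")]
    once = exclude_taxa(mixed_dataset, rules)
    twice = exclude_taxa(once, rules)
    pd.testing.assert_frame_equal(once.counts, twice.counts)


def test_exclusion_removing_everything_raises(mixed_dataset):
    with pytest.raises(FilterError, match="no taxa remain"):
        exclude_taxa(mixed_dataset, [ExclusionRule("domain", "Eukaryota")])


def test_marker_scoped_rule_ignores_other_marker(mixed_dataset):
    out = exclude_taxa(
        mixed_dataset, [ExclusionRule("class", "Crustacea", marker="16S")]
    )
    assert "cr" in out.taxa  # rule scoped to 16S, dataset is 18S


def test_unknown_rank_rejected():
    with pytest.raises(Exception, match="rank"):
        ExclusionRule("kingdom", "Animalia")


# -- aggregation ------------------------------------------------------------


def test_aggregation_sums_within_class(mixed_dataset):
    out = aggregate_taxa(mixed_dataset, RankPolicy(default_rank="class"))
    assert out.counts.loc["Bacillariophyceae", "G1"] == 13  # 10 + 3
    # totals conserved exactly per sample
    assert (out.counts.sum() == mixed_dataset.counts.sum()).all()


def test_aggregation_routes_missing_rank_to_unclassified_parent():
    ds = make_dataset(
        counts={"x": [5], "y": [7]},
        lineages={"x": ("Eukaryota", "Ochrophyta", ""), "y": ("Eukaryota", "Ochrophyta", "")},
        samples={"G1": {"type": "gut"}},
    )
    out = aggregate_taxa(ds, RankPolicy(default_rank="class"))
    assert list(out.counts.index) == ["Unclassified_Ochrophyta"]
    assert out.counts.iloc[0, 0] == 12


def test_mixed_policy_conserves_totals(mixed_dataset):
    # 18S convention: order level by default, photoautotroph classes at class
    policy = RankPolicy(
        default_rank="order",
        overrides=(
            RankOverride(
                match_rank="class",
                labels=frozenset({"Bacillariophyceae", "Trebouxiophyceae"}),
                to_rank="class",
            ),
        ),
    )
    out = aggregate_taxa(mixed_dataset, policy)
    # each input taxon lands under exactly one output label
    assert set(out.counts.index) == {
        "Bacillariophyceae",
        "Trebouxiophyceae",
        "Calanoida",
    }
    assert (out.counts.sum() == mixed_dataset.counts.sum()).all()


def test_ambiguous_override_raises(mixed_dataset):
    policy = RankPolicy(
        default_rank="order",
        overrides=(
            RankOverride("class", frozenset({"Bacillariophyceae"}), "class"),
            RankOverride("phylum", frozenset({"Ochrophyta"}), "phylum"),
        ),
    )
    with pytest.raises(FilterError, match="ambiguous"):
        aggregate_taxa(mixed_dataset, policy)


def test_exclusion_then_aggregation_commutes_on_rank_consistent_rules(mixed_dataset):
    rules = [ExclusionRule("class", "Crustacea")]
    policy = RankPolicy(default_rank="class")
    a = aggregate_taxa(exclude_taxa(mixed_dataset, rules), policy)
    b = exclude_taxa(aggregate_taxa(mixed_dataset, policy), rules)
    pd.testing.assert_frame_equal(a.counts, b.counts)


# -- prevalence/abundance filter --------------------------------------------


def test_filter_worked_example(mixed_dataset):
    """Prevalence 2/5 = 0.40 and pooled share 10% retains; prevalence 1/5 drops."""
    ds = exclude_taxa(mixed_dataset, [ExclusionRule("class", "Crustacea")])
    # group totals: a1=20, a2=3, a3=167 -> total 190; rescale to match the
    # textbook arithmetic by checking conditions directly
    keep = prevalence_abundance_filter(
        ds, ("Acartia", "MS", "2019-06"), FilterParams(0.40, 0.05)
    )
    assert "a1" in keep  # present in 2/5 reps, 20/190 = 10.5% of reads
    assert "a2" not in keep  # present in 1/5 reps only
    assert "a3" in keep


def test_filter_vacuous_thresholds_keep_everything(mixed_dataset):
    keep = prevalence_abundance_filter(
        mixed_dataset, ("Acartia", "MS", "2019-06"), FilterParams(0.0, 0.0)
    )
    assert keep == {"a1", "a2", "a3", "cr"}


def test_filter_empty_group_raises(mixed_dataset):
    with pytest.raises(FilterError, match="no gut samples"):
        prevalence_abundance_filter(
            mixed_dataset, ("Temora", "MS", "2019-06"), FilterParams()
        )


def test_filter_monotone_in_both_thresholds():
    """Raising either threshold never adds a taxon to the retained set."""
    rng = np.random.default_rng(42)
    for _ in range(40):
        n_taxa = rng.integers(3, 10)
        counts = {
            f"t{i}": rng.integers(0, 50, size=5).tolist() for i in range(n_taxa)
        }
        if not any(sum(v) for v in counts.values()):
            continue
        ds = make_dataset(
            counts,
            lineages={},
            samples={
                f"G{i}": {"type": "gut", "predator": "P", "replicate": f"r{i}"}
                for i in range(1, 6)
            },
        )
        grid = [0.0, 0.2, 0.4, 0.6, 1.0]
        prev_sets = [
            prevalence_abundance_filter(
                ds, ("P", "MS", "2019-06"), FilterParams(p, 0.0)
            )
            for p in grid
        ]
        for a, b in zip(prev_sets, prev_sets[1:]):
            assert b <= a
        ab_sets = [
            prevalence_abundance_filter(
                ds, ("P", "MS", "2019-06"), FilterParams(0.0, q)
            )
            for q in grid
        ]
        for a, b in zip(ab_sets, ab_sets[1:]):
            assert b <= a


def test_filter_per_replicate_mean_mode_differs_when_depths_skew():
    # one deep replicate dominates pooled reads but not the mean of proportions
    ds = make_dataset(
        counts={"t1": [900, 1, 1, 1, 1], "t2": [100, 99, 99, 99, 99]},
        lineages={},
        samples={
            f"G{i}": {"type": "gut", "predator": "P", "replicate": f"r{i}"}
            for i in range(1, 6)
        },
    )
    pooled = prevalence_abundance_filter(
        ds, ("P", "MS", "2019-06"), FilterParams(0.0, 0.5), mode="pooled"
    )
    mean = prevalence_abundance_filter(
        ds, ("P", "MS", "2019-06"), FilterParams(0.0, 0.5), mode="per_replicate_mean"
    )
    assert "t1" in pooled  # 904/1400 = 65% of pooled reads
    assert "t1" not in mean  # mean per-replicate proportion ~ 18%


# -- relative abundance ------------------------------------------------------


def test_relative_abundance_basic():
    counts = pd.DataFrame({"s1": [2, 3, 5]}, index=["a", "b", "c"])
    props = relative_abundance(counts)
    assert np.allclose(props["s1"], [0.2, 0.3, 0.5])


def test_relative_abundance_idempotent_on_compositions():
    counts = pd.DataFrame({"s1": [2, 3, 5]}, index=["a", "b", "c"])
    once = relative_abundance(counts)
    twice = relative_abundance(once)
    assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-12


def test_relative_abundance_with_subset_renormalizes():
    counts = pd.DataFrame({"s1": [2, 3, 5]}, index=["a", "b", "c"])
    props = relative_abundance(counts, taxon_subset=["a", "c"])
    assert np.allclose(props["s1"], [2 / 7, 5 / 7])


def test_relative_abundance_zero_column_names_sample():
    counts = pd.DataFrame({"s1": [1, 2], "empty": [0, 0]}, index=["a", "b"])
    with pytest.raises(FilterError, match="empty"):
        relative_abundance(counts)
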