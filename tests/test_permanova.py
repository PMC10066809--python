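"""Pseudo-F, permutation p-values and pairwise tests with BH correction."""

from __future__ import annotations

from itertools import permutations as iter_permutations

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from zoodiet.data_model import DomainError
from zoodiet.diet_overlap import DistanceMatrix
from zoodiet.permanova import (
    PermanovaError,
    bh_adjust,
    pairwise_permanova,
    permanova_test,
    pseudo_F,
)

from conftest import brute_force_pseudo_F


def _dm(d: np.ndarray) -> DistanceMatrix:
    return DistanceMatrix(sample_ids=[f"s{i}" for i in range(len(d))], d=d)


def _random_dm(rng: np.random.Generator, n: int) -> DistanceMatrix:
    pts = rng.random((n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return _dm(d)


def test_pseudo_F_matches_brute_force_on_random_toys():
    rng = np.random.default_rng(17)
    for _ in range(20):
        dm = _random_dm(rng, 6)
        labels = ["a", "a", "a", "b", "b", "b"]
        f, r2 = pseudo_F(dm, labels)
        assert f == pytest.approx(brute_force_pseudo_F(dm.d, labels), abs=1e-12)
        assert 0.0 <= r2 <= 1.0


def test_pseudo_F_matches_scikit_bio():
    """Independent cross-check against the reference implementation."""
    import skbio

    rng = np.random.default_rng(23)
    dm = _random_dm(rng, 8)
    labels = ["a", "a", "a", "b", "b", "b", "b", "a"]
    f, _ = pseudo_F(dm, labels)
    sk = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(dm.d, ids=dm.sample_ids), labels, permutations=9
    )
    assert f == pytest.approx(sk["test statistic"], abs=1e-10)


def test_separated_clusters_give_infinite_F():
    d = np.array(
        [
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [1, 1, 0, 0],
            [1, 1, 0, 0],
        ],
        dtype=float,
    )
    with pytest.warns(RuntimeWarning):
        f, r2 = pseudo_F(_dm(d), ["a", "a", "b", "b"])
    assert np.isinf(f) and r2 == 1.0


def test_sample_order_invariance():
    rng = np.random.default_rng(4)
    dm = _random_dm(rng, 6)
    labels = np.array(["a", "b", "a", "b", "a", "b"])
    f, _ = pseudo_F(dm, list(labels))
    perm = rng.permutation(6)
    dm_p = _dm(dm.d[np.ix_(perm, perm)])
    f_p, _ = pseudo_F(dm_p, list(labels[perm]))
    assert f == pytest.approx(f_p, abs=1e-12)


def test_degenerate_all_zero_distances_raise():
    with pytest.raises(PermanovaError):
        pseudo_F(_dm(np.zeros((4, 4))), ["a", "a", "b", "b"])


def test_small_groups_rejected():
    rng = np.random.default_rng(1)
    dm = _random_dm(rng, 4)
    with pytest.raises(PermanovaError):
        pseudo_F(dm, ["a", "a", "a", "b"])


# -- permutation p-values ----------------------------------------------------


def exhaustive_p(dm: DistanceMatrix, labels: list[str]) -> float:
    """Enumerate all label permutations; p = share with F* >= F_obs."""
    f_obs = brute_force_pseudo_F(dm.d, labels)
    count = 0
    total = 0
    for perm in iter_permutations(range(len(labels))):
        lab = [labels[i] for i in perm]
        total += 1
        if brute_force_pseudo_F(dm.d, lab) >= f_obs - 1e-12:
            count += 1
    return count / total


def test_monte_carlo_p_close_to_exhaustive_on_4_sample_toy():
    # two tight pairs far apart: of the three distinct 2|2 partitions the
    # observed one maximizes F; each partition is realized by two label
    # assignments (swapping group names leaves F unchanged), so exhaustive
    # enumeration gives p = 1/3
    pts = np.array([0.0, 0.05, 1.0, 1.08])
    d = np.abs(pts[:, None] - pts[None, :])
    dm = _dm(d)
    labels = ["a", "a", "b", "b"]
    p_ex = exhaustive_p(dm, labels)
    assert p_ex == pytest.approx(1 / 3, abs=1e-12)
    res = permanova_test(dm, labels, n_permutations=9999, seed=0)
    assert abs(res.p_value - p_ex) < 0.02


def test_p_value_lower_bound_and_determinism():
    rng = np.random.default_rng(9)
    dm = _random_dm(rng, 8)
    labels = ["a"] * 4 + ["b"] * 4
    r1 = permanova_test(dm, labels, n_permutations=99, seed=5)
    r2 = permanova_test(dm, labels, n_permutations=99, seed=5)
    assert r1.p_value == r2.p_value
    assert r1.p_value >= 1 / 100


def test_label_order_invariance_of_p():
    rng = np.random.default_rng(19)
    dm = _random_dm(rng, 6)
    labels = ["a", "a", "a", "b", "b", "b"]
    swapped = ["b" if l == "a" else "a" for l in labels]
    p1 = permanova_test(dm, labels, n_permutations=999, seed=3).p_value
    p2 = permanova_test(dm, swapped, n_permutations=999, seed=3).p_value
    assert p1 == p2


def test_identical_samples_raise():
    with pytest.raises(PermanovaError):
        permanova_test(_dm(np.zeros((6, 6))), ["a"] * 3 + ["b"] * 3, seed=0)


def test_invalid_n_permutations():
    rng = np.random.default_rng(2)
    with pytest.raises(DomainError):
        permanova_test(_random_dm(rng, 4), ["a", "a", "b", "b"], n_permutations=0)


# -- BH adjustment and pairwise tests ----------------------------------------


def test_bh_hand_example_and_statsmodels_agreement():
    raw = [0.01, 0.02, 0.9]
    adj = bh_adjust(raw)
    assert np.allclose(adj, [0.03, 0.03, 0.9], atol=1e-12)
    sm = multipletests(raw, method="fdr_bh")[1]
    assert np.allclose(adj, sm, atol=1e-12)


def test_bh_fixed_point_on_equal_ps():
    adj = bh_adjust([0.2, 0.2, 0.2, 0.2])
    assert np.allclose(adj, 0.2, atol=1e-15)


def test_pairwise_three_groups_three_rows():
    rng = np.random.default_rng(31)
    pts = np.concatenate(
        [rng.normal(loc=3 * g, size=(3, 2)) for g in range(3)]
    )
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    dm = _dm(d)
    labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    rows = pairwise_permanova(dm, labels, n_permutations=99, seed=1)
    assert len(rows) == 3
    assert {(r.group_a, r.group_b) for r in rows} == {
        ("a", "b"),
        ("a", "c"),
        ("b", "c"),
    }
    for r in rows:
        assert r.p_adjusted >= r.p_raw - 1e-15


def test_pairwise_degenerate_pair_flagged_others_returned():
    # groups a and b are identical points (all-zero distances within the
    # a/b restriction); c is far away
    d = np.zeros((6, 6))
    for i in range(4):
        for j in range(4, 6):
            d[i, j] = d[j, i] = 1.0
    dm = _dm(d)
    labels = ["a", "a", "b", "b", "c", "c"]
    rows = pairwise_permanova(dm, labels, n_permutations=99, seed=1)
    flagged = {(r.group_a, r.group_b): r.degenerate for r in rows}
    assert flagged[("a", "b")] is True
    assert flagged[("a", "c")] is False and flagged[("b", "c")] is False
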