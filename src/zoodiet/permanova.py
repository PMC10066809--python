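"""One-factor PERMANOVA on a distance matrix, with pairwise group tests.

The pseudo-F statistic (Anderson's distance-based one-way form) is computed
directly from squared pairwise distances:

    SS_T = (1/N) * sum_{i<j} d_ij^2
    SS_W = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_A = SS_T - SS_W
    F    = (SS_A / (a-1)) / (SS_W / (N-a)),   R^2 = SS_A / SS_T

Significance comes from unrestricted permutation of the group labels; the
p-value uses the add-one estimator p = (1 + #{F* >= F_obs}) / (1 + n_perm),
so it is never exactly zero and is bounded below by 1/(n_perm+1).

Pairwise tests run the same procedure on each unordered pair of groups with
Benjamini-Hochberg adjustment across pairs by default.  Each pair draws its
permutations from an independent substream derived from the root seed, so
results do not depend on the order in which pairs are evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .data_model import DomainError
from .diet_overlap import DistanceMatrix


class PermanovaError(ValueError):
    """Raised for degenerate designs (all-zero distances, tiny groups...)."""


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    pseudo_F: float
    p_raw: float
    p_adjusted: float
    degenerate: bool = False


def _group_indices(groups: Sequence[str]) -> dict[str, np.ndarray]:
    labels: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        labels.setdefault(str(g), []).append(i)
    return {g: np.array(ix) for g, ix in labels.items()}


def _ss_parts(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_T, SS_W) from a squared-distance matrix and integer group codes."""
    n = d2.shape[0]
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in np.unique(groups):
        ix = np.flatnonzero(groups == g)
        sub = d2[np.ix_(ix, ix)]
        ss_w += sub[np.triu_indices(len(ix), 1)].sum() / len(ix)
    return float(ss_t), float(ss_w)


def pseudo_F(d: DistanceMatrix, groups: Sequence[str]) -> tuple[float, float]:
    """Pseudo-F and R^2 for one grouping factor on a distance matrix.

    Requires at least two groups with at least two members each.  If the
    within-group sum of squares is exactly zero while groups differ, F is
    +inf (perfectly separated clusters) and a warning is issued.
    """
    n = len(d.sample_ids)
    if len(groups) != n:
        raise DomainError(f"{len(groups)} labels for {n} samples")
    codes, uniques = _encode(groups)
    a = len(uniques)
    if a < 2:
        raise PermanovaError("need at least 2 groups")
    sizes = np.bincount(codes)
    if np.any(sizes < 2):
        small = [uniques[i] for i in np.flatnonzero(sizes < 2)]
        raise PermanovaError(f"every group needs >= 2 members; too small: {small}")
    d2 = d.d**2
    if not d2.any():
        raise PermanovaError("all distances are zero; grouping is untestable")
    ss_t, ss_w = _ss_parts(d2, codes)
    ss_a = ss_t - ss_w
    if ss_w == 0.0:
        warnings.warn(
            "within-group sum of squares is zero; pseudo-F is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf"), 1.0
    f = (ss_a / (a - 1)) / (ss_w / (n - a))
    return float(f), float(ss_a / ss_t)


def _encode(groups: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    uniques = sorted({str(g) for g in groups})
    lookup = {g: i for i, g in enumerate(uniques)}
    return np.array([lookup[str(g)] for g in groups]), uniques


def _permuted_F(
    d2: np.ndarray, codes: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """Pseudo-F for each row of ``perms`` (permutations of sample indices).

    Vectorized over permutations: for each group g with membership matrix
    M (n_perm x N), the within-group pair sum is (M @ D2 * M).sum(1) / 2.
    """
    n = d2.shape[0]
    a = codes.max() + 1
    n_perm = perms.shape[0]
    total = d2.sum() / (2 * n)  # SS_T, permutation-invariant
    # sample i gets the label of position perms[row, i]
    labels = codes[perms]  # n_perm x N
    ss_w = np.zeros(n_perm)
    for g in range(a):
        m = (labels == g).astype(float)
        n_g = m.sum(axis=1)
        pair_sum = np.einsum("pi,ij,pj->p", m, d2, m) / 2.0
        ss_w += pair_sum / n_g
    ss_a = total - ss_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_a / (a - 1)) / (ss_w / (n - a))
    f[ss_w == 0] = np.inf
    return f


def permanova_test(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutation test of group differences on a distance matrix.

    Labels are shuffled uniformly at random ``n_permutations`` times;
    deterministic for a fixed seed.
    """
    if n_permutations < 1:
        raise DomainError("n_permutations must be >= 1")
    f_obs, r2 = pseudo_F(d, groups)
    codes, _ = _encode(groups)
    d2 = d.d**2
    rng = np.random.default_rng(seed)
    n = d2.shape[0]
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    f_perm = _permuted_F(d2, codes, perms)
    # ties at machine precision count as exceedances
    exceed = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=f_obs,
        R2=r2,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def pairwise_permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
    correction: str = "BH",
) -> list[PairwiseResult]:
    """One permutation test per unordered pair of groups.

    A degenerate pair (all-zero distances, or a group too small) is flagged
    and excluded from the multiplicity correction; the other pairs are
    still returned.  ``correction`` is ``"BH"`` (Benjamini-Hochberg) or
    ``"none"``.
    """
    if correction not in ("BH", "none"):
        raise DomainError(f"unknown correction {correction!r}")
    by_group = _group_indices(groups)
    names = sorted(by_group)
    if len(names) < 2:
        raise PermanovaError("need at least 2 groups")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names) * (len(names) - 1) // 2)
    results: list[PairwiseResult] = []
    raw: list[float] = []
    for k, (ga, gb) in enumerate(combinations(names, 2)):
        ix = np.concatenate([by_group[ga], by_group[gb]])
        sub = DistanceMatrix(
            sample_ids=[d.sample_ids[i] for i in ix], d=d.d[np.ix_(ix, ix)]
        )
        sub_groups = [str(groups[i]) for i in ix]
        pair_seed = int(children[k].generate_state(1)[0] % (2**31))
        try:
            res = permanova_test(sub, sub_groups, n_permutations, seed=pair_seed)
        except PermanovaError:
            results.append(
                PairwiseResult(
                    group_a=ga,
                    group_b=gb,
                    pseudo_F=float("nan"),
                    p_raw=float("nan"),
                    p_adjusted=float("nan"),
                    degenerate=True,
                )
            )
            continue
        results.append(
            PairwiseResult(
                group_a=ga,
                group_b=gb,
                pseudo_F=res.pseudo_F,
                p_raw=res.p_value,
                p_adjusted=res.p_value,
            )
        )
        raw.append(res.p_value)
    if correction == "BH" and raw:
        adjusted = bh_adjust(raw)
        it = iter(adjusted)
        for r in results:
            if not r.degenerate:
                r.p_adjusted = float(next(it))
    return results
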