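"""Community statistics: Bray-Curtis, Kruskal NMDS, ANOSIM and SIMPER.

These are direct implementations of the classic Clarke/Kruskal procedures
used for community fingerprint ordination and hypothesis testing:

* Bray-Curtis dissimilarity d(i,j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk);
* non-metric multidimensional scaling minimizing Kruskal stress-1 by
  alternating isotonic (monotone) regression of configuration distances on
  the rank order of the input dissimilarities with Guttman-transform updates,
  best of many random starts;
* one-way ANOSIM, R = (mean between-group rank - mean within-group rank)
  / (M/2) with M = n(n-1)/2, with a permutation p-value (exact enumeration
  when the number of distinct relabelings is small enough, otherwise random
  sampling with the +1 correction);
* SIMPER decomposition of the average between-group Bray-Curtis dissimilarity
  into per-feature contributions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from scatyper.errors import InvalidParameterError
from scatyper.profiles import FeatureMatrix


def sqrt_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """Element-wise square root (dampens dominant features); no re-normalization."""
    if (matrix.data.to_numpy() < 0).any():
        raise InvalidParameterError("negative abundance value")
    return FeatureMatrix(
        data=np.sqrt(matrix.data),
        provenance={**matrix.provenance, "transform": "sqrt"},
    )


def bray_curtis(matrix: FeatureMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between all sample pairs.

    Pairs in which both samples are all-zero are defined as distance 0 (with
    a warning) rather than NaN.
    """
    x = matrix.data.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise InvalidParameterError("need at least 2 samples")
    if (x < 0).any():
        raise InvalidParameterError("negative abundance value")
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    total = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(total > 0, diff / np.where(total > 0, total, 1.0), 0.0)
    if (total == 0).any() and x.shape[0] > 1:
        both_zero = (total == 0) & ~np.eye(x.shape[0], dtype=bool)
        if both_zero.any():
            warnings.warn("all-zero sample pair(s); distance defined as 0")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, ids=matrix.sample_ids)


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame  # n x dims, centered at the origin
    stress: float  # Kruskal stress-1 of the best start
    best_start: int
    n_starts: int
    seed: int
    converged: bool
    stress_history: list = field(default_factory=list)  # best start's trajectory


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float((dist**2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((dist - disp) ** 2).sum()) / denom)


def _pairwise(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return squareform(np.sqrt((diff**2).sum(axis=2)), checks=False)


def nmds(
    dm: DistanceMatrix,
    dims: int = 2,
    n_starts: int = 200,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> NmdsResult:
    """Kruskal non-metric MDS: minimize stress-1 over random starts.

    Within a start, configuration distances are isotonically regressed on the
    rank order of the input dissimilarities to obtain disparities, and the
    configuration is updated by the Guttman transform; iteration stops when
    the stress decrease falls below ``tol`` (or stress rises, in which case
    the previous configuration is kept, so the reported stress trajectory is
    non-increasing).  The best (lowest-stress) start wins; coordinates are
    centered at the origin.
    """
    d_obs = dm.condensed_form()
    n = dm.shape[0]
    m = d_obs.size
    if m == 0:
        raise InvalidParameterError("need at least 2 samples")
    order = np.argsort(d_obs, kind="stable")

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    best = None
    for start in range(n_starts):
        coords = rng.uniform(-1.0, 1.0, size=(n, dims))
        dist = _pairwise(coords)
        history = []
        prev_stress = np.inf
        converged = False
        for _ in range(max_iter):
            # monotone (isotonic) regression of configuration distances on
            # the rank order of the observed dissimilarities
            disp = np.empty_like(dist)
            disp[order] = isotonic_regression(dist[order]).x
            stress = _stress1(dist, disp)
            if stress > prev_stress + 1e-15:
                break  # keep previous configuration
            history.append(stress)
            if prev_stress - stress < tol:
                converged = True
                prev_coords = coords
                prev_stress = stress
                break
            prev_coords = coords
            prev_stress = stress
            # Guttman transform
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(dist > 0, disp / np.where(dist > 0, dist, 1.0), 0.0)
            B = np.zeros((n, n))
            B[iu] = -ratio
            B = B + B.T
            np.fill_diagonal(B, -B.sum(axis=1))
            coords = B @ coords / n
            dist = _pairwise(coords)
        if best is None or prev_stress < best["stress"]:
            best = {
                "stress": prev_stress,
                "coords": prev_coords,
                "start": start,
                "converged": converged,
                "history": history,
            }
    coords = best["coords"] - best["coords"].mean(axis=0)
    return NmdsResult(
        coordinates=pd.DataFrame(
            coords, index=list(dm.ids), columns=[f"dim{i+1}" for i in range(dims)]
        ),
        stress=float(best["stress"]),
        best_start=best["start"],
        n_starts=n_starts,
        seed=seed,
        converged=best["converged"],
        stress_history=best["history"],
    )


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    grouping: dict
    exact: bool = False
    pairwise: list = field(default_factory=list)  # (level_a, level_b, AnosimResult)


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def _anosim_r_batch(ranks: np.ndarray, perms: np.ndarray, iu) -> np.ndarray:
    """Vectorized R over a batch of label vectors (rows of ``perms``)."""
    within = perms[:, iu[0]] == perms[:, iu[1]]
    m = ranks.size
    sum_all = ranks.sum()
    n_within = within.sum(axis=1)
    sum_within = within @ ranks
    r_w = sum_within / n_within
    r_b = (sum_all - sum_within) / (m - n_within)
    return (r_b - r_w) / (m / 2.0)


def _count_distinct_labelings(counts: list[int]) -> int:
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return total


def anosim(
    dm: DistanceMatrix,
    grouping: dict | pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
    pairwise: bool = False,
) -> AnosimResult:
    """One-way ANOSIM with a permutation p-value.

    Dissimilarities are ranked (average ranks on ties); R contrasts mean
    between-group and within-group ranks.  If the number of distinct label
    arrangements is at most ``n_permutations`` the permutation distribution
    is enumerated exactly; otherwise ``n_permutations`` random relabelings
    are sampled and p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations).
    """
    if isinstance(grouping, pd.Series):
        grouping = grouping.to_dict()
    ids = list(dm.ids)
    missing = [i for i in ids if i not in grouping]
    if missing:
        raise InvalidParameterError(f"samples without a group label: {missing}")
    labels = np.asarray([grouping[i] for i in ids])
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2 or counts.min() < 2:
        raise InvalidParameterError(
            "need >= 2 groups with >= 2 samples each "
            f"(got {dict(zip(levels.tolist(), counts.tolist()))})"
        )

    n = len(ids)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.condensed_form())
    codes = np.unique(labels, return_inverse=True)[1]
    within_obs = codes[iu[0]] == codes[iu[1]]
    r_obs = _anosim_r(ranks, within_obs)

    n_distinct = _count_distinct_labelings(counts.tolist())
    if n_distinct <= n_permutations:
        perms = np.array(list(_multiset_permutations(codes.tolist())))
        r_perm = _anosim_r_batch(ranks, perms, iu)
        p = int((r_perm >= r_obs - 1e-12).sum()) / n_distinct
        exact = True
        n_perm_used = n_distinct
    else:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(codes, (n_permutations, 1)), axis=1)
        r_perm = _anosim_r_batch(ranks, perms, iu)
        p = (1 + int((r_perm >= r_obs - 1e-12).sum())) / (1 + n_permutations)
        exact = False
        n_perm_used = n_permutations

    result = AnosimResult(
        R=r_obs, p=p, n_permutations=n_perm_used, grouping=dict(grouping), exact=exact
    )
    if pairwise:
        for a, b in itertools.combinations(levels.tolist(), 2):
            keep = [i for i in ids if grouping[i] in (a, b)]
            sub = dm.filter(keep)
            sub_grouping = {i: grouping[i] for i in keep}
            result.pairwise.append(
                (a, b, anosim(sub, sub_grouping, n_permutations, seed, pairwise=False))
            )
    return result


def _multiset_permutations(items):
    """Distinct permutations of a multiset, lexicographic order."""
    items = sorted(items)
    n = len(items)
    while True:
        yield list(items)
        # next lexicographic permutation
        i = n - 2
        while i >= 0 and items[i] >= items[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while items[j] <= items[i]:
            j -= 1
        items[i], items[j] = items[j], items[i]
        items[i + 1:] = reversed(items[i + 1:])


@dataclass
class SimperResult:
    group_pair: tuple
    average_dissimilarity: float  # delta-bar
    contributions: pd.DataFrame  # feature, mean_contribution, percent
    top10: pd.DataFrame
    degenerate: bool = False  # True when delta-bar == 0 (percents undefined)


def simper(
    matrix: FeatureMatrix,
    grouping: dict | pd.Series,
    pair: tuple,
) -> SimperResult:
    """SIMPER: decompose average between-group dissimilarity by feature.

    For each between-group sample pair (i, j) the per-feature term is
    c_k(i,j) = |x_ik - x_jk| / sum_m (x_im + x_jm); averaging over pairs gives
    per-feature contributions whose sum is the average Bray-Curtis
    dissimilarity between the two groups.  Features are ranked by percent
    contribution and the top 10 reported.
    """
    if isinstance(grouping, pd.Series):
        grouping = grouping.to_dict()
    a, b = pair
    ids_a = [s for s in matrix.sample_ids if grouping.get(s) == a]
    ids_b = [s for s in matrix.sample_ids if grouping.get(s) == b]
    if not ids_a or not ids_b:
        raise InvalidParameterError(f"empty group in pair {pair}")
    xa = matrix.data.loc[ids_a].to_numpy(dtype=float)
    xb = matrix.data.loc[ids_b].to_numpy(dtype=float)

    contrib = np.zeros(xa.shape[1])
    n_pairs = 0
    for i in range(xa.shape[0]):
        for j in range(xb.shape[0]):
            denom = (xa[i] + xb[j]).sum()
            if denom > 0:
                contrib += np.abs(xa[i] - xb[j]) / denom
            n_pairs += 1
    contrib /= n_pairs
    delta_bar = float(contrib.sum())
    degenerate = delta_bar == 0.0
    percent = 100.0 * contrib / delta_bar if not degenerate else np.full_like(contrib, np.nan)

    table = (
        pd.DataFrame(
            {
                "feature": matrix.feature_ids,
                "mean_contribution": contrib,
                "percent": percent,
            }
        )
        .sort_values("mean_contribution", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return SimperResult(
        group_pair=(a, b),
        average_dissimilarity=delta_bar,
        contributions=table,
        top10=table.head(10).copy(),
        degenerate=degenerate,
    )
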