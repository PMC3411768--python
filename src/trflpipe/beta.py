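"""Between-community structure: Bray-Curtis, NMDS, ANOSIM, NPMANOVA, SIMPER.

All computations run on Bray-Curtis *dissimilarity* (1 - similarity), on
square-root-transformed abundances upstream.  NMDS is Kruskal's non-metric
scaling restarted from many random configurations (the reported stress is
the minimum over restarts).  ANOSIM and NPMANOVA are permutation tests on
the distance matrix; p-values use the (b + 1)/(m + 1) estimator and so are
never exactly zero.  SIMPER decomposes the average between-group
Bray-Curtis dissimilarity into additive per-OTU contributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix
from sklearn.manifold import MDS

logger = logging.getLogger(__name__)


@dataclass
class NmdsResult:
    """Best-restart non-metric MDS configuration."""

    coordinates: pd.DataFrame
    stress: float          # Kruskal stress-1 of the best restart
    k: int
    n_restarts: int
    best_restart_seed: int


@dataclass
class PermutationTestResult:
    statistic: float
    n_permutations: int
    p_value: float
    name: str = ""


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample rows.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i).  A pair of all-zero rows has
    an undefined dissimilarity; it is set to 0 with a warning.
    """
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundance matrix has negative entries")
    if x.shape[1] == 0:
        d = np.zeros((len(matrix), len(matrix)))
        return DistanceMatrix(d, ids=[str(i) for i in matrix.index])
    with np.errstate(invalid="ignore"):
        condensed = pdist(x, metric="braycurtis")
    if np.isnan(condensed).any():
        logger.warning("all-zero sample pair(s); their dissimilarity set to 0")
        condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in matrix.index])


def nmds(
    dm: DistanceMatrix,
    k: int = 3,
    restarts: int = 110,
    seed: int | None = None,
) -> NmdsResult:
    """Non-metric MDS with random-restart stress selection.

    Each restart runs Kruskal's monotone-regression NMDS from a fresh random
    configuration; the configuration with the lowest stress-1 is returned
    together with the restart seed that produced it.
    """
    n = dm.shape[0]
    if k >= n - 1:
        raise ValueError(f"k={k} must be below n_samples-1={n - 1}")
    if restarts < 1:
        raise ValueError("restarts must be positive")
    child_seeds = np.random.SeedSequence(seed).generate_state(restarts)
    best = None
    for i in range(restarts):
        rs = int(child_seeds[i] % (2 ** 31))
        model = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            n_init=1,
            init="random",
            max_iter=500,
            eps=1e-9,
            random_state=rs,
            normalized_stress="auto",
        )
        coords = model.fit_transform(dm.data)
        if best is None or model.stress_ < best[0]:
            best = (float(model.stress_), coords, rs)
    stress, coords, rs = best
    cdf = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return NmdsResult(cdf, stress, k, restarts, rs)


def _validate_groups(dm: DistanceMatrix, grouping) -> np.ndarray:
    g = np.asarray(pd.Series(grouping).reindex(list(dm.ids))
                   if isinstance(grouping, (dict, pd.Series)) else grouping)
    if len(g) != dm.shape[0]:
        raise ValueError("grouping length does not match distance matrix")
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("at least two groups required")
    if (counts < 2).any():
        small = labels[counts < 2]
        raise ValueError(f"group(s) {list(small)} have fewer than 2 samples")
    return g


def _anosim_r(rank_matrix: np.ndarray, within: np.ndarray, iu) -> float:
    ranks = rank_matrix[iu]
    w = within[iu]
    m = ranks.size
    return float((ranks[~w].mean() - ranks[w].mean()) / (m / 2.0))


def anosim(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Clarke's analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (M/2), with
    M = n(n-1)/2 distance pairs and midranks for ties; significance by
    permutation of the group labels.
    """
    g = _validate_groups(dm, grouping)
    n = dm.shape[0]
    iu = np.triu_indices(n, k=1)
    rank_matrix = np.zeros((n, n))
    rank_matrix[iu] = rankdata(dm.data[iu])  # midranks
    within = g[:, None] == g[None, :]
    r_obs = _anosim_r(rank_matrix, within, iu)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[perm]
        within_p = gp[:, None] == gp[None, :]
        if _anosim_r(rank_matrix, within_p, iu) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(r_obs, n_perm, p, name="ANOSIM R")


def _pseudo_f(d2: np.ndarray, g: np.ndarray) -> float:
    n = len(g)
    labels = np.unique(g)
    a = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_t = d2[iu].sum() / n
    ss_w = 0.0
    for lab in labels:
        idx = np.flatnonzero(g == lab)
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_a = ss_t - ss_w
    # a zero within-group sum (coincident points) gives an infinite F
    with np.errstate(divide="ignore"):
        return (ss_a / (a - 1)) / (ss_w / (n - a))


def npmanova(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-way non-parametric (permutational) MANOVA pseudo-F.

    SS_T = (1/N) sum_{i<j} d_ij^2; SS_W sums within-group squared distances
    scaled by group size; F = (SS_A/(a-1)) / (SS_W/(N-a)); significance by
    label permutation.
    """
    g = _validate_groups(dm, grouping)
    d2 = dm.data ** 2
    f_obs = _pseudo_f(d2, g)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, g[rng.permutation(len(g))]) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(f_obs, n_perm, p, name="NPMANOVA pseudo-F")


def simper(
    matrix: pd.DataFrame,
    grouping,
    cumulative_cutoff: float = 0.25,
) -> pd.DataFrame:
    """Similarity-percentage decomposition between exactly two groups.

    For each between-group sample pair the Bray-Curtis dissimilarity splits
    additively over OTUs as |x_i - y_i| / sum_j (x_j + y_j); SIMPER averages
    these per-OTU terms over all between-group pairs, ranks them and flags
    the top rows up to ``cumulative_cutoff`` of the total dissimilarity as
    reported.

    Returns a DataFrame with columns: otu, contribution, pct, cumulative_pct,
    reported; contributions sum to the mean between-group dissimilarity.
    """
    g = pd.Series(grouping).reindex(matrix.index)
    labels = g.dropna().unique()
    if len(labels) != 2:
        raise ValueError("SIMPER requires exactly two groups (one-vs-one)")
    xa = matrix.loc[g == labels[0]].to_numpy(float)
    xb = matrix.loc[g == labels[1]].to_numpy(float)
    contrib = np.zeros(matrix.shape[1])
    n_pairs = 0
    for x in xa:
        for y in xb:
            denom = (x + y).sum()
            if denom == 0:
                continue
            contrib += np.abs(x - y) / denom
            n_pairs += 1
    if n_pairs:
        contrib /= n_pairs
    total = contrib.sum()
    order = np.argsort(-contrib, kind="stable")
    out = pd.DataFrame({
        "otu": matrix.columns[order],
        "contribution": contrib[order],
        "pct": 100.0 * contrib[order] / total if total > 0 else 0.0,
    })
    out["cumulative_pct"] = out["pct"].cumsum()
    if total > 0:
        cutoff_pct = 100.0 * cumulative_cutoff
        reported = np.zeros(len(out), bool)
        for i, cum in enumerate(out["cumulative_pct"]):
            reported[i] = True
            if cum >= cutoff_pct:
                break
        out["reported"] = reported
    else:
        out = out.iloc[0:0]
        out["reported"] = pd.Series(dtype=bool)
    out.attrs["mean_between_group_dissimilarity"] = float(total)
    return out


def concat_enzyme_matrices(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Column-concatenate per-enzyme matrices on a shared sample index.

    Columns are prefixed with the enzyme name; samples missing from one
    enzyme get zero abundances there.
    """
    parts = []
    for enzyme in sorted(matrices):
        m = matrices[enzyme].copy()
        m.columns = [f"{enzyme}:{c}" for c in m.columns]
        parts.append(m)
    combined = pd.concat(parts, axis=1).fillna(0.0)
    return combined.sort_index()
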