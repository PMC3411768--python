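"""Richness accounting, paired richness testing and Renyi diversity profiles.

The Renyi profile generalizes the familiar diversity indices into a single
one-parameter family

    H_a = ln(sum_i p_i**a) / (1 - a),      a != 1,

with the Shannon entropy as the a -> 1 limit and the Berger-Parker view
``-ln(max p)`` at a -> infinity.  H_0 is the log of richness.  Profiles are
non-increasing in ``a``; a community whose profile lies pointwise at or
above another's at every ``a`` is ranked at least as diverse, while crossing
profiles are non-comparable.  Profiles are computed on raw (untransformed)
relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

#: Default alpha grid, including the index-equivalent markers 0, 1, 2, inf.
DEFAULT_ALPHAS = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, np.inf)


@dataclass
class DiversityProfile:
    """Renyi diversity values H_a (nats) over a grid of alpha values."""

    alphas: np.ndarray
    values: np.ndarray
    label: str = ""

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.alphas, name=self.label or "H_alpha")


@dataclass
class PairedTResult:
    statistic: float
    df: int
    p_value: float
    n: int
    flag: str | None = None


def richness(matrix: pd.DataFrame, by: str = "sample", groups=None):
    """OTU richness: count of OTUs with positive abundance.

    ``by="sample"`` returns a per-sample Series; ``by="group"`` (with a
    sample -> group mapping) returns mean and sd per group.
    """
    counts = (matrix > 0).sum(axis=1).astype(int)
    counts.name = "richness"
    if by == "sample":
        return counts
    if by == "group":
        if groups is None:
            raise ValueError("by='group' requires a groups mapping")
        g = pd.Series(groups).reindex(counts.index)
        out = counts.groupby(g).agg(["mean", "std", "count"])
        out.columns = ["mean", "sd", "n"]
        return out
    raise ValueError("by must be 'sample' or 'group'")


def paired_richness_test(richness_a, richness_b) -> PairedTResult:
    """Two-sided paired t-test of equal richness.

    Vectors must be paired (same length, matching order, e.g. by
    month x enzyme).  Degenerate inputs (fewer than two pairs, or
    zero-variance differences) are flagged rather than erroring.
    """
    a = np.asarray(richness_a, dtype=float)
    b = np.asarray(richness_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired richness vectors differ in length")
    n = len(a)
    if n < 2:
        return PairedTResult(float("nan"), max(n - 1, 0), float("nan"), n,
                             flag="too_few_pairs")
    diffs = a - b
    if np.std(diffs, ddof=1) == 0:
        if np.allclose(diffs, 0):
            return PairedTResult(0.0, n - 1, 1.0, n, flag="identical")
        return PairedTResult(float("inf"), n - 1, 0.0, n, flag="zero_variance")
    t, p = stats.ttest_rel(a, b)
    return PairedTResult(float(t), n - 1, float(p), n)


def renyi_profile(p, alphas=DEFAULT_ALPHAS, label: str = "") -> DiversityProfile:
    """Renyi diversity profile of one abundance vector.

    Zeros are excluded from the sums; a vector not summing to one is
    renormalized with a warning.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty abundance vector")
    if (p < 0).any():
        raise ValueError("negative abundances")
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("abundance vector has no positive entry")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        warnings.warn("abundances do not sum to 1; renormalizing", stacklevel=2)
        p = p / total

    alphas = np.asarray(alphas, dtype=float)
    values = np.empty_like(alphas)
    for i, a in enumerate(alphas):
        if np.isinf(a):
            values[i] = -np.log(p.max())
        elif a == 1.0:
            values[i] = float(-(p * np.log(p)).sum())
        else:
            values[i] = float(np.log((p ** a).sum()) / (1.0 - a))
    return DiversityProfile(alphas, values, label)


def compare_profiles(a: DiversityProfile, b: DiversityProfile, tol: float = 0.0) -> str:
    """Diversity ordering of two profiles on a shared alpha grid.

    Returns ``"a"`` / ``"b"`` when one profile dominates pointwise,
    ``"equal"`` when they coincide, and ``"non-comparable"`` when the
    profiles cross (the ordering is then undefined).
    """
    if not np.array_equal(a.alphas, b.alphas):
        raise ValueError("profiles use different alpha grids")
    diff = a.values - b.values
    if np.all(np.abs(diff) <= tol):
        return "equal"
    if np.all(diff >= -tol):
        return "a"
    if np.all(diff <= tol):
        return "b"
    return "non-comparable"


def group_renyi(
    matrix: pd.DataFrame,
    groups,
    alphas=DEFAULT_ALPHAS,
    mode: str = "pooled",
) -> dict[str, DiversityProfile]:
    """Per-group Renyi profiles of a samples x OTUs matrix.

    ``mode="pooled"`` (default) profiles each group's mean relative
    abundance vector; ``mode="per_sample"`` averages the per-sample profile
    values instead.
    """
    g = pd.Series(groups).reindex(matrix.index)
    out: dict[str, DiversityProfile] = {}
    for name, idx in matrix.groupby(g).groups.items():
        sub = matrix.loc[idx]
        if mode == "pooled":
            pooled = sub.mean(axis=0).to_numpy()
            out[str(name)] = renyi_profile(pooled / pooled.sum(), alphas, label=str(name))
        elif mode == "per_sample":
            profs = np.array([
                renyi_profile(row / row.sum(), alphas).values
                for row in sub.to_numpy() if row.sum() > 0
            ])
            out[str(name)] = DiversityProfile(
                np.asarray(alphas, float), profs.mean(axis=0), label=str(name)
            )
        else:
            raise ValueError("mode must be 'pooled' or 'per_sample'")
    return out
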