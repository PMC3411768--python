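"""Canonical correspondence analysis with Monte-Carlo significance testing.

CCA relates a community abundance matrix Y to explanatory variables X under
the chi-square metric: the doubly-standardized residual matrix

    Qbar = D_r^{-1/2} (P - r c^T) D_c^{-1/2},     P = Y / y++,

(r, c the row/column mass vectors) is projected, with row-mass weighting,
onto the span of the standardized explanatory variables, and the canonical
axes are the singular axes of the fitted matrix.  The canonical eigenvalues
are the squared singular values; their sum cannot exceed the total inertia
||Qbar||_F^2.  Scaling of the output scores focuses on inter-sample
distances (site scores carry the square-root eigenvalue).

Here Y holds square-root-transformed relative abundances rather than raw
counts - fidelity to the fingerprint workflow this package implements takes
precedence over the textbook count convention.

The permutation test permutes whole sample rows of X (unrestricted, the
default) or of the residuals of X about its weighted mean (reduced-model
scheme), recomputing the canonical eigenvalue sum (or first eigenvalue)
each time; p = (b + 1) / (m + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CcaResult:
    eigenvalues: np.ndarray            # canonical eigenvalues, descending
    total_inertia: float
    site_scores: pd.DataFrame          # inter-sample-distance scaling
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame        # one row per explanatory variable
    aliased: list = field(default_factory=list)

    @property
    def fraction_first_two(self) -> float:
        """Share of total inertia on the first two canonical axes."""
        lead = self.eigenvalues[:2].sum()
        return float(lead / self.total_inertia)

    @property
    def fraction_constrained(self) -> float:
        return float(self.eigenvalues.sum() / self.total_inertia)


@dataclass
class CcaPermutationResult:
    statistic: float
    n_permutations: int
    p_value: float
    scheme: str
    test_statistic: str


def _prepare(y: pd.DataFrame, x: pd.DataFrame):
    """Validate/align inputs; return the pieces shared by fit and permutations."""
    if not y.index.equals(x.index):
        try:
            x = x.loc[y.index]
        except KeyError as exc:
            raise ValueError("y and x rows do not match") from exc
    yv = y.to_numpy(dtype=float)
    if (yv < 0).any():
        raise ValueError("community matrix has negative entries")
    if (yv.sum(axis=1) <= 0).any():
        raise ValueError("community matrix has all-zero sample rows")
    col_ok = yv.sum(axis=0) > 0
    if not col_ok.all():
        logger.warning("dropping %d all-zero OTU columns", int((~col_ok).sum()))
        y = y.loc[:, col_ok]
        yv = yv[:, col_ok]

    total = yv.sum()
    p = yv / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    qbar = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return y, x, qbar, r, c


def _standardize_weighted(x: np.ndarray, r: np.ndarray):
    """Weighted (row-mass) centering and unit-variance scaling of X columns."""
    mean = r @ x
    xc = x - mean
    var = r @ (xc ** 2)
    var[var == 0] = 1.0
    return xc / np.sqrt(var)


def _drop_aliased(xstd: np.ndarray, names: list, r: np.ndarray):
    """Greedy removal of collinear explanatory columns (weighted metric)."""
    keep: list[int] = []
    aliased: list = []
    w = np.sqrt(r)[:, None]
    for j in range(xstd.shape[1]):
        cols = keep + [j]
        m = w * xstd[:, cols]
        if np.linalg.matrix_rank(m, tol=1e-10) == len(cols):
            keep.append(j)
        else:
            aliased.append(names[j])
    if aliased:
        logger.warning("aliased explanatory variables dropped: %s", aliased)
    return keep, aliased


def _canonical_eigenvalues(qbar: np.ndarray, xw: np.ndarray) -> np.ndarray:
    """Eigenvalues of the row-weighted projection of Qbar onto span(xw)."""
    beta, *_ = np.linalg.lstsq(xw, qbar, rcond=None)
    yhat = xw @ beta
    s = np.linalg.svd(yhat, compute_uv=False)
    rank = np.linalg.matrix_rank(xw, tol=1e-10)
    eig = (s ** 2)[:rank]
    return eig[eig > 1e-12]


def cca(y: pd.DataFrame, x: pd.DataFrame) -> CcaResult:
    """ter Braak canonical correspondence analysis of y constrained by x.

    Parameters
    ----------
    y : DataFrame
        Samples x OTUs non-negative abundances (square-root-transformed
        relative abundances in this workflow); no all-zero rows.
    x : DataFrame
        Samples x explanatory variables; standardized internally with
        row-mass weights.  Collinear columns are dropped with a warning.
    """
    y, x, qbar, r, c = _prepare(y, x)
    n = len(y)
    names = list(x.columns)
    if len(names) > n - 1:
        raise ValueError("more explanatory variables than samples - 1")
    xstd = _standardize_weighted(x.to_numpy(dtype=float), r)
    keep, aliased = _drop_aliased(xstd, names, r)
    names = [names[j] for j in keep]
    xw = np.sqrt(r)[:, None] * xstd[:, keep]

    beta, *_ = np.linalg.lstsq(xw, qbar, rcond=None)
    yhat = xw @ beta
    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    rank = int(np.linalg.matrix_rank(xw, tol=1e-10))
    pos = s[:rank] ** 2 > 1e-12
    u, s, vt = u[:, :rank][:, pos], s[:rank][pos], vt[:rank][pos]
    eig = s ** 2
    total_inertia = float((qbar ** 2).sum())

    axes = [f"CCA{i + 1}" for i in range(len(eig))]
    # inter-sample-distance scaling: sites carry the singular values
    site = (u * s) / np.sqrt(r)[:, None]
    species = vt.T / np.sqrt(c)[:, None]
    site_scores = pd.DataFrame(site, index=y.index, columns=axes)
    species_scores = pd.DataFrame(species, index=y.columns, columns=axes)

    # biplot arrows: row-mass-weighted correlation of each variable with the
    # site axes
    bip = np.empty((len(names), len(eig)))
    xk = xstd[:, keep]
    for a in range(len(eig)):
        za = site[:, a]
        za = za - r @ za
        za_sd = np.sqrt(r @ (za ** 2))
        for j in range(len(names)):
            bip[j, a] = (r @ (xk[:, j] * za)) / za_sd if za_sd > 0 else 0.0
    biplot_scores = pd.DataFrame(bip, index=names, columns=axes)

    return CcaResult(
        eigenvalues=eig,
        total_inertia=total_inertia,
        site_scores=site_scores,
        species_scores=species_scores,
        biplot_scores=biplot_scores,
        aliased=aliased,
    )


def ca_eigenvalues(y: pd.DataFrame) -> np.ndarray:
    """Unconstrained correspondence-analysis eigenvalues of y."""
    _, _, qbar, _, _ = _prepare(y, y.iloc[:, :0].assign(_one=1.0))
    s = np.linalg.svd(qbar, compute_uv=False)
    eig = s ** 2
    return eig[eig > 1e-12]


def cca_permutation_test(
    y: pd.DataFrame,
    x: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    statistic: str = "trace",
    scheme: str = "unrestricted",
) -> CcaPermutationResult:
    """Monte-Carlo permutation test of the community-environment relation.

    Null hypothesis: community composition is unrelated to the measured
    explanatory variables.  ``statistic="trace"`` uses the sum of canonical
    eigenvalues (default), ``"first"`` the first eigenvalue alone.
    """
    if statistic not in ("trace", "first"):
        raise ValueError("statistic must be 'trace' or 'first'")
    if scheme not in ("unrestricted", "reduced"):
        raise ValueError("scheme must be 'unrestricted' or 'reduced'")
    y2, x2, qbar, r, _ = _prepare(y, x)
    n = len(y2)
    xstd = _standardize_weighted(x2.to_numpy(dtype=float), r)
    keep, _ = _drop_aliased(xstd, list(x2.columns), r)
    xk = xstd[:, keep]
    if scheme == "reduced":
        # residuals about the (weighted) mean; identical permutation units
        xk = xk - (r @ xk)

    def stat_of(xmat: np.ndarray) -> float:
        xw = np.sqrt(r)[:, None] * xmat
        eig = _canonical_eigenvalues(qbar, xw)
        if eig.size == 0:
            return 0.0
        return float(eig.sum()) if statistic == "trace" else float(eig[0])

    observed = stat_of(xk)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat_of(xk[rng.permutation(n)]) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return CcaPermutationResult(observed, n_perm, p, scheme, statistic)
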