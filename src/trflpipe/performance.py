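"""Plant-performance statistics and the species-flow power law.

Covers the removal-efficiency arithmetic, the influent-vs-effluent BOD
correlation/regression per plant, the Wald test of whether that
relationship differs between plants, and the log-log least-squares fit of
the species-flow relationship ``S = c * A**z`` (richness S against average
daily flow A standing in for reactor size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class InOutRegression:
    """Pearson correlation and OLS fit of effluent on influent concentration."""

    r: float
    p_value: float
    slope: float
    intercept: float
    r_squared: float
    n: int
    flag: str | None = None


@dataclass
class WaldInteractionResult:
    statistic: float
    p_value: float
    interaction_coef: float
    df_num: int
    df_denom: int


@dataclass
class PowerLawFit:
    """Log-log least-squares fit of S = c * A**z."""

    c: float
    z: float
    r_squared: float
    z_se: float
    n_points: int

    def z_confint(self, alpha: float = 0.05) -> tuple[float, float]:
        tcrit = stats.t.ppf(1 - alpha / 2, self.n_points - 2)
        return (self.z - tcrit * self.z_se, self.z + tcrit * self.z_se)


#: Reported macro-organism z ranges for habitat-type labeling.
Z_RANGES = {"continuous": (0.12, 0.19), "insular": (0.2, 0.4)}


def removal_efficiency(inflow, outflow):
    """Percent removal, 100 * (inflow - outflow) / inflow.

    Vectorized; every inflow must be positive.
    """
    inflow = np.asarray(inflow, dtype=float)
    outflow = np.asarray(outflow, dtype=float)
    if (inflow <= 0).any():
        raise ValueError("inflow concentrations must be positive")
    if (outflow < 0).any():
        raise ValueError("outflow concentrations must be non-negative")
    eff = 100.0 * (inflow - outflow) / inflow
    return float(eff) if eff.ndim == 0 else eff


def inout_correlation(series_in, series_out) -> InOutRegression:
    """Pearson r (two-sided t-based p) and OLS fit of effluent on influent."""
    x = np.asarray(series_in, dtype=float)
    y = np.asarray(series_out, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired series differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        return InOutRegression(float("nan"), float("nan"), float("nan"),
                               float("nan"), float("nan"), len(x),
                               flag="zero_variance")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return InOutRegression(float(r), float(p), float(fit.slope),
                           float(fit.intercept), float(fit.rvalue ** 2), len(x))


def interaction_wald_test(series_in, series_out, plants) -> WaldInteractionResult:
    """Wald test of a plant x influent interaction in the in-out regression.

    Fits ``out ~ in + plant + in:plant`` by least squares over the two
    plants and tests the interaction coefficient against zero (F form,
    equivalent to the squared t of the coefficient under normal errors).
    """
    df = pd.DataFrame({
        "bod_in": np.asarray(series_in, dtype=float),
        "bod_out": np.asarray(series_out, dtype=float),
        "plant": list(plants),
    })
    levels = df["plant"].unique()
    if len(levels) != 2:
        raise ValueError("exactly two plants required")
    if (df.groupby("plant").size() < 3).any():
        raise ValueError("each plant needs at least 3 points")
    dummy = (df["plant"] == levels[1]).astype(float)
    exog = pd.DataFrame({
        "const": 1.0,
        "bod_in": df["bod_in"],
        "plant": dummy,
        "bod_in:plant": df["bod_in"] * dummy,
    })
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; influent values do not vary "
            "within a plant (aliased: interaction with plant)"
        )
    res = sm.OLS(df["bod_out"], exog).fit()
    wt = res.wald_test("bod_in:plant = 0", use_f=True, scalar=True)
    return WaldInteractionResult(
        statistic=float(wt.statistic),
        p_value=float(wt.pvalue),
        interaction_coef=float(res.params["bod_in:plant"]),
        df_num=int(wt.df_num),
        df_denom=int(wt.df_denom),
    )


def species_flow_fit(richness, flow) -> PowerLawFit:
    """Least squares of log10 S on log10 A: S = c * A**z.

    ``z`` is the slope (with its standard error), ``c = 10**intercept``.
    Needs at least two distinct flow values.
    """
    s = np.asarray(richness, dtype=float)
    a = np.asarray(flow, dtype=float)
    if len(s) != len(a):
        raise ValueError("richness and flow differ in length")
    if (s < 1).any():
        raise ValueError("richness values must be >= 1")
    if (a <= 0).any():
        raise ValueError("flow values must be positive")
    if len(np.unique(a)) < 2:
        raise ValueError("need at least two distinct flow values (slope undefined)")
    fit = stats.linregress(np.log10(a), np.log10(s))
    return PowerLawFit(
        c=float(10 ** fit.intercept),
        z=float(fit.slope),
        r_squared=float(fit.rvalue ** 2),
        z_se=float(fit.stderr),
        n_points=len(s),
    )


def classify_z(z: float) -> str:
    """Label a fitted exponent against reported macro-organism z ranges."""
    for name, (lo, hi) in Z_RANGES.items():
        if lo <= z <= hi:
            return name
    return "outside reported ranges"
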