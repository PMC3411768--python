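"""Recursive noise-threshold filter separating real TRF peaks from baseline.

A normalized fingerprint profile mixes a large number of low-amplitude
baseline peaks with a smaller set of genuine fragment peaks.  The filter
estimates the noise band recursively: compute the median (or mean) and the
sample standard deviation of the current working set, discard every value
above ``center + k*sd`` as "higher than expected", and repeat on what is
left until nothing more can be removed (or the spread collapses to zero).
The last computed cutoff is saved as the profile's noise threshold, and the
real peaks are the original values above it.

The center defaults to the median: the robust choice when the working set is
still contaminated by signal peaks (a config switch restores the classical
mean variant).  Removal during iteration is *strictly* greater by default -
a literal greater-or-equal rule makes a perfectly uniform profile delete
itself, which is a pathology, but it is available as ``iteration_rule="ge"``
for fidelity to that reading.  Final retention is strictly greater than the
threshold by default (``retention="ge"`` keeps boundary values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Profile

#: Below this many peaks the median/sd of the working set is meaningless,
#: so the profile bypasses filtering and is returned whole.
MIN_PEAKS_TO_FILTER = 5


@dataclass
class ThresholdResult:
    """Outcome of filtering one profile.

    ``threshold`` is in relative-abundance units (NaN when undefined);
    ``retained`` is the sub-profile of real peaks; ``flag`` marks special
    cases: ``bypass_small`` (too few peaks to filter), ``degenerate``
    (zero-variance profile, nothing strictly exceeds the threshold) or
    ``empty``.
    """

    sample_id: str
    enzyme: str
    threshold: float
    n_iterations: int
    retained: Profile
    n_input: int
    n_removed: int
    flag: str | None = None
    #: per-iteration cutoff values m + k*s (last one equals the threshold)
    cutoffs: tuple = ()


def _center(values: np.ndarray, how: str) -> float:
    if how == "median":
        return float(np.median(values))
    if how == "mean":
        return float(np.mean(values))
    raise ValueError("center must be 'median' or 'mean'")


def peaks_filter(
    profile: Profile,
    k_sigma: float = 3.0,
    center: str = "median",
    iteration_rule: str = "strict",
    retention: str = "strict",
) -> ThresholdResult:
    """Split a normalized profile into real peaks and baseline noise.

    Parameters
    ----------
    profile : Profile
        Normalized relative-abundance profile.
    k_sigma : float
        Multiplier on the sample standard deviation (default 3).
    center : {"median", "mean"}
        Location statistic of the working set.
    iteration_rule : {"strict", "ge"}
        Whether iteration removes values ``> cutoff`` (default) or
        ``>= cutoff`` (literal reading).
    retention : {"strict", "ge"}
        Whether final real peaks are ``> threshold`` (default) or
        ``>= threshold``.

    Returns
    -------
    ThresholdResult
        With ``retained`` a sub-profile of the input whose values all exceed
        the threshold, and every removed value at or below it.
    """
    if iteration_rule not in ("strict", "ge") or retention not in ("strict", "ge"):
        raise ValueError("iteration_rule / retention must be 'strict' or 'ge'")
    values = profile.values
    n = len(values)
    empty = Profile(profile.sample_id, profile.enzyme, normalized=False)

    if n == 0:
        return ThresholdResult(profile.sample_id, profile.enzyme, float("nan"),
                               0, empty, 0, 0, flag="empty")
    if n < MIN_PEAKS_TO_FILTER:
        return ThresholdResult(profile.sample_id, profile.enzyme, float("nan"),
                               0, profile, n, 0, flag="bypass_small")

    work = values.copy()
    n_iter = 0
    cutoffs: list[float] = []
    while True:
        n_iter += 1
        m = _center(work, center)
        s = float(np.std(work, ddof=1))
        cutoff = m + k_sigma * s
        cutoffs.append(float(cutoff))
        if s == 0.0:
            break
        mask = work > cutoff if iteration_rule == "strict" else work >= cutoff
        if not mask.any():
            break
        work = work[~mask]
        if len(work) < 2:
            # spread is no longer estimable; keep the last cutoff
            break

    threshold = cutoff
    keep = values > threshold if retention == "strict" else values >= threshold
    retained = Profile(
        profile.sample_id, profile.enzyme, profile.abundances[keep],
        normalized=False,
    ) if keep.any() else empty
    flag = None
    if not keep.any():
        flag = "degenerate"
    return ThresholdResult(
        sample_id=profile.sample_id,
        enzyme=profile.enzyme,
        threshold=float(threshold),
        n_iterations=n_iter,
        retained=retained,
        n_input=n,
        n_removed=int(n - keep.sum()),
        flag=flag,
        cutoffs=tuple(cutoffs),
    )


def filter_profiles(profiles, **kwargs) -> list[ThresholdResult]:
    """Apply :func:`peaks_filter` to a list of profiles."""
    return [peaks_filter(p, **kwargs) for p in profiles]
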