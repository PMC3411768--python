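"""Reading, writing and elementary transforms for T-RFLP peak data.

A *peak table* is the long-form record of every sized terminal restriction
fragment (TRF) detected on the electropherograms: one row per
(sample, enzyme, fragment) with the fragment size in base pairs and the raw
peak fluorescence height.  A *profile* is one sample x enzyme slice of that
table after height normalization: an ordered map from fragment size to
relative abundance summing to one.  Fragment sizes are kept as real numbers
(sub-bp size calls) throughout - the cross-gel binning step needs the raw
size estimates, so nothing here ever rounds them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of a long-form peak table, in canonical order.
PEAK_COLUMNS = ["sample_id", "plant", "month", "enzyme", "size_bp", "height"]

#: Span of the size standard run alongside every gel; fragments outside it
#: have no reliable size call.
MARKER_RANGE = (50.0, 700.0)


class EmptyProfileError(ValueError):
    """Raised when a profile with no positive peak height is normalized."""


@dataclass
class Profile:
    """One sample x enzyme vector of relative fragment abundances.

    Attributes
    ----------
    sample_id, enzyme : str
        Identity of the profile.
    abundances : pandas.Series
        Relative abundances indexed by fragment size (bp), strictly
        increasing index, values summing to 1 (unless the profile is empty).
    """

    sample_id: str
    enzyme: str
    abundances: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    #: False for sub-profiles (e.g. the retained peaks after noise
    #: filtering), whose abundances keep their original normalized values
    #: and therefore sum to less than 1.
    normalized: bool = True

    def __post_init__(self) -> None:
        a = self.abundances
        if len(a):
            sizes = np.asarray(a.index, dtype=float)
            if not np.all(np.diff(sizes) > 0):
                a = a.sort_index()
                sizes = np.asarray(a.index, dtype=float)
            if not np.all(np.diff(sizes) > 0):
                raise ValueError("profile has duplicate fragment sizes")
            total = float(a.sum())
            if self.normalized and abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"profile abundances sum to {total!r}, expected 1"
                )
            self.abundances = a.astype(float)

    @property
    def sizes(self) -> np.ndarray:
        return np.asarray(self.abundances.index, dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.abundances.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.abundances)


def validate_peak_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check invariants of a long-form peak table and return it.

    Sizes must be positive, heights non-negative and the
    (sample_id, enzyme, size_bp) key unique.
    """
    missing = [c for c in PEAK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peak table missing columns {missing}")
    if len(table):
        if (table["size_bp"] <= 0).any():
            raise ValueError("peak table contains non-positive fragment sizes")
        if (table["height"] < 0).any():
            raise ValueError("peak table contains negative peak heights")
        if table.duplicated(["sample_id", "enzyme", "size_bp"]).any():
            raise ValueError("duplicate (sample_id, enzyme, size_bp) records")
    return table


def read_peak_table(path) -> pd.DataFrame:
    """Read a tab-delimited peak table written by :func:`write_peak_table`."""
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return validate_peak_table(table)


def write_peak_table(table: pd.DataFrame, path) -> None:
    """Write a peak table as UTF-8 TSV with a header row.

    Floats are written with ``str()`` (shortest round-tripping repr), so a
    write/read cycle reproduces every value to full precision.
    """
    validate_peak_table(table)
    table.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a wide samples x OTUs abundance matrix (TSV, first column = sample)."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a samples x OTUs matrix as TSV (rows = samples)."""
    matrix.to_csv(path, sep="\t", index_label="sample_id")


def restrict_to_marker_range(
    table: pd.DataFrame,
    min_bp: float = MARKER_RANGE[0],
    max_bp: float = MARKER_RANGE[1],
) -> pd.DataFrame:
    """Drop fragments whose size call lies outside the size-standard range.

    Only fragments co-migrating with the molecular marker can be sized, so
    analysis is restricted to ``min_bp <= size_bp <= max_bp``.  Both
    endpoints are inclusive: the marker itself spans the interval, so
    boundary fragments are sized.
    """
    if not min_bp < max_bp:
        raise ValueError("min_bp must be smaller than max_bp")
    validate_peak_table(table)
    if not len(table):
        return table.copy()
    keep = (table["size_bp"] >= min_bp) & (table["size_bp"] <= max_bp)
    dropped = int((~keep).sum())
    logger.info(
        "marker-range restriction [%g, %g] bp: kept %d, dropped %d fragments",
        min_bp, max_bp, int(keep.sum()), dropped,
    )
    return table.loc[keep].reset_index(drop=True)


def normalize_profile(heights: pd.Series) -> pd.Series:
    """Divide each peak height by the sum of heights in the profile.

    Parameters
    ----------
    heights : pandas.Series
        Raw peak heights indexed by fragment size.

    Returns
    -------
    pandas.Series
        Relative abundances summing to 1, index sorted by size.

    Raises
    ------
    EmptyProfileError
        If the profile is empty or all heights are zero; this is signalled
        explicitly rather than surfacing as a division by zero.
    """
    heights = heights.sort_index().astype(float)
    total = float(heights.sum())
    if len(heights) == 0 or total <= 0:
        raise EmptyProfileError("profile has no positive peak height")
    return heights / total


def normalize_profiles(table: pd.DataFrame) -> list[Profile]:
    """Normalize every sample x enzyme slice of a peak table.

    Empty / all-zero slices are skipped with a warning (an explicit empty
    Profile would otherwise break the sums-to-one invariant).
    """
    validate_peak_table(table)
    profiles: list[Profile] = []
    for (sample_id, enzyme), grp in table.groupby(["sample_id", "enzyme"], sort=True):
        heights = pd.Series(
            grp["height"].to_numpy(float), index=grp["size_bp"].to_numpy(float)
        )
        try:
            abund = normalize_profile(heights)
        except EmptyProfileError:
            logger.warning(
                "skipping empty profile sample=%s enzyme=%s", sample_id, enzyme
            )
            continue
        profiles.append(Profile(str(sample_id), str(enzyme), abund))
    return profiles


def profiles_to_table(profiles: list[Profile], meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flatten profiles back into a long table of relative abundances.

    ``meta`` (optional) maps sample_id to plant / month columns; absent
    metadata is filled with empty strings so the result still validates as a
    peak table with ``height`` holding the relative abundance.
    """
    rows = []
    for p in profiles:
        for size, ab in p.abundances.items():
            rows.append((p.sample_id, p.enzyme, float(size), float(ab)))
    out = pd.DataFrame(rows, columns=["sample_id", "enzyme", "size_bp", "height"])
    if meta is not None:
        out = out.merge(meta[["sample_id", "plant", "month"]].drop_duplicates(), on="sample_id", how="left")
    else:
        out["plant"] = ""
        out["month"] = -1
    return out[PEAK_COLUMNS]


def sqrt_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Entrywise square root of an abundance matrix.

    Used before Bray-Curtis / ordination to damp the influence of highly
    dominant OTUs; zeros stay zero.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundance matrix has negative entries")
    return pd.DataFrame(np.sqrt(values), index=matrix.index, columns=matrix.columns)
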