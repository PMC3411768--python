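"""Cross-profile alignment of TRFs into unified OTU bins.

Fragments of the same taxon are size-called with small between-gel
discrepancies, so profiles from different samples must be aligned before
they can share an OTU axis.  Alignment groups TRFs of similar size under
three criteria:

1. *fragment size* - the span of a bin (max member size minus min member
   size) may not exceed a size-dependent maximum width taken from a
   configurable step table (default: 2 bp across the whole 50-700 bp marker
   range, after the window widths used for ARISA fragment binning);
2. *congruence* - a bin may hold at most one TRF per profile; a second TRF
   from an already-represented sample forces a subdivision;
3. *peak count* - between candidate binnings, the one placing more TRFs in
   multi-member bins (then the one with higher mean bin occupancy) wins.

Binning is a greedy single pass over the TRFs sorted by size, run once in
ascending and once in descending size order; the two runs are reconciled by
the peak-count criterion, ties going to the ascending run.  Each bin is
labeled by its OTU size: the mean of its members' molecular weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Profile

#: Default width step table: (low_bp, high_bp, max_bin_span_bp), endpoints
#: inclusive.  A single 2 bp window covers the whole marker range.
DEFAULT_WIDTH_TABLE = ((50.0, 700.0, 2.0),)


@dataclass(frozen=True)
class TrfRecord:
    """One TRF assigned to a bin."""

    sample_id: str
    size_bp: float
    abundance: float


@dataclass
class Bin:
    """A group of like-sized TRFs from distinct samples forming one OTU."""

    members: list = field(default_factory=list)

    @property
    def otu_size(self) -> float:
        """Assigned OTU size: the average molecular weight of the members."""
        return float(np.mean([m.size_bp for m in self.members]))

    @property
    def span(self) -> float:
        sizes = [m.size_bp for m in self.members]
        return max(sizes) - min(sizes)

    @property
    def samples(self) -> set:
        return {m.sample_id for m in self.members}

    def __len__(self) -> int:
        return len(self.members)


def max_width(size_bp: float, width_table=DEFAULT_WIDTH_TABLE) -> float:
    """Maximum allowed bin span (bp) for a fragment of the given size."""
    for lo, hi, width in width_table:
        if lo <= size_bp <= hi:
            return float(width)
    raise ValueError(
        f"fragment size {size_bp:g} bp outside the configured width table"
    )


def _flatten(profiles: list[Profile]) -> list[TrfRecord]:
    records = []
    enzymes = {p.enzyme for p in profiles}
    if len(enzymes) > 1:
        raise ValueError(f"profiles mix enzymes {sorted(enzymes)}")
    for p in profiles:
        for size, ab in p.abundances.items():
            records.append(TrfRecord(p.sample_id, float(size), float(ab)))
    return records


def bin_profiles(
    profiles: list[Profile],
    direction: str = "ascending",
    width_table=DEFAULT_WIDTH_TABLE,
) -> list[Bin]:
    """Greedy single-pass binning of all TRFs sorted by size.

    The current bin grows while the span stays within the width allowance of
    the bin's running mean size and the incoming TRF's sample is not already
    represented; any violation closes the bin and opens a new one.  Every
    TRF is assigned to exactly one bin.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    records = _flatten(profiles)
    records.sort(key=lambda r: r.size_bp, reverse=(direction == "descending"))

    bins: list[Bin] = []
    current: list[TrfRecord] = []
    for rec in records:
        if not current:
            current = [rec]
            continue
        candidate = current + [rec]
        sizes = [m.size_bp for m in candidate]
        span = max(sizes) - min(sizes)
        congruent = rec.sample_id not in {m.sample_id for m in current}
        if congruent and span <= max_width(float(np.mean(sizes)), width_table):
            current = candidate
        else:
            bins.append(Bin(current))
            current = [rec]
    if current:
        bins.append(Bin(current))
    if direction == "descending":
        bins = bins[::-1]
        for b in bins:
            b.members.sort(key=lambda r: r.size_bp)
    return bins


def _objective(bins: list[Bin]) -> tuple:
    n_multi = sum(len(b) for b in bins if len(b) >= 2)
    total = sum(len(b) for b in bins)
    mean_occupancy = total / len(bins) if bins else 0.0
    return (n_multi, mean_occupancy)


def reconcile_runs(asc: list[Bin], desc: list[Bin]) -> list[Bin]:
    """Pick the better of the ascending and descending binnings.

    "Better" maximizes (TRFs placed in bins of two or more members, then
    mean peaks per bin); exact ties keep the ascending run.  Both runs must
    cover the same TRF multiset.
    """
    def coverage(bins):
        return sorted((m.sample_id, m.size_bp) for b in bins for m in b.members)

    if coverage(asc) != coverage(desc):
        raise ValueError("ascending and descending runs cover different TRF sets")
    return desc if _objective(desc) > _objective(asc) else asc


def to_matrix(bins: list[Bin], samples: list[str]) -> pd.DataFrame:
    """Build the unified samples x OTUs relative-abundance matrix.

    Columns are labeled by the OTU size formatted to 0.01 bp (suffixed when
    two bins round to the same label); entries are the member abundances
    carried through unchanged, 0 where a sample has no TRF in a bin.
    """
    ordered = sorted(bins, key=lambda b: b.otu_size)
    labels = []
    seen: dict = {}
    for b in ordered:
        base = f"{b.otu_size:.2f}"
        if base in seen:
            seen[base] += 1
            labels.append(f"{base}_{seen[base]}")
        else:
            seen[base] = 0
            labels.append(base)
    matrix = pd.DataFrame(0.0, index=list(samples), columns=labels)
    for b, label in zip(ordered, labels):
        if len(b.samples) != len(b):
            raise ValueError("bin violates congruence (duplicate sample)")
        for m in b.members:
            matrix.loc[m.sample_id, label] = m.abundance
    return matrix


def bin_enzyme(
    profiles: list[Profile],
    width_table=DEFAULT_WIDTH_TABLE,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, list[Bin]]:
    """Full binning of one enzyme's profiles: both directions, reconciled.

    Returns the unified matrix and the selected bins (for audit output).
    """
    asc = bin_profiles(profiles, "ascending", width_table)
    desc = bin_profiles(profiles, "descending", width_table)
    chosen = reconcile_runs(asc, desc)
    if samples is None:
        samples = sorted({p.sample_id for p in profiles})
    return to_matrix(chosen, samples), chosen


def audit_table(bins: list[Bin]) -> pd.DataFrame:
    """Bin audit: one row per bin with id, members, span and OTU size."""
    rows = []
    for i, b in enumerate(sorted(bins, key=lambda x: x.otu_size)):
        rows.append({
            "bin_id": i,
            "otu_size": round(b.otu_size, 4),
            "n_members": len(b),
            "span": round(b.span, 4),
            "members": ";".join(f"{m.sample_id}:{m.size_bp:.3f}" for m in b.members),
        })
    return pd.DataFrame(rows, columns=["bin_id", "otu_size", "n_members", "span", "members"])
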