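"""Interval arithmetic for region x feature overlap analyses, with BED I/O.

Implements the merge / intersect / fraction-of-regions-containing-a-feature
pipeline used to ask whether hyperdivergent genomic regions contain
germline-expressed genes (candidate parental-effect toxin loci). Coordinates
are BED-standard 0-based half-open; merging joins bookended intervals;
"containing" means an overlap of at least one base; strand is ignored. A
seeded fixture generator produces synthetic region/feature BED pairs with a
containment fraction known by construction, so the pipeline is testable
without any external genome data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "BedParseError",
    "Interval",
    "IntervalSet",
    "read_bed",
    "write_bed",
    "merge",
    "intersect",
    "fraction_containing",
    "make_fixtures",
]


class BedParseError(ValueError):
    """Malformed BED input (bad coordinates, wrong column count)."""


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class IntervalSet:
    """Ordered, strand-agnostic genomic intervals, per chromosome.

    Intervals are kept sorted by (chrom, start, end); construction validates
    start < end. Merged sets are additionally non-overlapping.
    """

    intervals: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        mine = [(iv.chrom, iv.start, iv.end) for iv in self.intervals]
        theirs = [(iv.chrom, iv.start, iv.end) for iv in other.intervals]
        return mine == theirs

    @classmethod
    def from_records(cls, records: Iterable[Tuple]) -> "IntervalSet":
        """Build from (chrom, start, end[, name]) tuples."""
        return cls([Interval(*rec) for rec in records])

    def by_chrom(self) -> Dict[str, List[Interval]]:
        out: Dict[str, List[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_bases(self) -> int:
        """Total covered bases; only meaningful after :func:`merge`."""
        return sum(len(iv) for iv in merge(self).intervals)


def read_bed(path) -> IntervalSet:
    """Read a 3+ column BED file, tolerating track/browser/comment lines.

    Raises :class:`BedParseError` with the offending line number on
    non-integer or inverted coordinates.
    """
    ivs: List[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {s!r}, {e!r}"
                ) from exc
            if end <= start or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 else None
            ivs.append(Interval(chrom, start, end, name))
    return IntervalSet(ivs)


def write_bed(iset: IntervalSet, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for iv in iset:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")
    return path


def merge(iset: IntervalSet) -> IntervalSet:
    """Union of overlapping or bookended intervals (bedtools merge default).

    Total covered bases are preserved; the output is sorted and
    non-overlapping.
    """
    out: List[Interval] = []
    for chrom, ivs in iset.by_chrom().items():
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or bookend
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(chrom, cur_s, cur_e))
    return IntervalSet(out)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-wise intersection pieces of two interval sets (bedtools intersect)."""
    trees = _build_trees(b)
    out: List[Interval] = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(iv.start, iv.end)):
            out.append(
                Interval(iv.chrom, max(iv.start, hit.begin), min(iv.end, hit.end))
            )
    return IntervalSet(out)


def _build_trees(iset: IntervalSet) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for chrom, ivs in iset.by_chrom().items():
        trees[chrom] = IntervalTree.from_tuples((iv.start, iv.end) for iv in ivs)
    return trees


def fraction_containing(
    regions: IntervalSet, features: IntervalSet
) -> Tuple[int, float, pd.DataFrame]:
    """Count and fraction of regions overlapped by at least one feature.

    A region counts if any feature overlaps it by >= 1 base (all or part of
    at least one feature). Returns ``(count, fraction, flags)`` where
    ``flags`` has one row per region with a boolean ``contains_feature``.
    """
    if len(regions) == 0:
        raise ValueError("regions set is empty")
    trees = _build_trees(features)
    rows = []
    for iv in regions:
        tree = trees.get(iv.chrom)
        hit = bool(tree is not None and tree.overlap(iv.start, iv.end))
        rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                     "name": iv.name, "contains_feature": hit})
    flags = pd.DataFrame(rows)
    count = int(flags["contains_feature"].sum())
    return count, count / len(regions), flags


def make_fixtures(
    n_regions: int,
    n_features: int,
    genome_length: int,
    overlap_fraction: float,
    seed: int,
    out_regions=None,
    out_features=None,
    chrom: str = "chrI",
) -> Tuple[IntervalSet, IntervalSet]:
    """Deterministic synthetic region/feature BED pair with a planted fraction.

    Partitions one synthetic chromosome into ``n_regions`` slots; each slot's
    left half holds a region and its right half is kept feature-free. Exactly
    ``round(overlap_fraction * n_regions)`` regions (a seeded random subset)
    receive a feature inside them; remaining features are decoys placed in
    slot right-halves, overlapping nothing. The realized containment
    fraction is therefore known by construction to within rounding. Writes
    BED files when output paths are given; byte-identical for a fixed seed.
    """
    if n_regions < 1 or n_features < 0:
        raise ValueError("need n_regions >= 1 and n_features >= 0")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError(f"overlap_fraction must be in [0, 1], got {overlap_fraction}")
    n_planted = int(round(overlap_fraction * n_regions))
    if n_features < n_planted:
        raise ValueError(
            f"need n_features >= {n_planted} to plant fraction {overlap_fraction}"
        )
    slot = genome_length // n_regions
    if slot < 16:
        raise ValueError(
            f"infeasible geometry: slot width {slot} < 16 "
            f"(genome_length={genome_length}, n_regions={n_regions})"
        )
    rng = np.random.default_rng(seed)
    half = slot // 2
    regions: List[Interval] = []
    for i in range(n_regions):
        s = i * slot
        regions.append(Interval(chrom, s, s + half - 1, name=f"region_{i}"))

    planted_idx = rng.permutation(n_regions)[:n_planted]
    features: List[Interval] = []
    for j, i in enumerate(sorted(planted_idx)):
        reg = regions[i]
        start = int(rng.integers(reg.start, reg.end))
        end = int(rng.integers(start + 1, reg.end + 1))
        features.append(Interval(chrom, start, end, name=f"feature_in_{i}"))
    n_decoys = n_features - n_planted
    for d in range(n_decoys):
        i = int(rng.integers(0, n_regions))
        gap_start = i * slot + half  # right half: region ends at half-1, gap >= 1 base away
        gap_end = (i + 1) * slot - 1 if i < n_regions - 1 else genome_length
        if gap_end - gap_start < 2:
            raise ValueError("infeasible geometry: no room for decoy features")
        start = int(rng.integers(gap_start, gap_end - 1))
        end = int(rng.integers(start + 1, gap_end))
        features.append(Interval(chrom, start, end, name=f"decoy_{d}"))

    region_set = IntervalSet(regions)
    feature_set = IntervalSet(features)
    if out_regions is not None:
        write_bed(region_set, out_regions)
    if out_features is not None:
        write_bed(feature_set, out_features)
    return region_set, feature_set
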