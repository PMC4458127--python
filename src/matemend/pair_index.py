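"""Per-contig interval trees over mate-pair spans.

One tree is built per contig, holding the outer span of every intra-contig
mate pair together with the per-read extents and an orientation flag.  A
position is then interrogated with a stabbing query in O(log n + m) rather
than re-fetching reads from the alignment file, so multiple passes over a
contig (different step sizes, windows or thresholds) reuse the same tree.

Mapping quality is deliberately not filtered at this stage: a drop in
uniquely mapping pairs is itself a signal of trouble, so all primary
intra-contig pairs are retained regardless of mapq.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .errors import MissingContigError
from .insert_stats import (
    AlignmentSource,
    iter_primary_pairs,
    orientation_is_correct,
    pair_outer_span,
)


@dataclass(frozen=True)
class MatePairRecord:
    """One mate pair's footprint on a contig.

    ``start``/``end`` are the 0-based half-open outer span of the pair;
    ``left_read_end`` (exclusive) and ``right_read_start`` are the aligned
    reference extents of the two mates, needed to decide whether the pair
    spans a region *entirely* (reads clear of the region, not merely the
    span containing it).  ``orientation_ok`` is the indicator C_l: wrongly
    oriented pairs contribute zero support.
    """

    start: int
    end: int
    insert_size: int
    orientation_ok: bool
    left_read_end: int
    right_read_start: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("pair span must be non-empty (end > start)")
        if self.insert_size != self.end - self.start:
            raise ValueError("insert_size must equal end - start")


@dataclass
class PairIntervalTree:
    """Interval tree of mate-pair spans for one contig."""

    contig_name: str
    contig_length: int
    tree: IntervalTree

    def __len__(self) -> int:
        return len(self.tree)

    @property
    def records(self) -> list[MatePairRecord]:
        return [iv.data for iv in sorted(self.tree)]


def build_index(
    source: AlignmentSource,
    contig: str,
    contig_length: int | None = None,
    orientation_layout: str = "fr",
) -> PairIntervalTree:
    """Build the mate-pair interval tree for one contig.

    Pairs whose mates map to different contigs are excluded; mapping quality
    is not filtered here.  ``contig_length`` defaults to the length recorded
    in the alignment header.

    Raises
    ------
    MissingContigError
        If the contig is not present in the alignment header.
    """
    import pysam

    own = False
    if isinstance(source, str):
        source = pysam.AlignmentFile(source)
        own = True
    try:
        if contig not in source.references:
            raise MissingContigError(
                f"contig {contig!r} not found in alignment header"
            )
        if contig_length is None:
            contig_length = source.get_reference_length(contig)
        tree = IntervalTree()
        for left, right in iter_primary_pairs(source, contig=contig):
            start, end = pair_outer_span(left, right)
            if start < 0 or end <= start:
                continue
            rec = MatePairRecord(
                start=start,
                end=end,
                insert_size=end - start,
                orientation_ok=orientation_is_correct(
                    left.is_reverse, right.is_reverse, orientation_layout
                ),
                left_read_end=min(left.reference_end, right.reference_end),
                right_read_start=max(left.reference_start, right.reference_start),
            )
            tree.addi(start, end, rec)
        return PairIntervalTree(
            contig_name=contig, contig_length=int(contig_length), tree=tree
        )
    finally:
        if own:
            source.close()


def spanning_pairs(index: PairIntervalTree, i: int, window: int) -> list[MatePairRecord]:
    """Mate pairs spanning the region [i - W, i + W] entirely.

    A pair spans when its left read's alignment ends strictly before i - W
    and its right read's alignment begins strictly after i + W.  Implemented
    as a stabbing query on the outer spans followed by the strict
    per-read-extent check.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lo, hi = i - window, i + window
    out = [
        iv.data
        for iv in index.tree.overlap(lo, hi + 1)
        # left read's last aligned base is left_read_end - 1 (half-open end)
        if iv.data.left_read_end - 1 < lo and iv.data.right_read_start > hi
    ]
    out.sort(key=lambda r: (r.start, r.end, r.right_read_start))
    return out
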