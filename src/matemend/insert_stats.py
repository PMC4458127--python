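"""Robust estimation of the global mate-pair insert-size distribution.

The null model for correctly paired inserts is a normal distribution whose
location is the arithmetic mean of filtered insert sizes and whose scale is
derived from the median absolute deviation (MAD), sigma = 1.4826 * MAD.
The MAD is insensitive to the long tail of real mate-pair libraries, so a
small fraction of anomalous inserts does not inflate the scale estimate.

Filtering for the global estimate: both mates on the same contig, correct
strand/pairing orientation for the configured library layout, insert size
at most ``maxinsert`` and mapping quality of *both* mates at least
``minmapq``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
import pysam

from .errors import NoUsablePairsError

# Conversion factor between the MAD and the standard deviation of a normal
# distribution: 1/Phi^{-1}(3/4).
MAD_TO_SIGMA = 1.4826

#: Supported library layouts: "fr" = leftmost mate forward / rightmost mate
#: reverse (innie); "rf" = the opposite (outie, raw mate-pair chemistry).
LAYOUTS = ("fr", "rf")

AlignmentSource = Union[str, pysam.AlignmentFile]


@dataclass(frozen=True)
class PairFilterConfig:
    """Filters applied when estimating global insert-size statistics.

    Parameters
    ----------
    maxinsert : int
        Maximum insert size (bases) below which a pair is included.
    minmapq : int
        Minimum mapping quality; both mates must reach it.
    orientation_layout : str
        Expected pair orientation, ``"fr"`` or ``"rf"``.
    """

    maxinsert: int = 30_000
    minmapq: int = 40
    orientation_layout: str = "fr"

    def __post_init__(self) -> None:
        if self.maxinsert <= 0:
            raise ValueError("maxinsert must be positive")
        if self.minmapq < 0:
            raise ValueError("minmapq must be non-negative")
        if self.orientation_layout not in LAYOUTS:
            raise ValueError(f"orientation_layout must be one of {LAYOUTS}")


@dataclass(frozen=True)
class GlobalInsertModel:
    """Robust parameters of the null insert-size distribution.

    Attributes
    ----------
    mu_hat : float
        Arithmetic mean insert size (bases) of pairs passing filters.
    mad : float
        Median absolute deviation of insert sizes (bases).
    sigma_hat : float
        Normal-equivalent standard deviation, ``1.4826 * mad``.
    n_pairs_used : int
        Number of pairs contributing to the estimate.
    """

    mu_hat: float
    mad: float
    sigma_hat: float
    n_pairs_used: int

    def __post_init__(self) -> None:
        if self.n_pairs_used < 1:
            raise ValueError("a model requires at least one pair")
        if self.mad < 0 or self.sigma_hat < 0:
            raise ValueError("mad and sigma_hat must be non-negative")


def orientation_is_correct(
    left_is_reverse: bool, right_is_reverse: bool, layout: str = "fr"
) -> bool:
    """Whether a pair's strands match the expected library layout.

    ``left``/``right`` refer to reference coordinate order.  Same-strand
    pairs are always incorrect; opposite-strand pairs are correct only when
    they point the way the layout expects ("fr": towards each other).
    """
    if layout not in LAYOUTS:
        raise ValueError(f"layout must be one of {LAYOUTS}")
    if left_is_reverse == right_is_reverse:
        return False
    if layout == "fr":
        return (not left_is_reverse) and right_is_reverse
    return left_is_reverse and (not right_is_reverse)


def _is_primary(rec: pysam.AlignedSegment) -> bool:
    return not (
        rec.is_secondary or rec.is_supplementary or rec.is_duplicate or rec.is_unmapped
    )


def iter_primary_pairs(
    source: AlignmentSource,
    contig: str | None = None,
) -> Iterator[tuple[pysam.AlignedSegment, pysam.AlignedSegment]]:
    """Yield (leftmost, rightmost) primary mate pairs from an alignment file.

    Pairs are matched by query name across a streaming pass, so the file
    need not be name-sorted.  Only pairs with both mates mapped on the same
    contig are yielded; ``contig`` optionally restricts to one contig
    (using the index via ``fetch`` when available).  Mates tied on start
    position are ordered read1-first for determinism.
    """
    own = False
    if isinstance(source, (str,)):
        source = pysam.AlignmentFile(str(source))
        own = True
    try:
        if contig is not None and source.has_index():
            records = source.fetch(contig)
        else:
            records = source.fetch(until_eof=True)
        pending: dict[str, pysam.AlignedSegment] = {}
        for rec in records:
            if not rec.is_paired or not _is_primary(rec):
                continue
            if rec.mate_is_unmapped or rec.reference_id != rec.next_reference_id:
                continue
            if contig is not None and rec.reference_name != contig:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            a, b = mate, rec
            if (b.reference_start, b.is_read2) < (a.reference_start, a.is_read2):
                a, b = b, a
            yield a, b
    finally:
        if own:
            source.close()


def pair_outer_span(
    left: pysam.AlignedSegment, right: pysam.AlignedSegment
) -> tuple[int, int]:
    """Outer span of a pair: leftmost aligned base to rightmost, half-open."""
    start = min(left.reference_start, right.reference_start)
    end = max(left.reference_end, right.reference_end)
    return start, end


def collect_proper_inserts(
    source: AlignmentSource,
    filters: PairFilterConfig | None = None,
) -> list[int]:
    """Collect insert sizes of properly oriented intra-contig pairs.

    The insert size is the outer distance: from the leftmost aligned base of
    the leftmost mate to the rightmost aligned base of the rightmost mate.
    Each pair contributes exactly one value.

    Raises
    ------
    NoUsablePairsError
        If no pair survives filtering; callers must abort rather than
        proceed with undefined statistics.
    """
    filters = filters or PairFilterConfig()
    inserts: list[int] = []
    for left, right in iter_primary_pairs(source):
        if left.mapping_quality < filters.minmapq:
            continue
        if right.mapping_quality < filters.minmapq:
            continue
        if not orientation_is_correct(
            left.is_reverse, right.is_reverse, filters.orientation_layout
        ):
            continue
        start, end = pair_outer_span(left, right)
        insert = end - start
        if insert > filters.maxinsert:
            continue
        inserts.append(insert)
    if not inserts:
        raise NoUsablePairsError(
            "no mate pairs passed the insert-size filters; cannot estimate "
            "the global insert-size distribution"
        )
    return inserts


def median_absolute_deviation(values: Sequence[float] | np.ndarray) -> float:
    """Median of absolute residuals from the median.

    Even-length medians are the mean of the two central order statistics.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_absolute_deviation requires a non-empty input")
    return float(np.median(np.abs(arr - np.median(arr))))


def mad_to_sigma(mad: float) -> float:
    """Normal-equivalent standard deviation for a given MAD (factor 1.4826)."""
    if mad < 0:
        raise ValueError("mad must be non-negative")
    return MAD_TO_SIGMA * mad


def estimate_global_model(inserts: Iterable[float]) -> GlobalInsertModel:
    """Estimate the null insert-size model from filtered insert sizes.

    The location is the plain arithmetic mean; the scale is the MAD scaled
    to a normal-equivalent standard deviation, making it robust to a small
    contaminating fraction of anomalous inserts.
    """
    arr = np.asarray(list(inserts), dtype=float)
    if arr.size == 0:
        raise NoUsablePairsError("cannot estimate a model from zero inserts")
    mad = median_absolute_deviation(arr)
    return GlobalInsertModel(
        mu_hat=float(arr.mean()),
        mad=mad,
        sigma_hat=mad_to_sigma(mad),
        n_pairs_used=int(arr.size),
    )
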