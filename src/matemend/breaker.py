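"""Turning low-support positions into misassembly calls and broken contigs.

Positions whose Z-score falls below the threshold T are candidate
misassemblies.  Low-scoring positions within the trimming distance of a
contig end are ignored: ends naturally lose spanning pairs (mates fall off
the contig, or wrap around a circular molecule such as a plasmid), so a dip
there is an edge artefact, not an error.  Surviving positions closer than
the trimming distance to each other are merged into a single call.  Each
call is then excised — the region plus ``trim`` bases on each side — and
the contig is replaced by the remaining fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import InvalidCallsError, MissingContigError
from .support_scan import ScoreTrack


@dataclass(frozen=True)
class BreakConfig:
    """Calling/trimming parameters.

    trim
        Bases removed on each side of a call (0 disables trimming but still
        breaks the contig at the call boundaries).
    threshold
        Z-score threshold T below which a position is flagged.
    """

    trim: int = 4_000
    threshold: float = -4.0

    def __post_init__(self) -> None:
        if self.trim < 0:
            raise ValueError("trim must be non-negative")


@dataclass(frozen=True)
class MisassemblyCall:
    """A merged low-support region on one contig slated for excision.

    ``region_start``/``region_end`` are the first and last flagged positions
    (0-based, inclusive).
    """

    contig_name: str
    region_start: int
    region_end: int
    min_zscore: float
    flagged_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.region_end < self.region_start:
            raise ValueError("region_end must be >= region_start")
        if any(
            p < self.region_start or p > self.region_end
            for p in self.flagged_positions
        ):
            raise ValueError("flagged positions must lie within the region")


def call_misassemblies(
    track: ScoreTrack,
    contig_length: int,
    config: BreakConfig | None = None,
) -> list[MisassemblyCall]:
    """Convert a Z-score track into merged, end-filtered misassembly calls.

    Positions with z < T are selected; positions within the trimming
    distance of either contig end are discarded first (so an edge artefact
    cannot drag an interior call outward); survivors are merged by
    single-linkage while consecutive gaps are below the trimming distance.
    With trim = 0 the end-exclusion window and merge adjacency both fall
    back to one step of the scan grid.
    """
    config = config or BreakConfig()
    flagged = sorted(
        int(p)
        for p, z in zip(track.positions, track.zscores)
        if z < config.threshold
    )
    end_excl = config.trim if config.trim > 0 else track.stepsize
    flagged = [p for p in flagged if p >= end_excl and p <= contig_length - end_excl]
    if not flagged:
        return []
    if config.trim > 0:
        def merges(gap: int) -> bool:
            return gap < config.trim
    else:
        def merges(gap: int) -> bool:
            return gap <= track.stepsize
    z_at = {int(p): float(z) for p, z in zip(track.positions, track.zscores)}
    calls: list[MisassemblyCall] = []
    cluster = [flagged[0]]
    for p in flagged[1:]:
        if merges(p - cluster[-1]):
            cluster.append(p)
        else:
            calls.append(_make_call(track.contig_name, cluster, z_at))
            cluster = [p]
    calls.append(_make_call(track.contig_name, cluster, z_at))
    return calls


def _make_call(
    contig: str, cluster: list[int], z_at: Mapping[int, float]
) -> MisassemblyCall:
    return MisassemblyCall(
        contig_name=contig,
        region_start=cluster[0],
        region_end=cluster[-1],
        min_zscore=min(z_at[p] for p in cluster),
        flagged_positions=tuple(cluster),
    )


def excision_intervals(
    calls: Sequence[MisassemblyCall], contig_length: int, trim: int
) -> list[tuple[int, int]]:
    """Half-open intervals removed from the contig, clamped and merged.

    Each call removes [region_start - trim, region_end + trim] inclusive.
    Adjacent excisions that touch after trimming are merged so the removed
    set is a disjoint union.
    """
    raw = sorted(
        (
            max(0, c.region_start - trim),
            min(contig_length, c.region_end + trim + 1),
        )
        for c in calls
    )
    merged: list[tuple[int, int]] = []
    for lo, hi in raw:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def break_contig(
    sequence: str,
    calls: Sequence[MisassemblyCall],
    config: BreakConfig | None = None,
) -> list[tuple[str, str]]:
    """Excise called regions and return the surviving fragments in order.

    Returns (name-suffix, sequence) tuples; suffixes are "_0", "_1", ...
    left to right.  Zero-length fragments are dropped.  With no calls the
    single fragment carries an empty suffix and equals the input.

    Raises
    ------
    InvalidCallsError
        If call regions overlap or fall outside the sequence.
    """
    config = config or BreakConfig()
    length = len(sequence)
    ordered = sorted(calls, key=lambda c: (c.region_start, c.region_end))
    for c in ordered:
        if c.region_start < 0 or c.region_end >= length:
            raise InvalidCallsError(
                f"call [{c.region_start}, {c.region_end}] outside contig of "
                f"length {length}"
            )
    for a, b in zip(ordered, ordered[1:]):
        if b.region_start <= a.region_end:
            raise InvalidCallsError("misassembly calls overlap")
    if not ordered:
        return [("", sequence)]
    fragments: list[str] = []
    cursor = 0
    for lo, hi in excision_intervals(ordered, length, config.trim):
        fragments.append(sequence[cursor:lo])
        cursor = hi
    fragments.append(sequence[cursor:])
    kept = [f for f in fragments if f]
    return [(f"_{k}", frag) for k, frag in enumerate(kept)]


def repair_assembly(
    assembly: Mapping[str, str],
    tracks: Mapping[str, ScoreTrack],
    config: BreakConfig | None = None,
) -> tuple[list[tuple[str, str]], list[MisassemblyCall]]:
    """Apply calling and breaking across a whole assembly.

    Contigs without a track (e.g. below the scan's minimum size) pass
    through unchanged.  Returns the corrected assembly as an ordered list of
    (name, sequence) and the full list of calls made.

    Raises
    ------
    MissingContigError
        If a track names a contig absent from the assembly.
    """
    config = config or BreakConfig()
    missing = [name for name in tracks if name not in assembly]
    if missing:
        raise MissingContigError(
            f"tracks refer to contigs absent from the assembly: {missing}"
        )
    out: list[tuple[str, str]] = []
    all_calls: list[MisassemblyCall] = []
    for name, seq in assembly.items():
        track = tracks.get(name)
        if track is None:
            out.append((name, seq))
            continue
        calls = call_misassemblies(track, len(seq), config)
        all_calls.extend(calls)
        if not calls:
            out.append((name, seq))
            continue
        for suffix, frag in break_contig(seq, calls, config):
            out.append((name + suffix, frag))
    return out, all_calls


def write_fasta(sequences: Sequence[tuple[str, str]], path: str, width: int = 80) -> None:
    """Write sequences as FASTA, line-wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in sequences:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_call_report(calls: Sequence[MisassemblyCall], path: str) -> None:
    """CSV report: contig, region_start, region_end, min_zscore, n_flagged_positions."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "contig": c.contig_name,
                "region_start": c.region_start,
                "region_end": c.region_end,
                "min_zscore": c.min_zscore,
                "n_flagged_positions": len(c.flagged_positions),
            }
            for c in calls
        ],
        columns=[
            "contig",
            "region_start",
            "region_end",
            "min_zscore",
            "n_flagged_positions",
        ],
    ).to_csv(path, index=False)
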