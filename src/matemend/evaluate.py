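"""ROC evaluation of misassembly calls against known truth.

Each contig is divided into fixed-width bins (1 kb by default, matching the
scan's step so evaluation resolution equals detection resolution).  A bin is
positive if a call region intersects it; truth bins are those containing an
engineered misassembly coordinate.  Per-bin confusion counts pooled across
contigs give TPR = TP/(TP+FN) and FPR = FP/(FP+TN) for each threshold in a
sweep; undefined rates (zero denominators) are reported as NaN, not errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .breaker import BreakConfig, MisassemblyCall, call_misassemblies
from .simulate import TruthSet
from .support_scan import ScoreTrack


@dataclass
class BinnedCalls:
    """Binary per-bin call indicator for one contig."""

    contig_name: str
    bin_width: int
    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=int)
        if not np.isin(self.flags, (0, 1)).all():
            raise ValueError("flags must be binary")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def fpr(self) -> float:
        d = self.fp + self.tn
        return self.fp / d if d else math.nan

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


def bin_calls(
    calls: Sequence[MisassemblyCall],
    contig_length: int,
    bin_width: int = 1_000,
    contig_name: str = "",
) -> BinnedCalls:
    """Mark every bin intersected by a call region.

    Call regions are inclusive coordinate ranges; bin i covers
    [i * bin_width, (i+1) * bin_width).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = math.ceil(contig_length / bin_width)
    flags = np.zeros(n_bins, dtype=int)
    for c in calls:
        lo = max(0, c.region_start // bin_width)
        hi = min(n_bins - 1, c.region_end // bin_width)
        flags[lo : hi + 1] = 1
    return BinnedCalls(contig_name or (calls[0].contig_name if calls else ""),
                       bin_width, flags)


def confusion(
    binned: BinnedCalls,
    truth: TruthSet | Sequence[int],
    bin_width: int | None = None,
) -> ConfusionCounts:
    """Per-bin confusion counts for one contig.

    ``truth`` is either a TruthSet (positions taken for the binned contig)
    or a plain sequence of truth coordinates.  A bin is truth-positive if an
    engineered misassembly coordinate falls inside it.
    """
    bw = bin_width or binned.bin_width
    positions = (
        truth.positions_for(binned.contig_name)
        if isinstance(truth, TruthSet)
        else list(truth)
    )
    truth_bins = {p // bw for p in positions if 0 <= p // bw < len(binned.flags)}
    tp = fp = tn = fn = 0
    for i, flag in enumerate(binned.flags):
        in_truth = i in truth_bins
        if flag and in_truth:
            tp += 1
        elif flag:
            fp += 1
        elif in_truth:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    counts: ConfusionCounts

    @property
    def tpr(self) -> float:
        return self.counts.tpr

    @property
    def fpr(self) -> float:
        return self.counts.fpr


def roc_sweep(
    tracks: Mapping[str, ScoreTrack],
    truth: TruthSet,
    thresholds: Sequence[float],
    trim: int = 4_000,
    bin_width: int = 1_000,
) -> list[RocPoint]:
    """TPR/FPR across a threshold sweep, bins pooled over all contigs.

    For each threshold the full calling pipeline (end-exclusion, merging)
    is re-run from the score tracks before binning.
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    points = []
    for t in thresholds:
        pooled = ConfusionCounts(0, 0, 0, 0)
        for name, track in tracks.items():
            length = truth.contig_lengths.get(name)
            if length is None:
                raise KeyError(f"truth set lacks a length for contig {name!r}")
            calls = call_misassemblies(
                track, length, BreakConfig(trim=trim, threshold=float(t))
            )
            binned = bin_calls(calls, length, bin_width, contig_name=name)
            pooled = pooled + confusion(binned, truth)
        points.append(RocPoint(float(t), pooled))
    return points


def write_roc_csv(points: Sequence[RocPoint], path: str) -> None:
    """ROC table: threshold, tp, fp, tn, fn, tpr, fpr."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "threshold": p.threshold,
                "tp": p.counts.tp,
                "fp": p.counts.fp,
                "tn": p.counts.tn,
                "fn": p.counts.fn,
                "tpr": p.tpr,
                "fpr": p.fpr,
            }
            for p in points
        ]
    ).to_csv(path, index=False)


def plot_roc(points: Sequence[RocPoint], path: str) -> None:
    """ROC curve (FPR vs TPR) annotated with thresholds, as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    xs = [p.fpr for p in points]
    ys = [p.tpr for p in points]
    ax.plot(xs, ys, "o-", ms=4)
    for p in points:
        if not (math.isnan(p.fpr) or math.isnan(p.tpr)):
            ax.annotate(f"{p.threshold:g}", (p.fpr, p.tpr), fontsize=7)
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
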