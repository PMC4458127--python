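"""Per-position assembly support and Z-scores from a two-component mixture.

Each insert size Y is modelled as a mixture of a normal null component
N(mu, sigma^2) (correct pairs) and a uniform anomaly component U(0, L) over
the contig length (pairs whose mates truly come from unrelated loci).  With
prior pi0 on the anomaly class, the posterior that a pair is correct is

    P(null | Y) = (1 - pi0) f_N(Y; mu, sigma^2)
                  ---------------------------------------
                  (1 - pi0) f_N(Y; mu, sigma^2) + pi0 / L

The support D_i at position i is the sum of these posteriors over all pairs
spanning [i - W, i + W], counting only correctly oriented pairs.  D is
standardised per contig by its mean mu_D and a mean-absolute-deviation
scale s_D, giving the Z-score z_i = (D_i - mu_D) / s_D; deep dips in z mark
candidate misassemblies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateModelError, SkippedContigError
from .insert_stats import GlobalInsertModel
from .pair_index import MatePairRecord, PairIntervalTree, spanning_pairs

log = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the support scan.

    window
        Half-window W (bases) around each evaluated position.
    stepsize
        Spacing (bases) between evaluated positions.
    prior_anomaly
        Prior probability pi0 that an insert is anomalous.
    minsize
        Minimum contig length (bases) to scan.
    threshold
        Z-score threshold T below which a position is flagged.
    """

    window: int = 200
    stepsize: int = 1_000
    prior_anomaly: float = 0.01
    minsize: int = 10_000
    threshold: float = -4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_anomaly < 1.0:
            raise ValueError("prior_anomaly must lie strictly in (0, 1)")
        if self.window <= 0 or self.stepsize <= 0 or self.minsize <= 0:
            raise ValueError("window, stepsize and minsize must be positive")


@dataclass
class ScoreTrack:
    """Support scores and Z-scores at stepped positions along one contig."""

    contig_name: str
    positions: np.ndarray
    support: np.ndarray
    zscores: np.ndarray
    mu_d: float
    s_d: float
    stepsize: int
    degenerate_scale: bool = field(default=False)

    def __len__(self) -> int:
        return len(self.positions)


def posterior_null(
    insert_size: float,
    model: GlobalInsertModel,
    contig_length: int,
    prior_anomaly: float = 0.01,
) -> float:
    """Posterior probability that one insert came from the null distribution.

    Evaluated in log space with a stable log-sum-exp; a normal density that
    underflows against the uniform term yields posterior 0, never NaN.
    """
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    if model.sigma_hat <= 0:
        raise DegenerateModelError(
            "sigma_hat is zero; the null insert-size model is degenerate"
        )
    if prior_anomaly <= 0.0:
        return 1.0
    z = (insert_size - model.mu_hat) / model.sigma_hat
    log_null = (
        math.log1p(-prior_anomaly)
        - _LOG_SQRT_2PI
        - math.log(model.sigma_hat)
        - 0.5 * z * z
    )
    log_anom = math.log(prior_anomaly) - math.log(contig_length)
    # posterior = exp(log_null) / (exp(log_null) + exp(log_anom))
    diff = log_anom - log_null
    if diff > 700.0:  # normal term underflows against the uniform term
        return 0.0
    return float(1.0 / (1.0 + math.exp(diff)))


def support_score(
    records: Sequence[MatePairRecord],
    model: GlobalInsertModel,
    contig_length: int,
    prior_anomaly: float = 0.01,
) -> float:
    """Total assembly support from a set of spanning pairs.

    Sum over pairs of the null posterior times the orientation indicator;
    wrongly oriented pairs contribute exactly zero.
    """
    total = 0.0
    for rec in records:
        if not rec.orientation_ok:
            continue
        total += posterior_null(rec.insert_size, model, contig_length, prior_anomaly)
    return total


def scan_positions(contig_length: int, config: ScanConfig) -> np.ndarray:
    """Evaluation grid: multiples of stepsize whose window fits the contig."""
    grid = np.arange(config.stepsize, contig_length, config.stepsize)
    return grid[(grid - config.window >= 0) & (grid + config.window < contig_length)]


def scan_contig(
    index: PairIntervalTree,
    model: GlobalInsertModel,
    config: ScanConfig | None = None,
) -> ScoreTrack:
    """Score assembly support along one contig.

    Evaluates D at positions stepsize, 2*stepsize, ... (windows fully inside
    the contig), then standardises by the contig's own support mean mu_D and
    mean-absolute-deviation scale s_D.  Contig-local standardisation keeps
    coverage differences between contigs from masking or faking anomalies.

    Raises
    ------
    SkippedContigError
        If the contig is shorter than ``config.minsize``.
    """
    config = config or ScanConfig()
    length = index.contig_length
    if length < config.minsize:
        raise SkippedContigError(
            f"contig {index.contig_name!r} ({length} bp) is shorter than "
            f"minsize ({config.minsize} bp)"
        )
    positions = scan_positions(length, config)
    support = np.array(
        [
            support_score(
                spanning_pairs(index, int(i), config.window),
                model,
                length,
                config.prior_anomaly,
            )
            for i in positions
        ],
        dtype=float,
    )
    if support.size == 0:
        return ScoreTrack(
            index.contig_name, positions, support, support.copy(), 0.0, 0.0,
            config.stepsize, degenerate_scale=True,
        )
    mu_d = float(support.mean())
    s_d = float(np.abs(support - mu_d).mean())
    if s_d > 0:
        zscores = (support - mu_d) / s_d
        degenerate = False
    else:
        zscores = np.zeros_like(support)
        degenerate = True
        log.warning(
            "contig %s: all support values identical (s_D = 0); "
            "Z-scores defined as 0", index.contig_name,
        )
    return ScoreTrack(
        contig_name=index.contig_name,
        positions=positions,
        support=support,
        zscores=zscores,
        mu_d=mu_d,
        s_d=s_d,
        stepsize=config.stepsize,
        degenerate_scale=degenerate,
    )


def write_scores_csv(tracks: Sequence[ScoreTrack], path: str) -> None:
    """Write per-position scores as CSV: contig, position (0-based), D, zscore."""
    import pandas as pd

    frames = [
        pd.DataFrame(
            {
                "contig": t.contig_name,
                "position": t.positions.astype(int),
                "D": t.support,
                "zscore": t.zscores,
            }
        )
        for t in tracks
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["contig", "position", "D", "zscore"])
    )
    out.to_csv(path, index=False)


def read_scores_csv(path: str) -> list[ScoreTrack]:
    """Rebuild ScoreTracks from a scores CSV written by write_scores_csv."""
    import pandas as pd

    df = pd.read_csv(path)
    tracks = []
    for contig, grp in df.groupby("contig", sort=False):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy(dtype=int)
        support = grp["D"].to_numpy(dtype=float)
        z = grp["zscore"].to_numpy(dtype=float)
        mu_d = float(support.mean()) if support.size else 0.0
        s_d = float(np.abs(support - mu_d).mean()) if support.size else 0.0
        step = int(np.diff(positions).min()) if positions.size > 1 else 1_000
        tracks.append(
            ScoreTrack(str(contig), positions, support, z, mu_d, s_d, step,
                       degenerate_scale=s_d == 0)
        )
    return tracks


def plot_track(track: ScoreTrack, threshold: float, path: str) -> None:
    """Plot position vs. Z-score with the calling threshold, as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(track.positions, track.zscores, lw=0.8, color="tab:blue")
    ax.axhline(threshold, color="tab:red", ls="--", lw=0.8, label=f"T = {threshold}")
    ax.set_xlabel(f"position on {track.contig_name} (bp)")
    ax.set_ylabel("Z-score")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
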