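"""Synthetic assemblies, engineered misassemblies and mate-pair libraries.

The generator emulates a long-insert (Nextera-style) mate-pair library:
insert sizes are approximately normal (mean a few kb, sd a few hundred bp)
with a small anomalous fraction of effectively uniform inserts, and a
configurable expected pair orientation.  Misassemblies are engineered as
junctions joining unrelated sequence, with machine-readable truth
coordinates, so detection can be validated without any external data.

Pairs are conceptually placed on the *true* source sequences.  A pair whose
fragment crosses an engineered junction has its two reads originating from
unrelated loci; an aligner would place the stray mate wherever its true
sequence happens to sit, so the simulator re-draws that mate's mapped
position uniformly on the contig.  Junction-spanning pairs therefore show
effectively uniform observed inserts (and arbitrary orientation), which is
exactly the anomaly class the mixture model targets.

Reads carry no base-calling errors: the detector only inspects coordinates,
flags and mapping quality, never base calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import UnsimulatableError

_BASES = np.frombuffer(b"ACGT", dtype="S1")

ERROR_CLASSES = ("junction", "large-insertion", "large-deletion")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic library.

    spanning_coverage is the expected number of pairs whose two reads lie
    strictly on opposite sides of a typical interior position (the quantity
    the support score counts at window 0).
    """

    contig_lengths: tuple[int, ...] = (200_000,)
    insert_mean: float = 3_000.0
    insert_sd: float = 300.0
    anomaly_fraction: float = 0.01
    read_length: int = 150
    spanning_coverage: float = 30.0
    orientation_layout: str = "fr"
    orientation_error_rate: float = 0.01
    maxinsert: int = 30_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insert_sd <= 0:
            raise ValueError("insert_sd must be positive")
        if not 0.0 <= self.anomaly_fraction < 1.0:
            raise ValueError("anomaly_fraction must lie in [0, 1)")
        if self.read_length < 30:
            raise ValueError("read_length must be at least 30")


@dataclass(frozen=True)
class TruthEntry:
    """One engineered misassembly with its true coordinate."""

    contig: str
    position: int
    error_class: str
    source_a: tuple[int, int] | None = None
    source_b: tuple[int, int] | None = None


@dataclass
class TruthSet:
    """Known misassembly coordinates per contig, plus contig lengths."""

    entries: list[TruthEntry] = field(default_factory=list)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def positions_for(self, contig: str) -> list[int]:
        return [e.position for e in self.entries if e.contig == contig]


@dataclass(frozen=True)
class SimulatedRead:
    """One aligned mate: placement and strand on the assembled contig."""

    contig: str
    pos: int
    is_reverse: bool


@dataclass(frozen=True)
class SimulatedPair:
    """A simulated mate pair mapped onto the assembly."""

    name: str
    left: SimulatedRead
    right: SimulatedRead
    anomalous_background: bool
    crosses_junction: bool


def make_clean_contig(length: int, seed: int | np.random.Generator) -> str:
    """An i.i.d. uniform ACGT sequence, deterministic given the seed."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def make_misassembled_contig(
    source_a: str,
    source_b: str,
    junction_at: int,
    contig_name: str = "misassembled",
) -> tuple[str, TruthEntry]:
    """Join a prefix of one sequence to another, recording the junction.

    The product is ``source_a[:junction_at] + source_b``: everything left of
    the junction derives from A, everything right of it from B.  Pairs later
    simulated across the junction have mates from unrelated loci, so their
    observed inserts are anomalous.
    """
    if junction_at < 0 or junction_at > len(source_a):
        raise ValueError("junction_at must lie within source_a")
    seq = source_a[:junction_at] + source_b
    entry = TruthEntry(
        contig=contig_name,
        position=junction_at,
        error_class="junction",
        source_a=(0, junction_at),
        source_b=(junction_at, len(seq)),
    )
    return seq, entry


def _draw_normal_insert(
    rng: np.random.Generator, config: SimConfig, contig_length: int
) -> int:
    """Null insert: N(mean, sd^2) truncated to +-6 sd and to the contig."""
    lo = max(2 * config.read_length + 2, config.insert_mean - 6 * config.insert_sd)
    hi = min(contig_length, config.insert_mean + 6 * config.insert_sd)
    while True:
        y = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        if lo <= y <= hi:
            return y


def simulate_pairs(
    contigs: Mapping[str, str],
    truth: TruthSet,
    config: SimConfig,
) -> tuple[list[SimulatedPair], dict]:
    """Simulate the mate-pair library over an assembly with known truth.

    Returns the mapped pairs plus a summary with pair counts and the
    per-contig expected spanning coverage.

    Raises
    ------
    UnsimulatableError
        If a contig is shorter than insert_mean + 4 * insert_sd.
    """
    # decorrelated from the sequence-drawing stream that uses the bare seed
    rng = np.random.default_rng([1, config.seed])
    rl = config.read_length
    pairs: list[SimulatedPair] = []
    summary: dict = {
        "n_pairs": 0,
        "n_anomalous_background": 0,
        "n_junction_crossing": 0,
        "per_contig": {},
    }
    span_per_pair = max(config.insert_mean - 2 * rl, 1.0)
    for name, seq in contigs.items():
        length = len(seq)
        if length < config.insert_mean + 4 * config.insert_sd:
            raise UnsimulatableError(
                f"contig {name!r} ({length} bp) is too short for inserts of "
                f"mean {config.insert_mean} sd {config.insert_sd}"
            )
        junctions = truth.positions_for(name)
        n_pairs = int(round(config.spanning_coverage * length / span_per_pair))
        for k in range(n_pairs):
            anomalous = bool(rng.random() < config.anomaly_fraction)
            if anomalous:
                y = int(rng.uniform(2 * rl + 2, min(config.maxinsert, length)))
            else:
                y = _draw_normal_insert(rng, config, length)
            s = int(rng.integers(0, length - y + 1))
            left_pos, right_pos = s, s + y - rl
            crossing = any(s < j < s + y for j in junctions)
            if crossing:
                # stray mate: its true locus is unrelated sequence, so its
                # mapped position on this contig is effectively uniform
                right_pos = int(rng.integers(0, length - rl + 1))
                if right_pos < left_pos:
                    left_pos, right_pos = right_pos, left_pos
                right_rev = bool(rng.random() < 0.5)
                left_rev = not right_rev if rng.random() < 0.5 else right_rev
            else:
                if config.orientation_layout == "fr":
                    left_rev, right_rev = False, True
                else:
                    left_rev, right_rev = True, False
                if rng.random() < config.orientation_error_rate:
                    if rng.random() < 0.5:
                        left_rev = not left_rev
                    else:
                        right_rev = not right_rev
            pairs.append(
                SimulatedPair(
                    name=f"{name}:pair{k}",
                    left=SimulatedRead(name, left_pos, left_rev),
                    right=SimulatedRead(name, right_pos, right_rev),
                    anomalous_background=anomalous,
                    crosses_junction=crossing,
                )
            )
        summary["per_contig"][name] = {
            "n_pairs": n_pairs,
            "expected_spanning_coverage": config.spanning_coverage,
        }
        summary["n_pairs"] += n_pairs
    summary["n_anomalous_background"] = sum(p.anomalous_background for p in pairs)
    summary["n_junction_crossing"] = sum(p.crosses_junction for p in pairs)
    return pairs, summary


def write_sam(
    pairs: Sequence[SimulatedPair],
    contigs: Mapping[str, str],
    path: str,
    read_length: int = 150,
) -> None:
    """Emit the library as coordinate-sorted SAM text.

    Full-length match CIGARs, mapq 60, reciprocal mate fields and
    sign-consistent template lengths; read bases are the reference substring
    (the simulation adds no sequencing errors).
    """
    rl = read_length
    order = {name: k for k, name in enumerate(contigs)}
    rows: list[tuple[int, int, str]] = []
    for p in pairs:
        seq = contigs[p.left.contig]
        span_start = min(p.left.pos, p.right.pos)
        span_end = max(p.left.pos, p.right.pos) + rl
        tlen = span_end - span_start
        for mate, other, first in ((p.left, p.right, True), (p.right, p.left, False)):
            flag = 0x1 | (0x40 if first else 0x80)
            if mate.is_reverse:
                flag |= 0x10
            if other.is_reverse:
                flag |= 0x20
            signed_tlen = tlen if mate.pos <= other.pos else -tlen
            if mate.pos == other.pos and not first:
                signed_tlen = -tlen
            bases = seq[mate.pos : mate.pos + rl]
            rows.append(
                (
                    order[mate.contig],
                    mate.pos,
                    "\t".join(
                        [
                            p.name,
                            str(flag),
                            mate.contig,
                            str(mate.pos + 1),
                            "60",
                            f"{rl}M",
                            "=",
                            str(other.pos + 1),
                            str(signed_tlen),
                            bases,
                            "I" * len(bases),
                        ]
                    ),
                )
            )
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, seq in contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for _, _, line in rows:
            fh.write(line + "\n")


def write_truth_csv(truth: TruthSet, path: str) -> None:
    """Truth table: contig, contig_length, position, error_class."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "contig": e.contig,
                "contig_length": truth.contig_lengths.get(e.contig, -1),
                "position": e.position,
                "error_class": e.error_class,
            }
            for e in truth.entries
        ],
        columns=["contig", "contig_length", "position", "error_class"],
    ).to_csv(path, index=False)
    # contigs with no engineered errors still need their lengths on record
    extra = [
        {"contig": c, "contig_length": l, "position": -1, "error_class": "none"}
        for c, l in truth.contig_lengths.items()
        if not any(e.contig == c for e in truth.entries)
    ]
    if extra:
        pd.concat(
            [pd.read_csv(path), pd.DataFrame(extra)], ignore_index=True
        ).to_csv(path, index=False)


def read_truth_csv(path: str) -> TruthSet:
    """Load a truth table written by :func:`write_truth_csv`."""
    import pandas as pd

    df = pd.read_csv(path)
    truth = TruthSet()
    for _, row in df.iterrows():
        contig = str(row["contig"])
        truth.contig_lengths[contig] = int(row["contig_length"])
        if int(row["position"]) >= 0 and str(row["error_class"]) != "none":
            truth.entries.append(
                TruthEntry(
                    contig=contig,
                    position=int(row["position"]),
                    error_class=str(row["error_class"]),
                )
            )
    return truth


def simulate_assembly(
    config: SimConfig,
    junction_at: int | None = None,
) -> tuple[dict[str, str], TruthSet, dict[str, tuple[str, str]]]:
    """Build an assembly per the config, optionally with one junction error.

    The first contig becomes a junction contig when ``junction_at`` is
    given: a prefix of one clean source joined to a second, independently
    drawn source.  Returns (contigs, truth, sources) where ``sources`` maps
    a misassembled contig to its two true source sequences.
    """
    rng = np.random.default_rng(config.seed)
    contigs: dict[str, str] = {}
    truth = TruthSet()
    sources: dict[str, tuple[str, str]] = {}
    for k, length in enumerate(config.contig_lengths):
        name = f"contig_{k}"
        if k == 0 and junction_at is not None:
            if not 0 < junction_at < length:
                raise ValueError("junction_at must be inside the first contig")
            src_a = make_clean_contig(junction_at, rng)
            src_b = make_clean_contig(length - junction_at, rng)
            seq, entry = make_misassembled_contig(src_a, src_b, junction_at, name)
            contigs[name] = seq
            truth.entries.append(entry)
            sources[name] = (src_a, src_b)
        else:
            contigs[name] = make_clean_contig(length, rng)
        truth.contig_lengths[name] = len(contigs[name])
    return contigs, truth, sources
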