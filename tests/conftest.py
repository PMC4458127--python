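"""Shared fixtures: tiny hand-built alignments and simulated datasets.

All fixtures are generated programmatically; SAM text is converted to
indexed BAM in a temporary directory at test time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pysam
import pytest

from matemend.simulate import (
    SimConfig,
    TruthSet,
    simulate_assembly,
    simulate_pairs,
    write_sam,
)


def sam_to_bam(sam_path: str, bam_path: str) -> str:
    """Convert coordinate-sorted SAM text to an indexed BAM."""
    pysam.view("-b", "-o", bam_path, sam_path, catch_stdout=False)
    pysam.index(bam_path)
    return bam_path


def pair_lines(
    qname: str,
    contig: str,
    pos1: int,
    pos2: int,
    read_length: int = 150,
    mapq: int = 60,
    mapq2: int | None = None,
    rev1: bool = False,
    rev2: bool = True,
    contig2: str | None = None,
    seq_char: str = "A",
) -> list[tuple[str, int, str]]:
    """Two SAM lines for one mate pair, as (contig, pos, line) for sorting."""
    contig2 = contig2 or contig
    mapq2 = mapq if mapq2 is None else mapq2
    tlen = (max(pos1, pos2) + read_length - min(pos1, pos2)) if contig == contig2 else 0
    lines = []
    for first, (c, p, rev, mq), (oc, op, orev) in (
        (True, (contig, pos1, rev1, mapq), (contig2, pos2, rev2)),
        (False, (contig2, pos2, rev2, mapq2), (contig, pos1, rev1)),
    ):
        flag = 0x1 | (0x40 if first else 0x80)
        if rev:
            flag |= 0x10
        if orev:
            flag |= 0x20
        if contig == contig2:
            st = tlen if (p < op or (p == op and first)) else -tlen
        else:
            st = 0
        rnext = "=" if oc == c else oc
        lines.append(
            (
                c,
                p,
                "\t".join(
                    [
                        qname, str(flag), c, str(p + 1), str(mq),
                        f"{read_length}M", rnext, str(op + 1), str(st),
                        seq_char * read_length, "I" * read_length,
                    ]
                ),
            )
        )
    return lines


def write_tiny_bam(
    directory: str,
    contig_lengths: dict[str, int],
    lines: list[tuple[str, int, str]],
    name: str = "tiny",
) -> str:
    """Assemble SAM text from pair_lines output and convert to indexed BAM."""
    order = {c: i for i, c in enumerate(contig_lengths)}
    sam_path = os.path.join(directory, f"{name}.sam")
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for c, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{c}\tLN:{length}\n")
        for _, _, line in sorted(lines, key=lambda r: (order[r[0]], r[1], r[2])):
            fh.write(line + "\n")
    return sam_to_bam(sam_path, os.path.join(directory, f"{name}.bam"))


@dataclass
class SimBundle:
    """One simulated dataset on disk plus its in-memory truth."""

    config: SimConfig
    contigs: dict[str, str]
    truth: TruthSet
    sources: dict[str, tuple[str, str]]
    bam: str
    sam: str
    summary: dict


def build_bundle(
    directory: str,
    seed: int,
    junction_at: int | None,
    contig_lengths: tuple[int, ...] = (200_000,),
    **overrides,
) -> SimBundle:
    os.makedirs(directory, exist_ok=True)
    config = SimConfig(
        contig_lengths=contig_lengths, seed=seed, **overrides
    )
    contigs, truth, sources = simulate_assembly(config, junction_at=junction_at)
    pairs, summary = simulate_pairs(contigs, truth, config)
    sam = os.path.join(directory, f"sim_{seed}.sam")
    write_sam(pairs, contigs, sam, read_length=config.read_length)
    bam = sam_to_bam(sam, os.path.join(directory, f"sim_{seed}.bam"))
    return SimBundle(config, contigs, truth, sources, bam, sam, summary)


@pytest.fixture(scope="session")
def junction_bundle(tmp_path_factory) -> SimBundle:
    """A 200 kb contig with one engineered junction at 100 kb, 30x spanning."""
    d = tmp_path_factory.mktemp("junction")
    return build_bundle(str(d), seed=0, junction_at=100_000)


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory) -> SimBundle:
    """A clean 200 kb contig with no engineered errors."""
    d = tmp_path_factory.mktemp("clean")
    return build_bundle(str(d), seed=0, junction_at=None)
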