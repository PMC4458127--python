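# Methods

## Model

A mate-pair library prepared to a target insert size gives, after alignment
back to the draft assembly, an insert-size observation `Y_l` and an
orientation for every pair `l`. Correctly assembled pairs are modelled as
`Y ~ N(μ̂, σ̂²)`; pairs whose mates truly derive from unrelated loci (the
signature of a junction misassembly, a large indel, or a chimeric pair) as
`Y ~ U(0, L)`, uniform over the contig length `L`. The uniform component
deliberately assumes nothing about the cause of the anomaly; it is bounded
by `L` because only pairs with both mates on the contig are considered.
With a user prior `π₀` on the anomaly class, the posterior that pair `l`
is correct is

    P(X_l = 1 | Y_l) = (1−π₀) f_N(Y_l; μ̂, σ̂²)
                       / [ (1−π₀) f_N(Y_l; μ̂, σ̂²) + π₀ / L ].

Per-position support is `D_i = Σ_l P(X_l = 1 | Y_l) · C_l` over pairs
spanning `[i−W, i+W]`, with `C_l = 1` iff the pair has the expected strand
layout. `D` is standardised within each contig: `μ_D` is the mean of all
evaluated `D` values and `s_D` their mean absolute deviation about `μ_D`;
`z_i = (D_i − μ_D)/s_D`. Contig-local standardisation keeps coverage
differences between contigs from either masking errors or causing false
positives. A position is flagged when `z_i < T`.

`s_D` is a mean-absolute-deviation scale parameter, not a variance: the
defining sum is `Σ √((D_l − μ_D)²) / N`, i.e. the average absolute
residual with divisor `N`. The Z-scores are therefore standardised by an
L1 scale; the default threshold is calibrated to that convention.

Two further rules shape calls. End exclusion: flagged positions within the
trimming distance of a contig end are discarded — ends naturally lose
spanning pairs (mates fall off the contig; circular molecules such as
plasmids wrap around), so dips there are artefacts. Merging: surviving
flags separated by less than the trimming distance are single-linkage
chained into one call, preventing excessive fragmentation. Each call's
region ± trim is excised and the contig broken; with trim = 0 the contig
is still broken at the call boundaries, and both the end-exclusion window
and the merge adjacency fall back to one scan step.

## Estimation of the null parameters

Pairs enter the global estimate only if both mates map to the same contig
with the expected orientation, the outer insert is ≤ `maxinsert`, and both
mates have mapping quality ≥ `minmapq` (pair-level exclusion — requiring
both mates is the conservative reading). The insert size is the outer
distance: leftmost aligned base of the leftmost mate to rightmost aligned
base of the rightmost mate, computed from aligned coordinates (CIGAR
reference spans), so clipping cannot distort it. `μ̂` is the plain
arithmetic mean; the scale is `σ̂ = 1.4826 · MAD`, the normal-consistent
MAD estimate, robust to the heavy right tail of real libraries (the tests
show 1% uniform contamination moves `σ̂` by ~2% while the naive SD is off
by ~400%). Each pair contributes one value. A degenerate model
(`σ̂ = 0`) aborts the scan with a diagnostic rather than producing
undefined posteriors.

When building the per-contig interval tree, mapping quality is *not*
filtered: a local excess of poorly mapping or wrongly oriented pairs is
itself evidence of misassembly and must stay visible to the score.

## Parameters

| name | default | unit | meaning |
|---|---|---|---|
| `maxinsert` | 30,000 | bp | max insert included in global statistics (~10× the target insert) |
| `minmapq` | 40 | — | min mapping quality for global statistics, both mates |
| `minsize` | 10,000 | bp | contigs shorter than this are not scanned |
| `prior` (`π₀`) | 0.01 | — | prior probability an insert is anomalous |
| `stepsize` | 1,000 | bp | spacing of evaluated positions |
| `trim` | 4,000 | bp | bases removed each side of a call; also the merge/end-exclusion distance |
| `T` | −4.0 | — | Z-score threshold for flagging |
| `window` (`W`) | 200 | bp | half-window a spanning pair must clear |
| layout | `fr` | — | expected orientation (forward–reverse); `rf` for raw outward-facing libraries |

## Numerical and convention choices

- "Spanning" is strict: the left read's last aligned base lies strictly
  before `i − W` and the right read's first aligned base strictly after
  `i + W` (the region interior has size `2W − 1`). The interval tree is
  stab-queried on the pair's outer span, then per-read extents apply the
  strict check.
- Coordinates are 0-based half-open internally; score CSVs report 0-based
  positions; SAM output is 1-based as the format requires.
- The posterior is evaluated in log space; if the normal log-density
  underflows against the uniform term the posterior is exactly 0, never
  NaN.
- The evaluation grid starts at `stepsize` and keeps only positions whose
  window fits inside the contig. If every `D` on a contig is identical
  (`s_D = 0`), all Z-scores are defined as 0 and a degenerate-scale
  warning is logged.
- Even-length medians are the mean of the two central order statistics.
- Excision intervals are clamped to `[0, L]`, merged when they touch, and
  empty fragments dropped; fragment names append `_0`, `_1`, … left to
  right. Duplicate pairs (identical coordinates) are retained.

## Simulator

`simulate` draws i.i.d. uniform ACGT contigs and engineers junction
misassemblies by concatenating a prefix of one independently drawn
sequence with a second. The library model: insert sizes
`N(3000, 300²)` truncated at ±6 sd (defaults; matching a typical
3–4 kb mate-pair prep), an anomalous background fraction (default 1%)
with `U(2·read_length, maxinsert)` inserts, orientation errors at 1%, and
`spanning_coverage` (default 30×) pairs whose reads flank a typical
position. A pair whose fragment crosses a junction has mates from
unrelated loci; the simulator re-draws that mate's mapped position
uniformly on the contig, so junction-spanning pairs acquire effectively
uniform observed inserts — the anomaly class the mixture targets. Output
is coordinate-sorted SAM (full-length-match CIGARs, mapq 60, reciprocal
mate fields), a FASTA assembly and a CSV truth table; BAM conversion is
left to samtools/pysam.

What the simulator does not emulate: sequencing errors and base-quality
profiles (the method never reads base calls), chimeric junction-adapter
reads, repeat-induced multi-mapping, GC-coverage bias, and real
heavy-tailed insert distributions. Passing tests therefore demonstrate the
statistical machinery under the stated library model, not performance on
adversarial real data, where repeats and coverage structure add false
signals.

## Evaluation

Calls are binned at 1 kb (the scan step, so evaluation resolution matches
detection resolution); a bin is positive if a call region intersects it
and truth-positive if an engineered misassembly coordinate falls in it.
TPR = TP/(TP+FN) and FPR = FP/(FP+TN) are computed with bins pooled across
contigs for each threshold in a sweep (default −10…0 in steps of 1); the
full calling pipeline, including end exclusion and merging, is re-run per
threshold. Zero denominators yield NaN rather than an error.

## Problem sizes

Tests and the acceptance script use 200 kb contigs at 30× spanning
coverage (~2,200 pairs per contig) with junctions at known coordinates —
large enough that a contig holds ~200 evaluated positions and the
contig-local statistics are stable, while a full pipeline run takes well
under a second. Detection margins at this size are comfortable: the
junction Z minimum sits near −5 to −6 against a −4 threshold across
seeds.

## Known limitations

- Sensitivity falls on contigs near `minsize`, where few positions feed
  `μ_D` and `s_D`.
- `π₀` is user-set, not co-estimated from the library; a library with a
  much higher chimera rate needs a larger prior.
- A single fixed threshold on `D` ignores the information in *which*
  inserts are anomalous; a fully probabilistic per-region test would be
  more sensitive.
- Errors within `trim` of contig ends are undetectable by design (the
  price of protecting circular molecules and edge artefacts).
- Misassemblies closer than ~`insert_mean` to each other merge into one
  call at this resolution.
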