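# Methods

## The recovery problem and its assumptions

The pipeline targets one regime: a tissue whose antibody repertoire is
dominated by a single expanded B-cell clone, sequenced from degraded
(FFPE) RNA as (i) constant-region-primed amplicons that cross the
V(D)J junction and (ii) short whole-transcriptome fragments. Under
near-monoclonality the rank-1 heavy and rank-1 light clonotype can be
paired without single-cell information; that assumption is explicit
and the clonality profile is the evidence for it. Reconstruction
further assumes the junction is unique enough in the read pool to act
as a seed, and that errors are substitution-dominated (Illumina-like
chemistry; FFPE deamination is also a substitution artifact).

## Alignment core

All germline comparisons go through one affine-gap local aligner
(match +2, mismatch −2, a gap of length *k* costs 4 + *k*). Every
tie is resolved by a stated rule: within a cell, diagonal over
gap-in-target over gap-in-query; the optimal cell is the smallest
(query index, target index) among score maxima; among alleles, score,
then identity, then lexicographic allele id, then '+' strand.
Identity is matches / alignment columns of that deterministic
traceback. This pedantry is load-bearing: the 80% VDJ filter's
accept/reject decision is required to be an exact function of the DP,
and the tests verify it read-by-read against an independently written
brute-force DP with the same conventions.

A k-mer prescreen (k = 12, top 4 candidate allele/strand pairs by
shared-k-mer count) accelerates per-read allele search in the Ig-seq
path; the VDJ filter defaults to the exact all-allele scan so its
decisions carry no prescreen dependence (`prescreen=True` is available
for large pools). A best alignment scoring below 40 is reported as no
hit: random 150-nt sequences essentially never reach that score, while
any genuine 30-nt segment context does (≥30 aligned nt at ≥85%
identity scores ≥ 42).

## Junction calling

Junctions are never taken from read coordinates: germline anchor
positions (V: the 2nd conserved Cys codon; J: the conserved Trp/Phe)
are projected through the alignment path onto the read, extrapolating
ungapped beyond alignment ends, and the extracted junction must still
translate to C…W (heavy) or C…F (light). Reads failing this are
tallied by reason (`no_v_hit`, `no_j_hit`, `low_v_identity`,
`vj_incoherent`, `anchor_uncovered`, `anchor_lost`); the tallies plus
accepted reads always sum to the input count. The translation frame
comes from the V anchor, never from the read start — primers and the
template-switch tail make read frames arbitrary.

Ig-seq acceptance requires V identity ≥ 0.85 over ≥ 30 aligned nt;
this is deliberately distinct from the transcriptome-side 0.80 filter,
which is part of the reconstruction procedure itself. Out-of-frame or
stop-containing junctions are kept in the table, flagged
non-productive, and excluded from frequency normalization — a
non-productive chain cannot be the secreted antibody being recovered.

Error correction collapses a clonotype into a same-locus/V/J/length
clonotype at least `ratio_threshold` (default 20) times more abundant
within `max_mismatches` (default 2) junction substitutions, children
in ascending count order, iterated to a fixed point. The mismatch
budget of 2 follows from the error model: at 0.5%/base a ~45-nt
junction carries two errors in ~2% of reads, and those doubles are
unambiguous satellites of a 20×-more-abundant parent.

## Clonality layers

The profile is a pure function of the clonotype table: inner layer =
frequency mass of clonotypes observed 1×, 2×, ≥3×; quantile layer =
clonotypes ranked by abundance and partitioned into five equal-size
rank bins (remainders go to the earlier bins, so bin masses are
monotone non-increasing); outer layer = the top-5 clonotypes
individually. Rank ties break lexicographically on the junction so
profiles are permutation-invariant. Both the per-locus (IGK, IGL) and
a merged light-chain view are available. The donut SVG is a thin
reporting layer; the numeric profile is the contract.

## Seed-and-extend reconstruction

Pool: reads whose best local V/J alignment reaches identity ≥ 0.80
over ≥ 30 aligned nt, strand-normalized to coding. ("80% alignment"
is read as alignment identity; the alternative reading — ≥ 80% of the
read aligned — is available as `filter_mode="read_fraction"`.)

Seeds: pool reads containing the target junction (exact by default),
each verified to carry the anchor Cys and, where present, the
conserved upstream Tyr codons in frame; sorted exact-first, then
longest 5' flank. The seed read becomes the initial contig.

Extension (5' then a bounded 3' pass): at each step all pool reads
whose terminal overlap with the contig is ≥ 20 nt at ≥ 0.95 Hamming
identity vote on the single leading column, one vote per read. Stops,
in order of evaluation: the projected germline segment start
(`v_start_reached`, overshoot trimmed), vote coverage below 2
(`no_overlap`), a tie or runner-up support ≥ 0.8× the winner
(`ambiguous_branch`), or 10,000 columns (`max_iterations`). The
boundary projection is checked every 20 columns and at termination; it
only fires when a segment alignment of identity ≥ 0.85 over ≥ 40 nt
*itself reaches the segment's first bases* (start offset ≤ 3) —
extrapolating a boundary from a distant or weak alignment once
truncated contigs through spurious constant-region hits, so observed
starts are required. The 3' pass is capped 60 nt into the constant
region (enough to call isotype; assembling the constant domain is not
the goal) and records `c_cap_reached` in its own field.

A final polish re-maps every pool read to the contig (edit-distance
placement, identity ≥ 0.90) and takes a column majority, yielding
per-position coverage and agreement; positions no read covers keep the
contig base with coverage 1. Overlap detection uses Hamming identity
because the simulator's error model (and the targeted chemistry) is
substitution-dominated; indel-bearing data would need the gapped
aligner in the overlap step.

## Maturation annotation

V is assigned over the contig 5' of the junction, J over the rest;
fewer than 60 nt of V context is an error (`insufficient_v_context`).
CDR1/CDR2 boundaries are projected from per-allele germline intervals
supplied in a scheme table shipped with the reference — projection
through the alignment, not a full IMGT gap-insertion engine, which
this logic does not require; CDR3 is the junction minus its anchor
codons. SHM calls compare contig to germline position-wise over V and
J with the junction excluded; a difference counts only where the
assembler supports the position (agreement ≥ 0.7, coverage ≥ 2),
otherwise it is "uncallable" — this is what separates sequencing noise
from mutation. Nucleotide differences are grouped per codon and split
into amino-acid-changing records and silent changes, so
`shm_count_aa ≤ shm_count_nt` by construction. Isotype is the best
constant allele over the contig tail (identity ≥ 0.80 over the leading
60 nt), falling back to a majority vote of junction-carrying pool
reads with a reported support fraction, else `unknown`.

## The synthetic-data generator

The generator emulates the study conditions, not generic RNA-seq:

| parameter | default | meaning |
|---|---|---|
| `dominance` | 0.6 | frequency of the rank-1 clone per chain |
| `n_clones` | 51 | dominant + 50 background |
| `power_exponent` | 1.0 | background clone sizes ∝ rank⁻¹ |
| `dominant_shm` | 15 | nonsilent SHMs planted in the dominant clone |
| `shm_rate` | 0.02 /nt | background SHM over V+J (junction excluded) |
| fragment lengths | log-normal, median 200 nt, σ_log 0.6, 40–500 | DV200 ≈ 50% regime |
| `damage_rate` | 0.002 /C | residual C→T deamination (sense strand) |
| `error_rate` | 0.005 /nt | i.i.d. substitution sequencing error |
| `read_len` | 150 | paired-end |

Toy germline references carry planted anchors (…TAT-TAC-TGT ends every
V; J = 12-nt tail + TGG-G… or TTC-GGC-x-GGC…), a 45-nt leader before
FR1, per-allele CDR1/CDR2 intervals, and constant regions embedding
the real constant-region primer sequences of the amplicon chemistry
(e.g. kappa `CACACAACAGAGGCAG`), so amplicon geometry — template-switch
tail, 5' UTR, junction within reach of the downstream mate — is
realistic. Transcripts carry a 60-nt UTR upstream of the V segment so
fragment coverage does not vanish exactly at the V start.

SHM placement spares the anchor codons, the two Tyr codons before the
V anchor and the WG/FGxG codons after the J anchor: these positions
are structurally constrained in real repertoires, and the seed search
leans on them. Exact-k planting puts k single-nucleotide,
amino-acid-changing mutations at distinct mature-V codons (never
creating stops), which is what makes the maturation round-trip an
exact test.

What the generator does **not** model — and hence what passing tests
do not show about real data: PCR chimeras and amplification bias,
indels, quality-score structure (qualities are constant and unused),
UMIs (the chemistry has none), allelic variation beyond the supplied
reference, and multiple co-dominant clones sharing a junction (branch
detection is tested, haplotype phasing is out of scope).

## Numerical and design choices

- Coordinates are 0-based half-open everywhere internally; 1-based
  codon indices appear only in human-readable SHM reports.
- D segments are not modeled as separate references; the junction
  absorbs D-derived nucleotides. The procedure keys on junction
  identity, and D-gene calls would add nothing to it.
- A chain-level repertoire is simulated per locus; the paired study
  scenario builds an IGH and an IGK repertoire whose rank-1 clones are
  the implied antibody. Chain pairing is by rank, justified only under
  near-monoclonality.
- All randomness descends from one top-level seed through named child
  streams, so every stage is individually re-runnable and all
  artifacts are byte-reproducible; artifacts embed the hash of the
  configuration (paths excluded) that produced them.
- Tissue-block identity is a sample label only; profiles and the
  cross-sample matrix make no assumption about which block is
  monoclonal.
- Problem sizes in the tests and the acceptance script — 20,000 Ig-seq
  reads, 20× noiseless / 30× noisy fragment coverage, 20 reconstruction
  seeds, 200 random clonality tables, 500 threshold-straddling filter
  reads — were chosen so each statistical check has the power it needs
  (e.g. a 99% binomial interval of half-width ~0.013 on the dominant
  frequency) at roughly a minute of total runtime.

## Known limitations

Greedy single-path extension cannot phase two clones that share a
junction but differ upstream at comparable abundance — it stops with
`ambiguous_branch`, by design. The 0.80/identity reading of the VDJ
filter and all MiGEC-style correction parameters are configurable
because the upstream tools' exact settings are not part of this
package's contract. Allele assignment is only ever relative to the
reference the user supplies; no allele inference is attempted.
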