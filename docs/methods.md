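# Methods

## Model and assumptions

`trfspace` deduces which short-RNA-seq reads can be *guaranteed* to derive
from mature tRNAs, and profiles them by source region. The central object is
the **tRNA space**: the genomic intervals of the nuclear tRNA genes, the
mitochondrial tRNA genes, and nuclear intervals that are exactly identical
copies of mitochondrial tRNAs. Exactly identical lookalikes are full members
(a read matching both the mitochondrial gene and its identical nuclear copy is
still unambiguously a tRNA read); *non-identical* lookalikes and partial tRNA
copies are deliberately not members — reads touching them are handled by the
exclusivity rule below, which discards anything that could have a non-tRNA
origin.

The method assumes reads are adapter-trimmed and quality-filtered upstream,
and that sequencing errors and modification-induced misincorporations make
mismatch-tolerant mapping unsafe for tRNAs: near-identical isodecoders of the
same or different anticodons become indistinguishable if even one replacement
is allowed. The contract is therefore **exact matching only**; reads carrying
a substitution are dropped rather than rescued. This understates true
abundance but never misassigns provenance.

### Mature sequences and the CCA genome

A mature tRNA is the genomic locus sequence, reverse-complemented for
minus-strand loci, with introns removed and `CCA` appended; its templated
length L excludes the CCA, which occupies mature positions L+1..L+3. Because
the CCA is nontemplated, occurrence analysis runs against a **modified
genome** in which the three bases immediately downstream of each locus (on
the transcribed strand) read `CCA`; those three positions are also part of
the locus's tRNA-space interval, so a CCA-ending read covering them remains
attributable to the tRNA. When two loci are so close that their substitution
windows overlap, substitutions are applied in locus-sorted order (later
writes win) and a warning is emitted.

### Exclusivity

Candidate fragments are all substrings of every mature sequence with length
in [16, 50]. For each distinct sequence, every exact occurrence in the
modified genome is located on both strands (an opposite-strand occurrence
outside tRNA space also disqualifies a fragment, since transcription of
either strand could produce the read). A fragment is **exclusive** iff all
occurrences lie fully inside tRNA-space intervals. A sequence with zero
genomic occurrences is exclusive iff it straddles an exon–exon junction of an
intron-bearing tRNA — it exists only in the spliced molecule; a
junction-spanning sequence that also happens to occur somewhere in the genome
is subjected to the ordinary test. Sequences with more than 10,000
occurrences (the multi-mapping cap) are dropped and logged.

Identical sequences arising from several matures merge into one record. Its
provenance counts are: `nA`, distinct anticodon names among the loci
containing the sequence; `nP`, how many of those loci are pseudo-tRNAs; `nL`,
the total count of containing loci. One **source-proxy** placement names the
record: placements are ordered by natural chromosome order (1..22, X, Y, then
the mitochondrial chromosome, then others), then start, strand, locus id and
mature start, and the first is taken — an arbitrary but reproducible choice.

### Region taxonomy

With endpoints (fs, fe) in mature coordinates: `3p` iff fe ∈ {L+1, L+2, L+3};
else `5p` iff fs = 1; else `i` (so fs ≥ 2 and fe ≤ L). The CCA rule is
checked first, so a full-span fragment (possible only if the configured
window exceeds L) is reported as `3p` with a full-span flag. The region of a
merged record is its proxy's region; if placements disagree (possible when
containing loci have different L), the record is flagged region-ambiguous and
the proxy's region is used.

### Profiling as dictionary lookup

Reads are collapsed to (sequence, count) pairs and matched against the
exclusive-fragment table. This is equivalent to exact whole-genome
multi-mapping followed by the inside/outside filter, because exclusivity was
decided exhaustively at lookup-build time — but it is deterministic,
self-contained and directly testable. Each matched read contributes its count
exactly once (single counting across multi-locus fragments). Discards are
tallied by cause (not in lookup, length out of range, non-ACGT bases), and
`counted + discarded = input` holds for every dataset.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_len`, `max_len` | 16, 50 nt | fragment window range |
| `cap` | 10,000 | occurrence cap; above it a sequence is dropped |
| `min_reads` / `min_datasets` | 30 / {30, 20, 3} | support filter; presets `lcl`, `brca`, `clip` |
| depth scale | 10⁶ | RPM normalization factor |
| `ref_lab` | most datasets | anchor laboratory for rescaling |
| `exact_threshold` | 8 | exact Mann-Whitney when min(n) ≤ 8 and no ties |

Sequencing depth defaults to the total input reads after collapsing; it is
configurable because pipelines disagree on whether depth means input or
genome-mapped reads.

Filtering applies to raw counts before any normalization. Laboratory
rescaling is computed on depth-normalized values (ratios of raw counts would
conflate depth with laboratory effects): for each lab X and fragment f,
`factor(f, X) = mean over shared samples in the reference lab / mean over
shared samples in X`, with undefined or zero-denominator factors replaced by
1 with a warning. After rescaling, shared-sample means agree across
laboratories for every fragment — asserted in the tests. Rank normalization
uses ascending average ranks; column sums are n(n+1)/2, and downstream
correlation or ordination is invariant to the ascending/descending choice up
to sign.

Length distributions normalize, by default, within the union of all three
regions, so the per-region panels sum to the combined panel; a
`normalize="region"` flag switches to within-region fractions. Group
aggregation reports mean ± SE (sd/√n, ddof = 1). In the nuclear-vs-
mitochondrial decomposition, lookalike-proxied fragments count as
mitochondrial by default (they are identical copies of mitochondrial tRNAs);
this is configurable. Per-length group tests report raw two-sided p-values;
Benjamini-Hochberg adjustment is available but off by default.

## The synthetic-data generator

The generator emulates the genomic situations the method must survive, not
real human sequence. A uniform-composition background (GC configurable)
carries planted elements at non-overlapping positions with a 10 nt margin:
nuclear tRNAs with templated lengths 59–95 nt (some on the minus strand, a
configurable fraction flagged pseudo, one anticodon planted as identical
multi-copies, early loci carrying a canonical intron after templated position
37), mitochondrial tRNAs on a separate `MT` record, exact nuclear lookalikes
of mitochondrial tRNAs, and two decoy classes outside tRNA space: a partial
copy of a tRNA 5′ end (which breaks the exclusivity of exactly the windows it
covers) and a single-mismatch full copy (which breaks the exclusivity of all
source windows not covering the mutated base, while its own sequence matches
nothing exclusively). Anticodon names are drawn from the 61-name alphabet
derived from the standard genetic code's sense codons, so provenance counts
are meaningful.

Read sets are multinomial draws over a fragment pool chosen per (region,
length) cell of the abundance law; the default law is LCL-like, with internal
fragments dominated by 36-mers and 5′/3′ fragments spread over 18/22/26/33/36
nt. Decoy-source loci are excluded from the pool so the truth manifest
exactly predicts profiler output. Optional noise reads — random sequences,
single-substitution variants of planted fragments, and decoy-derived
sequences — are verified at generation time to match no mature subsequence,
so they must be discarded. All randomness flows from one integer seed through
numpy seed-sequence spawning; identical seeds give byte-identical outputs.

What passing tests on this generator do show: the exclusivity logic equals an
independent brute-force scan; planted counts are recovered exactly;
single-substitution reads are never assigned; conservation laws hold. What
they do not show: behavior under real base-modification artifacts, real
repeat structure at genome scale, or adapter/quality artifacts — those are
outside the simulator's scope by design.

## Numerical choices

- Interval membership uses merged sorted intervals with bisection;
  membership queries are deterministic.
- Genome occurrence search uses exact substring scanning of each contig and
  of the reverse complement; saturation is signalled by returning cap+1 hits.
- `parse_label` requires locus id, anticodon and chromosome tokens to be
  underscore-free (enforced at construction); the label grammar is otherwise
  a total inverse of formatting, with position-reporting errors.
- Mann-Whitney: exact null distribution when min(n₁, n₂) ≤ 8 without ties,
  otherwise the tie-corrected normal approximation with continuity
  correction; all values tied across both groups yields p = 1 with a warning.
- Zero-variance fragments yield NaN ("undefined") entries in correlation
  matrices, with the diagonal fixed at 1.
- Degenerate inputs: empty read sets profile to empty (not an error);
  an empty region yields an empty distribution with a warning; loci too close
  to a contig edge for the CCA substitution are a hard error naming the
  locus.

## Problem sizes used in the checks

The oracle-equivalence suite runs 20 seeded genomes of one 8 kb chromosome
plus a 2 kb mitochondrial record with 3 nuclear + 1 mitochondrial tRNAs, a
lookalike, an identical copy pair, an intron locus and both decoy classes
(~6–8 k distinct windows each); end-to-end recovery runs 10 seeded cohorts of
3 datasets × 1,500 reads; the null calibration uses 1,000 Mann-Whitney
replicates at n = 20 vs 20 against the binomial 99% interval around α = 0.05.
These sizes exercise every code path while keeping the default suite fast;
the genome-scale count of exclusive fragments on a real assembly is an
external check, not a test, since it requires the real genome and annotation.

## Known limitations

- No mismatch-tolerant rescue of modified bases; abundance of modified
  fragments is underestimated by design.
- Precursor-derived (leader/trailer) fragments are out of scope; only the
  mature span, junctions included, is modeled.
- The exclusivity decision is as good as the annotation: a true tRNA missing
  from the annotation acts as a decoy and suppresses shared fragments.
- Multivariate analyses (PCA, PLS-DA, SAM, hierarchical clustering) are not
  reimplemented; the exported matrices are their inputs.
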