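# Methods

## The detection problem

A diversity-generating retroelement (DGR) rewrites the C-terminal coding
region of a target gene by reverse-transcribing a nearby template region
(TR) into the gene's variable region (VR). The copy process is error-prone
specifically at adenines of the template: TR adenines are replaced by
effectively random bases in the VR, while all other positions are copied
faithfully. A DGR therefore leaves a recognizable genomic signature — a
pair of similar repeats whose differences sit almost exclusively at
adenine positions of one copy — usually with a reverse-transcriptase (RT)
gene nearby and the VR inside the last codons of a target gene.
`dgrfinder` detects this signature de novo, or guided by known template
sequences on fragmented metagenome assemblies.

## Pair-calling rule

A repeat pair is reported as TR–VR when, over the aligned span:

- the span is at least `min_pair_len` = 60 bp;
- at least `min_a_subs` = 7 substitution columns carry an adenine in one
  copy (that copy is the template);
- strictly fewer than `max_non_a_frac` = 30% of the span's substitutions
  fall at non-adenines of that same copy (0.30 exactly fails).

Each copy is evaluated as the template in both reading directions. The
reverse-complement reading treats the copy's T positions as adenines: a
pair whose template lies on the minus strand shows its adenine signature
as T-substitutions in the forward reading, and without the second reading
the scan would not be strand-symmetric. The qualifying assignment with the
most adenine substitutions wins; when the winning reading is the reverse
complement both reported intervals carry flipped strands.

## Scan pipeline

1. **Seeding.** Candidate repeats are ungapped diagonal segments of at
   least `seed_min_len` = 60 bp at `seed_min_identity` = 0.70 or better.
   The fast path scans only diagonals on which the sequence shares an
   exact `seed_kmer` = 11-mer with itself (or with its reverse complement,
   for inverted repeats). Eleven was chosen because the default simulated
   implant — 9 substitutions in a 110 bp template — is guaranteed by
   pigeonhole to retain an exact run of ceil(101/10) = 11 matching bases,
   so implant detection is deterministic rather than probabilistic.
   Exhaustive mode (`--no-seed`) scans every diagonal with the identical
   segment-extraction rule; because the two modes differ only in which
   diagonals they visit, fast-vs-exhaustive agreement is structural, and
   the exhaustive mode doubles as the brute-force oracle in the tests.
2. **AAY prefilter.** A candidate survives if either copy contains a
   60 bp window with at least 3 AAY triplets (AAC/AAT, counted at every
   offset — the reading frame is unknown at scan time — in both readings,
   again for strand symmetry). DGR hypervariation targets AAY asparagine
   codons, which maximize encoded amino-acid diversity without creating
   stop codons, so true templates are AAY-rich. `--no-aay-filter` or
   `--no-speedups` disables the filter.
3. **N filter.** Candidate copies with more than 10% N are dropped;
   assembled metagenomes contain gap Ns and alignment across them is
   meaningless.
4. **Alignment.** The two copies, padded by `seed_pad` = 100 bp, are
   aligned with an affine-gap Smith–Waterman (match +2, mismatch −2, gap
   open −6, extend −2). The mismatch and gap costs keep the aligner in the
   logarithmic regime on random DNA — with a milder mismatch score the
   local alignment of a true repeat extends tens of bases into random
   flanking sequence via cheap gaps, polluting the substitution profile —
   while still tolerating the 30% divergence ceiling of a valid pair
   (expected column score 0.7·2 − 0.3·2 > 0).
5. **Boundary refinement.** The aligned columns are trimmed to their
   maximal-scoring run under an identity score (match +1, substitution
   −7/3, gap column −3), which removes chance flank pockets: a run scores
   positive only while local identity stays above the 70% seed floor.
   The trimmed ends are then re-extended, once per template assignment,
   by iterating three rules with the substitution-bearing copy and reading
   fixed: an identity extension (match +1, anything else −2, X-drop 2); a
   cluster rescue re-attaching a run of at least 3 same-template
   substitutions within 15 columns uninterrupted by any other
   substitution; and a terminal reattachment of 1–2 same-template
   substitutions backed by 2 matches. Genuine adenine-substitution
   clusters at repeat edges — which a pure identity criterion would
   discard, occasionally dropping a pair below the 7-substitution floor —
   match these patterns regularly, while random flanking sequence does so
   at per-end probabilities around a percent. Each template assignment is
   then judged over its own span, so edge columns consistent only with a
   competing assignment never pollute the called template's profile.
6. **Overlap reduction.** Among qualifying pairs no two reported templates
   overlap: candidates are kept greedily by more adenine substitutions,
   then longer span, then leftmost start. Output is sorted by template
   start and fully deterministic.

A substitution lying at the exact repeat boundary is information-
theoretically indistinguishable from flanking divergence, so reported
substitution counts can differ from an implanted count by a column or two
in either direction on individual simulations; the tests therefore assert
the exact count on fixed replicates where it is stable and the median
across replicates otherwise. `scripts/acceptance.py` reports the measured
rates.

## RT constraint and reference-guided mode

Reference RT proteins are searched against all six frames of each input
(tblastn when BLAST+ is on PATH, otherwise an internal translated
Smith–Waterman with BLOSUM62, open −11 / extend −1). Hits need
`rt_min_aln_aa` = 100 aligned residues and `rt_min_identity` = 25%
(e-value ≤ 1e-5 where the backend provides one); these floors are
conventional for translated homology and are exposed as flags. The de novo
scan is then restricted to `rt_flank` = 10 kbp on both sides of each hit,
the neighborhood within which functional DGRs keep their template. The
same radius attaches pairs to RT hits at assembly time — one neighborhood
notion, one parameter.

In reference mode, known template sequences are located on the input
(≥ 60 bp at ≥ 70% nucleotide identity, both strands; internal search uses
8-mer-seeded ungapped diagonals so a copy diverged to the identity floor
still shares an exact word), and each hit is held fixed as one repeat copy
while the whole record is searched for a partner under the standard
calling rules. Hits that gain no partner are reported as `tr_only`
partial systems — the signal that makes fragmented assemblies searchable.

## System assembly

Systems are labeled `complete` (RT + pair + target gene), `no_rt`,
`no_vr` (RT and pair but the VR is not inside any C-terminal gene
window), or `tr_only`. A gene is a target when the VR overlaps its coding
span and the VR's 3'-most gene-oriented coordinate lies within
`vr_cterm_buffer` = 60 bp of the stop end — on either side, because
assembled metagenome gene models have imprecise ends. When no annotation
is supplied, `--orf-fallback` provides minimal ATG-to-stop ORFs (≥ 150 bp,
both strands) flagged `orf_prediction`.

De-duplication follows the CD-HIT strategy without binding to the binary:
greedy incremental clustering, longest sequence first, joining a cluster
when global identity to its representative reaches the threshold
(matches over all alignment columns, gaps included — a reproducible,
bit-exact definition within this package). The 90% default matches the
redundancy cutoff used for RT-based de-duplication of DGR systems.

## The simulator

`simulate` implants a minimal DGR system into an i.i.d. background contig
(default 50 kb at 45% GC): a synthetic RT coding sequence, a 110 bp
template with at least max(3, len/20) AAY codons (so implants always
survive the AAY prefilter), and a target ORF whose final codons contain
the VR, its 3' end 16 bp upstream of the stop. The VR derives from the TR
by exactly `n_a_subs` = 9 adenine substitutions (preferring AAY adenines,
replacement uniform over {C,G,T} — the biology says "random" without a
distribution) and `n_non_a_subs` = 0 off-target substitutions, which are
drawn from non-adenine bases so every substitution column is unambiguous
about which copy carries the adenine. The defaults mirror reported DGR
systems, whose templates run roughly 60–160 bp with divergence
concentrated at adenines. Everything is deterministic under the seed;
identical parameters give byte-identical output.

What the simulator does not emulate: repeat structure in the background
(keeping the false-positive test clean), assembly or sequencing error,
real RT sequence diversity (the bundled RT coding sequence is synthetic,
designed around canonical RT motifs), IMH/IMH* initiation sites, and
accessory (avd) genes. Passing simulator tests therefore demonstrates the
detection arithmetic and pipeline plumbing, not robustness to repeat-rich
natural genomes; the virome benchmark (tests/test_acceptance.py, one-time
download) is the real-data check.

## Degenerate inputs and numerical choices

Empty FASTA entries, duplicate ids, non-IUPAC characters, inverted GFF3
coordinates and unknown strands are rejected with named errors. N never
counts as a match, an adenine, or part of an AAY triplet. All coordinate
arithmetic is 1-based inclusive end to end, so GFF3 round-trips exactly.
Ties anywhere (role assignment, overlap reduction, clustering order,
system ordering) are broken deterministically; two runs on identical
inputs produce byte-identical reports.

## Known limitations

- The strict < 30% non-adenine rule is evaluated over the refined span;
  a non-adenine substitution at the extreme repeat edge can fall outside
  the span and escape the denominator (the boundary ambiguity above).
- Template/variable boundaries are alignment-defined and may differ from
  annotation-defined boundaries by a few bases, as repeat ends in real
  systems are themselves annotation-dependent.
- No statistical significance model is attached to pairs; the thresholds
  are the model.
- Very long (> ~100 copies) low-complexity k-mers are excluded from
  seeding (`max_kmer_occ`); a TR–VR pair made entirely of such sequence
  would need `--no-seed`.
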