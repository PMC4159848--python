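# dgrfinder

Detection of diversity-generating retroelements (DGRs) in genomes,
metagenome contigs and scaffolds.

DGRs are a family of retroelements — first characterized in a *Bordetella*
phage, since found across bacteria, archaea and their viruses, and
widespread in host-associated microbial communities — that accelerate the
evolution of a target gene through error-prone reverse transcription. A
template region (TR) is copied into a variable region (VR) inside the
target gene's C-terminal coding sequence, and during the copy the
template's adenines are randomized (the substitution process is
A-specific, concentrated in AAY asparagine codons). A minimal functional
system is therefore a reverse-transcriptase (RT) gene, a TR, and a VR
inside a target gene.

`dgrfinder` finds these systems from sequence alone. It is aimed at
microbiome and phage researchers annotating assemblies where DGR
components are routinely mislabeled as hypothetical proteins or generic
reverse transcriptases.

## The detection rule

Two repeats form a candidate TR–VR pair when they align over at least
60 bp with

- **a_subs ≥ 7** substitutions at adenines of one copy (that copy is the
  TR; the other is the VR), and
- **(total − a_subs) / total < 0.30** — strictly fewer than 30% of
  substitutions at non-adenines of the TR.

Candidate repeats are seeded by ungapped diagonal matches (≥ 60 bp at
≥ 70% identity), refined by affine-gap Smith–Waterman alignment, and
pre-filtered by the AAY motif (a 60 bp window must contain ≥ 3 AAC/AAT
triplets). When reference RT proteins are supplied, the scan is
restricted to 10 kbp neighborhoods around translated-homology RT hits.
Given reference TR sequences instead, `dgrfinder` reports partial systems
(`tr_only`) on fragments where only the template survives — the mode that
makes fragmented metagenome assemblies searchable. Systems are assembled
with completeness labels (`complete`, `no_rt`, `no_vr`, `tr_only`) and
de-duplicated by CD-HIT-style greedy clustering of RT proteins at 90%
identity.

See `docs/methods.md` for the full model, parameter table and design
rationale.

## Worked example

Simulate a contig with an implanted DGR system, then find it:

```sh
$ dgrfinder simulate --out sim1 --seed 1
wrote sim1.fasta, sim1.truth.gff3, sim1.genes.gff3

$ dgrfinder denovo sim1.fasta --rt-ref rt_refs.faa --genes sim1.genes.gff3 --out out1
1 system(s) written to out1.tsv / .gff3

$ cat out1.tsv
seq_id        system_id           component  start  end   strand  a_substitutions  total_substitutions  non_a_fraction  partner_coordinates  completeness
sim_contig_1  sim_contig_1:DGR1   RT         1001   1990  +                                             rt_ref          complete
sim_contig_1  sim_contig_1:DGR1   TR         4504   4613  +       9                9                    0.0000          5692..5801           complete
sim_contig_1  sim_contig_1:DGR1   VR         5692   5801  +       9                9                    0.0000          4504..4613           complete
sim_contig_1  sim_contig_1:DGR1   target     5389   5817  +                                             5692..5801      complete
```

Reading the report: one complete DGR system was found on the contig. The
RT gene spans 1001–1990; the 110 bp template at 4504–4613 aligns to its
variable copy at 5692–5801 with 9 substitutions, every one at a template
adenine (`non_a_fraction` 0.0000 — the A-specific signature); and the VR
sits in the C-terminal window of the gene at 5389–5817, making that gene
the diversification target. The coordinates match the simulator's ground
truth (`sim1.truth.gff3`) exactly. A GFF3 version of the same report is
written alongside the TSV.

`rt_refs.faa` here is the translation of the simulator's (synthetic) RT;
with real data you would pass a reference collection of DGR reverse
transcriptases. Without `--rt-ref` the whole sequence is scanned.
Reference-guided search: `dgrfinder refsearch contigs.fasta known_trs.fasta
--out ref_out`. Every threshold is a flag (`--min-a-subs`,
`--max-non-a-frac`, `--rt-flank`, ...); `--no-speedups` disables the AAY
filter, the k-mer seeding and the RT constraint for an exhaustive scan.

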