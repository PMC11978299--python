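# Methods

This note describes the model behind `dramseq`: what the simulator emulates,
how sites are called, and which numerical choices were made and why.

## Biological model

An m5C-reader protein fused to a deaminase is expressed in cells alongside
controls. When the reader engages an m5C site on an mRNA, the tethered
deaminase edits nearby bases: a cytidine deaminase fusion (CBE) converts C to
U, an adenine deaminase fusion (ABE) converts A to G, both read out as
mismatches in RNA-seq. Editing is concentrated within a window of roughly
±20 nt around the m5C site because the tether limits the deaminase's reach.
Three conditions discriminate genuine reader-guided editing from noise:

- **fusion (DRAM)** — reader–deaminase fusion, multiple replicates;
- **knockout** — the same fusion in cells lacking the principal m5C
  methyltransferases, so reader-guided editing largely disappears;
- **deaminase-only** — the deaminase without the reader, capturing basal,
  untargeted editing activity.

## Simulator

`generate_transcriptome` builds one contig per transcript: a uniform-random
sequence with 50 nt intergenic pads on both sides, the gene body split into
5'UTR/CDS/3'UTR by configurable fractions (CDS length rounded to a multiple
of 3), strands alternating between genes so that every downstream component
is exercised on both strands. On minus-strand genes the transcript is the
reverse complement of the genomic interval, and a transcript C-to-U edit
manifests as a genomic G-to-A mismatch.

`plant_m5c_sites` samples site positions from the pool of sense-strand
cytosines, weighted by region (default CDS 0.50, 3'UTR 0.35, 5'UTR 0.15 —
m5C is predominantly found in CDS and 3'UTR). Each site gets an edit rate
drawn from a configurable range and a ±20 nt editing window.

`simulate_reads` draws reads uniformly along each transcript
(`n_reads = coverage_mean × length / read_length`). For each read, every
editable base (C for CBE, A for ABE) inside any site window is edited with
per-read Bernoulli probability; overlapping windows combine as
`p = 1 − ∏(1 − p_i)`. Background (untargeted) editing hits editable bases
anywhere at a low per-base rate with a 3:1 bias toward the 3'UTR, reflecting
where untethered deaminases preferentially act. Uniform sequencing error is
applied last, so errors can also corrupt edited bases. Reads are written as
coordinate-sorted SAM with correct NM/MD tags. Condition arms reuse the same
transcriptome and truth but scale the site edit rates: knockout multiplies
them by 0.1 (residual methylation), deaminase-only by 0 with a higher
background rate. Each replicate uses seed `spec.seed + replicate_index`;
the pipeline assigns disjoint per-condition seed offsets so no two arms share
a random stream.

Two orthogonal-validation simulators mirror wet-lab assays:
`simulate_bisulfite_amplicon` converts every unmethylated C to T with a given
efficiency while the target C is retained with probability `m5c_fraction`;
`simulate_sanger_trace` emits per-position base-call proportions in which the
edited base's partner peak equals the edit rate exactly.

## Pileup and candidate extraction

`build_pileup` streams a coordinate-sorted SAM (enforced from the header)
and tallies A/C/G/T/N per reference position, excluding unmapped, secondary,
supplementary and duplicate reads, reads with mapping quality <20, and
individual bases with base quality <20. `extract_candidates` then selects
positions matching the conversion in a strand-aware way: for C-to-U the
reference base must be C with T mismatches on plus-strand genes, or G with A
mismatches on minus-strand genes (symmetrically A/G and T/C for A-to-G).
Positions covered by genes on both strands are flagged ambiguous; positions
outside genes are evaluated on both strands. Coverage is the full read depth
at the position; the edit ratio is edited reads over coverage.

## Site calling

A candidate passes one replicate when all of the following hold, evaluated
in this order (the first failing predicate is reported):

1. coverage ≥ 10 reads;
2. edit ratio in [5%, 95%] — the lower bound suppresses sequencing noise,
   the upper bound removes apparent SNV-like positions edited in essentially
   every read;
3. ≥ 2 edited reads;
4. edit ratio ≥ 1.5 × the knockout ratio at the same position.

A site is called when it passes in ≥2 fusion replicates; reported coverage,
edited reads and ratio are means over the passing replicates. The
high-confidence tier re-evaluates the same per-replicate evidence with
ratio in [10%, 60%], 2-fold over knockout and ≥4 edited reads, and is by
construction a subset of the default tier.

Two design decisions deserve explanation:

- **Knockout pseudocount.** If the knockout covers a position without a
  single edited read, a literal ratio of 0 would make any fusion signal pass
  the fold test regardless of depth. We instead use
  `ratio = pc / (coverage + pc)` with pseudocount 1, so the fold requirement
  scales sensibly with knockout depth. Positions with no knockout coverage
  at all skip the fold test: absence of control coverage is not evidence
  about editing there. If no knockout condition is configured the fold
  filter is disabled with a warning.
- **Deaminase-only subtraction.** Sites are removed when editing "appears"
  in deaminase-only samples. Appearance is defined as passing the evidence
  predicates (coverage, ratio window, minimum edited reads) in at least one
  deaminase-only replicate, with no fold test. Removing any position with a
  single deaminase-only mismatch would be far too aggressive — at realistic
  background rates it would delete a large fraction of genuinely edited
  sites through chance single-read hits — while requiring replication in
  the control would be too lax for a subtractive filter.

## Annotation, motif and quantification

Region assignment uses precedence CDS > 5'UTR > 3'UTR > intron > intergenic,
with ties between overlapping genes broken toward the longer transcript.
The metagene coordinate maps a transcript position to [0,1) in the 5'UTR,
[1,2) in the CDS and [2,3) in the 3'UTR (90 bins by default); the profile is
a density and sums to 1. Distances from reference m5C sites to the nearest
called edit are signed and measured in transcript coordinates of the
reference site's gene (genomic offsets outside genes), with a default
±3000 nt search window and 50 nt histogram bins (1 nt bins when the window
is ≤80 nt); equidistant ties resolve downstream.

Motif analysis extracts ±k nt transcript-sense flanks (default k = 20,
N-padded and flagged at transcript ends) and builds a position frequency
matrix over A/C/G/U (T read as U, N excluded from column denominators).
Per-column information content is `2 − Shannon entropy` in bits against a
uniform background, so it lies in [0, 2].

Bisulfite quantification anchors each amplicon read to the reference
allowing C-to-T changes (≥90% compatibility required), then reports the
percentage of reads retaining C at the site among reads with C or T there
(other bases are treated as errors and excluded). A library passes QC only
with more than 1000 aligned reads. Trace quantification returns the
secondary-peak proportion of the conversion partner ×100, after validating
that the position's signal is confined to the conversion pair. Replicate
agreement is the Pearson correlation of per-gene edited-read counts over
the union of genes, absent genes counted as 0.

## Parameter defaults

| parameter | default | rationale |
| --- | --- | --- |
| editing window | ±20 nt | tether reach of the fusion |
| min coverage | 10 reads | below this, ratios are dominated by sampling noise |
| edit ratio window | 5–95% (HC 10–60%) | noise floor / SNV ceiling |
| fold vs knockout | 1.5 (HC 2.0) | comparative specificity |
| min edited reads | 2 (HC 4) | excludes single-read artifacts |
| min replicates | 2 | reproducibility across transfections |
| knockout pseudocount | 1 | see above |
| background rate (deaminase-only) | 0.001/base, 3:1 3'UTR bias | free parameter; chosen once to represent measurable basal activity |
| background rate (fusion arms) | 0.0002/base | basal activity is diluted by reader targeting |
| sequencing error | 0.001/base | typical short-read substitution error |
| bisulfite QC | >1000 reads | deep-amplicon requirement |
| metagene bins | 90 | 30 per region |
| distance window / bins | 3000 nt / 50 nt (80 nt / 1 nt for close-range) | transcriptome-scale vs window-scale views |

Default problem sizes (20 transcripts of 600–1200 nt, 40 sites, 100×
coverage, 3+1+2 replicates) are chosen so a full pipeline run completes in
seconds while every filter has non-trivial work to do; they are package
defaults, not biological claims.

## What the simulator does not model

Alignment itself (reads are emitted pre-aligned and error-free in
placement), indels and splicing (single-block genes only), PCR duplicates,
coverage biases beyond uniform sampling, strand-specific library artifacts,
SNVs, and RNA secondary-structure effects on editability. Consequently the
false-positive behavior of the cascade on real data — where mapping errors
and SNVs dominate — is outside what the synthetic benchmarks can certify.

## Limitations

- The deaminase-only "appearance" definition and the knockout pseudocount
  are principled but not canonical; both are parameters.
- Edit ratios are treated as independent across positions; reads spanning
  several edited positions are not used jointly (no haplotype/phasing
  signal).
- The high-confidence tier inherits the default tier's replicate evidence;
  it cannot rescue sites the default tier discarded.
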