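# Methods

This note records the model behind `exontile`, the reasoning for each
parameter default, what the benchmark generator does and does not capture,
and the numerical/implementation choices that affect results.

## 1. Model and assumptions

The assembler reconstructs **one transcript model per expressed locus**
from two inputs: aligned read blocks (genomic intervals covered by each
read, split at introns) and splice junctions (donor/acceptor coordinate
pairs with read support). It assumes:

- reads are short (default 50 nt) and stranded information is absent; all
  models are reported unstranded and downstream ORF calling scans both
  strands;
- coverage within an expressed exon is roughly uniform at the depths where
  structure is called, so that contiguity of coverage is evidence of
  exonic sequence and a sustained gap is evidence of an intron;
- junction calls from the aligner are mostly correct but contain
  similarity-driven artefacts, which motivates the span caps;
- isoform mixtures cannot be deconvolved reliably from short reads, so a
  single well-supported isoform per locus is the deliberate output. Loci
  where the dominant isoform switches along the gene will be reported as
  a hybrid of the overlapping isoforms.

The pipeline is a fixed five-stage cascade: tile → infer short exons →
merge → split/trim → link. Stage order matters: merging before splitting
lets a retained intron first be absorbed into one fragment and then be
adjudicated by the density rule, rather than fragment boundaries being an
accident of sampling.

## 2. Parameters and why

| Parameter | Default | Rationale |
| --- | --- | --- |
| `min_exon_rpke` | 50 | Expression floor for tiled fragments. RPKE = reads × 1000 / exonic nt is the library-size-free analogue of RPKM; at typical library sizes for 50-nt data, 50 RPKE sits near the conventional ~150 RPKM noise floor. Below it, coverage islands are dominated by multimapping and library artefacts. |
| `merge_gap` | 50 | One read length. A coverage dip shorter than a read within one exon is a sampling artefact (a handful of unsampled start positions), not an intron: true introns are rarely this short. |
| `read_len` | 50 | Drives three derived quantities: the short-exon inference window (an acceptor→donor gap < read_len implies a hidden exon), the flank window of the density rule, and the boundary-trim radius. |
| `density_ratio` | 0.5 | Intron-retention adjudication. For a junction inside a fragment, compare read-start density (starts per nt) in the intron interior against the mean of the two flanking read-length windows. A retained intron is transcribed and accumulates starts like its flanks (ratio near 1); a spurious fusion shows depleted starts. The midpoint 0.5 separates the two regimes symmetrically and is insensitive to overall depth because it is a ratio. Read *starts* rather than coverage are compared because coverage bleeds one read length past every exon boundary, biasing the intron side upward. |
| `max_junction_span` | 50,000 | Junctions spanning more than 50 kb are overwhelmingly alignment artefacts between paralogs or repeats; the cap is strict (`>`), so a 50 kb junction is kept. |
| `max_skip_span` | 50,000 | Stricter cap applied when a junction's intron fully contains another detected exon: exon-skipping over long distances is the classic paralog-bridging artefact. |
| `min_footprint` | 140 | Minimum summed exonic length of a reported model. Shorter models cannot be distinguished from clusters of multimapped reads. Footprint (exonic nt), not genomic span, is used: a two-exon model with a long intron is not made credible by its span. |
| edge tolerance | ±5 | Junction donors/acceptors are matched to fragment boundaries exactly first; unmatched ones fall back to the nearest boundary within 5 nt, absorbing one-off alignment jitter without letting junctions reach across real gaps. |
| `overlap_lo` / `overlap_hi` | 0.05 / 0.75 | Annotation-overlap classes for the novel-gene cascade: <5% of the model's exonic footprint overlapped by any single annotated gene → novel; ≥75% → annotated; in between → indeterminate (candidate unannotated splice form). The maximum over single annotated genes is used, not the union, so two flanking genes cannot jointly "explain" a model neither overlaps well. |
| `min_gene_rpke` | 100 | Novel calls carry a higher evidential burden than exon detection, hence double the exon floor. |
| `max_similarity` | 25 | A novel model whose spliced sequence recurs elsewhere in the genome above this fraction is a likely paralog shadow. |
| `min_orf_codons` | 40 | Coding/non-coding heuristic. In random sequence an ATG-initiated ORF runs ~64/3 ≈ 21 codons before a stop; 40 codons is ~2× that expectation, cheap to exceed for real coding sequence and unlikely by chance in short models. |

## 3. Similarity screen

The self-similarity percentage is defined as **query coverage**: the
fraction of the model's spliced sequence covered by ungapped matches
(≥90% identity, seeded by exact 16-mers, extended until 5 consecutive
mismatches, both strands) to any other place in the genome, the model's
own locus excluded. Coverage rather than best-hit identity is used because
the screen asks "how much of this sequence is explained elsewhere", which
is robust to a single high-identity short repeat. An external
similarity-percentage table (e.g. from a dedicated aligner) can be
supplied instead; the internal method is a deliberately simple,
dependency-free stand-in with the same contract.

## 4. Evaluation

Assembled models are matched to reference transcripts when the shared
exonic footprint exceeds 90% of the model's footprint; among qualifying
reference variants, one with the same exon count is preferred, since
exon-count-changing variants are the alternative-splicing signal the
discrepancy taxonomy is meant to isolate. Each matched pair receives
exactly one of seven categories: `match`, `extra_exon`, `missing_exon`,
`extra_intron`, `missing_intron`, `missing_junction`, `gap` — the last two
only arise when one reference locus was assembled in pieces — with two or
more elementary discrepancies collapsing to `multiple`. Transcript-end
offsets use the convention that positive means the assembly extends
beyond the reference.

The sampling arithmetic is the standard finite-population minimum sample
size, `n = N·x / ((N−1)·E² + x)` with `x = Zc²·r·(100−r)/100²`, rounded
up; extrapolated counts are rounded to whole genes and percentages to one
decimal, matching how such audits are reported.

## 5. Benchmark generator: realism and limits

The generator builds a random uniform-base genome and inserts
single-isoform genes of known structure: 20 genes per exon-count category
(1–4), exons 150–600 nt, introns 100–2,000 nt, ≥10 kb apart. Reads are
50 nt, error-free, uniformly distributed over the spliced transcript; a
read crossing an exon boundary is emitted as split blocks and contributes
junction support. At each titration level (1,000 → 50 reads per gene) a
fresh read set is drawn, so levels are independent samples rather than
nested subsets. A gene's **point of first failure** is the highest level
(expressed in RPKE = reads × 1000 / transcript nt) at which the assembler
does not report exactly one gene with the true exon count; accuracy at a
level is the fraction of genes whose point of first failure lies below it.

Deliberate idealizations: no sequencing error, no coverage bias
(fragmentation, GC, 3′ bias), no multimapping (the genome is random, so
spurious alignment is absent by construction), no overlapping genes, no
alternative isoforms. The benchmark therefore measures the *depth
requirement of the algorithm itself*, an upper bound on real-data
performance, not a forecast of it. Exon/intron length priors were chosen
so that 50-nt reads can both tile every exon and generate junction
support; they are configurable.

## 6. Numerical and implementation choices

- **Coordinates** are 0-based half-open internally; GTF output converts to
  1-based inclusive. RPKE values are serialized at 17 significant digits
  so that GTF round trips are lossless.
- **Read counting** is by distinct read identifier within the queried
  intervals, so a junction-spanning read contributes once to its gene, not
  once per exon.
- **Determinism**: every stochastic component takes an explicit seed
  (`numpy.random.default_rng`); identical inputs, config and seed give
  byte-identical outputs. Tie-breaks (equal-length ORFs, equally
  overlapping references) are resolved by fixed scan order.
- **Connected components** use an in-package union-find (a dozen lines);
  the test suite checks it against `networkx` and an independent
  breadth-first search.
- Aligner block lists are normalized by merging reference-contiguous
  blocks, so insertions in a read do not split its coverage interval.

## 7. Known limitations

- One isoform per locus: alternative splicing is reported as structural
  discrepancy, not as isoforms.
- Unstranded models: antisense overlapping genes are fused into one
  component when their coverage islands touch and junction edges match.
- The density rule needs flanking coverage; a junction at the extreme edge
  of a fragment (within one read length of its end) is handled by
  boundary trimming instead, and the untrimmed terminal ends of a model
  can overhang the true transcript ends by up to one read length.
- The internal similarity screen is ungapped; a diverged paralog with many
  small indels can score below its true similarity. Supplying an external
  similarity table is the escape hatch.
- Genes expressed below ~50 RPKE at the exon level are invisible by
  design; the floor trades sensitivity for a controlled false-positive
  rate, and the benchmark quantifies exactly where that trade bites.
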