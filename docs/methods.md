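# Methods

## The experimental model

Cas9 loaded with a subfamily-specific guide cuts genomic DNA inside (or
next to) every element copy the guide matches; nanopore adapters ligate
at the cut, so sequencing starts at the cleavage site and runs outward in
both directions.  Reads therefore begin a few bases from the PAM, carry
element sequence at one end, and run into unique flanking genome — which
is what lets a repeat insertion be placed unambiguously.  The package
models exactly this geometry: cut-offset distributions of {3: 0.5,
4: 0.5} for forward-strand reads and {7: 1.0} for reverse-strand reads
(base distance from the PAM N), and a 4.6-fold forward-strand excess,
both taken from the empirical behaviour of Cas9-targeted nanopore runs.
Insertions are modelled as TPRT products: a duplicated target word (TSD)
flanking `[element][poly(A)]`, at sites biased toward the L1 endonuclease
nicking motif 5′-TTTT/AA, with optional 5′ truncation and 5′ inversion
(twin priming).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| quality filter | mean Q > 7 (strict) | Phred | mean computed on the error-probability scale, matching base-caller summaries |
| mapping filter | MAPQ ≥ 10 | — | discards multi-mapping reads that land inside repeat bodies |
| end-scan bin | 100 | bp | terminal window aligned to each consensus; local scoring 2/−3, gaps −5/−2, signal at score ≥ 60 (~30 matched bases) |
| on-target overlap | ≥ 100 | bp | absolute read/element overlap that counts as on-target reference (see Design choices) |
| min insertion | 100 | bp | CIGAR `I` below this is indistinguishable from nanopore indel noise |
| min terminal clip | 200 | bp | soft clips must carry enough element sequence to be assignable |
| cluster window | 100 | bp | single-linkage gap along the reference; breakpoints of supporting reads agree to within tens of bp |
| min support | 4 | reads | reporting threshold for a putative insertion (15 is used as a stringent cutoff in saturation analysis) |
| TSD | 5–30 bp, ≤ 1 mismatch | — | duplicated word must begin and end on an exact match |
| poly(A) | ≥ 10 bp, purity ≥ 0.8 over 20 bp windows | — | tolerates interrupted tracts (e.g. A₁₂GA₁₂ → 25) |
| genotype | hom ≥ 0.8, het ≥ 0.2 | carrier fraction | of reads sampling the locus |
| depth filter | < 2-fold vs flanking median, 500 bp bins | — | optional empirical curation of pileup artefacts |
| cleavage heads | first 80 bp, score ≥ 100, start at read base 0 | — | scoring 2/−1 with strict gaps −10/−5 |

All are fields of `CallerParams` or the simulator config; none is
hard-coded.

## The synthetic generator: what it emulates, and what it does not

`simforge` emulates: subfamily consensus structure (a ~6 kb L1 pair with
a diverged L1PA2-like outgroup; ~300 bp Alu triplet in which the
AluYb8-like member carries the 7 bp CAGTCCG-style diagnostic insertion;
~1.4 kb SVA triplet), per-copy divergence and 5′ truncation of reference
copies, diploid zygosity, TPRT hallmark structure, EN-motif site bias,
the cut-offset/strand-bias read model, lognormal read lengths tuned to a
target N50 (test default 5 kb), and a per-base independent
substitution/insertion/deletion error model (3%/2%/2% defaults).

It does **not** emulate: homopolymer-correlated nanopore errors, basecall
quality-to-error coupling, chimeric or adapter-bearing reads, fragment
breakage (so one-end vs two-end signal length ratios are not a target),
source-locus transduction structure, or segmental duplications.  Passing
tests therefore demonstrate algorithmic correctness under a clean
generative model, not calibrated performance on real flow-cell data.

Two deliberate *truth-unambiguity* conventions make exact hallmark
round-trips well-posed: implant sites are resampled until the two
reference bases immediately after the duplicated target word differ from
the first two payload bases (otherwise the TSD boundary is ambiguous at
~1/4 of sites and "exact recovery" is not a meaningful assertion), and
the toy consensus sequences end in five non-A bases so the implanted
poly(A) is the unique maximal tract.  Real data offer no such guarantee;
on real reads the reported TSD/poly(A) are maximal qualifying words, not
certified truth.

Truth alignments are emitted directly by the generator (the external
aligner is out of scope), so simulated breakpoints are exact; the
breakpoint-error tolerance in the round-trip tests is therefore a
property of clustering, not of alignment wobble.

## Numerical and algorithmic choices

- **Coordinates** are 0-based half-open everywhere; RepeatMasker `.out`
  (1-based inclusive) and SAM positions convert at the I/O boundary only.
  CIGARs are stored in reference order and walk the aligned orientation
  of the read; PAF query coordinates stay on the original read.
- **Capture-bound upper class**: "≥ 14 of 23 bases matched" is computed
  as the number of aligned identities in the best-scoring semi-global
  placement (match +1 / mismatch −1 / gap −1, query anchored, free target
  ends), maximised over score ties.  The DP packs (score, matches) into
  one integer so a vectorised prefix-maximum resolves gap chains and
  ties in a single pass; an independent naive DP serves as the test
  oracle.  The intermediate class uses true edit distance (edlib),
  substitutions and gaps jointly, per the "≤ 3 bp mismatch or gap"
  definition.
- **TSD detection** uses the classic junction rule: the duplicated word
  is simultaneously a prefix of the inserted sequence and of the
  reference downstream of a left-aligned breakpoint (or a suffix of both
  the insertion and the upstream reference for right-aligned signals).
  Words must start and end on exact matches, with ≤ 1 internal mismatch;
  the longest candidate across up to eight cluster members wins, since a
  clip that does not span the junction can only produce short
  coincidental words.  With exact single-insertion alignments one TSD
  copy necessarily sits inside the inserted sequence, which is why the
  detector takes the insertion sequence as an argument rather than only
  the two reference flanks.
- **Subfamily assignment** screens candidate consensus/strand pairs by
  edit distance of the insertion's outer segments (5′ 350 bp + 3′ 450 bp
  — the 3′ end carries the subfamily diagnostics next to the poly(A)),
  then scores the winner with the local aligner; 5′ inversion is flagged
  when the two outer segments align the same consensus in opposite
  orientations.  Transduction detection aligns the final 600 bp of the
  poly(A)-stripped payload, so transductions longer than ~570 bp are
  truncated in the report.
- **Genotyping** divides cluster support by the number of reads sampling
  the locus: spanning alignments plus clip-supported members.  In
  capture data a heterozygous non-reference locus is cut only on the
  carrier haplotype, so nearly all sampling reads are carriers and calls
  trend homozygous — genotypes are meaningful under uniform (WGS-like)
  coverage, which the generator also produces; depth *ratios* are the
  quantity that separates zygosity in capture data.
- **Clustering** counts one signal per read per cluster (the longest),
  so paired clips from one read cannot inflate support.

## Design choices where the design was open

- *On-target overlap rule.* A span-fraction rule ("≥ 50% of the aligned
  read inside the element") was considered and rejected: enrichment
  reads deliberately run many kb past the element into unique flank, so
  genuine on-target reads rarely satisfy it.  An absolute ≥ 100 bp
  element overlap is used instead (configurable).
- *Guide-site geometry of the toy consensus.* Engineered guide sites sit
  220–280 bp from the element 3′ end so that forward-strand reads cut
  inside the element carry a clip long enough (≥ 200 bp) to reach the
  caller; placing the site directly at the 3′ terminus would silently
  discard the majority read class at the default clip threshold.
- *Single-pass calling.* The two-pass error-correct/re-align loop of
  assembly-based pipelines is replaced by a single pass over alignments;
  externally corrected reads can simply be fed in as input.
- *Secondary/supplementary alignments* are ignored; the first alignment
  per read is used.
- *k-mer counting* counts overlapping occurrences on both strands
  (forward text plus reverse-complement of the query); palindromic
  k-mers therefore count once per strand.

## Problem sizes

The packaged experiments run on one CPU: the zygosity depth-ratio
experiment uses a 2.4 Mb reference, 30 homozygous reference and 30
heterozygous non-reference L1Hs-like loci, ~10 reads per cut site, and
five derived seeds (~1 minute); round-trip calling uses 1.2 Mb with 10
implants; hallmark and genotype checks use a 400 kb donor at 20×
uniform coverage.  Locus spacing is kept large relative to read length
(tens of kb versus a 5 kb N50) so reads cut at one locus rarely reach
another — mirroring the megabase-scale spacing of active L1 copies in
real genomes; packing loci more densely couples their support counts and
biases depth ratios downward.

## Known limitations

- Genotypes in capture mode trend homozygous (see above).
- Transductions are reported verbatim without source-locus mapping, and
  are capped near 570 bp.
- The end-scan is O(bins × library) local alignment; for large consensus
  libraries it is the slowest step and is optional in the pipeline.
- BAM/CRAM are not parsed natively; convert to SAM/PAF first.
- The empty-site check only records whether any spanning read lacks the
  insertion; it does not reconstruct the pre-insertion allele.
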