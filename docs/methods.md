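# Methods

## Scope and model

`somacohort` implements the post-calling analysis layer of a two-group
somatic whole-genome study: it consumes allele-specific copy-number
segments (PURPLE-style: chromosome, interval, total and major-allele copy
number per sample) and somatic variant catalogs (VCF), and produces
sample-level genomic characterizations and cohort-level exact statistics.
Purity/ploidy estimation, read alignment, variant calling and consequence
annotation are upstream of this package and are treated as inputs.

## Coordinate system and arm model

All intervals are zero-based half-open internally; VCF positions (1-based)
are converted at the read boundary. Chromosome arms are built from
UCSC-layout cytoband tables: each arm is the union of its `p*`/`q*` bands,
and `acen` (centromeric) bands are split at the midpoint of their combined
extent so that every base belongs to exactly one arm — a requirement of
the half-of-bases arm rule. The acrocentric short arms (13p, 14p, 15p,
21p, 22p) carry only repetitive material and are excluded from arm-level
calling and from the aneuploidy denominator, following the convention of
the arm-level aneuploidy-scoring literature; the callable autosomal arm
count is therefore 39. Sex chromosomes are callable for arm events (Y loss
is a real and frequent event in male tumors) but never enter WGD inference
or the aneuploidy score.

## Copy-number rule system

**WGD.** A sample is whole-genome duplicated when ≥ 11 of the 22 autosomes
each have major-allele copy number strictly > 1.5 over at least half of
their covered bases. "At least half" is inclusive; "> 1.5" is strict.
Coverage gaps are excluded from numerator and denominator alike, since
segment files need not tile the genome. The flag is monotone: raising any
major-allele copy number can never un-flag a sample.

**Rounding.** Raw copy-number estimates are rounded to the nearest
integer with ties at .5 rounded half away from zero (0.5 → 1, 2.5 → 3).
Away-from-zero avoids the parity artifact of banker's rounding exactly at
the deletion boundary CN 0.5.

**Gene calls.** A gene's single copy number is the length-weighted mean of
the raw total copy number over the covered portion of the gene, then
rounded. (The minimum-over-exons convention used by some callers is a
known alternative; the weighted mean was chosen because it is robust to
single-exon noise and needs no transcript model. This is a documented
divergence risk when comparing with exon-level callers.) Two rule
families are exposed: the TCGA WGD-conditional convention (diploid:
deleted iff CN = 0, amplified iff CN ≥ 5; duplicated: deleted iff
CN ≤ ploidy − 3 with the *unrounded* ploidy — the literal reading of
"three copies less than the sample ploidy" — amplified iff CN ≥ 8) and
the absolute convention (deleted iff CN ∈ {0, 1}, amplified iff CN ≥ 6).
The two conventions conflict at CN 1 and CN 5 in diploid samples; both
are implemented, the TCGA rule is the default for headline gene-level
features (`rule_family: absolute` switches).

**Arm calls.** Per-base rounded copy number is compared with the rounded
sample ploidy: an arm is deleted (amplified) when at least half of its
covered bases are ≥ 1 copy below (above) rounded ploidy. With a whole arm
at CN 3 and ploidy 3.7, rounding gives ploidy 4 and the arm is *deleted* —
the rounded-ploidy convention resolves the ambiguity of comparing integer
per-base values with a real-valued ploidy. In the measure-zero case where
both fractions are exactly 0.5, deletion takes precedence and a warning is
logged. The aneuploidy score is the count of non-neutral callable
autosomal arms (0–39).

## Mutation burden and mutation flags

TMB is all somatic variants (SNVs and indels) divided by the genome size
of the configured build in Mb; the denominator is configurable. The
genome-wide denominator is the default because the cohort totals it is
designed to match are arithmetically consistent with genome-wide counting.
A gene's non-synonymous flag is set when ≥ 1 of its variants carries a
protein-altering consequence term (missense, nonsense/stop, frameshift,
inframe indel, splice donor/acceptor, start-lost); unannotated variants
never set flags and are logged.

## Signature refitting

Spectra use the standard 96-channel pyrimidine-centered scheme in
class-major order (C>A, C>G, C>T, T>A, T>C, T>G × 16 flank pairs,
A[C>A]A … T[T>G]T); purine-centered substitutions are reverse-complemented
onto this frame. Refitting solves min‖m − S·e‖₂ with e ≥ 0 by NNLS on the
frequency-normalized spectrum — no sparsity penalty and no signature
pre-selection, with a configurable catalog subset instead. Contributions
are reported relative (e normalized to sum 1) together with the cosine
similarity of the reconstruction, which equals 1 exactly when the spectrum
lies in the catalog's non-negative cone. The dominant biological group is
the group (clock-like SBS1/5, APOBEC SBS2/13, tobacco SBS4/92, other) with
the largest summed contribution; dominance is not otherwise defined by the
source analyses, so this summed-contribution convention is a package
decision. Ties break by fixed group order with a warning. The bundled
four-signature catalog is **synthetic**: peaked stand-ins shaped after
SBS1 (C>T at NpCpG), SBS2 (C>T at TpCpN), SBS13 (C>G at TpCpN) and a flat
SBS5-like background, each with a 10% uniform floor. It exists for tests
and simulation; real COSMIC v2/v3 TSVs are accepted as input files and are
never downloaded.

## Exact statistics

The two-sided Fisher test uses the point-probability criterion: the sum of
hypergeometric probabilities of all margin-preserving tables whose point
probability does not exceed the observed one. Probabilities are compared
with relative tolerance 1e-7 so analytically tied tables are not excluded
by floating-point noise; a zero margin returns p = 1 with a warning. This
is the convention that reproduces every verifiable published p-value in
the worked examples; the twice-one-tail alternative is not offered.
Mann–Whitney U uses the exact permutation null when the pooled sample has
≤ 20 observations and no ties, otherwise the normal approximation with tie
and continuity corrections. MAD is unscaled (no 1.4826 factor). Survival
uses the Kaplan–Meier product-limit estimator and the one-degree-of-freedom
log-rank test (via lifelines, cross-checked in the tests against hand
product-limit and O−E computations). No multiple-testing correction is
applied anywhere, matching the raw-p reporting of the study design.

## Synthetic cohort generator

The generator emulates the *structure* the analysis assumes, not raw
sequencing: per sample it draws group, sex, smoking, WGD (baseline
tetraploid with major-allele CN 2 when drawn, else diploid), whole-arm
events emitted as arm-length segments at ploidy ± 1, focal amplicons as
short segments at CN 20 (the study-scale average for EGFR amplicons),
an SNV catalog whose size follows a log-normal TMB (medians 3.20/8.45
variants/Mb) and whose channels follow the group's signature mixture, and
exponential survival with uniform censoring on 6–60 months calibrated to
24-month PFS targets of 0.56 (male) and 0.86 (female).

Default event frequencies are the study conditions: 8q gain 0.92/0.55,
whole-chr20 gain 0.62/0.09, 3p loss 0.82/0.62, 7p11 focal amplification
0.27/0.0, 11q13 focal amplification 0.23/0.82; mutation probabilities
TP53 0.85/0.82, LRP1B 0.12/0.45, NOTCH1 0.24/0.27, CDKN2A 0.23/0.36;
Y loss in 17% of young males and all old males. Where the design gives no
value, a single realistic choice was made and fixed: WGD probability
0.3 per group (WGD is common in HPV-negative head-and-neck tumors),
log-normal σ = 0.5 (matches the reported MAD/median ratios of ≈ 0.3),
signature mixtures {SBS1 .45, SBS5 .35, SBS2 .10, SBS13 .10} (young) and
{SBS2 .45, SBS13 .35, SBS1 .10, SBS5 .10} (old), male fractions 0.65/0.64
and smoking (ever/never/unknown) 0.42/0.39/0.19 and 0.91/0.09/0.

SNVs are placed by rejection-sampling reference positions whose canonical
trinucleotide context matches the drawn channel, on a toy genome generated
first with uniform base composition so every channel is reachable; mutated
gene flags are planted as missense-annotated variants inside the gene
body. The toy genome is 24 chromosomes scaled from hg38 proportions
(default: largest chromosome 5 Mb, ≈ 62 Mb total), with arms split at
approximate centromere fractions and a six-gene panel (EGFR 7p11, CCND1
11q13, TP53 17p, LRP1B 2q, NOTCH1 9q, CDKN2A 9p) placed on the correct
arms. Everything is drawn from a single seeded generator, so a fixture is
byte-identical across runs of the same config.

What the generator does **not** model: purity dilution and copy-number
estimation noise (an optional Gaussian jitter on segment CN is the only
noise knob), subclonal structure and intratumoral heterogeneity, coverage
gaps, germline contamination, realistic base composition or mutation
hotspots, and indel generation beyond planted annotations. Passing
recovery tests therefore demonstrates the correctness of the rule system
and statistics on data satisfying its assumptions, not robustness to
caller noise on real genomes.

## Problem sizes

Tests run the generator at reduced genome scales (largest chromosome
0.05–2 Mb) so a full 37-sample cohort simulates in well under a second;
scale changes only the genome length, never the per-Mb burden, event
probabilities or group sizes. `scripts/acceptance.py` uses 20 replicate
cohorts at the default 26/11 group sizes on a 2 Mb-scale genome (≈ 25 Mb),
chosen so that TMB quantization and the few planted panel variants
perturb the per-Mb burden by well under 2%. The signature
parameter-recovery check uses mixtures of ≤ 4 catalog signatures with
multinomial noise at 10,000 mutations over 20 seeds (mean absolute
contribution error < 0.05); the power check runs 100 seeded cohorts.

## Known limitations

- The gene copy number is a weighted mean, not a minimum over exons;
  focal intragenic deletions can be averaged away.
- Arm calls use rounded per-base CN and rounded ploidy; samples with
  near-half-integer ploidy sit on a rule boundary by construction.
- The exact Mann–Whitney path requires a tie-free pooled sample; TMB
  values from file inputs with repeated values fall back to the corrected
  normal approximation even at small n.
- The bundled catalog is synthetic; quantitative signature results on real
  tumors require supplying the real COSMIC TSV.
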