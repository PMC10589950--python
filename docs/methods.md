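# Methods

This note documents the models, conventions and design choices behind
`asmkit`, in the order data flows through the package.

## Locus model and coordinates

A `DiploidLocus` is one PCR amplicon over a region with exactly one
heterozygous SNP. Allele 1 is, by definition, the allele whose base appears
in the stored reference sequence; allele 2 differs only at the SNP. CpG
positions are the cytosine offsets of CpG dyads on the top strand of the
allele-1 sequence. All coordinates are 0-based half-open internally; SNP
tables and reports use 1-based positions (VCF convention); BED input keeps
its native 0-based starts.

A SNP can itself create or destroy a CpG (e.g. a C/T SNP immediately before
a G). The CpG list is defined on the allele-1 sequence; profiles for both
alleles are reported over that shared list so they stay comparable. Loci
where the SNP disrupts a CpG should declare the CpG list explicitly.

## Read simulator

The simulator emulates targeted bisulfite amplicon sequencing of a diploid
locus, per condition (untransfected / scrambled guide / specific guide):

1. Each read draws its allele (exactly `depth` reads per allele), its strand
   (original top, OT, with probability `strand_mix`; default 1.0 because
   amplicon primers fix the strand), and an independent Bernoulli
   methylation state per CpG from the truth probabilities. Per-read CpG
   states are independent — no co-methylation model is imposed.
2. The strand sequence is bisulfite converted: unmethylated cytosines read
   as T with probability `conversion_rate` (default 0.995 — a conventional
   conversion efficiency, chosen once; incomplete conversion is what the
   non-CpG QC below estimates), methylated CpG cytosines stay C with
   probability `methylated_protection` (default 0.99). The drawn CpG state
   applies to both strands of the dyad (symmetric CpG methylation; no
   hemimethylation model).
3. The SNP base comes from the allele of origin *before* conversion, so C-
   or G-containing alleles show realistic bisulfite ambiguity.
4. Uniform substitution errors (`seq_error_rate`, default 0.001) are applied
   last. Qualities are flat (Phred+33 `I`).

Single-end mode emits one full-amplicon read per fragment (the merged-read
equivalent); paired mode emits R1/R2 from opposite fragment ends with the
overlap implied by amplicon and read length. A truth table records allele,
strand and drawn states per read, keyed by read id.

The default truth template mirrors a pre-selected unmethylated promoter CGI:
untransfected ≈ 0 methylation, scrambled adds only the untargeted
methyltransferase background (~0.05–0.10), and the guide condition adds a
large on-allele gain with a configurable attenuation inside the guide
interval (the dCas9 binding footprint, which only ever *reduces* delivered
methylation).

What the simulator does **not** model: quality-score distributions, adapter
contamination, PCR duplicates and amplification bias, indels, co-methylation
correlation along reads, and genome-scale off-target reads. Passing tests on
simulated data therefore demonstrate correctness of the analysis logic under
the stated noise model, not robustness to every artefact of real libraries.

## Bisulfite quantification

Alignment is ungapped (amplicons are fixed, indel-free PCR products) and
exhaustive over offsets, performed in converted space: read C→T against the
C→T reference for OT, read G→A against the G→A reference for OB, in both
orientations. The SNP base is excluded from mismatch counting so allele-2
reads are not penalised against the allele-1 reference. The best
strand/orientation/offset wins; an exact tie between strand calls is
rejected as ambiguous (on amplicons with very few non-CpG cytosines a fully
methylated read can genuinely carry no strand information), and reads above
the mismatch threshold (default fraction 0.1) are rejected as unmapped.
Mate pairs are merged first by lowest-mismatch overlap (minimum 10 nt,
disagreements resolved by the higher base quality); merge failures fall back
to mapping read 1.

Allele assignment is bisulfite-aware: on OT reads an allele base C may be
observed as C or T; on OB reads a G as G or A; a read is assigned only if
its observed SNP base is compatible with exactly one allele. G/A SNPs read
on the OB strand (and C/T on OT) are intrinsically ambiguous and yield
`unassignable`, which is a value, not an error. Accounting is conserved:
assigned₁ + assigned₂ + unassignable + rejected = input, checked at run
time.

Methylation calling follows the usual convention: OT reads report C/T at the
CpG cytosine, OB reads G/A at the guanine. Cytosines outside CpG context
estimate the conversion-failure rate as QC. Levels are reported missing
(never 0) below a per-CpG coverage floor, default 10 reads — a repository
convention to keep downstream Δ/ratio statistics away from unstable
estimates. Base qualities are ignored in calls (the simulator emits flat
qualities); quality-aware masking is deliberately out of scope.

## ASM statistics

- **CpG selection**: threshold = 0.5 × the maximum covered level on the
  guide-treated on-target allele; all covered CpGs at or above it are
  selected, and the selection is frozen for every sample/allele of the
  locus. Optional variants: gain-based selection (subtract a baseline
  profile before thresholding) and exclusion of CpGs inside the guide
  interval. Both default off — footprint CpGs stay in the averaging.
- **Gains** are computed against the untransfected baseline; the scrambled
  condition is reported alongside as the specificity control, not
  subtracted (a `baseline_condition="scrambled"` switch exists).
- **Δ** is in percentage points; the **ratio** is reported missing (flagged)
  when the off-target gain is ≤ 0 rather than clipped or infinite. Report
  files round Δ to integer points and the ratio to one decimal; JSON output
  keeps full precision.
- **Footprint score** = mean of the nearest 3 covered flanking CpGs per side
  minus the mean inside the guide interval.
- **Stability retention** uses absolute levels (not gains) relative to day 3
  with the day-3 CpG selection frozen; a gain-based variant sits behind
  `use_gains`.
- **Outcome quadrants** use cuts Δ ≥ 25 points and ratio ≥ 3 by default —
  configurable descriptive thresholds for the scatter classification, not
  fitted quantities.

## Guide design

PAM positions are numbered N=1, G=2, G=3. A SNP at PAM position 2 or 3
yields exactly one candidate targeting the allele that reads G on the PAM
strand (the non-G allele has no PAM and cannot be targeted); the change type
is flagged, G>Y (Y = C/T) being preferred for discrimination. A SNP within
`seed_length` (default 7, configurable; seed positions are numbered from
the PAM-proximal base) of the protospacer 3' end with the PAM intact on
both alleles yields two candidates, one per allele. Risk features — ≥ 2 NGG
occurrences inside the protospacer, or a QGRS motif on either strand of the
binding site — are annotations, never filters: guides with such features can
still work, and the flags exist to explain failures.

The QGRS scan enumerates every run of four equal-length G-tracts
(length ≥ 2) within a 30-nt window and keeps a greedy non-overlapping
best-scoring set. The G-score is a QGRS-style ranking — more tetrads
dominate, then shorter motifs, then evenly sized loops
(`20·(g−2) + (30 − length) − (loopmax − loopmin)`); it reproduces the cited
tool's stated ordering principles, and only motif presence/ranking is used
downstream.

The TSS applicability scan counts (1) TSSs with ≥ 1 heterozygous SNP in the
strand-aware promoter window (default −50/+500 bp around the TSS), (2) the
fraction of in-window SNPs for which guide enumeration on a ±30 nt local
context returns ≥ 1 candidate, and (3) TSSs with ≥ 1 such suitable SNP.
Using in-window SNPs as the denominator of (2) makes the product
(1) × (2) = (3) exact whenever windows are disjoint and hold at most one SNP
each; a per-TSS variant of (2) is also reported. The same allele-discrimination
rules as locus-level design apply genome-wide, including the G-allele
requirement for PAM placements.

## Allelic expression

cDNA amplicon reads (no bisulfite) are aligned ungapped in both orientations
and counted by exact base match at the exonic SNP; N or third-allele bases
are uncounted. Fold change is computed from pooled counts per condition
(the convention when one summary ratio per sample is reported);
per-replicate proportions feed the
two-sided pooled-variance t-test. The tested quantity is the per-replicate
allele-1 proportion (a log-ratio variant sits behind a flag). Zero pooled
variance is flagged explicitly: equal means give (t=0, p=1), unequal means
(p=0 with the flag). PCR amplification bias between alleles is acknowledged
but not modelled.

The expression simulator draws replicate counts binomially around the
specified allele ratio, or beta-binomially with concentration 1/dispersion
when overdispersion across biological replicates is wanted.

## Problem sizes and numerical conventions

Simulated checks use amplicons of ~240 nt with ~12–25 CpGs, read depths of
120–1000 per allele per condition, and 2000 null simulations for t-test
calibration — sizes at which binomial sampling error is small enough for
3-SD checks while the whole suite runs in seconds. Determinism: every
stochastic routine takes an explicit seed and fixed seeds give byte-identical
outputs. Ties in alignment are broken by scan order (forward orientation,
OT space first) except strand ties, which reject; greedy QGRS selection
breaks score ties by leftmost start.

## Known limitations

Ungapped alignment cannot place reads from indel-bearing templates; the
coverage floor, outcome cuts and footprint flank count are conventions, not
fitted values; the QGRS G-score is a faithful re-ranking, not a
bit-identical reimplementation of the original web tool; and expression
analysis assumes the exonic SNP is the only variant in the amplicon.
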