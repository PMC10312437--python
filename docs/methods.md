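# Methods

## Generative models of the three assays

The simulator (`psiseq.simdata`) builds a loci-scale reference — one
1.5-kb rRNA locus, eight 76-nt tRNAs ending in CCA, 24 miRNA precursors
with 21-nt mature arms, six TE families × three ~300-nt copies on one
chromosome, a 2-kb piRNA-cluster contig, and four structural RNAs — and
plants Ψ sites with enzyme specificity:

* **PUS10** at tRNA position 55 (0-based index 54) on every tRNA;
* **PUS7** at the central U of a UNUAR motif (DNA-space `T.TA[AG]`,
  modified base = the second T) placed in half the tRNAs; accidental
  UNUAR occurrences elsewhere are scrubbed so motif flags are unambiguous;
* **DKC1** at 20 evenly spaced rRNA uridines and in the mature arm of 10
  of the 24 miRNAs;
* **OTHER** (unassigned synthases) at TE-family and piRNA-cluster sites.

Genotype switches (`pus7`, `pus10`, `dkc1`) delete exactly one enzyme
class from the truth table; `active_enzymes` restricts the truth further
for single-mechanism experiments. A species pool draws class-appropriate
fragments (miRNA mature 21 nt; 3'-CCA tRFs at every length 18–30 nt;
UNUAR-spanning internal tRFs that do not reach position 55; rRNA
fragments 18–30 nt; TE siRNAs 20–22 and 23–25 nt; piRNA-like 26–31 nt)
with log-normal abundances (σ = 1) normalized to the configured depth.

Assay mechanisms, per read:

* **Ψ-IP**: captured with probability ε_psi = 0.8 if the species spans
  ≥1 Ψ, else ε_bg = 0.05; uncaptured reads go to the unbound file, so
  bound + unbound conserve the pool draw exactly.
* **CMC RT-stop**: a read spanning k Ψ sites survives with probability
  (1−α)^k, default α = 0.8. Dropout, not truncation: the 3' adapter is
  ligated before CMC treatment, so a blocked cDNA lacks the second
  adapter and never amplifies.
* **CMC/Mn²⁺**: at each Ψ within a read, substitution with probability
  m = 0.3 (uniform non-cognate base), deletion with d = 0.1, else
  readthrough; independent across sites.

A background per-base error of 1e-3 applies everywhere (errored bases
get Q20, all others Q35, so the mouse Q20/90% filter has something to
act on). Every sample owns an RNG stream derived from (master seed,
sample name); identical configurations give byte-identical FASTQ. The
NextFlex dialect adds 4 random nucleotides to both insert ends; NEB adds
none. Not simulated: ligation bias, PCR duplicates, UMI collisions.

## Preprocessing and alignment

Trimming removes the longest read suffix matching an adapter prefix
(min overlap 6; one mismatch tolerated at overlap ≥10), then strips the
NextFlex 4N ends. Length presets per analysis arm: rRNA 15–30, TE
18–30, miRNA/siRNA 20–25, Mn²⁺ 18–42, mouse 14–44 with the Q20-over-90%
rule. Collapsing feeds unique sequences with multiplicities downstream;
all pileups and count matrices are weighted by collapsed counts.

The aligner is an exact k-mer index plus banded verification allowing
substitutions (≤3) and reference deletions (≤2; insertions are not part
of the Mn²⁺ chemistry and are not modeled). Provided
k ≤ (L − max_mm)/(max_mm + max_del + 1) the pigeonhole principle makes
the indexed search complete, and a brute-force scanner is kept as the
test oracle — the two are asserted identical on random reads. Leading
and trailing deletions are canonicalised away. Multimap policies: `all`
(every placement within policy, edit-minimal tier first), `unique_only`
(drop reads ambiguous at the best tier), `best_random` (seeded draw).
Position-level pileups use `unique_only`: it is the natural reading of a
one-placement-per-read metaplot mode, and secondary, worse-tier
placements would otherwise pollute mismatch profiles.

## The enrichment engine

Counts K_ij follow NB(mu_ij, alpha_i) with
log mu_ij = log s_j + x_j'beta_i; the design holds an intercept, pair
indicators and the treatment indicator. Size factors s_j are
median-of-ratios over features nonzero in all samples, rescaled to
geometric mean 1 (total-count fallback with a warning). Features enter
testing only above the mean-raw-count filter (strictly >10 by default;
piRNA-cluster mode uses ≥100 over the IP-arm samples) and excluded
features never enter the BH denominator.

Dispersion is estimated per feature by a degrees-of-freedom-corrected
Pearson method of moments after a Poisson fit, then shrunk 50/50 toward
a lowess trend over the mean — a deliberate simplification of full
empirical-Bayes dispersion machinery. Three numerical choices matter for
calibration and were chosen to keep the estimator unbiased:

* non-positive MoM values (features at or below the Poisson floor) are
  kept when fitting the trend — conditioning on positivity selects
  upward-biased noise — but fall back to the trend for testing;
* the trend is fitted in linear space with plain local regression
  (`it=0`); robustifying iterations trim the right-skewed MoM
  distribution and bias the trend low;
* the 50/50 average is arithmetic; the geometric mean of a chi²-like
  estimator is biased low.

Under the generator's own sampling model (multinomial library draws
from one pool, 1000 features, 3 pairs) the Wald p-values are calibrated
(p<0.05 fraction within the binomial 99% band). A known limitation:
with strong true extra-Poisson dispersion (alpha ≥ 0.05) and only three
pairs, the 50/50 weight on a 2-df point estimate leaves the test
anticonservative (~0.10–0.15 at nominal 0.05); stronger trend weighting
or full empirical-Bayes shrinkage would be needed there. The reported
log2FC uses a 0.5 normalized-count pseudocount on both sides (finite by
construction); the Wald statistic comes from the GLM coefficient. A
per-pair log-ratio t-test is available as a cross-check mode, and the
GLM coefficients are cross-checked against an independent reference NB
implementation in the test suite.

## Position-level evidence and the Mn²⁺ caller

Coverage is normalized to the total over the locus; paired log2FC
tracks (pseudocount 1e-6) are averaged across technical replicates and
summarized in metaplots (window 25, smoothing 6 for TE analysis; 50/12
for the wider regulatory-region setting), site at offset 0, edge
windows truncated and counted.

The Mn²⁺ caller evaluates every position with treated coverage ≥5:
treated event ratio (mismatch+deletion)/total against the mock ratio
with a (events+0.5)/(total+1) pseudocount (the mock may be clean), and
calls positions with fold change ≥1.5, boundary inclusive. Mismatches
and deletions are pooled (the chemistry produces both) but tallied
separately. Two readings of the published per-miRNA criterion are
provided: per-position calls and a per-feature maximum. Runs of
adjacent passed calls are collapsed to the best-supported position:
a deletion cannot be localized within a homopolymer (removing either T
of TT yields the same read), so deletion evidence from a Ψ in TT
context splits across neighbours; mismatch evidence localizes exactly
and dominates the argmax.

Site-caller validation is mechanism-isolated: a fragment pool tiling
the rRNA locus (24-mers, step 3) at 1e5 reads puts ≥500× on every
planted site, and the background error is set to zero so the m/d rates
are the only mutation source. In that regime all planted sites are
recovered, no non-Ψ uridine is called, and the m=d=0 control yields
zero calls. With background sequencing error the plain ratio rule needs
either much higher depth (the mock ratio must be estimated precisely
enough that 1.5-fold noise excursions are rare, roughly depth ≫ 1/e)
or an error-aware threshold; at 500× and e=1e-3 it would fire on
Poisson noise at a few percent of positions.

## Feature classification

tRFs anchor on the parent tRNA: start at position 1 → 5'-tRF, end at
the 3' terminus → 3'-tRF (CCA flag), else internal. `spans_psi55` is
computed from the alignment span covering index 54; on standard 76-nt
tRNAs this equals the length ≥22 shortcut for 3'-CCA tRFs, and the two
independent code paths are asserted to agree. TE aggregation counts a
read once per family regardless of how many copies it hits (1/n
fractional mode behind a flag); size classes are closed intervals
[20,22] and [23,25], piRNA size window [26,32]. Repeat categorization is
priority-ordered transposon → structural → neither, with piRNA-cluster
membership by ≥1 bp overlap. Terminal nucleotide bias excludes
structural-RNA-derived sequences (enforced) and reports per-end base
frequencies in RNA space with log2 enrichment over a background set.
AGO preference is the argmax of IP/input enrichment per (family, size
class); ties break lexicographically and are flagged.

## Problem sizes and determinism

Validation simulations use 1e5–2e5 reads per library and three pairs —
about 290 species at ~400–700 reads each, which puts every planted
effect (capture odds 0.8 vs 0.05; survival 0.2 or 0.1) far from the
detection boundary while keeping a full multi-arm run in seconds.
Acceptance-style runs are deterministic given the seed; every output
table carries the analytic-config hash in a header comment. The
synthetic pool has no isomiR heterogeneity, no ligation or PCR bias,
and abundance variation only at the species level, so passing tests
demonstrate correctness of the inference machinery under the stated
mechanisms — not robustness to every artifact of real libraries.
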