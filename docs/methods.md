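# Methods

## The cis/trans model

Let a gene carry a coding SNP with allele *a* fixed in one population and
allele *b* in the other. Write the transcript ratio in an F1 heterozygote as
R_F1 = n_a/n_b and in an equal-mass parental cDNA mix as R_mix. Because both
alleles of an F1 share one trans-acting environment, E[log R_F1] isolates the
cis component; the mix, pooling transcripts produced in the two separate
parental trans environments, measures the total difference. We define

- cis = mean log R_F1,
- total = mean log R_mix,
- trans = total − cis (additivity is exact by construction),
- percent cis = 100·cis/total (undefined and flagged when |total| ≤ 1e−9).

Log ratios are natural logs internally; proportions (n_b/(n_a+n_b)) are kept
alongside for reporting. A pseudocount of 0.5 is added to both counts only
when one of them is zero; at the depths this design targets (≥ 2×10⁴ reads
per SNP) it never triggers.

### Statistical contrasts

The design is population pairs × cross types (two reciprocal F1 directions
and the mix) × replicates. Instead of a mixed model with pair as a random
factor we use a declared two-stage procedure: (i) average log ratios within
each pair × cross-type cell; (ii) contrast cell means — a one-sample t
against 0 for cis (df = number of cells − 1) and a Welch two-sample t of mix
vs F1 cells for trans. For balanced designs the point estimates equal the
mixed-model ones; the df convention is ours and is stated with every result.
Both F1 directions are pooled in the cis contrast, but per-direction means
are always reported so parent-of-origin asymmetry remains visible.

Degenerate inputs are handled explicitly: all cell means identical at zero
reports "no deviation" (t = 0, p = 1); identical but nonzero cell means
report t = ±inf, p = 0 (directionally informative, no variance estimate).
Fewer than two cells is an error, not a silent p.

### Hemizygous-male check

For an X-linked gene, males express only the maternal allele, so each F1
direction should track its maternal parent if the difference is encoded on
the X. We place each F1 group's mean expression on the parent–parent axis,
s = (F1 − paternal)/(maternal − paternal), and classify maternal-like
(s > 0.75), paternal-like (s < 0.25) or intermediate; thresholds are
configurable and the raw s is always returned. Equal parental means make the
axis undefined (error). Note the check cannot distinguish X-linked cis from
X-linked trans; it is a consistency test, not a proof.

## Amplicon counting and QC

Reads are assigned to genes by the first k bases (anchor, default k = 20):
a read goes to the template whose anchor is at uniquely minimal Hamming
distance ≤ 2 from its prefix; ties and non-matches are unassigned. This is a
deterministic, auditable convention for amplicon pools, not an aligner — no
indels, no quality weighting (constant-quality synthetic reads; at ≥ 2×10⁴×
depth per-read quality is immaterial to a ratio statistic).

Parental fixation at the diagnostic SNP is verified on gDNA amplicons: the
opposite-allele frequency is compared with the lowest non-zero frequency
possible in a pool of n diploids, 1/(2n) (e.g. 7.1% for n = 7); below it,
"wrong" alleles are attributed to sequencing error and the population is
called fixed. The depth filter defaults to 1,000 for synthetic work and is
configurable upward for real pools.

## qPCR relative expression

log2 relative expression of a gene of interest (GOI) against reference genes
is

    log2[ (E_GOI+1)^(−Ct_GOI) / GeoMean_refs (E_ref+1)^(−Ct_ref) ]

with primer efficiency E ∈ (0,1] (amplification factor E+1; a validator
flags E > 1 with a conversion hint, since percent and factor encodings are
common). Everything is computed in log space — the geometric mean becomes an
arithmetic mean of Ct_ref·log2(E_ref+1) — avoiding underflow of
(E+1)^(−Ct) at Ct ≈ 20–35. Technical replicates are collapsed by median
first; if several measurements of the GOI remain within a sample, their
arithmetic mean is taken (the scope of that outer mean is ambiguous in
common write-ups of this formula; we state ours: mean over whatever multiple
measurements remain per sample, identity otherwise).

The plate simulator is the generative inverse: a template at 2^x times the
reference abundance crosses the detection threshold after (baseline − x)
doublings, and a primer with efficiency E needs 1/log2(E+1) cycles per
doubling, so Ct = (baseline_ct − x)/log2(E+1) + N(0, σ). This is the unique
form for which the expression formula recovers x exactly at zero noise for
*any* combination of per-gene efficiencies (at E = 1 it reduces to the
familiar baseline − x).

Group contrasts are two-stage (replicates averaged per biological unit —
population or bottle — then Welch t on unit means), mirroring a
unit-random-effect model without the machinery. Multiple-testing adjustment
is Holm step-down, delegated to statsmodels behind `holm_adjust`.

## Variant prioritization

The population is the unit of correlation: replicate expression measurements
are averaged per population before Pearson r between per-population
alternate-allele frequency and expression (≥ 3 populations, non-constant
vectors required; two-sided p from the t transform). "(Nearly) fixed" is
operationalized at alt frequency ≥ 0.95 / ≤ 0.05, configurable and reported
with raw frequencies. Polarization calls an allele ancestral when it is at
frequency ≥ 0.99 in an ancestral-range panel; an outgroup base is reported
as concordant/discordant independent support, and a polymorphic panel with
no usable outgroup is "unresolved" rather than an error. The two-site
haplotype check tabulates (ancestral/derived) × (ancestral/derived) calls
per sequence; exclusivity — both derived alleles present in the panel but
never on the same sequence — is the signature of independent origins.

## Motif disruption

A query window of 2·flank+1 bases (default 21 bp) is cut around the
candidate SNP, reverse complemented when the gene lies on the minus strand,
and scanned with a PWM as summed log2 odds against a background (uniform by
default) at every offset; probabilities are pseudocount-regularized
((p+c)/(1+4c), c = 0.01). Ambiguous bases score at background and are
flagged. `substitution_effect` rescored the window with the center base
replaced (alt given on the plus strand, complemented for minus-strand
windows): the verdict is **lost** when the alternate best score falls below
60% of the matrix's maximum attainable score, **retained** when
|Δscore| ≤ 0.25 bits, else **weakened**. No numeric criterion for "complete
loss" of a binding site exists in the literature, so both thresholds are
configurable and echoed in every result. The shipped JASPAR fixture
(`adf1_like_synthetic.jaspar`) is a synthetic GC-rich toy matrix for tests
and demos, not a real transcription-factor model; a genuine JASPAR PFM can
be supplied wherever the fixture is used.

## Life history

Per bottle: survival = eclosed/eggs (eclosed > eggs is a hard data-integrity
error); developmental time is the eclosion-count-weighted mean day,
optionally on the inverse scale (1/day), with the bottle as the unit of the
group SE; growth rate = ln(W/egg weight)/(eclosion day − offset) with
defaults egg weight 5 µg and offset 5 days (embryogenesis + metamorphosis),
strictly decreasing in day and increasing in weight. The weight-vs-time
contrast fits cohort weight ~ day + day² + genotype by OLS (shared
curvature, additive genotype offset; day centered to decorrelate the
polynomial terms), dropping the quadratic with a flag when a genotype has
fewer than 3 distinct eclosion days. An optional, logged studentized-residual
filter (|r| > 3) is available. Mixed models with bottle random effects are
deliberately replaced by these bottle-level summaries: identical point
estimates in balanced designs, far simpler to audit. Bottles with zero
eclosion enter survival but are excluded (with a warning) from
developmental-time summaries.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume:

- **Reads** — single merged full-length amplicons (the targeted amplicons of
  150–300 nt are fully spanned by 2×250 paired-end sequencing, so merging is
  lossless for the ratio statistic); the SNP base is allele *a* with
  probability `true_prop_a` (Binomial over the pool); sequencing error is an
  independent uniform per-base miscall to each of the other three bases, so
  the expected wrong-allele rate at the SNP is ε/3; constant Phred symbol;
  no indels, adapters, primer artifacts, PCR duplicates or per-cycle error
  profiles. Defaults target depth ≥ 2×10⁴ and ε in the 0.1–1% range
  observed as wrong-allele calls in deep amplicon pools.
- **Ct plates** — per-gene efficiencies, Gaussian cycle noise, exact
  inversion at zero noise (see above). No melt curves or plate effects.
- **Population panels** — expression as a noisy linear function of allele
  frequency across 12 populations (ten fixed at 0/1, two intermediate in the
  canonical test shape).
- **Life-history tables** — bottles of 200 eggs, Binomial eclosion, rounded
  Gaussian eclosion days (clipped at day 6, the biological minimum), per-day
  cohort weights linear in day. Real data add overdispersion between
  bottles, diet×genotype interactions and sexing error, none of which is
  modelled.

Consequently, passing tests demonstrate correctness of the estimators and
their calibration under the assumed sampling models — binomial read
sampling, Gaussian Ct noise — not robustness to artifacts these generators
do not produce (index hopping, reference bias, plate effects, bottle
overdispersion).

Every generator draws from one `numpy` Generator seeded per call; identical
configs and seeds give byte-identical outputs. Where the design needs many
per-sample streams, child seeds are drawn from the top-level generator.

## Problem sizes and numerical choices

The bundled checks use the design the method targets: 3 population pairs ×
2 cross directions × 4 replicates at depth 20,000 (read-level for the cis
recovery check; count-level Binomial draws — the exact distribution the read
pipeline induces at zero error — for the 200-run trans-power and 1,000-run
type-I Monte-Carlo loops). Tolerances in tests are 3·SE under the relevant
sampling distribution unless an exact identity is asserted (additivity,
round trips, oracle agreement at 1e−12). Ties in read assignment go to
"unassigned"; percent-cis is flagged undefined below |total| = 1e−9; Holm
output is capped at 1 and returned in input order.

## Known limitations

- The two-stage contrasts match mixed-model point estimates only in balanced
  designs; with heavy imbalance the df convention (cells − 1) is
  conservative relative to a fitted random-effects model.
- One diagnostic SNP per amplicon: multi-SNP phasing within an amplicon is
  out of scope (when an amplicon carries several SNPs, pick one).
- The maternal-allele check cannot separate X-linked cis from X-linked
  trans effects.
- The motif "loss" verdict is a relative-score heuristic, not a binding
  free-energy prediction.
- No genome-wide ASE (reference-bias correction, alignment filtering) —
  this package targets designed amplicons at known SNPs.
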