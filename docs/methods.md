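# Methods

This document records the statistical model, the synthetic-data generator,
parameter defaults with their rationale, numerical conventions, and known
limitations. Every number quoted here is computed by the code in this
repository; nothing is an external empirical claim.

## PTM regions and zones

A PTM region is the union of ±7-residue windows around modified residues of
one protein, clipped to the sequence and merged when windows overlap; merged
regions are maximal, disjoint and sorted. Within a region each residue gets
a zone by distance to the nearest modified residue: `DI` (distance 0,
directly modified), `N1` (1–2), `N2` (3–7); and a cluster level equal to the
number of modified residues within ±7, capped at 5. The ±7 window reflects
the length of linear motifs that modification enzymes and reader domains
recognise; the cap keeps cluster levels interpretable in dense regions.

## Variant annotation

Gene models are single-exon CDS strings (codon *k* encodes residue *k*).
Single-nucleotide variants are mapped to codons and classified synonymous /
non-synonymous by translating the edited codon; indels, out-of-CDS
positions, reference mismatches, stop gains and zero-frequency records are
rejected with a named reason. When several non-synonymous substitutions hit
one codon, all of them are dropped (the joint protein change is ambiguous).
"Rare" means derived allele frequency ≤ `rare_daf` (default 0.005,
inclusive), the conventional rare-variant cut-off at which purifying
selection dominates allele-frequency differences.

Per-variant covariates: GC content over a ±17-base window (a 35-base
context, the scale at which composition affects mutation and calling),
codon degeneracy of the reference residue, a BLOSUM-based conservation
score with gap score −10, disorder flag, distance-interpolated
recombination rate (ties to the lower coordinate), and read depth when the
cohort provides it.

## Selection statistics

**Fractional site counting.** Each codon contributes 1/3 synonymous or
non-synonymous site per possible single-nucleotide edit according to the
translated effect; edits creating stop codons are excluded from both
classes. Ka/Ks is (non-synonymous counts / non-synonymous sites) /
(synonymous counts / synonymous sites), undefined (NaN, flagged) when a
denominator is empty.

**Variation matching.** Proteins are ranked by observed substitutions per
residue and split into `n_bins` near-equal bins (default 100; the demo uses
50 because its cohort is small). Within each bin the rare fraction (and
Ka/Ks) is computed separately for PTM-region and non-region substitutions,
and the paired difference across bins is tested with a one-sided Wilcoxon
signed-rank test. Zero differences and missing bins are uninformative and
dropped; with < 6 informative pairs no p-value is produced (a warning is
raised); the exact null distribution is used up to 25 untied pairs,
otherwise the normal approximation with continuity correction. Pairing on
variation-matched bins removes the dominant confounder (overall variant
density) without modelling it.

**Confounder model.** On non-synonymous substitutions only, a binomial
logistic regression of `is_rare` on standardised continuous covariates
(variation rate, GC, conservation, recombination, depth when present), the
disorder flag, and interactions up to `interaction_order` (default 2). The
PTM-region flag is added to the null model and scored with a
likelihood-ratio test (Δdeviance ~ χ², df = number of added terms).
Backward selection minimises AIC while respecting marginality (a main
effect is never dropped while one of its interactions remains). Deviance
ranking refits the model leaving one term group out at a time, giving each
factor's share of explained deviance.

## Permutation tests

Disease burden on a residue set (e.g. all `N2` residues) is compared to
random residue sets drawn from a background universe with exactly matched
amino-acid composition (per amino acid, sampling without replacement), so
compositional biases of modified residues cannot create spurious
enrichment. The statistic is the rare fraction (or any user statistic) over
the sampled set; the p-value uses the add-one estimator
(1 + #{null ≥ observed}) / (n_perm + 1), which is never zero and is valid
for finite permutation counts. Default `n_perm` 1000 gives a minimum
attainable p of ~1e-3, appropriate for the screen-level FDR defaults.

## Kinase motifs and breakers

PWMs are 15×20 probability matrices (columns sum to 1) scored in log10
after adding pseudocount 1e-6 and renormalising; terminus padding scores a
column's mean probability (neutral). Binding thresholds are calibrated from
control windows: a site is predicted bound when its score reaches
max(10th percentile of positives, 90th percentile of negatives) — type-7
linear-interpolation quantiles, the numpy default. A flank residue of a
bound site is a motif breaker when substituting it can lose ≥ 4-fold
binding score; because other columns cancel, the fold change is exactly the
ratio of pseudocounted column probabilities, so uninformative (uniform)
columns can never produce breakers.

## Hotspot model

Per gene, disease mutation counts per residue are regressed on the disorder
flag with a Poisson GLM (intercept-only mean as fallback on
non-convergence, flagged). Each PTM region's p-value is the exact Poisson
upper tail of its observed record total against the summed fitted
expectation, inclusive of the observed value; zero-mutation regions score
p = 1. Region p-values combine to a gene p by Fisher's method, and genes
are corrected with Benjamini–Hochberg. The exact inclusive tail makes
region and gene p-values discretely conservative at low expected counts —
they are stochastically larger than uniform under the null, which is the
safe direction for discovery.

## Synthetic cohort generator

The generator is the package's ground-truth instrument: every planted
parameter is recorded in `cohort.truth` so recovery can be tested.

| Parameter | Default | Rationale |
|---|---|---|
| `n_proteins` | 300 | smallest cohort where 100-bin matching is meaningful |
| `length_dist` | (400, 120) | typical protein length scale; minimum 60 |
| `aa_freqs` | human-like table | realistic codon/amino-acid composition |
| `ptm_site_rate` | 2 per 100 residues | order of magnitude of curated site density |
| `ptm_type_mix` | .72/.12/.10/.06 | phospho-dominated, as in curated databases |
| `disorder_fraction` | 0.35 | share of disordered residues in proteomes |
| `disorder_ptm_odds` | 2.0 | modification sites favour disordered segments |
| `variant_rate` | 0.06 per residue | sequencing-cohort missense density scale |
| `rare_fraction_base` | 0.6 | rare variants dominate deep cohorts |
| `ptm_constraint_effect` | 1.5 | planted odds multiplier on rare inside regions |
| `disease_rate_base` | 0.01 | sparse per-residue disease annotation |
| `disease_ptm_effect` | 1.5 | planted disease enrichment inside regions |
| `n_pwms`, `pwm_sharpness` | 6, 0.8 | few sharp motifs; consensus columns at 0.8 |

Mechanics: protein sequences are drawn residue-wise from `aa_freqs`, CDSs
by choosing uniformly among each residue's codons, PTM sites by a
disorder-weighted Bernoulli over eligible residues (S/T/Y for
phosphorylation, K for ubiquitination/acetylation/methylation), and
variants by editing CDS positions at `variant_rate`. The **only** planted
selection signal is a logit shift of log(`ptm_constraint_effect`) on the
rare-classification probability of non-synonymous in-region variants:
Ka/Ks is null by design under defaults, so the Ka/Ks machinery is validated
for correctness, not for planted-effect recovery. Disease annotations get
an analogous logit shift of log(`disease_ptm_effect`). `plant_motif_breakers`
rewrites chosen phosphosite windows to a PWM's consensus (updating the CDS
consistently and dropping variants in the window) and records the planted
positions.

## Numerical and determinism conventions

- All randomness flows through `numpy.random.default_rng(seed)`; seeds are
  plain integers < 2³¹. No use of Python's `random`, no reliance on
  set/dict iteration order anywhere RNG draws occur (string sets are sorted
  before iteration — unsorted iteration order varies across processes with
  hash randomisation and would break byte-level reproducibility).
- TSV outputs are written with `%.10g` floats and `# key: value` metadata
  headers including a 12-hex-digit configuration hash; identical
  configuration and seed reproduce identical bytes.
- Exact tests delegate to scipy (`fisher_exact`, `poisson.sf`, `binomtest`,
  `wilcoxon`); BH-FDR uses statsmodels. The acceptance suite checks these
  package-level outputs against independent rational-arithmetic
  enumerations to 1e-10.
- Robust z-scores for tissue expression use (x − median)/(1.4826 × MAD)
  within each tissue across genes; genes with zero MAD across tissues
  (constant expression) are excluded; a protein is "ubiquitous" when high
  (z ≥ 2) in ≥ 18 tissues and is removed from tissue-specific sets.

## Limitations

- Gene models are single-exon and strand-agnostic; no splice forms, no
  codon-position mutation-rate asymmetry, no CpG effects.
- The generator draws sites and variants independently given the planted
  effects; real clustering of variants and sites is not emulated beyond the
  disorder preference.
- Discrete exact tails (Poisson, Fisher, binomial) are conservative at
  small counts; hotspot gene p-values are only approximately uniform under
  the null unless expected counts are large.
- PWM scoring assumes column independence, and breaker fold changes ignore
  the (separately handled) substitution of the modified residue itself.
- The drug–disease network is a deterministic relational join; it performs
  no statistical scoring beyond path counting.
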