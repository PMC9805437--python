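# Methods

## Fitness model

The assay follows a pooled barcoded-transposon mutant library of a focal
species through growth in 8 community compositions (growth alone plus every
subset of three partner species), in biological triplicate, with a shared
pre-growth (T0) sample.  Strain fitness is a compositional log-ratio
statistic,

    w(strain, sample) = log2((n_end + c) / N_end) − log2((n_T0 + c) / N_T0),

with pseudocount c = 0.5 guarding zero counts and N the full-pool column
totals (intergenic strains included, totals taken before filtering).  The
statistic is invariant under sequencing depth, monotone in the endpoint/T0
ratio, and — because growth enters multiplicatively on counts — equals the
strain's log2 growth advantage in expectation.

Raw values are re-centred per sample by subtracting the mean raw fitness of
the strains of a configurable reference-gene set (default glgP, acnA, modE,
leuA), making "neutral" the zero point of every sample.  Normalization is
location-only: within-sample differences are untouched.  Means, not medians,
are used for the reference centre; the post-condition (reference strains
average exactly zero per sample) is asserted in tests.

Strains enter a condition when gene-assigned, centrally inserted
(gene_fraction in [0.10, 0.90]) and covered by at least `t0_min` = 3 reads
in every relevant T0 sample.  The T0 threshold is configurable because the
community of practice uses values between 3 and ~30 depending on depth.
T0 matching prefers condition- and replicate-specific T0 samples when the
metadata provides them and falls back to the pooled (shared) T0 otherwise,
so both shared-T0 and per-assay-T0 designs are supported.  Gene fitness per
condition and replicate is the unweighted mean over the gene's retained
strains (a T0-count-weighted mean is available behind a flag); genes with no
retained strain in a condition are dropped and listed in a drop log, never
imputed.

Replicate concordance is summarised as the pairwise Pearson correlation of
gene fitness between replicates within each condition.  It is reported for
QC only and never used to drop data.

## Interaction fitness effects

The IFE of a gene in an interactive condition is the difference of gene
fitness means between that condition and growth alone, computed over the
per-replicate gene values (3 vs 3 by default).  Testing uses a variance
pre-check: a two-sided F-test at `var_alpha` = 0.05; if equality is not
rejected, a pooled-variance two-sample t-test (df = n₁+n₂−2), otherwise
Welch's t-test with Welch–Satterthwaite df.  Degenerate inputs (zero
variance in both groups) return p = 1 when means agree and p = 0 otherwise.

Benjamini–Hochberg correction is applied per interactive condition (7
families), matching the experiment's logic of one comparison family per
condition; a single global family is available via configuration.  Calls
use adjusted p ≤ `alpha_ife` = 0.1, signed by the IFE; a zero IFE passing
the threshold keeps sign "none".

## Transition set logic

Significant-IFE gene sets per condition feed exact set algebra:

* 2→3: a 2-species interaction gene is *maintained* when significant in at
  least one 3-species condition containing one of its 2-species partners,
  *dropped* when absent from every 3-species condition, and *unclassified*
  when it reappears only in unrelated 3-species conditions (the two
  published definitions are asymmetric and leave this gap; we surface it
  rather than forcing a label).  Genes first significant at the 3-species
  level are *emerging*.
* 3→4: maintained iff also significant in the single 4-species condition,
  else dropped; genes significant only at the 4-species level are emerging.
  A gene significant at 2- and 4-species but never at 3-species fits
  neither definition and is likewise reported unclassified.
* Provenance of the 4-species set: *from_2_species* requires the full
  2→3→4 conservation chain; *from_3_species* a 3-species occurrence
  without such a chain; *four_species_specific* otherwise.  A chain-free
  variant (any 2-species occurrence counts) is available behind a flag.

Set membership ignores the sign of the IFE by default (a gene flipping sign
still counts as present); sign-restricted sets are available.  Report
percentages are rounded half away from zero, with exact fractions retained
in the machine output.

## Epistasis decomposition

Community compositions are coded as presence/absence bit triples over the
partners in fixed (Gc, Ha, Pc) order; growth alone is 000, the full
community 111.  Per gene, the 8 condition means form a complete
genotype–phenotype map, and the local (biochemical) epistasis expansion

    f(x) = f0 + Σ βi xi + Σ εij xi xj + ε123 x1 x2 x3

is solved in closed form by inclusion–exclusion — the system is square, so
the decomposition is exact (reconstruction to machine precision, verified
against an 8×8 linear solve).  βi equals the 2-species IFE of partner i,
εij the deviation of the two-partner IFE from the sum of its parts, ε123
the residual of the full community beyond all lower-order terms; the
observed 111 phenotype minus the order-2 truncated prediction equals ε123
identically.

Significance uses parametric pseudoreplicates: each composition's phenotype
is redrawn B = 7000 times from N(mean, sem²) with sem = sd/√n (the model
consumes condition means; resampling at sd instead is available), the
decomposition recomputed, and the two-sided empirical p per coefficient
read off the resampled sign distribution with an add-one correction
(smallest attainable p is 1/(B+1), so p is never zero).  BH correction
pools all coefficients of all genes in a run into one family.  Categories
at α = 0.01: *additive* (no εij nor ε123), *eps3_only*, *eps2_only*,
*eps2_and_eps3*.

Because the plug-in sem from 3 replicates is treated as known, the raw
empirical p is mildly liberal under the null (roughly the t-versus-z
effect at ~16 effective degrees of freedom; measured ≈0.09 at nominal
0.05).  Downstream calls are made at BH-adjusted p ≤ 0.01, where the
measured false-call rate on 500 simulated null genes is 0 — the stringent
threshold plus the discreteness of the empirical p (minimum 1/(B+1))
absorbs the liberality.

A quadratic scale diagnostic (fit observed = a + b·pred + c·pred² across
pooled genotypes, bootstrap percentile interval on c) checks for global
nonlinearity that would distort an additive decomposition; data are flagged
nonlinear only when the interval excludes zero beyond numerical tolerance.

The identical machinery runs on community-level growth, with the phenotype
the mean final CFU count per composition on the raw scale (a log10 option
exists, off by default, since multiplicative growth arguably demands it).

## Synthetic assays

The simulator emulates the real experiment's structure: Poisson(16) strains
per gene (minimum 1), insertion positions uniform on (0,1) so ≈20% exercise
the centrality filter, ~15% intergenic strains, neutral reference-gene
strains, 3 replicates of 8 conditions sharing one T0 sample, and 2×10⁶
multinomial reads per sample.  Gene surfaces are planted in the
local-epistasis parameterisation, class by class: null (30%), additive
pairwise-only (25%), pairwise epistasis (15%), third-order epistasis (10%),
both (10%), and a conserved additive chain with equal same-sign βs (10%).
Effects are drawn from the grid {0.5, 1.0, 1.5} log2 units with random
signs — 0.5 sits near 7 standard errors of an IFE at the default noise, so
the grid spans comfortably detectable to saturated effects; baseline
fitness f0 ~ N(0, 0.3).

Noise has two additive log2-scale layers: per-strain offsets (sd 0.25,
reflecting insertion-position and barcode-efficiency idiosyncrasy) and
per-gene-per-replicate offsets (sd 0.05, biological replicate variation).
With ~13 retained strains per gene this yields a per-replicate gene-fitness
sd near 0.09 and replicate Pearson correlations around 0.9 — the same
order as well-replicated real assays.  Endpoint strain weights multiply the
T0 share by 2^(surface + noise), so the planted surface equals the
recovered fitness statistic in expectation (identity-calibrated recovery,
no correction factor).

The truth table records, besides the planted coefficients, analytic
expected significance per condition via the noncentral-t power formula at
the configured noise (expected significant when power ≥ 0.9 at α = 0.05),
expected transition statuses and provenance (by running the exact set logic
on the analytic calls), and the expected additivity category (from the
planted nonzero-ε pattern).

What the simulator does **not** model: chromosome-position effects,
strain-level outliers and essential-gene depletion, PCR/amplification
overdispersion beyond multinomial (a negative-binomial depth option is the
natural extension), condition-dependent library bottlenecks, and any
mechanistic community dynamics — it plants statistical structure, not
ecology.  Passing recovery tests therefore demonstrate the statistical
machinery is correct and calibrated for the assumed noise model, not that
real assays meet those assumptions.

## Problem sizes and numerical choices

The default simulated study is 200 genes (≈3,400 gene-assigned strains plus
references and intergenics) at depth 2×10⁶ — large enough that counting
noise is subdominant, small enough that the full pipeline runs in seconds.
Calibration checks use 500 null-only genes; pseudoreplicate counts are
B = 7000 for inference and B = 500 for null-rate checks.  Reconstruction
and oracle agreement are asserted at 1e-12; reference-centreing at 1e-9.
Tie handling: pseudoreplicate sign counts include zeros on both sides
(conservative); BH uses the standard step-up with capping at 1;
percentages round half away from zero.  A single user seed drives every
stage through independent substreams (seeded per stage), so changing B
does not perturb the simulated data and identical seeds give byte-identical
artifact directories.

## Known limitations

* The t-test operates on 3-replicate groups; its power and the F-test
  pre-check are crude at this sample size (by design, matching the assay).
* The pseudoreplicate empirical p ignores sd-estimation uncertainty (see
  above); interpret raw empirical p near the threshold cautiously.
* The 2→3 "associated condition" logic follows the published asymmetric
  definitions; the unclassified category quantifies the genes they cannot
  place.
* Growth-mode epistasis on raw CFUs inherits the scale sensitivity of any
  additive decomposition of multiplicative data; use the log10 option when
  fold-changes span decades.
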