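# Methods

## Process model

The simulator tracks integer molecule counts per fragment identity
(locus, parent allele, stutter level, fragment length in bp) through six
stages: `sampled → extracted → aliquoted → amplified → degraded →
injected`. All physics keys off fragment length; allele designations
are opaque labels.

**Cell sampling.** A fixed mode deposits exactly the target number of
cells; a Poisson mode draws the cell count from Poisson(target), the
natural model for crime stains whose mean DNA amount corresponds to a
fractional number of cells. Each diploid cell contributes one copy of
every allele at every locus. Haploid cells carry one allele per locus,
chosen with probability ½ independently per cell and locus, so the
split of *n* cells over a heterozygote is Binomial(*n*, ½). Homozygous
diploid loci pool both copies into a single fragment identity, matching
what an EPG shows.

**Transfers.** Extraction, PCR aliquot and CE aliquot are binomial
thinnings with probabilities *ex*<sub>e</sub>, *pcr*<sub>a</sub>,
*ce*<sub>a</sub>: every molecule survives independently. This is the
entire content of the "loss" steps — no volume bookkeeping is needed
beyond the survival probability.

**PCR.** Per cycle, each template independently produces a correct copy
with probability *pcr*<sub>e</sub>·(1 − *stutter*<sub>p</sub>), a
stutter copy one repeat unit shorter with probability
*pcr*<sub>e</sub>·*stutter*<sub>p</sub>, and nothing otherwise (a
multinomial selection). Efficiency is constant across cycles — a good
approximation for low-template STR work, where the plateau phase is not
reached; plateau kinetics and sequence-specific inhibition are out of
scope. Stutter products are themselves templates and may stutter again
(two repeats down); no special case forbids it, though at the default
*stutter*<sub>p</sub> = 0.005 the double-stutter mass is negligible.
Reduced amplification of inhibited or degraded templates is modelled
through *pcr*<sub>e</sub> and the degradation parameter jointly.

**Degradation.** Each fragment of length *x* survives with probability
(1 − *P(deg)*)<sup>*x*</sup>; stutter fragments use their own, shorter
length. The thinning is applied *after* amplification
(N_intact = Bin(N_molecules, P(intact)) on the post-PCR counts), which
is the convention this model family defines, even though cleavage
physically precedes PCR; a pre-PCR placement is available
(`degrade_pre_pcr=True`) but off by default. The two placements agree
in expectation up to the branching factor, and the post-PCR form is
what the closed-form drop-out reasoning assumes.

**CE detection.** The injected counts are pooled per (locus, fragment
length) — a stutter that co-migrates with a true allele merges into
that allele's peak. Identity mode reports height = molecule count with
a zero trigger threshold; every molecule-level study below uses it.
Calibrated mode models the instrument with two log-log linear maps: a
peak of N molecules triggers when ln N exceeds
`threshold_intercept + threshold_slope·ln(h₀) + ε`,
ε ~ N(0, threshold_sigma²), h₀ = 1 RFU, and its height satisfies
`ln h = scaling_intercept + scaling_slope·ln N + ε'`,
ε' ~ N(0, scaling_sigma²). The intercept/slope/residual-SE triplets for
the bundled 3500xL and 3130xL calibrations are regression summaries
whose original regressors are not public; the log-log contract is this
package's documented assumption, and no quantitative result reported by
the acceptance script depends on it (identity mode is used for all of
them). Peaks below the limit-of-detection threshold (LDT, in RFU) are
marked undetected; zero molecules produce no peak at all.

## Degradation closed forms

From concentrations c(x₁), c(x₂) at two amplicon lengths x₁ < x₂
(requiring c(x₂) ≤ c(x₁)):

* DI = c(x₁)/c(x₂) — kit-dependent, because it depends on the target
  lengths;
* ln(1 − P(deg)) = (ln c(x₂) − ln c(x₁))/(x₂ − x₁) — kit-independent;
  implemented with `log1p`/`expm1` so the inversion is exact to ~1e-12
  relative error for P(deg) ≥ 1e-4 (below that the two-point inversion
  is conditioning-limited in double precision: the relative error of
  ln(c₂/c₁) grows like eps/((x₂−x₁)·P(deg)));
* a pair with c(x₂) > c(x₁) has no valid decay slope; the estimate is
  clamped to 0 with a `DegradationWarning` rather than returning a
  negative probability;
* drop-out for n copies: P(drop_n) = 1 − (1 − P(drop₁))ⁿ, implemented
  exactly as this printed form (note it equals the probability that at
  least one of the n copies is degraded; the per-copy form P(intact) is
  what the process simulator consumes).

The cells-per-aliquot planner is ceil(amount / (pg_per_cell · aliquot)).
`pg_per_cell` is an explicit argument because two conventions coexist:
6 pg/cell reproduces the published planning grid exactly (its printed
amounts are exact multiples of 6), while 6.6 pg/diploid cell
(3.3 pg/haploid) is the constant used for pg↔cells conversion in the
simulation experiments. Neither is hard-coded.

## Heterozygote balance

Hb = HMW/LMW exactly (not the more common LMW/HMW); log₁₀ symmetry
makes spread summaries direction-agnostic. Loci with a dropped allele
are excluded from the ratio and counted as drop-out. Two filters mirror
standard practice for stutter-contaminated, saturated data: loci whose
two alleles are exactly one repeat apart are removed (the HMW allele's
stutter co-migrates with the LMW allele), and loci whose mean peak
height strictly exceeds 10,000 RFU are removed (detector saturation).

`enumerate_haploid_hb(n)` gives the exact law of Hb for n haploid
cells, from Binomial(n, ½) with exact rational arithmetic: finite
support {k/(n−k)}, drop-out atoms at k ∈ {0, n} with mass 2·2⁻ⁿ.
P(accepted) uses the closed range [0.6, 1.67] — closed bounds are
required for 3/5 and 5/3 (=1.6̄) to count, which the published
probabilities demand — and keeps the drop-out atoms in the denominator
(an unconditional probability). The published table of these
probabilities describes its model as Poisson; every printed value in
fact equals the exact binomial enumeration, which is what this package
implements and verifies.

## Synthetic data

There is no real kit or genotype data in the package.
`make_fixture_kit` builds a deterministic panel in the style of a
modern 16/17-locus kit: loci spread evenly over a 70–450 bp size range,
ten alleles per locus one tetranucleotide repeat (4 bp) apart, dyes
assigned in contiguous blocks. The 4 bp repeat is an assumption
(standard tetranucleotide STRs); real kits' bin sets, microvariant
alleles and tri-allelic patterns are not modelled. Published
dual-target qPCR concentrations for nine degraded tissue extracts are
bundled (`strsim.datasets`) as the canonical degradation-estimation
input.

What passing tests therefore show: that the stochastic arithmetic of
the process chain is right (exact enumerations, branching-process
moments, closed forms, distribution-level agreement between pipeline
and oracle). What they do not show: fidelity of any particular
instrument calibration, inter-locus differences (amplification
efficiency is locus-independent here), or real-world extraction
chemistry.

## Experiments and their study sizes

The named studies in `strsim.experiments` default to their designed
replicate counts: 500 samples/condition (efficiency sweep), 1500
(aliquot), 1000 (extraction), 250 (combined grid), 1000 (dilution vs.
stain, per arm), 1000 draws (degraded-fragment demo), 50 per amount
(Hb vs. amount). Cell grids double from 1–128 diploid / 2–256 haploid
cells. The test suite runs them at one tenth or less of these sizes
with 1–2 locus kits — Hb observations are i.i.d. across loci under the
idealised settings, so a smaller kit only reduces the observation
count — and the acceptance script uses 10,000 replicates for the
pipeline enumeration check and 4,000 for the diamond-effect SDs.

The dilution-vs-stain study models the serial dilution literally: a
57 ng/µl stock in a 450 µl transfer volume (≈3.9 × 10⁶ copies per
allele), nine 2-fold binomial halvings, and a fixed pipette fraction
into PCR so the mean reaction amounts run 845 down to 1.65 pg. Large
transfer volumes make the pre-PCR thinning nearly deterministic, which
is exactly why dilution series under-represent the stochasticity of
real stains at direct-PCR settings. Crime-stain arms use Poisson cell
targets chosen so the mean amount *in the reaction* matches the
dilution arm, under four (ex_e, pcr_a) ∈ {0.30, 1.00} × {0.35, 1.00}
settings.

Distribution comparisons ("practically identical" vs. "clearly
different") are made assertable with a two-sided Mann–Whitney rank test
on |log₁₀ Hb| at α = 0.01 under fixed seeds.

## Numerical and design choices

* Randomness: numpy `SeedSequence(seed, spawn_key=(index,))` gives each
  simulated sample an independent stream; identical (config, seed) is
  bit-reproducible, and experiments parallelise without sharing state.
* Counts are int64 throughout; the largest realistic yields
  (≈10¹⁰ molecules after 28–35 cycles) are far below overflow.
* A stutter child whose length would be ≤ 0 is discarded (unreachable
  with realistic panels).
* Degenerate inputs: p = 0 or 1 thinnings short-circuit exactly;
  `P(deg) = 1` is rejected (its logarithm is undefined downstream);
  zero cells yield an empty EPG (full drop-out), not an error.
* Only back-stutter (one repeat shorter) is modelled; forward stutter
  is not.
* Config files reject unknown keys outright so a typo cannot silently
  fall back to a default.

## Known limitations

Locus-independent efficiency and stutter rates; no dye-specific
baselines, pull-up, or plateau-phase kinetics; the CE calibration's
functional form is an assumption (see above); the drop-out formula for
n copies is kept in its printed form even though its name and its
algebra diverge (documented, not "fixed"); likelihood-ratio evidence
evaluation is out of scope.
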