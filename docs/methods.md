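# Methods

This note documents the models, parameter choices, numerical details and
limitations of `kinboost`. It is written for a reader who wants to know
exactly what the package computes and what its synthetic-data tests do
and do not demonstrate.

## 1. Parentage likelihood

### Dyad model

For each candidate parent–offspring pair, the per-locus likelihood ratio
compares two hypotheses for the pair's genotypes: *parent–offspring*
(the candidate transmitted one allele; the other parent is an unsampled
Hardy–Weinberg random mate) versus *unrelated* (two independent
Hardy–Weinberg genotypes). The LOD is the natural-log ratio summed over
loci genotyped in both members. Natural logs are used throughout; the
default acceptance thresholds (`lod_accept = 4.5`, `lod_strict = 9`) are
expressed on that scale, and the power module can recalibrate them
in-system for any panel rather than treating them as portable constants.

### Genotyping error

Mistyping is modelled symmetrically: an observed genotype equals the
true genotype with probability 1−ε and is otherwise an independent
Hardy–Weinberg draw at the locus frequencies. Integrating this over both
members of a dyad gives the closed form

    LR_obs = (1−ε)² · LR_exact + (2ε − ε²),

because Hardy–Weinberg replacement leaves the unrelated likelihood and
the marginals of the parent–offspring joint unchanged. The same model is
used by the simulator, so simulation and inference are mutually
consistent; ε defaults to 0.005 for both marker types. Triad
(dam–sire–offspring) likelihoods fold the same per-member error matrix
into the exact three-way joint numerically; the resulting per-locus
tables are small (≤36³ for an 8-allele STR) and are cached per
(panel, ε).

### Assignment procedure

Offspring returning in year *Y* are compared against all candidates that
returned in years *Y−6 … Y−3* and pass the parent completeness filters.
Dyads with more than 2 Mendelian mismatches are discarded; the remaining
candidates are ranked by LOD (ties broken by number of loci used, then
id). Among the top K = 20 candidates, all dam–sire pairs **from the same
return year** (a spawning pair must co-occur in the brood year) with at
most 3 triad mismatches are scored jointly, and the pair maximising the
triad LOD is reported; otherwise the single best dyad. K = 20 was
verified against exhaustive pairing on small fixtures; with a panel this
informative the true parents essentially always rank at the top.
Thresholds are applied downstream, per dyad, so one assignment pass
serves both the productivity threshold and the stricter phenotype
threshold.

The candidate-parent cap Nmax (half the summed weir counts over the four
parent years, plus 5%, rounded up to the nearest five) is computed and
reported (`compute_nmax`) but is not used as a prior by default: an
optional prior-odds term was considered and rejected to keep the LOD
interpretable as a pure likelihood ratio, which is what the calibrated
thresholds act on.

### Field-sex reconciliation

Field sexing is unreliable (~5% error is simulated), so candidates of
either field sex may occupy either parent slot and apparent same-sex
pairs are resolved afterwards: (1) if exactly one member's label is
corroborated by its other mates, the other member is relabelled;
(2) monogamous pairs are split randomly (seeded) into one dam and one
sire; (3) if mate evidence corroborates both labels, the lower-LOD
parent is dropped. Jacks (age-3 precocious males) are treated as male
throughout and are never broodstock.

## 2. Threshold calibration

`simulate_dyad_lods` draws parent–offspring, unrelated, or avuncular
dyads directly from the panel allele frequencies (avuncular pairs via
shared grandparents: two full sibs, one sib's offspring against the
other sib), applies mistyping at ε, and scores each pair with the same
tables used for assignment. FNR(t) and FPR(t) are empirical tail
frequencies with Wilson intervals; `choose_threshold` returns the
smallest threshold meeting a target FPR. Naive Monte Carlo resolves
FPRs down to 1/n; beyond that, the importance-sampling estimator draws
dyads from the parent–offspring distribution and reweights by
exp(−LOD), since P_U(LOD ≥ t) = E_PO[exp(−LOD)·1{LOD ≥ t}]. A single
per-dyad FPR target is appropriate when asking "how often is a true
parent missed"; when asking "how often does an offspring with *no*
sampled parent acquire one", the budget should be divided by the number
of candidates, which requires the importance-sampled tail.

## 3. Relative productivity

Productivity is the mean number of accepted adult offspring per spawner,
computed per brood year and sex; every spawner of the brood year that
passes the parent filters appears in the denominator, zeroes included.
Excluded spawners (insufficient genotypes) are dropped from both
numerator and denominator, under the assumption that their unassignable
offspring are distributed proportionately. Headline RP is reported for
females; male RP is inflated by design in supplemented years (two dams
per sire) and is flagged accordingly. Jacks count as male spawners on
the wild side.

The 95% CI models each assigned offspring as hatchery-parented with
probability p(w) = N_h·w/(N_h·w + N_w) and profiles
ℓ(w) = O_h ln p + O_w ln(1−p); endpoints solve 2[ℓ(ŵ)−ℓ(w)] = χ²₁,0.95
by Brent root-finding on brackets (0, ŵ) and (ŵ, ∞), to a deviance
tolerance well below 1e−8. Degenerate inputs: O_h = 0 gives a one-sided
interval from 0; O_w = 0 gives ŵ = ∞ with an upper endpoint of ∞, both
flagged rather than raised. A per-dam percentile bootstrap is included
purely as a cross-check oracle; the profile interval is the reported
one. A no-cutoff sensitivity estimate (`threshold_sensitivity`)
quantifies the bias introduced by LOD thresholds.

## 4. Phenotype battery

All phenotype contrasts use strict-threshold assignments only. Run
timing is compared per return year (two-sided two-sample KS; exact
enumeration when min(n) ≤ 10, asymptotic otherwise; the reported δ is
the hatchery-minus-wild median, negative = hatchery earlier). Age
composition uses a 2-df χ² on classes {3+4, 5, 6}; an expected-zero
class raises an error naming the class. Freshwater age uses two-sided
Fisher exact tests per brood year and pooled, restricted to scale-aged
fish whose scale total age agrees with the parentage age. Size at age is
an OLS of MEFL on origin, sex, and scale age per brood year, with scale
age coded as treatment contrasts over the ordered levels
1.2 < 2.2 < 1.3 < 2.3 (ordered by total age then lake years; the
ordering is a configuration choice, exposed via `scale_age_levels`) and
restricted to ages observed in both origins. Holm step-down adjustment
is applied within each test family (one family per test type across its
strata), and residual diagnostics (skew, kurtosis, Shapiro p) are
emitted for the size model.

## 5. Synthetic-data generator

The generator emulates a small, exhaustively weir-sampled sockeye system
with three supplemented brood years. Defaults follow the study system:
twelve return years with run sizes from the observed weir counts
(≈900–4,700 adults; the three pre-study seed years are set inside the
observed range), a 30-dam/15-sire broodstock target crossed 2:1 with 10%
prespawn failure, wild mean productivity 0.8 adult offspring per dam,
hatchery mean 17 (the observed per-year hatchery means span ≈10–32),
total-age distributions skewed younger for hatchery fish, freshwater-
age-1 probabilities 0.25 (wild) vs 0.75 (hatchery), normal run days
(mean day 200, sd 12, truncated to the season), sex- and age-specific
lengths (sd 30 mm; jacks capped at 400 mm), a 12% scale-aged subsample,
and 5% field sex misidentification.

Design choices where the real system's data-generating process is
unknown:

- **Offspring-number distribution**: negative binomial per dam with
  dispersion k = 0.3 for wild spawners, chosen so that >60% of wild dams
  produce zero returning adults when the mean is below 1 — the
  heavy-tailed reproductive success typical of salmonids. The family
  itself is a stand-in, not an inference.
- **Run entry** is normal per year; real entry is episodic and
  flow-driven, which the package deliberately does not model.
- **Panel**: 9 STRs with 8 equifrequent alleles and 45 SNPs with minor
  allele frequencies uniform on [0.1, 0.5], error 0.005, 1% missingness;
  all configurable. Null alleles segregate as an invisible extra allele:
  visible/null heterozygotes are recorded homozygous, null homozygotes
  as missing.
- **Scale ages** are recorded without ageing error, so the
  age-agreement filter passes all scale-aged fish in simulation; real
  scale ageing is error-prone, especially for freshwater annuli.
- Annual run sizes are met by topping up simulated offspring with
  founder (unpedigreed) immigrant-equivalents, so early-year fish have
  no recorded parents and pedigree truth covers only in-horizon births.

Because the generator shares its error model with the likelihood and
lacks ecological confounders (environmental mortality, scale-ageing
error, episodic entry, relatedness structure among founders beyond the
simulated pedigree), passing tests demonstrate internal correctness and
statistical calibration — not that real-data assignment rates or
phenotype effects would match.

## 6. Numerical details and scaling

Per-locus likelihood tables are precomputed over unordered-genotype
codes, so scoring reduces to integer indexing; dyad scoring is
vectorised and offspring are processed in blocks (≈4M dyad entries per
block) to bound memory. −∞ LODs can occur only at ε = 0 (opposing
homozygotes); any ε > 0 bounds every per-locus ratio away from zero.
Monomorphic loci yield chi2 = 0 with F_IS undefined (flagged, not
raised). The LD test is a Monte-Carlo permutation test of the genotypic
contingency-table G statistic with the add-one rule (p ≥ 1/(n+1));
per-year p-values pool across years by Fisher's method. Multi-allelic
HWE χ² uses all k(k+1)/2 genotype classes with df = k(k−1)/2 and no
rare-class pooling — the screen is advisory, and flagged loci are
retained for parentage.

Test-suite and example problem sizes are scaled to desk hardware: runs
of 300 fish/year for end-to-end tests, a 500-offspring/800-candidate
census fixture for assignment recovery, 2×10⁴–5×10⁴ dyads for power
curves, and 300 replicates for CI coverage. These sizes were chosen so
the whole suite runs in minutes while keeping Monte-Carlo noise well
inside the asserted tolerances.

## 7. Known limitations

- No sibship reconstruction or multi-generation linking; avuncular pairs
  are simulated for power analysis but not explicitly competed against
  parents during assignment beyond their LOD behaviour.
- No modelling of ocean/freshwater survival mechanisms, environmental
  covariates, or spatial spawning structure.
- The binomial profile CI conditions on total assigned offspring and
  ignores overdispersion between dams; the bootstrap cross-check gives
  similar intervals at study-like sizes, but both can undercover if
  family sizes are extremely skewed.
- Second-generation reproductive success of hatchery-born spawners and
  effective-population-size consequences are out of scope.
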