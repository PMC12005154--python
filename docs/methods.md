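# Methods

This document describes the statistical model implemented by `surfbat`, the
parameter defaults and why they were chosen, the design of the bundled
simulator, and the package's numerical choices and limitations.

## 1. Overview

`surfbat` approximates the transmission-disequilibrium test (TDT) without
parental genotypes. The TDT's strength is that the un-transmitted parental
allele is a perfectly ancestry-matched control for the transmitted one.
`surfbat` reconstructs both quantities probabilistically from a phased
reference panel:

1. each case haplotype is modelled as a mosaic of panel haplotypes
   (Li–Stephens copying HMM);
2. the posterior copying distribution identifies *surrogate parents* — panel
   individuals locally haplotype-sharing with the case;
3. the copied haplotype's allele plays the role of the transmitted allele
   (dosage ρ), and the **partner haplotype of the same panel individual**
   plays the role of the un-transmitted allele (dosage π);
4. per-site χ² statistics compare ρ against π across case haplotypes.

Because the partner haplotype shares the ancestry of the copied segment,
ρ and π are locally ancestry-matched, and allele-frequency differences that
are purely due to (local) ancestry cancel.

## 2. The copying HMM

Hidden state at typed site *j*: the panel haplotype (of `H` total) being
copied. Uniform prior `1/H` at the first site.

**Transitions.** Between adjacent typed sites separated by `d` cM the switch
probability is

```
r = 1 − exp(−0.04 · Ne · d / H)
```

(`0.04 · d` is `4 d_Morgans`), and the kernel is
`P(k→l) = r/H + (1−r)·[k=l]` — on a switch, the new haplotype is drawn
uniformly, including the current one.

**Emissions.** `P(obs | copy k) = 1−ε` if the target allele matches panel
haplotype *k* at the site, else `ε`. ε absorbs genotyping error, recent
mutation, and imperfect mosaicism.

**Posteriors.** A scaled forward–backward pass; per-site renormalization
keeps the recursion in the normalized domain so arbitrarily long chromosomes
do not underflow (verified on 20,000-site instances). The uniform-kernel
structure reduces each transition step to the rank-1 update
`f ← (1−r)·f + r/H`, making a full pass `O(T·H)` per target haplotype; the
implementation batches targets and uses BLAS matrix products throughout.

A brute-force path-enumeration oracle (`brute_force_posteriors`) is included
for testing; forward–backward agrees with it to 1e-10.

### HMM parameter defaults

| parameter | default | rationale |
|---|---|---|
| `ne` | 20 000 | classic effective-size scaling used by imputation engines for human panels; enters only through `Ne/H` |
| `eps` | 1e-4 | of the order of array genotyping error; small enough that an exact local match dominates, large enough to tolerate isolated mismatches |
| `min_switch` | 1e-12 | floor on `r` for strictly positive distances so the chain is never exactly absorbing |

## 3. Dosages

With posterior `p_ij(k)` for case haplotype *i* at typed site *j*:

```
ρ_ij = Σ_k p_ij(k) · [H_kj = 1]
π_ij = Σ_k p_ij(k) · [H_partner(k),j = 1]
```

`partner(k) = k XOR 1` (0-based): columns 2m and 2m+1 belong to panel
individual *m*. Both dosages lie in [0, 1].

**Untyped sites.** For a panel site between typed sites L and R, the
flanking posteriors are applied to the untyped site's panel alleles and
combined linearly with weight `w = (cM − cM_L)/(cM_R − cM_L)`; before the
first or after the last typed site the nearest typed posterior is used, and
a zero-cM span collapses to `w = 0.5`. Because ρ and π are linear in the
posterior, interpolating the dosage pair is identical to interpolating the
posterior rows.

**Quality summaries.** Per site: case MAF `min(θ, 1−θ)` with
`θ = mean_i ρ_ij`, and the INFO score

```
INFO = 1 − Σ_i ρ_ij(1−ρ_ij) / (M · θ(1−θ))
```

— the standard ratio-of-variances imputation-quality measure, stated on
haploid doses; defined as 1 when θ ∈ {0, 1} and equal to 1 whenever all
doses are hard. Defaults filter sites with case MAF < 0.01 or INFO < 0.3,
the usual post-imputation thresholds.

**Diagnostics.** When the panel carries group labels, the mean posterior
mass per group and the mass falling outside each site's dominant group are
reported; large cross-group mass warns that pseudo-controls may be
imperfectly ancestry-matched (small or mismatched panels).

## 4. Association statistics

**Paired (default).** The conditional-likelihood TDT analogue on soft doses:

```
NUM = Σ_i ρ_i (1 − π_i)          (transmitted-not-untransmitted mass)
DEN = NUM + Σ_i π_i (1 − ρ_i)    (all "discordant" mass)
β̂  = logit(NUM / DEN)
Var(β̂) = DEN / (NUM · (DEN − NUM))
X = β̂² / Var(β̂)  ~  χ²₁ under H0
```

With hard 0/1 doses NUM and DEN reduce to the classical discordant-pair
counts and X to the McNemar/TDT statistic. Boundary tables
(`NUM ∈ {0, DEN}`) are reported as degenerate (NaN statistic, flagged); an
optional Haldane correction (+0.5 to both discordant sums) is available.

**Unpaired.** A marginal-homogeneity χ² on the soft 2×2 table
`A = Σ(1−ρ)(1−π)`, `B = Σ(1−ρ)π`, `C = Σρ(1−π)`, `D = Σρπ`:
`X = Σ_m (n_m· − n_·m)² / (n_m· + n_·m)` over the two margins. Both margin
differences equal ±(C−B), so the statistic depends on the discordant mass
only, and is χ²₁ under H0.

**Inflation.** `λ = median(X) / F⁻¹_{χ²₁}(0.5)` over tested sites
(0.4549…); genomic control (optional) divides all statistics by λ only when
λ > 1 — deflation is never amplified.

## 5. Panel QC

When combining reference panels, per-site Hudson Fst between the two panels
(ratio-of-averages form with sample-size bias correction)

```
Fst = [(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)] / [p1(1−p2) + p2(1−p1)]
```

flags batch-effect variants; sites with Fst strictly above mean + 6 SD are
excluded. The 6-SD rule targets gross technical artifacts only — genuine
drift produces a tight Fst distribution between cohorts of the same
ancestry, and the threshold adapts to it.

## 6. The simulator

The simulator exists to validate calibration and robustness claims, not to
be demographically realistic. It emulates:

- **a chromosome**: 100 cM over 100 Mb at a constant 1 cM/Mb;
- **group-differentiated panels**: per-group allele frequencies follow a
  Balding–Nichols model around a shared ancestral frequency
  `p0 ~ U(0.05, 0.95)` at differentiation `F = 0.15` — an intentionally
  strong, continental-scale differentiation so that ancestry confounding is
  a hard test, chosen a priori and used unchanged in every scenario;
- **within-group LD**: each group's haplotypes are 0.5-cM mosaics of 40
  founder haplotypes, creating realistic haplotype sharing so that LD
  thinning and the copying HMM have structure to work with;
- **admixed cases**: case haplotypes are tile mosaics of the panel with
  breakpoints from a Poisson process on the cM axis (exponential tile
  lengths, mean `tile_cm`), tile source group drawn from configurable
  weights, source haplotype uniform within the group, alleles copied
  verbatim (imperfection is the HMM's ε, not the simulator's);
- **genotyping arrays**: typed sites are chosen by MAF ≥ 0.1, greedy
  left-to-right LD thinning (`r² > 0.8` against the last retained site
  within 1 cM), then a uniform draw to the requested count.

It does **not** emulate: mutation on case haplotypes, phasing error,
genotyping error, recombination hotspots or map nonlinearity, selection,
relatedness within the panel, or realistic site-frequency spectra.

### Scenarios

| name | design | purpose |
|---|---|---|
| `null` | two groups (250+250 individuals), 200 cases, 10-cM tiles, 50/50 weights | type-I error and λ calibration |
| `ancestry_signal` | 450 cases selected so the tile overlapping a mid-chromosome locus is group-EUR for 650/900 of haplotypes (drawn from a pre-simulated pool); no allele constraint | a *pure local-ancestry* signal: a robust test must stay flat where a naive case-vs-panel frequency test rejects |
| `allelic_signal` | 450 cases with 500/900 haplotypes carrying the ALT allele at one common site (MAF ≥ 0.2 in every group) | power at a true allelic signal |
| `admixed_null` | three groups, weights 1/6, 1/3, 1/2, mean tile 100/12 cM (expected segment length ~12 generations after admixture) | calibration under three-way recent admixture |
| `small_panel_inflation` | 500 cases as 5-cM EUR mosaics; scan against 2,000 well-matched EUR haplotypes vs 100 EUR + 1,900 non-EUR | demonstrates directional λ inflation when the matched panel is small |

Scenario sizes (cases, panel depth, site counts) are this package's own
desk-scale choices, sized so the full acceptance suite runs in minutes on
one CPU while keeping Monte-Carlo noise small enough for the calibration
checks to be sharp. Every scenario is deterministic given `(name, scale,
seed)` and can be written to disk as VCFs + truth tables + map + config.

## 7. Numerical choices

- Scaled (renormalized) forward–backward rather than log-space: faster,
  and exactness against the enumeration oracle is verified to 1e-10.
- Batched targets with BLAS matmuls for emissions, dosages and group-mass
  summaries; memory is bounded by chunking targets so the posterior block
  stays ≈ 2×10⁷ doubles.
- Dosage interpolation operates on (ρ, π) functionals, not posterior rows —
  mathematically identical (linearity) and `O(S·H)` cheaper.
- Dosages are clipped to [0, 1] after assembly to absorb last-ulp float
  drift.
- λ uses `scipy.stats.chi2.ppf(0.5, 1)` rather than a hard-coded 0.4549.
- p-values come from `chi2.sf`, never `1 − cdf`.

## 8. Limitations

- **Phased inputs are assumed correct.** Phasing error mixes ρ and π and
  attenuates signal; no switch-error model is included.
- **Pseudo-control validity rests on panel individuals being locally
  ancestry-homogeneous** (both haplotypes of a panel individual from the
  same population). Panels of recently admixed individuals weaken the
  matching; the cross-group copying-mass diagnostic flags this.
- **Small or mismatched panels inflate the statistic** (reproduced by the
  `small_panel_inflation` scenario). λ should always be inspected; genomic
  control is a blunt instrument for it.
- **Rare variants** carry little copying information; the MAF/INFO filters
  remove the worst sites but power at low MAF is limited by panel depth.
- The statistic treats the two haplotypes of a case as independent
  contributions, which slightly understates variance under strong
  within-individual correlation.
- The simulator's constant-rate map and two/three-group Balding–Nichols
  world are deliberately stylized; absolute power numbers do not transfer
  to real cohorts.
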