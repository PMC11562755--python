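# Methods

This note documents the modelling choices and estimator definitions in
`drgstereo`, in the order data flows through the package.

## 1. Synthetic ganglion

A DRG is modelled as an axis-aligned ellipsoid (default semi-axes
300 × 250 × 400 µm) containing `n` neurons (default 8000) with centres drawn
uniformly in the ellipsoid (isotropic Gaussian direction × U^(1/3) radius,
scaled per axis — an affine image of a uniform ball is uniform). Each neuron
belongs to one molecular subpopulation; the default composition is
Mrgprd+ 15%, CGRP+ 48.1%, Trpm8+ 8.3%, Thy1+ 15.6%, other 13%.

Soma size is parameterized by the *maximal cross-sectional area*: per
subpopulation, areas are drawn from a lognormal whose parameters are
moment-matched to the target arithmetic mean and SD (e.g. 361 ± 138 µm² for
Mrgprd+). The soma is a sphere of radius r = √(area/π) with a concentric
spherical nucleus of radius 0.45·r.

Each neuron projects to one sciatic territory (tibial 35%, peroneal 45%,
sural 20%). A sciatic injury axotomizes the tibial + peroneal projections
(80% of neurons); spared (sural) neurons never die.

**Injury-induced death.** A scenario assigns each subpopulation a
non-increasing survival schedule over days (linearly interpolated, day 0 = 1).
Each neuron draws a single latent uniform `u` from the injury seed alone and
is alive at day `d` iff `u ≤ survival(subpop, d)`; because the draw does not
depend on `d`, alive sets are nested over time (no resurrection), matching a
longitudinal death process.

**Labelling.** A label (genetic reporter, injury-induced reporter, or
retrograde tracer) targets a membership set (marker-bearing subpopulations,
axotomized neurons, or one territory) and is applied by independent
Bernoulli draws: probability `sensitivity` on members, `false_positive` off
them.

**Odds-ratio survival calibration.** Some experiments are summarized by a
co-labelling proportion before (`p_contra`) and after (`p_ipsi`) injury
among tracer-filled neurons. If marker-positive neurons survive with
probability `s·ρ` and marker-negative ones with `s`, the expected
post-injury marker share among survivors is

    p·s·ρ / (p·s·ρ + (1−p)·s) = p·ρ / (p·ρ + 1 − p),

independent of `s`; hence odds(p_ipsi) = ρ·odds(p_contra) and
ρ = odds(p_ipsi)/odds(p_contra). Scenario files store the two proportions
and derive ρ at load time (never hard-coding the survival), applying it to
the baseline schedule only once baseline loss has begun. A closure test
confirms the simulated proportion recovers `p_ipsi` within 3 binomial SEs.

## 2. Virtual sectioning

Tissue processing shrinks the z-axis by a factor (default 0.8) before
cutting. Serial sections of nominal thickness 30 µm tile the tissue z-extent
starting one uniform random phase above it — systematic uniform random
sampling, which is what makes the Cavalieri estimator unbiased. Section `i`
lands on slide `i mod 5`; one slide is chosen uniformly at random for
analysis (1-in-5 sampling). Sections containing no cells are flagged
excluded (they reduce the analyzed set but not the total section count `l`).

Per section, a confocal z-stack is built with optical planes every
`dz = 3 µm` spanning the *full* section thickness including both cut
surfaces: the top plane sits at the upper cut (the dissector's exclusion
plane) and, since `dz` divides the thickness, the bottom plane coincides
with the lower cut — which is simultaneously the next section's top plane.
Soma profiles are analytic circle–plane intersections
(area = π(r² − Δz²) strictly inside the soma); nucleus visibility is strict
(`|z − z_nuc| < r_nuc`), so a plane exactly tangent to a nucleus does not
see it.

**Measured thickness** emulates the standard practice of averaging the
thickest and thinnest cell-containing region: local thickness varies
uniformly within ±10% of nominal and the reported value is the mean of one
draw from each tail, which is unbiased. **Mid-plane cell area** is the
analytic ellipse cross-section π·a_x·a_y·(1 − (z_m/a_z)²) at the section's
middle plane, clipped to 0 beyond the poles.

## 3. Optical-dissector counting and its exactness

A neuron is counted in a stack iff its nucleus is visible on at least one
plane *and not* on the top plane; the bottom plane is included. With the
stack geometry above, the set of nucleus centres counted in section
`[z_lo, z_hi)` is exactly those in `[z_lo + r_n, z_hi + r_n)` (per-neuron
nuclear radius `r_n`) whenever the nuclear diameter exceeds `dz`: visibility
on some plane but not the top one means the nucleus extends below the top
plane by more than its radius. These per-section counting windows tile the
z-axis exactly — every nucleus is counted in exactly one section of the full
series. The test suite verifies this brute-force: summing dissector counts
over all sections of all slides equals the number of living neurons with a
visible nucleus (8000/8000 at default geometry).

## 4. Stereological estimators

Per analyzed section `i`: `V_sec,i = t_i · a_i` (measured thickness ×
mid-plane area) and a dissector count `N_sec,i`. For the whole ganglion:

- **Cavalieri volume** `V_DRG = ā · t̄ · l`, where `l` is the *dimensionless
  total number of sections collected across all slides* (ā·t̄·l only has
  volume units if `l` is a count). With analytic mid-plane areas over the
  full series this is the midpoint rule under a random phase and lands
  within 0.1% of the true ellipsoid volume in practice (within 10% on every
  replicate is the tested guarantee).
- **Numerical density**: the pipeline default is the pooled ratio
  `N_v = Σ N_sec / Σ V_sec` over the analyzed slide. The per-section-averaged
  alternative `mean(N_sec,i / V_sec,i)` is available (`pooled=False`) but is
  substantially noisier without being less biased: end sections near the
  ganglion poles can pair a near-zero analytic mid-plane area with a nonzero
  count (the counting window, shifted by the nuclear radius, reaches into
  bulk tissue), producing extreme per-section densities. At default
  geometry, the per-section mean yields a replicate CV of ~23% versus ~13%
  for the pooled ratio; both are unbiased within 5% over 200 replicates.
- **Total number** `N_DRG = N_v · V_DRG`.

Sections with zero `V_sec` and a nonzero count (an end section whose
analytic mid-plane misses a polar cap the counting window still samples) are
contradictory as data; the pipeline drops them from the density with a
warning, while the low-level estimator raises by default.

## 5. Cleared-tissue nuclear spots

Imaris-style spot exports (one row per nuclear spot with XYZ and volume) are
ingested with header-dialect normalization. Volumes below 5 µm³ or above
2000 µm³ are flagged debris/doublets (strict inequalities; the boundary
values pass). Passing spots are binned small (≤ 258 µm³), medium
(258–400 µm³] and large (> 400 µm³); "combined" = medium + large. The bins
partition the passing spots exactly.

## 6. Soma-size distributions

Soma areas are measured as each neuron's largest optical profile on the
analyzed slide, restricted to neurons with a visible nucleus (the same
inclusion rule as counting). Two samples are compared with the two-sample
Kolmogorov–Smirnov statistic `D = sup |F_x − F_y|`, evaluated exactly over
the pooled sample points (correct under ties). The default p-value uses the
asymptotic Kolmogorov distribution at the effective sample size with the
standard small-sample argument correction `(√n_eff + 0.12 + 0.11/√n_eff)·D`,
which holds the null rejection rate at its nominal 5% for routine sample
sizes (calibration-tested at n = 200); a seeded permutation p-value is
available as an alternative.

## 7. Co-labelling proportions

Per animal and side, the proportion of reference-labelled cells (e.g.
tracer-filled, nucleus visible) that also carry a marker label is a plain
profile proportion — no stereological correction, mirroring two-channel
scoring practice. Group summaries report mean ± SEM (SD/√n over animals) and
support a paired ipsi/contra design with per-animal deltas.

## 8. Inference conventions

All p-values are two-sided. Posttest families are declared by the caller,
never inferred from the data. The mixed (split-plot) ANOVA tests the
between-groups effect against the subject-within-group error and the within
effect and interaction against the residual within-subject error, assuming
sphericity (uncorrected); effects whose sum of squares is exactly zero are
reported as F = 0, p = 1 even when the error term is degenerate. Power for
the two-sample t-test uses the noncentral t distribution with noncentrality
d·√(n/2) and df 2n − 2; the planning routine returns the smallest n
attaining the requested power.

## 9. Validation summary

The acceptance suite verifies, among others: dissector exactness (exact);
stereology unbiasedness (mean N_DRG within 5% of truth, replicate CV < 15%,
200 ganglia); Cavalieri accuracy (within 10% per replicate); spot boundary
semantics; KS exactness against a brute-force sup-scan plus null
calibration; split-plot ANOVA equivalence to an independent sums-of-squares
oracle on random balanced designs; Šídák/power monotonicity; Shapiro–Wilk
type-I calibration; and odds-ratio calibration closure. Emergent end-to-end
outcomes — a ~61% decrease in reporter-positive counts between 7 and 56 days
after transection, ~4.6% reporter-positive neurons in uninjured ganglia, and
the collapse of tracer-referenced co-labelling to ~1.7% — are reproduced by
`scripts/acceptance.py` from seeds alone.
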