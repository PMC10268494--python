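# Methods

## The branched fermentation network

The model is the generic butyrogen network: glycolysis (glucose → 2
pyruvate, 2 ATP, 2 NADH), lactate dehydrogenase, PFOR and PFL routes to
acetyl-CoA, acetate kinase, the butyrate branch (thiolase →
hydroxybutyryl-CoA dehydrogenase → crotonase → electron-bifurcating
butyryl-CoA dehydrogenase, lumped per butyryl-CoA: 2 acetyl-CoA + 3 NADH in,
1 reduced-ferredoxin pair out), the butyryl-CoA:acetate CoA transferase
(one free acetate consumed and one acetyl-CoA released per butyrate, the
release feeding back to acetate kinase), a ferredoxin hydrogenase, and the
Rnf complex (ferredoxin:NAD⁺ oxidoreductase conserving energy
chemiosmotically).

Cofactors are *difference pseudo-species*: NADH is the reducing equivalent
of the NAD⁺/NADH couple (composition H, charge −1, two available
electrons), a reduced ferredoxin pair is two bare electrons (charge −2),
and acyl-CoA species are the acyl group relative to free CoA-SH. Under
these conventions every elementary reaction in the table balances C, H, O
and charge exactly (asserted by a test per reaction), so any flux
combination yields an exactly balanced net reaction.

Given branch fractions (λ pyruvate→lactate, φ of acetyl-CoA formation via
PFL, β of acetyl-CoA to butyrate), the two cofactor balances are solved in
closed form: Rnf flux `r = max(2λ + 3B − 2, 0)` closes NADH (B = butyrate
per glucose), hydrogenase flux closes ferredoxin. If NADH is in excess
(λ and β both small) the strict network has no sink: this is reported as an
explicit infeasibility naming the violated balance, because the network
names only a ferredoxin hydrogenase. An optional generic NADH → H₂ route
(`allow_nadh_to_h2`) can be enabled; with it the λ = φ = 0 solutions
reproduce the overall balance family exactly at b = β, which is a tested
invariant. The flux network can recycle free acetate through the CoA
transferase but never net-consume it, so butyrate yields above 1 mol/mol
(net acetate uptake) exist only in the balance family, not in the flux
solutions.

**Rnf ATP stoichiometry.** The chemiosmotic yield of Rnf is not fixed by
the network. The default is 0.5 ATP per reduced-ferredoxin pair (two
translocated ions per pair, four per ATP), a mid-range literature value,
exposed as `BranchParams.rnf_atp_per_fd`. With it the pure-butyrate
solution conserves 3.5 ATP/glucose and the homolactate shift forgoes
(3.5 − 2)/3.5 ≈ 43% — "roughly half" — of the ATP; the ratio moves with η
and every η-dependent output carries the parameter used.

## The overall balance family

The family `glucose → b butyrate + a acetate + h H₂ + c CO₂ (+ H₂O, H⁺)`
has four conservation constraints (C, H, O, charge) for five unknown
coefficients; the degree-of-reduction balance is a linear combination of
these and adds nothing. The missing constraint is metabolic: the family
assumes complete pyruvate decarboxylation via PFOR, fixing CO₂ = 2 per
glucose. With that, the linear solve gives uniquely a = 2 − 2b and
h = 4 − 2b, so net acetate crosses zero at exactly b = 1 and the b = 2
balance is H₂-free. A general closure (`close_balance`) instead fixes the
four organic-acid yields and solves for H₂, CO₂, H₂O and H⁺, rejecting
yield vectors whose closure would require negative H₂ or CO₂.

## Thermodynamics

Formation energies ship as *standard transformed* values at pH 7 and
298.15 K, derived from the classical anaerobe-bioenergetics compilation by
adding `N_H · RT ln(10) · 7` (= 39.956 kJ per hydrogen atom) to each
standard value; the proton entry is 0, so transformed reaction energies are
plain coefficient sums and protons drop out automatically for any
H-balanced reaction. Cross-checks against well-known reaction values:
glucose → 2 lactate⁻ + 2 H⁺ gives −197.05 kJ/mol, the b = 1 balance
−264.09, the b = 0 balance −215.89.

ΔG at conditions adds RT ln Q with aqueous solutes as molar concentrations,
gases as partial pressures in atm against a 1 atm standard state (the
headspace-style convention; the dissolved-phase view is available through
`henry_dissolved_h2`, ~0.73 mM per atm at 310 K, van 't Hoff-corrected),
and water activity 1. The default temperature is 310.15 K while the table
stays at its 298.15 K reference — no enthalpy correction is applied, and
the docstrings flag this; only the RT ln Q term follows temperature. A
product gas at zero partial pressure raises an explicit "unbounded
favorability" error rather than returning −∞.

Default "representative colonic" conditions (glucose 10 mM, acetate 30 mM,
butyrate 10 mM, lactate and formate 1 mM, CO₂ 0.3 atm, H₂ 0.15 atm, pH 7)
are literature-typical config values shipped in `data/conditions.yaml`,
chosen once; the exact values used for any published figure of this kind
are not recoverable, so these defaults are documented as illustrative, not
asserted as anyone's measurements. ATP-feasibility annotation reports the
largest n with ΔG ≤ −n · 70 kJ/mol (ΔG_ATP = +70 kJ/mol default).

Deliberately out of scope: ionic-strength corrections, pKa-resolved
speciation, kinetics.

## Carbon accounting

For monocultures, net acetate can be negative while acetate kinase still
runs, because the CoA transferase consumes one free acetate per butyrate.
The metric therefore sets theoretical acetate consumed = butyrate produced,
total fermented carbon = 6·glucose consumed + 2·butyrate produced (mM C),
total acetate produced = butyrate produced + measured Δacetate, and each
product's share = 100 · (carbon in product) / (total fermented carbon),
with butyrate/lactate/formate taken from endpoint concentrations (absent
from the medium). Gas-phase CO₂ and H₂ are not entered. A negative total
acetate produced violates the accounting assumption and flags the result
instead of being clipped; small negative productions of medium-absent acids
(noise below blank) are clipped to zero with a warning. One blank per
record is assumed (replicate-blank averaging, if any, happens upstream).
Community data use Δproduct per mole of hexose consumed instead. Contrasts
are per-product two-sided pooled-variance t-tests with no multiple-testing
correction, starred at 0.05/0.01/0.001; identical constant groups report
t = 0, p = 1 rather than the 0/0 form.

## Cohort pipeline

Breath H₂ and CH₄ are scaled by 3.5 / (sample CO₂ %) — an alveolar-air
correction. Outliers are removed per metric across *all* samples of that
metric (not per subject) by Tukey's fences at k = 3 IQR, quartiles by
linear interpolation (the common statistical default; the convention is
configurable since "Tukey's fences" alone does not fix one). A
subject-period is methanogenic iff any corrected CH₄ sample is strictly
over 4 ppm, after subtracting an optional 1 ppm instrument baseline in
flagged semesters and flooring at zero (negative gas concentrations are
non-physical); before and during periods are classified separately.
Subject-period means feed two-sided two-sample t-tests between MG and
non-MG groups, with explicit subject exclusions supported. The
during-versus-before contrast is exposed in both paired and unpaired forms,
since a before/during design supports either reading and the choice is not
forced by the analysis itself. No mixed-effects modelling is attempted —
the pipeline reproduces a per-subject-mean, two-group design faithfully.

## Synthetic data

The culture generator draws endpoint concentrations from strain profiles
(baseline yields per glucose plus multiplicative shifts under H₂/CO).
Before noise, every yield vector — baseline and shifted — must close into a
full elemental balance, so generated data respect conservation by
construction, and headspace H₂ falls mechanically when butyrate rises.
Hydrogenase-free profiles are doubly constrained: no H₂ response at all and
an electron balance closing with exactly zero H₂. Default profiles encode
the three qualitative phenotypes (reductant to butyrate + formate;
reductant mostly to lactate; no response); effect sizes are illustrative
defaults, not measured values. Noise is mean-one multiplicative log-normal
on the concentration *changes* (positive quantities, roughly proportional
HPLC error), switchable to additive Gaussian.

The cohort generator gives each subject a persistent methanogenic status
and subject-level random effects, with within-subject sample noise on top
(defaults: breath H₂ 12 ± 3 ppm between subjects, ±2 ppm within; fecal
butyrate 10 ± 2.5 µmol/g, ±1.5 within; 3 samples per period). The
supplement raises H₂ (+6 ppm) and butyrate (+3) in everyone; the
methanogen deficits (−6 ppm H₂, −5 µmol/g butyrate) act *only* during
supplementation, so the before period is an exact null. Deficits correspond
to Cohen's d ≈ 1.9 at the subject-mean level, sized so that a 20-per-group
cohort detects them with near-certain power while the before-period
false-positive rate stays at the nominal 5% test size — which is what the
end-to-end acceptance test asserts (detection in ≥95% of seeded replicates
during; before-period significant fraction inside the binomial envelope of
α = 0.05). MG subjects are guaranteed at least one CH₄ draw over the
classification threshold per period, and non-MG CH₄ is capped at the
threshold, making generator truth and classifier output match by
construction. Injected outliers shift a sample by a multiple (default 10)
of the metric's combined between+within SD and are tagged in `_truth_*`
columns that the analysis ignores.

What the generators do *not* emulate: growth dynamics and co-culture
kinetics, correlated multi-analyte noise, non-normal heavy-tailed breath
distributions, dropout/missing samples, or dose heterogeneity. Passing
tests therefore demonstrate correctness of the accounting, classification
and testing machinery under the assumed statistical structure — not
robustness of the biological conclusions to real-data messiness.

## Numerical choices

Residual tolerance for "zero" in conservation checks is 1e−9 after the
dense linear solve; balance coefficients at |c| < 1e−9 are snapped to 0 in
flux-derived net balances. ATP-threshold bucketing uses
floor(−ΔG/ΔG_ATP + 1e−12) so exact multiples of 70 land on the line they
touch. The acceptance script locates the acetate sign change on a
2001-point grid followed by 80 bisection steps; all simulation sizes used
in tests (100 seeded replicates, 40-subject cohorts, 5-replicate cultures)
were chosen as the smallest designs at which the tested properties are
statistically decidable.
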