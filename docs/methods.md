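# Methods

This note documents the models, defaults and numerical choices behind
`pectolyze`, and what the synthetic-data tests do and do not demonstrate
about real LC-MS data.

## Compositional mass model

An oligogalacturonide is described by (dp, n_methyl, n_acetyl, unsaturated).
At unit (iontrap) resolution the nominal mass is built from integer blocks:
anhydro-GalA 176, methyl esterification +14 (CH₂), acetylation +42 (C₂H₂O),
and +18 (H₂O) for saturated species — β-elimination products carry the
Δ4,5 unsaturation, which formally cancels the terminal water. Monoisotopic
masses use the exact counterparts (176.03209, 14.01565, 42.01057, 18.01056)
and are provided for ppm-tolerance matching; they round to the nominal mass
for every inventory compound. Nominal masses are primary because the
reference observations are unit-resolution iontrap data, and they reproduce
the printed inventory exactly.

Adduct m/z in nominal mode: [M−H]⁻ = M−1, [M+FA]⁻ = M+45, [M+NH₄]⁺ = M+18,
and (M+2·18)/2 for the doubly charged ammonium adduct. Electron and
proton-vs-hydrogen mass distinctions are ignored in nominal mode;
monoisotopic mode uses −1.00728 (deprotonation) and +18.03383 (NH₄⁺).

The shipped 48-compound reference inventory preserves its source cells
verbatim. Three rows are internally inconsistent (printed m/z 746 where the
rule gives 764; printed MW 1335 where the rule and the row's own printed
z=2 m/z imply 1316; GalA/methyl cells reading 9/6 where the label and MW
imply 8/7); they are flagged in `KNOWN_INCONSISTENCIES` rather than
silently corrected, and excluded from exact-regeneration checks.

## Fragment model

Glycosidic fragments follow Domon–Costello nomenclature with masses from
the same building blocks: a C_i ion is the intact non-reducing i-mer
(176·i + substituents + 18, −18 if it contains the unsaturated end), B_i =
C_i − 18, Z_j = 176·j + substituents. Substituent masses travel with the
fragment containing the substituted residue, which gives the complement
identity composition(C_i) + composition(Z_{dp−i}) = parent — the invariant
the test suite brute-forces over all labelings with dp ≤ 6 and ≤ 2 acetyls.
The single cross-ring series emitted is ⁰,²A (C_i − 60, loss of the C1–C2
ring fragment), the only one reported for these compounds; its acetyl
handling is count-based because O-2 vs O-3 positions are not resolved by
the underlying MS² data. Two empirical behaviours are modeled as such:
methanol loss (−32 Da) offered only by ions containing a methyl-esterified
reducing-end residue, and the series-wide −7 Da offset of positive-mode
B/C ladders, which is chemically unexplained and therefore applied as an
opaque, per-ion-flagged offset (configurable, default on) — never folded
into the underlying masses. C/Z isomeric-mass ambiguity is preserved by
emitting both series rather than forcing one.

Acetyl localization treats each retained/lost observation on a B/C fragment
as a window constraint (retained → position ≤ i; lost → position > i) and
intersects windows; contradictory evidence yields the empty set.

## Identification

Matching tolerance defaults to ±0.5 Da, appropriate to unit-resolution
iontrap spectra; ppm-style matching against monoisotopic masses is
available. Ties break by smaller |error|, then lower charge, then compound
name, making the result independent of library order. Compositions that are
isobaric at unit resolution (e.g. three methyls vs one acetyl, both +42)
cannot be separated by m/z alone; the matcher can return all in-tolerance
candidates so downstream logic (or MS² evidence) can adjudicate.
Retention-time isomer grouping uses a 0.5 min gap: same-composition peaks
separated by at least the gap become #1/#2 in elution order, closer peaks
merge with summed intensity. Profiles are completed with zeros for
undetected library compounds, so profile matrices are rectangular with no
missing values.

## Fingerprinting statistics

Each sample's intensities are divided by the sample maximum, so a profile
records product proportions, not productivity; all-zero profiles are
flagged and passed through. This makes fingerprints invariant to any
per-sample global intensity scale — the property the clustering tests
verify — at the cost of coupling every value to the noise of the single
largest compound. DP aggregation sums normalized values per degree of
polymerization, optionally split into non-acetylated and acetylated bins;
the aggregation conserves the profile total. Clustering is agglomerative
with complete linkage on Euclidean distances (scipy backend, verified
against a brute-force oracle on small instances), performed within each
(substrate, time) stratum by default, with cross-stratum clustering behind
a flag. Rows are pre-sorted lexicographically by sample key so leaf order
is reproducible under distance ties; column order is fixed, not clustered.

## Digestion simulator

Chains are explicit residue sequences (methyl flag, O-2/O-3 acetyl flags).
The generator's defaults are the measured degrees of the four substrate
presets: apple DM 69 / DAc 2, citrus 53 / 1, sugar beet 56 / 19,
polygalacturonic acid 0 / 0, with random (Bernoulli) methyl placement by
default and a blockwise mode that lays runs of 10 methylated residues until
the per-chain target count is met exactly. Acetyls are Bernoulli per
residue, O-2 or O-3 with equal probability; methyl + acetyl on one residue
is allowed. Chain length defaults to 100 residues × 100 chains (10⁴
residues): far shorter than polymeric pectin, but long enough that realized
DM concentrates tightly around the target and end effects are small. An
optional inert-residue fraction stands in for RG-I/neutral-sugar content;
it is modeled only as lyase-inert positions, not structurally.

Cleavage follows a subsite model across −4..+4. A bond is cleavable at
relative rate 1 when the residues in subsites +1 and +3 are both
methyl-esterified; when +3 is present but unesterified the rate is ρ
(default 0.25; ρ = 0 is the strict rule); the +3 subsite must be occupied
in every mode, so chains of DP ≤ 3 are never substrates — the choice that
makes DP3 the terminal accumulating product, as observed for real pectin
lyases. Each acetyl group on a residue within −4..+4 multiplies the rate by
an acetyl penalty (default 0.5); direction, not magnitude, of both ρ and
the penalty is empirically grounded, so both are configuration knobs and
"enzyme variants" are simply different (ρ, penalty) pairs. An optional flag
hard-blocks bonds whose +1 residue is acetylated (default off — whether
acetylation at +1 blocks the elimination chemistry itself is unknown).

Digestion is an exact Gillespie simulation (desk-scale populations make
exactness affordable): event propensity is rate_constant × relative rate,
one bond is cleaved per event, and the reducing-side product gains the
Δ4,5 unsaturated non-reducing end. Residue/methyl/acetyl totals are
conserved exactly and unsaturated ends equal cleavage events — invariants
checked over 50 seeded trajectories. A235 progress curves follow
Beer–Lambert from the cleavage count (ε = 5500 M⁻¹cm⁻¹ default) with an
explicit count→mol scale factor.

Synthetic peak tables map unsaturated products of dp ≤ 8 with library
compositions to positive-mode ammonium adducts (z = 1 up to 1100 Da, z = 2
above, mirroring the observed charge-state tendency of larger oligomers);
intensity is molar count × lognormal noise with CV 9% by default — the
replicate-injection variability of the measurement method being emulated —
with mean 1 so expected intensity is count-proportional. Saturated
original-end fragments, dp > 8 products and out-of-library compositions are
excluded and reported separately, mimicking a finite annotation library.

What passing tests show: the mass/adduct arithmetic, bookkeeping,
normalization, clustering and fitting are internally correct, and the
subsite mechanism alone reproduces the qualitative biology (substrate
ranking apple > citrus > sugar beet > PGA, blockwise > random, DP3-dominated
end profiles of near-fully methylated oligomers). What they do not show:
real chromatographic behaviour (retention times here are synthetic and
composition-deterministic), ion suppression, isotope patterns, in-source
fragmentation, or enzyme-specific rate constants — none of which the
simulator attempts.

## Kinetics

The Hanes–Woolf linearization (regress S/v on S; slope = 1/Vmax, intercept
= Km/Vmax) is the primary estimator, mirroring standard practice for these
assays; a direct nonlinear least-squares Michaelis–Menten fit is provided
as a diagnostic cross-check only. Substrate concentrations are GalA-bond
molarities from the measured GalA content (bonds ≈ GalA moles; the
(n−1)/n end correction is negligible for polymeric pectin and is not
applied). kcat = Vmax·MW/60000 converts specific activity (µmol·min⁻¹·mg⁻¹)
to s⁻¹. Recovery conditions in the analysis and acceptance runs — Km 21 mM,
kcat 96 s⁻¹, MW 37.9 kDa, 8 substrate levels from a 0.25–10 g/L series on a
sugar-beet-like substrate, 5% multiplicative rate noise, 100 replicate
experiments — represent a realistic plate-reader kinetics campaign for
these enzymes.

## Degenerate inputs and tie-breaks

All-zero profiles: flagged, not divided. dp = 1 oligomers: no fragments,
not an error. Empty library ranges: empty result. Contradictory acetyl
evidence: empty set, not an exception. Co-eluting same-composition peaks:
merged, intensities summed. Matching ties: |error|, then charge, then name.
Clustering ties: lexicographic row pre-sort. Every stochastic routine takes
an explicit seed or Generator and is reproducible bit-for-bit under it.

## Problem sizes

Default simulations use 10⁴ residues per substrate (100 × 100), 50 seeds
for conservation/monotonicity audits, 100 Monte-Carlo replicates for
kinetics, and exhaustive enumeration up to DP 6 for terminal-state and
fragment-bookkeeping checks — sizes chosen so the full audit runs in about
a minute on a single core while keeping binomial sampling error on realized
DM below half a percentage point.

## Known limitations

The −7 Da positive-mode offset is reproduced, not explained. Acetyl O-2 vs
O-3 positions are carried only as counts at the composition level. The
blockwise generator controls block length and count, not the full
block-length distribution of real pectins. Quantification uses whatever
adduct is observed and records the mode; cross-adduct response differences
are not modeled. Cluster significance is not tested — the clustering is a
descriptive fingerprint display, and none is performed on columns.
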