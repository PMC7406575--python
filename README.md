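# pectolyze

Discriminative substrate degradation profiling of pectin lyases
(EC 4.2.2.10): a tested pipeline for annotating and fingerprinting the
unsaturated oligogalacturonides these enzymes release from pectin, plus a
mechanistic digestion simulator that makes every stage testable without any
instrument data.

## The problem

Pectin lyases cleave the homogalacturonan backbone of pectin — α-(1,4)-linked
D-galacturonic acid (GalA), optionally methyl-esterified at O-6 and
acetylated at O-2/O-3 — by β-elimination, leaving a Δ4,5-unsaturated
non-reducing end that absorbs at 235 nm. Fungal genomes carry several
near-identical copies of these enzymes, and the copies can differ subtly in
which substitution patterns they attack. Comparing the **product profiles**
(which oligomers accumulate, with how many methyl and acetyl groups) is a
sharper discriminator than activity alone. This package implements that
comparison for LC-ESI-MS peak data and for simulated digests:

* **Composition & mass model** — an oligomer `gA_x_m_y_a_z` (x GalA, y
  methyl, z acetyl, Δ4,5-unsaturated) has nominal mass
  `M = 176·x + 14·y + 42·z` (saturated species: +18), observed as
  `[M−H]⁻`, `[M+FA]⁻`, `[M+NH₄]⁺` or `[½M+NH₄]²⁺` adducts. A transcribed
  48-compound reference inventory ships with the package and is regenerated
  exactly by these rules (three internally inconsistent printed rows are
  flagged, not corrected).
* **MS² fragments** — Domon–Costello B/C/Z and ⁰,²A ladders with composition
  bookkeeping, methanol loss (−32 Da) for methylated reducing ends, the
  empirical series-wide −7 Da positive-mode offset, and acetyl-position
  localization from retained/lost fragments.
* **Identification & fingerprinting** — tolerance-based peak matching,
  retention-time isomer grouping, per-sample max-normalization
  (`v_i / max_j v_j`), DP aggregation, and complete-linkage hierarchical
  clustering on Euclidean distances of the normalized profiles.
* **Digestion simulator** — explicit homogalacturonan chains with configurable
  degree of methoxylation (DM), acetylation (DAc) and blockwise/random methyl
  placement; exact Gillespie simulation of β-elimination under a subsite
  model (methyl required at +1, strongly preferred at +3, acetyl groups in
  the −4..+4 window slow cleavage; trimers are never substrates).
* **Enzymology** — DM/DAc from released methanol/acetate, GalA-bond molarity,
  A235→specific-activity conversion (ε = 5500 M⁻¹cm⁻¹), and Michaelis–Menten
  fitting via the Hanes–Woolf linearization (S/v vs S).

## Worked example

```python
from pectolyze import (OligoComposition, nominal_mass, adduct_mz, AdductSpec,
                       preset_spec, generate_chains, CleavageRule,
                       simulate_digest)

trimer = OligoComposition(dp=3, n_methyl=3)     # gA_3_m_3
print(nominal_mass(trimer))                      # 570
print(adduct_mz(570, AdductSpec.ammonium(1)))    # 588.0  [M+NH4]+

chains = generate_chains(preset_spec("apple"), seed=1)   # DM 69%, DAc 2%
states = simulate_digest(chains, CleavageRule(), time_points=(0, 1440), seed=2)
print(states[-1].cleavage_count)                 # 3929
```

Running the numbered drivers in `analysis/` prints, among other things:

```
ranking: apple > citrus > sugarbeet > pga        # initial cleavable-bond rate
dominant products (normalized):
  gA_3_m_2            1.000
  gA_3_m_3            0.902
  gA_2_m_2            0.743
```

i.e. the simulated apple-pectin digest is dominated by short, fully or
near-fully methylated oligomers — DP3 accumulates because chains shorter
than four residues cannot span the required +1/+3 subsites — and substrate
preference follows DM and DAc exactly as observed for the real enzymes.

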