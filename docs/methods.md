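# Methods

## Quantification model

Each identified peptidoform (sequence + modification set + charge) with at
least one arginine has a light form at m/z = (M + z·1.007276)/z and a heavy
form one label shift higher, Δm/z = n_Arg · 6.020129 / z. Monoisotopic
masses are residue sums (pyteomics `std_aa_mass`) plus one water (18.010565
Da) plus explicit modification deltas; the built-in modification table
carries acetyl (+42.010565), oxidation (+15.994915) and carbamidomethyl
(+57.021464). Identifications are consumed as a fixed-dialect PSM TSV with a
search-engine q-value; the pipeline applies the 1% FDR cutoff (`q ≤ 0.01`,
configurable) and drops arginine-free peptides, which carry no light/heavy
pair.

For each PSM, MS1 scans within ±15 s (configurable) of the PSM retention
time are searched. Peak matching takes the nearest centroid within ±10 ppm
(the precursor tolerance reused as extraction tolerance; distance ties break
toward higher intensity; absence is a value, not an error). In the default
`apex` mode the scan with the maximal light monoisotopic intensity is
chosen and **both** channels are read from that one scan, which cancels
scan-to-scan ionization fluctuations — the core robustness of isotopic
ratios; `summed` mode integrates each channel over the window instead.
Percent light is I_L/(I_L + I_H). A missing heavy peak yields percent light
1 with flag `heavy_missing` (the bait control is genuinely heavy-absent, so
absence is signal), a missing light peak yields 0 with `light_missing`;
records with both channels absent, or with no scans in the window, are
excluded and reported.

### Envelope-overlap correction

Six ¹³C substitutions are exactly what separates the heavy monoisotopic peak
from the light peptide's M+6·n_Arg isotopologue, so the two coincide on the
m/z axis and the light envelope inflates the measured heavy intensity — by
several percent of I_L for peptides near 4 kDa. The correction estimates the
light peptidoform's isotope envelope from its mass with the averagine model
(mean composition C 4.9384, H 7.7583, N 1.3577, O 1.4773, S 0.0417 per
111.1254 Da; C/N/O/S rounded to integers, hydrogen adjusted to match the
mass within one unit; per-element multinomial distributions convolved, NIST
isotope abundances) and subtracts I_L · A(M+6·n_Arg)/A(M+0) from the raw
heavy intensity, clamping negative results to 0 with flag `clamped`.
Without correction, percent light is biased *low* (toward apparent
exchange); the paired bias at 4 kDa exceeds 0.01 and correction reduces it
below 10⁻³ (tested).

### Peptidoform collapse

PSM-level quants pool into unique peptidoforms by summing intensities, so
the collapsed percent light equals the (I_L+I_H)-weighted mean of per-PSM
values — the pooled-intensity estimator, robust to low-intensity PSMs.
Charge states collapse together; distinct modification sets never do.

## Stratification and summaries

Classes are protein sets plus PTM signatures in protein coordinates
(peptide position + protein_start − 1). A peptidoform matches a class iff
its protein is listed, every required modification whose position its span
covers is present (spans covering no required position cannot attest the
class), and no forbidden modification in the span is present. "Bulk" classes
forbid the signature acetylations rather than all modifications, so
oxidation or carbamidomethyl does not eject a peptide from bulk. Overlapping
definitions are a configuration error; unmatched peptidoforms report as
`unassigned`. Per (class, condition): mean percent light, SEM (sample SD,
n−1 denominator, absent at n = 1), `exchange_fraction` = 1 − mean, and
`normalized_exchange` = exchange_fraction/0.5 clamped to [0, 1] (1 = full
equilibration with the 1:1 heavy pool). Both exchange readouts are reported
because "10% exchange" naturally refers to the raw fraction heavy while
"50% light = rapid exchange" implies the normalized scale. Replicates, if
present in the input tables, are pooled before averaging; conditions are
opaque ordered labels, not a numeric axis.

## The synthetic experiment generator

The generator emulates the study design so every stage is testable without
instrument data: a light-only bait protein (TAP-tagged H2B analog),
non-specific proteins mixed 1:1 (true light fraction f = 0.5), and
histone-like proteins whose f depends on the cross-linking condition.
Protein sequences are synthetic histone-like fixtures — an H3-like sequence
whose KSTGGKAPR peptide spans the K9/K14 acetylation signature and an
H4-like sequence with the K12/K16 signature (K12 followed by proline so
several distinct tryptic peptides span both sites within two missed
cleavages) — plus bait and background proteins built from distinct
Arg-terminated tryptic units. They are fixtures, not proteome entries.

Default true light fractions across (FA0, FA0.05, FA0.25, FA1.25):

| class         | FA0  | FA0.05 | FA0.25 | FA1.25 |
|---------------|------|--------|--------|--------|
| bait          | 1.0  | 1.0    | 1.0    | 1.0    |
| non-specific  | 0.5  | 0.5    | 0.5    | 0.5    |
| bulk-H3       | 0.90 | 0.80   | 0.93   | 0.98   |
| H3K9acK14ac   | 0.88 | 0.55   | 0.85   | 0.98   |
| bulk-H4       | 0.90 | 0.70   | 0.90   | 0.98   |
| H4K12acK16ac  | 0.88 | 0.68   | 0.80   | 0.98   |

The anchored cells are the reported observations this package validates
against: bait ~100% and non-specific ~50% everywhere, ~10% bulk exchange
without cross-linking, bulk H3 ~80% light at 0.05% FA, and ~100% for all
classes at 1.25% FA. The remaining cells encode the qualitative ordering
(acetylated ≤ bulk at every condition; a dip at mild cross-linking;
convergence at the top condition) and are scenario parameters stated in
config, not measured claims.

Rendering: each peptidoform gets its own retention-time slot (3 scans, 2 s
apart, slots 60 s apart), a log-uniform base intensity in [10⁵, 10⁷], and a
primary charge drawn from {2: 0.7, 3: 0.3} (a second charge state with
probability 0.3, exercising cross-charge collapse). I_L = f·base,
I_H = (1−f)·base. Light and heavy averagine envelopes are placed on a shared
isotopologue grid spaced 1.003355/z with the heavy monoisotopic peak at
offset 6·n_Arg, reproducing the M+6·n_Arg coincidence the overlap correction
exists for; with all noise off the pipeline therefore recovers every
injected percent light to ≤ 10⁻⁹ across 300–5000 Da (tested).

Noise model and defaults:

- shared lognormal ionization factor per species-scan, CV 0.2, applied to
  both channels — co-eluting isotopic pairs experience the same spray
  fluctuation, which is why same-scan ratios are robust; a purely
  channel-independent noise of this size would not reproduce that physics
  and would bias apex-scan ratio selection by several points;
- independent per-channel lognormal residual, CV 0.05 (detector-level);
- uniform m/z calibration jitter within ±5 ppm (bounded, as calibration
  error is; half the ±10 ppm matching window);
- 20 baseline peaks per scan, uniform over 300–1800 m/z, log-uniform
  intensity 10²–10⁴;
- whole-channel dropout probability 0.005 per scan, modeling rare
  centroiding failures of otherwise high-S/N monoisotopic peaks.

Decoy PSM rows (10% rate, q-values in (0.02, 0.5]) and confident but
arginine-free rows exercise the identification filters; both are drawn from
a separate random substream, so disabling them leaves every spectrum
byte-identical. All randomness flows from a single mandatory seed;
same-seed runs are byte-identical.

What the generator does **not** model — chromatographic peak shapes and
retention-time drift, MS2, full-proteome backgrounds, correlated abundance
structure, PTM-blocked tryptic cleavage — bounds what passing tests show:
they validate the extraction, correction and aggregation arithmetic under a
plausible noise model, not performance on real chromatography.

## Numerical and design choices

- Constants to six decimals (proton 1.007276, water 18.010565, ¹³C−¹²C
  1.003355) from one constants module; residue and isotope data from
  pyteomics.
- Non-standard residue codes (B, Z, X, U, O) are rejected, not approximated:
  silent mass errors corrupt pair matching.
- mzML support is implemented directly on lxml (centroided MS1,
  32/64-bit float arrays, optional zlib), written as plain non-indexed
  mzML 1.1; profile spectra are rejected loudly. The writer's output is
  cross-validated against Bioconductor's mzR parser in the test suite.
- The digest uses the plain trypsin rule (cleave after K/R except before P)
  rather than the Expasy variant with WKP/MRP exceptions.
- Envelope truncation at M+k_max then renormalization; convolution
  truncation is exact for the retained coefficients.
- Class means are plain arithmetic means over peptidoforms, matching the
  reported averaging; flagged records (`heavy_missing`, `clamped`) are
  included by default because for the bait the absent heavy channel *is*
  the measurement — downstream users can exclude by flag.
- Recovery checks of the stochastic scenario report the mean over several
  deterministic replicate sub-seeds: a single-replicate class mean of ~12
  peptidoforms has sd ≈ 0.5 points and a small chance that one dropout
  outlier moves it by >1 point, so the replicate mean is the quantity that
  reflects the estimator rather than one draw.

## Known limitations

- The averagine envelope is an approximation to the true elemental
  composition; adequate for the M+6/M+0 ratio correction, not for isotope
  fine structure.
- q-values are consumed, never computed; whether they are PSM- or
  peptide-level is up to the search engine that produced them.
- No retention-time alignment across runs; conditions are independent files.
- The apex/summed extraction modes bracket, but do not model, real XIC
  integration.
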