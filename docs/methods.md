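# Methods

## Scope and data model

The pipeline starts from centroided data: MS1 features (m/z, retention
time, integrated XIC area, raw intensity, sample id) and MS2 spectra
(precursor m/z, polarity, peak list). Peak picking, smoothing and
integration are upstream concerns and out of scope. Fourteen polar lipid
classes are modelled; neutral lipids, oxidized species, isotopologue fine
structure and multiply charged ions are not.

## Chemistry

Elemental compositions are maps over {C, H, N, O, P, S} with element-wise
arithmetic that rejects negative counts. Monoisotopic masses use IUPAC
atomic masses of the most abundant isotopes (H 1.00782503207,
C 12 exactly, N 14.0030740048, O 15.9949146196, P 30.97376163,
S 31.97207100); the electron mass (0.00054858 Da) is included in all
charged-species masses. At m/z ≈ 500 the 5 ppm matching window is
0.0025 Da, so the electron term is borderline significant and correctness
is cheap.

A species formula is `backbone + Σ FA − n_acyl·H₂O`. The backbone of each
class is encoded once in `constants.yaml` and annotated with the LIPID MAPS
record used to verify it (composing the backbone with that record's chains
reproduces its published molecular formula); the committed oracle table
`tests/data/lipidmaps_oracle.tsv` cross-checks 27 adduct m/z values across
all 14 classes against direct formula summation, independent of the
composition code path.

**PI-Cer.** The two PI-Cer species are identified at class level only.
The backbone assumes a d18:1 sphingoid base (sphingosine +
inositol-phosphate − H₂O); the amide-linked fatty acid plays the role of
the single chain, and names render the base explicitly (amide 16:0 →
PI-Cer(d34:1)). A hydroxylated (t-type) base would shift the mass by one
oxygen; with no evidence either way the d-type default is configurable by
editing the backbone.

**Adducts.** Quantification adducts per class: [M+NH₄]⁺ for
galactolipids, [M+H]⁺ for betaine lipids and PC/LPC/PE, [M−H]⁻ for
SQDG/SQMG/PG/PI/PI-Cer. PC and LPC use a second channel, the acetate
adduct [M+CH₃COO]⁻, for chain-level MS2 only. The acetate delta is
+59.013851 (acetate anion including its electron, the same convention that
gives −1.007276 for [M−H]⁻).

## Annotation rules

* Intensity floor: "below 1×10⁴ excluded" is read strictly; a feature at
  exactly 1×10⁴ is kept.
* MS1 match: |ppm| ≤ 5 (signed ppm stored), retention time inside the
  class window. Windows default to the generator's canonical class centers
  ± 1.0 min and are fully configurable — they are instrument properties,
  not constants of the method.
* MS2 link: a spectrum belongs to a species channel when its precursor is
  within 10 ppm of the channel adduct m/z and the polarity matches.
  Fragment matching is ±0.01 Da (Orbitrap MS2 at 17,500 resolution).
  Fragment evidence is credited only within its own channel, so planted
  carboxylates in a positive-mode spectrum cannot confirm PC chains.
* Chain evidence per class: carboxylate anions (RCOO⁻ = FA − 1.007276)
  for SQDG/SQMG/PG/PI, PE ([M−H]⁻) and PC/LPC (acetate channel);
  [RCO+74]⁺ = (FA − OH − e) + C₃H₆O₂ for galactolipids; neutral losses of
  the free acid (FA) or ketene (FA − H₂O) for DGTS/MGTS. Head-group ions
  and losses are computed from elemental formulas in `constants.yaml`
  (e.g. phosphocholine 184.0733, betaine core 236.1493, sulfoquinovose
  anion 225.0075, inositol-phosphate anion 241.0119, PE loss 141.0191,
  galactosyl+NH₃ losses 179.0794/341.1322), never hard-coded as literals.
* PI-Cer has no chain-diagnostic fragment (the class is identified at
  sum-composition level), so its chain requirement is vacuous: the
  inositol-phosphate head-group ion alone yields a full confirmation.
* A species covered by MS2 must reach `confirmed_both` to be reported;
  species without MS2 coverage remain `ms1_only` rather than being
  silently dropped.
* Competition for a feature is resolved by (1) MS2 status, (2) |ppm|,
  (3) RT distance to the window center. sn-positions are never inferred;
  species are reported with "_" unless the library flags them resolved.

## Quantification

Normalized abundance = species XIC area / internal-standard area, per
sample. The IS mix (dMPC, dMPE, SM d18:1/17:0, LPC 19:0, dPPI, dMPG, dMPS,
dMPA, C17 ceramide) is encoded with published molecular formulas; classes
with a chemically matching standard use it, all others (the glycolipids
and betaine lipids) fall back to the standard with the closest retention
time, ties broken by name. dMPS, dMPA and SM match no modelled class but
stay eligible for the fallback. Samples whose required standard has
non-positive area are flagged and excluded with a warning. Zeros are kept
(no imputation); the glog transform is defined at zero.

## Statistics

The chain order glog → EigenMS → autoscale → PCA/tests is enforced by a
provenance tag on the transformed matrix.

* **glog** `g(x) = log₂((x + √(x² + λ²))/2)` with λ defaulting to the
  minimum positive matrix value (configurable).
* **EigenMS.** Residuals are data minus per-species group means. The
  number of bias eigentrends is chosen by comparing each leading singular
  value against its permutation null at α = 0.05 (default 500
  permutations). Permutations shuffle each species' residuals *within
  groups*: this preserves both the zero-group-mean constraint and each
  row's variance, so the null spectrum is comparable to the observed one;
  permuting across groups systematically flattens the spectrum and
  overestimates the trend count. The estimated bias (residuals projected
  onto the significant right singular vectors) is re-centered within
  groups before subtraction, so group means are preserved to machine
  precision.
* **Autoscale** per species, ddof = 1; zero-variance species dropped with
  a warning.
* **PCA** on samples (scikit-learn full SVD); variance explained is
  σᵢ²/Σσ² in percent, non-increasing, summing to 100.
* **Kruskal–Wallis** (scipy, tie-corrected, χ² with k−1 df) per species
  across the six groups; the all-identical degenerate case returns
  H = 0, p = 1.
* **Dunn post-hoc** on mean ranks with tie-corrected variance, two-sided
  normal p per pair, all 15 pairs (hand-implemented; no installed package
  provides it).
* **BH** step-up q-values via statsmodels; the Benjamini–Yekutieli
  variant is available behind a flag since the abbreviation in common use
  is ambiguous, with BH as the default.
* **Discriminant species**: q ≤ 0.05, ranked by |PC1 loading|, truncated
  to the top 16.

Calibration (in the test suite): Kruskal–Wallis empirical size is checked
at the study design (6 groups × 5 replicates) over 2000 null simulations;
Dunn null uniformity is checked at 6 × 8, the asymptotic regime of its z
statistic, because a Kolmogorov–Smirnov test on 2000 p-values is sensitive
to rank discreteness at n = 5. BH is verified against a brute-force
step-up implementation on 1000 random p-vectors.

## Antioxidant assays

Endpoint at 120 min; intermediate reads are retained for QC only.
% remaining = 100·A(end)/A(0); % inhibition =
100·(A_radical − (A_sample − A_control))/A_radical, identically for ABTS
and DPPH; a radical blank is stable iff its decline is strictly less than
10%. Concentrations are final in-well values: mixing 150 µL extract with
150 µL radical halves the prepared dilutions, which is why prepared
100/500/1000 µg/mL correspond to reported 50/250/500 µg/mL. Trolox
calibration is an ordinary least-squares line of % inhibition vs
concentration (5–75 µmol/L); no IC50 or kinetic rate model is fitted
(the dose response is deliberately non-linear).

## Synthetic data: what it emulates, and what it does not

The generator produces every input with known truth. Defaults define the
study conditions: 6 groups × 5 replicates; ppm-error SD 1.0 ppm (refused
at ≥ tolerance/2, where matching would fail by construction); RT jitter
SD 0.1 min; log-scale abundance noise σ = 0.25; IS area noise σ = 0.1;
batch-trend strength 0.15; 20 near-mass decoys (20–80 ppm off real
species, rejected until ≥ 15 ppm from every true m/z); 10 sub-floor junk
features. Class RT centers follow HILIC head-group elution logic
(glycolipids early, charged phospholipids late), spaced 2 min apart so
windows never overlap.

The batch trend is a linear drift over a **randomized injection order**.
With injections ordered by group, drift is confounded with the design:
every species inherits real group-mean differences that no
group-preserving normalization may remove, and the false-positive rate of
the downstream tests is inflated by construction. Randomized injection
order is standard acquisition practice for exactly this reason and makes
the planted null species truly null.

Two factory designs:

* `default_design` — class-level depletion of PI, PG, DGDG and SQDG in the
  ethanol-containing solvents (E 0.40, DE 0.50, E+USB 0.85, E+USP 0.88,
  DM 1.0 relative to CM) plus stronger effects (E 0.35, DE 0.45,
  E+USB 0.80, E+USP 0.82) on 16 discriminant species (6 PG, 5 PI, 3 DGDG,
  1 PE, 1 PC). This reproduces, by construction, the qualitative PCA
  geometry of the solvent comparison: CM and DM cluster, E and DE
  separate, the ultrasound-assisted extracts sit near the chlorinated
  cluster.
* `discriminant_design` — only the 16 species carry effects, the rest are
  null, for FDR-controlled precision/recall experiments (class-wide
  depletion would make ~41 species truly non-null and precision against
  a 16-species target meaningless).

The generator does **not** emulate: chromatographic peak shape or
integration error, co-elution and in-source fragmentation, isotope
patterns, missing values from data-dependent acquisition undersampling,
or inter-batch effects beyond a single smooth trend. Passing tests
therefore demonstrate the correctness and calibration of the pipeline
logic on idealized centroided data, not robustness to those acquisition
artifacts.

The bundled 128-species library is a synthetic stand-in: per-class counts
match the published totals, every species named in the source literature
appears verbatim, and the remaining slots are filled from
literature-typical *Nannochloropsis* chains (14:0, 16:0, 16:1, 18:1, 18:2,
18:3, 20:4, 20:5) with unique sum compositions per class. Two species that
would be chemically identical to spiked standards (PC 28:0, PI 32:0) are
deliberately absent so standard peaks remain distinguishable from
endogenous species. The published class-level variance figures of the
original study depend on its appendix abundance tables, which are not
public; they are replaced by construction-level guarantees (geometry and
variance conservation), not re-targeted.

## Numerical choices and degenerate inputs

Ties in standard assignment break by name; ties in hit competition by
ppm then RT. Empty feature tables and empty libraries are warnings, not
errors; malformed rows raise errors naming file, line and field. All
stochastic routines take explicit seeds (default 20211021) and identical
inputs yield byte-identical output files (sorted rows, shortest
round-trip float formatting). Problem sizes used by the test suite —
2000 null simulations for each calibration check, 100 seeded end-to-end
runs for recovery — were chosen as the smallest sizes at which the
binomial/KS uncertainty of the checked quantity is well inside the
asserted bands.
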