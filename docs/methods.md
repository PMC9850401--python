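# Methods

## The measurement model

glycoquant implements the computational half of a bottom-up glycomic assay
for polysaccharide quantitation. The wet-lab half (not modelled here beyond
its data signature) depolymerizes each polysaccharide into a ladder of
oligosaccharides by Fenton chemistry, reduces them with borohydride to
alditols, and runs them on a porous-graphitized-carbon (PGC) column coupled
to a positive-mode QTOF. The computational half then rests on three facts:

1. **Composition from mass.** An oligosaccharide's monoisotopic mass is a
   linear combination of residue-class masses (Hex 162.052824, Pnt
   132.042259, HxA 176.032088, HexNAc 203.079373 Da), plus one water, plus
   2.015650 Da for the reduced terminus and 14.015650 Da per O-methyl.
   Inverting a measured precursor m/z over all residue-count combinations
   within bounds yields its candidate compositions; composition-level B/Y
   glycosidic fragments score the MS2 spectrum.
2. **Isomer identity from retention.** Starch, cellulose, β-glucan, mannan
   and galactan all shred into Hex_n ladders — identical masses. PGC
   separates the anomeric/linkage isomers, so the (composition, RT) pair,
   catalogued per polysaccharide standard in a *fingerprint library*, is
   the identification key. Entries whose composition **and** RT collide
   across polysaccharides are flagged non-unique and excluded from
   quantitation.
3. **Concentration from calibrated area.** For each polysaccharide, the
   areas of its three most abundant *unique* oligosaccharides (fixed on the
   standards' library, so every sample uses the same three) are averaged
   and regressed on standard concentration through the origin with equal
   weights, using at least five levels: slope = Σxy/Σx², r² = 1 − SS_res/Σy²
   (uncentered total SS — the through-origin convention; the centered
   variant can go negative). Samples are read off as area/slope. The method
   detection limit (MDL) is the lowest calibration level whose averaged
   top-3 peak S/N exceeds 3.

Relative quantitation is simply the per-polysaccharide share of total
assigned extracted-ion-chromatogram peak area; annotated peaks matching no
fingerprint go into an explicit "unassigned" pool rather than being
silently dropped.

## Key numerical procedures

**EIC extraction.** Per MS1 scan, intensity is summed over a ±15 ppm window
(QTOF-class default, configurable) around the monoisotopic m/z. A flat
m/z-sorted index over all MS1 points makes thousands of EIC pulls per run
cheap.

**Peak detection (discovery mode).** Local maxima above
`baseline + min_snr·σ` (baseline = trace median, σ = 1.4826·MAD of the
trace) with a 3σ prominence requirement, so noise riding on a peak cannot
split it. Boundaries walk outward tracking the running minimum, stopping at
baseline return or when the trace climbs >3σ back above that minimum; the
comparisons are non-strict because a Gaussian sampled symmetrically about
its center produces a two-point apex plateau. Areas are baseline-subtracted
trapezoids. Apex S/N divides peak height by the scaled MAD of peak-free
flanking baseline. A noiseless baseline reports the cap (10⁶) rather than
infinity. Detection is invariant to uniform intensity scaling.

**Deisotoping guard.** A detected peak is rejected when the channel one
isotope spacing (1.0033548/z) below it holds a coeluting signal ≥30% of the
peak height: the peak is then an M+n satellite of a larger ion, not a
monoisotopic species. Without this, high-mass annotation can land on M+2
satellites (a 15 ppm window at m/z 1850 is ±0.028, and e.g. Hex3Pnt9HxA1
sits 15 ppm from the Pnt14 M+2).

**Targeted quantitation.** Top-3 areas are integrated over a fixed
±0.35 min window (±3.5 chromatographic σ) at the library RT after
subtracting the flanking-baseline median, rather than using data-driven
peak boundaries. Fixed geometry keeps the estimator unbiased at any S/N —
noise integrates to ~zero instead of being clipped — so below-MDL signal is
reported with a `below_mdl` flag rather than censored to zero, and the
user decides downstream.

**S/N for the MDL.** Rated at the *expected* (library) RT against a
fixed-geometry flanking window (0.4–2.0 min from the target), not at the
detected apex. Picking the maximum excursion near the expected RT biases
S/N upward at sub-detection levels and saturates as noise grows; the
fixed-position estimate scales inversely with noise, which is what a
dilution-based MDL search relies on.

**Annotation tie-breaking.** Candidates sort by |ppm error|, then fewer
residue classes, then lower DP, then adduct order — fully deterministic.
The default search space (DP ≤ 25, ≤3 HxA, methyl only on HxA, HexNAc only
as pure chitin-type series, reduced forms only) keeps enumeration well
under 10⁵ candidates; the borohydride step justifies the reduced-only
default, and all of it is configurable.

## The synthetic-data generator

`glycoquant.simulate` emulates the statistical structure the pipeline
assumes, with ground truth, so every stage is testable without instrument
data:

- **Oligomer ladders.** Nine polysaccharide models with field-typical DP
  ranges (starch Hex 3–21; cellulose, β-glucan, galactan Hex 3–12; mannan
  Hex 3–10; arabinan Pnt 3–15; xylan Pnt 3–12 plus methyl-glucuronic
  Pnt_nHxA1Me1 branches; xyloglucan mixed Hex/Pnt 4–14; chitin HexNAc 3–8),
  geometric per-DP abundance decay (0.75), and per-species response slopes
  spanning ~12× (chitin highest, cellulose lowest).
- **Chromatography.** RT linear in DP per species, Gaussian peaks
  (σ = 0.1 min) on a 45-min gradient sampled at 0.63 MS1 spectra/s.
  Retention bases are offset so same-composition ladders from different
  polymers stay ≥2 min apart — the PGC isomer separation.
- **Signal model.** True area = concentration × response × decay^(DP−DPmin),
  optional per-oligomer log-normal area noise (`area_cv`, 5% in validation
  studies), optional per-oligomer ppm mass error, M+1/M+2 isotope
  satellites from a crude carbohydrate envelope. Baseline (5σ) plus
  Gaussian noise is added once per **unique m/z channel** — detector noise
  belongs to the m/z window, not the analyte, so species sharing Hex_n
  channels do not stack baselines.
- **Noise scaling.** Default noise σ is 0.5% of the run's tallest apex
  (proportional mode, emulating TIC-coupled chemical noise). An absolute
  mode (`noise_abs`) pins σ in counts; the MDL studies use it, anchored to
  the top calibration level, so S/N genuinely falls with dilution.
- **MS2.** Optional data-dependent top-5 scheduling with 30 s dynamic
  exclusion and a linear collision-energy ramp CE(m/z) = 1.45·(m/z) − 3.5
  stored as acquisition metadata; fragment spectra come from the B/Y
  enumerator.

Deliberately **not** emulated: reaction-yield chemistry, matrix ion
suppression, retention prediction from structure, detector saturation, and
drift between runs. Passing recovery tests therefore demonstrate the
correctness of the computational pipeline under its stated assumptions, not
the wet-lab assay's accuracy on real food matrices.

## Validation studies and problem sizes

`glycoquant.workflow` chains the full pipeline at the package's default
study scale, chosen to finish in seconds per study on one core:

- **Recovery:** nine standards (2000 µg/mL) → library; six two-fold
  calibration levels from 2000 µg/mL (all nine species per level, 5% area
  noise); three independent 500 µg/mL unknown replicates. Reported: r²
  (≥0.999 typical), per-species % bias and % CV (typically ≤7% each).
- **Relative mixture:** concentrations composed so per-species total areas
  hit 70/20/10 exactly; measured fractions recover within ~0.1 points.
- **MDL:** absolute-noise calibration series at 1× and 2× noise; MDL is
  level-quantized (62.5–2000 µg/mL) and non-decreasing in noise across
  seeds.

All randomness flows from a single seed through a deterministic
seed-derivation scheme; identical seeds give byte-identical outputs.

## Known limitations

- Fragment scoring is intensity coverage of B/Y composition-level ions; no
  cross-ring (A/X) ions, no intensity modelling, and no isomer information
  — a stand-in where published tools do not document their scoring.
- Library RT transfer assumes at most a global shift between runs; no
  nonlinear warping.
- Charge state defaults to 1+ (appropriate for these DPs in positive mode);
  multiply-charged support is configuration, not default.
- Fructan and pectic galacturonan backbones are outside the supported
  nine-polysaccharide set.
- The MDL is quantized to the calibration levels by definition; it is a
  "lowest qualifying level", not an extrapolated limit.
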