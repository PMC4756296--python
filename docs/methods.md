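# Methods

This note records the models, parameter choices and numerical conventions
behind `nglyq`, and what the simulation-based tests do and do not establish.

## Mass and formula conventions

All masses derive from one pinned isotope table (IUPAC/NIST values) in
`chem.py`; residue masses are computed from residue formulas at import time,
so the residue-sum and formula-sum code paths agree to float precision and
database builds are bit-reproducible. Conventions: proton 1.007276 Da;
water 18.010565 Da; carbamidomethyl (+57.02146 Da) applied to every Cys as a
fixed modification (iodoacetamide alkylation is assumed); monosaccharide
residue masses Hex 162.05282, HexNAc 203.07937, Fuc 146.05791, NeuAc
291.09542. Variable modifications and O-glycosylation are out of scope.
Glycans are compositions only — no topology or linkage — written as 4-digit
codes in Hex, HexNAc, Fuc, NeuAc order (`5402`), with a delimited dialect
(`12-11-0-2`) for counts above 9 (polylactosamine series).

One worked value is deliberately composition-derived: for the
`CANLVPVPITNATLDQITGK` backbone, the Hex6HexNAc5Fuc2NeuAc2 glycoform's
(M+4H)4+ computes to 1247.5436, about 0.010 m/z above a commonly quoted
1247.533 for this species; the Hex6HexNAc5NeuAc3 partner computes to
1247.2885. The package always reports composition-derived values.

## Isotope engine

Patterns are aggregated at unit-nucleon resolution: the instruments this
targets (Rs ≥ 30,000) resolve isotope peaks of multiply charged precursors
but not fine structure. The predictor convolves per-element nucleon-offset
distributions (binary exponentiation; probability and first-moment arrays
propagated together), so each bin's m/z is the exact probability-weighted
centroid of the fine masses it aggregates. Bins below 1e-4 of the base peak
are pruned and at most 12 peaks kept. A brute-force oracle enumerates
isotopologue multinomials for formulas of ≤ 60 atoms and bins them
identically; predictor and oracle agree to ~1e-13, far inside the 1e-6
test tolerance. One pattern is stored per record (neutral scale) and
re-expressed per charge on demand.

## Glycan library and protein fixture

The packaged library (`data/glycan_library_synthetic.tsv`) is a synthetic
stand-in with the documented structure of serum N-glycan libraries: 331
rule-based compositions (HexNAc 2–6 with antenna count a = HexNAc−2, Hex
from the Man3 core to a+5, NeuAc ≤ a, Fuc capped by class) plus 20
penta/hexa polylactosamine entries — 351 total. The protein fixture
(`data/agp_synthetic.fasta`) is likewise synthetic: a tryptic scaffold
containing the two literature-documented glycopeptides (`ENGTISR`,
`CANLVPVPITNATLDQITGK`) among other sequon-bearing peptides. Both files say
so in their names and headers. Analyses that depend only on structure
(divisibility of the database size, sequon chemistry, mass arithmetic) are
unaffected by the stand-in status.

## Database builder

Trypsin cleaves after K/R except before P; 0–2 missed cleavages by default
(common practice; the count is a parameter). Records are unique by (peptide
sequence, glycosite, glycan); a peptide with n sequons yields n records per
glycan, each carrying the whole glycan on one site — multiply-glycosylated
peptides are not enumerated. Semi-tryptic peptides are excluded. The table
serializes as TSV with a `#`-prefixed JSON header and is searched by binary
search over a sorted neutral-mass index.

## Identification cascade

**M-score.** 15 oxonium ions with weights favoring the HexNAc fragment
series (204/186/168/144/138/126), matched at ≤ 20 ppm. The threshold fits a
Gaussian to scores below the 90th percentile (the null mode) and returns
μ + 3σ, floored at 0.5; spectra from runs too small to fit (< 100 HCD
scans) use the floor directly. The score is intensity-scale invariant by
construction (intensities enter relative to the sub-700 Da base peak).

**S-score.** Over theoretical peaks ≥ 5% relative intensity whose slot lies
inside the extracted envelope (8 isotope slots at mz + k·1.00336/z), each
peak contributes `w_j (0.9 m_j + 0.1 t_j)` with `w_j ∝` theoretical
intensity, `m_j = max(0, 1 − |Δppm|/tol)` and `t_j = max(0, 1 − |ΔI|)`,
scaled to 0–100. The mass-term tolerance defaults to 200 ppm: with the 9:1
weighting fixed, S ≥ 98 is reachable for real mass accuracy (1–3 ppm
errors) only if the mass term saturates; the term still zeroes out
candidates tens of ppm off, while the intensity term arbitrates co-elution
interference near the threshold. Envelope extraction *sums* peaks inside
each slot's window (±10 ppm): species 3–4 ppm apart are unresolved at these
resolutions, so a centroider would merge them — summing reproduces that,
and makes interference visible to the gate as envelope distortion.

**Fragments.** Glycan loss follows an outer-in ladder: NeuAc/Fuc removable
at any step, Hex only when NeuAc = Fuc = 0 or Hex > 3 (antenna hexoses
under remaining decorations), HexNAc last; the bare-peptide Y0 terminates
every ladder. CID sets carry Y-ions at charges 1..z−1 plus singly charged
B-ions; HCD sets carry Y-ions at +1 only, plus b/y ions of the
deglycosylated peptide and the oxonium table. The match score retains the
200 most intense peaks and reports the matched fraction of their summed
intensity; each peak matches at most its nearest fragment within 20 ppm,
ties toward lower m/z.

**Decoys and FDR.** Decoys swap Hex↔HexNAc and Fuc↔NeuAc counts (an
involution; fixed points remain distinct through peptide reversal, which
preserves mass) and reverse the peptide with the glycosite mirrored. Decoys
are scored on the same spectra as their targets after the S-stage; the best
target and best decoy per spectrum enter
`FDR(t) = #{decoy ≥ t}/max(1, #{target ≥ t})`, q-values are the running
minimum toward lower thresholds, and acceptance is q ≤ 0.01. Precursor
candidates are taken within ±10 ppm with ±1-nucleon recovery for mispicked
monoisotopic peaks. Site localization on multi-sequon peptides is
*undetermined* by this fragment model (b/y ions are deglycosylated), so the
simulator plants ground truth only on single-sequon backbones while keeping
multi-sequon records in the search space.

## Quantitation

3TIQ channels are the three most intense peaks of the *theoretical* pattern
(for > 4 kDa species these are M+1..M+3, which carry more ion current than
the monoisotopic peak). Scans within ±2 min of the retention-time hint
qualify only if their local envelope scores S ≥ 98 against the theoretical
pattern; the abundance is the sum of the three highest qualifying per-scan
channel sums. The three points need not be contiguous in retention time.
The XIC oracle (trapezoidal area of the monoisotopic channel) is retained
as an independent cross-check, not used in quantitation.

Two regimes in the tests: a dilution series of a single species establishes
linearity (R² ≥ 0.99), mirroring spiked-standard calibration; the
cross-species XIC regression uses species of one size regime (4.3–5.7 kDa
at z = 4, abundances log-uniform over three decades), because a
monoisotopic-channel XIC is proportional to 3TIQ only when envelope shapes
are comparable — which is also the regime of standard-glycoprotein
experiments.

## Cross-run comparison

Match-between-runs requires S ≥ 98 within ±5 min of the reference
retention time and never overwrites a direct quantitation. Charge states of
one (peptide, glycan, site) are summed per run. Normalization scales each
run's total abundance to the across-run median total ("global"
normalization; note the compositional side effect — large planted changes
pull background fold changes slightly the other way). Replicate groups of
three require ≥ 2 observations and sample CV < 30%. The differential test
is Welch's t-test on log2 abundances (the volcano p-value source is
otherwise unspecified in the field's descriptions; Welch is the
conservative default), with no multiple-testing correction by default and
Benjamini-Hochberg available. Fold-change direction is group B over group A
(case/control). Species flagged at |log2 FC| ≥ 1.

## Synthetic data

The generator emulates: MS1 scans every 0.05 min carrying each species'
theoretical envelope under a Gaussian elution profile (σ = 0.1 min) with
Poisson count noise and 2 ppm (1σ) mass jitter; one HCD + one CID spectrum
per species near its apex with class-weighted fragment intensities,
log-normal fragment variation and 100 uniform-m/z, exponential-intensity
noise peaks; noise-only HCD spectra with random precursors; and triplicate
two-group designs with log-normal replicate noise (σ = 0.15, i.e. ~15%
CV — typical of technical LC-MS replicates). Identical seeds give
byte-identical runs.

It does **not** emulate: profile peak shapes or centroiding artifacts,
charge-state envelopes competing for precursor selection, chimeric MS2
spectra, retention-time drift between runs, in-source fragmentation, or
real chromatographic tailing. Passing tests therefore demonstrate that the
algorithms are correct under their stated models — not that thresholds
tuned here transfer unchanged to instrument data.

The interference fixture plants the two glycoforms three elution sigmas
apart (overlapping tails, distinct apexes). When two equal-abundance
species fully co-elute at 3–4 ppm, the S gate sits within ±0.5 of its
threshold and cannot reliably separate them — a genuine limitation of
envelope-similarity gating with 9:1 mass weighting, documented here rather
than hidden by the fixture.

## Degenerate inputs and tie-breaks

Empty spectra and all-zero envelopes score 0; runs without MS1 skip the
S-stage with every PSM flagged `no_ms1`; an empty decoy set makes FDR 0
everywhere with a warning; all-zero runs are dropped from normalization;
fold changes with a zero denominator are reported infinite and flagged.
Nearest-fragment ties break toward lower m/z; equal-scoring candidates for
one spectrum keep the first encountered (database mass order).

## Known limitations

Site localization within multi-sequon peptides is not attempted (no
glycan-retaining peptide fragments are modeled). The S ≥ 98 gate's
discrimination margin is thin for fully co-eluting near-isobars (above).
mzML support is read-only and covers the centroided subset of the standard;
the simulator writes MGF + MS1-TSV. The 9:1 and 7:3 weightings are adopted
as constants, not re-derived.
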