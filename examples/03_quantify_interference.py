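"""Top-three-isotope quantitation under near-isobar interference.

Two glycoforms of one backbone differ by 2 Fuc vs 1 NeuAc: their masses are
>150 ppm apart, yet at z = 4 the heavier form's monoisotopic peak sits only
3-4 ppm from the lighter form's first isotope.  A plain XIC of that channel
is contaminated wherever the elution tails overlap; the per-scan isotope-
pattern gate (S >= 98) rejects those scans, so 3TIQ recovers each species'
abundance from clean spectral points.
"""

from nglyq import RunConfig, SimConfig, interference_pair, simulate_run, tiq3
from nglyq.chem import ppm

cfg = RunConfig()
pair = interference_pair()
a, b = pair
theo_a = a.record.pattern_for_charge(4)
theo_b = b.record.pattern_for_charge(4)
print(f"species 1: {a.record.glycopeptide}  mono m/z {theo_a.mz[0]:.4f}")
print(f"species 2: {b.record.glycopeptide}  mono m/z {theo_b.mz[0]:.4f}")
print(f"mass gap: {abs(ppm(b.record.neutral_mass, a.record.neutral_mass)):.0f} ppm; "
      f"mono(2) vs first isotope(1): "
      f"{abs(ppm(theo_b.mz[0], theo_a.mz[1])):.1f} ppm")

# quantify each species alone, then together
solo = {}
for sp in pair:
    run, _ = simulate_run(SimConfig(species=[sp], seed=3, ms1_noise_peaks=5))
    solo[sp.record.glycopeptide.glycan.code] = tiq3(
        run, sp.record, sp.charge, sp.rt, cfg).abundance

run, _ = simulate_run(SimConfig(species=pair, seed=3, ms1_noise_peaks=5))
print("\n              alone        together     error")
for sp in pair:
    code = sp.record.glycopeptide.glycan.code
    got = tiq3(run, sp.record, sp.charge, sp.rt, cfg).abundance
    err = (got - solo[code]) / solo[code] * 100
    print(f"  {code}:  {solo[code]:12.0f} {got:12.0f}   {err:+.1f}%")
print("\nQuantitation error stays within a few percent despite the overlap,")
print("because contaminated scans fail the isotope-pattern gate and are")
print("never used as spectral points.")
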