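"""Far-UV CD spectral normalisation: blanking, MRE, ME, and co-solvent math.

Simulates a disorder-dominated CD acquisition in instrument millidegrees,
blanks it, converts to mean residue ellipticity (MRE) and to the molar
extinction scale (ME), and prints the helix-stabilising co-solvent dilution
arithmetic.
"""

import numpy as np

from idrkit import (
    CDSpectrum,
    MILLIDEGREES,
    SyntheticCDConfig,
    convert_mre_me,
    plan_dilution,
    simulate_cd,
    subtract_blank,
    to_mre,
)

cfg = SyntheticCDConfig(noise_sd=0.1, seed=2)
sample = simulate_cd(cfg)
blank = CDSpectrum(
    sample.wavelengths,
    np.random.default_rng(3).normal(0.0, 0.05, len(sample)),
    MILLIDEGREES,
)
blanked = subtract_blank(sample, blank)
mre = to_mre(blanked, cfg.meta)
me = convert_mre_me(mre, "MRE->ME")

print("10 µM protein, 1 mm cuvette, 111 peptide bonds, 190-250 nm")
print(f"signal at 200 nm: {blanked.value_at(200):8.3f} mdeg")
print(f"MRE    at 200 nm: {mre.value_at(200):8.1f} deg cm^2 dmol^-1")
print(f"ME     at 200 nm: {me.value_at(200):8.3f}  (= MRE / 3298)")
print("the deep negative band near 200 nm is the signature of a disordered chain")

plan = plan_dilution(sample_volume_ul=320, sample_conc_um=12.5, additive_volume_ul=80)
print(
    f"\nTFE recipe: {plan.additive_volume_ul:g} µL into {plan.sample_volume_ul:g} µL "
    f"of {plan.sample_conc_um:g} µM protein"
)
print(
    f"  -> {plan.final_conc_um:g} µM final at {plan.additive_fraction_pct:g}% v/v TFE"
)
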