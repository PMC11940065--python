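"""Partner-induced structure via difference spectra.

Forward-simulates a disordered protein, its partner, and their 1:1 mixture
in which binding shifts 15% of the bound protein's ensemble from disordered
to helical.  The difference spectrum (non-interacting expectation minus the
measured mixture) deviates from zero exactly where structure was induced.
"""

import numpy as np

from idrkit import (
    MixtureMeta,
    SyntheticCDConfig,
    SyntheticMixtureConfig,
    difference_spectrum,
    expected_noninteracting,
    simulate_mixture,
    to_mre,
    to_mre_mixture,
)
from idrkit.synthetic import DEFAULT_PARTNER_META, bound_fraction

cfg = SyntheticMixtureConfig(
    component_a=SyntheticCDConfig(noise_sd=0.05, seed=4),
    component_b=SyntheticCDConfig(
        fractions={"helix": 0.25, "sheet": 0.35, "turn": 0.20, "disordered": 0.20},
        meta=DEFAULT_PARTNER_META,
        noise_sd=0.05,
        seed=5,
    ),
    kd=4e-6,
    induced_delta={"helix": 0.15, "sheet": 0.0, "turn": 0.0, "disordered": -0.15},
    seed=4,
)
spec_a, spec_b, spec_mix = simulate_mixture(cfg)
meta_a, meta_b = cfg.component_a.meta, cfg.component_b.meta

expected = expected_noninteracting(
    to_mre(spec_a, meta_a), to_mre(spec_b, meta_b), "weighted"
)
mix = to_mre_mixture(spec_mix, MixtureMeta(meta_a, meta_b), "total-residue")
diff = difference_spectrum(expected, mix)

print(f"true K_D {cfg.kd * 1e6:g} µM at 10 µM each")
print(f"fraction of the disordered protein bound: {bound_fraction(cfg):.2f}")
print(f"difference at 200 nm: {diff.value_at(200):+8.1f} MRE units")
print(f"difference at 222 nm: {diff.value_at(222):+8.1f} MRE units")
print(f"max |difference|:     {np.max(np.abs(diff.values)):8.1f} MRE units")
print(
    "nonzero values indicate secondary structure the non-interacting mixture\n"
    "cannot explain, i.e. binding-induced (here: helix gained at the expense\n"
    "of disorder, so the 190-210 nm region moves the most)"
)
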