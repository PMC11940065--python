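"""Secondary-structure deconvolution and two-wavelength classification.

Deconvolves a simulated MRE spectrum against the built-in Gaussian-band
basis (recovering the generating fractions) and places the spectrum on the
200-vs-222 nm plane used to tell random-coil from pre-molten-globule
disordered proteins.
"""

import numpy as np

from idrkit import (
    SyntheticCDConfig,
    TwoWavelengthPoint,
    classify_conformation,
    deconvolve,
    simulate_cd,
    to_mre,
    two_wavelength,
)

truth = {"helix": 0.10, "sheet": 0.10, "turn": 0.15, "disordered": 0.65}
cfg = SyntheticCDConfig(fractions=truth, noise_sd=0.1, seed=6)
mre = to_mre(simulate_cd(cfg), cfg.meta)

result = deconvolve(mre)
print("class       true   estimated")
for label in truth:
    print(f"{label:<11} {truth[label]:.2f}   {result.fractions[label]:.3f}")
print(f"fit NRMSD: {result.nrmsd:.4f} (0 = perfect reconstruction)")

# synthetic reference cohorts for the two-wavelength plane
rng = np.random.default_rng(0)
reference = [
    TwoWavelengthPoint(rng.normal(-19000, 1200), rng.normal(-2200, 500), "random_coil")
    for _ in range(20)
] + [
    TwoWavelengthPoint(
        rng.normal(-11000, 1200), rng.normal(-5200, 500), "pre_molten_globule"
    )
    for _ in range(20)
]
point = two_wavelength(mre)
assignment = classify_conformation(point, reference)
print(f"\ntheta_200 = {point.theta_200:.0f}, theta_222 = {point.theta_222:.0f}")
print(f"assigned cohort: {assignment.label}")
for label, dist in sorted(assignment.distances.items(), key=lambda kv: kv[1]):
    print(f"  distance to {label}: {dist:.2f} (standardised units)")
print(
    "the deep theta_200 of this mostly disordered chain places it with the\n"
    "random-coil cohort, but its theta_222 (residual helix/sheet) already\n"
    "leans toward the pre-molten-globule cluster - membership is graded,\n"
    "which is why both distances are reported"
)
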