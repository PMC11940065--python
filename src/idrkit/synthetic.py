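"""Seeded generators for sequences, CD spectra, mixtures, and binding curves.

Each generator is a pure function of its config: the config carries an
integer seed, a fresh ``numpy.random.Generator`` is built from it on every
call, and no global random state is touched.  The generators emulate the
study conditions of the experimental protocol this package analyses — a
~112-residue disorder-biased construct scanned from 190 to 250 nm in a 1 mm
cuvette at 10 µM, a 1:1 partner mixture with binding-induced helix gain, and
a 17-point 2-fold microscale-thermophoresis dilution series from 40 µM with
duplicate measurements — so that every analysis stage has a forward model
whose ground truth it can be checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .binding import BindingCurve, DilutionLadder, binding_model, dilution_ladder
from .deconvolution import BasisSet, SecondaryStructureFractions, default_basis
from .sequences import AMINO_ACIDS, DISORDER_PROMOTING, ProteinSequence
from .spectra import MILLIDEGREES, CDSpectrum, SampleMeta

# Study-condition defaults: 1 mm cuvette, 10 µM protein, 112-residue
# construct (111 peptide bonds), 190-250 nm at 1 nm.
DEFAULT_META = SampleMeta(pathlength_cm=0.1, molarity=10e-6, n_peptide_bonds=111)
DEFAULT_GRID = np.arange(190.0, 251.0)
#: Partner defaults: a linear tri-ubiquitin chain is 228 residues (3 x 76),
#: i.e. 227 peptide bonds, mixed 1:1 at the same 10 µM.
DEFAULT_PARTNER_META = SampleMeta(
    pathlength_cm=0.1, molarity=10e-6, n_peptide_bonds=227
)


@dataclass(frozen=True)
class SyntheticSequenceConfig:
    """Disorder-biased random sequence: composition shifted onto the
    disorder-promoting residue set with probability 0.4 + 0.6*bias."""

    length: int = 112
    disorder_bias: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 <= self.disorder_bias <= 1.0:
            raise ValueError("disorder_bias must lie in [0, 1]")


def generate_sequence(cfg: SyntheticSequenceConfig) -> ProteinSequence:
    """Draw a sequence with composition biased toward disorder-promoting
    residues.

    With bias 0 every residue is uniform over the 20; with bias 1 every
    residue comes from the disorder-promoting set.  The probability mass on
    the set interpolates linearly: 0.4 + 0.6*bias (0.4 being its share under
    the uniform distribution).
    """
    rng = np.random.default_rng(cfg.seed)
    dis = sorted(DISORDER_PROMOTING)
    other = sorted(set(AMINO_ACIDS) - DISORDER_PROMOTING)
    p_set = 0.4 + 0.6 * cfg.disorder_bias
    probs = np.array(
        [p_set / len(dis)] * len(dis) + [(1 - p_set) / len(other)] * len(other)
    )
    letters = np.array(dis + other)
    residues = "".join(rng.choice(letters, size=cfg.length, p=probs))
    return ProteinSequence(f"synthetic_seq_{cfg.seed}", residues)


def generate_alignment(
    cfg: SyntheticSequenceConfig,
    n_sequences: int = 5,
    conserved_columns: tuple[int, ...] = (),
    mutation_rate: float = 0.3,
) -> list[str]:
    """A toy alignment: a master sequence plus mutated copies, with the
    1-based ``conserved_columns`` held fixed in every row."""
    master = generate_sequence(cfg).residues
    rng = np.random.default_rng(cfg.seed + 1)
    rows = [master]
    letters = list(AMINO_ACIDS)
    for _ in range(n_sequences - 1):
        row = list(master)
        for j in range(len(row)):
            if (j + 1) in conserved_columns:
                continue
            if rng.random() < mutation_rate:
                row[j] = letters[rng.integers(20)]
        rows.append("".join(row))
    return rows


@dataclass(frozen=True)
class SyntheticCDConfig:
    """Ground-truth fractions plus acquisition parameters for one spectrum."""

    fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "helix": 0.10,
            "sheet": 0.10,
            "turn": 0.15,
            "disordered": 0.65,
        }
    )
    meta: SampleMeta = DEFAULT_META
    noise_sd: float = 0.1  # millidegrees, i.i.d. per point
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    seed: int = 0

    def __post_init__(self):
        SecondaryStructureFractions(self.fractions)  # simplex validation
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_cd(cfg: SyntheticCDConfig, basis: BasisSet | None = None) -> CDSpectrum:
    """Forward-model a CD acquisition in instrument units.

    The true MRE spectrum is the fraction-weighted basis combination; it is
    converted to millidegrees by the inverse of the MRE normalisation with
    ``cfg.meta`` and Gaussian noise of sd ``noise_sd`` mdeg is added.
    """
    if basis is None:
        basis = default_basis(cfg.grid)
    elif not np.array_equal(basis.wavelengths, np.asarray(cfg.grid, float)):
        raise ValueError("basis grid does not match cfg.grid")
    mre = basis.combine(dict(cfg.fractions))
    meta = cfg.meta
    mdeg = mre * (10.0 * meta.pathlength_cm * meta.molarity * meta.n_peptide_bonds)
    rng = np.random.default_rng(cfg.seed)
    noisy = mdeg + rng.normal(0.0, cfg.noise_sd, size=mdeg.size) if cfg.noise_sd > 0 else mdeg
    return CDSpectrum(np.asarray(cfg.grid, float), noisy, MILLIDEGREES, meta)


@dataclass(frozen=True)
class SyntheticMixtureConfig:
    """A 1:1 mixture experiment with optional binding-induced structure.

    ``induced_delta`` is the per-class fraction shift applied to the BOUND
    portion of component A (it must sum to zero so the shifted fractions stay
    on the simplex); the bound fraction comes from the 1:1 mass-action model
    at the stated concentrations.  ``induced_delta`` of all zeros gives a
    strictly additive, non-interacting mixture.
    """

    component_a: SyntheticCDConfig = field(default_factory=SyntheticCDConfig)
    component_b: SyntheticCDConfig = field(
        default_factory=lambda: SyntheticCDConfig(
            fractions={
                "helix": 0.25,
                "sheet": 0.35,
                "turn": 0.20,
                "disordered": 0.20,
            },
            meta=DEFAULT_PARTNER_META,
            seed=1,
        )
    )
    kd: float = 4e-6  # mol/L, low-micromolar partner affinity
    induced_delta: Mapping[str, float] = field(
        default_factory=lambda: {
            "helix": 0.15,
            "sheet": 0.0,
            "turn": 0.0,
            "disordered": -0.15,
        }
    )
    seed: int = 0

    def __post_init__(self):
        total = sum(self.induced_delta.values())
        if abs(total) > 1e-9:
            raise ValueError(f"induced_delta must sum to 0, got {total}")
        if self.kd <= 0:
            raise ValueError("kd must be > 0")


def bound_fraction(cfg: SyntheticMixtureConfig) -> float:
    """Fraction of component A bound at the configured 1:1 concentrations."""
    return float(
        binding_model(
            cfg.component_b.meta.molarity, cfg.kd, cfg.component_a.meta.molarity
        )
    )


def mixture_fractions_a(cfg: SyntheticMixtureConfig) -> dict[str, float]:
    """Component A's ensemble fractions in the mixture (bound-weighted)."""
    fb = bound_fraction(cfg)
    shifted = {
        c: cfg.component_a.fractions[c] + fb * cfg.induced_delta[c]
        for c in cfg.component_a.fractions
    }
    if any(v < -1e-12 for v in shifted.values()):
        raise ValueError(
            f"induced_delta pushes fractions off the simplex: {shifted}"
        )
    return {c: max(v, 0.0) for c, v in shifted.items()}


def simulate_mixture(
    cfg: SyntheticMixtureConfig, basis: BasisSet | None = None
) -> tuple[CDSpectrum, CDSpectrum, CDSpectrum]:
    """(spectrum A alone, spectrum B alone, 1:1 mixture), all in millidegrees.

    The mixture signal is the sum of B's signal and the signal of A with its
    fractions shifted by ``induced_delta`` scaled by the bound fraction;
    each of the three spectra gets independent noise from one seeded stream.
    """
    grid = np.asarray(cfg.component_a.grid, float)
    if not np.array_equal(grid, np.asarray(cfg.component_b.grid, float)):
        raise ValueError("components must share a wavelength grid")
    basis = basis if basis is not None else default_basis(grid)
    rng = np.random.default_rng(cfg.seed)

    def signal(fractions: Mapping[str, float], meta: SampleMeta) -> np.ndarray:
        mre = basis.combine(dict(fractions))
        return mre * (10.0 * meta.pathlength_cm * meta.molarity * meta.n_peptide_bonds)

    a_cfg, b_cfg = cfg.component_a, cfg.component_b
    clean_a = signal(a_cfg.fractions, a_cfg.meta)
    clean_b = signal(b_cfg.fractions, b_cfg.meta)
    clean_mix = signal(mixture_fractions_a(cfg), a_cfg.meta) + clean_b

    def noisy(clean: np.ndarray, sd: float) -> np.ndarray:
        return clean + rng.normal(0.0, sd, size=clean.size) if sd > 0 else clean

    spec_a = CDSpectrum(grid, noisy(clean_a, a_cfg.noise_sd), MILLIDEGREES, a_cfg.meta)
    spec_b = CDSpectrum(grid, noisy(clean_b, b_cfg.noise_sd), MILLIDEGREES, b_cfg.meta)
    mix_sd = float(np.hypot(a_cfg.noise_sd, b_cfg.noise_sd))
    spec_mix = CDSpectrum(grid, noisy(clean_mix, mix_sd), MILLIDEGREES)
    return spec_a, spec_b, spec_mix


@dataclass(frozen=True)
class SyntheticBindingConfig:
    """An MST titration: 2-fold ladder from 40 µM, duplicates, low-µM K_D."""

    kd: float = 5e-6
    ct: float = 50e-9
    ladder: DilutionLadder = field(
        default_factory=lambda: dilution_ladder(40e-6, 2.0, 16)
    )
    noise_sd: float = 0.02  # fraction-bound units per replicate
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.kd <= 0 or self.ct <= 0:
            raise ValueError("kd and ct must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_binding(cfg: SyntheticBindingConfig) -> BindingCurve:
    """Per-replicate Gaussian noise around the mass-action model; the curve
    carries the replicate mean and (for n >= 2) the per-point sample SD."""
    rng = np.random.default_rng(cfg.seed)
    conc = cfg.ladder.concentrations
    truth = binding_model(conc, cfg.kd, cfg.ct)
    reps = truth[None, :] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_replicates, conc.size)
    )
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if cfg.n_replicates > 1 else np.zeros_like(mean)
    return BindingCurve(
        conc,
        np.clip(mean, -0.2, 1.2),
        cfg.ct,
        replicate_sd=sd,
        is_fraction_bound=True,
    )


def simulate_binding_replicates(cfg: SyntheticBindingConfig) -> np.ndarray:
    """The raw replicate matrix (n_replicates x n_points), same stream as
    :func:`simulate_binding` — useful for writing long-format CSV."""
    rng = np.random.default_rng(cfg.seed)
    conc = cfg.ladder.concentrations
    truth = binding_model(conc, cfg.kd, cfg.ct)
    return truth[None, :] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_replicates, conc.size)
    )
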