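"""Far-UV circular-dichroism spectral arithmetic.

A far-UV CD measurement leaves the instrument as an ellipticity trace in
millidegrees on a wavelength grid (conventionally 190-250 nm in 1 nm steps).
Before spectra of different constructs can be compared they are blanked and
normalised to mean residue ellipticity,

    MRE = m_deg / (10 * l * M * n)        [deg cm^2 dmol^-1]

with pathlength l (cm), molar concentration M (mol/L) and n the number of
peptide bonds (residue count - 1).  For deconvolution software working on a
molar-extinction scale the further conversion ME = MRE / 3298 applies.

For a 1:1 two-protein mixture two normalisations are provided.  The
``paper`` convention divides by the mean molarity times the mean bond count,

    MRE_mix = m_deg / (10 * l * (M_A + M_B)/2 * (n_A + n_B)/2),

exactly as printed in the protocol this module follows.  That convention is
internally inconsistent with the arithmetic-mean "non-interacting
expectation": for a strictly additive signal at equal molarity it returns
roughly the SUM of the component MREs rather than their mean.  The default
``total-residue`` convention divides by 10 * l * (M_A n_A + M_B n_B), which
makes the difference spectrum of a truly non-interacting mixture identically
zero.  Both are available; choose deliberately.

All arithmetic refuses mixed units or mismatched grids; resampling is an
explicit, separate step (:func:`resample`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MILLIDEGREES = "millidegrees"
MRE = "MRE"
ME = "ME"
UNITS = (MILLIDEGREES, MRE, ME)

#: MRE (deg cm^2 dmol^-1) per unit molar extinction: ME = MRE / 3298.
MRE_PER_ME = 3298.0

WAVELENGTH_MIN_NM = 170.0
WAVELENGTH_MAX_NM = 300.0


class UnitError(ValueError):
    """An operation received a spectrum in the wrong unit state."""


class GridMismatchError(ValueError):
    """Two spectra do not share a wavelength grid."""

    def __init__(self, grid_a: np.ndarray, grid_b: np.ndarray):
        self.grid_a = grid_a
        self.grid_b = grid_b
        super().__init__(
            "wavelength grids differ: "
            f"[{grid_a[0]:g}..{grid_a[-1]:g}] n={grid_a.size} vs "
            f"[{grid_b[0]:g}..{grid_b[-1]:g}] n={grid_b.size}; "
            "resample explicitly before combining"
        )


@dataclass(frozen=True)
class SampleMeta:
    """Physical parameters entering the MRE normalisation."""

    pathlength_cm: float
    molarity: float
    n_peptide_bonds: int

    def __post_init__(self):
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength_cm must be > 0")
        if self.molarity <= 0:
            raise ValueError("molarity must be > 0 (mol/L)")
        if self.n_peptide_bonds < 1:
            raise ValueError("n_peptide_bonds must be >= 1")

    @classmethod
    def from_residue_count(
        cls, pathlength_cm: float, molarity: float, n_residues: int
    ) -> "SampleMeta":
        """n_peptide_bonds = residue count - 1."""
        return cls(pathlength_cm, molarity, n_residues - 1)


@dataclass(frozen=True)
class MixtureMeta:
    """Per-component parameters of a two-protein mixture."""

    component_a: SampleMeta
    component_b: SampleMeta

    def __post_init__(self):
        if self.component_a.pathlength_cm != self.component_b.pathlength_cm:
            raise ValueError("mixture components must share a pathlength")


@dataclass(frozen=True)
class CDSpectrum:
    """A CD spectrum: strictly ascending wavelength grid, values, unit tag."""

    wavelengths: np.ndarray
    values: np.ndarray
    unit: str
    meta: SampleMeta | None = None

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("need at least two wavelength points")
        if wl.shape != vals.shape:
            raise ValueError("wavelengths and values must have equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if wl[0] < WAVELENGTH_MIN_NM or wl[-1] > WAVELENGTH_MAX_NM:
            raise ValueError(
                f"wavelengths must lie within [{WAVELENGTH_MIN_NM:g}, "
                f"{WAVELENGTH_MAX_NM:g}] nm"
            )
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {UNITS}")

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "CDSpectrum":
        return replace(self, values=np.asarray(values, float), unit=unit or self.unit)

    def value_at(self, wavelength_nm: float) -> float:
        """Value at a wavelength, linearly interpolated within the span."""
        wl = self.wavelengths
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(
                f"{wavelength_nm:g} nm outside spectral span "
                f"[{wl[0]:g}, {wl[-1]:g}] nm"
            )
        return float(np.interp(wavelength_nm, wl, self.values))


def _require_unit(spectrum: CDSpectrum, unit: str, op: str) -> None:
    if spectrum.unit != unit:
        raise UnitError(f"{op} requires unit {unit!r}, got {spectrum.unit!r}")


def _require_same_grid(a: CDSpectrum, b: CDSpectrum) -> None:
    if not np.array_equal(a.wavelengths, b.wavelengths):
        raise GridMismatchError(a.wavelengths, b.wavelengths)


def subtract_blank(sample: CDSpectrum, blank: CDSpectrum) -> CDSpectrum:
    """Pointwise sample - blank, both in millidegrees on the same grid."""
    _require_unit(sample, MILLIDEGREES, "subtract_blank")
    _require_unit(blank, MILLIDEGREES, "subtract_blank")
    _require_same_grid(sample, blank)
    return sample.with_values(sample.values - blank.values)


def to_mre(spectrum: CDSpectrum, meta: SampleMeta) -> CDSpectrum:
    """Millidegrees -> mean residue ellipticity: m_deg / (10 l M n)."""
    _require_unit(spectrum, MILLIDEGREES, "to_mre")
    denom = 10.0 * meta.pathlength_cm * meta.molarity * meta.n_peptide_bonds
    return replace(
        spectrum, values=spectrum.values / denom, unit=MRE, meta=meta
    )


def from_mre(spectrum: CDSpectrum, meta: SampleMeta) -> CDSpectrum:
    """Inverse of :func:`to_mre` (MRE -> instrument millidegrees)."""
    _require_unit(spectrum, MRE, "from_mre")
    denom = 10.0 * meta.pathlength_cm * meta.molarity * meta.n_peptide_bonds
    return replace(
        spectrum, values=spectrum.values * denom, unit=MILLIDEGREES, meta=meta
    )


PAPER_CONVENTION = "paper"
TOTAL_RESIDUE_CONVENTION = "total-residue"


def to_mre_mixture(
    spectrum: CDSpectrum,
    mix: MixtureMeta,
    convention: str = TOTAL_RESIDUE_CONVENTION,
) -> CDSpectrum:
    """Normalise a 1:1 mixture signal to MRE.

    ``total-residue`` (default) divides by 10*l*(M_A n_A + M_B n_B) and makes
    a strictly additive (non-interacting) mixture reproduce the
    concentration-weighted mean of the component MREs.  ``paper`` divides by
    10*l*mean(M)*mean(n) — the printed protocol equation, kept for
    bit-for-bit reproduction; see the module docstring for the caveat.
    """
    _require_unit(spectrum, MILLIDEGREES, "to_mre_mixture")
    a, b = mix.component_a, mix.component_b
    pathlength = a.pathlength_cm
    if convention == PAPER_CONVENTION:
        denom = (
            10.0
            * pathlength
            * ((a.molarity + b.molarity) / 2.0)
            * ((a.n_peptide_bonds + b.n_peptide_bonds) / 2.0)
        )
    elif convention == TOTAL_RESIDUE_CONVENTION:
        denom = 10.0 * pathlength * (
            a.molarity * a.n_peptide_bonds + b.molarity * b.n_peptide_bonds
        )
    else:
        raise ValueError(
            f"unknown convention {convention!r}; expected "
            f"{PAPER_CONVENTION!r} or {TOTAL_RESIDUE_CONVENTION!r}"
        )
    return replace(spectrum, values=spectrum.values / denom, unit=MRE)


def convert_mre_me(spectrum: CDSpectrum, direction: str = "MRE->ME") -> CDSpectrum:
    """Convert between MRE and the molar-extinction scale (ME = MRE/3298)."""
    if direction == "MRE->ME":
        _require_unit(spectrum, MRE, "convert_mre_me")
        return spectrum.with_values(spectrum.values / MRE_PER_ME, ME)
    if direction == "ME->MRE":
        _require_unit(spectrum, ME, "convert_mre_me")
        return spectrum.with_values(spectrum.values * MRE_PER_ME, MRE)
    raise ValueError(f"direction must be 'MRE->ME' or 'ME->MRE', got {direction!r}")


def average_spectra(spectra: Sequence[CDSpectrum]) -> CDSpectrum:
    """Pointwise mean of replicate spectra (same grid, same unit)."""
    if not spectra:
        raise ValueError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if s.unit != first.unit:
            raise UnitError(
                f"cannot average units {first.unit!r} and {s.unit!r}"
            )
        _require_same_grid(first, s)
    stacked = np.vstack([s.values for s in spectra])
    return first.with_values(stacked.mean(axis=0))


ARITHMETIC = "arithmetic"
WEIGHTED = "weighted"


def expected_noninteracting(
    spec_a: CDSpectrum,
    spec_b: CDSpectrum,
    mode: str = ARITHMETIC,
    meta_a: SampleMeta | None = None,
    meta_b: SampleMeta | None = None,
) -> CDSpectrum:
    """Spectrum expected from two proteins in solution but not interacting.

    ``arithmetic`` is the plain pointwise mean of the two MRE spectra (the
    protocol's "mathematical average"); ``weighted`` weights each component
    by its molarity times bond count, the combination that pairs exactly with
    the total-residue mixture normalisation.
    """
    _require_unit(spec_a, MRE, "expected_noninteracting")
    _require_unit(spec_b, MRE, "expected_noninteracting")
    _require_same_grid(spec_a, spec_b)
    if mode == ARITHMETIC:
        values = (spec_a.values + spec_b.values) / 2.0
    elif mode == WEIGHTED:
        meta_a = meta_a or spec_a.meta
        meta_b = meta_b or spec_b.meta
        if meta_a is None or meta_b is None:
            raise ValueError("weighted mode needs SampleMeta for both spectra")
        wa = meta_a.molarity * meta_a.n_peptide_bonds
        wb = meta_b.molarity * meta_b.n_peptide_bonds
        values = (wa * spec_a.values + wb * spec_b.values) / (wa + wb)
    else:
        raise ValueError(f"mode must be 'arithmetic' or 'weighted', got {mode!r}")
    return replace(spec_a, values=values, meta=None)


def difference_spectrum(
    expected: CDSpectrum, experimental_mixture: CDSpectrum
) -> CDSpectrum:
    """Expected minus measured mixture (mixture subtracted FROM the average).

    Deviations from zero indicate secondary structure not present in a
    non-interacting mixture, i.e. partner-induced conformational change.
    """
    _require_unit(expected, MRE, "difference_spectrum")
    _require_unit(experimental_mixture, MRE, "difference_spectrum")
    _require_same_grid(expected, experimental_mixture)
    return expected.with_values(expected.values - experimental_mixture.values)


def resample(spectrum: CDSpectrum, new_grid: np.ndarray) -> CDSpectrum:
    """Linear interpolation onto a new grid (must lie within the span)."""
    new_grid = np.asarray(new_grid, dtype=float)
    wl = spectrum.wavelengths
    if new_grid[0] < wl[0] or new_grid[-1] > wl[-1]:
        raise ValueError(
            f"target grid [{new_grid[0]:g}, {new_grid[-1]:g}] nm exceeds "
            f"spectral span [{wl[0]:g}, {wl[-1]:g}] nm"
        )
    values = np.interp(new_grid, wl, spectrum.values)
    return replace(spectrum, wavelengths=new_grid, values=values)


@dataclass(frozen=True)
class DilutionPlan:
    """Adding a co-solvent volume to a protein sample: final state."""

    sample_volume_ul: float
    sample_conc_um: float
    additive_volume_ul: float
    final_conc_um: float
    additive_fraction_pct: float


def plan_dilution(
    sample_volume_ul: float, sample_conc_um: float, additive_volume_ul: float
) -> DilutionPlan:
    """Final concentration and % v/v after adding a co-solvent (e.g. TFE).

    Conservation of moles: c_final = c * V_sample / (V_sample + V_additive).
    """
    if sample_volume_ul < 0 or additive_volume_ul < 0:
        raise ValueError("volumes must be >= 0")
    if sample_conc_um <= 0:
        raise ValueError("sample concentration must be > 0")
    total = sample_volume_ul + additive_volume_ul
    if total == 0:
        raise ValueError("total volume is zero")
    final_conc = sample_conc_um * sample_volume_ul / total
    fraction = 100.0 * additive_volume_ul / total
    return DilutionPlan(
        sample_volume_ul, sample_conc_um, additive_volume_ul, final_conc, fraction
    )


# ---------------------------------------------------------------------------
# Spectral text I/O.  Two dialects of two-column wavelength/value text:
#   .txt  — ascending wavelengths, optional non-numeric header line
#   .gen  — the same columns with wavelengths in DESCENDING order
# '#'-prefixed lines are comments in both.

TXT_DIALECT = "txt"
GEN_DIALECT = "gen"


def _dialect_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return GEN_DIALECT if path.suffix.lower() == ".gen" else TXT_DIALECT


def read_spectrum(
    path: str | Path,
    unit: str = MILLIDEGREES,
    dialect: str | None = None,
    meta: SampleMeta | None = None,
) -> CDSpectrum:
    """Read a two-column spectral text file (.txt ascending, .gen descending).

    The on-disk unit is not recorded in either dialect, so the caller states
    it via ``unit``.
    """
    path = Path(path)
    dialect = _dialect_for(path, dialect)
    wavelengths, values = [], []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            wl, val = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            if not wavelengths:  # tolerate a single header line
                continue
            raise ValueError(f"{path}: malformed line {raw!r}")
        wavelengths.append(wl)
        values.append(val)
    if len(wavelengths) < 2:
        raise ValueError(f"{path}: fewer than 2 data points")
    wl = np.array(wavelengths)
    vals = np.array(values)
    if dialect == GEN_DIALECT:
        if np.any(np.diff(wl) >= 0):
            raise ValueError(f"{path}: .gen dialect requires descending wavelengths")
        wl, vals = wl[::-1], vals[::-1]
    return CDSpectrum(wl, vals, unit, meta)


def write_spectrum(
    path: str | Path, spectrum: CDSpectrum, dialect: str | None = None
) -> None:
    path = Path(path)
    dialect = _dialect_for(path, dialect)
    wl, vals = spectrum.wavelengths, spectrum.values
    if dialect == GEN_DIALECT:
        wl, vals = wl[::-1], vals[::-1]
    lines = [f"# unit: {spectrum.unit}"]
    lines += [f"{w:.6g}\t{v:.10g}" for w, v in zip(wl, vals)]
    path.write_text("\n".join(lines) + "\n")


def spectrum_to_csv(path: str | Path, spectrum: CDSpectrum) -> None:
    """CSV export with columns wavelength_nm, value, unit."""
    import pandas as pd

    pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelengths,
            "value": spectrum.values,
            "unit": spectrum.unit,
        }
    ).to_csv(path, index=False)
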