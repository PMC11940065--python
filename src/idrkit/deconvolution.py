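"""Secondary-structure estimation from far-UV CD spectra.

Deconvolution treats a measured MRE spectrum as a convex combination of
per-class reference spectra (helix, sheet, turn, disordered) and recovers
the class fractions by ridge-regularised least squares on the probability
simplex:

    minimise  ||y - B f||^2 + lambda ||f||^2   s.t.  f >= 0,  sum(f) = 1.

The reference sets used by the deconvolution servers (SP175, IDP175, the
CONTIN "dataset 7" basis) are curated protein databases distributed with
those tools; this module ships a parametric stand-in basis — per-class sums
of Gaussian bands at the canonical far-UV positions — and reads any
user-supplied basis from CSV.  Fractions estimated against the synthetic
basis are internally consistent (generator <-> estimator) but are not the
numbers a database-driven server would report for real spectra.

The two-wavelength (Uversky) plot reduces a spectrum to its MRE at 200 and
222 nm, a plane in which random-coil and pre-molten-globule proteins form
separable clusters; classification here is nearest-centroid on axes
standardised by the reference cohorts' pooled standard deviation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .spectra import MRE, CDSpectrum, resample

HELIX = "helix"
SHEET = "sheet"
TURN = "turn"
DISORDERED = "disordered"

RANDOM_COIL = "random_coil"
PRE_MOLTEN_GLOBULE = "pre_molten_globule"

#: Gaussian bands (center nm, amplitude in MRE units, width nm) per class.
#: Positions follow the canonical far-UV CD features: helix +193/-208/-222,
#: sheet +195/-218, disordered strong negative near 198; amplitudes are
#: order-of-magnitude typical for fully formed structure.
DEFAULT_BANDS: Mapping[str, tuple[tuple[float, float, float], ...]] = {
    HELIX: ((193.0, 68000.0, 7.0), (208.0, -33000.0, 8.0), (222.0, -35000.0, 10.0)),
    SHEET: ((195.0, 38000.0, 7.0), (218.0, -20000.0, 10.0)),
    TURN: ((190.0, -10000.0, 7.0), (205.0, 7000.0, 9.0), (225.0, -3000.0, 10.0)),
    DISORDERED: ((198.0, -42000.0, 9.0), (222.0, 2500.0, 12.0)),
}

DEFAULT_FIT_RANGE = (190.0, 240.0)

SIMPLEX_ATOL = 1e-6


@dataclass(frozen=True)
class BasisSet:
    """Per-class reference MRE spectra on a shared wavelength grid."""

    wavelengths: np.ndarray
    spectra: Mapping[str, np.ndarray]

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        spectra = {k: np.asarray(v, dtype=float) for k, v in self.spectra.items()}
        object.__setattr__(self, "spectra", spectra)
        if len(spectra) < 2:
            raise ValueError("basis needs at least 2 classes")
        for label, ref in spectra.items():
            if ref.shape != wl.shape:
                raise ValueError(f"class {label!r} not on the shared grid")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("basis grid must be strictly ascending")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.spectra)

    def matrix(self) -> np.ndarray:
        """Columns are class reference spectra, in label order."""
        return np.column_stack([self.spectra[c] for c in self.labels])

    def combine(self, fractions: Mapping[str, float]) -> np.ndarray:
        """Spectrum of a fractional mixture of the classes."""
        if set(fractions) != set(self.labels):
            raise ValueError(
                f"fraction classes {sorted(fractions)} != basis classes "
                f"{sorted(self.labels)}"
            )
        return sum(fractions[c] * self.spectra[c] for c in self.labels)

    def restricted(self, lo: float, hi: float) -> "BasisSet":
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if mask.sum() < len(self.labels):
            raise ValueError("fit range leaves fewer points than classes")
        return BasisSet(
            self.wavelengths[mask], {c: v[mask] for c, v in self.spectra.items()}
        )


def default_basis(
    wavelengths: np.ndarray | None = None,
    bands: Mapping[str, tuple[tuple[float, float, float], ...]] = DEFAULT_BANDS,
) -> BasisSet:
    """Parametric Gaussian-band basis on a grid (default 190-250 nm, 1 nm)."""
    if wavelengths is None:
        wavelengths = np.arange(190.0, 251.0)
    wavelengths = np.asarray(wavelengths, dtype=float)
    spectra = {}
    for label, band_list in bands.items():
        ref = np.zeros_like(wavelengths)
        for center, amplitude, width in band_list:
            ref += amplitude * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
        spectra[label] = ref
    return BasisSet(wavelengths, spectra)


@dataclass(frozen=True)
class SecondaryStructureFractions:
    """Per-class fractions on the probability simplex."""

    fractions: Mapping[str, float]

    def __post_init__(self):
        fr = dict(self.fractions)
        object.__setattr__(self, "fractions", fr)
        vals = np.array(list(fr.values()))
        if np.any(vals < -SIMPLEX_ATOL):
            raise ValueError(f"negative fraction in {fr}")
        if abs(vals.sum() - 1.0) > SIMPLEX_ATOL:
            raise ValueError(f"fractions sum to {vals.sum():.8f}, not 1")

    def __getitem__(self, label: str) -> float:
        return self.fractions[label]

    def as_dict(self) -> dict[str, float]:
        return dict(self.fractions)


@dataclass(frozen=True)
class DeconvolutionResult:
    fractions: SecondaryStructureFractions
    nrmsd: float
    ridge_lambda: float

    def __post_init__(self):
        if self.nrmsd < 0 or self.ridge_lambda < 0:
            raise ValueError("nrmsd and ridge_lambda must be >= 0")


def _solve_on_support(
    B: np.ndarray, y: np.ndarray, ridge_lambda: float
) -> np.ndarray | None:
    """Minimise ||y - B f||^2 + lambda||f||^2 s.t. sum(f)=1 (no sign bound).

    The sum constraint is removed by the substitution f = f0 + N u with f0
    uniform and N an orthonormal null-space basis of the all-ones row.
    Returns None when the reduced system is singular (duplicate columns).
    """
    k = B.shape[1]
    f0 = np.full(k, 1.0 / k)
    if k == 1:
        return f0
    # Orthonormal basis of {u : sum(u) = 0} via QR of ones^T's null space.
    ones = np.ones((k, 1))
    q, _ = np.linalg.qr(np.eye(k) - ones @ ones.T / k)
    N = q[:, : k - 1]
    A = B @ N
    r = y - B @ f0
    lhs = A.T @ A + ridge_lambda * (N.T @ N)
    rhs = A.T @ r - ridge_lambda * (N.T @ f0)
    try:
        u = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        return None
    return f0 + N @ u


def _simplex_ridge(B: np.ndarray, y: np.ndarray, ridge_lambda: float) -> np.ndarray:
    """Exact simplex-constrained ridge LS by active-set enumeration.

    At the optimum the nonzero coordinates satisfy the equality-constrained
    stationarity conditions on their support, so enumerating all non-empty
    supports, solving each reduced equality-constrained problem, and keeping
    the feasible candidate with the lowest objective recovers the global
    minimiser exactly.  Exponential in the class count, which is small.
    """
    k = B.shape[1]
    best_f, best_obj = None, np.inf
    for size in range(1, k + 1):
        for support in itertools.combinations(range(k), size):
            sub = _solve_on_support(B[:, support], y, ridge_lambda)
            if sub is None or np.any(sub < -1e-12):
                continue
            f = np.zeros(k)
            f[list(support)] = np.clip(sub, 0.0, None)
            f /= f.sum()
            resid = y - B @ f
            obj = float(resid @ resid + ridge_lambda * (f @ f))
            if obj < best_obj:
                best_obj, best_f = obj, f
    assert best_f is not None  # the k vertices are always feasible
    return best_f


def deconvolve(
    spectrum: CDSpectrum,
    basis: BasisSet | None = None,
    ridge_lambda: float = 0.0,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
) -> DeconvolutionResult:
    """Estimate secondary-structure fractions of an MRE spectrum.

    The spectrum is linearly resampled onto the basis grid restricted to
    ``fit_range`` (default 190-240 nm, the far-UV window in which the class
    spectra are most distinctive); its span must cover that grid.  NRMSD is
    sqrt(sum((fit-y)^2)/sum(y^2)) over the fitted range.
    """
    if spectrum.unit != MRE:
        raise ValueError(f"deconvolve expects an MRE spectrum, got {spectrum.unit!r}")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    basis = basis if basis is not None else default_basis()
    sub_basis = basis.restricted(*fit_range)
    grid = sub_basis.wavelengths
    if spectrum.wavelengths[0] > grid[0] or spectrum.wavelengths[-1] < grid[-1]:
        raise ValueError(
            f"spectrum span [{spectrum.wavelengths[0]:g}, "
            f"{spectrum.wavelengths[-1]:g}] nm does not cover the basis grid "
            f"[{grid[0]:g}, {grid[-1]:g}] nm"
        )
    y = resample(spectrum, grid).values
    B = sub_basis.matrix()
    # Scale the problem so ridge_lambda is comparable across spectra of
    # different magnitudes: normalise by the largest basis column norm.
    scale = max(np.linalg.norm(B[:, j]) for j in range(B.shape[1]))
    f = _simplex_ridge(B / scale, y / scale, ridge_lambda)
    fit = B @ f
    denom = float(y @ y)
    nrmsd = float(np.sqrt(((fit - y) @ (fit - y)) / denom)) if denom > 0 else 0.0
    fractions = SecondaryStructureFractions(
        {c: float(f[j]) for j, c in enumerate(sub_basis.labels)}
    )
    return DeconvolutionResult(fractions, nrmsd, ridge_lambda)


@dataclass(frozen=True)
class TwoWavelengthPoint:
    """A spectrum reduced to its (theta_200, theta_222) coordinates."""

    theta_200: float
    theta_222: float
    label: str | None = None

    def __post_init__(self):
        if not (np.isfinite(self.theta_200) and np.isfinite(self.theta_222)):
            raise ValueError("two-wavelength coordinates must be finite")

    def coords(self) -> np.ndarray:
        return np.array([self.theta_200, self.theta_222])


def two_wavelength(spectrum: CDSpectrum) -> TwoWavelengthPoint:
    """MRE at exactly 200 and 222 nm (interpolated if off-grid)."""
    if spectrum.unit != MRE:
        raise ValueError(
            f"two_wavelength expects an MRE spectrum, got {spectrum.unit!r}"
        )
    return TwoWavelengthPoint(spectrum.value_at(200.0), spectrum.value_at(222.0))


@dataclass(frozen=True)
class ClassificationResult:
    """Nearest-centroid assignment with per-cohort standardised distances.

    ``tie`` is set when the two nearest cohorts are indistinguishable, in
    which case ``label`` is None rather than an arbitrary pick.
    """

    label: str | None
    distances: Mapping[str, float]
    tie: bool


def classify_conformation(
    point: TwoWavelengthPoint,
    reference: Sequence[TwoWavelengthPoint],
    tie_rtol: float = 1e-9,
) -> ClassificationResult:
    """Assign a two-wavelength point to the nearest reference cohort.

    Axes are standardised by the pooled within-cohort standard deviation so
    the two (very differently scaled) wavelengths contribute comparably;
    distances to every cohort centroid are returned so that partial
    membership ("to varying degrees") stays quantifiable.
    """
    cohorts: dict[str, list[np.ndarray]] = {}
    for ref in reference:
        if ref.label is None:
            raise ValueError("reference points must be labeled")
        cohorts.setdefault(ref.label, []).append(ref.coords())
    if len(cohorts) < 1:
        raise ValueError("empty reference set")
    arrays = {label: np.vstack(pts) for label, pts in cohorts.items()}
    centroids = {label: a.mean(axis=0) for label, a in arrays.items()}
    # Pooled within-cohort variance per axis.
    ss = np.zeros(2)
    dof = 0
    for label, a in arrays.items():
        ss += ((a - centroids[label]) ** 2).sum(axis=0)
        dof += max(a.shape[0] - 1, 0)
    if dof == 0 or np.any(ss == 0):
        # Degenerate reference (single points or zero spread on an axis).
        if len(reference) <= len(cohorts):
            scale = np.ones(2)  # one point per cohort: raw axes
        else:
            raise ValueError("degenerate reference: zero within-cohort variance")
    else:
        scale = np.sqrt(ss / dof)
    x = point.coords() / scale
    distances = {
        label: float(np.linalg.norm(x - centroids[label] / scale))
        for label in centroids
    }
    ordered = sorted(distances.items(), key=lambda kv: kv[1])
    if len(ordered) > 1:
        best, second = ordered[0][1], ordered[1][1]
        tie = abs(best - second) <= tie_rtol * max(1.0, best, second)
    else:
        tie = False
    label = None if tie else ordered[0][0]
    return ClassificationResult(label, distances, tie)


# ---------------------------------------------------------------------------
# CSV I/O


def read_basis_csv(path: str | Path) -> BasisSet:
    """Multi-column CSV: wavelength_nm plus one MRE column per class."""
    import pandas as pd

    df = pd.read_csv(path)
    wl_col = df.columns[0]
    classes = [c for c in df.columns if c != wl_col]
    return BasisSet(
        df[wl_col].to_numpy(float), {c: df[c].to_numpy(float) for c in classes}
    )


def write_basis_csv(path: str | Path, basis: BasisSet) -> None:
    import pandas as pd

    data = {"wavelength_nm": basis.wavelengths}
    data.update({c: basis.spectra[c] for c in basis.labels})
    pd.DataFrame(data).to_csv(path, index=False)


def read_reference_csv(path: str | Path) -> list[TwoWavelengthPoint]:
    """Reference points as CSV with columns theta_200, theta_222, label."""
    import pandas as pd

    df = pd.read_csv(path)
    return [
        TwoWavelengthPoint(row.theta_200, row.theta_222, str(row.label))
        for row in df.itertuples()
    ]


def write_reference_csv(
    path: str | Path, points: Sequence[TwoWavelengthPoint]
) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "theta_200": [p.theta_200 for p in points],
            "theta_222": [p.theta_222 for p in points],
            "label": [p.label for p in points],
        }
    ).to_csv(path, index=False)
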