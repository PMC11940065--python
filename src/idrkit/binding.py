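"""Binding-affinity estimation from microscale-thermophoresis dose-response
data.

The labeled target (concentration ct, constant across the titration) is
incubated with a serial dilution of ligand; the observed response is the
fraction of target bound.  The 1:1 mass-action model with ligand depletion,

    fb(c) = ((c + ct + K_D) - sqrt((c + ct + K_D)^2 - 4 c ct)) / (2 ct),

is fitted by weighted nonlinear least squares with a multi-start over
log-spaced K_D initial values, and every fit carries a saturation diagnostic:
a K_D estimated from a titration that never approaches saturation is
systematically unreliable, so such fits are flagged and reported as bounds
rather than values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

DEFAULT_TARGET_CONC = 50e-9  # mol/L; typical for His-tag dye labeling
KD_INIT_GRID = np.logspace(-9, -3, 13)  # mol/L multi-start initial values
KD_RELIABLE_RANGE = (1e-10, 1e-2)  # outside -> flagged "at search bound"

SATURATION_CONC_MARGIN = 5.0  # require top conc >= margin * kd ...
SATURATION_FB_THRESHOLD = 0.8  # ... and model fb(top) >= this


@dataclass(frozen=True)
class DilutionLadder:
    """Geometric (serial) dilution: top, top/fold, ..., top/fold^n_steps."""

    top_conc: float
    fold: float
    n_steps: int
    concentrations: np.ndarray

    def __len__(self) -> int:
        return self.concentrations.size


def dilution_ladder(top_conc: float, fold: float, n_steps: int) -> DilutionLadder:
    """Serial dilution with ``n_steps`` dilutions, hence n_steps+1 points."""
    if top_conc <= 0:
        raise ValueError("top_conc must be > 0")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    conc = top_conc / fold ** np.arange(n_steps + 1, dtype=float)
    return DilutionLadder(top_conc, fold, n_steps, conc)


def binding_model(
    c: np.ndarray | float, kd: float, ct: float
) -> np.ndarray | float:
    """Fraction of target bound under 1:1 mass action with depletion.

    Evaluated as 2c / (s + sqrt(s^2 - 4 c ct)) with s = c + ct + kd, the
    algebraically equivalent form that avoids catastrophic cancellation at
    small c.
    """
    if kd < 0:
        raise ValueError("kd must be >= 0")
    if ct <= 0:
        raise ValueError("ct must be > 0")
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("ligand concentrations must be >= 0")
    s = c_arr + ct + kd
    disc = np.sqrt(np.maximum(s * s - 4.0 * c_arr * ct, 0.0))
    fb = np.where(c_arr > 0, 2.0 * c_arr / (s + disc), 0.0)
    fb = np.clip(fb, 0.0, 1.0)
    return float(fb) if np.isscalar(c) else fb


@dataclass(frozen=True)
class BindingCurve:
    """A dose-response series: ligand concentrations and per-point response.

    ``is_fraction_bound`` distinguishes normalised fraction-bound data from
    raw (e.g. normalised-fluorescence) responses that still need baseline and
    plateau estimation.
    """

    ligand_conc: np.ndarray
    response: np.ndarray
    target_conc: float
    replicate_sd: np.ndarray | None = None
    is_fraction_bound: bool = True

    def __post_init__(self):
        conc = np.asarray(self.ligand_conc, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "ligand_conc", conc)
        object.__setattr__(self, "response", resp)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise ValueError("ligand_conc and response must be equal-length 1-d")
        if np.any(conc <= 0):
            raise ValueError("ligand concentrations must be positive")
        d = np.diff(conc)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ligand concentrations must be strictly ordered")
        if self.target_conc <= 0:
            raise ValueError("target_conc must be > 0")
        if self.replicate_sd is not None:
            sd = np.asarray(self.replicate_sd, dtype=float)
            object.__setattr__(self, "replicate_sd", sd)
            if sd.shape != conc.shape or np.any(sd < 0):
                raise ValueError("replicate_sd must be non-negative, same length")
        if self.is_fraction_bound and (
            np.any(resp < -0.2) or np.any(resp > 1.2)
        ):
            raise ValueError(
                "fraction-bound responses outside [-0.2, 1.2]; pass "
                "is_fraction_bound=False for raw responses"
            )

    def __len__(self) -> int:
        return self.ligand_conc.size


@dataclass(frozen=True)
class SaturationDiagnostics:
    ok: bool
    conc_margin: float  # top conc / kd
    fb_at_top: float  # model fraction bound at the top concentration
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class KdFitResult:
    """Fitted dissociation constant with uncertainty and diagnostics.

    For non-saturating titrations ``kd`` retains the numerical optimum but
    ``saturation_ok`` is False and :meth:`report_kd` renders no value, only
    the lower bound implied by the top concentration.
    """

    kd: float
    kd_se: float
    target_conc: float
    n_points: int
    sse: float
    saturation_ok: bool
    saturation: SaturationDiagnostics
    unbound_baseline: float = 0.0
    bound_plateau: float = 1.0
    at_search_bound: bool = False

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.kd_se < 0:
            raise ValueError("kd_se must be >= 0")

    def report_kd(self) -> str:
        """Human-readable K_D: value ± SE, or a bound when not saturated."""
        if self.saturation_ok:
            return f"{self.kd * 1e6:.2f} ± {self.kd_se * 1e6:.2f} µM"
        top_conc = self.saturation.conc_margin * self.kd
        bound = top_conc / SATURATION_CONC_MARGIN
        return f"n.d. (no saturation; K_D ≳ {bound * 1e6:.2g} µM)"


def saturation_check(
    kd: float,
    curve: BindingCurve,
    conc_margin: float = SATURATION_CONC_MARGIN,
    fb_threshold: float = SATURATION_FB_THRESHOLD,
) -> SaturationDiagnostics:
    """Has the titration plausibly reached saturation for this K_D?

    Passes iff the top ligand concentration is at least ``conc_margin`` times
    the fitted K_D AND the model fraction bound at the top concentration is
    at least ``fb_threshold``.  Always returns a verdict with both margins.
    """
    top = float(curve.ligand_conc.max())
    margin = top / kd
    fb_top = float(binding_model(top, kd, curve.target_conc))
    reasons = []
    if margin < conc_margin:
        reasons.append(
            f"top concentration only {margin:.2f}x K_D (< {conc_margin:g}x)"
        )
    if fb_top < fb_threshold:
        reasons.append(
            f"model fraction bound at top {fb_top:.2f} (< {fb_threshold:g})"
        )
    return SaturationDiagnostics(not reasons, margin, fb_top, tuple(reasons))


def _weights(curve: BindingCurve) -> np.ndarray:
    if curve.replicate_sd is None:
        return np.ones(len(curve))
    sd = curve.replicate_sd.copy()
    positive = sd[sd > 0]
    floor = positive.min() if positive.size else 1.0
    sd[sd == 0] = floor  # zero-SD points would otherwise dominate
    return 1.0 / sd


def fit_kd(
    curve: BindingCurve,
    inits: Sequence[float] | None = None,
    conc_margin: float = SATURATION_CONC_MARGIN,
    fb_threshold: float = SATURATION_FB_THRESHOLD,
) -> KdFitResult:
    """Weighted least-squares fit of the 1:1 depletion model.

    K_D is optimised in log-space (guaranteeing positivity) from each of 13
    log-spaced starting values spanning 1 nM-1 mM (or user ``inits``); the
    best final SSE wins.  The standard error comes from the Jacobian at the
    optimum; weights are 1/sd when replicate SDs are present.  Raw-response
    curves additionally fit an unbound baseline and bound plateau jointly.
    """
    if len(curve) < 5:
        raise ValueError("need at least 5 points to fit a binding curve")
    conc = curve.ligand_conc
    if np.log10(conc.max() / conc.min()) < 2:
        raise ValueError("titration must span at least 2 decades of concentration")
    y = curve.response
    w = _weights(curve)
    ct = curve.target_conc
    raw = not curve.is_fraction_bound
    inits = KD_INIT_GRID if inits is None else np.asarray(inits, float)

    def residuals(params: np.ndarray) -> np.ndarray:
        kd = np.exp(np.clip(params[0], -230.0, 230.0))  # keep kd^2 finite
        fb = binding_model(conc, kd, ct)
        if raw:
            baseline, plateau = params[1], params[2]
            model = baseline + (plateau - baseline) * fb
        else:
            model = fb
        return w * (model - y)

    best = None
    for kd0 in inits:
        if raw:
            x0 = np.array([np.log(kd0), float(y.min()), float(y.max())])
        else:
            x0 = np.array([np.log(kd0)])
        try:
            sol = least_squares(residuals, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("kd fit failed to converge from every starting value")

    kd = float(np.exp(np.clip(best.x[0], -230.0, 230.0)))
    n, p = len(curve), best.x.size
    sse = float(2.0 * best.cost)
    # Covariance from the Jacobian at the optimum (Gauss-Newton approx).
    J = best.jac
    dof = max(n - p, 1)
    s2 = sse / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se_log_kd = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_log_kd = np.inf
    kd_se = kd * se_log_kd  # delta method from log-space

    baseline = float(best.x[1]) if raw else 0.0
    plateau = float(best.x[2]) if raw else 1.0
    sat = saturation_check(kd, curve, conc_margin, fb_threshold)
    at_bound = not (KD_RELIABLE_RANGE[0] <= kd <= KD_RELIABLE_RANGE[1])
    return KdFitResult(
        kd=kd,
        kd_se=kd_se,
        target_conc=ct,
        n_points=n,
        sse=sse,
        saturation_ok=sat.ok,
        saturation=sat,
        unbound_baseline=baseline,
        bound_plateau=plateau,
        at_search_bound=at_bound,
    )


class FlatCurveError(ValueError):
    """Raw responses show no usable signal (plateau ≈ baseline)."""


def fraction_bound_from_raw(curve: BindingCurve) -> tuple[BindingCurve, KdFitResult]:
    """Rescale raw responses to fraction bound via a joint baseline/plateau fit.

    The unbound baseline and bound plateau are estimated jointly with K_D in
    the full model fit (taking min/max of noisy data would bias both), then
    the responses are affinely rescaled.  Returns the rescaled curve and the
    underlying fit.
    """
    if curve.is_fraction_bound:
        raise ValueError("curve is already fraction bound")
    fit = fit_kd(curve)
    span = fit.bound_plateau - fit.unbound_baseline
    scale = np.ptp(curve.response)
    if scale == 0 or abs(span) < 1e-6 * max(scale, 1e-30):
        raise FlatCurveError(
            "no resolvable signal: fitted plateau and baseline coincide"
        )
    fb = (curve.response - fit.unbound_baseline) / span
    sd = curve.replicate_sd / abs(span) if curve.replicate_sd is not None else None
    rescaled = BindingCurve(
        curve.ligand_conc,
        np.clip(fb, -0.2, 1.2),
        curve.target_conc,
        sd,
        is_fraction_bound=True,
    )
    return rescaled, fit


# ---------------------------------------------------------------------------
# CSV I/O.  Long format: ligand_conc_M, response, replicate.


def read_binding_csv(
    path: str | Path,
    target_conc: float = DEFAULT_TARGET_CONC,
    is_fraction_bound: bool = True,
) -> BindingCurve:
    """Read a long-format dose-response CSV and collapse replicates.

    Per-concentration mean becomes the response; the sample SD across
    replicates (where >= 2) populates ``replicate_sd``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    grouped = df.groupby("ligand_conc_M")["response"]
    mean = grouped.mean()
    sd = grouped.std(ddof=1).fillna(0.0)
    conc = mean.index.to_numpy(float)
    order = np.argsort(conc)[::-1]  # descending, titration order
    return BindingCurve(
        conc[order],
        mean.to_numpy(float)[order],
        target_conc,
        sd.to_numpy(float)[order],
        is_fraction_bound=is_fraction_bound,
    )


def write_binding_csv(path: str | Path, curve: BindingCurve) -> None:
    import pandas as pd

    data = {
        "ligand_conc_M": curve.ligand_conc,
        "response": curve.response,
    }
    if curve.replicate_sd is not None:
        data["replicate_sd"] = curve.replicate_sd
    pd.DataFrame(data).to_csv(path, index=False)


def write_fit_csv(path: str | Path, fits: dict[str, KdFitResult]) -> None:
    """One row per curve: kd, SE, saturation verdict and margins."""
    import pandas as pd

    rows = []
    for name, fit in fits.items():
        rows.append(
            {
                "curve": name,
                "kd_M": fit.kd if fit.saturation_ok else np.nan,
                "kd_se_M": fit.kd_se if fit.saturation_ok else np.nan,
                "kd_display": fit.report_kd(),
                "saturation_ok": fit.saturation_ok,
                "conc_margin_x_kd": fit.saturation.conc_margin,
                "model_fb_at_top": fit.saturation.fb_at_top,
                "target_conc_M": fit.target_conc,
                "n_points": fit.n_points,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
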