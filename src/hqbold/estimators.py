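"""Parameter estimation: sqBOLD, hqBOLD ingredients, and TRUST oximetry.

The sqBOLD estimator solves the two-regime linear system

    [0    0   1] [DBV ]   [ln S(tau=0)]
    [1  -tau  1] [R2' ] = [ln S(tau_i)]   (tau_i > 15 ms)
    [...        ] [lnS0 - TE R2]

by ordinary least squares; tau points in the 3-12 ms transition regime are
excluded rather than modelled.  hqBOLD replaces the sqBOLD DBV by an
independent estimate from the hyperoxia-BOLD response: a petO2-derived
regressor is fitted voxelwise to the BOLD time series, the fractional signal
change (deltaBOLD) is scaled to DBV with a heuristic model, and OEF follows
from R2' / DBV.  TRUST estimates whole-brain venous saturation from the T2
decay of tag-control difference signals in the sagittal sinus.

No clipping is applied at the voxel level: negative DBV or OEF > 1 are
reported as-is (flagging happens at reporting time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import brentq

from .forward_models import DCHI0, GAMMA, AseProtocol, TrustProtocol

__all__ = [
    "QboldFitResult",
    "HeuristicCoefficients",
    "TrustResult",
    "CalibrationModel",
    "sqbold_fit",
    "oef_from_r2p_dbv",
    "r2p_longtau_fit",
    "peto2_regressor",
    "delta_bold_glm",
    "delta_peto2",
    "dbv_heuristic",
    "trust_preprocess",
    "trust_t2b_fit",
]

BASELINE_WINDOW = (1, 100)  # 1-based volume windows of the hyperoxia paradigm
HYPEROXIA_WINDOWS = ((175, 225), (415, 465))


class InsufficientDataError(ValueError):
    """Not enough usable tau points for the requested fit."""


@dataclass
class QboldFitResult:
    """R2' (s^-1), DBV (fraction), log-signal offset, and optionally OEF."""

    r2p: float
    dbv: float
    ln_s0_minus_te_r2: float
    oef: float = np.nan
    method: str = "sqBOLD"


@dataclass(frozen=True)
class HeuristicCoefficients:
    """Coefficients of the hyperoxia-BOLD DBV scaling model.

    DBV = (A/TE + B) (C/dPaO2 + D) deltaBOLD, with TE in ms and dPaO2 in
    mmHg; DBV inherits the units of deltaBOLD (normally percent).
    """

    a: float = 27.0  # ms
    b: float = 0.2
    c: float = 245.1  # mmHg
    d: float = 0.1

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) <= 0:
            raise ValueError("heuristic coefficients must be positive")


@dataclass
class TrustResult:
    """TRUST fit: decay exponent C (ms^-1), blood T2 (ms), SvO2 and OEF."""

    c_exponent: float
    t2b: float
    svo2: float
    oef: float
    s0: float
    ok: bool = True


@dataclass(frozen=True)
class CalibrationModel:
    """Quadratic blood T2-oxygenation calibration at fixed hematocrit.

    1/T2b [s^-1] = a0 + a1 (1 - Y) + a2 (1 - Y)^2.  The default coefficients
    follow the published TRUST calibration at 3 T (tau_CPMG = 10 ms),
    evaluated at the large-vessel hematocrit; they are configurable because
    different sites adopt different calibrations.
    """

    a0: float
    a1: float
    a2: float

    @classmethod
    def for_hct(cls, hct: float = 0.42) -> "CalibrationModel":
        if not 0 < hct < 1:
            raise ValueError("hct must lie in (0, 1)")
        return cls(
            a0=-13.5 + 80.2 * hct - 75.9 * hct**2,
            a1=-0.5 + 3.4 * hct,
            a2=247.4 * hct * (1.0 - hct),
        )

    def rate(self, y):
        """1/T2b in s^-1 at venous saturation ``y``."""
        x = 1.0 - np.asarray(y, dtype=float)
        return self.a0 + self.a1 * x + self.a2 * x**2

    def t2b(self, y):
        """Blood T2 in ms at venous saturation ``y``."""
        return 1000.0 / self.rate(y)

    def invert(self, t2b_ms: float) -> float:
        """Venous saturation from blood T2 (ms) by bracketed root finding."""
        if t2b_ms <= 0:
            raise ValueError("t2b must be positive")
        target = 1000.0 / t2b_ms

        def f(y):
            return self.rate(y) - target

        lo, hi = 0.0, 1.0
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            # Rate is monotone decreasing in Y; clamp outside the model range.
            return 1.0 if target < self.rate(1.0) else 0.0
        return brentq(f, lo, hi, xtol=1e-12)


def sqbold_fit(
    taus,
    signals,
    protocol: AseProtocol | None = None,
    tau_cutoff: float = 15.0,
) -> QboldFitResult:
    """Fit the sqBOLD two-regime linear system to one tau-series.

    Uses the tau = 0 acquisition(s) and all points with tau > ``tau_cutoff``
    ms; intermediate points are excluded.  Signals must be positive.
    """
    taus = np.asarray(taus, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if taus.shape != signals.shape:
        raise ValueError("taus and signals must have matching shapes")
    if np.any(signals <= 0):
        raise ValueError("signals must be strictly positive")
    zero = taus == 0
    long_t = taus > tau_cutoff
    if not np.any(zero) or np.count_nonzero(long_t) < 3:
        raise InsufficientDataError(
            "need a tau=0 acquisition and >= 3 points with tau > cutoff"
        )
    keep = zero | long_t
    t = taus[keep]
    y = np.log(signals[keep])
    a = np.column_stack(
        [(t > tau_cutoff).astype(float), -t * 1e-3 * (t > tau_cutoff), np.ones_like(t)]
    )
    x, *_ = np.linalg.lstsq(a, y, rcond=None)
    return QboldFitResult(r2p=x[1], dbv=x[0], ln_s0_minus_te_r2=x[2])


def r2p_longtau_fit(taus, signals, tau_cutoff: float = 15.0) -> tuple[float, float]:
    """Log-linear least-squares R2' from tau > cutoff points.

    Returns ``(r2p s^-1, intercept)`` where the intercept is the
    extrapolated log-signal at tau = 0.
    """
    taus = np.asarray(taus, dtype=float)
    signals = np.asarray(signals, dtype=float)
    mask = taus > tau_cutoff
    if np.count_nonzero(mask) < 2:
        raise InsufficientDataError("need >= 2 points with tau > cutoff")
    if np.any(signals[mask] <= 0):
        raise ValueError("signals must be strictly positive")
    slope, intercept = np.polyfit(taus[mask] * 1e-3, np.log(signals[mask]), 1)
    return -slope, intercept


def oef_from_r2p_dbv(
    r2p,
    dbv,
    hct: float = 0.34,
    field: float = 3.0,
    dchi0: float = DCHI0,
    gamma: float = GAMMA,
    negative_dbv: str = "nan",
):
    """OEF from R2' (s^-1) and DBV (fraction): the inverse of the R2' model.

    OEF = R2' / (DBV gamma (4/3) pi dchi0 Hct B0).  Voxels with dbv <= 0 are
    undefined and yield NaN by default; ``negative_dbv='propagate'`` performs
    the raw signed division instead (used when studying how noise on DBV
    propagates through the inversion).
    """
    r2p = np.asarray(r2p, dtype=float)
    dbv = np.asarray(dbv, dtype=float)
    k = gamma * (4.0 / 3.0) * np.pi * dchi0 * hct * field
    with np.errstate(divide="ignore", invalid="ignore"):
        oef = r2p / (k * dbv)
    if negative_dbv == "nan":
        oef = np.where(dbv > 0, oef, np.nan)
    elif negative_dbv != "propagate":
        raise ValueError("negative_dbv must be 'nan' or 'propagate'")
    return float(oef) if oef.ndim == 0 else oef


def peto2_regressor(
    times,
    peto2,
    tr: float = 1.0,
    n_volumes: int = 600,
    smooth_width: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a petO2 trace onto the BOLD volume grid and smooth it.

    Linear interpolation onto acquisition times ``k * tr`` (k = 0..n-1)
    followed by a moving average of width ``smooth_width`` seconds with
    reflected edges (a mean-preserving linear filter).  Returns
    ``(regressor, centered)`` where ``centered`` has zero mean.
    """
    times = np.asarray(times, dtype=float)
    peto2 = np.asarray(peto2, dtype=float)
    grid = np.arange(n_volumes) * tr
    if times[0] > grid[0] + 1e-9 or times[-1] < grid[-1] - 1e-9:
        raise ValueError("petO2 trace does not span the acquisition")
    reg = np.interp(grid, times, peto2)
    size = max(int(round(smooth_width / tr)), 1)
    reg = uniform_filter1d(reg, size=size, mode="reflect")
    return reg, reg - reg.mean()


def delta_peto2(
    trace,
    baseline_window: tuple[int, int] = BASELINE_WINDOW,
    hyper_windows=HYPEROXIA_WINDOWS,
) -> float:
    """Change in end-tidal pO2 (mmHg) between hyperoxia and baseline windows.

    Windows are inclusive 1-based volume numbers.  The pooled mean over the
    hyperoxia windows minus the baseline-window mean; treated downstream as
    the arterial dPaO2.
    """
    trace = np.asarray(trace, dtype=float)
    needed = max(w[1] for w in hyper_windows)
    if trace.size < needed:
        raise ValueError(f"trace must contain at least {needed} volumes")
    base = trace[baseline_window[0] - 1 : baseline_window[1]]
    hyper = np.concatenate([trace[lo - 1 : hi] for lo, hi in hyper_windows])
    return float(hyper.mean() - base.mean())


def delta_bold_glm(
    series,
    regressor,
    baseline_window: tuple[int, int] = BASELINE_WINDOW,
    hyper_windows=HYPEROXIA_WINDOWS,
):
    """Fractional BOLD response (percent) to the hyperoxia challenge.

    Fits ``series = intercept + beta * centered_regressor`` voxelwise by
    least squares and converts beta to the percentage signal change between
    the normoxic and hyperoxic plateaus:
    deltaBOLD = 100 * beta * plateau_amplitude(regressor) / intercept, so the
    result is the plateau-to-plateau fractional change regardless of the
    regressor's scale.  ``series`` may be 1-D (single voxel) or N-D with
    time as the last axis.
    """
    series = np.asarray(series, dtype=float)
    regressor = np.asarray(regressor, dtype=float)
    if series.shape[-1] != regressor.size:
        raise ValueError("series length must match the regressor")
    centered = regressor - regressor.mean()
    var = float(centered @ centered)
    if var == 0:
        raise ValueError("regressor has zero variance")
    amplitude = delta_peto2(regressor, baseline_window, hyper_windows)
    beta = series @ centered / var
    # Normalize by the fitted signal at the regressor's baseline plateau.
    lo, hi = baseline_window
    r_base = regressor[lo - 1 : hi].mean()
    baseline = series.mean(axis=-1) + beta * (r_base - regressor.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * beta * amplitude / baseline
    return float(out) if np.ndim(out) == 0 else out


def dbv_heuristic(
    delta_bold,
    te: float,
    delta_pao2: float,
    coeffs: HeuristicCoefficients = HeuristicCoefficients(),
):
    """DBV from the hyperoxia-BOLD signal change via the heuristic model.

    DBV = (A/TE + B)(C/dPaO2 + D) deltaBOLD with TE in ms and dPaO2 in mmHg;
    the output carries the units of ``delta_bold`` (percent in, percent out).
    """
    if te <= 0 or delta_pao2 <= 0:
        raise ValueError("te and delta_pao2 must be positive")
    delta_bold = np.asarray(delta_bold, dtype=float)
    out = (
        (coeffs.a / te + coeffs.b)
        * (coeffs.c / delta_pao2 + coeffs.d)
        * delta_bold
    )
    return float(out) if out.ndim == 0 else out


def sqbold_fit_image(data, taus, mask=None, tau_cutoff: float = 15.0):
    """Voxelwise sqBOLD fit over a 4-D array (tau on the last axis).

    One shared pseudo-inverse serves every voxel.  Voxels with a
    non-positive signal (or outside ``mask``) yield NaN.  Returns a dict of
    3-D maps: ``r2p`` (s^-1), ``dbv`` (fraction), ``ln_s0_minus_te_r2``.
    """
    data = np.asarray(data, dtype=float)
    taus = np.asarray(taus, dtype=float)
    zero = taus == 0
    long_t = taus > tau_cutoff
    if not np.any(zero) or np.count_nonzero(long_t) < 3:
        raise InsufficientDataError(
            "need a tau=0 acquisition and >= 3 points with tau > cutoff"
        )
    keep = zero | long_t
    t = taus[keep]
    a = np.column_stack(
        [(t > tau_cutoff).astype(float), -t * 1e-3 * (t > tau_cutoff), np.ones_like(t)]
    )
    pinv = np.linalg.pinv(a)
    y = data[..., keep]
    valid = np.all(y > 0, axis=-1)
    if mask is not None:
        valid &= np.asarray(mask) > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ln_y = np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), np.nan)
        x = ln_y @ pinv.T
    x[~valid] = np.nan
    return {"dbv": x[..., 0], "r2p": x[..., 1], "ln_s0_minus_te_r2": x[..., 2]}


def r2p_longtau_image(data, taus, mask=None, tau_cutoff: float = 15.0):
    """Voxelwise long-tau log-linear R2' fit; returns ``r2p`` and intercept maps."""
    data = np.asarray(data, dtype=float)
    taus = np.asarray(taus, dtype=float)
    long_t = taus > tau_cutoff
    if np.count_nonzero(long_t) < 2:
        raise InsufficientDataError("need >= 2 points with tau > cutoff")
    t = taus[long_t] * 1e-3
    a = np.column_stack([t, np.ones_like(t)])
    pinv = np.linalg.pinv(a)
    y = data[..., long_t]
    valid = np.all(y > 0, axis=-1)
    if mask is not None:
        valid &= np.asarray(mask) > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ln_y = np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), np.nan)
        x = ln_y @ pinv.T
    x[~valid] = np.nan
    return {"r2p": -x[..., 0], "intercept": x[..., 1]}


@dataclass
class TrustPreprocessed:
    """Averaged tag-control differences, the SSS ROI, and per-eTE mean dS."""

    diff: np.ndarray  # (n_ete, x, y, z)
    roi: np.ndarray  # boolean mask, shape (x, y, z)
    ds: np.ndarray  # mean difference signal per eTE over the ROI


def trust_preprocess(
    series,
    protocol: TrustProtocol = TrustProtocol(),
    roi_size: int = 4,
    prior_mask=None,
) -> TrustPreprocessed:
    """Pairwise tag-control subtraction, repeat averaging and ROI selection.

    ``series`` is 4-D with time ordered as, per eTE (in protocol order),
    ``n_repeats`` consecutive (control, tag) pairs.  The ROI is the
    ``roi_size`` voxels with the highest averaged difference signal at the
    first (eTE = 0) echo, optionally restricted to ``prior_mask``; ties are
    broken toward the lowest linear voxel index.
    """
    series = np.asarray(series, dtype=float)
    n_ete = len(protocol.etes)
    expected = n_ete * protocol.n_repeats * 2
    if series.ndim != 4 or series.shape[-1] != expected:
        raise ValueError(
            f"expected a 4-D series with {expected} volumes "
            f"({n_ete} eTEs x {protocol.n_repeats} repeats x tag/control)"
        )
    vols = series.reshape(series.shape[:3] + (n_ete, protocol.n_repeats, 2))
    diff = (vols[..., 0] - vols[..., 1]).mean(axis=-1)  # control - tag
    diff = np.moveaxis(diff, -1, 0)

    selector = diff[0].copy()
    if prior_mask is not None:
        selector = np.where(np.asarray(prior_mask, dtype=bool), selector, -np.inf)
    flat = selector.ravel()
    if np.all(flat <= 0):
        warnings.warn("degenerate TRUST difference signal: no positive voxels")
    # Stable sort on (-signal, index) implements the documented tie-break.
    order = np.lexsort((np.arange(flat.size), -flat))
    roi = np.zeros(flat.size, dtype=bool)
    roi[order[:roi_size]] = True
    roi = roi.reshape(selector.shape)
    ds = diff[:, roi].mean(axis=1)
    return TrustPreprocessed(diff=diff, roi=roi, ds=ds)


def trust_t2b_fit(
    etes,
    ds,
    t1b: float = 1624.0,
    calibration: CalibrationModel | None = None,
    hct: float = 0.42,
) -> TrustResult:
    """Fit the mono-exponential TRUST decay and convert to SvO2 / OEF.

    Log-linear least squares of ln(dS) on eTE yields the exponent C
    (ms^-1, negative for decay); the blood T2 follows from
    T2b = 1 / (1/T1b - C), accounting for the T1 recovery between the
    labelling and the readout.  SvO2 is obtained by inverting the
    calibration model at the large-vessel hematocrit, and whole-brain
    OEF = 1 - SvO2 (arterial blood assumed fully saturated).
    """
    etes = np.asarray(etes, dtype=float)
    ds = np.asarray(ds, dtype=float)
    if np.any(ds <= 0):
        raise ValueError("difference signals must be positive at all eTEs")
    c, ln_s0 = np.polyfit(etes, np.log(ds), 1)
    t2b = 1.0 / (1.0 / t1b - c)
    if calibration is None:
        calibration = CalibrationModel.for_hct(hct)
    if t2b <= 0:
        return TrustResult(
            c_exponent=c, t2b=t2b, svo2=np.nan, oef=np.nan,
            s0=float(np.exp(ln_s0)), ok=False,
        )
    svo2 = calibration.invert(t2b)
    return TrustResult(
        c_exponent=c, t2b=t2b, svo2=svo2, oef=1.0 - svo2,
        s0=float(np.exp(ln_s0)), ok=True,
    )
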