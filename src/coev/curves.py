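"""Biosensor data reductions.

Implements the standard plate-reader curve models for a BRET conformational
biosensor study:

* BRET ratio: acceptor / donor emission.
* Bioluminescence spectra decomposed into one (donor alone) or two
  (donor + acceptor) Gaussian components.
* Four-parameter logistic (variable-slope) dose-response in log10
  concentration, reporting EC50 and log10(EC50).
* Boltzmann sigmoid thermal melt, reporting Tm (the temperature of
  half-maximal signal) and the signed slope.

All fits are bounded nonlinear least squares with deterministic
multi-start initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


class FitError(RuntimeError):
    pass


def bret_ratio(donor_emission: float, acceptor_emission: float) -> float:
    """BRET = acceptor emission / donor emission (donor must be positive)."""
    if donor_emission <= 0:
        raise ValueError("donor emission must be > 0")
    return acceptor_emission / donor_emission


def percent_bret_change(bret_cgmp: float, bret_basal: float) -> float:
    """Percentage change in BRET = 100*(BRET_ligand - BRET_basal)/BRET_basal."""
    if bret_basal == 0:
        raise ValueError("basal BRET must be nonzero")
    return 100.0 * (bret_cgmp - bret_basal) / bret_basal


# ---------------------------------------------------------------------------
# spectral decomposition

@dataclass
class SpectrumFit:
    """Gaussian spectral components sorted by center wavelength."""

    amplitudes: list[float]
    centers: list[float]      # nm
    widths: list[float]       # nm (Gaussian sigma)
    residual_rms: float
    n_components: int

    def predict(self, wavelengths) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(lam)
        for A, mu, sig in zip(self.amplitudes, self.centers, self.widths):
            out += A * np.exp(-((lam - mu) ** 2) / (2 * sig ** 2))
        return out


def _gauss_model(p: np.ndarray, lam: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(lam)
    for c in range(k):
        A, mu, sig = p[3 * c: 3 * c + 3]
        out += A * np.exp(-((lam - mu) ** 2) / (2 * sig ** 2))
    return out


def fit_spectrum(wavelengths, intensities, n_components: int = 2) -> SpectrumFit:
    """Least-squares fit of a sum of ``n_components`` Gaussians.

    Amplitudes are bounded >= 0, widths > 0, centers within the measured
    wavelength window. Components are reported sorted by center.
    """
    lam = np.asarray(wavelengths, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if len(lam) < 3 * n_components + 1:
        raise ValueError("not enough points for the requested components")
    span = lam.max() - lam.min()
    ymax = y.max()
    if ymax <= 0:
        raise FitError("spectrum has no positive signal; nothing to fit")

    if n_components == 1:
        inits = [np.array([ymax, lam[np.argmax(y)], span / 6])]
    else:
        peak1 = lam[np.argmax(y)]
        # second start: strongest point at least a quarter-window away
        far = np.abs(lam - peak1) > span / 4
        peak2 = lam[far][np.argmax(y[far])] if far.any() else peak1 + span / 3
        inits = [
            np.array([ymax, peak1, span / 8, 0.5 * ymax, peak2, span / 8]),
            np.array([ymax, lam.min() + span / 4, span / 8,
                      0.5 * ymax, lam.min() + 3 * span / 4, span / 8]),
        ]
    lo = np.tile([0.0, lam.min(), 1e-3], n_components)
    hi = np.tile([np.inf, lam.max(), span], n_components)
    best = None
    for p0 in inits:
        p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(
                lambda p: _gauss_model(p, lam, n_components) - y,
                p0, bounds=(lo, hi),
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        rms = float("nan") if best is None else float(
            np.sqrt(2 * best.cost / len(y)))
        raise FitError(f"spectrum fit did not converge (residual RMS {rms})")
    p = best.x
    comps = sorted(
        [(p[3 * c], p[3 * c + 1], p[3 * c + 2]) for c in range(n_components)],
        key=lambda c: c[1],
    )
    rms = float(np.sqrt(np.mean((_gauss_model(p, lam, n_components) - y) ** 2)))
    return SpectrumFit(
        amplitudes=[float(c[0]) for c in comps],
        centers=[float(c[1]) for c in comps],
        widths=[float(c[2]) for c in comps],
        residual_rms=rms,
        n_components=n_components,
    )


# ---------------------------------------------------------------------------
# dose-response

@dataclass
class DoseResponseFit:
    """4-parameter logistic (variable slope) dose-response fit."""

    bottom: float
    top: float
    log_ec50: float          # log10 molar
    hill: float
    se: dict
    residual_rms: float
    underdetermined: bool = False   # no plateau within the data

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50

    def predict(self, conc) -> np.ndarray:
        logc = np.log10(np.asarray(conc, dtype=float))
        return self.bottom + (self.top - self.bottom) / (
            1 + 10 ** ((self.log_ec50 - logc) * self.hill)
        )


def _logistic4(p: np.ndarray, logc: np.ndarray) -> np.ndarray:
    bottom, top, logec50, hill = p
    return bottom + (top - bottom) / (1 + 10 ** ((logec50 - logc) * hill))


def fit_dose_response(conc, response) -> DoseResponseFit:
    """Fit ``y = bottom + (top-bottom)/(1 + 10^((logEC50 - log c) * h))``.

    Concentrations are molar; zero-concentration points are excluded from
    the fit itself (they have no finite log). When the response does not
    plateau within the data the fit is flagged ``underdetermined`` and the
    reported EC50 is a lower bound.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    pos = conc > 0
    logc = np.log10(conc[pos])
    y = response[pos]
    if len(np.unique(conc[pos])) < 5:
        raise ValueError("need >= 5 distinct nonzero concentrations")
    span = y.max() - y.min()
    if span == 0:
        raise FitError("flat response; dose-response fit is degenerate")
    half = y.min() + span / 2
    # logEC50 seeded at the half-max crossing
    order = np.argsort(logc)
    lc, yy = logc[order], y[order]
    cross = np.interp(half, yy, lc) if yy[0] < yy[-1] else np.interp(
        half, yy[::-1], lc[::-1])
    # deterministic multi-start over response-range quartiles
    inits = []
    for b_frac, t_frac in ((0.0, 1.0), (0.25, 0.75), (0.0, 1.25),
                           (-0.25, 1.0), (0.25, 1.25)):
        inits.append(np.array([
            y.min() + b_frac * span, y.min() + t_frac * span, cross, 1.0,
        ]))
    lo = np.array([-np.inf, -np.inf, logc.min() - 6, -50.0])
    hi = np.array([np.inf, np.inf, logc.max() + 6, 50.0])
    best = None
    for p0 in inits:
        try:
            res = least_squares(lambda p: _logistic4(p, logc) - y, p0,
                                bounds=(lo, hi))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("dose-response fit did not converge")
    p = best.x
    se = _se_from_jacobian(best, len(y))
    rms = float(np.sqrt(np.mean((_logistic4(p, logc) - y) ** 2)))
    # plateau check: highest-dose prediction must approach the top plateau
    yend = _logistic4(p, np.array([logc.max()]))[0]
    plateau_end = p[1] if p[3] > 0 else p[0]
    under = abs(yend - plateau_end) > 0.05 * abs(p[1] - p[0])
    return DoseResponseFit(
        bottom=float(p[0]), top=float(p[1]), log_ec50=float(p[2]),
        hill=float(p[3]),
        se={k: v for k, v in zip(("bottom", "top", "log_ec50", "hill"), se)},
        residual_rms=rms, underdetermined=bool(under),
    )


def zero_conc_display_position(conc) -> float:
    """log10 axis position for zero-dose points: 3 decades below the lowest
    nonzero dose (display convention only; zeros never enter the fit)."""
    conc = np.asarray(conc, dtype=float)
    nz = conc[conc > 0]
    if len(nz) == 0:
        raise ValueError("no nonzero concentrations")
    return float(np.log10(nz.min()) - 3.0)


# ---------------------------------------------------------------------------
# thermal melt

@dataclass
class MeltFit:
    """Boltzmann sigmoid melt fit: Tm and signed slope (deg C)."""

    bottom: float
    top: float
    tm: float
    slope: float
    se: dict
    residual_rms: float

    def predict(self, temperature) -> np.ndarray:
        T = np.asarray(temperature, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1 + np.exp((self.tm - T) / self.slope)
        )


def _boltzmann(p: np.ndarray, T: np.ndarray) -> np.ndarray:
    bottom, top, tm, slope = p
    z = np.clip((tm - T) / slope, -500, 500)  # overflow guard for tiny slopes
    return bottom + (top - bottom) / (1 + np.exp(z))


def fit_melt(temperature, bret) -> MeltFit:
    """Fit ``y = bottom + (top-bottom)/(1 + exp((Tm - T)/slope))``.

    ``Tm`` is the temperature at which the fitted curve crosses the midpoint
    between its plateaus (half-maximal relative BRET). A negative slope
    corresponds to a signal decreasing with temperature, following the
    printed sign convention for melts.
    """
    T = np.asarray(temperature, dtype=float)
    y = np.asarray(bret, dtype=float)
    if len(np.unique(T)) < 6:
        raise ValueError("need >= 6 distinct temperatures")
    span = y.max() - y.min()
    if span == 0:
        raise FitError("constant melt data; fit is degenerate")
    half = y.min() + span / 2
    order = np.argsort(T)
    Ts, ys = T[order], y[order]
    decreasing = ys[0] > ys[-1]
    if decreasing:
        tm0 = np.interp(half, ys[::-1], Ts[::-1])
        slope0 = -(Ts.max() - Ts.min()) / 10
    else:
        tm0 = np.interp(half, ys, Ts)
        slope0 = (Ts.max() - Ts.min()) / 10
    inits = [
        np.array([y.min(), y.max(), tm0, slope0]),
        np.array([y.min() - 0.25 * span, y.max() + 0.25 * span, tm0, slope0]),
        np.array([y.min(), y.max(), Ts.mean(), slope0 * 2]),
        np.array([y.min(), y.max(), tm0, slope0 / 4]),
        np.array([y.min() + 0.25 * span, y.max() - 0.25 * span, tm0, slope0]),
    ]
    lo = np.array([-np.inf, -np.inf, T.min(), -np.inf])
    hi = np.array([np.inf, np.inf, T.max(), np.inf])
    best = None
    for p0 in inits:
        p0 = p0.copy()
        p0[2] = np.clip(p0[2], T.min() + 1e-9, T.max() - 1e-9)
        try:
            res = least_squares(lambda p: _boltzmann(p, T) - y, p0,
                                bounds=(lo, hi))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise FitError("melt fit did not converge")
    p = best.x
    se = _se_from_jacobian(best, len(y))
    rms = float(np.sqrt(np.mean((_boltzmann(p, T) - y) ** 2)))
    # bottom/top labelled so 'top' is the larger plateau: model already
    # symmetric under (bottom<->top, slope -> -slope); keep fitted signs.
    return MeltFit(
        bottom=float(p[0]), top=float(p[1]), tm=float(p[2]),
        slope=float(p[3]),
        se={k: v for k, v in zip(("bottom", "top", "tm", "slope"), se)},
        residual_rms=rms,
    )


def _se_from_jacobian(res, n: int) -> np.ndarray:
    """Asymptotic parameter standard errors from the least-squares Jacobian."""
    J = res.jac
    dof = max(n - J.shape[1], 1)
    s2 = 2 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(J.shape[1], np.nan)


# convenience only: plain two-sample t-test on fitted parameters
def two_sample_t(a, b):
    """Two-tailed, unpaired, equal-variance t-test (convenience wrapper)."""
    from scipy.stats import ttest_ind

    r = ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=True)
    return float(r.statistic), float(r.pvalue)
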