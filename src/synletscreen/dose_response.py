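"""Single-agent concentration-effect fitting and IC50 determination.

The model is the four-parameter logistic (4PL) on log concentration,

    v(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill),

the standard sigmoid used by plate-reader software for "logistic
interpolation" of viability curves.  With hill > 0 the curve decreases
from ``top`` (no drug) to ``bottom`` (maximal inhibition); ``ic50`` is the
inflection concentration.  Fitting is nonlinear least squares on
log10(concentration) with a small multi-start over the midpoint to avoid
local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from synletscreen.errors import ConfigurationError, DegenerateFitError, FitRangeError

#: The screen's single-agent ladder: 10 two-fold dilutions from 20 nM to 20 uM.
SCREEN_CONCENTRATIONS_UM = 20.0 / 2.0 ** np.arange(9, -1, -1.0)

_FLAT_TOL = 1e-6  # variance below this means "no signal"


def logistic4(c, top, bottom, ic50, hill):
    """Four-parameter logistic viability at concentration(s) ``c`` (uM)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


@dataclass
class DoseResponseProfile:
    """A single-agent 10-point (by default) dose-response curve.

    ``viability`` may be 1-D (replicate-averaged) or 2-D with one row per
    replicate; rows are averaged before fitting unless the fit is asked
    for per-replicate curves.
    """

    concentrations: np.ndarray
    viability: np.ndarray
    compound: str = ""
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.ndim != 1:
            raise ConfigurationError("concentrations must be 1-D")
        if np.any(self.concentrations <= 0):
            raise ConfigurationError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ConfigurationError("concentrations must be strictly increasing")
        if self.viability.shape[-1] != self.concentrations.size:
            raise ConfigurationError("viability and concentrations sizes differ")

    def averaged(self) -> np.ndarray:
        v = self.viability
        return v if v.ndim == 1 else v.mean(axis=0)


@dataclass
class LogisticFit:
    """Fitted 4PL parameters plus fit diagnostics."""

    top: float
    bottom: float
    hill: float
    ic50: float
    residual_sse: float
    converged: bool
    extrapolated: bool = False

    def predict(self, c) -> np.ndarray:
        return logistic4(c, self.top, self.bottom, self.ic50, self.hill)


def fit_logistic(
    profile: DoseResponseProfile,
    *,
    fix_top: float | None = None,
    fix_bottom: float | None = None,
    top_bounds: tuple[float, float] = (0.8, 1.2),
    bottom_bounds: tuple[float, float] = (0.0, 1.0),
    hill_bounds: tuple[float, float] = (0.05, 10.0),
) -> LogisticFit:
    """Fit the 4PL to a dose-response profile by least squares.

    Replicate rows are averaged first.  ``fix_top`` / ``fix_bottom`` pin
    the plateaus (e.g. ``fix_top=1.0, fix_bottom=0.0`` for a normalized
    full-response curve); otherwise the plateaus float within
    ``top_bounds`` / ``bottom_bounds``.  Three starts bracketing the
    concentration range are tried and the best kept.  An optimizer failure
    returns a fit with ``converged=False`` (parameters NaN) rather than
    raising, so batch callers can triage; flat data raise
    :class:`DegenerateFitError`.
    """
    conc = profile.concentrations
    v = profile.averaged()
    if conc.size < 4:
        raise ConfigurationError("at least 4 distinct concentrations are required")
    if not np.all(np.isfinite(v)):
        raise ConfigurationError("viability contains non-finite values")
    if np.var(v) < _FLAT_TOL:
        raise DegenerateFitError(
            f"flat dose-response (variance {np.var(v):.2e}) for "
            f"{profile.compound or '<compound>'} / {profile.cell_line or '<cell line>'}"
        )

    order = np.argsort(conc)
    conc, v = conc[order], v[order]
    logc = np.log10(conc)
    lo, hi = logc[0], logc[-1]

    # parameter vector: any of (top, bottom, log10 ic50, hill) not fixed
    def model(lc, *theta):
        it = iter(theta)
        top = fix_top if fix_top is not None else next(it)
        bottom = fix_bottom if fix_bottom is not None else next(it)
        lic50 = next(it)
        hill = next(it)
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((lc - lic50) * hill))

    p_lo, p_hi, p0_tpl = [], [], []
    if fix_top is None:
        p_lo.append(top_bounds[0]); p_hi.append(top_bounds[1]); p0_tpl.append(np.clip(v.max(), *top_bounds))
    if fix_bottom is None:
        p_lo.append(bottom_bounds[0]); p_hi.append(bottom_bounds[1]); p0_tpl.append(np.clip(v.min(), *bottom_bounds))
    p_lo += [lo - 2.0, hill_bounds[0]]
    p_hi += [hi + 2.0, hill_bounds[1]]

    best = None
    for lic0 in (lo + 0.25 * (hi - lo), 0.5 * (lo + hi), hi - 0.25 * (hi - lo)):
        p0 = list(p0_tpl) + [lic0, 1.0]
        try:
            popt, _ = curve_fit(model, logc, v, p0=p0, bounds=(p_lo, p_hi), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((model(logc, *popt) - v) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, np.nan, converged=False)

    popt, sse = best
    it = iter(popt)
    top = fix_top if fix_top is not None else float(next(it))
    bottom = fix_bottom if fix_bottom is not None else float(next(it))
    ic50_um = float(10.0 ** next(it))
    hill = float(next(it))
    extrapolated = not (conc[0] / 10.0 <= ic50_um <= conc[-1] * 10.0)
    return LogisticFit(top, bottom, hill, ic50_um, sse, converged=True, extrapolated=extrapolated)


def ic50(fit: LogisticFit, level: float = 0.5) -> float:
    """Concentration at which the fitted viability equals ``level``.

    Inverts the 4PL: ``c = ic50 * ((top - level) / (level - bottom))^(1/hill)``.
    ``level`` must lie strictly between the fitted plateaus.
    """
    if not fit.converged:
        raise FitRangeError("cannot interpolate a non-converged fit")
    lo, hi = sorted((fit.bottom, fit.top))
    if not (lo < level < hi):
        raise FitRangeError(
            f"level {level} outside the fitted response range ({lo:.3g}, {hi:.3g})"
        )
    return float(fit.ic50 * ((fit.top - level) / (level - fit.bottom)) ** (1.0 / fit.hill))


def fit_profiles(df: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Fit every (compound, cell line) single-agent curve in a long table.

    Expects the canonical screen columns with ``compound_b == "none"``
    (combination rows are ignored); replicates are averaged per
    concentration before fitting.  Returns one row per curve with the
    fitted parameters, suitable for TSV export.
    """
    single = df[(df["compound_b"].isin(["none", ""])) & (df["conc_a"] > 0)]
    rows = []
    for (compound, cell_line), grp in single.groupby(["compound_a", "cell_line"], sort=False):
        mean = grp.groupby("conc_a")["value"].mean()
        profile = DoseResponseProfile(
            mean.index.to_numpy(), mean.to_numpy(), compound=compound, cell_line=cell_line
        )
        try:
            fit = fit_logistic(profile, **kwargs)
        except DegenerateFitError:
            fit = LogisticFit(np.nan, np.nan, np.nan, np.nan, np.nan, converged=False)
        rows.append(
            {
                "compound": compound,
                "cell_line": cell_line,
                "top": fit.top,
                "bottom": fit.bottom,
                "hill": fit.hill,
                "ic50": fit.ic50,
                "sse": fit.residual_sse,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
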