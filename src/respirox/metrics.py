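"""Per-animal metabolic endpoints.

* MMR: the fastest O2 decline across the trial's measurement periods,
  either as an OLS regression over each period's bin means (default) or
  as the steepest single bin.
* Mass scaling: nonlinear least squares of mo2 = c * W**b (mass-specific
  convention), used to re-scale rates to a common mass.
* Oxygen supply capacity (alpha): mean of the three largest per-bin
  supply ratios alpha0 = mo2 / PO2 from the hypoxia trial, with the bin
  width chosen automatically from a stability scan.
* pcmax: the critical PO2 for maximum metabolism, MMR / alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, DomainError, FitError, MetricsError
from .traces import (
    Trace,
    bin_slopes,
    clip_trace,
    effective_volume,
    measurement_periods,
    subtract_background,
)
from .units import solubility_per_kpa

__all__ = [
    "ScalingFit",
    "AnimalMetrics",
    "AlphaEstimate",
    "HypoxiaAlpha",
    "DEFAULT_BIN_WIDTH_S",
    "DEFAULT_SCAN_WIDTHS_S",
    "DEFAULT_PO2_FLOOR_KPA",
    "mmr_from_trial",
    "fit_mass_scaling",
    "mass_correct",
    "alpha0_series",
    "estimate_alpha",
    "bin_width_scan",
    "select_bin_width",
    "alpha_from_hypoxia",
    "pcmax",
]

DEFAULT_BIN_WIDTH_S = 45.0
DEFAULT_SCAN_WIDTHS_S = (30.0, 45.0, 60.0, 90.0, 120.0, 180.0, 240.0, 300.0, 450.0, 600.0)
#: PO2 floor below which alpha0 ratios are discarded (division blow-up guard).
DEFAULT_PO2_FLOOR_KPA = 0.5

MMR_MODES = ("period_regression", "max_bin")


@dataclass(frozen=True)
class ScalingFit:
    """Power-law mass scaling mo2 = c * W**b fitted across animals."""

    c: float
    b: float
    common_mass: float = 594.1
    rss: float = float("nan")
    n: int = 0


@dataclass(frozen=True)
class AlphaEstimate:
    alpha: float
    top3: tuple[float, float, float]
    sd_top3: float


@dataclass(frozen=True)
class HypoxiaAlpha:
    """Full automatic-bin-width alpha estimate for one hypoxia trial."""

    alpha: float
    sd_top3: float
    top3: tuple[float, float, float]
    selected_width_s: float
    stable: bool
    scan: pd.DataFrame


@dataclass(frozen=True)
class AnimalMetrics:
    animal_id: str
    mmr_per_trial: dict
    mmr_max: float
    alpha: float
    pcmax: float
    selected_bin_width_s: float
    alpha0_top3: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.isclose(self.pcmax * self.alpha, self.mmr_max, rtol=1e-12):
            raise MetricsError("pcmax * alpha must equal mmr_max")
        lo, hi = min(self.alpha0_top3), max(self.alpha0_top3)
        if not lo - 1e-12 <= self.alpha <= hi + 1e-12:
            raise MetricsError("alpha must lie within its top-3 alpha0 values")


def mmr_from_trial(
    trace: Trace,
    chamber_volume_l: float,
    mass_g: float,
    *,
    background_umol_h: float = 0.0,
    width_s: float = DEFAULT_BIN_WIDTH_S,
    measure_duration_s: float = 900.0,
    n_periods: int | None = None,
    mode: str = "period_regression",
) -> tuple[float, list[float]]:
    """MMR (umol O2 g-1 h-1) from a trial's measurement periods.

    ``period_regression`` (default): one OLS slope over each period's bin
    means, MMR = fastest period. ``max_bin``: the steepest single bin
    anywhere in the trial. Returns ``(mmr, per_period_rates)``; for
    max_bin the per-period rates are each period's steepest bin.
    """
    if mode not in MMR_MODES:
        raise ConfigError(f"mode must be one of {MMR_MODES}")
    beta = solubility_per_kpa(trace.cond)
    veff = effective_volume(chamber_volume_l, mass_g)
    periods = measurement_periods(trace, measure_duration_s, n_periods)
    if not periods:
        raise MetricsError("trace has no sealed measurement periods")
    rates: list[float] = []
    for label, sl in periods:
        sub = clip_trace(trace, sl)
        bins = bin_slopes(sub, width_s, label, chamber_volume_l, mass_g)
        usable = bins[bins["flags"] == ""]
        if usable.empty:
            continue
        if mode == "period_regression":
            if len(usable) >= 2:
                slope_s = np.polyfit(usable["t_mid_s"], usable["po2_kpa"], 1)[0]
                rate = -slope_s * 3600.0 * beta * veff / mass_g
            else:
                rate = float(usable["mo2_umol_g_h"].iloc[0])
        else:
            rate = float(usable["mo2_umol_g_h"].max())
        rates.append(rate - background_umol_h / mass_g)
    if not rates:
        raise MetricsError("all bins flagged; cannot estimate MMR")
    return max(rates), rates


def fit_mass_scaling(
    masses, mmrs, common_mass: float = 594.1, max_iter: int = 500
) -> ScalingFit:
    """Nonlinear least-squares fit of mo2 = c * W**b.

    Initialised from a log-log OLS line; iterated to 1e-10 relative
    tolerance. Raises :class:`FitError` (carrying the last iterate) on
    non-convergence and :class:`ConfigError` for degenerate inputs.
    """
    w = np.asarray(masses, dtype=float)
    y = np.asarray(mmrs, dtype=float)
    if w.size != y.size or w.size < 3:
        raise ConfigError("need at least 3 (mass, mmr) pairs")
    if np.unique(w).size < 2:
        raise ConfigError("masses must not all be identical")
    if np.any(w <= 0) or np.any(y <= 0):
        raise ConfigError("masses and rates must be positive")
    b0, logc0 = np.polyfit(np.log(w), np.log(y), 1)
    x0 = np.array([np.exp(logc0), b0])

    def residuals(p):
        return p[0] * w ** p[1] - y

    res = optimize.least_squares(
        residuals, x0, method="lm", ftol=1e-10, xtol=1e-10, gtol=1e-10,
        max_nfev=max_iter,
    )
    if not res.success:
        raise FitError(
            f"mass-scaling fit did not converge: {res.message}", last_params=res.x
        )
    c, b = res.x
    return ScalingFit(
        c=float(c), b=float(b), common_mass=common_mass,
        rss=float(res.cost * 2), n=int(w.size),
    )


def mass_correct(mo2, mass_g: float, fit: ScalingFit):
    """Re-scale a mass-specific rate to the fit's common mass.

    ``mo2 * (common_mass / mass)**b`` -- the mass-specific exponent
    convention; identity at b = 0 or mass = common_mass.
    """
    if not mass_g > 0:
        raise DomainError("mass must be > 0")
    return mo2 * (fit.common_mass / mass_g) ** fit.b


def alpha0_series(
    bins: pd.DataFrame, po2_floor: float = DEFAULT_PO2_FLOOR_KPA
) -> np.ndarray:
    """Per-bin instantaneous supply ratio alpha0 = mo2 / mean PO2.

    Flagged bins and bins with mean PO2 at or below ``po2_floor`` are
    excluded. Input bins are expected background-subtracted.
    """
    if bins.empty:
        raise MetricsError("no bins supplied")
    ok = (bins["flags"] == "") & (bins["po2_kpa"] > po2_floor)
    usable = bins[ok]
    return (usable["mo2_umol_g_h"] / usable["po2_kpa"]).to_numpy()


def estimate_alpha(alpha0) -> AlphaEstimate:
    """Oxygen supply capacity: mean of the three largest alpha0 values."""
    a = np.asarray(alpha0, dtype=float)
    if a.size < 3:
        raise MetricsError(f"need >= 3 alpha0 values, got {a.size}")
    top3 = np.sort(a)[-3:][::-1]
    return AlphaEstimate(
        alpha=float(top3.mean()),
        top3=tuple(float(v) for v in top3),
        sd_top3=float(np.std(top3, ddof=1)),
    )


def bin_width_scan(
    trace: Trace,
    chamber_volume_l: float,
    mass_g: float,
    *,
    segment: str | None = None,
    background_umol_h: float = 0.0,
    widths=DEFAULT_SCAN_WIDTHS_S,
    po2_floor: float = DEFAULT_PO2_FLOOR_KPA,
) -> pd.DataFrame:
    """Evaluate the alpha pipeline at each bin width for diagnostics.

    Uses the trial's final sealed segment by default (the hypoxia
    portion). Widths yielding fewer than 3 usable alpha0 values produce
    NaN rows.
    """
    if segment is None:
        segs = trace.sealed_segments()
        if not segs:
            raise MetricsError("trace has no sealed segment")
        segment = segs[-1][0]
    rows = []
    for width in widths:
        bins = bin_slopes(trace, width, segment, chamber_volume_l, mass_g)
        if background_umol_h:
            bins = subtract_background(bins, background_umol_h, mass_g)
        try:
            a0 = alpha0_series(bins, po2_floor)
            est = estimate_alpha(a0)
            rows.append((width, est.alpha, est.sd_top3, len(bins), a0.size))
        except MetricsError:
            rows.append((width, np.nan, np.nan, len(bins), 0))
    return pd.DataFrame(
        rows, columns=["width_s", "alpha", "sd_top3", "n_bins", "n_alpha0"]
    )


def select_bin_width(scan: pd.DataFrame, rel_tol: float = 0.02) -> tuple[float, bool]:
    """Pick the bin width that minimises both alpha and its top-3 SD.

    The stable region is the longest contiguous run of widths whose
    successive relative alpha changes stay below ``rel_tol``; within it
    each width is scored rank(alpha) + rank(sd_top3) and the lowest rank
    sum wins (ties -> smallest width). Returns ``(width, stable)``; with
    no stable region the rank sum is taken over all widths and a warning
    is raised.
    """
    df = scan.dropna(subset=["alpha"]).sort_values("width_s").reset_index(drop=True)
    if len(df) < 3:
        raise MetricsError("bin-width scan needs >= 3 usable widths")
    a = df["alpha"].to_numpy()
    ok_edge = np.abs(np.diff(a)) / a[:-1] < rel_tol

    best_run: tuple[int, int] | None = None  # [start, stop) in df rows
    run_start = None
    for i, ok in enumerate(ok_edge):
        if ok and run_start is None:
            run_start = i
        if (not ok or i == len(ok_edge) - 1) and run_start is not None:
            stop = (i + 2) if ok else (i + 1)
            if best_run is None or stop - run_start > best_run[1] - best_run[0]:
                best_run = (run_start, stop)
            run_start = None

    if best_run is None:
        warnings.warn(
            "no stable bin-width region found; falling back to a global rank sum",
            stacklevel=2,
        )
        region = df
        stable = False
    else:
        region = df.iloc[best_run[0]: best_run[1]]
        stable = True

    ranks = stats.rankdata(region["alpha"], method="average") + stats.rankdata(
        region["sd_top3"], method="average"
    )
    winner = int(np.argmin(ranks))  # argmin -> first = smallest width on ties
    return float(region["width_s"].iloc[winner]), stable


def alpha_from_hypoxia(
    trace: Trace,
    chamber_volume_l: float,
    mass_g: float,
    *,
    background_umol_h: float = 0.0,
    widths=DEFAULT_SCAN_WIDTHS_S,
    po2_floor: float = DEFAULT_PO2_FLOOR_KPA,
) -> HypoxiaAlpha:
    """Full alpha estimator: scan widths, select one, average the top 3."""
    scan = bin_width_scan(
        trace, chamber_volume_l, mass_g,
        background_umol_h=background_umol_h, widths=widths, po2_floor=po2_floor,
    )
    width, stable = select_bin_width(scan)
    segs = trace.sealed_segments()
    bins = bin_slopes(trace, width, segs[-1][0], chamber_volume_l, mass_g)
    if background_umol_h:
        bins = subtract_background(bins, background_umol_h, mass_g)
    est = estimate_alpha(alpha0_series(bins, po2_floor))
    return HypoxiaAlpha(
        alpha=est.alpha, sd_top3=est.sd_top3, top3=est.top3,
        selected_width_s=width, stable=stable, scan=scan,
    )


def pcmax(mmr_max: float, alpha: float) -> float:
    """Critical oxygen pressure for maximum metabolism: MMR / alpha (kPa)."""
    if not alpha > 0:
        raise DomainError("alpha must be > 0")
    if not mmr_max > 0:
        raise DomainError("mmr_max must be > 0")
    return mmr_max / alpha
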