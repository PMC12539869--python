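"""Chamber oxygen traces and their conversion to binned uptake rates.

A :class:`Trace` is a timestamped O2 series (either % air saturation or
kPa) with per-sample phase labels marking sealed measurement segments
and flush segments. Processing turns sealed segments into consecutive
fixed-width bins, fits an ordinary least-squares decline to each bin and
converts the slope into a mass-specific oxygen uptake rate with the
microbial background removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, MetricsError
from .units import WaterConditions, percent_sat_to_kpa, solubility_per_kpa

__all__ = [
    "Trace",
    "BinSlope",
    "MicrobialRate",
    "effective_volume",
    "mo2_from_slope",
    "bin_trace",
    "bin_slopes",
    "slope_mo2",
    "microbial_rate",
    "subtract_background",
    "measurement_periods",
]

UNIT_PERCENT_SAT = "percent_sat"
UNIT_KPA = "kpa"
_KNOWN_UNITS = (UNIT_PERCENT_SAT, UNIT_KPA)

#: Paper convention: microbial blanks are referenced to a nominal mass of
#: 0.0001 g when expressed "mass-specifically".
NOMINAL_BLANK_MASS_G = 1e-4


@dataclass
class Trace:
    """Timestamped oxygen series with phase labels and water context.

    ``phase`` holds one label per sample, e.g. ``sealed_0``, ``flush_0``,
    ``sealed_1`` ...; consecutive runs of equal labels form segments.
    """

    time_s: np.ndarray
    o2: np.ndarray
    unit: str
    cond: WaterConditions
    phase: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.unit not in _KNOWN_UNITS:
            raise DomainError(
                f"unknown o2 unit {self.unit!r}; expected one of {_KNOWN_UNITS}"
            )
        if self.time_s.shape != self.o2.shape or self.time_s.ndim != 1:
            raise DomainError("time_s and o2 must be 1-d arrays of equal length")
        bad = np.flatnonzero(np.diff(self.time_s) <= 0)
        if bad.size:
            raise DomainError(
                f"time not strictly increasing at sample index {bad[0] + 1}"
            )
        if np.any(self.o2 < 0):
            raise DomainError("o2 values must be >= 0")
        if self.phase is None:
            self.phase = np.full(self.time_s.shape, "sealed_0", dtype=object)
        else:
            self.phase = np.asarray(self.phase, dtype=object)
            if self.phase.shape != self.time_s.shape:
                raise DomainError("phase must have one label per sample")

    def __len__(self) -> int:
        return self.time_s.size

    def o2_kpa(self) -> np.ndarray:
        """The oxygen series converted to kPa (no-op for kPa traces)."""
        if self.unit == UNIT_KPA:
            return self.o2.copy()
        return percent_sat_to_kpa(self.o2, self.cond)

    def segments(self) -> list[tuple[str, slice]]:
        """Consecutive runs of equal phase labels, in time order."""
        labels = self.phase
        breaks = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        starts = np.concatenate(([0], breaks))
        stops = np.concatenate((breaks, [labels.size]))
        return [(str(labels[a]), slice(a, b)) for a, b in zip(starts, stops)]

    def sealed_segments(self) -> list[tuple[str, slice]]:
        return [(lab, sl) for lab, sl in self.segments() if lab.startswith("sealed")]


@dataclass(frozen=True)
class BinSlope:
    """One bin's least-squares O2 decline and derived uptake rate."""

    t_mid: float          # s
    po2_mean: float       # kPa
    slope: float          # kPa / h  (<= 0 expected)
    mo2: float            # umol O2 g-1 h-1
    n_points: int
    r_squared: float
    flags: str = ""


@dataclass(frozen=True)
class MicrobialRate:
    """Background (blank-chamber) oxygen uptake in several conventions."""

    volumetric: float          # umol O2 L-1 h-1
    whole_chamber: float       # umol O2 h-1
    nominal_mass_mo2: float    # umol O2 g-1 h-1 at nominal mass 0.0001 g
    slope_kpa_h: float
    r_squared: float
    duration_s: float


def effective_volume(chamber_volume_l: float, mass_g: float) -> float:
    """Water volume in the chamber, subtracting animal volume.

    Assumes tissue density 1 g/mL (the respirometry convention).
    """
    veff = chamber_volume_l - mass_g / 1000.0
    if veff <= 0:
        raise DomainError(
            f"animal ({mass_g} g) does not fit chamber ({chamber_volume_l} L)"
        )
    return veff


def mo2_from_slope(
    slope_kpa_h: float, beta: float, chamber_volume_l: float, mass_g: float
) -> float:
    """Convert a PO2 decline slope into mass-specific uptake.

    ``mo2 = -slope * beta * V_eff / mass`` with ``beta`` the oxygen
    capacitance (umol L-1 kPa-1) and ``V_eff = volume - mass/1000``.
    """
    return -slope_kpa_h * beta * effective_volume(chamber_volume_l, mass_g) / mass_g


def _ols_line(t_s: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope (per second) and r-squared of an OLS line fit."""
    t = t_s - t_s.mean()
    y = np.asarray(y, dtype=float)
    stt = float(t @ t)
    sty = float(t @ (y - y.mean()))
    syy = float((y - y.mean()) @ (y - y.mean()))
    if stt == 0.0:
        raise MetricsError("cannot fit a slope to coincident time points")
    slope = sty / stt
    r2 = 0.0 if syy == 0.0 else sty * sty / (stt * syy)
    return slope, r2


def bin_trace(
    trace: Trace, width_s: float, segment: str
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split one sealed segment into consecutive left-closed bins.

    Returns ``[(time_s, po2_kpa), ...]`` per bin, kPa-converted. A
    trailing partial bin shorter than ``width_s / 2`` is dropped; bins
    with fewer than 3 samples are dropped. An empty list (with a
    warning) is returned when the segment is shorter than one bin.
    """
    seg = dict(trace.segments()).get(segment)
    if seg is None:
        raise MetricsError(f"trace has no segment {segment!r}")
    t = trace.time_s[seg]
    p = trace.o2_kpa()[seg]
    dt = np.median(np.diff(t)) if t.size > 1 else np.inf
    if width_s < 3 * dt:
        raise DomainError(
            f"bin width {width_s}s must be >= 3 sample intervals ({dt}s)"
        )
    span = t[-1] - t[0]
    if span < width_s:
        warnings.warn(
            f"segment {segment!r} ({span:.0f}s) shorter than one {width_s:.0f}s bin",
            stacklevel=2,
        )
        return []
    n_full = int(span // width_s)
    remainder = span - n_full * width_s
    n_bins = n_full + (1 if remainder >= width_s / 2 else 0)
    edges = t[0] + width_s * np.arange(1, n_bins)
    idx = np.searchsorted(t, edges, side="left")
    bounds = np.concatenate(([0], idx, [t.size]))
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= 3:
            out.append((t[a:b], p[a:b]))
    return out


def slope_mo2(
    t_s: np.ndarray,
    po2_kpa: np.ndarray,
    chamber_volume_l: float,
    mass_g: float,
    cond: WaterConditions,
) -> BinSlope:
    """OLS fit of PO2 against time for one bin, converted to uptake.

    Positive slopes (O2 rising) are flagged ``positive_slope`` but the
    bin is retained so protocol faults stay visible downstream.
    """
    t_s = np.asarray(t_s, dtype=float)
    po2_kpa = np.asarray(po2_kpa, dtype=float)
    if t_s.size < 3:
        raise MetricsError("a bin needs at least 3 points")
    slope_s, r2 = _ols_line(t_s, po2_kpa)
    slope_h = slope_s * 3600.0
    beta = solubility_per_kpa(cond)
    mo2 = mo2_from_slope(slope_h, beta, chamber_volume_l, mass_g)
    flags = "positive_slope" if slope_h > 0 else ""
    return BinSlope(
        t_mid=float(t_s.mean()),
        po2_mean=float(po2_kpa.mean()),
        slope=slope_h,
        mo2=mo2,
        n_points=int(t_s.size),
        r_squared=r2,
        flags=flags,
    )


def bin_slopes(
    trace: Trace,
    width_s: float,
    segment: str,
    chamber_volume_l: float,
    mass_g: float,
) -> pd.DataFrame:
    """Per-bin slope table for one sealed segment (vectorised).

    Columns: ``t_mid_s, po2_kpa, slope_kpa_h, mo2_umol_g_h, n, r2, flags``.
    """
    bins = bin_trace(trace, width_s, segment)
    beta = solubility_per_kpa(trace.cond)
    veff = effective_volume(chamber_volume_l, mass_g)
    rows = []
    for t, p in bins:
        slope_s, r2 = _ols_line(t, p)
        slope_h = slope_s * 3600.0
        rows.append(
            (
                t.mean(),
                p.mean(),
                slope_h,
                -slope_h * beta * veff / mass_g,
                t.size,
                r2,
                "positive_slope" if slope_h > 0 else "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=["t_mid_s", "po2_kpa", "slope_kpa_h", "mo2_umol_g_h", "n", "r2", "flags"],
    )


def microbial_rate(
    blank: Trace, chamber_volume_l: float, cond: WaterConditions | None = None
) -> MicrobialRate:
    """Background uptake from an empty-chamber blank trace.

    One OLS slope over the blank's (first) sealed segment, converted to a
    whole-chamber rate (umol/h; no animal, so the effective volume is the
    full chamber volume) and additionally to the nominal-mass convention
    (mass 0.0001 g). Warns when the blank is shorter than 10 minutes.
    """
    cond = cond or blank.cond
    segs = blank.sealed_segments()
    if not segs:
        raise MetricsError("blank trace has no sealed segment")
    _, sl = segs[0]
    t = blank.time_s[sl]
    p = blank.o2_kpa()[sl]
    duration = float(t[-1] - t[0])
    if duration < 600.0:
        warnings.warn(
            f"blank trial only {duration:.0f}s long (< 10 min)", stacklevel=2
        )
    slope_s, r2 = _ols_line(t, p)
    slope_h = slope_s * 3600.0
    beta = solubility_per_kpa(cond)
    whole_chamber = -slope_h * beta * chamber_volume_l
    return MicrobialRate(
        volumetric=whole_chamber / chamber_volume_l,
        whole_chamber=whole_chamber,
        nominal_mass_mo2=whole_chamber / NOMINAL_BLANK_MASS_G,
        slope_kpa_h=slope_h,
        r_squared=r2,
        duration_s=duration,
    )


def subtract_background(
    bins: pd.DataFrame, microbial_whole_chamber: float, mass_g: float
) -> pd.DataFrame:
    """Remove the whole-chamber microbial rate from each bin's mo2.

    ``mo2_corrected = mo2 - microbial_whole_chamber / mass``; negative
    results are floored at zero and flagged ``floored``.
    """
    if microbial_whole_chamber < 0:
        raise DomainError("microbial whole-chamber rate must be >= 0")
    out = bins.copy()
    corrected = out["mo2_umol_g_h"] - microbial_whole_chamber / mass_g
    floored = corrected < 0
    corrected[floored] = 0.0
    out["mo2_umol_g_h"] = corrected
    if floored.any():
        out.loc[floored, "flags"] = out.loc[floored, "flags"].apply(
            lambda f: f + ";floored" if f else "floored"
        )
    return out


def measurement_periods(
    trace: Trace, measure_duration_s: float, n_periods: int | None = None
) -> list[tuple[str, slice]]:
    """Sealed segments clipped to the nominal measurement duration.

    In hypoxia trials the final sealed segment runs on past the last
    measurement period; clipping recovers the comparable 15-min windows.
    """
    segs = trace.sealed_segments()
    if n_periods is not None:
        segs = segs[:n_periods]
    out = []
    for lab, sl in segs:
        t = trace.time_s[sl]
        stop = np.searchsorted(t, t[0] + measure_duration_s, side="right")
        out.append((lab, slice(sl.start, sl.start + int(stop))))
    return out


def clip_trace(trace: Trace, sl: slice) -> Trace:
    """A view-free sub-trace covering ``sl``."""
    return replace(
        trace,
        time_s=trace.time_s[sl].copy(),
        o2=trace.o2[sl].copy(),
        phase=trace.phase[sl].copy(),
    )
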