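"""From raw oxygen traces to QC-filtered, blank-corrected, mass-specific rates.

The stages, in pipeline order:

1. ``trim_acclimation`` — drop the chamber-acclimation segment (default 30 min).
2. ``derive_rates`` — sliding ordinary-least-squares oxygen-decline slopes.
3. ``blank_correct`` — subtract background (bacterial) oxygen demand measured
   in animal-free chambers.
4. ``to_mass_specific`` — convert %airsat/s slopes into mL O2 h^-1 g wet
   weight^-1 using chamber volume, oxygen solubility and animal wet mass.
5. ``qc_filter`` — flag profiles whose oxygen never dropped to half the start
   concentration (too little of the hypoxic range observed to score regulation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io import RateProfile, RespirometryTrace, TraceMetadata, ValidationError
from .units import UnitContext, o2_solubility_ml_per_l

logger = logging.getLogger("oxyreg")

__all__ = [
    "RateWindow",
    "ConversionCoefficients",
    "trim_acclimation",
    "derive_rates",
    "blank_correct",
    "to_mass_specific",
    "dry_to_wet",
    "qc_filter",
    "trace_to_profile",
]


@dataclass(frozen=True)
class RateWindow:
    """One sliding-window slope estimate on a trace."""

    t_mid_s: float
    do_mid_pct: float
    slope_pct_per_s: float
    n_points: int


@dataclass(frozen=True)
class ConversionCoefficients:
    """Dry-to-wet weight conversion, supplied by configuration.

    forms:
      - ``identity``:  wet = dry
      - ``ratio``:     wet = dry / f          (f = dry fraction of wet mass)
      - ``linear``:    wet = a + b * dry
      - ``loglinear``: wet = exp(a + b * ln(dry))
    """

    form: str = "identity"
    a: float = 0.0
    b: float = 1.0
    f: float = 1.0
    source: str = ""

    def __post_init__(self):
        if self.form not in ("identity", "ratio", "linear", "loglinear"):
            raise ValueError(f"unknown conversion form {self.form!r}")


def trim_acclimation(trace: RespirometryTrace, trim_min: float = 30.0) -> RespirometryTrace:
    """Discard the first ``trim_min`` minutes (chamber acclimation) and re-zero time."""
    if trim_min < 0:
        raise ValueError("trim_min must be >= 0")
    if trim_min == 0:
        return trace
    cut = trace.time_s[0] + trim_min * 60.0
    keep = trace.time_s >= cut
    if keep.sum() < 3:
        raise ValidationError(
            f"{trace.trace_id}: trace shorter than {trim_min} min acclimation trim"
        )
    t = trace.time_s[keep]
    return RespirometryTrace(trace.metadata, t - t[0], trace.do_pct_airsat[keep])


def derive_rates(
    trace: RespirometryTrace,
    window_s: float = 300.0,
    step_s: float | None = None,
) -> list[RateWindow]:
    """Sliding-window OLS slopes of oxygen (%airsat) against time (s).

    Each window of width ``window_s`` yields one slope; windows advance by
    ``step_s`` (default half the window). Windows with fewer than 3 samples
    are skipped with a log entry.
    """
    if step_s is None:
        step_s = window_s / 2.0
    t, o = trace.time_s, trace.do_pct_airsat
    dt = np.median(np.diff(t))
    if window_s < 3 * dt:
        raise ValueError("window_s must cover at least 3 sampling intervals")
    windows: list[RateWindow] = []
    start = t[0]
    while start + window_s <= t[-1] + 1e-9:
        mask = (t >= start - 1e-9) & (t <= start + window_s + 1e-9)
        n = int(mask.sum())
        if n < 3:
            logger.info(
                "derive_rates: %s window at t=%.0f s has %d points, skipped",
                trace.trace_id, start, n,
            )
        else:
            tw, ow = t[mask], o[mask]
            slope = np.polyfit(tw, ow, 1)[0]
            windows.append(
                RateWindow(
                    t_mid_s=float(tw.mean()),
                    do_mid_pct=float(ow.mean()),
                    slope_pct_per_s=float(slope),
                    n_points=n,
                )
            )
        start += step_s
    return windows


def blank_correct(
    windows: list[RateWindow],
    blank_windows: list[list[RateWindow]] | None = None,
    constant_blank_slope: float | None = None,
    disabled: bool = False,
) -> list[RateWindow]:
    """Subtract background oxygen demand from animal-chamber slopes.

    ``blank_windows`` holds the window lists of one or more blank chambers;
    their slopes are interpolated in time and averaged. Alternatively a
    ``constant_blank_slope`` (%airsat/s) can be supplied. Corrected slopes are
    capped at 0 from above — a chamber cannot produce oxygen — and cap events
    are logged.
    """
    if disabled:
        return list(windows)
    if not blank_windows and constant_blank_slope is None:
        raise ValueError(
            "no blank chambers and no constant blank slope configured; "
            "pass disabled=True to skip blank correction explicitly"
        )
    t_mid = np.array([w.t_mid_s for w in windows])
    if constant_blank_slope is not None and not blank_windows:
        blank_at = np.full_like(t_mid, constant_blank_slope, dtype=float)
    else:
        per_blank = []
        for bw in blank_windows:
            bt = np.array([w.t_mid_s for w in bw])
            bs = np.array([w.slope_pct_per_s for w in bw])
            per_blank.append(np.interp(t_mid, bt, bs))
        blank_at = np.mean(per_blank, axis=0)
    out = []
    n_capped = 0
    for w, b in zip(windows, blank_at):
        corrected = w.slope_pct_per_s - float(b)
        if corrected > 0:
            corrected = 0.0
            n_capped += 1
        out.append(replace(w, slope_pct_per_s=corrected))
    if n_capped:
        logger.warning("blank_correct: %d corrected slopes capped at 0", n_capped)
    return out


def to_mass_specific(
    windows: list[RateWindow],
    meta: TraceMetadata,
    ctx: UnitContext,
) -> RateProfile:
    """Convert oxygen-decline slopes to mass-specific respiration rates.

    rate [mL O2 h^-1 g^-1] = (-slope [mL O2 L^-1 s^-1]) * V [L] * 3600 / W [g],
    where the %airsat/s slope is scaled by the air-saturation solubility at the
    measurement temperature and salinity. The oxygen axis stays in %airsat.
    """
    if not np.isfinite(meta.weight_mg):
        raise ValueError(f"{meta.trace_id}: animal weight unknown")
    if meta.weight_basis != "wet":
        raise ValueError(
            f"{meta.trace_id}: weight basis is {meta.weight_basis!r}; "
            "convert with dry_to_wet first"
        )
    if not np.isfinite(meta.chamber_volume_mL):
        raise ValueError(f"{meta.trace_id}: chamber volume unknown")
    c_sat = o2_solubility_ml_per_l(ctx.temperature_C, ctx.salinity_psu) * ctx.pressure_atm
    v_l = meta.chamber_volume_mL / 1000.0
    w_g = meta.weight_mg / 1000.0
    do = np.array([w.do_mid_pct for w in windows])
    slopes = np.array([w.slope_pct_per_s for w in windows])
    rates = (-slopes / 100.0 * c_sat) * v_l * 3600.0 / w_g
    n_floored = int((rates < 0).sum())
    if n_floored:
        logger.warning(
            "to_mass_specific: %s: %d negative rates floored at 0",
            meta.trace_id, n_floored,
        )
        rates = np.maximum(rates, 0.0)
    return RateProfile(
        trace_id=meta.trace_id,
        do_pct_airsat=do,
        rate_mlO2_h_gww=rates,
        species=meta.species,
        temperature_C=meta.temperature_C,
    )


def dry_to_wet(weight_dry_mg: float, coeff: ConversionCoefficients | None) -> float:
    """Convert dry mass to wet mass with configured coefficients.

    The coefficients (from the species-appropriate literature regression) must
    be supplied by configuration; there is no built-in default other than the
    degenerate identity form.
    """
    if coeff is None:
        raise ValueError(
            "dry-basis weight supplied but no dry-to-wet conversion configured; "
            "set preprocessing.dry_to_wet coefficients in the run configuration"
        )
    if weight_dry_mg <= 0:
        raise ValueError("dry weight must be > 0")
    if coeff.form == "identity":
        return float(weight_dry_mg)
    if coeff.form == "ratio":
        return float(weight_dry_mg / coeff.f)
    if coeff.form == "linear":
        return float(coeff.a + coeff.b * weight_dry_mg)
    return float(np.exp(coeff.a + coeff.b * np.log(weight_dry_mg)))


def qc_filter(profile: RateProfile, max_min_frac: float = 0.5) -> RateProfile:
    """Flag profiles whose oxygen did not drop to ``max_min_frac`` of the start.

    The check is on the ratio min/start only, so it is unit-invariant. Failing
    profiles are retained (qc_pass=False) and excluded from RI statistics
    downstream, never silently dropped.
    """
    if len(profile) == 0:
        raise ValueError(f"{profile.trace_id}: empty profile")
    start = float(profile.do_pct_airsat[0])  # profiles are descending in oxygen
    lo = float(profile.do_pct_airsat[-1])
    ok = lo <= max_min_frac * start + 1e-12
    reason = "" if ok else (
        f"oxygen only dropped to {lo:.1f} of start {start:.1f} "
        f"(> {max_min_frac:.0%} of start)"
    )
    return replace(profile, qc_pass=ok, qc_reason=reason)


def trace_to_profile(
    trace: RespirometryTrace,
    ctx: UnitContext,
    trim_min: float = 30.0,
    window_s: float = 300.0,
    step_s: float | None = None,
    blank_windows: list[list[RateWindow]] | None = None,
    constant_blank_slope: float | None = None,
    blank_disabled: bool = False,
    max_min_frac: float = 0.5,
    dry_coeff: ConversionCoefficients | None = None,
) -> RateProfile:
    """Convenience composition: trim -> derive -> blank-correct -> mass-specific -> QC."""
    meta = trace.metadata
    if meta.weight_basis == "dry":
        meta = TraceMetadata(
            **{
                **{f: getattr(meta, f) for f in meta.__dataclass_fields__},
                "weight_mg": dry_to_wet(meta.weight_mg, dry_coeff),
                "weight_basis": "wet",
            }
        )
    trimmed = trim_acclimation(trace, trim_min)
    windows = derive_rates(trimmed, window_s=window_s, step_s=step_s)
    windows = blank_correct(
        windows,
        blank_windows=blank_windows,
        constant_blank_slope=constant_blank_slope,
        disabled=blank_disabled,
    )
    profile = to_mass_specific(windows, meta, ctx)
    return qc_filter(profile, max_min_frac=max_min_frac)
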