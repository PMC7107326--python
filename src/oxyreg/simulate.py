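"""Synthetic respirometry with analytically known Regulation Index.

Four response archetypes formalize the strategy taxonomy:

- ``power_law``: rate = Rmax (DO/DOmax)^gamma. gamma = 0 is a perfect
  regulator (RI = 1), gamma = 1 a perfect conformer (RI = 0), gamma > 1 falls
  below the conformity line (negative RI). Closed form over the full range:
  RI = 2/(gamma+1) - 1.
- ``saturation``: Michaelis-type rate = Rmax DO/(K + DO), a partial regulator.
- ``pcrit_regulator``: constant rate above a critical oxygen level, declining
  linearly toward zero below it (the classic breakpoint regulator).
- ``suppressor``: a conformer that, below a threshold, ramps its rate down to
  a fraction of the conformity expectation — the metabolic-suppression
  geometry that makes RI negative.

``true_ri`` evaluates the exact RI of each archetype by closed-form piecewise
integration over any oxygen interval, so every downstream estimate has an
analytic oracle. ``simulate_trace`` forward-integrates the closed-chamber
oxygen balance dC/dt = -R(C) W / V (plus background drift and sensor noise)
at the sensor sampling interval, giving raw traces whose processed RI can be
compared against the oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import RateProfile, RespirometryTrace, TraceMetadata
from .units import UnitContext, o2_solubility_ml_per_l

logger = logging.getLogger("oxyreg")

__all__ = [
    "ArchetypeSpec",
    "NoiseModel",
    "response",
    "true_ri",
    "sample_rate_profile",
    "simulate_trace",
    "make_study",
]

_KINDS = ("power_law", "saturation", "pcrit_regulator", "suppressor")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parametric respiration response with analytically known RI.

    Parameters
    ----------
    kind : one of power_law, saturation, pcrit_regulator, suppressor
    rmax_mlO2_h_gww : rate scale (the normoxic rate for all kinds except
        ``saturation``, where it is the asymptote).
    gamma : power-law exponent (power_law).
    K : half-saturation oxygen, %airsat (saturation).
    pcrit_pct : breakpoint oxygen, %airsat (pcrit_regulator).
    below_slope : rate per %airsat below the breakpoint (pcrit_regulator);
        default Rmax/pcrit (decline to zero at anoxia).
    threshold_pct, suppression_fraction, ramp_pct : suppressor geometry —
        below ``threshold_pct`` the rate ramps down over ``ramp_pct`` %airsat
        to ``suppression_fraction`` of the conformity-line rate.
    do_max_pct : oxygen at the top of the response (normoxia).
    """

    kind: str
    rmax_mlO2_h_gww: float = 1.0
    gamma: float = 1.0
    K: float = 25.0
    pcrit_pct: float = 25.0
    below_slope: float | None = None
    threshold_pct: float = 60.0
    suppression_fraction: float = 0.3
    ramp_pct: float = 10.0
    do_max_pct: float = 100.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.rmax_mlO2_h_gww <= 0:
            raise ValueError("rmax must be > 0")
        if self.kind == "power_law" and self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.kind == "saturation" and self.K <= 0:
            raise ValueError("K must be > 0")
        if self.kind == "pcrit_regulator" and not (0 < self.pcrit_pct < self.do_max_pct):
            raise ValueError("pcrit_pct must lie inside (0, do_max_pct)")
        if self.kind == "suppressor":
            if not (0 < self.suppression_fraction < 1):
                raise ValueError("suppression_fraction must be in (0, 1)")
            if not (0 < self.threshold_pct < self.do_max_pct):
                raise ValueError("threshold_pct must lie inside (0, do_max_pct)")
            if not (0 < self.ramp_pct <= self.threshold_pct):
                raise ValueError("ramp_pct must be in (0, threshold_pct]")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: additive Gaussian on oxygen readings (%airsat),
    background chamber drift (%airsat consumed per hour), and — for directly
    sampled rate profiles — rate noise as a fraction of Rmax."""

    sensor_sd_pct: float = 0.0
    blank_slope_pct_per_h: float = 0.0
    rate_sd_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sensor_sd_pct < 0 or self.rate_sd_frac < 0:
            raise ValueError("noise standard deviations must be >= 0")


def response(spec: ArchetypeSpec, do_pct) -> np.ndarray:
    """Evaluate the archetype respiration rate at oxygen ``do_pct`` (%airsat)."""
    x = np.asarray(do_pct, dtype=float)
    r, X = spec.rmax_mlO2_h_gww, spec.do_max_pct
    if spec.kind == "power_law":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = r * np.where(x > 0, (x / X) ** spec.gamma, 0.0 if spec.gamma > 0 else 1.0)
        return out
    if spec.kind == "saturation":
        return r * x / (spec.K + x)
    if spec.kind == "pcrit_regulator":
        s = spec.below_slope if spec.below_slope is not None else r / spec.pcrit_pct
        return np.minimum(r, s * x)
    # suppressor
    c = r / X
    a, t = spec.threshold_pct - spec.ramp_pct, spec.threshold_pct
    g = np.clip((x - a) / spec.ramp_pct, 0.0, 1.0)
    factor = spec.suppression_fraction + (1 - spec.suppression_fraction) * g
    return factor * c * x


def _antiderivative(spec: ArchetypeSpec, x: float) -> float:
    """Closed-form integral of the response from 0 to x."""
    r, X = spec.rmax_mlO2_h_gww, spec.do_max_pct
    if spec.kind == "power_law":
        g = spec.gamma
        return r * X / (g + 1.0) * (x / X) ** (g + 1.0) if x > 0 else 0.0
    if spec.kind == "saturation":
        return r * (x - spec.K * np.log1p(x / spec.K))
    if spec.kind == "pcrit_regulator":
        s = spec.below_slope if spec.below_slope is not None else r / spec.pcrit_pct
        b = r / s  # oxygen where the linear branch reaches rmax
        if x <= b:
            return s * x**2 / 2.0
        return s * b**2 / 2.0 + r * (x - b)
    # suppressor: quadratic / cubic pieces
    c = r / X
    f, w = spec.suppression_fraction, spec.ramp_pct
    a, t = spec.threshold_pct - w, spec.threshold_pct

    def seg_low(u):  # [0, a]
        return f * c * u**2 / 2.0

    def seg_ramp(u):  # [a, t], factor = f + (1-f)(u-a)/w
        return c * (
            f * (u**2 - a**2) / 2.0
            + (1 - f) / w * ((u**3 - a**3) / 3.0 - a * (u**2 - a**2) / 2.0)
        )

    if x <= a:
        return seg_low(x)
    if x <= t:
        return seg_low(a) + seg_ramp(x)
    return seg_low(a) + seg_ramp(t) + c * (x**2 - t**2) / 2.0


def true_ri(spec: ArchetypeSpec, do_lo: float = 0.0, do_hi: float | None = None) -> float:
    """Exact RI of an archetype over [do_lo, do_hi] (default the full range).

    All archetype responses are nondecreasing in oxygen, so the regulation
    level equals the response at ``do_hi``; areas are closed-form.
    """
    hi = spec.do_max_pct if do_hi is None else do_hi
    if not 0 <= do_lo < hi:
        raise ValueError("need 0 <= do_lo < do_hi")
    a_c = _antiderivative(spec, hi) - _antiderivative(spec, do_lo)
    top = float(response(spec, hi))
    a_f = top / hi * (hi**2 - do_lo**2) / 2.0
    a_r = top * (hi - do_lo)
    if a_c >= a_f:
        return float((a_c - a_f) / (a_r - a_f))
    return float((a_c - a_f) / a_f)


def sample_rate_profile(
    spec: ArchetypeSpec,
    n_points: int,
    noise: NoiseModel,
    trace_id: str = "sim",
    floor_pct: float = 1.0,
    rng: np.random.Generator | None = None,
    species: str = "",
    temperature_C: float = float("nan"),
) -> RateProfile:
    """Sample a rate-vs-oxygen profile on a descending oxygen grid.

    Gaussian rate noise (sd = ``noise.rate_sd_frac`` x Rmax) is added and the
    result floored at zero (rates are physically non-negative).
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    do = np.linspace(spec.do_max_pct, floor_pct, n_points)
    rates = response(spec, do)
    if noise.rate_sd_frac > 0:
        rates = rates + rng.normal(0.0, noise.rate_sd_frac * spec.rmax_mlO2_h_gww, n_points)
    rates = np.maximum(rates, 0.0)
    return RateProfile(
        trace_id=trace_id,
        do_pct_airsat=do,
        rate_mlO2_h_gww=rates,
        species=species,
        temperature_C=temperature_C,
    )


def simulate_trace(
    spec: ArchetypeSpec,
    meta: TraceMetadata,
    noise: NoiseModel,
    duration_h: float,
    ctx: UnitContext | None = None,
    start_pct: float = 100.0,
    floor_pct: float = 0.5,
    step_s: float | None = None,
    rng: np.random.Generator | None = None,
) -> RespirometryTrace:
    """Forward-Euler simulation of a closed respirometry chamber.

    The oxygen balance is dC/dt = -R(pct) W / V with C in mL O2 L^-1
    (converted to %airsat via the air-saturation solubility at the chamber
    temperature/salinity), plus background drift ``blank_slope_pct_per_h``.
    The trace includes the initial acclimation segment; it is truncated (and
    logged) if oxygen would fall below ``floor_pct``. Sensor noise is added
    to the readings, which are clipped to the sensor range [0, 110].
    """
    if ctx is None:
        sal = meta.salinity_psu if np.isfinite(meta.salinity_psu) else 34.0
        ctx = UnitContext(temperature_C=meta.temperature_C, salinity_psu=sal)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    dt = step_s if step_s is not None else meta.sampling_interval_s
    if not np.isfinite(dt) or dt <= 0:
        dt = 15.0
    c_sat = o2_solubility_ml_per_l(ctx.temperature_C, ctx.salinity_psu) * ctx.pressure_atm
    v_l = meta.chamber_volume_mL / 1000.0
    w_g = 0.0 if meta.is_blank else meta.weight_mg / 1000.0
    n = int(round(duration_h * 3600.0 / dt)) + 1
    pct = np.empty(n)
    pct[0] = start_pct
    kept = n
    for i in range(1, n):
        p = pct[i - 1]
        rate = float(response(spec, p)) if w_g > 0 else 0.0  # mL O2 / h / g
        dpct = -(rate * w_g / v_l) / c_sat * 100.0 / 3600.0 * dt
        dpct -= noise.blank_slope_pct_per_h / 3600.0 * dt
        nxt = p + dpct
        if nxt < floor_pct:
            kept = i
            logger.info(
                "simulate_trace: %s reached the %.1f%% floor at %.2f h; truncating",
                meta.trace_id, floor_pct, i * dt / 3600.0,
            )
            break
        pct[i] = nxt
    pct = pct[:kept]
    t = np.arange(kept) * dt
    if noise.sensor_sd_pct > 0:
        pct = pct + rng.normal(0.0, noise.sensor_sd_pct, kept)
    pct = np.clip(pct, 0.0, 110.0)
    return RespirometryTrace(meta, t, pct)


def make_study(
    design: Mapping[str, tuple[ArchetypeSpec, int]],
    noise: NoiseModel,
    mode: str = "profile",
    n_points: int = 60,
    floor_pct: float = 1.0,
    duration_h: float = 8.0,
    meta_template: Mapping | None = None,
    temperatures: Mapping[str, float] | None = None,
) -> tuple[list, pd.DataFrame]:
    """Generate a whole synthetic study with per-individual ground truth.

    ``design`` maps a group label (used as the species name) to an
    (archetype, n_individuals) pair. Returns (data, truth): ``data`` is a
    list of RateProfile (mode="profile") or RespirometryTrace
    (mode="trace"); ``truth`` has one row per individual with its group,
    archetype kind and analytic full-range RI. All randomness descends from
    ``noise.seed`` via spawned child generators, so the study is reproducible.
    """
    if not design:
        raise ValueError("design must contain at least one group")
    if mode not in ("profile", "trace"):
        raise ValueError(f"unknown mode {mode!r}")
    ss = np.random.SeedSequence(noise.seed)
    children = ss.spawn(sum(n for _, n in design.values()))
    data: list = []
    rows = []
    ci = 0
    defaults = dict(
        chamber_volume_mL=20.0, weight_mg=50.0, sampling_interval_s=15.0,
        temperature_C=10.0, salinity_psu=34.0,
    )
    if meta_template:
        defaults.update(meta_template)
    for group, (spec, n_ind) in design.items():
        temp = (temperatures or {}).get(group, defaults["temperature_C"])
        for i in range(n_ind):
            tid = f"{group}_{i + 1:02d}"
            rng = np.random.default_rng(children[ci])
            ci += 1
            if mode == "profile":
                data.append(
                    sample_rate_profile(
                        spec, n_points, noise, trace_id=tid, floor_pct=floor_pct,
                        rng=rng, species=group, temperature_C=temp,
                    )
                )
            else:
                meta = TraceMetadata(
                    trace_id=tid, species=group, temperature_C=temp,
                    chamber_volume_mL=defaults["chamber_volume_mL"],
                    weight_mg=defaults["weight_mg"],
                    sampling_interval_s=defaults["sampling_interval_s"],
                    salinity_psu=defaults["salinity_psu"],
                )
                data.append(simulate_trace(spec, meta, noise, duration_h, rng=rng))
            rows.append(
                {
                    "trace_id": tid,
                    "group": group,
                    "temperature_C": temp,
                    "kind": spec.kind,
                    "true_ri": true_ri(spec),
                }
            )
    return data, pd.DataFrame(rows)
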