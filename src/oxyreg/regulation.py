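"""The Regulation Index (RI): locating a rate-vs-oxygen response between
perfect oxyconformity and perfect oxyregulation.

Geometry
--------
Over the observed oxygen range [do_lo, do_hi], three areas are integrated:

- ``A_c``: area under the fitted response curve (natural cubic spline through
  the (oxygen, rate) points, optionally pre-smoothed by local regression);
- ``A_f``: area under the perfect-conformity reference, the straight line
  through the origin reaching the curve value at the highest observed oxygen
  (a conformer with the same normoxic rate);
- ``A_r``: area under the perfect-regulation reference, a horizontal line at
  the maximum of the fitted curve.

If the response runs at or above conformity (A_c >= A_f), the index is the
proportion of the regulation-to-conformity band the curve fills::

    RI = (A_c - A_f) / (A_r - A_f)        # 1 = perfect regulator, 0 = conformer

If the response falls below the conformity line, the deficit is scored against
the area between the conformity line and zero, giving a negative index that
bottoms out at -1 when respiration has collapsed to the floor::

    RI = (A_c - A_f) / A_f                # metabolic suppression / hypoxia sensitivity

The two branches agree (RI = 0) on the conformity line, so RI is continuous in
the data. Integration never extrapolates beyond the observed oxygen range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.interpolate import CubicSpline

from .io import RateProfile

logger = logging.getLogger("oxyreg")

__all__ = [
    "RegulationIndex",
    "RIResults",
    "ReferenceLines",
    "DegenerateProfileError",
    "fit_response_curve",
    "build_reference_lines",
    "integrate_auc",
    "compute_ri",
    "ri_batch",
]


class DegenerateProfileError(ValueError):
    """Profile geometry does not admit an RI (too few points or zero area)."""


@dataclass(frozen=True)
class ReferenceLines:
    """The two reference responses the measured curve is scored against."""

    conformity_slope: float  # rate per % air saturation, line through the origin
    regulation_level: float  # horizontal line at the curve maximum


@dataclass
class RIResults:
    """Fitted Regulation Index for one individual, with its area components.

    ``branch`` is "positive" when the curve stays at/above the conformity
    line, "negative" when it stays below, and "mixed" when it crosses (the
    net-area rule then decides which formula applied).
    """

    trace_id: str
    ri: float
    auc_curve: float
    auc_conformity: float
    auc_regulation: float
    do_lo_pct: float
    do_hi_pct: float
    branch: str
    n_points: int
    conformity_slope: float = float("nan")
    regulation_level: float = float("nan")
    clamped: bool = False
    species: str = ""
    temperature_C: float = float("nan")
    curve: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def summary(self) -> str:
        lines = [
            "Regulation Index Results",
            "=" * 46,
            f"trace_id:            {self.trace_id}",
            f"species:             {self.species or '-'}",
            f"n points:            {self.n_points}",
            f"oxygen range:        {self.do_lo_pct:.1f} - {self.do_hi_pct:.1f} %airsat",
            f"branch:              {self.branch}",
            f"AUC curve:           {self.auc_curve:.6g}",
            f"AUC conformity:      {self.auc_conformity:.6g}",
            f"AUC regulation:      {self.auc_regulation:.6g}",
            "-" * 46,
            f"RI:                  {self.ri:.4f}" + ("  (clamped)" if self.clamped else ""),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the fitted response with both reference lines (as in the
        classic RI geometry figure)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.linspace(self.do_lo_pct, self.do_hi_pct, 400)
        if self.curve is not None:
            ax.plot(x, self.curve(x), label="fitted response", color="C0")
        ax.plot(
            [0, self.do_hi_pct],
            [0, self.conformity_slope * self.do_hi_pct],
            "--", color="C1", label="perfect conformity",
        )
        ax.axhline(self.regulation_level, ls=":", color="C2", label="perfect regulation")
        ax.set_xlabel("dissolved oxygen (% air saturation)")
        ax.set_ylabel("respiration rate (mL O$_2$ h$^{-1}$ g$^{-1}$)")
        ax.set_title(f"{self.trace_id}: RI = {self.ri:.3f}")
        ax.legend()
        return ax


def fit_response_curve(
    profile: RateProfile | None = None,
    do: Sequence[float] | None = None,
    rate: Sequence[float] | None = None,
    smooth: bool = False,
    span: float = 0.75,
) -> CubicSpline:
    """Fit the continuous rate-vs-oxygen response for a profile.

    A natural cubic interpolating spline through the (oxygen, rate) points,
    sorted ascending in oxygen, with duplicate oxygen values mean-aggregated.
    With ``smooth=True`` a local-regression (lowess) pass with fraction
    ``span`` is applied first and the spline interpolates the smoothed values.
    """
    if profile is not None:
        do = profile.do_pct_airsat
        rate = profile.rate_mlO2_h_gww
    x = np.asarray(do, dtype=float)
    y = np.asarray(rate, dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # aggregate duplicate abscissae by mean rate
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size != x.size:
        uy = np.bincount(inv, weights=y) / np.bincount(inv)
        x, y = ux, uy
    if x.size < 3:
        raise DegenerateProfileError(
            f"degenerate profile: {x.size} distinct oxygen values (need >= 3)"
        )
    if smooth:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        y = lowess(y, x, frac=span, return_sorted=False)
    return CubicSpline(x, y, bc_type="natural")


def build_reference_lines(
    curve: Callable[[np.ndarray], np.ndarray],
    do_lo: float,
    do_hi: float,
    grid_size: int = 512,
) -> ReferenceLines:
    """Build the conformity and regulation references for a fitted curve.

    The conformity line passes through the origin (zero rate at anoxia) and
    the curve value at the highest observed oxygen; the regulation level is
    the curve maximum over the observed range, found on a dense grid.
    """
    top = float(curve(do_hi))
    grid = np.linspace(do_lo, do_hi, grid_size)
    level = float(np.max(curve(grid)))
    # tolerate float round-off when the normoxic rate is exactly zero
    if top < -1e-12 * max(1.0, abs(level)):
        raise ValueError("curve value at do_hi is negative; rates must be >= 0")
    top = max(top, 0.0)
    return ReferenceLines(conformity_slope=top / do_hi, regulation_level=level)


def integrate_auc(f: Callable, lo: float, hi: float) -> float:
    """Adaptive-quadrature area under ``f`` over [lo, hi]."""
    if not lo < hi:
        raise ValueError("integration bounds must satisfy lo < hi")
    # relative tolerance only, so the integral is equivariant under rescaling
    # of f (RI must be invariant to the rate unit); round-off warnings at this
    # tolerance are expected for many-knot splines and harmless
    import warnings
    from scipy.integrate import IntegrationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IntegrationWarning)
        val, _ = quad(f, lo, hi, limit=200, epsabs=0.0, epsrel=1e-10)
    if not np.isfinite(val):
        raise ValueError("non-finite integral")
    return float(val)


class RegulationIndex:
    """Model object: the RI geometry fitted to one rate-vs-oxygen profile.

    Parameters
    ----------
    do, rate : array-like
        Dissolved oxygen (% air saturation) and mass-specific respiration
        rate for one individual; any order, duplicates mean-aggregated.
    smooth, span :
        Optional lowess pre-smoothing before spline interpolation.
    grid_size :
        Grid resolution used to locate the curve maximum (regulation level)
        and to detect crossings of the conformity line.

    ``fit()`` returns :class:`RIResults`.
    """

    def __init__(
        self,
        do: Sequence[float],
        rate: Sequence[float],
        trace_id: str = "",
        species: str = "",
        temperature_C: float = float("nan"),
        smooth: bool = False,
        span: float = 0.75,
        grid_size: int = 512,
    ):
        self.do = np.asarray(do, dtype=float)
        self.rate = np.asarray(rate, dtype=float)
        self.trace_id = trace_id
        self.species = species
        self.temperature_C = temperature_C
        self.smooth = smooth
        self.span = span
        self.grid_size = grid_size

    @classmethod
    def from_profile(cls, profile: RateProfile, **kwargs) -> "RegulationIndex":
        return cls(
            profile.do_pct_airsat,
            profile.rate_mlO2_h_gww,
            trace_id=profile.trace_id,
            species=profile.species,
            temperature_C=profile.temperature_C,
            **kwargs,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        oxygen: str = "do_pct_airsat",
        rate: str = "rate_mlO2_h_gww",
        **kwargs,
    ) -> "RegulationIndex":
        return cls(df[oxygen].to_numpy(), df[rate].to_numpy(), **kwargs)

    def fit(self) -> RIResults:
        curve = fit_response_curve(
            do=self.do, rate=self.rate, smooth=self.smooth, span=self.span
        )
        do_lo = float(curve.x[0])
        do_hi = float(curve.x[-1])
        refs = build_reference_lines(curve, do_lo, do_hi, grid_size=self.grid_size)

        a_c = integrate_auc(curve, do_lo, do_hi)
        # reference areas are closed-form (line and constant)
        a_f = refs.conformity_slope * (do_hi**2 - do_lo**2) / 2.0
        a_r = refs.regulation_level * (do_hi - do_lo)

        if np.isclose(a_r, a_f, rtol=0, atol=1e-300) or a_r == 0.0:
            raise DegenerateProfileError(
                "degenerate geometry: regulation and conformity areas coincide"
            )

        grid = np.linspace(do_lo, do_hi, self.grid_size)
        resid = curve(grid) - refs.conformity_slope * grid
        tol = 1e-9 * max(1.0, float(np.max(np.abs(curve(grid)))))
        above = bool(np.any(resid > tol))
        below = bool(np.any(resid < -tol))
        net_positive = a_c >= a_f
        if above and below:
            branch = "mixed"
        elif net_positive:
            branch = "positive"
        else:
            branch = "negative"

        if net_positive:
            ri = (a_c - a_f) / (a_r - a_f)
        else:
            if a_f <= 0:
                raise DegenerateProfileError(
                    "degenerate geometry: zero conformity area on the negative branch"
                )
            ri = (a_c - a_f) / a_f
        clamped = False
        if ri > 1.0 or ri < -1.0:
            logger.warning("compute_ri: %s: RI %.4f clamped to [-1, 1]", self.trace_id, ri)
            ri = float(np.clip(ri, -1.0, 1.0))
            clamped = True

        return RIResults(
            trace_id=self.trace_id,
            ri=float(ri),
            auc_curve=float(a_c),
            auc_conformity=float(a_f),
            auc_regulation=float(a_r),
            do_lo_pct=do_lo,
            do_hi_pct=do_hi,
            branch=branch,
            n_points=int(curve.x.size),
            conformity_slope=refs.conformity_slope,
            regulation_level=refs.regulation_level,
            clamped=clamped,
            species=self.species,
            temperature_C=self.temperature_C,
            curve=curve,
        )


def compute_ri(profile: RateProfile, **kwargs) -> RIResults:
    """Compute the Regulation Index for one QC-passing rate profile."""
    if not profile.qc_pass:
        raise ValueError(
            f"{profile.trace_id}: profile failed QC ({profile.qc_reason}); "
            "RI is only defined on QC-passing profiles"
        )
    return RegulationIndex.from_profile(profile, **kwargs).fit()


def ri_batch(
    profiles: Iterable[RateProfile], **kwargs
) -> tuple[list[RIResults], list[dict]]:
    """Compute RI for every QC-passing profile in a collection.

    Returns (results, skipped) where each skip record carries the trace id
    and the reason; failures are recorded, never silently dropped.
    """
    results: list[RIResults] = []
    skipped: list[dict] = []
    for p in profiles:
        if not p.qc_pass:
            skipped.append({"trace_id": p.trace_id, "reason": f"qc_fail: {p.qc_reason}"})
            continue
        try:
            results.append(compute_ri(p, **kwargs))
        except (DegenerateProfileError, ValueError) as exc:
            skipped.append({"trace_id": p.trace_id, "reason": str(exc)})
    for rec in skipped:
        logger.info("ri_batch: skipped %(trace_id)s (%(reason)s)", rec)
    return results, skipped
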