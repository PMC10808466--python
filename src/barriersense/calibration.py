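"""Four-parameter logistic (4PL) calibration and flat-field correction.

The sensor reports 8-bit pixel intensities; quantification requires mapping
mean ROI intensity back to tracer concentration. The forward model is the
standard sigmoidal dose-response curve

    F(x) = d + (a - d) / (1 + (x/c)^b)

with minimum asymptote ``a`` (AU), Hill slope ``b``, half-maximal
concentration ``c`` (mg/mL) and maximum asymptote ``d`` (AU). This module
fits that curve to replicate calibration measurements, inverts it, estimates
the per-pixel illumination correction mask from uniform-concentration frames,
and propagates the regression error into concentration space to delimit the
sensor's usable sensitivity region.

All intensities are handled as floats; 8-bit quantization applies only when
frames are ingested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegeneratePixelError,
    InvalidInputError,
    NonConvergenceError,
    OutOfRangeError,
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted 4PL parameters with uncertainty for one fluorophore channel."""

    channel_label: str
    a: float                    # minimum asymptote (AU)
    b: float                    # Hill slope
    c: float                    # half-maximal concentration (mg/mL)
    d: float                    # maximum asymptote (AU)
    r_squared: float = float("nan")
    se_regression: float = float("nan")   # standard error of regression (AU)
    # parameter name -> (lower, upper) 95% confidence bounds
    param_ci95: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.c > 0:
            raise InvalidInputError(f"4PL midpoint c must be positive, got {self.c}")
        if self.a == self.d:
            raise InvalidInputError("4PL asymptotes a and d must differ")
        if np.isfinite(self.r_squared) and not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise InvalidInputError(f"r_squared must lie in [0, 1], got {self.r_squared}")
        for name, (lo, hi) in self.param_ci95.items():
            est = getattr(self, name)
            if not lo <= est <= hi:
                raise InvalidInputError(
                    f"95% CI for '{name}' ({lo}, {hi}) does not bracket estimate {est}"
                )

    @property
    def f_min(self) -> float:
        """Lower end of the intensity response range."""
        return min(self.a, self.d)

    @property
    def f_max(self) -> float:
        """Upper end of the intensity response range."""
        return max(self.a, self.d)

    def to_dict(self) -> dict:
        return {
            "channel_label": self.channel_label,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "r_squared": self.r_squared,
            "se_regression": self.se_regression,
            "param_ci95": {k: list(v) for k, v in self.param_ci95.items()},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CalibrationCurve":
        ci = {k: (float(v[0]), float(v[1])) for k, v in payload.get("param_ci95", {}).items()}
        return cls(
            channel_label=payload["channel_label"],
            a=float(payload["a"]),
            b=float(payload["b"]),
            c=float(payload["c"]),
            d=float(payload["d"]),
            r_squared=float(payload.get("r_squared", float("nan"))),
            se_regression=float(payload.get("se_regression", float("nan"))),
            param_ci95=ci,
        )


@dataclass(frozen=True)
class CalibrationDataset:
    """Replicate intensity measurements at known tracer concentrations.

    ``concentrations`` and ``intensities`` are flat, parallel sequences: one
    entry per replicate measurement (so a concentration measured three times
    appears three times).
    """

    concentrations: tuple[float, ...]
    intensities: tuple[float, ...]

    def __init__(self, concentrations: Sequence[float], intensities: Sequence[float]):
        conc = tuple(float(x) for x in concentrations)
        inten = tuple(float(y) for y in intensities)
        if len(conc) != len(inten):
            raise InvalidInputError(
                f"{len(conc)} concentrations but {len(inten)} intensities"
            )
        if any(x <= 0 for x in conc):
            raise InvalidInputError("calibration concentrations must be strictly positive")
        if len(set(conc)) < 5:
            raise InvalidInputError(
                f"need at least 5 distinct concentrations, got {len(set(conc))}"
            )
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "intensities", inten)

    @property
    def distinct_concentrations(self) -> np.ndarray:
        return np.unique(np.asarray(self.concentrations))


@dataclass(frozen=True)
class IlluminationMask:
    """Per-pixel multiplicative flat-field correction factors.

    The multipliers are the ratio of the global mean of the calibration
    image to each pixel's mean, so applying the mask to that image yields a
    spatially flat field with the original global mean.
    """

    multipliers: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.multipliers, dtype=float)
        if m.ndim != 2:
            raise InvalidInputError("mask multipliers must be a 2D array")
        if not np.all(m > 0):
            raise InvalidInputError("mask multipliers must all be positive")
        object.__setattr__(self, "multipliers", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.multipliers.shape


class SensitivityRegion(NamedTuple):
    """Concentration interval over which inverted readings are reliable."""

    lower: float        # mg/mL
    upper: float        # mg/mL
    lower_err: float    # mg/mL
    upper_err: float    # mg/mL


class ConcentrationError(NamedTuple):
    """Concentration-space half-width of the regression error at an intensity."""

    value: float        # mg/mL
    one_sided: bool     # True when only one side of f +/- se was invertible


# ---------------------------------------------------------------------------
# forward / inverse evaluation
# ---------------------------------------------------------------------------


def eval_4pl(curve: CalibrationCurve, x):
    """Evaluate the 4PL response F(x) = d + (a-d)/(1+(x/c)^b) at x >= 0 (mg/mL).

    At x = 0 the limit convention applies: F(0) = a for b > 0 (and d for
    b < 0, where the asymptote roles swap).
    """
    xs = np.asarray(x, dtype=float)
    if np.any(xs < 0):
        raise InvalidInputError("concentration must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.power(xs / curve.c, curve.b)
    out = curve.d + (curve.a - curve.d) / (1.0 + ratio)
    # 0^b: numpy yields 0 for b>0 (giving a) and inf for b<0 (giving d) — both
    # already the wanted limits; guard only the 1/inf -> d branch for exactness
    out = np.where(np.isinf(ratio), curve.d, out)
    return float(out) if np.isscalar(x) or xs.ndim == 0 else out


def invert_4pl(curve: CalibrationCurve, f: float) -> float:
    """Concentration x such that eval_4pl(curve, x) == f.

    ``f`` must lie strictly between the asymptotes; outside that open
    interval the curve carries no concentration information and an
    :class:`OutOfRangeError` is raised naming the violated asymptote. The
    caller may clamp; the library never does so silently.
    """
    f = float(f)
    if not f > curve.f_min:
        raise OutOfRangeError(
            f"intensity {f} AU is at or below the lower asymptote {curve.f_min} AU",
            asymptote="lower",
        )
    if not f < curve.f_max:
        raise OutOfRangeError(
            f"intensity {f} AU is at or above the upper asymptote {curve.f_max} AU",
            asymptote="upper",
        )
    return curve.c * ((curve.a - curve.d) / (f - curve.d) - 1.0) ** (1.0 / curve.b)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _4pl_model(x, a, b, c, d):
    return d + (a - d) / (1.0 + (x / c) ** b)


def fit_4pl(dataset: CalibrationDataset, channel_label: str = "") -> CalibrationCurve:
    """Least-squares 4PL fit over all replicate points.

    Minimizes the summed squared intensity residuals on the linear intensity
    scale with multi-start initialization: a = min intensity, d = max
    intensity, c = geometric mean of the concentrations, and Hill slopes
    b in {+-0.5, +-1, +-2}; c is bounded positive. 95% confidence intervals
    come from the asymptotic (Jacobian-based) covariance of the best fit
    with Student-t critical values at n-4 degrees of freedom.
    """
    x = np.asarray(dataset.concentrations, dtype=float)
    y = np.asarray(dataset.intensities, dtype=float)
    n = len(x)
    if n < 5:
        raise InvalidInputError("need at least 5 calibration points")
    if np.ptp(y) == 0:
        raise NonConvergenceError(
            "all intensities are equal: no dose response to fit", residual_norm=None
        )

    a0, d0 = float(y.min()), float(y.max())
    if a0 == d0:  # unreachable given the ptp guard, kept for clarity
        raise NonConvergenceError("degenerate intensity range")
    c0 = float(np.exp(np.mean(np.log(x))))
    span = d0 - a0
    lower = [-np.inf, -np.inf, 1e-300, -np.inf]
    upper = [np.inf, np.inf, np.inf, np.inf]

    best = None
    last_norm = None
    for b0 in (0.5, -0.5, 1.0, -1.0, 2.0, -2.0):
        # pair each slope sign with the asymptote assignment it implies
        p0 = (a0, b0, c0, d0) if b0 > 0 else (d0, b0, c0, a0)
        try:
            popt, pcov = optimize.curve_fit(
                _4pl_model, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - _4pl_model(x, *popt)
        ssr = float(resid @ resid)
        last_norm = float(np.sqrt(ssr))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)

    if best is None:
        raise NonConvergenceError(
            "4PL fit failed to converge from any start", residual_norm=last_norm
        )

    ssr, popt, pcov = best
    a, b, c, d = (float(v) for v in popt)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    if b < 0:
        # the 4PL is invariant under (a, b, d) -> (d, -b, a); canonicalize to
        # a positive Hill slope so a is always the zero-concentration response
        a, b, d = d, -b, a
        perr = perr[[3, 1, 2, 0]]
    if a == d or not np.isfinite([a, b, c, d]).all():
        raise NonConvergenceError(
            f"degenerate 4PL fit (a={a}, d={d})", residual_norm=float(np.sqrt(ssr))
        )

    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    dof = max(n - 4, 1)
    se_reg = float(np.sqrt(ssr / dof))
    tcrit = float(stats.t.ppf(0.975, dof))
    ci = {
        name: (val - tcrit * err, val + tcrit * err)
        for name, val, err in zip("abcd", (a, b, c, d), perr)
    }
    return CalibrationCurve(
        channel_label=channel_label,
        a=a, b=b, c=c, d=d,
        r_squared=r2,
        se_regression=se_reg,
        param_ci95=ci,
    )


# ---------------------------------------------------------------------------
# illumination correction
# ---------------------------------------------------------------------------


def estimate_illumination_mask(frames: Sequence) -> IlluminationMask:
    """Estimate the flat-field mask from >=3 frames at one uniform concentration.

    The per-pixel multiplier is (global mean of the pixelwise-mean image) /
    (pixelwise mean), so the corrected calibration image is spatially flat at
    the original global mean.
    """
    if len(frames) < 3:
        raise InvalidInputError(f"need at least 3 frames, got {len(frames)}")
    shapes = {f.pixels.shape for f in frames}
    if len(shapes) != 1:
        raise InvalidInputError(f"frames have mismatched shapes: {sorted(shapes)}")
    channels = {f.led_channel for f in frames}
    if len(channels) != 1:
        raise InvalidInputError(f"frames mix LED channels: {sorted(channels)}")
    pixmean = np.mean([np.asarray(f.pixels, dtype=float) for f in frames], axis=0)
    bad = np.argwhere(pixmean <= 0)
    if bad.size:
        raise DegeneratePixelError(
            f"{len(bad)} pixel(s) have non-positive mean intensity",
            pixels=[tuple(int(i) for i in rc) for rc in bad],
        )
    return IlluminationMask(multipliers=pixmean.mean() / pixmean)


def apply_mask(frame, mask: IlluminationMask):
    """Multiply a frame pixelwise by the mask; output stays at float precision."""
    from .quantify import Frame  # local import to avoid a cycle

    pixels = np.asarray(frame.pixels, dtype=float)
    if pixels.shape != mask.shape:
        raise InvalidInputError(
            f"frame shape {pixels.shape} != mask shape {mask.shape}"
        )
    return Frame(
        pixels=pixels * mask.multipliers,
        led_channel=frame.led_channel,
        timestamp=frame.timestamp,
        validate_range=False,
    )


# ---------------------------------------------------------------------------
# error propagation and sensitivity region
# ---------------------------------------------------------------------------


def concentration_error(curve: CalibrationCurve, f: float) -> ConcentrationError:
    """Map the regression standard error into concentration space at intensity f.

    Returns the symmetric half-width |x(f+se) - x(f-se)| / 2. When only one
    of f +/- se is invertible the one-sided width |x(f+/-se) - x(f)| is
    returned with ``one_sided=True``; when neither side is invertible an
    :class:`OutOfRangeError` propagates.
    """
    se = curve.se_regression
    if not np.isfinite(se) or se < 0:
        raise InvalidInputError("curve has no valid se_regression")
    if se == 0:
        invert_4pl(curve, f)  # still demand f itself be invertible
        return ConcentrationError(0.0, one_sided=False)
    lo_x = hi_x = None
    lo_err = hi_err = None
    try:
        lo_x = invert_4pl(curve, f - se)
    except OutOfRangeError as e:
        lo_err = e
    try:
        hi_x = invert_4pl(curve, f + se)
    except OutOfRangeError as e:
        hi_err = e
    if lo_x is not None and hi_x is not None:
        return ConcentrationError(abs(hi_x - lo_x) / 2.0, one_sided=False)
    if lo_x is None and hi_x is None:
        raise hi_err if hi_err is not None else lo_err
    x0 = invert_4pl(curve, f)
    side = hi_x if hi_x is not None else lo_x
    return ConcentrationError(abs(side - x0), one_sided=True)


def sensitivity_region(curve: CalibrationCurve) -> SensitivityRegion:
    """Concentration bounds of reliable sensing, from the asymptote CIs.

    Reverse-maps the 95% confidence edge of each asymptote that lies nearest
    the interior of the response (toward the other asymptote): for an
    increasing curve the upper CI edge of the minimum asymptote and the lower
    CI edge of the maximum asymptote. CI edges at or beyond the asymptotes
    themselves (e.g. zero-width CIs from a noiseless fit) are not invertible
    — the corresponding limits would be 0 and infinity — and raise
    :class:`OutOfRangeError`.
    """
    for name in ("a", "d"):
        if name not in curve.param_ci95:
            raise InvalidInputError(f"curve lacks a 95% CI for asymptote '{name}'")
    a_lo, a_hi = curve.param_ci95["a"]
    d_lo, d_hi = curve.param_ci95["d"]
    if curve.a < curve.d:  # increasing response: interior is above a, below d
        f_low_edge, f_high_edge = a_hi, d_lo
    else:                  # decreasing response
        f_low_edge, f_high_edge = a_lo, d_hi
    # f_low_edge sits near the minimum asymptote, f_high_edge near the maximum
    lower = invert_4pl(curve, f_low_edge)
    upper = invert_4pl(curve, f_high_edge)
    lower, upper = min(lower, upper), max(lower, upper)
    lower_f, upper_f = (f_low_edge, f_high_edge)
    if invert_4pl(curve, lower_f) != lower:
        lower_f, upper_f = upper_f, lower_f
    lower_err = concentration_error(curve, lower_f).value
    upper_err = concentration_error(curve, upper_f).value
    return SensitivityRegion(lower=lower, upper=upper, lower_err=lower_err, upper_err=upper_err)
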