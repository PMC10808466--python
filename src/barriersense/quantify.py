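"""Frame-stream quantification: intensities -> concentrations -> diffusion %.

Implements the automated acquisition loop of the sensor: LEDs are cycled one
at a time (cyan 490 nm exciting FITC, then amber 590 nm exciting Texas Red),
one frame per channel per time point. Each frame is background-subtracted,
flat-field corrected, reduced to mean intensities over the capillary and
filtrate ROIs, and inverted through the channel's calibration curve. The
output time series carries, per point, both ROI intensities and
concentrations, the diffusion percentage

    Diff% = 100 * C_filtrate / C_capillary_initial

the filtrate/capillary intensity ratio used as a stability QC, and the
instantaneous percentage relative to the *current* capillary concentration
(relevant when the capillary gradient is stepped during a run).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationCurve,
    ConcentrationError,
    IlluminationMask,
    apply_mask,
    concentration_error,
    invert_4pl,
)
from .errors import (
    ConfigurationError,
    InvalidInputError,
    OutOfRangeError,
    UndefinedRatioError,
)

#: canonical LED cycle order within one acquisition time point
CHANNEL_ORDER = ("cyan", "amber")

#: default binned sensor resolution (rows, cols)
DEFAULT_FRAME_SHAPE = (380, 507)

#: hardware floor on the acquisition cycle time, seconds
MIN_CYCLE_PERIOD_S = 7.0

#: fraction of saturated (255) ROI pixels above which a point is flagged
SATURATION_FLAG_FRACTION = 0.01


@dataclass(frozen=True)
class Frame:
    """One grayscale sensor image with its LED channel and acquisition time.

    Pixels are ingested at 8-bit depth (values in [0, 255]) but held as
    floats; derived frames (background-subtracted, mask-corrected) bypass
    the range check via ``validate_range=False``.
    """

    pixels: np.ndarray
    led_channel: str
    timestamp: float  # seconds since acquisition start
    meta: dict = dc_field(default_factory=dict, compare=False)
    validate_range: bool = True

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise InvalidInputError("frame pixels must be a 2D array")
        if self.validate_range and (px.min() < 0 or px.max() > 255):
            raise InvalidInputError(
                f"ingested pixel values must lie in [0, 255], got "
                f"[{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Rect:
    """Pixel rectangle in 0-based, half-open indexing [r0, r1) x [c0, c1)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self):
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise InvalidInputError(f"empty ROI rectangle {self}")
        if min(self.row_start, self.col_start) < 0:
            raise InvalidInputError(f"ROI rectangle {self} has negative bounds")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_end), slice(self.col_start, self.col_end)

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.row_end <= other.row_start
            or other.row_end <= self.row_start
            or self.col_end <= other.col_start
            or other.col_end <= self.col_start
        )

    def within(self, shape: tuple[int, int]) -> bool:
        return self.row_end <= shape[0] and self.col_end <= shape[1]


@dataclass(frozen=True)
class ROISet:
    """The two imaging rectangles: capillary channel and filtrate channel."""

    capillary: Rect
    filtrate: Rect

    def __post_init__(self):
        if self.capillary.overlaps(self.filtrate):
            raise InvalidInputError("capillary and filtrate ROIs overlap")


@dataclass(frozen=True)
class MeasurementEvent:
    """One scheduled single-channel exposure within an acquisition cycle."""

    time_s: float
    channel: str


#: fixed column order of the analysis output
TIMESERIES_COLUMNS = [
    "time_s",
    "channel",
    "capillary_intensity",
    "filtrate_intensity",
    "capillary_concentration",
    "filtrate_concentration",
    "capillary_concentration_err",
    "filtrate_concentration_err",
    "diffusion_percent",
    "intensity_ratio",
    "instant_percent",
    "flags",
]


@dataclass
class TimeSeries:
    """Per-timepoint, per-channel quantification results.

    Thin wrapper over a :class:`pandas.DataFrame` with the fixed column set
    ``TIMESERIES_COLUMNS``. ``flags`` is a semicolon-joined string of
    per-point markers (empty when the point is clean); concentrations of
    flagged out-of-range points are NaN, never silently clamped.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in TIMESERIES_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"time series missing columns: {missing}")
        self.data = self.data[TIMESERIES_COLUMNS].reset_index(drop=True)
        for ch, grp in self.data.groupby("channel"):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise InvalidInputError(f"times not strictly increasing for channel {ch}")
        dp = self.data["diffusion_percent"].to_numpy(dtype=float)
        if np.any(dp[np.isfinite(dp)] < 0):
            raise InvalidInputError("diffusion_percent must be non-negative where defined")

    def channel(self, label: str) -> pd.DataFrame:
        return self.data[self.data["channel"] == label].reset_index(drop=True)


# ---------------------------------------------------------------------------
# frame operations
# ---------------------------------------------------------------------------


def subtract_background(frame: Frame, background: Frame) -> Frame:
    """Pixelwise difference, clipped at zero (8-bit data has no negatives)."""
    if frame.led_channel != background.led_channel:
        raise InvalidInputError(
            f"channel mismatch: frame is {frame.led_channel!r}, "
            f"background is {background.led_channel!r}"
        )
    if frame.shape != background.shape:
        raise InvalidInputError(
            f"shape mismatch: frame {frame.shape}, background {background.shape}"
        )
    return Frame(
        pixels=np.clip(frame.pixels - background.pixels, 0.0, None),
        led_channel=frame.led_channel,
        timestamp=frame.timestamp,
        meta=dict(frame.meta),
        validate_range=False,
    )


def roi_mean_intensity(frame: Frame, roi: Rect) -> float:
    """Arithmetic mean pixel intensity over an ROI rectangle (AU)."""
    if not roi.within(frame.shape):
        raise InvalidInputError(f"ROI {roi} outside frame of shape {frame.shape}")
    return float(frame.pixels[roi.slices()].mean())


def acquisition_schedule(
    channels: Sequence[str],
    period_s: float,
    duration_s: float,
    min_period_s: float = MIN_CYCLE_PERIOD_S,
) -> list[MeasurementEvent]:
    """Non-overlapping LED exposure events: per time point, one per channel.

    Time points run t = 0, period, 2*period, ... endpoint-inclusive. Within a
    cycle channels fire in the fixed order cyan then amber (LEDs on one at a
    time to prevent crosstalk); channels outside the canonical pair keep
    their given order after it.
    """
    if not channels:
        raise InvalidInputError("schedule needs at least one channel")
    if len(set(channels)) != len(channels):
        raise InvalidInputError("duplicate channels in schedule")
    if period_s < min_period_s:
        raise InvalidInputError(
            f"period {period_s} s below the minimum cycle time {min_period_s} s"
        )
    if duration_s < 0:
        raise InvalidInputError("duration must be non-negative")
    ordered = [ch for ch in CHANNEL_ORDER if ch in channels]
    ordered += [ch for ch in channels if ch not in CHANNEL_ORDER]
    n_points = int(np.floor(duration_s / period_s + 1e-9)) + 1
    return [
        MeasurementEvent(time_s=i * period_s, channel=ch)
        for i in range(n_points)
        for ch in ordered
    ]


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------


def diffusion_percentage(c_filtrate: float, c_capillary_initial: float) -> float:
    """Diff% = 100 * C_filtrate / C_capillary_initial."""
    if not c_capillary_initial > 0:
        raise UndefinedRatioError(
            f"initial capillary concentration must be positive, got {c_capillary_initial}"
        )
    if c_filtrate < 0:
        raise InvalidInputError("filtrate concentration must be non-negative")
    return 100.0 * c_filtrate / c_capillary_initial


def intensity_ratio(filtrate_intensity: float, capillary_intensity: float) -> float:
    """Filtrate/capillary mean-intensity ratio (stability QC; ~1 at equal loading)."""
    if not capillary_intensity > 0:
        raise UndefinedRatioError(
            f"capillary intensity must be positive, got {capillary_intensity}"
        )
    return filtrate_intensity / capillary_intensity


# ---------------------------------------------------------------------------
# the acquisition/analysis loop
# ---------------------------------------------------------------------------


def _saturated_fraction(frame: Frame, roi: Rect) -> float:
    return float(np.mean(frame.pixels[roi.slices()] >= 255))


def _invert_or_flag(curve, f, flags, prefix):
    try:
        conc = invert_4pl(curve, f)
    except OutOfRangeError as e:
        flags.append(f"{prefix}_{'below' if e.asymptote == 'lower' else 'above'}_range")
        return np.nan, np.nan
    try:
        err = concentration_error(curve, f)
    except (OutOfRangeError, InvalidInputError):
        err = ConcentrationError(np.nan, one_sided=True)
    if err.one_sided and np.isfinite(err.value):
        flags.append(f"{prefix}_error_one_sided")
    return conc, err.value


def analyze_timeseries(
    frames: Iterable[Frame],
    rois: ROISet,
    curves: Mapping[str, CalibrationCurve],
    masks: Mapping[str, IlluminationMask],
    backgrounds: Mapping[str, Frame],
) -> TimeSeries:
    """Run the full per-frame pipeline and assemble the output time series.

    Per frame: subtract the channel's background, apply the channel's
    illumination mask, take the two ROI means, invert each through the
    channel's calibration curve, and accumulate diffusion percentage
    (relative to the first in-range capillary reading of that channel) and
    the filtrate/capillary intensity ratio. Intensities outside the curve's
    invertible range yield flagged points with concentration omitted; the
    pipeline continues. An ROI with more than 1% saturated (255) pixels
    flags the point.
    """
    rows = []
    baseline: dict[str, float] = {}  # channel -> initial capillary concentration
    for frame in frames:
        ch = frame.led_channel
        if ch not in backgrounds or ch not in masks:
            raise ConfigurationError(f"no background/mask configured for channel {ch!r}")
        if ch not in curves:
            raise ConfigurationError(f"no calibration curve configured for channel {ch!r}")
        if not (rois.capillary.within(frame.shape) and rois.filtrate.within(frame.shape)):
            raise InvalidInputError("ROIs fall outside the frame")

        flags: list[str] = []
        if _saturated_fraction(frame, rois.capillary) > SATURATION_FLAG_FRACTION:
            flags.append("capillary_saturated")
        if _saturated_fraction(frame, rois.filtrate) > SATURATION_FLAG_FRACTION:
            flags.append("filtrate_saturated")

        corrected = apply_mask(subtract_background(frame, backgrounds[ch]), masks[ch])
        f_cap = roi_mean_intensity(corrected, rois.capillary)
        f_fil = roi_mean_intensity(corrected, rois.filtrate)

        curve = curves[ch]
        c_cap, e_cap = _invert_or_flag(curve, f_cap, flags, "capillary")
        c_fil, e_fil = _invert_or_flag(curve, f_fil, flags, "filtrate")

        if ch not in baseline and np.isfinite(c_cap):
            baseline[ch] = c_cap

        if np.isfinite(c_fil) and ch in baseline:
            diff_pct = diffusion_percentage(c_fil, baseline[ch])
        else:
            if ch not in baseline:
                flags.append("no_baseline")
            diff_pct = np.nan

        if np.isfinite(c_fil) and np.isfinite(c_cap) and c_cap > 0:
            instant_pct = 100.0 * c_fil / c_cap
        else:
            instant_pct = np.nan

        try:
            ratio = intensity_ratio(f_fil, f_cap)
        except UndefinedRatioError:
            flags.append("undefined_intensity_ratio")
            ratio = np.nan

        rows.append(
            {
                "time_s": frame.timestamp,
                "channel": ch,
                "capillary_intensity": f_cap,
                "filtrate_intensity": f_fil,
                "capillary_concentration": c_cap,
                "filtrate_concentration": c_fil,
                "capillary_concentration_err": e_cap,
                "filtrate_concentration_err": e_fil,
                "diffusion_percent": diff_pct,
                "intensity_ratio": ratio,
                "instant_percent": instant_pct,
                "flags": ";".join(flags),
            }
        )
    if not rows:
        return TimeSeries(pd.DataFrame(columns=TIMESERIES_COLUMNS))
    return TimeSeries(pd.DataFrame(rows))
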