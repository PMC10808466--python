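"""Ground-truth chip simulator: renders sensor frames and whole experiments.

No public dataset accompanies the hardware, so every downstream module is
tested against this simulator. It composes the same forward physics the
analysis inverts: tracer concentrations map to ROI intensities through the
4PL response, an uneven illumination field divides the image (the inverse of
the flat-field correction), a uniform dark offset and Gaussian/Poisson noise
are added, and the result is quantized to 8 bits. Experiment-level dynamics
follow the lumped-parameter model: within each protocol segment the filtrate
concentration relaxes exponentially (time constant tau, default 120 s) from
its current value toward the Darcy steady-state equilibrium of that
segment's flowrate and capillary loading.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, CalibrationDataset, IlluminationMask, eval_4pl
from .errors import InvalidInputError
from .quantify import Frame, ROISet
from .transport import (
    DEFAULT_TAU_S,
    ChipGeometry,
    FluidProperties,
    OperatingPoint,
    Tracer,
    steady_state_filtrate_concentration,
    transient_response,
)

#: default rendered frame shape (rows, cols), the sensor's binned resolution
DEFAULT_SHAPE = (380, 507)


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise: additive Gaussian read noise plus optional shot noise.

    ``poisson_scale`` is the photon count per intensity unit; 0 disables the
    shot-noise term. ``dark_offset`` is the uniform dark/leakage level added
    to every pixel (the background frame the analysis subtracts).
    """

    gaussian_sigma: float = 1.0
    poisson_scale: float = 0.0
    seed: int = 0
    dark_offset: float = 0.0

    def __post_init__(self):
        if self.gaussian_sigma < 0 or self.poisson_scale < 0 or self.dark_offset < 0:
            raise InvalidInputError("noise parameters must be non-negative")


@dataclass(frozen=True)
class ProtocolSegment:
    """One constant-condition stretch of an experiment."""

    duration_s: float
    capillary_concentration: float  # mg/mL, commanded value
    flowrate_ml_s: float

    def __post_init__(self):
        if not self.duration_s > 0:
            raise InvalidInputError("segment duration must be positive")
        if self.capillary_concentration < 0 or self.flowrate_ml_s <= 0:
            raise InvalidInputError("segment needs C0 >= 0 and Q > 0")


@dataclass(frozen=True)
class ExperimentProtocol:
    """A sequence of step-input segments sampled at a fixed period."""

    segments: tuple[ProtocolSegment, ...]
    sampling_period_s: float
    initial_filtrate_concentration: float = 0.0

    def __init__(self, segments: Sequence[ProtocolSegment], sampling_period_s: float,
                 initial_filtrate_concentration: float = 0.0):
        if not segments:
            raise InvalidInputError("protocol needs at least one segment")
        if not sampling_period_s > 0:
            raise InvalidInputError("sampling period must be positive")
        if initial_filtrate_concentration < 0:
            raise InvalidInputError("initial filtrate concentration must be non-negative")
        object.__setattr__(self, "segments", tuple(segments))
        object.__setattr__(self, "sampling_period_s", float(sampling_period_s))
        object.__setattr__(self, "initial_filtrate_concentration",
                           float(initial_filtrate_concentration))

    @property
    def total_duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)


@dataclass
class SimulatedExperiment:
    """Rendered frames plus manifest and the exact ground-truth time series."""

    frames: list[Frame]
    manifest: pd.DataFrame          # columns: filename, channel, timestamp_s
    ground_truth: pd.DataFrame      # per sample: time_s, capillary/filtrate conc, ...
    background: Frame               # the dark frame the analysis should subtract


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------


def _add_noise(arr: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.poisson_scale > 0:
        arr = rng.poisson(np.clip(arr, 0, None) * noise.poisson_scale) / noise.poisson_scale
    if noise.gaussian_sigma > 0:
        arr = arr + rng.normal(0.0, noise.gaussian_sigma, size=arr.shape)
    return arr


def render_frame(
    cap_conc: float,
    filt_conc: float,
    curve: CalibrationCurve,
    truth_mask: IlluminationMask,
    rois: ROISet | None,
    noise: NoiseModel,
    *,
    led_channel: str | None = None,
    timestamp: float = 0.0,
    rng: np.random.Generator | None = None,
    quantize: bool = True,
) -> Frame:
    """Render one sensor frame for given true ROI concentrations.

    ROI pixels carry the 4PL response of their concentration, the background
    region sits at the zero-dye response (the minimum asymptote for an
    increasing curve); the whole field is divided by the truth mask — the
    physical inverse of the flat-field correction — then the dark offset and
    noise are added and the image is quantized to 8 bits with clipping.

    ``rois=None`` renders a uniform calibration field: the entire frame at
    ``cap_conc`` (used to estimate illumination masks). A frame whose ROI
    saturates over half its pixels is tagged with ``meta['saturation_warning']``.
    Identical seeds render identical frames.
    """
    if cap_conc < 0 or filt_conc < 0:
        raise InvalidInputError("concentrations must be non-negative")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    shape = truth_mask.shape
    if rois is None:
        signal = np.full(shape, eval_4pl(curve, cap_conc), dtype=float)
    else:
        if not (rois.capillary.within(shape) and rois.filtrate.within(shape)):
            raise InvalidInputError("ROIs fall outside the mask/frame shape")
        signal = np.full(shape, eval_4pl(curve, 0.0), dtype=float)
        signal[rois.capillary.slices()] = eval_4pl(curve, cap_conc)
        signal[rois.filtrate.slices()] = eval_4pl(curve, filt_conc)
    raw = signal / truth_mask.multipliers + noise.dark_offset
    raw = _add_noise(raw, noise, rng)
    if quantize:
        raw = np.clip(np.rint(raw), 0.0, 255.0)
    meta: dict = {}
    if rois is not None and quantize:
        for name, rect in (("capillary", rois.capillary), ("filtrate", rois.filtrate)):
            if float(np.mean(raw[rect.slices()] >= 255)) > 0.5:
                meta["saturation_warning"] = True
    return Frame(
        pixels=raw,
        led_channel=led_channel or curve.channel_label or "cyan",
        timestamp=timestamp,
        meta=meta,
        validate_range=quantize,
    )


def render_background(
    truth_mask: IlluminationMask, noise: NoiseModel, led_channel: str
) -> Frame:
    """The dark frame a real run collects before sample input."""
    return Frame(
        pixels=np.full(truth_mask.shape, float(np.rint(noise.dark_offset))),
        led_channel=led_channel,
        timestamp=0.0,
    )


# ---------------------------------------------------------------------------
# experiment simulation
# ---------------------------------------------------------------------------


def ground_truth_timeseries(
    protocol: ExperimentProtocol,
    geom: ChipGeometry,
    fluid: FluidProperties,
    tracer: Tracer,
    tau_s: float = DEFAULT_TAU_S,
) -> pd.DataFrame:
    """Exact concentration dynamics of the protocol, no rendering.

    Piecewise first-order relaxation: at each segment boundary the starting
    value ``a`` is the filtrate concentration reached so far and ``a + b``
    is the Darcy steady-state equilibrium of the new segment.
    """
    rows = []
    filt = protocol.initial_filtrate_concentration
    seg_start = 0.0
    times = np.arange(
        0.0, protocol.total_duration_s + 1e-9, protocol.sampling_period_s
    )
    boundaries = np.cumsum([s.duration_s for s in protocol.segments])
    seg_idx = 0
    a = filt
    op = OperatingPoint(protocol.segments[0].flowrate_ml_s,
                        protocol.segments[0].capillary_concentration)
    eq = steady_state_filtrate_concentration(geom, fluid, tracer, op)
    for t in times:
        while seg_idx < len(boundaries) - 1 and t >= boundaries[seg_idx] - 1e-9:
            # close out the segment: carry the exact boundary value forward
            a = transient_response(a, eq - a, tau_s, boundaries[seg_idx] - seg_start)
            seg_start = boundaries[seg_idx]
            seg_idx += 1
            seg = protocol.segments[seg_idx]
            op = OperatingPoint(seg.flowrate_ml_s, seg.capillary_concentration)
            eq = steady_state_filtrate_concentration(geom, fluid, tracer, op)
        filt = transient_response(a, eq - a, tau_s, t - seg_start)
        seg = protocol.segments[seg_idx]
        rows.append(
            {
                "time_s": float(t),
                "capillary_concentration": seg.capillary_concentration,
                "filtrate_concentration": float(filt),
                "flowrate_ml_s": seg.flowrate_ml_s,
                "segment": seg_idx,
                "equilibrium_concentration": float(eq),
            }
        )
    return pd.DataFrame(rows)


def simulate_experiment(
    protocol: ExperimentProtocol,
    geom: ChipGeometry,
    fluid: FluidProperties,
    tracer: Tracer,
    curve: CalibrationCurve,
    truth_mask: IlluminationMask,
    rois: ROISet,
    noise: NoiseModel,
    tau_s: float = DEFAULT_TAU_S,
) -> SimulatedExperiment:
    """Render a full experiment for one tracer channel.

    Returns the frame sequence (one frame per sampling time), a manifest
    naming each frame ``{cycle:05d}_{channel}.tif``, the exact ground-truth
    time series, and the dark background frame. Two-tracer experiments are
    two calls with the channel-specific configuration, merged by timestamp.
    """
    truth = ground_truth_timeseries(protocol, geom, fluid, tracer, tau_s=tau_s)
    rng = np.random.default_rng(noise.seed)
    channel = tracer.dye_channel
    frames: list[Frame] = []
    manifest_rows = []
    for cycle, row in truth.iterrows():
        frame = render_frame(
            row["capillary_concentration"],
            row["filtrate_concentration"],
            curve,
            truth_mask,
            rois,
            noise,
            led_channel=channel,
            timestamp=row["time_s"],
            rng=rng,
        )
        frames.append(frame)
        manifest_rows.append(
            {
                "filename": f"{cycle:05d}_{channel}.tif",
                "channel": channel,
                "timestamp_s": row["time_s"],
            }
        )
    return SimulatedExperiment(
        frames=frames,
        manifest=pd.DataFrame(manifest_rows),
        ground_truth=truth,
        background=render_background(truth_mask, noise, channel),
    )


# ---------------------------------------------------------------------------
# calibration data synthesis
# ---------------------------------------------------------------------------


def generate_calibration_dataset(
    truth_curve: CalibrationCurve,
    concentrations: Sequence[float],
    replicates: int,
    noise: NoiseModel,
) -> CalibrationDataset:
    """Replicate calibration intensities: eval_4pl(truth) + Gaussian noise."""
    if len(set(concentrations)) < 5:
        raise InvalidInputError("need at least 5 distinct concentrations")
    if replicates < 1:
        raise InvalidInputError("need at least 1 replicate")
    rng = np.random.default_rng(noise.seed)
    conc, inten = [], []
    for x in concentrations:
        f = eval_4pl(truth_curve, float(x))
        for _ in range(replicates):
            conc.append(float(x))
            inten.append(f + (rng.normal(0.0, noise.gaussian_sigma)
                              if noise.gaussian_sigma > 0 else 0.0))
    return CalibrationDataset(concentrations=conc, intensities=inten)


def make_gradient_mask(shape: tuple[int, int] = DEFAULT_SHAPE,
                       strength: float = 0.3) -> IlluminationMask:
    """A smooth synthetic illumination field (brighter centre, dim corners)."""
    if not 0 <= strength < 1:
        raise InvalidInputError("strength must lie in [0, 1)")
    rows = np.linspace(-1.0, 1.0, shape[0])[:, None]
    cols = np.linspace(-1.0, 1.0, shape[1])[None, :]
    profile = 1.0 - strength * 0.5 * (rows**2 + cols**2)
    # unit-mean illumination so flat-field estimation recovers intensities
    # without a global gain bias
    profile /= profile.mean()
    return IlluminationMask(multipliers=1.0 / profile)
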