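"""File formats and run configuration.

Formats are deliberately plain: calibration datasets and time series as CSV
(9 significant digits, UTF-8, LF), calibration curves as JSON, illumination
masks as 32-bit float TIFF, frames as 8-bit grayscale TIFF/PNG accompanied
by a manifest CSV (filename, channel, timestamp_s). Configuration is YAML
validated against a small schema with explicit unit normalization
(e.g. flowrates given as "8 uL/min" become mL/s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationCurve, CalibrationDataset, IlluminationMask
from .errors import ConfigurationError, InvalidInputError, SchemaError
from .quantify import TIMESERIES_COLUMNS, Frame, ROISet, Rect, TimeSeries
from .transport import ChipGeometry, FluidProperties, Tracer
from .units import parse_flowrate_ml_per_s

KNOWN_CHANNELS = ("cyan", "amber")
_FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated configuration for an acquisition/analysis run."""

    geometry: ChipGeometry
    fluid: FluidProperties
    tracers: list[Tracer]
    rois: ROISet
    schedule_period_s: float
    schedule_duration_s: float
    schedule_min_period_s: float
    tau_s: float
    seed: int
    calibration_paths: dict[str, Path] = field(default_factory=dict)
    mask_paths: dict[str, Path] = field(default_factory=dict)
    background_paths: dict[str, Path] = field(default_factory=dict)

    def tracer_for_channel(self, channel: str) -> Tracer:
        for tr in self.tracers:
            if tr.dye_channel == channel:
                return tr
        raise ConfigurationError(f"no tracer configured for channel {channel!r}")

    def load_curves(self) -> dict[str, CalibrationCurve]:
        return {ch: read_curve(p) for ch, p in self.calibration_paths.items()}

    def load_masks(self) -> dict[str, IlluminationMask]:
        return {ch: read_mask(p) for ch, p in self.mask_paths.items()}

    def load_backgrounds(self) -> dict[str, Frame]:
        return {
            ch: Frame(pixels=_read_image(p), led_channel=ch, timestamp=0.0)
            for ch, p in self.background_paths.items()
        }


def default_config_text() -> str:
    """The packaged default chip configuration (synthetic geometry), as YAML."""
    return resources.files("barriersense.data").joinpath("default_chip.yaml").read_text()


def _require(mapping: dict, key: str, section: str, expected: str):
    if key not in mapping:
        raise SchemaError(f"{section}.{key}", expected)
    return mapping[key]


def _positive(value, fieldname: str, expected: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise SchemaError(fieldname, expected) from None
    if not out > 0:
        raise SchemaError(fieldname, expected)
    return out


def _parse_rect(spec, fieldname: str) -> Rect:
    if not (isinstance(spec, (list, tuple)) and len(spec) == 4):
        raise SchemaError(fieldname, "a 4-list [row_start, row_end, col_start, col_end]")
    return Rect(*(int(v) for v in spec))


def _file_map(section: dict | None, section_name: str, base: Path) -> dict[str, Path]:
    out: dict[str, Path] = {}
    for ch, rel in (section or {}).items():
        if ch not in KNOWN_CHANNELS:
            raise SchemaError(f"{section_name}.{ch}", f"a channel in {KNOWN_CHANNELS}")
        p = (base / rel).resolve() if not Path(rel).is_absolute() else Path(rel)
        if not p.exists():
            raise ConfigurationError(f"{section_name}.{ch}: file not found: {p}")
        out[ch] = p
    return out


def parse_config(raw: dict, base_dir: Path | None = None) -> RunConfig:
    """Validate a parsed YAML mapping into a :class:`RunConfig`.

    Missing sections fall back to the packaged defaults; referenced files
    (calibration curves, masks, backgrounds) must exist at load time.
    """
    defaults = yaml.safe_load(default_config_text())
    base = Path(base_dir) if base_dir is not None else Path.cwd()

    g = {**defaults["geometry"], **(raw.get("geometry") or {})}
    geometry = ChipGeometry(
        channel_width_w_cm=_positive(_require(g, "channel_width_cm", "geometry", "cm"),
                                     "geometry.channel_width_cm", "a positive length in cm"),
        channel_height_h_cm=_positive(g.get("channel_height_cm"),
                                      "geometry.channel_height_cm", "a positive length in cm"),
        capillary_height_cm=_positive(g.get("capillary_height_cm"),
                                      "geometry.capillary_height_cm", "a positive length in cm"),
        membrane_thickness_um=_positive(g.get("membrane_thickness_um"),
                                        "geometry.membrane_thickness_um", "a positive length in um"),
        exposed_area_A_cm2=_positive(g.get("exposed_area_cm2"),
                                     "geometry.exposed_area_cm2", "a positive area in cm^2"),
        capillary_volume_Vc_ml=_positive(g.get("capillary_volume_ml"),
                                         "geometry.capillary_volume_ml", "a positive volume in mL"),
        filtrate_volume_Vf_ml=_positive(g.get("filtrate_volume_ml"),
                                        "geometry.filtrate_volume_ml", "a positive volume in mL"),
    )

    f = {**defaults["fluid"], **(raw.get("fluid") or {})}
    fluid = FluidProperties(
        viscosity_mu_poise=_positive(f.get("viscosity_poise"),
                                     "fluid.viscosity_poise", "a positive viscosity in poise"),
        density_rho_g_cm3=_positive(f.get("density_g_per_cm3"),
                                    "fluid.density_g_per_cm3", "a positive density in g/cm^3"),
        temperature_T_K=_positive(f.get("temperature_K"),
                                  "fluid.temperature_K", "a positive temperature in K"),
    )

    tracer_specs = raw.get("tracers") or defaults["tracers"]
    tracers = []
    for i, tspec in enumerate(tracer_specs):
        tracers.append(
            Tracer(
                name=str(_require(tspec, "name", f"tracers[{i}]", "a tracer name")),
                molecular_weight=_positive(tspec.get("molecular_weight"),
                                           f"tracers[{i}].molecular_weight", "g/mol > 0"),
                permeability_kappa_um2=_positive(tspec.get("permeability_um2"),
                                                 f"tracers[{i}].permeability_um2", "um^2 > 0"),
                dye_channel=str(tspec.get("channel", "cyan")),
            )
        )

    r = {**defaults["rois"], **(raw.get("rois") or {})}
    rois = ROISet(
        capillary=_parse_rect(r.get("capillary"), "rois.capillary"),
        filtrate=_parse_rect(r.get("filtrate"), "rois.filtrate"),
    )

    s = {**defaults["schedule"], **(raw.get("schedule") or {})}
    tr = {**defaults["transient"], **(raw.get("transient") or {})}

    return RunConfig(
        geometry=geometry,
        fluid=fluid,
        tracers=tracers,
        rois=rois,
        schedule_period_s=_positive(s.get("period_s"), "schedule.period_s", "seconds > 0"),
        schedule_duration_s=float(s.get("duration_s", 600.0)),
        schedule_min_period_s=_positive(s.get("min_period_s"),
                                        "schedule.min_period_s", "seconds > 0"),
        tau_s=_positive(tr.get("tau_s"), "transient.tau_s", "seconds > 0"),
        seed=int(raw.get("seed", defaults.get("seed", 0))),
        calibration_paths=_file_map(raw.get("calibration"), "calibration", base),
        mask_paths=_file_map(raw.get("masks"), "masks", base),
        background_paths=_file_map(raw.get("backgrounds"), "backgrounds", base),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration from disk."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError("<root>", "a YAML mapping")
    if "geometry" not in raw:
        # chip dimensions must be stated deliberately; only the packaged
        # default config (used when no config is given at all) carries the
        # synthetic stand-in geometry
        raise SchemaError("geometry", "a geometry section with chip dimensions")
    return parse_config(raw, base_dir=path.parent)


# ---------------------------------------------------------------------------
# calibration artifacts
# ---------------------------------------------------------------------------


def write_curve(curve: CalibrationCurve, path: str | Path) -> None:
    Path(path).write_text(json.dumps(curve.to_dict(), indent=2) + "\n")


def read_curve(path: str | Path) -> CalibrationCurve:
    return CalibrationCurve.from_dict(json.loads(Path(path).read_text()))


def write_mask(mask: IlluminationMask, path: str | Path) -> None:
    tifffile.imwrite(str(path), mask.multipliers.astype(np.float32))


def read_mask(path: str | Path) -> IlluminationMask:
    return IlluminationMask(multipliers=tifffile.imread(str(path)).astype(float))


def read_calibration_csv(path: str | Path) -> CalibrationDataset:
    """CSV with columns concentration_mg_per_ml, replicate, intensity_au."""
    df = pd.read_csv(path)
    required = {"concentration_mg_per_ml", "intensity_au"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"calibration CSV missing columns: {sorted(missing)}")
    return CalibrationDataset(
        concentrations=df["concentration_mg_per_ml"].tolist(),
        intensities=df["intensity_au"].tolist(),
    )


def write_calibration_csv(dataset: CalibrationDataset, path: str | Path) -> None:
    reps: dict[float, int] = {}
    rows = []
    for x, f in zip(dataset.concentrations, dataset.intensities):
        reps[x] = reps.get(x, 0) + 1
        rows.append({"concentration_mg_per_ml": x, "replicate": reps[x], "intensity_au": f})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT,
                              lineterminator="\n")


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(str(path)), dtype=float)
    return np.asarray(iio.imread(path), dtype=float)


def write_frames(frames, out_dir: str | Path, manifest_name: str = "manifest.csv") -> Path:
    """Write frames as 8-bit TIFFs plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for cycle, frame in enumerate(frames):
        name = f"{cycle:05d}_{frame.led_channel}.tif"
        tifffile.imwrite(str(out / name),
                         np.clip(np.rint(frame.pixels), 0, 255).astype(np.uint8))
        rows.append({"filename": name, "channel": frame.led_channel,
                     "timestamp_s": frame.timestamp})
    manifest = out / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format=_FLOAT_FMT,
                              lineterminator="\n")
    return manifest


def read_frames(manifest_path: str | Path) -> Iterator[Frame]:
    """Stream frames listed in a manifest CSV (filename, channel, timestamp_s).

    Image paths are resolved relative to the manifest's directory. Malformed
    rows and unknown channel tags raise with the offending row number.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"filename", "channel", "timestamp_s"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"manifest missing columns: {sorted(missing)}")
    base = manifest_path.parent
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, counting the header line
        channel = str(row["channel"])
        if channel not in KNOWN_CHANNELS:
            raise InvalidInputError(
                f"manifest row {rowno}: unknown channel tag {channel!r}"
            )
        try:
            timestamp = float(row["timestamp_s"])
            pixels = _read_image(base / str(row["filename"]))
        except (ValueError, OSError, FileNotFoundError) as e:
            raise InvalidInputError(f"manifest row {rowno}: {e}") from e
        yield Frame(pixels=pixels, led_channel=channel, timestamp=timestamp)


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------


def write_timeseries(series: TimeSeries, path: str | Path) -> None:
    """Fixed-column CSV, 9 significant digits, UTF-8, LF line endings."""
    series.data.to_csv(path, index=False, float_format=_FLOAT_FMT,
                       lineterminator="\n", encoding="utf-8")


def read_timeseries(path: str | Path) -> TimeSeries:
    df = pd.read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"time series CSV missing columns: {missing}")
    df["flags"] = df["flags"].fillna("")
    return TimeSeries(df)
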