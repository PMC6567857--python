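"""Recording, stimulus-train, configuration and result-table I/O.

All on-disk formats are deliberately plain: a recording is a flat
little-endian binary array (sample-major: all channels of sample *i*
contiguous) with a plain-text ``key = value`` sidecar declaring sampling
rate, channel geometry and amplitude scale; stimulus trains are one onset
time (ms) per line; analysis configuration is the same key/value document;
result tables are tab-separated text with a header row.  Everything
round-trips bit-stably, which is what makes simulator fixtures diffable.

Units follow the analysis layer throughout: potentials in μV, times in ms,
depths in μm (below the pial surface, increasing downward), rates in Hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, SchemaError, ValidationError

__all__ = [
    "ProbeGeometry",
    "WidebandRecording",
    "StimulusTrain",
    "AnalysisConfig",
    "read_recording",
    "write_recording",
    "read_stimulus_train",
    "write_stimulus_train",
    "read_config",
    "write_config",
    "read_table",
    "write_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeGeometry:
    """Linear multi-site probe geometry.

    Channel index 0 is the most superficial site; depths are μm below the
    pial surface and must be strictly increasing.
    """

    n_channels: int
    spacing_um: float
    tip_depth_um: float
    channel_depths_um: tuple[float, ...]

    def __post_init__(self):
        if self.n_channels < 3:
            raise ValidationError("a laminar probe needs at least 3 channels")
        if self.spacing_um <= 0:
            raise ValidationError("spacing_um must be positive")
        depths = np.asarray(self.channel_depths_um, dtype=float)
        if depths.size != self.n_channels:
            raise ValidationError("one depth per channel required")
        if not np.all(np.diff(depths) > 0):
            raise ValidationError("channel depths must be strictly increasing")
        object.__setattr__(self, "channel_depths_um", tuple(float(d) for d in depths))

    @classmethod
    def uniform(cls, n_channels: int, spacing_um: float, top_depth_um: float) -> "ProbeGeometry":
        depths = tuple(top_depth_um + i * spacing_um for i in range(n_channels))
        return cls(n_channels, spacing_um, depths[-1], depths)

    @property
    def depths(self) -> np.ndarray:
        return np.asarray(self.channel_depths_um, dtype=float)

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.depths)
        return bool(np.allclose(d, d[0], rtol=rtol))


def default_geometry() -> ProbeGeometry:
    """16-site probe, 100 μm pitch, most superficial site at 60 μm."""
    return ProbeGeometry.uniform(16, 100.0, 60.0)


@dataclass
class WidebandRecording:
    """Continuous multichannel extracellular recording in μV.

    ``data`` is samples × channels; ``t0_ms`` is the absolute time of the
    first sample so spike/stimulus times can be kept on one clock.
    """

    data: np.ndarray
    fs_hz: float
    geometry: ProbeGeometry
    t0_ms: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError("data must be samples × channels")
        if self.data.shape[1] != self.geometry.n_channels:
            raise ValidationError(
                f"data has {self.data.shape[1]} columns but geometry declares "
                f"{self.geometry.n_channels} channels"
            )
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs_hz * 1000.0

    def time_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) / self.fs_hz * 1000.0


@dataclass(frozen=True)
class StimulusTrain:
    """Ordered stimulus onset times (ms) with pulse metadata."""

    onsets_ms: tuple[float, ...]
    pulse_duration_ms: float = 200.0
    isi_range_ms: tuple[float, float] = (5000.0, 10000.0)

    def __post_init__(self):
        onsets = np.asarray(self.onsets_ms, dtype=float)
        if onsets.size and not np.all(np.diff(onsets) > 0):
            raise ValidationError("stimulus onsets must be strictly increasing")
        if onsets.size > 1 and np.any(np.diff(onsets) < self.pulse_duration_ms):
            raise ValidationError("inter-stimulus interval shorter than the pulse")
        object.__setattr__(self, "onsets_ms", tuple(float(t) for t in onsets))

    @property
    def onsets(self) -> np.ndarray:
        return np.asarray(self.onsets_ms, dtype=float)

    def __len__(self) -> int:
        return len(self.onsets_ms)


@dataclass
class AnalysisConfig:
    """Every tunable of the analysis chain, with defaults.

    Filter bands in Hz, windows in ms relative to stimulus onset
    (half-open ``[lo, hi)``), depths in μm.  The serialized form is a flat
    ``key = value`` document; round-trips are lossless.
    """

    # signal conditioning
    lfp_rate_hz: float = 1000.0
    spike_band_hz: tuple[float, float] = (300.0, 5000.0)
    align_window_ms: tuple[float, float] = (-1100.0, 400.0)
    # spike detection
    threshold_k: float = 5.0
    dead_time_ms: float = 1.0
    quietest_span_ms: float = 1000.0
    quietest_step_ms: float = 100.0
    # MUA density and metrics
    density_bin_ms: float = 1.0
    density_step_ms: float = 0.2
    mua_baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    mua_search_window_ms: tuple[float, float] = (3.0, 50.0)
    mua_criterion_k: float = 3.0
    osc_window_span_ms: float = 15.0
    osc_prominence_frac: float = 0.25
    # SEP
    sep_baseline_window_ms: tuple[float, float] = (-100.0, 0.0)
    sep_search_window_ms: tuple[float, float] = (3.0, 50.0)
    sep_criterion_k: float = 4.0
    sep_amplitude_at_ms: tuple[float, ...] = (50.0,)
    # CSD / layers
    csd_baseline_window_ms: tuple[float, float] = (-1000.0, 0.0)
    expected_l4_depth_um: float = 600.0
    # epochs
    epoch_edges_ms: tuple[float, ...] = (5.0, 8.0, 10.0, 20.0, 50.0, 100.0)
    spont_window_ms: tuple[float, float] = (-1000.0, 0.0)
    # decomposition
    contrib_latencies_ms: tuple[float, ...] = (10.5, 12.6, 14.3, 17.5, 46.0)
    second_peak_after_ms: float = 30.0
    second_peak_prominence_frac: float = 0.10
    decay_fit_floor_frac: float = 0.05
    # misc
    firing_probability: float = 0.2
    seed: int = 0


# ---------------------------------------------------------------------------
# key = value documents
# ---------------------------------------------------------------------------


def _format_value(v) -> str:
    if isinstance(v, (tuple, list)):
        return ",".join(_format_value(x) for x in v)
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _write_kv(path: Path, items: dict) -> None:
    lines = [f"{k} = {_format_value(v)}" for k, v in items.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _read_kv(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def _coerce_like(template, raw: str):
    """Parse ``raw`` into the type of ``template`` (scalars and flat tuples)."""
    if isinstance(template, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(template, int):
        return int(raw)
    if isinstance(template, float):
        return float(raw)
    if isinstance(template, tuple):
        if raw == "":
            return ()
        elem = template[0] if template else 0.0
        return tuple(_coerce_like(elem, part) for part in raw.split(","))
    return raw


def write_config(cfg: AnalysisConfig, path) -> None:
    _write_kv(Path(path), dataclasses.asdict(cfg))


def read_config(path) -> AnalysisConfig:
    raw = _read_kv(Path(path))
    defaults = AnalysisConfig()
    kwargs = {}
    for f in dataclasses.fields(AnalysisConfig):
        if f.name in raw:
            kwargs[f.name] = _coerce_like(getattr(defaults, f.name), raw[f.name])
    return AnalysisConfig(**kwargs)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

_DTYPES = {"float32": np.dtype("<f4"), "int16": np.dtype("<i2")}


def write_recording(rec: WidebandRecording, path_data, path_meta, dtype: str = "float32",
                    scale_uv_per_count: float = 1.0) -> None:
    """Write a recording as flat little-endian binary plus a sidecar.

    ``float32`` stores μV directly (scale 1); ``int16`` stores
    ``round(μV / scale)``.  Reading back reproduces the data bit-exactly for
    the declared sample width.
    """
    if dtype not in _DTYPES:
        raise ParameterError(f"unsupported dtype {dtype!r}")
    data = np.asarray(rec.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValidationError("recording contains non-finite samples")
    if dtype == "float32":
        stored = (data / scale_uv_per_count).astype("<f4")
    else:
        counts = np.round(data / scale_uv_per_count)
        if np.any(np.abs(counts) > np.iinfo(np.int16).max):
            raise ValidationError("data exceeds int16 range at this scale")
        stored = counts.astype("<i2")
    Path(path_data).write_bytes(np.ascontiguousarray(stored).tobytes())
    g = rec.geometry
    _write_kv(Path(path_meta), {
        "fs_hz": rec.fs_hz,
        "n_channels": g.n_channels,
        "dtype": dtype,
        "scale_uv_per_count": scale_uv_per_count,
        "t0_ms": rec.t0_ms,
        "spacing_um": g.spacing_um,
        "tip_depth_um": g.tip_depth_um,
        "channel_depths_um": g.channel_depths_um,
    })


def read_recording(path_data, path_meta) -> WidebandRecording:
    meta = _read_kv(Path(path_meta))
    required = ("fs_hz", "n_channels", "dtype", "scale_uv_per_count",
                "channel_depths_um", "spacing_um")
    for key in required:
        if key not in meta:
            raise SchemaError(f"{path_meta}: missing required key {key!r}")
    n_channels = int(meta["n_channels"])
    dtype_name = meta["dtype"]
    if dtype_name not in _DTYPES:
        raise FormatError(f"{path_meta}: unknown dtype {dtype_name!r}")
    dtype = _DTYPES[dtype_name]
    scale = float(meta["scale_uv_per_count"])
    depths = tuple(float(x) for x in meta["channel_depths_um"].split(","))
    geometry = ProbeGeometry(
        n_channels=n_channels,
        spacing_um=float(meta["spacing_um"]),
        tip_depth_um=float(meta.get("tip_depth_um", depths[-1])),
        channel_depths_um=depths,
    )
    raw = Path(path_data).read_bytes()
    frame_bytes = n_channels * dtype.itemsize
    if len(raw) % frame_bytes:
        raise FormatError(
            f"{path_data}: {len(raw)} bytes is not a multiple of the "
            f"{frame_bytes}-byte frame ({n_channels} ch × {dtype.itemsize} B)"
        )
    stored = np.frombuffer(raw, dtype=dtype).reshape(-1, n_channels)
    if dtype_name == "float32":
        data = stored.astype(np.float32) * np.float32(scale)
    else:
        data = stored.astype(np.float32) * np.float32(scale)
    return WidebandRecording(data=data, fs_hz=float(meta["fs_hz"]), geometry=geometry,
                             t0_ms=float(meta.get("t0_ms", 0.0)))


# ---------------------------------------------------------------------------
# stimulus trains
# ---------------------------------------------------------------------------


def write_stimulus_train(stim: StimulusTrain, path) -> None:
    lines = [
        f"# pulse_duration_ms = {_format_value(stim.pulse_duration_ms)}",
        f"# isi_range_ms = {_format_value(stim.isi_range_ms)}",
    ]
    lines += [repr(float(t)) for t in stim.onsets_ms]
    Path(path).write_text("\n".join(lines) + "\n")


def read_stimulus_train(path) -> StimulusTrain:
    pulse = 200.0
    isi = (5000.0, 10000.0)
    onsets: list[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key = key.strip()
                if key == "pulse_duration_ms":
                    pulse = float(value)
                elif key == "isi_range_ms":
                    isi = tuple(float(x) for x in value.split(","))  # type: ignore[assignment]
            continue
        try:
            onsets.append(float(line))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: cannot parse onset {line!r}") from None
    onsets.sort()
    if len(set(onsets)) != len(onsets):
        raise ValidationError(f"{path}: duplicate stimulus onset times")
    return StimulusTrain(tuple(onsets), pulse_duration_ms=pulse, isi_range_ms=isi)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
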