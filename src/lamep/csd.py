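"""Current-source-density mapping and cortical layer assignment.

CSD is the negated second spatial difference of the baseline-subtracted
laminar LFP, ``CSD_i = -(V_{i-1} - 2 V_i + V_{i+1}) / h²`` (h in mm), so
current sinks — loci of inward transmembrane current — appear negative.
The top and bottom probe sites are excluded (no boundary padding); no
conductivity scaling is applied, so units are μV/mm² up to a constant.

Layers are assigned from sink timing: the granular layer (L4) is the
adjacent interior channel pair with the earliest sink onsets nearest the
expected depth (600 μm by default, ties broken toward it), and the
supragranular group (L2/3) is every channel more than 100 μm below the
pial surface and more than 100 μm above the shallowest L4 site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._detect import backtrack_onset, first_trough, front_baseline_onset
from .conditioning import EvokedAverage
from .errors import GeometryError, LayerAssignmentError

__all__ = ["CSDMap", "LayerAssignment", "compute_csd", "sink_onset",
           "assign_layers", "interpolate_csd"]


@dataclass
class CSDMap:
    """Interior-channel × time CSD in the sink-negative convention."""

    data: np.ndarray
    depths_um: np.ndarray
    time_ms: np.ndarray
    baseline_window_ms: tuple[float, float]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class LayerAssignment:
    l4_channels: list[int]
    l23_channels: list[int]
    l23_mid_channel: int
    depths_um: dict[int, float]


def compute_csd(avg: EvokedAverage,
                baseline_window_ms: tuple[float, float] = (-1000.0, 0.0),
                sink_negative: bool = True) -> CSDMap:
    """Second-spatial-difference CSD of the trial-averaged LFP.

    The per-channel mean over ``baseline_window_ms`` is subtracted first.
    """
    geom = avg.geometry
    if geom.n_channels < 3:
        raise GeometryError("CSD needs at least 3 channels")
    if not geom.is_uniform():
        raise GeometryError("CSD requires uniform channel spacing")
    t = avg.time_ms
    bmask = (t >= baseline_window_ms[0]) & (t < baseline_window_ms[1])
    if not bmask.any():
        raise GeometryError("baseline window not covered by the averaged trace")
    v = np.asarray(avg.data, dtype=float)
    v = v - v[:, bmask].mean(axis=1, keepdims=True)
    h_mm = geom.spacing_um / 1000.0
    second_diff = (v[:-2] - 2.0 * v[1:-1] + v[2:]) / h_mm**2
    csd = -second_diff if sink_negative else second_diff
    return CSDMap(csd, geom.depths[1:-1].copy(), t.copy(), baseline_window_ms)


def interpolate_csd(csd: CSDMap, factor: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Linear depth up-interpolation for display; original nodes are honored."""
    depths = csd.depths_um
    fine = np.linspace(depths[0], depths[-1], (len(depths) - 1) * factor + 1)
    out = np.empty((fine.size, csd.data.shape[1]))
    for j in range(csd.data.shape[1]):
        out[:, j] = np.interp(fine, depths, csd.data[:, j])
    return fine, out


def sink_onset(csd_row: np.ndarray, time_ms: np.ndarray,
               baseline_window_ms: tuple[float, float] = (-1000.0, 0.0),
               search_window_ms: tuple[float, float] = (3.0, 50.0),
               criterion_k: float = 4.0) -> float | None:
    """Onset of the earliest sink: baseline back-crossing of the first
    qualifying negative CSD deflection, or ``None`` when absent."""
    x = np.asarray(csd_row, dtype=float)
    hit = first_trough(x, time_ms, baseline_window_ms, search_window_ms, criterion_k)
    if hit is None:
        return None
    trough, mu, _sd = hit
    onset = front_baseline_onset(x, time_ms, trough, mu)
    if onset is None:
        onset = backtrack_onset(x, time_ms, trough, mu)
    return onset


def assign_layers(csd: CSDMap, mua_onsets_ms: dict[int, float] | None = None,
                  expected_l4_depth_um: float = 600.0,
                  search_window_ms: tuple[float, float] = (3.0, 50.0),
                  criterion_k: float = 4.0,
                  onset_tie_ms: float = 0.5,
                  sink_fraction: float = 0.2) -> LayerAssignment:
    """Identify L4 and L2/3 channels from sink onsets.

    Only channels carrying a substantial sink — at least ``sink_fraction``
    of the map's largest sink magnitude — are candidates, so small noise
    troughs that pass the SD criterion cannot masquerade as the earliest
    sink.  ``mua_onsets_ms`` maps full-probe channel index to MUA onset
    latency (used as a late tie-break between equally early, equally near
    pairs).  Channel indices in the result refer to the full probe.
    """
    smask = (csd.time_ms >= search_window_ms[0]) & (csd.time_ms < search_window_ms[1])
    mags = np.maximum(-csd.data[:, smask].min(axis=1), 0.0)
    mag_floor = sink_fraction * mags.max() if mags.max() > 0 else 0.0
    onsets = np.full(csd.n_channels, np.nan)
    for i in range(csd.n_channels):
        if mags[i] < mag_floor:
            continue
        o = sink_onset(csd.data[i], csd.time_ms, csd.baseline_window_ms,
                       search_window_ms, criterion_k)
        if o is not None:
            onsets[i] = o
    candidates = []
    for i in range(csd.n_channels - 1):
        if np.isnan(onsets[i]) or np.isnan(onsets[i + 1]):
            continue
        pair_depth = 0.5 * (csd.depths_um[i] + csd.depths_um[i + 1])
        mean_onset = 0.5 * (onsets[i] + onsets[i + 1])
        full = (i + 1, i + 2)  # interior row i is probe channel i+1
        mua_key = 0.0
        if mua_onsets_ms:
            vals = [mua_onsets_ms[c] for c in full if c in mua_onsets_ms]
            mua_key = float(np.mean(vals)) if vals else np.inf
        candidates.append((round(mean_onset / onset_tie_ms),
                           abs(pair_depth - expected_l4_depth_um), mua_key, full))
    if not candidates:
        raise LayerAssignmentError(
            "no adjacent channel pair with detectable sinks",
            diagnostics={"sink_onsets_ms": onsets.tolist()})
    candidates.sort()
    l4 = list(candidates[0][3])
    all_depths = np.concatenate(([csd.depths_um[0] - (csd.depths_um[1] - csd.depths_um[0])],
                                 csd.depths_um,
                                 [csd.depths_um[-1] + (csd.depths_um[1] - csd.depths_um[0])]))
    l4_top = all_depths[l4[0]]
    l23 = [c for c in range(len(all_depths))
           if 100.0 < all_depths[c] < l4_top - 100.0]
    if len(l23) < 2:
        raise LayerAssignmentError(
            f"fewer than 2 supragranular channels above L4 at {l4_top:.0f} μm",
            diagnostics={"sink_onsets_ms": onsets.tolist(), "l4": l4})
    if len(l23) > 3:
        l23 = l23[-3:]  # keep the three sites adjacent to L4
    mid = l23[len(l23) // 2]
    return LayerAssignment(
        l4_channels=l4,
        l23_channels=l23,
        l23_mid_channel=mid,
        depths_um={c: float(all_depths[c]) for c in l4 + l23},
    )
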