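"""Analysis chain for 16-channel insole recordings.

Raw capacitance -> pressure calibration, center-of-pressure trajectories,
the 227-cell display grid with its ten-level 0-450 kPa color scale,
rule-based gait-phase segmentation and per-zone peak summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import median_filter

from .errors import CalibrationError, ConfigurationError, FormatError
from .gait_simulator import (
    PHASE_ORDER,
    SENSOR_IDS,
    SWING,
    ZONES,
    InsoleLayout,
    PressureFrameSeries,
    default_layout,
)
from .sensor_model import SensorSpec

__all__ = [
    "GRID_PITCH_MM",
    "GRID_ORIGIN_MM",
    "N_GRID_CELLS",
    "COLOR_SCALE_MAX_KPA",
    "N_COLOR_LEVELS",
    "CoPTrajectory",
    "GridCell",
    "HeatmapGrid",
    "PhaseSegmentation",
    "calibrate",
    "center_of_pressure",
    "cop_trajectory",
    "grid_heatmap",
    "segment_phases",
    "zone_summaries",
]

# Frozen display-grid tessellation: a square raster over the insole bounding
# box, keeping the cells whose center falls inside the elliptical outline.
# The pitch/origin pair is chosen once so that exactly 227 cells survive for
# the shipped 250 mm x 85 mm outline, then frozen.
GRID_PITCH_MM = 8.5
GRID_ORIGIN_MM = (1.0, 3.0)
N_GRID_CELLS = 227

COLOR_SCALE_MAX_KPA = 450.0
N_COLOR_LEVELS = 10

#: Default zone-activation threshold for phase segmentation, kPa (~ LoD).
PHASE_THRESHOLD_KPA = 45.0


@dataclass
class CoPTrajectory:
    """Center-of-pressure positions per frame; invalid frames carry NaN."""

    times: np.ndarray
    positions: np.ndarray  # (n, 2) mm
    validity: np.ndarray  # bool per frame


@dataclass(frozen=True)
class GridCell:
    cell_id: int
    sensor_id: str
    x_mm: float
    y_mm: float
    pressure_kpa: float
    level: int


@dataclass
class HeatmapGrid:
    """The 227-cell pressure display for one frame."""

    cells: list

    def __post_init__(self) -> None:
        if len(self.cells) != N_GRID_CELLS:
            raise ConfigurationError(
                f"heatmap must have exactly {N_GRID_CELLS} cells, got {len(self.cells)}"
            )

    def levels(self) -> np.ndarray:
        return np.array([c.level for c in self.cells])

    def pressures(self) -> np.ndarray:
        return np.array([c.pressure_kpa for c in self.cells])


@dataclass
class PhaseSegmentation:
    """Per-frame phase labels plus detected cycle starts (frame indices)."""

    labels: list
    cycle_starts: list
    sample_rate: float

    def phase_onsets(self) -> list:
        """(frame_index, label) at every label change."""
        out = []
        prev = None
        for i, lab in enumerate(self.labels):
            if lab != prev:
                out.append((i, lab))
                prev = lab
        return out


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------


def _spec_for(sensor_id: str, index: int, specs) -> SensorSpec:
    if isinstance(specs, SensorSpec):
        return specs
    if isinstance(specs, dict):
        if sensor_id not in specs:
            raise CalibrationError(f"no calibration record for sensor {sensor_id}")
        return specs[sensor_id]
    return specs[index]


def calibrate(traces: dict, specs, order=SENSOR_IDS) -> PressureFrameSeries:
    """Convert raw capacitance traces to a pressure frame series.

    Inverts the linear transduction per sensor: ``P = ((C/C0) - 1)/S``
    (MPa, reported in kPa).  Negative estimates are floored at zero and
    values below the sensor's LoD are flagged in ``below_lod`` rather than
    clipped.

    ``traces`` maps sensor id to :class:`CapacitanceTrace`; ``specs`` is a
    single :class:`SensorSpec`, a sequence in channel order, or a dict keyed
    by sensor id.
    """
    missing = [sid for sid in order if sid not in traces]
    if missing:
        raise CalibrationError(f"missing traces for sensors {missing}")
    if not isinstance(specs, (SensorSpec, dict)) and len(specs) != len(order):
        raise ConfigurationError(f"need {len(order)} sensor specs, got {len(specs)}")
    rates = {traces[sid].sample_rate for sid in order}
    lengths = {len(traces[sid]) for sid in order}
    if len(rates) != 1 or len(lengths) != 1:
        raise FormatError("all channel traces must share sample rate and length")
    fs = rates.pop()
    n = lengths.pop()
    frames = np.zeros((n, len(order)))
    below_lod = np.zeros((n, len(order)), dtype=bool)
    for j, sid in enumerate(order):
        spec = _spec_for(sid, j, specs)
        if spec.C0 is None or spec.C0 <= 0:
            raise CalibrationError(f"sensor {sid} has no valid C0")
        tr = traces[sid]
        rel = tr.values if tr.units == "relative" else tr.values / spec.C0 - 1.0
        p_kpa = np.maximum(rel / spec.S * 1e3, 0.0)
        frames[:, j] = p_kpa
        below_lod[:, j] = p_kpa < spec.p_min
    start = next(iter(traces.values())).start_time
    return PressureFrameSeries(fs, frames, tuple(order), start_time=start, below_lod=below_lod)


# --------------------------------------------------------------------------
# center of pressure
# --------------------------------------------------------------------------

#: Frames with less total pressure than this are flagged invalid, kPa.
COP_MIN_TOTAL_KPA = 1.0


def center_of_pressure(frame, layout: InsoleLayout, order=SENSOR_IDS):
    """Pressure-weighted centroid of one frame, or None when unloaded.

    All sensors share the same face area, so pressure weighting and force
    weighting coincide.
    """
    p = np.asarray(frame, dtype=float)
    total = p.sum()
    if total < COP_MIN_TOTAL_KPA:
        return None
    xy = layout.coordinates(order)
    cop = (p[:, None] * xy).sum(axis=0) / total
    return float(cop[0]), float(cop[1])


def cop_trajectory(frames: PressureFrameSeries, layout: InsoleLayout | None = None) -> CoPTrajectory:
    layout = layout or default_layout()
    xy = layout.coordinates(frames.sensor_ids)
    totals = frames.frames.sum(axis=1)
    valid = totals >= COP_MIN_TOTAL_KPA
    positions = np.full((len(frames), 2), np.nan)
    if valid.any():
        positions[valid] = (
            frames.frames[valid] @ xy / totals[valid, None]
        )
    return CoPTrajectory(frames.times, positions, valid)


# --------------------------------------------------------------------------
# heatmap grid
# --------------------------------------------------------------------------


def _inside_outline(x: float, y: float, length: float, width: float) -> bool:
    cx, cy = width / 2.0, length / 2.0
    return ((x - cx) / cx) ** 2 + ((y - cy) / cy) ** 2 <= 1.0


@lru_cache(maxsize=8)
def _tessellation(layout: InsoleLayout):
    """Frozen raster cells inside the outline, each mapped to its nearest
    sensor.  Returns (centers (m,2), sensor index per cell)."""
    ox, oy = GRID_ORIGIN_MM
    xs = np.arange(ox, layout.insole_width, GRID_PITCH_MM)
    ys = np.arange(oy, layout.insole_length, GRID_PITCH_MM)
    centers = [
        (x, y)
        for y in ys
        for x in xs
        if _inside_outline(x, y, layout.insole_length, layout.insole_width)
    ]
    centers = np.array(centers)
    xy = layout.coordinates(SENSOR_IDS)
    d2 = ((centers[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    return centers, d2.argmin(axis=1)


def color_level(pressure_kpa: float) -> int:
    """Ten-level color bin over 0-450 kPa (level 9 saturates)."""
    clipped = min(max(pressure_kpa, 0.0), COLOR_SCALE_MAX_KPA)
    return min(int(math.floor(N_COLOR_LEVELS * clipped / COLOR_SCALE_MAX_KPA)), N_COLOR_LEVELS - 1)


def grid_heatmap(frame, layout: InsoleLayout | None = None, order=SENSOR_IDS) -> HeatmapGrid:
    """Map one 16-vector frame onto the 227-cell display grid.

    Every cell inherits the pressure of its nearest sensor and the ten-level
    color bin on the 0-450 kPa scale.
    """
    layout = layout or default_layout()
    p = np.asarray(frame, dtype=float)
    centers, owner = _tessellation(layout)
    ids = list(order)
    cells = [
        GridCell(
            cell_id=i,
            sensor_id=ids[owner[i]],
            x_mm=float(centers[i, 0]),
            y_mm=float(centers[i, 1]),
            pressure_kpa=float(p[owner[i]]),
            level=color_level(float(p[owner[i]])),
        )
        for i in range(len(centers))
    ]
    return HeatmapGrid(cells)


# --------------------------------------------------------------------------
# phase segmentation
# --------------------------------------------------------------------------

_PHASE_CODES = {phase: i for i, phase in enumerate(PHASE_ORDER)}
_PHASE_CODES[SWING] = len(PHASE_ORDER)
_CODE_PHASES = {v: k for k, v in _PHASE_CODES.items()}


def _classify(zone_active: dict) -> str:
    heel = zone_active["calcaneus"]
    met = zone_active["metatarsals"]
    arch = zone_active["plantar_arch"]
    toe = zone_active["phalanges"]
    if heel and not met:
        return "heel_strike"
    if heel:
        return "foot_flat"
    if met and toe:
        return "heel_off"
    if met or arch:
        return "midstance"
    if toe:
        return "toe_off"
    return SWING


def segment_phases(
    frames: PressureFrameSeries,
    layout: InsoleLayout | None = None,
    threshold: float = PHASE_THRESHOLD_KPA,
    median_window: int = 5,
) -> PhaseSegmentation:
    """Rule-based per-frame gait-phase labelling.

    A zone counts as active when its mean pressure exceeds ``threshold``
    (default ~= the sensor LoD).  Heel-only activation marks heel strike,
    heel plus metatarsals foot flat, midfoot/forefoot without heel midstance,
    metatarsals plus toes heel off, toes alone toe off and full unloading
    swing.  A short median filter removes label chatter and cycle starts are
    the swing -> heel-strike transitions.
    """
    del layout  # zone membership is fixed by sensor ids, not coordinates
    zone_idx = {
        zone: [frames.sensor_ids.index(sid) for sid in ids] for zone, ids in ZONES.items()
    }
    zone_means = {zone: frames.frames[:, idx].mean(axis=1) for zone, idx in zone_idx.items()}
    n = len(frames)
    codes = np.empty(n, dtype=int)
    for i in range(n):
        active = {zone: zone_means[zone][i] > threshold for zone in ZONES}
        codes[i] = _PHASE_CODES[_classify(active)]
    if np.all(codes == _PHASE_CODES[SWING]):
        warnings.warn("no zone activation anywhere; returning an all-swing segmentation")
    elif median_window > 1:
        codes = median_filter(codes, size=median_window, mode="nearest")
    labels = [_CODE_PHASES[c] for c in codes]
    hs = _PHASE_CODES["heel_strike"]
    sw = _PHASE_CODES[SWING]
    cycle_starts = [0] if n and codes[0] == hs else []
    cycle_starts += [
        i for i in range(1, n) if codes[i] == hs and codes[i - 1] == sw
    ]
    return PhaseSegmentation(labels, cycle_starts, frames.sample_rate)


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

#: Arch-zone peaks at or above this value raise the check flag, kPa.
ARCH_PEAK_LIMIT_KPA = 150.0


def zone_summaries(
    frames: PressureFrameSeries, segmentation: PhaseSegmentation | None = None
) -> dict:
    """Per-sensor and per-zone peak pressures with the phase of occurrence.

    The phase tags come from ``segmentation`` when given, else from the
    frame series' own ground-truth labels if present.
    """
    labels = segmentation.labels if segmentation is not None else frames.labels
    times = frames.times
    sensors = {}
    for j, sid in enumerate(frames.sensor_ids):
        col = frames.frames[:, j]
        k = int(np.argmax(col)) if len(col) else 0
        sensors[sid] = {
            "peak_kpa": float(col[k]) if len(col) else 0.0,
            "time_s": float(times[k]) if len(col) else None,
            "phase": labels[k] if labels is not None and len(col) else None,
        }
    zones = {}
    for zone, ids in ZONES.items():
        best = max(ids, key=lambda sid: sensors[sid]["peak_kpa"])
        zones[zone] = {
            "peak_kpa": sensors[best]["peak_kpa"],
            "sensor": best,
            "phase": sensors[best]["phase"],
        }
    return {
        "sensors": sensors,
        "zones": zones,
        "arch_below_limit": zones["plantar_arch"]["peak_kpa"] < ARCH_PEAK_LIMIT_KPA,
    }
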