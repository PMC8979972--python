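"""Planimetric LV quantification: volumes, mass, EF, heart rate, flow SV.

Volumes use summation of discs over the short-axis stack: each slice
contributes its cavity area times the slice spacing (thickness + gap).
LV mass is the myocardial volume (epicardial minus endocardial) times the
specific density of myocardium, 1.05 g/cm^3.  SV = EDV - ESV and
EF = SV / EDV.  Phase-contrast stroke volume is the net flow integrated
from the first to the last diastole divided by the number of beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MaskSet
from .sort import SortedStack

__all__ = [
    "VolumetricResult",
    "FlowCurve",
    "area_from_mask",
    "volume_summation_of_discs",
    "lv_mass",
    "sv_ef",
    "lv_mass_index",
    "heart_rate_from_ed_frames",
    "flow_stroke_volume",
    "quantify_sorted_stack",
    "MYOCARDIUM_DENSITY_G_PER_CM3",
]

MYOCARDIUM_DENSITY_G_PER_CM3 = 1.05


@dataclass
class VolumetricResult:
    """LV volumetry for one respiratory state.

    EDV/ESV/SV in ml, EF as a fraction in [0, 1], LVM in g, optional LVMI in
    g/m^2 and heart rate in beats/min; ``slice_table`` holds the per-slice
    areas (cm^2).
    """

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef: float
    lvm_g: float
    state: str = ""
    lvmi_g_m2: float | None = None
    heart_rate_bpm: float | None = None
    slice_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.esv_ml <= self.edv_ml:
            raise ValueError("negative stroke volume: require 0 <= ESV <= EDV")
        if abs(self.sv_ml - (self.edv_ml - self.esv_ml)) > 1e-9:
            raise ValueError("SV must equal EDV - ESV")
        if self.lvm_g < 0:
            raise ValueError("LVM must be non-negative")

    def to_dict(self) -> dict:
        d = {"state": self.state, "EDV_ml": self.edv_ml, "ESV_ml": self.esv_ml,
             "SV_ml": self.sv_ml, "EF": self.ef, "LVM_g": self.lvm_g}
        if self.lvmi_g_m2 is not None:
            d["LVMI_g_m2"] = self.lvmi_g_m2
        if self.heart_rate_bpm is not None:
            d["heart_rate_bpm"] = self.heart_rate_bpm
        return d


@dataclass
class FlowCurve:
    """Flow-rate time series with diastole markers.

    ``time_ms`` strictly increasing sample times, ``flow_ml_s`` flow rate
    per sample, ``diastole_markers`` strictly increasing sample indices of
    successive diastoles (>= 2).
    """

    time_ms: np.ndarray
    flow_ml_s: np.ndarray
    diastole_markers: np.ndarray

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.flow_ml_s = np.asarray(self.flow_ml_s, dtype=float)
        self.diastole_markers = np.asarray(self.diastole_markers, dtype=int)
        if len(self.time_ms) != len(self.flow_ml_s):
            raise ValueError("time and flow must have equal length")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time must be strictly increasing")
        if len(self.diastole_markers) < 2:
            raise ValueError("insufficient beats: need >= 2 diastole markers")
        if np.any(np.diff(self.diastole_markers) <= 0):
            raise ValueError("diastole markers must be strictly increasing")


def area_from_mask(mask: np.ndarray, pixel_spacing: tuple[float, float]) -> float:
    """Area of a binary mask in cm^2 (pixel count x row x col spacing / 100)."""
    m = np.asarray(mask)
    if m.dtype != bool and not np.isin(np.unique(m), (0, 1)).all():
        raise ValueError("invalid mask: not binary")
    sr, sc = pixel_spacing
    if sr <= 0 or sc <= 0:
        raise ValueError("invalid mask: non-positive pixel spacing")
    return float(np.count_nonzero(m)) * sr * sc / 100.0


def volume_summation_of_discs(areas_cm2, thickness_mm: float,
                              gap_mm: float = 0.0) -> float:
    """Summation-of-discs volume in ml: sum(area_i) * (thickness + gap) / 10."""
    areas = np.asarray(areas_cm2, dtype=float)
    if areas.size and np.any(areas < 0):
        raise ValueError("invalid area: negative")
    if thickness_mm <= 0:
        raise ValueError("invalid area: non-positive thickness")
    if gap_mm < 0:
        raise ValueError("invalid area: negative gap")
    return float(areas.sum() * (thickness_mm + gap_mm) / 10.0)


def lv_mass(epi_volume_ml: float, endo_volume_ml: float) -> float:
    """Myocardial mass in g: (epi - endo volume) x 1.05 g/cm^3."""
    if endo_volume_ml < 0:
        raise ValueError("invalid area: negative endo volume")
    if endo_volume_ml > epi_volume_ml:
        raise ValueError("inverted delineation: endo volume exceeds epi volume")
    return (epi_volume_ml - endo_volume_ml) * MYOCARDIUM_DENSITY_G_PER_CM3


def sv_ef(edv_ml: float, esv_ml: float) -> tuple[float, float]:
    """Stroke volume (ml) and ejection fraction (fraction of EDV)."""
    if esv_ml < 0 or esv_ml > edv_ml:
        raise ValueError("negative stroke volume: require 0 <= ESV <= EDV")
    if edv_ml <= 0:
        raise ValueError("EF undefined: EDV must be positive")
    sv = edv_ml - esv_ml
    return sv, sv / edv_ml


def lv_mass_index(lvm_g: float, bsa_m2: float) -> float:
    """LVM indexed to body surface area, g/m^2."""
    if bsa_m2 <= 0:
        raise ValueError("invalid BSA: must be positive")
    return lvm_g / bsa_m2


def bsa_mosteller(height_cm: float, weight_kg: float) -> float:
    """Convenience Mosteller BSA (m^2); never applied implicitly."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("invalid BSA: non-positive height/weight")
    return float(np.sqrt(height_cm * weight_kg / 3600.0))


def heart_rate_from_ed_frames(ed_frames_per_slice: list, frame_interval_ms: float) -> float:
    """Heart rate (beats/min) averaged over slices.

    Each slice supplies its ED event frame indices (>= 2); the slice rate is
    60000 / mean ED-to-ED interval in ms, and the result is the arithmetic
    mean over slices (typically three: near beginning, middle and end of the
    acquisition).
    """
    if frame_interval_ms <= 0:
        raise ValueError("invalid length: non-positive frame interval")
    rates = []
    for frames in ed_frames_per_slice:
        frames = np.asarray(frames, dtype=float)
        if len(frames) < 2:
            raise ValueError("insufficient beats: need >= 2 ED events per slice")
        interval_ms = float(np.mean(np.diff(np.sort(frames)))) * frame_interval_ms
        rates.append(60000.0 / interval_ms)
    return float(np.mean(rates))


def flow_stroke_volume(curve: FlowCurve) -> float:
    """Average stroke volume (ml) from a flow-rate curve.

    Trapezoidal net flow between the first and last diastole markers,
    divided by the number of beats (markers - 1).
    """
    lo, hi = int(curve.diastole_markers[0]), int(curve.diastole_markers[-1])
    t_s = curve.time_ms[lo:hi + 1] / 1000.0
    q = curve.flow_ml_s[lo:hi + 1]
    net = float(np.trapezoid(q, t_s))
    return net / (len(curve.diastole_markers) - 1)


def quantify_sorted_stack(sorted_stack: SortedStack, masks: MaskSet, state: str,
                          bsa_m2: float | None = None,
                          heart_rate_bpm: float | None = None) -> VolumetricResult:
    """Volumes and mass for one respiratory state from delineation masks.

    Only slices with both ED and ES masks (complete slices) contribute.
    LVM is computed from the ED delineations.
    """
    meta = sorted_stack.slice_meta[0]
    spacing = tuple(meta["pixel_spacing"])
    th, gap = meta["slice_thickness"], meta["slice_gap"]
    rows = []
    for i in sorted_stack.complete_slices(state):
        if (i, state, "ed") not in masks or (i, state, "es") not in masks:
            continue
        med = masks.get(i, state, "ed")
        mes = masks.get(i, state, "es")
        rows.append({
            "slice": i,
            "endo_ed_cm2": area_from_mask(med["endo"], spacing),
            "epi_ed_cm2": area_from_mask(med["epi"], spacing),
            "endo_es_cm2": area_from_mask(mes["endo"], spacing),
            "epi_es_cm2": area_from_mask(mes["epi"], spacing),
        })
    if not rows:
        raise ValueError("empty stack: no delineated slices")
    table = pd.DataFrame(rows).set_index("slice")
    edv = volume_summation_of_discs(table["endo_ed_cm2"], th, gap)
    esv = volume_summation_of_discs(table["endo_es_cm2"], th, gap)
    epi_edv = volume_summation_of_discs(table["epi_ed_cm2"], th, gap)
    sv, ef = sv_ef(edv, esv)
    lvm = lv_mass(epi_edv, edv)
    lvmi = lv_mass_index(lvm, bsa_m2) if bsa_m2 is not None else None
    return VolumetricResult(edv_ml=edv, esv_ml=esv, sv_ml=sv, ef=ef, lvm_g=lvm,
                            state=state, lvmi_g_m2=lvmi,
                            heart_rate_bpm=heart_rate_bpm, slice_table=table)
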