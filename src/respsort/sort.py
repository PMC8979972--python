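"""Respiratory extrema detection, state windows, ED/ES selection, stack assembly.

On the oriented respiratory curve, end expiration and end inspiration are
local maxima and minima.  Around each extreme a frame window is opened
(wider for expiration than inspiration, narrower during exercise, matching
the physiological asymmetry of the breathing cycle), and within the windows
the frames of maximum (ED) and minimum (ES) lumen blood volume are
suggested from a bright-blood lumen proxy.  Selected frames are assembled
into respiratory-matched short-axis stacks with QC flags (duplicate slices,
incomplete slices, LV length mismatch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .io import CineSeries, CineStack, RespROI, crop_roi
from .embed import RespCurve

__all__ = [
    "RespExtrema",
    "StateWindow",
    "SliceStateSelection",
    "SortedStack",
    "detect_extrema",
    "state_windows",
    "lumen_signal",
    "suggest_ed_es",
    "select_frames",
    "assemble_stack",
    "flag_duplicate_slices",
    "check_lv_length",
    "detect_ed_events",
    "EXPIRATION",
    "INSPIRATION",
    "WINDOW_HALFWIDTHS",
]

EXPIRATION = "expiration"
INSPIRATION = "inspiration"

# window half-widths in time-frames per mode and state
WINDOW_HALFWIDTHS = {
    "rest": {EXPIRATION: 15, INSPIRATION: 10},
    "exercise": {EXPIRATION: 8, INSPIRATION: 5},
}


@dataclass
class RespExtrema:
    """Classified respiratory extrema on the frame grid."""

    expiration_frames: np.ndarray
    inspiration_frames: np.ndarray
    estimated_period_frames: float
    confidence: float
    n_frames: int
    window_halfwidth_exp: int | None = None
    window_halfwidth_insp: int | None = None

    def frames(self, state: str) -> np.ndarray:
        if state == EXPIRATION:
            return self.expiration_frames
        if state == INSPIRATION:
            return self.inspiration_frames
        raise ValueError(f"unknown respiratory state {state!r}")

    def events(self) -> list[tuple[int, str]]:
        ev = [(int(f), EXPIRATION) for f in self.expiration_frames]
        ev += [(int(f), INSPIRATION) for f in self.inspiration_frames]
        return sorted(ev)


@dataclass(frozen=True)
class StateWindow:
    extreme_frame: int
    state: str
    lo: int
    hi: int

    def __len__(self) -> int:
        return self.hi - self.lo + 1

    def __contains__(self, frame: int) -> bool:
        return self.lo <= frame <= self.hi


@dataclass
class SliceStateSelection:
    """Selected ED/ES frames for one slice and respiratory state."""

    slice_index: int
    state: str
    ed_frame: int | None
    es_frame: int | None
    source: str = "auto"
    ed_anchor: int | None = None  # respiratory extreme the frame belongs to
    es_anchor: int | None = None
    ed_window: tuple[int, int] | None = None
    es_window: tuple[int, int] | None = None


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y.astype(float)
    pad = width // 2
    ypad = np.pad(y.astype(float), pad, mode="reflect")
    kernel = np.ones(width) / width
    out = np.convolve(ypad, kernel, mode="same")
    return out[pad:pad + len(y)] if pad else out


def _dominant_period(y: np.ndarray) -> float:
    """Period (frames) of the dominant nonzero frequency of the signal."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    spec = np.abs(np.fft.rfft(y - y.mean()))
    if len(spec) < 2:
        raise ValueError("no respiratory signal: sequence too short")
    kbin = int(np.argmax(spec[1:]) + 1)
    return n / kbin


def detect_extrema(curve: RespCurve, smoothing_width: int | None = None,
                   min_prominence_frac: float = 0.2,
                   orientation: str | None = None) -> RespExtrema:
    """Detect end-expiration / end-inspiration extrema on the oriented curve.

    The curve is smoothed by a centered moving average (default width: a
    quarter of the estimated respiratory period), extrema are found with a
    prominence threshold relative to the curve range and a minimum
    separation of half the estimated period, and alternation is enforced.
    Indices refer to the unsmoothed frame grid.
    """
    y = np.asarray(curve.values, dtype=float)
    n = len(y)
    rng_y = float(y.max() - y.min())
    if rng_y <= 0 or rng_y < 1e-12 * max(1.0, abs(float(y.mean()))):
        raise ValueError("no respiratory signal: constant curve")
    orientation = orientation or curve.orientation
    if orientation == "undetermined":
        raise ValueError("curve orientation undetermined: supply orientation")

    period0 = _dominant_period(y)
    if smoothing_width is None:
        smoothing_width = max(1, int(round(0.25 * period0)))
    ys = _moving_average(y, smoothing_width)
    period = _dominant_period(ys)
    if n < 2 * period:
        raise ValueError("insufficient cycles: need two respiratory periods")

    prom = min_prominence_frac * float(ys.max() - ys.min())
    dist = max(1, int(round(0.5 * period)))
    maxima, _ = find_peaks(ys, prominence=prom, distance=dist)
    minima, _ = find_peaks(-ys, prominence=prom, distance=dist)

    # enforce alternation: keep the more extreme of same-type neighbours
    events = sorted([(int(i), +1) for i in maxima] + [(int(i), -1) for i in minima])
    cleaned: list[tuple[int, int]] = []
    for idx, typ in events:
        if cleaned and cleaned[-1][1] == typ:
            prev = cleaned[-1][0]
            better = idx if typ * ys[idx] > typ * ys[prev] else prev
            cleaned[-1] = (better, typ)
        else:
            cleaned.append((idx, typ))
    maxima = np.array([i for i, t in cleaned if t == +1], dtype=int)
    minima = np.array([i for i, t in cleaned if t == -1], dtype=int)

    if orientation in ("expiration-up",):
        exp_f, insp_f = maxima, minima
    elif orientation == "expiration-down":
        exp_f, insp_f = minima, maxima
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if len(exp_f) < 2 or len(insp_f) < 2:
        raise ValueError("insufficient cycles: fewer than 2 extrema per state")

    intervals = np.diff(np.sort(np.r_[exp_f]))
    if len(intervals):
        cv = float(np.std(intervals) / np.mean(intervals))
    else:
        cv = 1.0
    confidence = float(np.clip(1.0 - cv, 0.0, 1.0))
    return RespExtrema(expiration_frames=exp_f, inspiration_frames=insp_f,
                       estimated_period_frames=float(period),
                       confidence=confidence, n_frames=n)


def state_windows(extrema: RespExtrema, mode: str = "rest") -> list[StateWindow]:
    """Frame windows around each extreme, clipped and non-overlapping.

    Default half-widths: rest +-15 (expiration) / +-10 (inspiration);
    exercise +-8 / +-5.  Windows are clipped to the acquisition and
    truncated at the midpoint between adjacent opposite-state extrema (the
    earlier window keeps the midpoint frame).
    """
    if mode not in WINDOW_HALFWIDTHS:
        raise ValueError(f"unknown mode {mode!r}")
    hw = WINDOW_HALFWIDTHS[mode]
    events = extrema.events()
    if not events:
        raise ValueError("insufficient cycles: no extrema")
    n = extrema.n_frames
    lo = [max(0, f - hw[s]) for f, s in events]
    hi = [min(n - 1, f + hw[s]) for f, s in events]
    for a in range(len(events) - 1):
        b = a + 1
        if hi[a] >= lo[b]:
            mid = (events[a][0] + events[b][0]) // 2
            hi[a] = min(hi[a], mid)
            lo[b] = max(lo[b], mid + 1)
    extrema.window_halfwidth_exp = hw[EXPIRATION]
    extrema.window_halfwidth_insp = hw[INSPIRATION]
    return [StateWindow(f, s, int(l), int(h))
            for (f, s), l, h in zip(events, lo, hi)]


def lumen_signal(series: CineSeries, lv_roi: RespROI) -> np.ndarray:
    """Per-frame bright-blood lumen area proxy (cm^2).

    Counts pixels above an Otsu threshold computed over the whole cropped
    sub-sequence, times pixel area; assumes a bright-blood (bSSFP-like)
    contrast.
    """
    sub = crop_roi(series, lv_roi)
    if float(sub.max() - sub.min()) <= 0:
        raise ValueError("lumen proxy unavailable: uniform ROI")
    try:
        thr = threshold_otsu(sub.ravel())
    except ValueError as e:
        raise ValueError("lumen proxy unavailable: degenerate histogram") from e
    return (sub > thr).sum(axis=1) * series.pixel_area_cm2


def suggest_ed_es(proxy: np.ndarray, window: StateWindow | tuple[int, int],
                  centre: int | None = None) -> tuple[int, int]:
    """Suggest (ED, ES) = (argmax, argmin) of the lumen proxy in a window.

    Ties are broken toward the window centre (the respiratory extreme);
    ties at equal distance resolve to the later frame.
    """
    if isinstance(window, StateWindow):
        lo, hi = window.lo, window.hi
        if centre is None:
            centre = window.extreme_frame
    else:
        lo, hi = window
    if hi - lo + 1 < 3:
        raise ValueError("window too narrow: need at least 3 frames")
    if centre is None:
        centre = (lo + hi) // 2
    frames = np.arange(lo, hi + 1)
    vals = np.asarray(proxy, dtype=float)[lo:hi + 1]
    if float(vals.max() - vals.min()) <= 0:
        raise ValueError("no cardiac variation in window: flat proxy")

    def pick(cands: np.ndarray) -> int:
        return int(min(cands, key=lambda f: (abs(int(f) - centre), -int(f))))

    ed = pick(frames[vals >= vals.max() - 1e-12])
    es = pick(frames[vals <= vals.min() + 1e-12])
    if ed == es:
        raise ValueError("no cardiac variation in window: flat proxy")
    return ed, es


def select_frames(proxy: np.ndarray, windows: Sequence[StateWindow], state: str,
                  slice_index: int = 0) -> SliceStateSelection:
    """Pick ED and ES for one state across all its windows.

    ED is taken from the window whose suggested ED has the globally largest
    proxy value, ES from the window with the smallest; the two may come from
    different breaths (the paper's criterion is coincidence with the
    respiratory state, not with a single cycle).
    """
    best_ed: tuple[float, int, int] | None = None
    best_es: tuple[float, int, int] | None = None
    for w in windows:
        if w.state != state:
            continue
        try:
            ed, es = suggest_ed_es(proxy, w)
        except ValueError:
            continue
        if best_ed is None or proxy[ed] > best_ed[0]:
            best_ed = (float(proxy[ed]), ed, w.extreme_frame)
        if best_es is None or proxy[es] < best_es[0]:
            best_es = (float(proxy[es]), es, w.extreme_frame)
    if best_ed is None or best_es is None:
        return SliceStateSelection(slice_index, state, None, None, source="auto")
    win_by_anchor = {w.extreme_frame: (w.lo, w.hi) for w in windows if w.state == state}
    return SliceStateSelection(
        slice_index, state, ed_frame=best_ed[1], es_frame=best_es[1],
        source="auto", ed_anchor=best_ed[2], es_anchor=best_es[2],
        ed_window=win_by_anchor.get(best_ed[2]), es_window=win_by_anchor.get(best_es[2]))


@dataclass
class SortedStackEntry:
    slice_index: int
    state: str
    ed_image: np.ndarray | None
    es_image: np.ndarray | None
    provenance: dict = field(default_factory=dict)


@dataclass
class SortedStack:
    """Respiratory-matched short-axis stack of selected ED/ES frames."""

    entries: dict = field(default_factory=dict)  # (slice_index, state) -> entry
    slice_meta: list = field(default_factory=list)
    states: tuple = ()
    incomplete: list = field(default_factory=list)       # (slice_index, state)
    duplicate_pairs: list = field(default_factory=list)  # (i, j, state, ncc)
    lv_length_mismatch: bool | None = None

    def get(self, slice_index: int, state: str) -> SortedStackEntry:
        return self.entries[(slice_index, state)]

    def slice_indices(self, state: str) -> list[int]:
        return sorted(i for (i, s) in self.entries if s == state)

    def complete_slices(self, state: str) -> list[int]:
        return [i for i in self.slice_indices(state)
                if (i, state) not in self.incomplete]

    @property
    def slice_spacing_mm(self) -> float:
        m = self.slice_meta[0]
        return m["slice_thickness"] + m["slice_gap"]

    def save(self, directory) -> None:
        """Write selected frames (npz per slice/state) plus a JSON manifest."""
        import json
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"states": list(self.states), "slice_meta": self.slice_meta,
                    "incomplete": [list(x) for x in self.incomplete],
                    "duplicate_pairs": [list(x) for x in self.duplicate_pairs],
                    "lv_length_mismatch": self.lv_length_mismatch,
                    "entries": []}
        for n, ((i, state), e) in enumerate(sorted(self.entries.items())):
            name = f"entry_{n:03d}.npz"
            arrays = {}
            if e.ed_image is not None:
                arrays["ed"] = e.ed_image
            if e.es_image is not None:
                arrays["es"] = e.es_image
            np.savez_compressed(directory / name, **arrays)
            manifest["entries"].append({"slice": i, "state": state, "file": name,
                                        "provenance": e.provenance})
        (directory / "sorted_stack.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "SortedStack":
        import json
        from pathlib import Path
        directory = Path(directory)
        manifest = json.loads((directory / "sorted_stack.json").read_text())
        out = cls(states=tuple(manifest["states"]),
                  slice_meta=manifest["slice_meta"],
                  incomplete=[tuple(x) for x in manifest["incomplete"]],
                  duplicate_pairs=[tuple(x) for x in manifest["duplicate_pairs"]],
                  lv_length_mismatch=manifest["lv_length_mismatch"])
        for rec in manifest["entries"]:
            with np.load(directory / rec["file"]) as z:
                ed = z["ed"] if "ed" in z else None
                es = z["es"] if "es" in z else None
            out.entries[(rec["slice"], rec["state"])] = SortedStackEntry(
                rec["slice"], rec["state"], ed, es, rec["provenance"])
        return out


def assemble_stack(stack: CineStack, selections: Sequence[SliceStateSelection],
                   states: Sequence[str] = (EXPIRATION,)) -> SortedStack:
    """Copy the selected ED/ES frames per slice and state into a SortedStack.

    Slices missing a phase are included but flagged incomplete (mirroring
    basal slices where no suitable coincidence exists).
    """
    by_key = {(s.slice_index, s.state): s for s in selections}
    out = SortedStack(states=tuple(states),
                      slice_meta=[s.metadata() for s in stack.slices])
    any_selected = False
    for i, series in enumerate(stack.slices):
        for state in states:
            sel = by_key.get((i, state))
            ed_img = es_img = None
            prov: dict = {"source": None}
            if sel is not None:
                prov = {"source": sel.source,
                        "ed_frame": sel.ed_frame, "es_frame": sel.es_frame,
                        "ed_anchor": sel.ed_anchor, "es_anchor": sel.es_anchor,
                        "ed_window": sel.ed_window, "es_window": sel.es_window}
                if sel.ed_frame is not None:
                    ed_img = series.frames[sel.ed_frame]
                    any_selected = True
                if sel.es_frame is not None:
                    es_img = series.frames[sel.es_frame]
                    any_selected = True
            out.entries[(i, state)] = SortedStackEntry(i, state, ed_img, es_img, prov)
            if ed_img is None or es_img is None:
                out.incomplete.append((i, state))
    if not any_selected:
        raise ValueError("empty stack: no slice selected")
    return out


def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    if den == 0:
        return 0.0
    return float(a @ b / den)


def flag_duplicate_slices(sorted_stack: SortedStack,
                          ncc_threshold: float = 0.98) -> SortedStack:
    """Flag adjacent slice pairs whose ED images are near-identical.

    Uses zero-normalized cross-correlation; flags only, never removes.
    """
    for state in sorted_stack.states:
        idx = sorted_stack.slice_indices(state)
        if len(idx) < 2:
            continue
        for a, b in zip(idx[:-1], idx[1:]):
            ea, eb = sorted_stack.get(a, state), sorted_stack.get(b, state)
            if ea.ed_image is None or eb.ed_image is None:
                continue
            ncc = _zncc(ea.ed_image, eb.ed_image)
            if ncc >= ncc_threshold:
                sorted_stack.duplicate_pairs.append((a, b, state, ncc))
    return sorted_stack


def check_lv_length(lv_length_4ch_mm: float, delineated_slice_count: int,
                    slice_thickness: float, slice_gap: float = 0.0) -> tuple[bool, float]:
    """Compare LV length from the 4-chamber view against the short-axis stack.

    The short-axis length is ``count * (thickness + gap)``; a mismatch is
    flagged when the two differ by more than one slice spacing.
    Returns ``(mismatch_flag, computed_length_mm)``.
    """
    if lv_length_4ch_mm <= 0 or delineated_slice_count <= 0 or slice_thickness <= 0:
        raise ValueError("invalid length: non-positive input")
    if slice_gap < 0:
        raise ValueError("invalid length: negative gap")
    spacing = slice_thickness + slice_gap
    computed = delineated_slice_count * spacing
    return abs(computed - lv_length_4ch_mm) > spacing, computed


def detect_ed_events(proxy: np.ndarray, min_prominence_frac: float = 0.25) -> np.ndarray:
    """ED (maximum lumen) events across the whole acquisition.

    Peaks of the lumen proxy at the dominant cardiac frequency; used for
    heart-rate estimation.
    """
    proxy = np.asarray(proxy, dtype=float)
    if float(proxy.max() - proxy.min()) <= 0:
        raise ValueError("no cardiac variation in window: flat proxy")
    period = _dominant_period(proxy)
    dist = max(1, int(round(0.6 * period)))
    prom = min_prominence_frac * float(proxy.max() - proxy.min())
    peaks, _ = find_peaks(proxy, distance=dist, prominence=prom)
    if len(peaks) < 2:
        raise ValueError("insufficient beats: fewer than 2 ED events")
    return peaks
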