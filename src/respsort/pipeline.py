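"""End-to-end orchestration: embed -> sort -> assemble -> quantify."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CineSeries, CineStack, MaskSet, RespROI, crop_roi
from .embed import respiratory_curve, RespCurve
from .sort import (
    RespExtrema, SliceStateSelection, SortedStack,
    assemble_stack, detect_extrema, flag_duplicate_slices, lumen_signal,
    select_frames, state_windows, detect_ed_events, EXPIRATION,
)
from .quant import VolumetricResult, heart_rate_from_ed_frames, quantify_sorted_stack

__all__ = ["SliceDiagnostics", "sort_stack", "quantify_states", "heart_rate_from_stack"]


@dataclass
class SliceDiagnostics:
    """Per-slice intermediates kept for provenance and QC."""

    curve: RespCurve | None = None
    extrema: RespExtrema | None = None
    windows: list = field(default_factory=list)
    lumen_proxy: np.ndarray | None = None
    selections: list = field(default_factory=list)
    error: str | None = None


def sort_stack(
    stack: CineStack,
    resp_roi: RespROI,
    lv_roi: RespROI,
    mode: str = "rest",
    states: tuple[str, ...] = (EXPIRATION,),
    k: int = 10,
    sigma2: float | None = None,
    graph_mode: str = "hybrid",
    smoothing_width: int | None = None,
    min_prominence_frac: float = 0.2,
    ncc_threshold: float = 0.98,
) -> tuple[SortedStack, list[SliceDiagnostics]]:
    """Run the respiratory sorting pipeline over every slice of a stack.

    For each slice: crop the diaphragm ROI, compute and orient the
    respiratory curve, detect extrema, open state windows, compute the
    lumen proxy and select ED/ES frames per requested state.  Slices where
    any stage fails are included but flagged incomplete, mirroring the
    manual fallback for slices where the diaphragm leaves the ROI.
    """
    diagnostics: list[SliceDiagnostics] = []
    selections: list[SliceStateSelection] = []
    for i, series in enumerate(stack.slices):
        diag = SliceDiagnostics()
        try:
            diag.curve = respiratory_curve(series, resp_roi, k=k, sigma2=sigma2,
                                           graph_mode=graph_mode)
            diag.extrema = detect_extrema(diag.curve, smoothing_width=smoothing_width,
                                          min_prominence_frac=min_prominence_frac)
            diag.windows = state_windows(diag.extrema, mode=mode)
            diag.lumen_proxy = lumen_signal(series, lv_roi)
            for state in states:
                sel = select_frames(diag.lumen_proxy, diag.windows, state,
                                    slice_index=i)
                diag.selections.append(sel)
                selections.append(sel)
        except ValueError as e:
            diag.error = str(e)
            for state in states:
                selections.append(SliceStateSelection(i, state, None, None))
        diagnostics.append(diag)
    sorted_stack = assemble_stack(stack, selections, states=states)
    flag_duplicate_slices(sorted_stack, ncc_threshold=ncc_threshold)
    return sorted_stack, diagnostics


def heart_rate_from_stack(diagnostics: list[SliceDiagnostics],
                          frame_interval_ms: float) -> float:
    """Average heart rate from three slices (beginning, middle, end of stack)."""
    usable = [d for d in diagnostics if d.lumen_proxy is not None]
    if len(usable) < 3:
        raise ValueError("insufficient beats: need lumen proxies from 3 slices")
    picks = [usable[0], usable[len(usable) // 2], usable[-1]]
    ed_lists = [detect_ed_events(d.lumen_proxy) for d in picks]
    return heart_rate_from_ed_frames(ed_lists, frame_interval_ms)


def quantify_states(sorted_stack: SortedStack, masks: MaskSet,
                    bsa_m2: float | None = None,
                    heart_rate_bpm: float | None = None) -> dict[str, VolumetricResult]:
    """Quantify every requested respiratory state of a sorted stack."""
    return {state: quantify_sorted_stack(sorted_stack, masks, state,
                                         bsa_m2=bsa_m2, heart_rate_bpm=heart_rate_bpm)
            for state in sorted_stack.states}
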