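"""Synthetic real-time cine phantom with exact ground truth.

The phantom emulates a free-breathing, non-ECG-gated short-axis acquisition:

* a bright "lung" / dark "abdomen" intensity step whose edge (the
  diaphragm) translates vertically with a respiratory waveform that has a
  prolonged end-expiratory plateau;
* a bright LV blood disc contracting inside a mid-grey myocardial ring,
  translated with a fraction of the diaphragm displacement, with a mild
  respiratory-linked intensity modulation standing in for through-plane
  content change;
* i.i.d. Gaussian noise.

Every frame carries exact, noise-free truth (displacement, respiratory
state, cardiac phase, analytic endo/epi areas), so each downstream stage of
the sorting and quantification pipeline has an oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import CineSeries, CineStack, MaskSet

__all__ = [
    "RespWaveformParams",
    "CardiacParams",
    "PhantomGeometry",
    "PhantomTruth",
    "StackTruth",
    "generate_cine_slice",
    "generate_cine_stack",
    "noise_sd_from_snr",
    "masks_from_truth",
    "EXPIRATION",
    "INSPIRATION",
]

EXPIRATION = "expiration"
INSPIRATION = "inspiration"

# rendered intensities (arbitrary units)
_LUNG = 0.9
_ABDOMEN = 0.25
_THORAX = 0.35
_MYO = 0.45
_BLOOD = 1.0


@dataclass
class RespWaveformParams:
    """Respiratory waveform: raised cosine with a flattened expiratory plateau.

    ``plateau_asymmetry`` is the fraction of each cycle spent at the
    end-expiratory extreme; it reproduces the physiological asymmetry in
    which end expiration lasts longer than end inspiration.
    """

    period_frames: float = 90.0
    amplitude_px: float = 8.0
    plateau_asymmetry: float = 0.3
    period_jitter_frac: float = 0.0
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.period_frames < 4:
            raise ValueError("period_frames must be >= 4")
        if self.amplitude_px < 0:
            raise ValueError("amplitude_px must be non-negative")
        if not 0 <= self.plateau_asymmetry < 1:
            raise ValueError("plateau_asymmetry must lie in [0, 1)")
        if self.period_jitter_frac < 0:
            raise ValueError("period_jitter_frac must be non-negative")


@dataclass
class CardiacParams:
    """LV geometry over the cardiac cycle.

    The endocardial radius interpolates smoothly between its ED and ES
    values with a systolic fraction of the cycle; with
    ``epi_mode="incompressible"`` the epicardial radius co-varies so the
    myocardial ring keeps constant cross-sectional area (incompressible
    myocardium), with ``"fixed"`` it stays at ``epi_radius_px``.
    """

    period_frames: float = 27.0
    endo_radius_ed_px: float = 17.0
    endo_radius_es_px: float = 10.0
    epi_radius_px: float = 21.0
    systolic_fraction: float = 1.0 / 3.0
    phase_offset: float = 0.0
    epi_mode: str = "incompressible"

    def __post_init__(self) -> None:
        if not (0 < self.endo_radius_es_px < self.endo_radius_ed_px < self.epi_radius_px):
            raise ValueError("radii must satisfy 0 < ES < ED < epi")
        if self.period_frames <= 0:
            raise ValueError("period_frames must be positive")
        if not 0 < self.systolic_fraction < 1:
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if self.epi_mode not in ("incompressible", "fixed"):
            raise ValueError("epi_mode must be 'incompressible' or 'fixed'")


@dataclass
class PhantomGeometry:
    n_rows: int = 128
    n_cols: int = 128
    pixel_spacing: tuple[float, float] = (1.5, 1.5)
    frame_interval: float = 35.0
    slice_thickness: float = 10.0
    slice_gap: float = 0.0
    diaphragm_row: float = 92.0
    lung_top_row: float = 72.0
    lv_center: tuple[float, float] = (42.0, 64.0)
    heart_resp_fraction: float = 0.4
    through_plane_frac: float = 0.05


@dataclass
class PhantomTruth:
    """Noise-free per-frame ground truth for one phantom slice."""

    displacement_px: np.ndarray          # + = cranial (toward row 0)
    resp_state: np.ndarray               # "expiration" / "inspiration" / "transit"
    cardiac_phase: np.ndarray            # in [0, 1), 0 = ED
    endo_radius_px: np.ndarray
    epi_radius_px: np.ndarray
    endo_area_cm2: np.ndarray
    epi_area_cm2: np.ndarray
    lv_center_row: np.ndarray
    lv_center_col: np.ndarray
    diaphragm_edge_row: np.ndarray
    expiration_extrema: np.ndarray       # frame indices
    inspiration_extrema: np.ndarray
    geometry: PhantomGeometry

    def extrema(self, state: str) -> np.ndarray:
        if state == EXPIRATION:
            return self.expiration_extrema
        if state == INSPIRATION:
            return self.inspiration_extrema
        raise ValueError(f"unknown respiratory state {state!r}")

    def true_ed_es_in_window(self, lo: int, hi: int) -> tuple[int, int]:
        """Frames inside ``[lo, hi]`` whose cardiac phase is closest to ED / ES."""
        frames = np.arange(lo, hi + 1)
        ph = self.cardiac_phase[lo:hi + 1]
        d_ed = np.minimum(ph, 1 - ph)                       # circular distance to 0
        es_phase = self._es_phase
        d_es = np.minimum(np.abs(ph - es_phase), 1 - np.abs(ph - es_phase))
        return int(frames[np.argmin(d_ed)]), int(frames[np.argmin(d_es)])

    _es_phase: float = 1.0 / 3.0

    def masks_for_frame(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """Rasterized endo/epi masks from the analytic disc at ``frame``."""
        g = self.geometry
        rr, cc = np.mgrid[0:g.n_rows, 0:g.n_cols]
        d2 = (rr - self.lv_center_row[frame]) ** 2 + (cc - self.lv_center_col[frame]) ** 2
        endo = d2 <= self.endo_radius_px[frame] ** 2
        epi = d2 <= self.epi_radius_px[frame] ** 2
        return endo, epi

    def to_json(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
            elif isinstance(v, PhantomGeometry):
                out[k] = v.__dict__ | {"pixel_spacing": list(v.pixel_spacing),
                                       "lv_center": list(v.lv_center)}
            else:
                out[k] = v
        return out


@dataclass
class StackTruth:
    """Per-slice truths plus closed-form stack volumes."""

    slices: list[PhantomTruth]
    edv_ml: float
    esv_ml: float
    epi_edv_ml: float
    epi_esv_ml: float

    @property
    def sv_ml(self) -> float:
        return self.edv_ml - self.esv_ml

    @property
    def lvm_g(self) -> float:
        return (self.epi_edv_ml - self.edv_ml) * 1.05


def noise_sd_from_snr(snr_db: float, signal: float = _LUNG - _ABDOMEN) -> float:
    """Noise SD giving the requested SNR (dB) against the diaphragm step."""
    return signal / 10.0 ** (snr_db / 20.0)


def _respiratory_phase(n_frames: int, resp: RespWaveformParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Continuous (unwrapped) respiratory phase per frame, cycles as units."""
    if resp.period_jitter_frac == 0:
        return resp.phase_offset + np.arange(n_frames) / resp.period_frames
    phase = np.empty(n_frames)
    phi = resp.phase_offset
    period = resp.period_frames * float(np.clip(
        1 + resp.period_jitter_frac * rng.standard_normal(), 0.5, 1.5))
    for t in range(n_frames):
        phase[t] = phi
        nxt = phi + 1.0 / period
        if np.floor(nxt) > np.floor(phi):  # new cycle: redraw the period
            period = resp.period_frames * float(np.clip(
                1 + resp.period_jitter_frac * rng.standard_normal(), 0.5, 1.5))
        phi = nxt
    return phase


def _warp_displacement(phase: np.ndarray, resp: RespWaveformParams) -> np.ndarray:
    """Displacement in px; + = cranial. Flat plateau of width p around u = 0."""
    u = np.mod(phase, 1.0)
    p = resp.plateau_asymmetry
    theta = np.where((u < p / 2) | (u > 1 - p / 2), 0.0,
                     (u - p / 2) / (1 - p) if p < 1 else 0.0)
    return resp.amplitude_px * np.cos(2 * np.pi * theta)


def _contraction(phase: np.ndarray, systolic_fraction: float) -> np.ndarray:
    """0 at ED (phase 0), 1 at ES (phase = systolic fraction), smooth."""
    fs = systolic_fraction
    ph = np.mod(phase, 1.0)
    c = np.empty_like(ph)
    sys_mask = ph <= fs
    c[sys_mask] = 0.5 * (1 - np.cos(np.pi * ph[sys_mask] / fs))
    c[~sys_mask] = 0.5 * (1 + np.cos(np.pi * (ph[~sys_mask] - fs) / (1 - fs)))
    return c


def _extreme_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, end) inclusive."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[splits + 1]]
    ends = np.r_[idx[splits], idx[-1]]
    return list(zip(starts.tolist(), ends.tolist()))


def _cycle_extrema(d: np.ndarray, amplitude: float, period: float,
                   eps_frac: float = 0.05, margin_frac: float = 0.1
                   ) -> tuple[np.ndarray, np.ndarray]:
    """True expiration (max d) / inspiration (min d) frames per cycle.

    An extreme is the centre of a contiguous run of frames within eps of the
    waveform extreme.  Runs touching the acquisition boundary (within a
    tenth of a period) are not counted: an extreme whose neighbourhood is
    only partially acquired is not identifiable in principle.
    """
    n = len(d)
    if amplitude <= 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    eps = eps_frac * 2 * amplitude
    margin = max(1, int(round(margin_frac * period)))
    out = []
    for mask in (d >= amplitude - eps, d <= -amplitude + eps):
        centres = [int((a + b) // 2) for a, b in _extreme_runs(mask)
                   if a >= margin and b <= n - 1 - margin]
        out.append(np.array(centres, dtype=int))
    return out[0], out[1]


def _render_frames(n_frames: int, geometry: PhantomGeometry, d: np.ndarray,
                   r_endo: np.ndarray, r_epi: np.ndarray, blood_gain: np.ndarray,
                   noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    g = geometry
    rows = np.arange(g.n_rows, dtype=float)[:, None]
    cols = np.arange(g.n_cols, dtype=float)[None, :]
    frames = np.empty((n_frames, g.n_rows, g.n_cols))
    for t in range(n_frames):
        edge = g.diaphragm_row - d[t]
        # dark thorax above the lung band; bright lung down to the moving
        # diaphragm edge; dark abdomen below (subpixel edge)
        band = _LUNG - (_LUNG - _ABDOMEN) * np.clip(rows - edge + 0.5, 0.0, 1.0)
        img = np.where(rows < g.lung_top_row, _THORAX, band)
        img = np.broadcast_to(img, (g.n_rows, g.n_cols)).copy()
        cy = g.lv_center[0] - g.heart_resp_fraction * d[t]
        cx = g.lv_center[1]
        dist = np.sqrt((rows - cy) ** 2 + (cols - cx) ** 2)
        cov_epi = np.clip(r_epi[t] + 0.5 - dist, 0.0, 1.0)
        img = img * (1 - cov_epi) + _MYO * cov_epi
        cov_endo = np.clip(r_endo[t] + 0.5 - dist, 0.0, 1.0)
        img = img * (1 - cov_endo) + _BLOOD * blood_gain[t] * cov_endo
        frames[t] = img
    if noise_sd > 0:
        frames += noise_sd * rng.standard_normal(frames.shape)
    return frames


def generate_cine_slice(
    resp: RespWaveformParams | None = None,
    cardiac: CardiacParams | None = None,
    geometry: PhantomGeometry | None = None,
    n_frames: int = 500,
    noise_sd: float = 0.065,
    seed: int = 0,
    slice_index: int = 0,
) -> tuple[CineSeries, PhantomTruth]:
    """Generate one synthetic real-time cine slice plus its exact truth.

    Requires at least two full respiratory cycles (``n_frames >= 2 *
    resp.period_frames``) and a field of view large enough to contain the
    diaphragm excursion and the translated LV disc.
    """
    resp = resp or RespWaveformParams()
    cardiac = cardiac or CardiacParams()
    geometry = geometry or PhantomGeometry()
    if n_frames < 2 * resp.period_frames:
        raise ValueError("insufficient respiratory coverage: "
                         "need n_frames >= 2 * resp.period_frames")
    g = geometry
    A = resp.amplitude_px
    if not (g.lung_top_row + 1 <= g.diaphragm_row - A
            and g.diaphragm_row + A <= g.n_rows - 2):
        raise ValueError("phantom exceeds field of view: diaphragm excursion")
    max_shift = g.heart_resp_fraction * A
    cy, cx = g.lv_center
    r_max = cardiac.epi_radius_px
    if cardiac.epi_mode == "incompressible":
        ring = cardiac.epi_radius_px ** 2 - cardiac.endo_radius_ed_px ** 2
        r_max = float(np.sqrt(ring + cardiac.endo_radius_ed_px ** 2))
    if (cy - max_shift - r_max < 0 or cy + max_shift + r_max > g.lung_top_row
            or cx - r_max < 0 or cx + r_max > g.n_cols - 1):
        raise ValueError("phantom exceeds field of view: LV disc")

    rng = np.random.default_rng([seed, slice_index])
    phase = _respiratory_phase(n_frames, resp, rng)
    d = _warp_displacement(phase, resp)
    exp_idx, insp_idx = _cycle_extrema(d, A, resp.period_frames)

    cphase = np.mod(cardiac.phase_offset + np.arange(n_frames) / cardiac.period_frames, 1.0)
    contraction = _contraction(cphase, cardiac.systolic_fraction)
    r_endo = cardiac.endo_radius_ed_px + (cardiac.endo_radius_es_px
                                          - cardiac.endo_radius_ed_px) * contraction
    if cardiac.epi_mode == "incompressible":
        ring = cardiac.epi_radius_px ** 2 - cardiac.endo_radius_ed_px ** 2
        r_epi = np.sqrt(ring + r_endo ** 2)
    else:
        r_epi = np.full(n_frames, cardiac.epi_radius_px)

    # respiratory state labels: within 5% of peak-to-peak of either extreme
    if A > 0:
        eps = 0.05 * 2 * A
        state = np.where(d >= A - eps, EXPIRATION,
                         np.where(d <= -A + eps, INSPIRATION, "transit"))
    else:
        state = np.full(n_frames, "transit")

    blood_gain = 1.0 + g.through_plane_frac * (-d / A if A > 0 else np.zeros(n_frames))
    frames = _render_frames(n_frames, g, d, r_endo, r_epi, blood_gain, noise_sd, rng)

    px_cm2 = g.pixel_spacing[0] * g.pixel_spacing[1] / 100.0
    truth = PhantomTruth(
        displacement_px=d,
        resp_state=state.astype(object),
        cardiac_phase=cphase,
        endo_radius_px=r_endo,
        epi_radius_px=r_epi,
        endo_area_cm2=np.pi * r_endo ** 2 * px_cm2,
        epi_area_cm2=np.pi * r_epi ** 2 * px_cm2,
        lv_center_row=g.lv_center[0] - g.heart_resp_fraction * d,
        lv_center_col=np.full(n_frames, g.lv_center[1]),
        diaphragm_edge_row=g.diaphragm_row - d,
        expiration_extrema=exp_idx,
        inspiration_extrema=insp_idx,
        geometry=g,
    )
    truth._es_phase = cardiac.systolic_fraction
    series = CineSeries(
        frames=frames,
        pixel_spacing=g.pixel_spacing,
        frame_interval=g.frame_interval,
        slice_thickness=g.slice_thickness,
        slice_gap=g.slice_gap,
        slice_location=slice_index * (g.slice_thickness + g.slice_gap),
        label=f"phantom slice {slice_index}",
    )
    return series, truth


def default_slice_scales(n_slices: int) -> np.ndarray:
    """Ellipsoid-like apex taper: base scale 1, non-increasing toward apex."""
    z = np.arange(n_slices) / max(n_slices - 1, 1)
    return np.sqrt(1.0 - 0.8 * z ** 2)


def generate_cine_stack(
    n_slices: int = 8,
    resp: RespWaveformParams | None = None,
    cardiac: CardiacParams | None = None,
    geometry: PhantomGeometry | None = None,
    n_frames: int = 500,
    noise_sd: float = 0.065,
    seed: int = 0,
    slice_scales: np.ndarray | None = None,
    randomize_phases: bool = True,
) -> tuple[CineStack, StackTruth]:
    """Generate a multi-slice phantom stack with analytic true volumes.

    Slices are independent acquisitions: respiratory and cardiac phase
    offsets are randomized per slice (non-gated acquisition) unless
    ``randomize_phases`` is False. True EDV/ESV and epicardial volumes are
    closed-form sums of discs over the per-slice scaled radii.
    """
    if n_slices < 3:
        raise ValueError("stack too short: need at least 3 slices")
    resp = resp or RespWaveformParams()
    cardiac = cardiac or CardiacParams()
    geometry = geometry or PhantomGeometry()
    if slice_scales is None:
        slice_scales = default_slice_scales(n_slices)
    slice_scales = np.asarray(slice_scales, dtype=float)
    if len(slice_scales) != n_slices:
        raise ValueError("slice_scales length must equal n_slices")
    if np.any(np.diff(slice_scales) > 1e-12):
        raise ValueError("slice_scales must be non-increasing toward the apex")

    rng = np.random.default_rng([seed, 987654321])
    slices, truths = [], []
    for i in range(n_slices):
        s = float(slice_scales[i])
        card_i = CardiacParams(
            period_frames=cardiac.period_frames,
            endo_radius_ed_px=cardiac.endo_radius_ed_px * s,
            endo_radius_es_px=cardiac.endo_radius_es_px * s,
            epi_radius_px=cardiac.epi_radius_px * s,
            systolic_fraction=cardiac.systolic_fraction,
            phase_offset=float(rng.random()) if randomize_phases else cardiac.phase_offset,
            epi_mode=cardiac.epi_mode,
        )
        resp_i = RespWaveformParams(
            period_frames=resp.period_frames,
            amplitude_px=resp.amplitude_px,
            plateau_asymmetry=resp.plateau_asymmetry,
            period_jitter_frac=resp.period_jitter_frac,
            phase_offset=float(rng.random()) if randomize_phases else resp.phase_offset,
        )
        series, truth = generate_cine_slice(resp_i, card_i, geometry, n_frames,
                                            noise_sd, seed=seed, slice_index=i)
        slices.append(series)
        truths.append(truth)

    g = geometry
    px_cm2 = g.pixel_spacing[0] * g.pixel_spacing[1] / 100.0
    dz_cm = (g.slice_thickness + g.slice_gap) / 10.0
    r_ed = cardiac.endo_radius_ed_px * slice_scales
    r_es = cardiac.endo_radius_es_px * slice_scales
    if cardiac.epi_mode == "incompressible":
        ring = (cardiac.epi_radius_px ** 2 - cardiac.endo_radius_ed_px ** 2) * slice_scales ** 2
        repi_ed = np.sqrt(ring + r_ed ** 2)
        repi_es = np.sqrt(ring + r_es ** 2)
    else:
        repi_ed = repi_es = cardiac.epi_radius_px * slice_scales
    truth = StackTruth(
        slices=truths,
        edv_ml=float(np.sum(np.pi * r_ed ** 2 * px_cm2) * dz_cm),
        esv_ml=float(np.sum(np.pi * r_es ** 2 * px_cm2) * dz_cm),
        epi_edv_ml=float(np.sum(np.pi * repi_ed ** 2 * px_cm2) * dz_cm),
        epi_esv_ml=float(np.sum(np.pi * repi_es ** 2 * px_cm2) * dz_cm),
    )
    return CineStack(slices), truth


def masks_from_truth(truths: list[PhantomTruth], selections) -> MaskSet:
    """Build a MaskSet by rasterizing the analytic LV discs at selected frames.

    ``selections`` is an iterable of records with ``slice_index``, ``state``,
    ``ed_frame`` and ``es_frame`` attributes (see :mod:`respsort.sort`).
    Stands in for manual delineation on phantom data.
    """
    masks = MaskSet()
    for sel in selections:
        t = truths[sel.slice_index]
        for phase, frame in (("ed", sel.ed_frame), ("es", sel.es_frame)):
            if frame is None:
                continue
            endo, epi = t.masks_for_frame(frame)
            masks.add(sel.slice_index, sel.state, phase, endo, epi)
    return masks


def write_truth(truth: PhantomTruth | StackTruth, path: str | Path) -> None:
    path = Path(path)
    if isinstance(truth, PhantomTruth):
        path.write_text(json.dumps(truth.to_json(), indent=1))
    else:
        payload = {
            "edv_ml": truth.edv_ml, "esv_ml": truth.esv_ml,
            "epi_edv_ml": truth.epi_edv_ml, "epi_esv_ml": truth.epi_esv_ml,
            "lvm_g": truth.lvm_g,
            "slices": [t.to_json() for t in truth.slices],
        }
        path.write_text(json.dumps(payload, indent=1))
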