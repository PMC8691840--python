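"""Single-channel PCNA cell-cycle reporter analysis.

A tracked nucleus (circular ROI per frame) yields two traces: the mean
nuclear intensity, normalized to its first value, and the width of the
pixel-intensity frequency distribution inside the ROI.  Phases follow from
the known PCNA phenomenology: G1 cells lose nuclear signal over time, S
cells gain it, late-S nuclei show replication-focus speckles, the S/G2
transition is the point of maximal intensity-distribution width, and M
onset is a sharp drop in nuclear signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.stats import theilslopes
from skimage.feature import peak_local_max
from skimage.filters import gaussian

PHASES = ("G1", "S", "lateS", "G2", "M", "unclassified")

DEFAULT_N_BINS = 64
DEFAULT_OCCUPANCY_FRAC = 0.05
DEFAULT_DROP_FRAC = 0.3
DEFAULT_DROP_WINDOW = 3
DEFAULT_SPECKLE_MIN = 3
SLOPE_WINDOW = 5  # frames per Theil-Sen sliding window


class ROIError(ValueError):
    pass


@dataclass(frozen=True)
class CircleROI:
    cx: float
    cy: float
    r: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        m = (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.r ** 2
        if not m.any():
            raise ROIError("ROI covers no pixels")
        return m


@dataclass
class IntensityTrace:
    t_min: np.ndarray
    I: np.ndarray
    I_norm: np.ndarray | None = None


@dataclass
class WidthTrace:
    t_min: np.ndarray
    W: np.ndarray


@dataclass
class PhaseSegmentation:
    labels: list[str]
    t_sg2_frame: int | None
    t_m_frame: int | None
    t_sg2_min: float | None
    t_m_min: float | None
    speckle_counts: list[int]
    flags: list[str] = field(default_factory=list)


def _rois_per_frame(roi, n_frames: int) -> list[CircleROI]:
    if isinstance(roi, CircleROI):
        return [roi] * n_frames
    rois = list(roi)
    if len(rois) != n_frames:
        raise ROIError(f"{len(rois)} ROIs for {n_frames} frames")
    return rois


def extract_trace(movie: np.ndarray, roi, frame_interval_min: float = 20.0
                  ) -> IntensityTrace:
    """Mean ROI intensity per frame; time axis in minutes."""
    rois = _rois_per_frame(roi, len(movie))
    vals = np.array([frame[r.mask(frame.shape)].mean()
                     for frame, r in zip(movie, rois)], dtype=float)
    t = np.arange(len(movie), dtype=float) * frame_interval_min
    return IntensityTrace(t_min=t, I=vals)


def normalize_trace(trace: IntensityTrace) -> IntensityTrace:
    """Divide by the first tracked frame's intensity (I_norm[0] == 1)."""
    if trace.I[0] <= 0:
        raise ValueError("initial intensity must be positive to normalize")
    trace.I_norm = trace.I / trace.I[0]
    return trace


def intensity_histogram(frame: np.ndarray, roi: CircleROI, n_bins: int = DEFAULT_N_BINS,
                        value_range: tuple[float, float] | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of ROI pixel values; (counts, bin_centers).

    ``value_range`` should span the whole movie so widths are comparable
    across frames; it defaults to the frame's own min..max.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = frame[roi.mask(frame.shape)].astype(float)
    if value_range is None:
        value_range = (float(vals.min()), float(vals.max()) or 1.0)
    counts, edges = np.histogram(vals, bins=n_bins, range=value_range)
    centers = (edges[:-1] + edges[1:]) / 2
    return counts, centers


def distribution_width(counts: np.ndarray, centers: np.ndarray,
                       occupancy_frac: float = DEFAULT_OCCUPANCY_FRAC) -> float:
    """Span (intensity units) between the extreme bins whose count reaches
    ``occupancy_frac`` of the modal bin count."""
    if not 0 < occupancy_frac < 1:
        raise ValueError("occupancy_frac must be in (0, 1)")
    counts = np.asarray(counts)
    if counts.sum() == 0:
        raise ValueError("empty histogram")
    thr = occupancy_frac * counts.max()
    occ = np.flatnonzero(counts >= max(thr, 1))
    return float(centers[occ[-1]] - centers[occ[0]])


def width_trace(movie: np.ndarray, roi, n_bins: int = DEFAULT_N_BINS,
                occupancy_frac: float = DEFAULT_OCCUPANCY_FRAC,
                frame_interval_min: float = 20.0) -> WidthTrace:
    """Distribution width per frame, binned over the global movie range."""
    rois = _rois_per_frame(roi, len(movie))
    rng = (float(movie.min()), float(movie.max()))
    W = np.empty(len(movie))
    for f, (frame, r) in enumerate(zip(movie, rois)):
        counts, centers = intensity_histogram(frame, r, n_bins, rng)
        W[f] = distribution_width(counts, centers, occupancy_frac)
    t = np.arange(len(movie), dtype=float) * frame_interval_min
    return WidthTrace(t_min=t, W=W)


def detect_speckles(frame: np.ndarray, roi: CircleROI, k_sigma: float = 2.0,
                    min_prominence: float | None = None, min_sep: int = 2,
                    smooth_sigma: float = 1.0) -> int:
    """Count replication-focus-like puncta inside the ROI.

    Local maxima of the lightly smoothed frame that exceed the ROI level by
    ``k_sigma`` robust standard deviations (median/MAD, so the foci being
    counted do not inflate their own threshold), are at least ``min_sep``
    pixels apart, and rise ``min_prominence`` above the ROI median
    (default: 3 robust SDs, rejecting ordinary nuclear-texture bumps).
    Statistics and peaks are taken on an eroded ROI interior so the
    nucleus-to-background falloff at the ROI rim does not inflate the
    spread.
    """
    mask = roi.mask(frame.shape)
    if mask.sum() < 9:
        raise ROIError("ROI smaller than 9 pixels")
    erode = int(np.ceil(2 * smooth_sigma + 1))
    inner = binary_erosion(mask, iterations=erode)
    if inner.sum() >= 9:
        mask = inner
    sm = gaussian(frame.astype(float), sigma=smooth_sigma, preserve_range=True)
    vals = sm[mask]
    med = float(np.median(vals))
    sd_rob = 1.4826 * float(np.median(np.abs(vals - med)))
    thr = med + k_sigma * sd_rob
    if min_prominence is None:
        # strictly positive floor so perfectly flat frames yield no peaks
        min_prominence = max(3.0 * sd_rob, 1e-9)
    peaks = peak_local_max(sm, min_distance=min_sep, threshold_abs=thr,
                           exclude_border=False)
    n = 0
    for y, x in peaks:
        if mask[y, x] and sm[y, x] - med >= min_prominence:
            n += 1
    return n


def speckle_counts(movie: np.ndarray, roi, **kw) -> list[int]:
    rois = _rois_per_frame(roi, len(movie))
    return [detect_speckles(frame, r, **kw) for frame, r in zip(movie, rois)]


def locate_sg2(wtrace: WidthTrace, smooth_window: int = 3) -> int:
    """Frame of maximal (moving-mean smoothed) distribution width; first
    frame on ties.  This is the S/G2 transition estimate."""
    W = np.asarray(wtrace.W, dtype=float)
    if W.size < 3:
        raise ValueError("need at least 3 frames")
    kernel = np.ones(smooth_window) / smooth_window
    sm = np.convolve(W, kernel, mode="same")
    # restore edge means (same-mode convolution divides by full window)
    half = smooth_window // 2
    for i in range(half):
        sm[i] = W[:i + half + 1].mean()
        sm[-1 - i] = W[-(i + half + 1):].mean()
    return int(np.argmax(sm))


def locate_m_onset(trace: IntensityTrace, drop_frac: float = DEFAULT_DROP_FRAC,
                   window: int = DEFAULT_DROP_WINDOW) -> int | None:
    """Earliest frame whose normalized intensity sits >= ``drop_frac``
    (as a fraction of the earlier value) below some frame at most
    ``window`` frames before it; None if the track never drops."""
    I = trace.I_norm if trace.I_norm is not None else trace.I / trace.I[0]
    n = I.size
    if n < window + 1:
        raise ValueError("trace shorter than window + 1 frames")
    for g in range(1, n):
        for d in range(1, window + 1):
            f = g - d
            if f >= 0 and I[f] > 0 and (I[f] - I[g]) / I[f] >= drop_frac:
                return g
    return None


def _sliding_theil_sen(I: np.ndarray, window: int = SLOPE_WINDOW) -> np.ndarray:
    """Robust per-frame slope: Theil-Sen over a centred sliding window."""
    n = I.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        seg = I[lo:hi]
        if seg.size < 2:
            out[i] = 0.0
            continue
        out[i] = theilslopes(seg, np.arange(seg.size))[0]
    return out


def _fill_gaps(labels: list[str], passes: int = 2) -> list[str]:
    """Majority-fill isolated dissenting frames so phase runs stay contiguous."""
    labels = list(labels)
    for _ in range(passes):
        for i in range(1, len(labels) - 1):
            if labels[i] != labels[i - 1] and labels[i - 1] == labels[i + 1]:
                labels[i] = labels[i - 1]
    return labels


def segment_phases(trace: IntensityTrace, wtrace: WidthTrace,
                   speckles: list[int], speckle_min: int = DEFAULT_SPECKLE_MIN,
                   drop_frac: float = DEFAULT_DROP_FRAC,
                   drop_window: int = DEFAULT_DROP_WINDOW,
                   frame_interval_min: float | None = None) -> PhaseSegmentation:
    """Per-frame phase labels from the intensity and width traces.

    Rules, in order: frames at/after M onset are M; frames between the
    S/G2 transition and M onset are G2; frames before the transition with
    positive robust intensity slope are S, refined to late S where the
    speckle count reaches ``speckle_min``; non-dividing tracks with overall
    negative robust slope are G1 throughout; anything left is
    unclassified.  Isolated one-frame disagreements are majority-filled so
    each phase forms one contiguous run.
    """
    if trace.I_norm is None:
        normalize_trace(trace)
    I = trace.I_norm
    n = I.size
    if frame_interval_min is None:
        frame_interval_min = float(trace.t_min[1] - trace.t_min[0]) if n > 1 else 1.0
    t_m = locate_m_onset(trace, drop_frac, drop_window)
    flags: list[str] = []

    overall_slope = theilslopes(I, np.arange(n))[0]
    if t_m is None and overall_slope < 0:
        # non-dividing, decaying track: G1 throughout
        return PhaseSegmentation(["G1"] * n, None, None, None, None,
                                 list(speckles), flags)

    t_sg2 = locate_sg2(wtrace)
    if t_m is not None and t_m < t_sg2:
        flags.append(f"M onset (frame {t_m}) precedes S/G2 estimate "
                     f"(frame {t_sg2}); check traces")
        warnings.warn(flags[-1], UserWarning, stacklevel=2)

    slopes = _sliding_theil_sen(I)
    labels = ["unclassified"] * n
    for f in range(n):
        if t_m is not None and f >= t_m:
            labels[f] = "M"
        elif t_sg2 <= f < (t_m if t_m is not None else n):
            labels[f] = "G2"
        elif f < t_sg2 and slopes[f] > 0:
            labels[f] = "lateS" if speckles[f] >= speckle_min else "S"
    labels = _fill_gaps(labels)
    return PhaseSegmentation(
        labels, t_sg2, t_m,
        t_sg2 * frame_interval_min if t_sg2 is not None else None,
        t_m * frame_interval_min if t_m is not None else None,
        list(speckles), flags)
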