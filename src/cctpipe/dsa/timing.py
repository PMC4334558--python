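"""Time-to-peak analysis of digital-subtraction angiography sequences.

The cerebral circulation time (CCT) is the time between the frames of maximum
contrast concentration in the carotid siphon and in the cortical parietal
veins.  This module subtracts the pre-contrast mask frame, finds per-curve and
per-pixel peak times, and renders colour-coded circulation-time maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ContrastError(ValueError):
    """Raised when a time-intensity curve carries no contrast arrival."""


@dataclass(frozen=True)
class DsaSequence:
    """Time-ordered 2-D contrast frames with their acquisition times."""

    frames: np.ndarray  # (T, H, W)
    frame_times_s: np.ndarray  # (T,), strictly increasing
    mask_frame_index: int = 0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        times = np.asarray(self.frame_times_s, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if frames.shape[0] < 3:
            raise ValueError("need at least 3 frames")
        if times.shape != (frames.shape[0],):
            raise ValueError("frame_times_s must match the number of frames")
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame_times_s must be strictly increasing")
        if not (0 <= self.mask_frame_index < frames.shape[0]):
            raise ValueError("mask_frame_index out of range")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_times_s", times)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def frame_interval_s(self) -> float:
        return float(np.median(np.diff(self.frame_times_s)))


@dataclass(frozen=True)
class RoiMask:
    """A 2-D boolean region of interest with a semantic label."""

    mask: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not mask.any():
            raise ValueError("ROI mask has no true pixel")
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class TtpMap:
    """Per-pixel time-to-peak in seconds with a validity mask."""

    ttp_s: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class PeakTime:
    """Peak time of one time-intensity curve."""

    t_s: float
    boundary: bool = False
    interpolated: bool = False

    def __float__(self) -> float:
        return self.t_s


@dataclass(frozen=True)
class CctMeasurement:
    cct_s: float
    siphon_peak_s: float
    vein_peak_s: float
    side: str = "right"
    rater_id: str = "r1"
    flags: tuple[str, ...] = field(default_factory=tuple)


def subtracted_contrast(seq: DsaSequence) -> DsaSequence:
    """Subtract the pre-contrast mask frame from every frame."""
    mask = seq.frames[seq.mask_frame_index]
    return replace(seq, frames=seq.frames - mask[None, :, :])


def peak_time(
    curve: np.ndarray, times_s: np.ndarray, interpolate: bool = False
) -> PeakTime:
    """Time of the maximal sample of a time-intensity curve.

    Ties resolve to the first (earliest) maximum.  With ``interpolate`` the
    vertex of the parabola through the maximum and its two neighbours is
    returned, clamped to the neighbour interval; a boundary maximum is
    returned un-interpolated and flagged.
    """
    curve = np.asarray(curve, dtype=np.float64)
    times_s = np.asarray(times_s, dtype=np.float64)
    if curve.ndim != 1 or curve.size < 3:
        raise ValueError("curve must be 1-D with at least 3 samples")
    if curve.shape != times_s.shape:
        raise ValueError("curve and times_s must have the same length")
    if np.ptp(curve) == 0:
        raise ContrastError("no contrast arrival: curve is constant")

    i = int(np.argmax(curve))
    if not interpolate:
        return PeakTime(float(times_s[i]))
    if i == 0 or i == curve.size - 1:
        return PeakTime(float(times_s[i]), boundary=True)
    y0, y1, y2 = curve[i - 1], curve[i], curve[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:  # flat top: keep the sample time
        return PeakTime(float(times_s[i]), interpolated=True)
    # vertex offset in units of the local (uniform) sample spacing
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    dt = times_s[i + 1] - times_s[i] if delta >= 0 else times_s[i] - times_s[i - 1]
    return PeakTime(float(times_s[i] + delta * dt), interpolated=True)


def estimate_ttp_map(seq: DsaSequence, arrival_threshold: float = 0.2) -> TtpMap:
    """Per-pixel peak time where contrast actually arrives.

    A pixel is valid when its curve maximum reaches ``arrival_threshold``
    times the global maximum of the subtracted sequence.
    """
    frames = seq.frames
    per_pixel_max = frames.max(axis=0)
    global_max = float(per_pixel_max.max())
    if global_max <= 0:
        raise ContrastError("sequence contains no positive contrast signal")
    valid = per_pixel_max >= arrival_threshold * global_max
    if not valid.any():
        raise ContrastError("no pixel passes the arrival threshold")
    argmax = np.argmax(frames, axis=0)
    ttp = seq.frame_times_s[argmax]
    ttp = np.where(valid, ttp, np.nan)
    return TtpMap(ttp_s=ttp, valid=valid)


def compute_cct(
    seq: DsaSequence,
    roi_siphon: RoiMask,
    roi_vein: RoiMask,
    interpolate: bool = False,
    side: str = "right",
    rater_id: str = "r1",
) -> CctMeasurement:
    """CCT as the vein-minus-siphon difference of ROI-averaged peak times.

    Each ROI's pixels are averaged to a single time-intensity curve first
    (reading "the frame" of maximum concentration for the structure), then
    :func:`peak_time` is applied.  A negative difference is returned with a
    ``negative_cct`` warning flag rather than raised.
    """
    for roi in (roi_siphon, roi_vein):
        if roi.mask.shape != seq.frame_shape:
            raise ValueError(
                f"ROI shape {roi.mask.shape} does not match frames {seq.frame_shape}"
            )
    sub = subtracted_contrast(seq)
    flags: list[str] = []
    peaks = []
    for roi in (roi_siphon, roi_vein):
        curve = sub.frames[:, roi.mask].mean(axis=1)
        pt = peak_time(curve, sub.frame_times_s, interpolate=interpolate)
        if pt.boundary:
            flags.append(f"boundary_peak_{roi.label}")
        peaks.append(pt.t_s)
    cct = peaks[1] - peaks[0]
    if cct < 0:
        flags.append("negative_cct")
    return CctMeasurement(
        cct_s=float(cct),
        siphon_peak_s=float(peaks[0]),
        vein_peak_s=float(peaks[1]),
        side=side,
        rater_id=rater_id,
        flags=tuple(flags),
    )


# early -> late colour ramp anchors (red, yellow, green, blue)
_RAMP = np.array(
    [[1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)


def ramp_fraction(ttp_s, t_min_s: float, t_max_s: float) -> np.ndarray:
    """Position of a TTP value on the colour ramp, clamped to [0, 1]."""
    if not t_min_s < t_max_s:
        raise ValueError("t_min_s must be < t_max_s")
    return np.clip((np.asarray(ttp_s, dtype=float) - t_min_s) / (t_max_s - t_min_s), 0.0, 1.0)


def color_code(ttp: TtpMap, t_min_s: float, t_max_s: float) -> np.ndarray:
    """Render a TTP map as an (H, W, 3) float RGB image.

    Monotone piecewise-linear hue ramp red -> yellow -> green -> blue over
    ``[t_min_s, t_max_s]``; out-of-range values clamp to the ramp ends and
    invalid pixels render black.
    """
    frac = ramp_fraction(np.nan_to_num(ttp.ttp_s, nan=0.0), t_min_s, t_max_s)
    pos = frac * (len(_RAMP) - 1)
    lo = np.clip(np.floor(pos).astype(int), 0, len(_RAMP) - 2)
    w = (pos - lo)[..., None]
    rgb = (1.0 - w) * _RAMP[lo] + w * _RAMP[lo + 1]
    rgb[~ttp.valid] = 0.0
    return rgb
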