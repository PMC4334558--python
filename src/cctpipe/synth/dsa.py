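"""Synthetic DSA sequences with gamma-variate contrast bolus propagation.

Each pixel belongs to one of four regions (carotid siphon, capillary bed,
cortical parietal vein, background); its time course is the region's
gamma-variate curve on top of a static anatomical baseline, plus Gaussian
noise.  The analytic curve maximum is at ``onset_s + peak_delay_s``, so the
ground-truth CCT is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ..dsa.timing import DsaSequence, RoiMask


@dataclass(frozen=True)
class BolusParams:
    """Gamma-variate bolus: ``A ((t-t0)/tp)^a exp(a (1 - (t-t0)/tp))``.

    The curve rises from ``onset_s``, attains its maximum ``amplitude`` at
    ``onset_s + peak_delay_s``, and decays with tail heaviness controlled by
    ``shape_alpha``.
    """

    onset_s: float
    peak_delay_s: float
    amplitude: float = 100.0
    shape_alpha: float = 3.0

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.peak_delay_s <= 0:
            raise ValueError("peak_delay_s must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.shape_alpha <= 0:
            raise ValueError("shape_alpha must be > 0")

    @property
    def peak_time_s(self) -> float:
        return self.onset_s + self.peak_delay_s

    def curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        u = (t - self.onset_s) / self.peak_delay_s
        out = np.zeros_like(u)
        pos = u > 0
        a = self.shape_alpha
        out[pos] = self.amplitude * u[pos] ** a * np.exp(a * (1.0 - u[pos]))
        return out


@dataclass(frozen=True)
class DsaGroundTruth:
    """Analytic peak times and ROI masks for a generated sequence."""

    cct_true_s: float
    siphon_peak_s: float
    vein_peak_s: float
    roi_siphon: RoiMask
    roi_vein: RoiMask


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _region_masks(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    h, w = shape
    siphon = _disk(shape, (0.35 * h, 0.25 * w), 0.06 * min(h, w))
    vein = _disk(shape, (0.30 * h, 0.75 * w), 0.06 * min(h, w))
    head = _disk(shape, (0.5 * h, 0.5 * w), 0.42 * min(h, w))
    capillary = head & ~siphon & ~vein
    background = ~(siphon | vein | capillary)
    return {
        "siphon": siphon,
        "vein": vein,
        "capillary": capillary,
        "background": background,
    }


def gen_dsa_sequence(
    bolus: Mapping[str, BolusParams],
    frame_rate_hz: float,
    duration_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
) -> tuple[DsaSequence, DsaGroundTruth]:
    """Generate a DSA sequence and its ground truth.

    ``bolus`` must contain :class:`BolusParams` for ``siphon``, ``capillary``
    and ``vein`` (a ``background`` entry is optional and normally absent).
    Every region's analytic peak must fall inside the acquisition window and
    after the first (pre-contrast mask) frame.
    """
    if not 2.0 <= frame_rate_hz <= 4.0:
        raise ValueError("frame_rate_hz must be within [2, 4]")
    for region in ("siphon", "capillary", "vein"):
        if region not in bolus:
            raise ValueError(f"missing bolus parameters for region {region!r}")
    times = np.arange(0.0, duration_s, 1.0 / frame_rate_hz)
    if times.size < 3:
        raise ValueError("duration too short for 3 frames")
    for region, params in bolus.items():
        if params.peak_time_s >= times[-1]:
            raise ValueError(
                f"bolus peak of region {region!r} at {params.peak_time_s:.2f} s "
                f"falls outside the acquisition window (last frame {times[-1]:.2f} s)"
            )
        if params.onset_s <= times[0]:
            raise ValueError(
                f"bolus onset of region {region!r} precedes the mask frame"
            )

    masks = _region_masks(shape)
    baseline = np.full(shape, 100.0)
    baseline[masks["siphon"] | masks["vein"]] += 20.0  # vessels on anatomy
    frames = np.repeat(baseline[None, :, :], times.size, axis=0)
    for region, params in bolus.items():
        curve = params.curve(times)
        frames[:, masks[region]] += curve[:, None]

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)

    seq = DsaSequence(frames=frames, frame_times_s=times, mask_frame_index=0)
    truth = DsaGroundTruth(
        cct_true_s=bolus["vein"].peak_time_s - bolus["siphon"].peak_time_s,
        siphon_peak_s=bolus["siphon"].peak_time_s,
        vein_peak_s=bolus["vein"].peak_time_s,
        roi_siphon=RoiMask(masks["siphon"], label="siphon"),
        roi_vein=RoiMask(masks["vein"], label="cortical_parietal_vein"),
    )
    return seq, truth


def bolus_preset(cct_true_s: float, siphon_peak_s: float = 0.5) -> dict[str, BolusParams]:
    """Bolus parameter set with a prescribed ground-truth CCT."""
    if cct_true_s <= 0:
        raise ValueError("cct_true_s must be > 0")
    vein_peak = siphon_peak_s + cct_true_s
    return {
        "siphon": BolusParams(onset_s=0.2, peak_delay_s=siphon_peak_s - 0.2, amplitude=120.0),
        "capillary": BolusParams(
            onset_s=0.4,
            peak_delay_s=(siphon_peak_s + vein_peak) / 2.0 - 0.4,
            amplitude=40.0,
        ),
        "vein": BolusParams(onset_s=0.8, peak_delay_s=vein_peak - 0.8, amplitude=90.0),
    }


def ms_like() -> dict[str, BolusParams]:
    """Bolus preset with the MS-group mean CCT of 4.9 s."""
    return bolus_preset(4.9)


def control_like() -> dict[str, BolusParams]:
    """Bolus preset with the control-group mean CCT of 2.8 s."""
    return bolus_preset(2.8)
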