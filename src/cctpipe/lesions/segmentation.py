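"""Brain extraction and three-class tissue segmentation on T1 volumes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import Volume3D


class SegmentationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TissueMaps:
    """Posterior probability maps for CSF/GM/WM plus the brain mask.

    Probabilities are zero outside ``brain_mask`` and sum to one inside it.
    """

    prob_csf: np.ndarray
    prob_gm: np.ndarray
    prob_wm: np.ndarray
    brain_mask: np.ndarray
    means: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sds: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def hard_labels(self) -> np.ndarray:
        """0 background, 1 CSF, 2 GM, 3 WM by maximum posterior."""
        stacked = np.stack([self.prob_csf, self.prob_gm, self.prob_wm])
        labels = np.argmax(stacked, axis=0) + 1
        labels[~self.brain_mask] = 0
        return labels


def extract_brain(t1: Volume3D, closing_iterations: int = 2) -> np.ndarray:
    """Binary brain mask: Otsu threshold, morphological closing, largest
    connected component, hole filling."""
    data = t1.data
    if np.ptp(data) == 0:
        raise SegmentationError("cannot extract brain from a constant volume")
    mask = data > threshold_otsu(data)
    if closing_iterations:
        mask = ndimage.binary_closing(mask, iterations=closing_iterations)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise SegmentationError("brain extraction produced an empty mask")
    largest = np.argmax(ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))) + 1
    mask = labels == largest
    return ndimage.binary_fill_holes(mask)


def _kmeans_1d(x: np.ndarray, k: int, seed: int, iters: int = 25) -> np.ndarray:
    """Deterministic 1-D k-means; centers initialised at spread quantiles."""
    rng = np.random.default_rng(seed)
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    centers = centers + rng.normal(0.0, 1e-9, size=k)  # break exact ties stably
    for _ in range(iters):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [x[assign == j].mean() if np.any(assign == j) else centers[j] for j in range(k)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    return np.sort(centers)


def segment_tissues(
    t1: Volume3D,
    brain_mask: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> TissueMaps:
    """Fit a 3-component univariate Gaussian mixture to in-brain intensities.

    EM with k-means initialisation; components are labelled CSF < GM < WM by
    ascending mean (T1 convention).  A small variance floor keeps the
    noiseless (point-mass) case well defined; a component whose mixing weight
    collapses to zero is reported as degenerate.
    """
    if not np.any(brain_mask):
        raise SegmentationError("empty brain mask")
    x = t1.data[brain_mask].astype(np.float64)
    spread = np.ptp(x)
    if spread == 0:
        raise SegmentationError("constant in-brain intensities")
    var_floor = (1e-3 * spread) ** 2

    means = _kmeans_1d(x, 3, seed)
    variances = np.full(3, np.maximum(x.var() / 9.0, var_floor))
    weights = np.full(3, 1.0 / 3.0)

    prev_ll = -np.inf
    n = x.size
    for _ in range(max_iter):
        # E-step in log space for stability
        log_pdf = (
            -0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
            - 0.5 * np.log(2.0 * np.pi * variances[None, :])
            + np.log(weights[None, :])
        )
        mx = log_pdf.max(axis=1, keepdims=True)
        log_norm = mx[:, 0] + np.log(np.exp(log_pdf - mx).sum(axis=1))
        resp = np.exp(log_pdf - log_norm[:, None])
        ll = log_norm.mean()

        nk = resp.sum(axis=0)
        if np.any(nk < 10.0 * np.finfo(float).tiny * n + 1e-8):
            raise SegmentationError("degenerate mixture component (empty class)")
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)

        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll

    order = np.argsort(means)
    means, variances, weights = means[order], variances[order], weights[order]
    resp = resp[:, order]

    maps = []
    for j in range(3):
        vol = np.zeros(t1.shape, dtype=np.float64)
        vol[brain_mask] = resp[:, j]
        maps.append(vol)
    return TissueMaps(
        prob_csf=maps[0],
        prob_gm=maps[1],
        prob_wm=maps[2],
        brain_mask=np.asarray(brain_mask, dtype=bool),
        means=tuple(means),
        sds=tuple(np.sqrt(variances)),
    )
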