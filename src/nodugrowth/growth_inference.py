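"""Monte-Carlo post-processing of segmentation samples into growth estimates.

A trained probabilistic segmentation model is sampled K times (default
1000) for one baseline patch.  Each sampled soft mask is thresholded,
reduced to its largest connected component, and its longest (Feret)
diameter is measured in mm.  Subtracting the baseline diameter D0 gives
a vector of K growth sizes whose mean and standard deviation quantify
the predicted growth and its uncertainty; a logistic transform centred
on the 2 mm guideline threshold converts each growth size to a growth
probability.  Per-pixel mean and standard deviation images of the soft
samples summarise the expected future appearance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cohort_io import GROWTH_THRESHOLD_MM

__all__ = [
    "GrowthEstimate",
    "extract_longest_diameter",
    "growth_probability",
    "monte_carlo_predict",
    "classify_growth",
]

#: 4-connectivity structuring element for component labelling
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class GrowthEstimate:
    """Summary of K Monte-Carlo growth samples for one nodule."""

    deltas: np.ndarray  # (K,) growth sizes in mm
    delta_mean: float
    delta_std: float
    prob_mean: float
    prob_std: float
    mean_image: np.ndarray  # (32,32) per-pixel mean of soft samples
    std_image: np.ndarray  # (32,32) per-pixel std of soft samples
    K: int
    d0_mm: float
    all_empty: bool = False  # every sampled mask was empty (delta = -D0)

    @property
    def interval_2std(self) -> tuple[float, float]:
        return self.delta_mean - 2 * self.delta_std, self.delta_mean + 2 * self.delta_std


def extract_longest_diameter(mask: np.ndarray, spacing_mm: float) -> float:
    """Longest diameter (mm) of the largest 4-connected component.

    The diameter is the maximum pairwise Euclidean distance between
    foreground pixel centres plus one pixel extent, scaled by the pixel
    spacing, so a single pixel measures one pixel spacing and a
    rasterized disk returns its nominal diameter.  An empty mask
    measures 0.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        return 0.0
    labels, n = ndimage.label(mask, structure=_CROSS)
    if n > 1:
        largest = np.argmax(ndimage.sum_labels(mask, labels, range(1, n + 1))) + 1
        mask = labels == largest
    coords = np.argwhere(mask).astype(np.float64)
    if len(coords) == 1:
        return float(spacing_mm)
    # max pairwise distance; 32x32 patches keep this cheap
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    return float((np.sqrt(d2.max()) + 1.0) * spacing_mm)


def growth_probability(delta_mm):
    """Logistic probability that growth exceeds the 2 mm threshold.

    F(delta) = 1 / (1 + exp(-(delta - 2))); strictly increasing with
    F(2) = 0.5 exactly.
    """
    delta_mm = np.asarray(delta_mm, dtype=np.float64)
    out = 1.0 / (1.0 + np.exp(-(delta_mm - GROWTH_THRESHOLD_MM)))
    return float(out) if out.ndim == 0 else out


def monte_carlo_predict(
    model,
    image_t0: np.ndarray,
    t_norm: float,
    d_norm: float,
    d0_mm: float,
    spacing_mm: float,
    K: int = 1000,
    threshold: float = 0.5,
    seed: int | None = None,
) -> GrowthEstimate:
    """Draw K segmentation samples and summarise them as a GrowthEstimate.

    ``model`` must expose ``sample(image_t0, t_norm, d_norm, rng) ->
    soft mask in [0,1]``.  Samples are thresholded at ``threshold``
    before diameter extraction; the mean/std images are computed on the
    soft samples.  Standard deviations are population (1/K) for
    bit-reproducibility.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    samples = np.empty((K,) + np.asarray(image_t0).shape)
    deltas = np.empty(K)
    for k in range(K):
        soft = np.asarray(model.sample(image_t0, t_norm, d_norm, rng))
        samples[k] = soft
        d1 = extract_longest_diameter(soft > threshold, spacing_mm)
        deltas[k] = d1 - d0_mm
    probs = growth_probability(deltas)
    probs = np.atleast_1d(probs)
    return GrowthEstimate(
        deltas=deltas,
        delta_mean=float(deltas.mean()),
        delta_std=float(deltas.std()),
        prob_mean=float(probs.mean()),
        prob_std=float(probs.std()),
        mean_image=samples.mean(axis=0),
        std_image=samples.std(axis=0),
        K=K,
        d0_mm=d0_mm,
        all_empty=bool((deltas == -d0_mm).all() and d0_mm > 0),
    )


def classify_growth(estimate: GrowthEstimate) -> int:
    """Binary growth decision: 1 iff the mean growth probability exceeds 0.5."""
    return int(estimate.prob_mean > 0.5)
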