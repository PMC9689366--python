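import numpy as np
import pytest

from nodugrowth import SimulationParams, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small multi-annotator cohort shared by read-only tests."""
    return generate_cohort(SimulationParams(n_nodules=10, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def disk_mask(radius_px: float, size: int = 32, centre=None) -> np.ndarray:
    centre = (size // 2, size // 2) if centre is None else centre
    yy, xx = np.mgrid[0:size, 0:size]
    return (((yy - centre[0]) ** 2 + (xx - centre[1]) ** 2) <= radius_px**2).astype(
        np.uint8
    )


def line_mask(n_pixels: int, size: int = 32, row: int = 16, col0: int = 4) -> np.ndarray:
    m = np.zeros((size, size), dtype=np.uint8)
    m[row, col0 : col0 + n_pixels] = 1
    return m


def brute_force_feret(mask: np.ndarray, spacing_mm: float) -> float:
    """All-pairs-distance oracle for the longest diameter (largest
    4-connected component), independent of the implementation."""
    from scipy import ndimage

    mask = np.asarray(mask) > 0
    if not mask.any():
        return 0.0
    labels, n = ndimage.label(
        mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    if n > 1:
        sizes = [(labels == i).sum() for i in range(1, n + 1)]
        mask = labels == (int(np.argmax(sizes)) + 1)
    pts = np.argwhere(mask).astype(float)
    best = 0.0
    for i in range(len(pts)):  # all pairs, one row at a time
        d = np.hypot(pts[i + 1 :, 0] - pts[i, 0], pts[i + 1 :, 1] - pts[i, 1])
        if d.size:
            best = max(best, float(d.max()))
    return (best + 1.0) * spacing_mm
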