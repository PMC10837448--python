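"""Back-projection of classifier weights into visual space.

Each voxel's influence on classification (its primal SVM weight x_j) is
spread over the visual field according to its pRF Gaussian, and every
pixel receives the pRF-weighted average of the contributing voxels'
weights:

    y_i = sum_j(w_ij * x_j) / sum_j(w_ij)

where w_ij is voxel j's (unnormalised, peak-1) pRF Gaussian evaluated at
pixel i, truncated to zero beyond 2 sigma of its centre. Pixels with no
pRF coverage (sum_j w_ij = 0) are set to 0, preventing the ratio from
blowing up where coverage is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import WeightMap
from .retinotopy import PRFModel
from .synth import VisualFieldGrid

__all__ = ["ProjectionMap", "backproject_weights"]


@dataclass
class ProjectionMap:
    """Pixel-wise influence values over the visual field."""

    grid: VisualFieldGrid
    values: np.ndarray  # (n_pixels,)
    coverage: np.ndarray  # (n_pixels,) sum of truncated pRF weights

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projection values must be finite")
        if np.any(self.values[self.coverage == 0] != 0):
            raise ValueError("uncovered pixels must be zero")

    def as_image(self) -> np.ndarray:
        n = self.grid.n_pixels_per_side
        return self.values.reshape(n, n)


def backproject_weights(
    weights: WeightMap | np.ndarray,
    models: list[PRFModel],
    grid: VisualFieldGrid,
) -> ProjectionMap:
    """pRF-weighted average of voxel weights over the visual-field grid.

    ``models`` must carry one pRF per weight (same voxel order). Each pRF
    contributes its Gaussian profile, zeroed where the pixel's Euclidean
    distance to the centre exceeds 2 sigma (boundary inclusive at exactly
    2 sigma).
    """
    x = weights.weights if isinstance(weights, WeightMap) else np.asarray(weights, dtype=float)
    if len(models) != len(x):
        raise ValueError(
            f"{len(x)} weights but {len(models)} pRF models; voxel sets must match"
        )
    px, py = grid.pixel_centres()
    cx = np.array([m.x for m in models])
    cy = np.array([m.y for m in models])
    sig = np.array([m.sigma for m in models])
    d2 = (px[:, None] - cx[None, :]) ** 2 + (py[:, None] - cy[None, :]) ** 2
    w = np.exp(-d2 / (2.0 * sig[None, :] ** 2))
    w[d2 > (2.0 * sig[None, :]) ** 2] = 0.0
    coverage = w.sum(axis=1)
    values = np.zeros_like(coverage)
    covered = coverage > 0
    values[covered] = (w[covered] @ x) / coverage[covered]
    return ProjectionMap(grid=grid, values=values, coverage=coverage)
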