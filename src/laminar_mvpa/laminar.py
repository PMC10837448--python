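"""Cortical-depth binning.

Voxels are assigned to six equidistant, partially overlapping depth bins
centred at 0.1, 0.26, 0.42, 0.58, 0.74 and 0.9 of cortical thickness
(0 = white-matter boundary, 1 = pial surface). With the default bin
halfwidth of 0.1 a voxel can fall into two neighbouring bins (adjacent
bins overlap by 0.04 depth units), emulating depth grids that partly
share voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DEPTH_BIN_CENTRES", "DepthAssignment", "assign_depth_bins"]

DEPTH_BIN_CENTRES = (0.1, 0.26, 0.42, 0.58, 0.74, 0.9)
DEFAULT_BIN_HALFWIDTH = 0.1


@dataclass
class DepthAssignment:
    """Membership of voxels in the six depth bins (sets of voxel indices)."""

    bin_centres: tuple[float, ...]
    membership: list[set[int]]
    bin_halfwidth: float

    def __post_init__(self) -> None:
        if len(self.bin_centres) != 6 or len(self.membership) != 6:
            raise ValueError("exactly 6 depth bins expected")

    def bins_for_depth(self, depth: float) -> list[int]:
        return [
            k
            for k, c in enumerate(self.bin_centres)
            if abs(depth - c) <= self.bin_halfwidth
        ]

    def indices(self, k: int) -> np.ndarray:
        """Sorted member voxel indices of bin ``k``."""
        return np.array(sorted(self.membership[k]), dtype=int)

    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.membership])


def assign_depth_bins(
    voxel_depths: np.ndarray,
    bin_halfwidth: float = DEFAULT_BIN_HALFWIDTH,
) -> DepthAssignment:
    """Assign voxels to depth bins by interval membership.

    Voxel ``v`` belongs to bin ``k`` iff ``|depth_v - centre_k| <=
    bin_halfwidth``. Depths at the extremes ([0, 0.2] and [0.8, 1.0] with
    the default halfwidth) map to the outermost bins, so all of [0, 1] is
    covered.
    """
    depths = np.asarray(voxel_depths, dtype=float)
    bad = np.flatnonzero((depths < 0.0) | (depths > 1.0) | ~np.isfinite(depths))
    if bad.size:
        raise ValueError(f"depths outside [0, 1] at voxel indices {bad.tolist()}")
    membership: list[set[int]] = []
    for centre in DEPTH_BIN_CENTRES:
        inside = np.abs(depths - centre) <= bin_halfwidth
        membership.append(set(np.flatnonzero(inside).tolist()))
    return DepthAssignment(
        bin_centres=DEPTH_BIN_CENTRES,
        membership=membership,
        bin_halfwidth=float(bin_halfwidth),
    )
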