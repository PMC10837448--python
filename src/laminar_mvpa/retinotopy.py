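"""Retinotopic phase mapping, pRF grid fitting and ROI definition.

Phase-encoded mapping runs (rotating wedge, expanding ring) are analysed
by Fourier transform: each voxel's amplitude and phase at the stimulation
frequency, plus an F-ratio of squared amplitude at that frequency over the
mean squared amplitude at all other frequencies, index how retinotopically
driven the voxel is.

Population receptive fields are estimated with an isotropic Gaussian grid
model: 24 candidate sizes (standard deviations), with candidate centres of
each size spaced one standard deviation apart across the mapped field. For
every candidate, a predicted time course is built by overlapping the
Gaussian with the stimulus aperture frames and convolving with the
two-gamma HRF; the winning model maximises the squared Pearson correlation
(r^2) between prediction and data concatenated across the wedge and ring
runs.

Regions of interest collect voxels whose fitted pRF, with a spread of one
standard deviation, lies entirely inside a target region of the visual
field and whose fit exceeds an r^2 threshold; an optional stacked-column
completion adds all voxels of a passing voxel's cortical column so that
deep layers are represented without a superficial bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glm import HRFParams, _hrf_at
from .synth import StimulusAperture, VisualFieldGrid

__all__ = [
    "PhaseMapResult",
    "PRFModel",
    "PRFGrid",
    "Disc",
    "HalfPlane",
    "RegionIntersection",
    "RegionUnion",
    "semicircle",
    "ROI",
    "fourier_phase_map",
    "predict_prf_timecourse",
    "grid_predictions",
    "fit_prf_grid",
    "define_roi",
]


# ---------------------------------------------------------------------------
# Fourier phase mapping
# ---------------------------------------------------------------------------

@dataclass
class PhaseMapResult:
    """Per-voxel amplitude, phase and F-ratio at the stimulation frequency."""

    amplitude: np.ndarray
    phase: np.ndarray  # radians, in (-pi, pi]
    f_ratio: np.ndarray


def fourier_phase_map(
    run: np.ndarray,
    stimulation_period_s: float,
    tr_s: float,
    baseline_vols: int = 0,
) -> PhaseMapResult:
    """Amplitude/phase/F-ratio of each voxel at the stimulation frequency.

    ``run`` is voxels x time. ``baseline_vols`` volumes are dropped from
    both ends before the transform (phase-encoded runs open and close with
    a stimulus-free baseline); the remaining window must hold an integer
    number (>= 2) of stimulation cycles. The F-ratio is the squared
    amplitude at the stimulation frequency divided by the mean squared
    amplitude over all other nonzero frequencies.
    """
    run = np.atleast_2d(np.asarray(run, dtype=float))
    if baseline_vols:
        run = run[:, baseline_vols:-baseline_vols]
    n = run.shape[1]
    cycles = n * tr_s / stimulation_period_s
    k = int(round(cycles))
    if abs(cycles - k) > 1e-9 or k < 2:
        raise ValueError(
            "analysis window must contain an integer number (>= 2) of "
            f"stimulation cycles, got {cycles:g}"
        )
    spectrum = np.fft.rfft(run, axis=1)
    power = np.abs(spectrum) ** 2
    amplitude = np.abs(spectrum[:, k]) * 2.0 / n
    phase = np.angle(spectrum[:, k])
    others = np.ones(power.shape[1], dtype=bool)
    others[[0, k]] = False
    denom = power[:, others].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_ratio = np.where(denom > 0, power[:, k] / denom, 0.0)
    return PhaseMapResult(amplitude=amplitude, phase=phase, f_ratio=f_ratio)


# ---------------------------------------------------------------------------
# pRF grid model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRFModel:
    """Isotropic Gaussian pRF: centre (deg), size sigma (deg), fit r^2."""

    x: float
    y: float
    sigma: float
    r2: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must lie in [0, 1]")


@dataclass(frozen=True)
class PRFGrid:
    """Search grid: candidate sizes and centres.

    For each of the (by default 24, log-spaced) sigma levels, candidate
    centres form a square lattice spaced exactly one sigma apart, centred
    on fixation and restricted to ``|x|, |y| <= field_extent``.
    """

    sigma_levels: tuple[float, ...] = tuple(
        float(s) for s in np.geomspace(0.2, 4.8, 24)
    )
    field_extent: float = 6.0

    def __post_init__(self) -> None:
        if len(self.sigma_levels) < 1:
            raise ValueError("at least one sigma level required")
        if any(s <= 0 for s in self.sigma_levels):
            raise ValueError("sigma levels must be positive")

    def candidates(self) -> np.ndarray:
        """All (x, y, sigma) candidates, ordered by (sigma, x, y).

        The ordering implements the tie-break rule of the fit: smallest
        sigma first, then lexicographic centre.
        """
        rows = []
        for s in sorted(self.sigma_levels):
            n = int(np.floor(2.0 * self.field_extent / s)) + 1
            offs = (np.arange(n) - (n - 1) / 2.0) * s
            offs = offs[np.abs(offs) <= self.field_extent + 1e-12]
            for x in offs:
                for y in offs:
                    rows.append((x, y, s))
        return np.array(rows, dtype=float)


def predict_prf_timecourse(
    model: PRFModel | tuple[float, float, float],
    aperture: StimulusAperture,
    hrf: HRFParams = HRFParams(),
) -> np.ndarray:
    """Predicted response of a Gaussian pRF to an aperture sequence.

    The neural drive per frame is the sum over pixels of the binary
    aperture times the (peak-1) Gaussian; the drive is convolved with the
    two-gamma HRF sampled at the aperture TR. Output length equals the
    frame count.
    """
    if isinstance(model, PRFModel):
        x, y, s = model.x, model.y, model.sigma
    else:
        x, y, s = model
    g = aperture.grid.gaussian(x, y, s)
    drive = aperture.frames @ g
    kern = _hrf_at(np.arange(0.0, 32.0, aperture.tr_s), hrf)
    return np.convolve(drive, kern)[: aperture.n_frames]


def grid_predictions(
    grid: PRFGrid,
    apertures: list[StimulusAperture],
    hrf: HRFParams = HRFParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted time courses for every grid candidate.

    Returns ``(candidates, predictions)`` where ``candidates`` is (n, 3)
    rows of (x, y, sigma) in tie-break order and ``predictions`` is
    (n, total_frames) with the apertures' predictions concatenated.
    Computed with one matrix product per aperture; this is the costly step
    of the grid fit and can be reused across voxels.
    """
    cands = grid.candidates()
    vf = apertures[0].grid
    px, py = vf.pixel_centres()
    # (n_candidates, n_pixels) Gaussian lookup, built level by level
    parts = []
    for ap in apertures:
        if ap.grid != vf:
            raise ValueError("all apertures must share one visual-field grid")
        kern = _hrf_at(np.arange(0.0, 32.0, ap.tr_s), hrf)
        gauss = np.exp(
            -(
                (px[None, :] - cands[:, 0:1]) ** 2
                + (py[None, :] - cands[:, 1:2]) ** 2
            )
            / (2.0 * cands[:, 2:3] ** 2)
        )
        drive = gauss @ ap.frames.T  # (n_candidates, T)
        # FFT-based convolution over all candidates at once
        from scipy.signal import fftconvolve

        conv = fftconvolve(drive, kern[None, :], axes=1)[:, : ap.n_frames]
        parts.append(conv)
    return cands, np.hstack(parts)


def fit_prf_grid(
    voxel_ts: np.ndarray,
    apertures: list[StimulusAperture],
    grid: PRFGrid,
    hrf: HRFParams = HRFParams(),
    predictions: tuple[np.ndarray, np.ndarray] | None = None,
) -> PRFModel | list[PRFModel]:
    """Best-fitting grid pRF model for one voxel or a voxel x time matrix.

    The score is the squared Pearson correlation between the candidate's
    predicted time course and the observed time course, both concatenated
    across the given runs (amplitude and offset are implicitly free). Ties
    are broken towards the smallest sigma, then lexicographically smallest
    centre. An all-constant voxel gets an r^2 = 0 sentinel model.

    ``voxel_ts`` must be the mapping runs concatenated in the same order as
    ``apertures``. Pass ``predictions`` (from :func:`grid_predictions`) to
    amortise the grid evaluation across many voxels.
    """
    single = np.asarray(voxel_ts).ndim == 1
    data = np.atleast_2d(np.asarray(voxel_ts, dtype=float))
    if predictions is None:
        predictions = grid_predictions(grid, apertures, hrf)
    cands, preds = predictions
    if data.shape[1] != preds.shape[1]:
        raise ValueError(
            f"voxel_ts has {data.shape[1]} volumes but predictions have "
            f"{preds.shape[1]}"
        )

    pc = preds - preds.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(pc, axis=1)
    ok = pn > 0
    pc[ok] /= pn[ok, None]

    dc = data - data.mean(axis=1, keepdims=True)
    dn = np.linalg.norm(dc, axis=1)
    flat = dn == 0
    dc[~flat] /= dn[~flat, None]

    r2 = (dc @ pc.T) ** 2  # (n_voxels, n_candidates)
    r2[:, ~ok] = 0.0
    best = np.argmax(r2, axis=1)  # first max wins = tie-break order
    models = []
    for v, b in enumerate(best):
        if flat[v]:
            x, y, s = cands[0]
            models.append(PRFModel(x=x, y=y, sigma=s, r2=0.0))
        else:
            x, y, s = cands[b]
            models.append(PRFModel(x=x, y=y, sigma=s, r2=min(float(r2[v, b]), 1.0)))
    return models[0] if single else models


# ---------------------------------------------------------------------------
# Visual-field regions and ROI definition
# ---------------------------------------------------------------------------

class Region:
    """A target region of the visual field (degrees)."""

    def contains_disc(self, x: float, y: float, radius: float) -> bool:
        raise NotImplementedError

    def area_positive(self) -> bool:
        raise NotImplementedError

    def describe(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class Disc(Region):
    """Closed disc of given radius centred at (cx, cy)."""

    cx: float
    cy: float
    radius: float

    def contains_disc(self, x: float, y: float, radius: float) -> bool:
        return np.hypot(x - self.cx, y - self.cy) + radius <= self.radius + 1e-12

    def area_positive(self) -> bool:
        return self.radius > 0

    def describe(self) -> dict:
        return {"type": "disc", "cx": self.cx, "cy": self.cy, "radius": self.radius}


@dataclass(frozen=True)
class HalfPlane(Region):
    """Half-plane ``nx*x + ny*y >= offset`` (unbounded; combine with a disc)."""

    nx: float
    ny: float
    offset: float

    def contains_disc(self, x: float, y: float, radius: float) -> bool:
        norm = np.hypot(self.nx, self.ny)
        return (self.nx * x + self.ny * y - self.offset) / norm >= radius - 1e-12

    def area_positive(self) -> bool:
        return np.hypot(self.nx, self.ny) > 0

    def describe(self) -> dict:
        return {"type": "halfplane", "nx": self.nx, "ny": self.ny, "offset": self.offset}


@dataclass(frozen=True)
class RegionIntersection(Region):
    parts: tuple[Region, ...]

    def contains_disc(self, x: float, y: float, radius: float) -> bool:
        return all(p.contains_disc(x, y, radius) for p in self.parts)

    def area_positive(self) -> bool:
        return all(p.area_positive() for p in self.parts)

    def describe(self) -> dict:
        return {"type": "intersection", "parts": [p.describe() for p in self.parts]}


@dataclass(frozen=True)
class RegionUnion(Region):
    """Union of disjoint component regions.

    A disc counts as contained if it is contained in at least one
    component — the appropriate rule for unions of well-separated parts
    (e.g. the four semicircles along an illusory square's edges).
    """

    parts: tuple[Region, ...]

    def contains_disc(self, x: float, y: float, radius: float) -> bool:
        return any(p.contains_disc(x, y, radius) for p in self.parts)

    def area_positive(self) -> bool:
        return any(p.area_positive() for p in self.parts)

    def describe(self) -> dict:
        return {"type": "union", "parts": [p.describe() for p in self.parts]}


def semicircle(
    cx: float, cy: float, radius: float, edge_normal: tuple[float, float],
    edge_offset: float | None = None,
) -> RegionIntersection:
    """Half-disc: the part of a disc on the ``edge_normal`` side of its chord.

    ``edge_normal`` points from the straight edge into the region; the edge
    passes through the disc centre unless ``edge_offset`` (signed distance
    of the edge from the origin along the normal) is given.
    """
    nx, ny = edge_normal
    if edge_offset is None:
        norm = np.hypot(nx, ny)
        edge_offset = (nx * cx + ny * cy) / norm
        nx, ny = nx / norm, ny / norm
    return RegionIntersection(
        parts=(Disc(cx, cy, radius), HalfPlane(nx, ny, edge_offset))
    )


@dataclass
class ROI:
    """Voxels whose pRFs lie inside a visual-field region."""

    name: str
    region: Region
    voxel_indices: np.ndarray
    r2_threshold: float
    direct: set[int] = field(default_factory=set)
    completed: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.voxel_indices)


def define_roi(
    models: list[PRFModel],
    region: Region,
    r2_threshold: float,
    stacked_columns: np.ndarray | None = None,
    name: str = "roi",
) -> ROI:
    """Select voxels whose 1-sigma pRF disc lies inside ``region``.

    A voxel passes directly if its fit satisfies ``r2 > r2_threshold`` and
    the closed disc of radius one sigma around its centre is contained in
    the region (boundary inclusive). If ``stacked_columns`` (per-voxel
    cortical-column ids) is given, every voxel sharing a column with a
    directly passing voxel is added and flagged as completed — ensuring all
    depths of an identified column are represented.
    """
    if not region.area_positive():
        raise ValueError("region has zero area")
    direct = {
        v
        for v, m in enumerate(models)
        if m.r2 > r2_threshold and region.contains_disc(m.x, m.y, m.sigma)
    }
    completed: set[int] = set()
    if stacked_columns is not None:
        cols = np.asarray(stacked_columns)
        if len(cols) != len(models):
            raise ValueError("stacked_columns must have one entry per voxel")
        passing_cols = {cols[v] for v in direct}
        completed = {
            v
            for v in range(len(models))
            if cols[v] in passing_cols and v not in direct
        }
    members = np.array(sorted(direct | completed), dtype=int)
    return ROI(
        name=name,
        region=region,
        voxel_indices=members,
        r2_threshold=float(r2_threshold),
        direct=direct,
        completed=completed,
    )
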