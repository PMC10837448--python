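"""Seeded synthetic laminar-fMRI subjects with known ground truth.

Emulates a blocked V1 experiment at 7T-like timing: five stimulus
conditions (perception, imagery, illusory, amodal, mock) in two colours,
8-s blocks with 7-8-s jittered ISIs, six blocks per condition per run and
six runs at TR = 2 s; plus phase-encoded retinotopic mapping runs (a 22.5
degree wedge rotating anti-clockwise in 12 cycles of 64 s, and an expanding
ring in 8 cycles of 64 s, each flanked by 12-s baselines).

Every simulated voxel carries a ground-truth Gaussian population receptive
field (pRF), a cortical-depth coordinate (0 = white-matter boundary,
1 = pial surface; "deep" means low values), a vascular amplitude gain that
increases toward the pial surface, and condition/colour-specific multivoxel
pattern weights that are nonzero only inside a configured depth band — so
the depth at which content is decodable is known by construction.

Also simulates the binocular-rivalry imagery-strength pre-test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import HRFParams, _hrf_at

__all__ = [
    "CONDITIONS",
    "COLOURS",
    "VisualFieldGrid",
    "StimulusAperture",
    "GroundTruthVoxel",
    "ConditionEffect",
    "SubjectConfig",
    "SubjectData",
    "make_retinotopy_stimulus",
    "make_task_design",
    "simulate_subject",
    "simulate_rivalry_trials",
]

CONDITIONS = ("perception", "imagery", "illusory", "amodal", "mock")
COLOURS = ("red", "green")

#: Volumes per mapping run: 12 wedge cycles (or 8 ring cycles) of 64 s at
#: TR 2 s, plus a 12-s baseline before and after.
WEDGE_N_VOLS = 396
RING_N_VOLS = 268
CYCLE_S = 64.0
BASELINE_S = 12.0
WEDGE_WIDTH_DEG = 22.5

#: Volumes per task run at TR 2 s.
TASK_N_VOLS = 272
BLOCK_S = 8.0
ISI_RANGE_S = (7.0, 8.0)
ISI_RESOLUTION_S = 0.5
TASK_INITIAL_REST_S = 10.0


class ApertureError(ValueError):
    """Raised for unknown or malformed stimulus apertures."""


# ---------------------------------------------------------------------------
# Visual field geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VisualFieldGrid:
    """Square, fixation-centred pixel grid over the visual field.

    ``half_extent`` is the distance (degrees of visual angle) from fixation
    to the grid edge; pixel coordinates are the centres of an
    ``n_pixels_per_side`` x ``n_pixels_per_side`` lattice.
    """

    half_extent: float = 6.0
    n_pixels_per_side: int = 32

    def __post_init__(self) -> None:
        if self.n_pixels_per_side < 8:
            raise ValueError("n_pixels_per_side must be >= 8")
        if self.half_extent <= 0:
            raise ValueError("half_extent must be positive")

    @property
    def pixel_spacing(self) -> float:
        return 2.0 * self.half_extent / self.n_pixels_per_side

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) coordinates of all pixel centres, degrees."""
        step = self.pixel_spacing
        coords = -self.half_extent + step * (np.arange(self.n_pixels_per_side) + 0.5)
        xx, yy = np.meshgrid(coords, coords)
        return xx.ravel(), yy.ravel()

    def gaussian(self, x0: float, y0: float, sigma: float) -> np.ndarray:
        """Unnormalised (peak-1) isotropic Gaussian over the pixel grid."""
        px, py = self.pixel_centres()
        return np.exp(-((px - x0) ** 2 + (py - y0) ** 2) / (2.0 * sigma**2))


@dataclass
class StimulusAperture:
    """Per-volume binary occupancy of a stimulus over the pixel grid."""

    grid: VisualFieldGrid
    frames: np.ndarray  # (n_frames, n_pixels) in {0, 1}
    tr_s: float
    kind: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        n_pix = self.grid.n_pixels_per_side**2
        if self.frames.ndim != 2 or self.frames.shape[1] != n_pix:
            raise ApertureError("frames must be (n_frames, n_pixels)")
        if not np.isin(self.frames, (0, 1)).all():
            raise ApertureError("frame values must be binary")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def make_retinotopy_stimulus(
    kind: str,
    grid: VisualFieldGrid,
    tr_s: float = 2.0,
) -> StimulusAperture:
    """Binary aperture frames for a phase-encoded mapping run.

    ``wedge``: a 22.5-degree sector rotating anti-clockwise, 12 cycles of
    64 s (396 frames at TR 2 s including the two 12-s baselines).
    ``ring``: an annulus expanding from fixation to the grid edge, 8 cycles
    of 64 s (268 frames).
    """
    if kind == "wedge":
        n_cycles = 12
    elif kind == "ring":
        n_cycles = 8
    else:
        raise ApertureError(f"unknown stimulus kind: {kind!r}")

    frames_per_cycle = int(round(CYCLE_S / tr_s))
    n_baseline = int(round(BASELINE_S / tr_s))
    px, py = grid.pixel_centres()
    ecc = np.hypot(px, py)
    in_field = ecc <= grid.half_extent

    cycle = np.zeros((frames_per_cycle, px.size))
    if kind == "wedge":
        angle = np.degrees(np.arctan2(py, px)) % 360.0
        width = WEDGE_WIDTH_DEG
        for f in range(frames_per_cycle):
            start = 360.0 * f / frames_per_cycle  # anti-clockwise sweep
            rel = (angle - start) % 360.0
            cycle[f] = ((rel < width) & in_field).astype(float)
    else:
        thickness = grid.half_extent / 8.0
        for f in range(frames_per_cycle):
            inner = grid.half_extent * f / frames_per_cycle
            cycle[f] = ((ecc >= inner) & (ecc < inner + thickness) & in_field).astype(float)

    stim = np.tile(cycle, (n_cycles, 1))
    baseline = np.zeros((n_baseline, px.size))
    frames = np.vstack([baseline, stim, baseline])
    return StimulusAperture(grid=grid, frames=frames, tr_s=tr_s, kind=kind)


def task_block_aperture(
    events: pd.DataFrame,
    grid: VisualFieldGrid,
    n_vols: int = TASK_N_VOLS,
    tr_s: float = 2.0,
    radius: float = 3.1,
) -> StimulusAperture:
    """Central-disc occupancy frames for a task run (kind ``task_block``)."""
    px, py = grid.pixel_centres()
    disc = (np.hypot(px, py) <= radius).astype(float)
    frames = np.zeros((n_vols, px.size))
    t = np.arange(n_vols) * tr_s
    for _, row in events.iterrows():
        on = (t >= row["onset_s"]) & (t < row["onset_s"] + row["duration_s"])
        frames[on] = disc
    return StimulusAperture(grid=grid, frames=frames, tr_s=tr_s, kind="task_block")


# ---------------------------------------------------------------------------
# Task design
# ---------------------------------------------------------------------------

def make_task_design(n_runs: int, seed: int) -> pd.DataFrame:
    """Randomised balanced block design.

    Per run: each of the five conditions appears six times, three per
    colour, in a seeded random order; blocks last 8 s and are separated by
    ISIs drawn uniformly from [7, 8] s and rounded to 0.5 s.

    Returns a tidy table with columns ``run``, ``condition``, ``colour``,
    ``onset_s``, ``duration_s``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 (leave-one-run-out needs >= 2 folds)")
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(n_runs):
        blocks = [
            (cond, colour)
            for cond in CONDITIONS
            for colour in COLOURS
            for _ in range(3)
        ]
        order = rng.permutation(len(blocks))
        onset = TASK_INITIAL_REST_S
        for idx in order:
            cond, colour = blocks[idx]
            rows.append(
                {
                    "run": run,
                    "condition": cond,
                    "colour": colour,
                    "onset_s": onset,
                    "duration_s": BLOCK_S,
                }
            )
            isi = rng.uniform(*ISI_RANGE_S)
            isi = round(isi / ISI_RESOLUTION_S) * ISI_RESOLUTION_S
            onset += BLOCK_S + isi
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthVoxel:
    """Ground truth for one simulated voxel."""

    prf_x: float
    prf_y: float
    prf_sigma: float
    depth: float
    baseline_intensity: float
    amplitude_gain: float
    pattern_weights: dict  # (condition, colour) -> fractional amplitude
    column: int = 0

    def __post_init__(self) -> None:
        if self.prf_sigma <= 0:
            raise ValueError("prf_sigma must be positive")
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("depth must lie in [0, 1]")
        if self.amplitude_gain <= 0:
            raise ValueError("amplitude_gain must be positive")


@dataclass(frozen=True)
class ConditionEffect:
    """Pattern effect size for one condition and its target depth band.

    ``effect_size`` is the fractional BOLD amplitude (e.g. 0.02 = 2% signal
    change per unit pattern weight); the colour pattern is injected only
    into voxels whose depth lies in ``depth_band`` (inclusive).
    """

    effect_size: float = 0.0
    depth_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def default_condition_effects() -> dict[str, ConditionEffect]:
    """Study-like effect layout under the 0 = white-matter convention.

    Perception is decodable at all depths; imagery only in deep depths,
    illusory (and weakly amodal) only in superficial depths; the mock
    control carries no colour information.
    """
    return {
        "perception": ConditionEffect(0.020, (0.0, 1.0)),
        "imagery": ConditionEffect(0.015, (0.0, 0.35)),
        "illusory": ConditionEffect(0.015, (0.65, 1.0)),
        "amodal": ConditionEffect(0.008, (0.65, 1.0)),
        "mock": ConditionEffect(0.0, None),
    }


@dataclass
class SubjectConfig:
    """Generator settings for one synthetic subject.

    Voxels are organised in cortical columns: all voxels of a column share
    one pRF centre and size (the hypercolumn assumption) and are stacked at
    jittered depths around the six canonical depth levels. The vascular
    gain is ``1 + gain_slope * depth`` (superficial bias), and the noise sd
    is ``noise_frac`` times the voxel's mean intensity, so the amplitude
    gradient carries no information after per-voxel rescaling.
    """

    n_columns: int = 40
    depths_per_column: int = 6
    n_runs: int = 6
    tr_s: float = 2.0
    grid: VisualFieldGrid = field(default_factory=VisualFieldGrid)
    prf_max_ecc: float = 4.5
    sigma_range: tuple[float, float] = (0.5, 2.0)
    baseline_intensity: float = 800.0
    gain_slope: float = 0.6
    noise_frac: float = 0.01
    common_response: float = 0.01
    retinotopy_response: float = 0.05
    effects: dict[str, ConditionEffect] = field(
        default_factory=default_condition_effects
    )
    depth_jitter: float = 0.05
    prf_candidates: np.ndarray | None = None  # (n, 3) rows of (x, y, sigma)

    @property
    def n_voxels(self) -> int:
        return self.n_columns * self.depths_per_column

    def validated(self) -> "SubjectConfig":
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")
        if self.gain_slope < 0:
            raise ValueError("gain_slope must be >= 0")
        for cond in self.effects:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
        return self


@dataclass
class SubjectData:
    """One synthetic subject: runs, design, apertures and ground truth."""

    task_runs: list[np.ndarray]
    retinotopy_runs: dict[str, np.ndarray]
    design: pd.DataFrame
    truth: list[GroundTruthVoxel]
    seed: int
    config: SubjectConfig
    apertures: dict[str, StimulusAperture] = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.task_runs[0].shape[0]

    @property
    def depths(self) -> np.ndarray:
        return np.array([v.depth for v in self.truth])


def _in_band(depth: float, band: tuple[float, float] | None) -> bool:
    return band is not None and band[0] <= depth <= band[1]


def _condition_regressors(
    events: pd.DataFrame, n_vols: int, tr_s: float, hrf: HRFParams
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """HRF-convolved boxcar per (condition, colour), sampled at the TR."""
    from .glm import _convolve_boxcar

    cols, keys = [], []
    for cond in CONDITIONS:
        for colour in COLOURS:
            grp = events[(events["condition"] == cond) & (events["colour"] == colour)]
            cols.append(
                _convolve_boxcar(
                    grp["onset_s"].to_numpy(),
                    grp["duration_s"].to_numpy(),
                    n_vols,
                    tr_s,
                    hrf,
                )
            )
            keys.append((cond, colour))
    return np.column_stack(cols), keys


def simulate_subject(
    config: SubjectConfig, seed: int, hrf: HRFParams = HRFParams()
) -> SubjectData:
    """Generate one synthetic subject with full ground truth.

    Each voxel's task time course is::

        baseline * gain * (1 + common + pattern responses, HRF-convolved)
        + Gaussian noise with sd = noise_frac * baseline * gain

    where the (condition, colour) pattern amplitude is ``effect_size * w_v``
    for red and ``-effect_size * w_v`` for green (``w_v`` a seeded standard
    normal per voxel and condition), and is zero outside the condition's
    target depth band. Retinotopy time courses are driven by the overlap of
    the true pRF Gaussian with the wedge/ring aperture frames, convolved
    with the same HRF. Identical config + seed reproduce identical data.
    """
    config = config.validated()
    rng = np.random.default_rng(seed)
    grid = config.grid

    # --- ground-truth voxels, stacked in columns -------------------------
    from .laminar import DEPTH_BIN_CENTRES

    voxels: list[GroundTruthVoxel] = []
    band_has_voxel = {cond: False for cond in config.effects}
    col_prfs = []
    for c in range(config.n_columns):
        if config.prf_candidates is not None:
            cand = np.asarray(config.prf_candidates, dtype=float)
            cand = cand[np.hypot(cand[:, 0], cand[:, 1]) <= config.prf_max_ecc]
            if len(cand) == 0:
                raise ValueError("no pRF candidates within prf_max_ecc")
            x0, y0, sig = cand[rng.integers(0, len(cand))]
        else:
            r = config.prf_max_ecc * np.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2.0 * np.pi)
            x0, y0 = r * np.cos(th), r * np.sin(th)
            lo, hi = config.sigma_range
            sig = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        col_prfs.append((x0, y0, sig))
        if config.depths_per_column == len(DEPTH_BIN_CENTRES):
            depths = np.clip(
                np.asarray(DEPTH_BIN_CENTRES)
                + rng.uniform(-config.depth_jitter, config.depth_jitter, 6),
                0.0,
                1.0,
            )
        else:
            depths = rng.uniform(0.0, 1.0, config.depths_per_column)
        for d in depths:
            gain = 1.0 + config.gain_slope * d
            voxels.append(
                GroundTruthVoxel(
                    prf_x=float(x0),
                    prf_y=float(y0),
                    prf_sigma=float(sig),
                    depth=float(d),
                    baseline_intensity=config.baseline_intensity,
                    amplitude_gain=gain,
                    pattern_weights={},
                    column=c,
                )
            )
            for cond, eff in config.effects.items():
                if _in_band(d, eff.depth_band):
                    band_has_voxel[cond] = True
    for cond, eff in config.effects.items():
        if eff.effect_size > 0 and not band_has_voxel[cond]:
            raise ValueError(
                f"condition {cond!r} has nonzero effect but no voxel in its depth band"
            )

    n_vox = len(voxels)
    depths_arr = np.array([v.depth for v in voxels])
    gains = np.array([v.amplitude_gain for v in voxels])

    # --- colour patterns: antisymmetric, depth-band gated -----------------
    pattern = np.zeros((n_vox, len(CONDITIONS) * 2))
    raw_w = {cond: rng.standard_normal(n_vox) for cond in CONDITIONS}
    keys = [(cond, colour) for cond in CONDITIONS for colour in COLOURS]
    for k, (cond, colour) in enumerate(keys):
        eff = config.effects.get(cond, ConditionEffect())
        if eff.effect_size == 0 or eff.depth_band is None:
            continue
        in_band = (depths_arr >= eff.depth_band[0]) & (depths_arr <= eff.depth_band[1])
        sign = 1.0 if colour == "red" else -1.0
        pattern[:, k] = sign * eff.effect_size * raw_w[cond] * in_band
    weights_records = [
        {key: float(pattern[v, k]) for k, key in enumerate(keys)}
        for v in range(n_vox)
    ]
    voxels = [
        dataclasses.replace(vox, pattern_weights=weights_records[v])
        for v, vox in enumerate(voxels)
    ]

    # --- task runs --------------------------------------------------------
    design = make_task_design(config.n_runs, int(rng.integers(0, 2**31 - 1)))
    base = config.baseline_intensity * gains  # (n_vox,)
    noise_sd = config.noise_frac * base
    task_runs = []
    for run in range(config.n_runs):
        events = design[design["run"] == run]
        X, _ = _condition_regressors(events, TASK_N_VOLS, config.tr_s, hrf)
        frac = config.common_response * X.sum(axis=1)  # (T,)
        signal = 1.0 + frac[None, :] + pattern @ X.T  # (n_vox, T)
        ts = base[:, None] * signal
        ts = ts + noise_sd[:, None] * rng.standard_normal(ts.shape)
        task_runs.append(ts)

    # --- retinotopy runs --------------------------------------------------
    wedge = make_retinotopy_stimulus("wedge", grid, config.tr_s)
    ring = make_retinotopy_stimulus("ring", grid, config.tr_s)
    gauss = np.stack([grid.gaussian(x, y, s) for x, y, s in col_prfs])  # (cols, pix)
    gauss /= gauss.sum(axis=1, keepdims=True)
    kern = _hrf_at(np.arange(0.0, 32.0, config.tr_s), hrf)
    retinotopy_runs = {}
    for ap in (wedge, ring):
        drive = gauss @ ap.frames.T  # (cols, T), in [0, 1]
        conv = np.apply_along_axis(
            lambda d: np.convolve(d, kern)[: ap.n_frames], 1, drive
        )
        col_idx = np.array([v.column for v in voxels])
        sig = 1.0 + config.retinotopy_response * conv[col_idx]
        ts = base[:, None] * sig
        ts = ts + noise_sd[:, None] * rng.standard_normal(ts.shape)
        retinotopy_runs[ap.kind] = ts

    return SubjectData(
        task_runs=task_runs,
        retinotopy_runs=retinotopy_runs,
        design=design,
        truth=voxels,
        seed=seed,
        config=config,
        apertures={"wedge": wedge, "ring": ring},
    )


# ---------------------------------------------------------------------------
# Behavioural pre-test simulation
# ---------------------------------------------------------------------------

def simulate_rivalry_trials(
    n_trials: int,
    true_priming: float,
    catch_fraction: float = 0.1,
    mixed_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one binocular-rivalry imagery-strength run.

    Catch trials (a physical colour mixture shown to both eyes) are
    allocated deterministically as ``round(n_trials * catch_fraction)``
    trials at seeded random positions and answered "mixed". On non-catch
    trials the report is "mixed" with probability ``mixed_rate``; otherwise
    it matches the cued colour with probability ``true_priming``.
    """
    for name, p in (
        ("true_priming", true_priming),
        ("catch_fraction", catch_fraction),
        ("mixed_rate", mixed_rate),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_catch = int(round(n_trials * catch_fraction))
    is_catch = np.zeros(n_trials, dtype=bool)
    is_catch[rng.choice(n_trials, size=n_catch, replace=False)] = True
    cue_idx = rng.integers(0, 2, size=n_trials)
    vividness = rng.integers(1, 5, size=n_trials)
    mixed = rng.uniform(size=n_trials) < mixed_rate
    primed = rng.uniform(size=n_trials) < true_priming
    cues = np.array(COLOURS)[cue_idx]
    others = np.array(COLOURS)[1 - cue_idx]
    response = np.where(
        is_catch | mixed, "mixed", np.where(primed, cues, others)
    )
    return pd.DataFrame(
        {
            "cue": cues,
            "response": response,
            "vividness": vividness,
            "is_catch": is_catch,
        }
    )
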