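"""Trial-wise general linear modelling of task runs.

Builds the canonical two-gamma haemodynamic response function (HRF),
constructs boxcar design matrices from block-design event tables, estimates
per-trial (or per-condition) response amplitudes by ordinary least squares,
filters voxels with implausibly low raw intensity, and summarises response
amplitude across cortical-depth bins.

The trial-wise betas produced here (:class:`BetaMatrix`) are the substrate
for all multivariate decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "HRFParams",
    "BetaMatrix",
    "two_gamma_hrf",
    "build_design_matrix",
    "estimate_trial_betas",
    "filter_low_intensity_voxels",
    "depth_amplitude_profile",
]

#: Time resolution (s) at which boxcars are built and convolved before
#: resampling to the TR grid. Fine enough to represent 0.5-s onset jitter.
DESIGN_DT_S = 0.1


@dataclass(frozen=True)
class HRFParams:
    """Parameters of the canonical two-gamma HRF.

    The kernel is a difference of two gamma densities whose *modes* sit
    exactly at ``time_to_peak_s`` and ``time_to_undershoot_s``; the positive
    and negative lobes have peak-amplitude ratio ``pos_neg_ratio``.
    """

    time_to_peak_s: float = 5.0
    time_to_undershoot_s: float = 15.0
    pos_neg_ratio: float = 6.0
    onset_delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.time_to_peak_s < 0 or self.time_to_undershoot_s < 0:
            raise ValueError("HRF peak times must be non-negative")
        if self.pos_neg_ratio <= 0:
            raise ValueError("pos_neg_ratio must be positive")


@dataclass
class BetaMatrix:
    """Trial x voxel response estimates with trial labels.

    ``values[t, v]`` is the OLS beta of trial ``t`` for voxel ``v``.
    ``labels`` has one row per trial with columns ``run``, ``condition``,
    ``colour`` and ``onset_s``, ordered by (run, onset).
    """

    values: np.ndarray
    labels: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x voxels)")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels must have one row per trial")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("beta values must be finite")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def select(self, mask: np.ndarray) -> "BetaMatrix":
        """Row-subset by a boolean trial mask."""
        mask = np.asarray(mask, dtype=bool)
        return BetaMatrix(
            self.values[mask],
            self.labels.loc[mask].reset_index(drop=True),
            dict(self.meta),
        )


def two_gamma_hrf(
    params: HRFParams = HRFParams(),
    tr_s: float = 2.0,
    duration_s: float = 30.0,
) -> np.ndarray:
    """Sample the two-gamma HRF kernel at the given repetition time.

    Each gamma density uses unit scale, so a density with shape ``m + 1``
    has its mode exactly at ``m`` seconds. Both lobes are peak-normalised
    before being combined with peak-amplitude ratio ``pos_neg_ratio``; the
    final kernel is normalised to peak 1.
    """
    if duration_s < params.time_to_undershoot_s:
        raise ValueError(
            "duration_s must cover the undershoot "
            f"({params.time_to_undershoot_s} s)"
        )
    t = np.arange(0.0, duration_s + 0.5 * tr_s, tr_s) - params.onset_delay_s
    return _hrf_at(t, params)


def _hrf_at(t: np.ndarray, params: HRFParams) -> np.ndarray:
    """Evaluate the peak-normalised two-gamma kernel at times ``t`` (s)."""
    a_pos = params.time_to_peak_s + 1.0
    a_neg = params.time_to_undershoot_s + 1.0
    pos = _gamma_dist.pdf(t, a_pos)
    neg = _gamma_dist.pdf(t, a_neg)
    pos = pos / _gamma_dist.pdf(params.time_to_peak_s, a_pos)
    neg = neg / _gamma_dist.pdf(params.time_to_undershoot_s, a_neg)
    h = pos - neg / params.pos_neg_ratio
    h[t < 0] = 0.0
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def _convolve_boxcar(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_vols: int,
    tr_s: float,
    hrf: HRFParams,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at the TR grid."""
    run_len_s = n_vols * tr_s
    n_fine = int(round(run_len_s / DESIGN_DT_S))
    box = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / DESIGN_DT_S))
        i1 = int(round((onset + dur) / DESIGN_DT_S))
        box[i0:i1] = 1.0
    t_kernel = np.arange(0.0, 32.0, DESIGN_DT_S)
    kernel = _hrf_at(t_kernel, hrf)
    fine = np.convolve(box, kernel)[:n_fine] * DESIGN_DT_S
    idx = np.round(np.arange(n_vols) * tr_s / DESIGN_DT_S).astype(int)
    return fine[idx]


def build_design_matrix(
    events: pd.DataFrame,
    hrf: HRFParams,
    n_vols: int,
    tr_s: float = 2.0,
    per_trial: bool = True,
    nuisance_events: pd.DataFrame | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build a GLM design matrix for one run.

    Parameters
    ----------
    events
        One run's event table with columns ``onset_s``, ``duration_s``,
        ``condition``, ``colour``.
    per_trial
        If true, one HRF-convolved boxcar column per block (for trial-wise
        beta estimation); otherwise one column per condition x colour.
    nuisance_events
        Optional extra events (e.g. end-of-run target/surround mapping
        blocks) regressed out as additional columns, one per ``condition``
        label present.

    Returns
    -------
    (matrix, column_labels)
        ``matrix`` is ``n_vols x n_columns`` with a trailing intercept.
    """
    required = {"onset_s", "duration_s", "condition", "colour"}
    if len(events) and not required.issubset(events.columns):
        raise ValueError(f"events table needs columns {sorted(required)}")
    if len(events):
        ends = events["onset_s"] + events["duration_s"]
        if ends.max() > n_vols * tr_s:
            raise ValueError("events extend past the end of the run")

    columns: list[np.ndarray] = []
    names: list[str] = []
    if len(events) == 0:
        pass
    elif per_trial:
        ordered = events.sort_values("onset_s").reset_index(drop=True)
        for i, row in ordered.iterrows():
            columns.append(
                _convolve_boxcar(
                    np.array([row["onset_s"]]),
                    np.array([row["duration_s"]]),
                    n_vols,
                    tr_s,
                    hrf,
                )
            )
            names.append(f"trial{i:02d}_{row['condition']}_{row['colour']}")
    else:
        for (cond, colour), grp in events.groupby(
            ["condition", "colour"], sort=True
        ):
            onsets = grp["onset_s"].to_numpy()
            if _any_overlap(onsets, grp["duration_s"].to_numpy()):
                raise ValueError(
                    f"overlapping events in column {cond}_{colour}"
                )
            columns.append(
                _convolve_boxcar(
                    onsets, grp["duration_s"].to_numpy(), n_vols, tr_s, hrf
                )
            )
            names.append(f"{cond}_{colour}")
    if nuisance_events is not None and len(nuisance_events):
        for cond, grp in nuisance_events.groupby("condition", sort=True):
            columns.append(
                _convolve_boxcar(
                    grp["onset_s"].to_numpy(),
                    grp["duration_s"].to_numpy(),
                    n_vols,
                    tr_s,
                    hrf,
                )
            )
            names.append(f"nuisance_{cond}")
    columns.append(np.ones(n_vols))
    names.append("intercept")
    return np.column_stack(columns), names


def _any_overlap(onsets: np.ndarray, durations: np.ndarray) -> bool:
    order = np.argsort(onsets)
    o, d = onsets[order], durations[order]
    return bool(np.any(o[1:] < o[:-1] + d[:-1]))


def estimate_trial_betas(
    run_ts: np.ndarray,
    design: np.ndarray,
    names: list[str],
    labels: pd.DataFrame,
) -> BetaMatrix:
    """Ordinary-least-squares per-trial betas for one run.

    ``run_ts`` is voxels x time; ``design`` the per-trial matrix from
    :func:`build_design_matrix`; ``labels`` one row per trial column, in
    the same (onset) order. The intercept and any nuisance columns are
    estimated but not returned.
    """
    run_ts = np.asarray(run_ts, dtype=float)
    design = np.asarray(design, dtype=float)
    if run_ts.shape[1] != design.shape[0]:
        raise ValueError("time dimension of run_ts and design disagree")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = _collinear_columns(design, names)
        raise ValueError(
            f"design matrix is rank deficient; collinear columns: {collinear}"
        )
    coef, *_ = np.linalg.lstsq(design, run_ts.T, rcond=None)
    trial_idx = [i for i, n in enumerate(names) if n.startswith("trial")]
    if len(trial_idx) != len(labels):
        raise ValueError("labels must match the number of trial columns")
    return BetaMatrix(coef[trial_idx, :], labels.reset_index(drop=True))


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = piv[np.flatnonzero(diag < tol)]
    bad = np.concatenate([bad, piv[len(diag):]]) if len(piv) > len(diag) else bad
    return [names[i] for i in sorted(bad)]


def filter_low_intensity_voxels(
    run_ts_list: list[np.ndarray], threshold: float = 100.0
) -> np.ndarray:
    """Mask of voxels whose grand-mean raw intensity is at least ``threshold``.

    Voxels with raw mean BOLD intensity below the threshold (default 100
    scanner units) carry essentially no tissue signal and are removed before
    decoding. A voxel at exactly the threshold is retained.
    """
    grand = np.hstack([np.asarray(r, dtype=float) for r in run_ts_list])
    return grand.mean(axis=1) >= threshold


def depth_amplitude_profile(
    betas: BetaMatrix,
    assignment,
    condition: str | None = None,
) -> pd.DataFrame:
    """Mean response amplitude per cortical-depth bin.

    For each depth bin, averages the per-voxel condition-mean beta over the
    bin's member voxels. Returns a tidy frame with ``depth``, ``mean`` and
    ``sd`` (dispersion across member voxels). Used to exhibit the
    superficial vascular amplitude gradient, which per-depth decoding is
    insensitive to.
    """
    if condition is not None:
        mask = (betas.labels["condition"] == condition).to_numpy()
        if not mask.any():
            raise ValueError(f"no trials of condition {condition!r}")
        values = betas.values[mask]
    else:
        values = betas.values
    voxel_mean = values.mean(axis=0)
    rows = []
    for centre, members in zip(assignment.bin_centres, assignment.membership):
        if len(members) == 0:
            raise ValueError(f"depth bin at {centre} is empty")
        sel = voxel_mean[np.asarray(sorted(members), dtype=int)]
        rows.append({"depth": centre, "mean": sel.mean(), "sd": sel.std(ddof=1) if len(sel) > 1 else 0.0})
    return pd.DataFrame(rows)
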