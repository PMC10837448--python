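"""End-to-end conveniences: subject -> betas -> per-depth decoding.

Chains the standard analysis path on one (typically simulated) subject:
low-intensity voxel filtering, per-run trial-wise GLM with the two-gamma
HRF, cortical-depth bin assignment, and per-condition leave-one-run-out
colour decoding in every depth bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decoding import DecoderConfig, decode_subject_colours
from .glm import (
    BetaMatrix,
    HRFParams,
    build_design_matrix,
    estimate_trial_betas,
    filter_low_intensity_voxels,
)
from .laminar import DepthAssignment, assign_depth_bins
from .synth import SubjectData

__all__ = ["subject_betas", "subject_depth_assignment", "decode_subject"]


def subject_betas(
    subject: SubjectData, hrf: HRFParams = HRFParams()
) -> BetaMatrix:
    """Trial-wise betas for all runs of one subject.

    Removes voxels whose raw mean intensity is below 100, fits one
    per-trial OLS model per run and stacks the rows across runs. The
    retained voxels' original indices and depths are carried in ``meta``.
    """
    mask = filter_low_intensity_voxels(subject.task_runs)
    kept = np.flatnonzero(mask)
    parts = []
    for run in sorted(subject.design["run"].unique()):
        events = (
            subject.design[subject.design["run"] == run]
            .sort_values("onset_s")
            .reset_index(drop=True)
        )
        X, names = build_design_matrix(
            events,
            hrf,
            n_vols=subject.task_runs[run].shape[1],
            tr_s=subject.config.tr_s,
            per_trial=True,
        )
        parts.append(
            estimate_trial_betas(
                subject.task_runs[run][mask], X, names, events
            )
        )
    values = np.vstack([p.values for p in parts])
    labels = pd.concat([p.labels for p in parts], ignore_index=True)
    depths = subject.depths[kept]
    return BetaMatrix(
        values,
        labels,
        meta={"voxel_indices": kept, "depths": depths},
    )


def subject_depth_assignment(betas: BetaMatrix) -> DepthAssignment:
    """Depth-bin assignment for the voxels retained in ``betas``."""
    return assign_depth_bins(betas.meta["depths"])


def decode_subject(
    subject: SubjectData,
    config: DecoderConfig = DecoderConfig(),
    hrf: HRFParams = HRFParams(),
) -> pd.DataFrame:
    """Full single-subject pipeline: tidy per-fold accuracy table.

    Returns rows (condition, depth, fold, accuracy, n_voxels) from
    leave-one-run-out red-vs-green decoding of every condition in every
    depth bin.
    """
    betas = subject_betas(subject, hrf)
    assignment = subject_depth_assignment(betas)
    return decode_subject_colours(betas, assignment, config)
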