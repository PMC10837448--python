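"""Statistical inference on decoding accuracies.

First level: one-sided bootstrap-of-the-mean tests of per-subject decoding
accuracy against chance (50%), with Benjamini-Hochberg FDR correction over
the family of (depth x condition x ROI) comparisons and 90% confidence
intervals (5th/95th percentiles of the bootstrapped means, matching the
one-sided test).

Second level: a linear mixed model of decoding accuracy parameterised
across cortical depth (treated as a continuous covariate), with fixed
effects for depth, experiment, condition and all their interactions, and
per-subject random intercept, depth slope and condition x depth slope,
fitted by REML. A companion model checks that per-depth voxel counts show
no depth trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BootstrapResult",
    "LMMFit",
    "bootstrap_mean_test",
    "fdr_adjust",
    "fit_depth_lmm",
    "check_depth_voxel_balance",
]


@dataclass
class BootstrapResult:
    """One-sided bootstrap test of a mean accuracy against chance."""

    mean_accuracy: float
    p_raw: float
    ci90: tuple[float, float]
    n_boot: int
    chance: float
    p_adj: float | None = None


def bootstrap_mean_test(
    accuracies: np.ndarray,
    chance: float = 0.5,
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap the across-subject mean accuracy against chance.

    Subjects are resampled with replacement ``n_boot`` times; the one-sided
    p-value uses the add-one rule ``p = (1 + #{resampled means <= chance})
    / (n_boot + 1)`` (so p is never exactly 0), and the 90% CI is the
    empirical 5th/95th percentile of the resampled means. The accuracy
    vector is sorted before resampling, making the result invariant to
    subject order under a fixed seed.
    """
    acc = np.sort(np.asarray(accuracies, dtype=float))
    if acc.size < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, acc.size, size=(n_boot, acc.size))
    means = acc[idx].mean(axis=1)
    p_raw = (1 + int(np.sum(means <= chance))) / (n_boot + 1)
    ci = (float(np.percentile(means, 5)), float(np.percentile(means, 95)))
    return BootstrapResult(
        mean_accuracy=float(acc.mean()),
        p_raw=float(p_raw),
        ci90=ci,
        n_boot=n_boot,
        chance=chance,
    )


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LMMFit:
    """Mixed-model fit summary.

    ``params`` has one row per fixed effect: estimate, se, t, df, p and a
    95% CI. ``t`` is the Wald statistic; the reported df is the residual
    convention ``nobs - n_fixed_effects`` and is stated alongside because
    df conventions differ between mixed-model implementations.
    """

    params: pd.DataFrame
    method: str
    degenerate: bool = False
    random_structure: str = ""

    def effect(self, name: str) -> pd.Series:
        return self.params.set_index("name").loc[name]


def _wald_table(result, names: list[str], df: int) -> pd.DataFrame:
    est = np.asarray(result.fe_params)
    se = np.asarray(result.bse_fe)
    t = est / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    half = sps.t.ppf(0.975, df) * se
    return pd.DataFrame(
        {
            "name": names,
            "estimate": est,
            "se": se,
            "t": t,
            "df": df,
            "p": p,
            "ci_low": est - half,
            "ci_high": est + half,
        }
    )


def _fit_mixed(
    y: np.ndarray,
    fixed: pd.DataFrame,
    re_cols: list[str],
    groups: np.ndarray,
    fallback_re: list[str],
) -> LMMFit:
    """REML MixedLM fit with a degeneracy fallback on the random structure."""
    exog = fixed.to_numpy()
    exog_re = fixed[re_cols].to_numpy() if re_cols else None

    def run(re_mat, re_names):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, exog, groups=groups, exog_re=re_mat)
            return model.fit(reml=True, method="lbfgs", maxiter=500), re_names

    result, re_names = run(exog_re, re_cols)
    degenerate = False
    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    if cov_re.size and (
        not np.all(np.isfinite(cov_re))
        or np.min(np.linalg.eigvalsh(cov_re)) < 1e-10 * max(1.0, cov_re.max())
    ):
        degenerate = True
        if fallback_re != re_cols:
            result, re_names = run(fixed[fallback_re].to_numpy(), fallback_re)
    df = len(y) - fixed.shape[1]
    return LMMFit(
        params=_wald_table(result, list(fixed.columns), df),
        method="REML",
        degenerate=degenerate,
        random_structure=" + ".join(re_names),
    )


def fit_depth_lmm(
    table: pd.DataFrame,
    condition_order: tuple[str, str] = ("imagery", "illusory"),
) -> LMMFit:
    """Depth-parameterised linear mixed model of decoding accuracy.

    ``table`` needs columns ``subject``, ``experiment``, ``condition``,
    ``depth`` (continuous bin centre in [0, 1]) and ``accuracy``. Fixed
    effects: intercept, depth, experiment, condition and all two- and
    three-way interactions; random effects across subjects: intercept,
    depth and condition x depth. Condition and experiment are coded 0/1
    (``condition_order[0]`` = 0; experiments in sorted order). If the full
    random structure is singular the model is refitted with random
    intercept + depth and flagged ``degenerate``.

    With a single experiment level, the experiment terms are dropped.
    """
    required = {"subject", "experiment", "condition", "depth", "accuracy"}
    if not required.issubset(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    conds = set(table["condition"].unique())
    if conds != set(condition_order):
        raise ValueError(
            f"expected exactly conditions {condition_order}, got {sorted(conds)}"
        )
    for subj, grp in table.groupby("subject"):
        if grp["depth"].nunique() < 2 or grp["condition"].nunique() < 2:
            raise ValueError(
                f"subject {subj!r} needs >= 2 depths and both conditions"
            )
    depth = table["depth"].to_numpy(dtype=float)
    cond = (table["condition"] == condition_order[1]).to_numpy(dtype=float)
    exp_levels = np.sort(table["experiment"].unique())
    fixed = pd.DataFrame(
        {
            "intercept": np.ones(len(table)),
            "depth": depth,
            "condition": cond,
            "condition:depth": cond * depth,
        }
    )
    if len(exp_levels) > 1:
        exp = (table["experiment"] == exp_levels[1]).to_numpy(dtype=float)
        fixed["experiment"] = exp
        fixed["experiment:depth"] = exp * depth
        fixed["experiment:condition"] = exp * cond
        fixed["experiment:condition:depth"] = exp * cond * depth
    return _fit_mixed(
        y=table["accuracy"].to_numpy(dtype=float),
        fixed=fixed,
        re_cols=["intercept", "depth", "condition:depth"],
        groups=table["subject"].to_numpy(),
        fallback_re=["intercept", "depth"],
    )


def check_depth_voxel_balance(counts: pd.DataFrame) -> LMMFit:
    """Mixed model of per-depth voxel counts: a QC gate for depth bias.

    Fits ``voxel_count ~ depth + roi + roi:depth`` with per-subject random
    intercept, depth, roi and roi:depth. A significant depth effect (or
    roi x depth interaction) indicates a laminar sampling bias that could
    confound depth-resolved decoding. With a single ROI, the roi terms are
    dropped. Depth may be given as the bin centre (slope is then per depth
    unit).
    """
    required = {"subject", "roi", "depth", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts needs columns {sorted(required)}")
    if counts["depth"].nunique() < 2:
        raise ValueError("need >= 2 depth levels")
    depth = counts["depth"].to_numpy(dtype=float)
    roi_levels = np.sort(counts["roi"].unique())
    fixed = pd.DataFrame(
        {"intercept": np.ones(len(counts)), "depth": depth}
    )
    re_cols = ["intercept", "depth"]
    if len(roi_levels) > 1:
        roi = (counts["roi"] == roi_levels[1]).to_numpy(dtype=float)
        fixed["roi"] = roi
        fixed["roi:depth"] = roi * depth
        re_cols += ["roi", "roi:depth"]
    return _fit_mixed(
        y=counts["count"].to_numpy(dtype=float),
        fixed=fixed,
        re_cols=re_cols,
        groups=counts["subject"].to_numpy(),
        fallback_re=["intercept", "depth"],
    )
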