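"""Second trial endpoint: behavioral intent via nested list experiments.

Each participant sees either a control list (5 neutral items) or a
treatment list (the same 5 items plus one sensitive item about a COVID-19
preventive behavior) and reports only *how many* statements they agree
with.  Under the no-design-effect and no-liars assumptions of the
item-count technique, the prevalence of the sensitive behavior in arm k,
experiment i, is identified by the treatment-minus-control difference in
mean counts:

    P_i^k = (T̄_i^k − C̄_i^k) × 100        (percentage points)

Between-arm contrasts of these prevalences are difference-in-difference
quantities and are estimated in an ordinary least squares regression

    y = b0 + b1·VideoArm + b2·TreatList + b3·(VideoArm × TreatList)

whose interaction coefficient b3 equals the cell-mean
difference-in-difference exactly (the model is saturated in the four
cells).  For three arms, one joint OLS with two arm dummies and full
interactions yields the total (intervention − do-nothing), attention
(APC − do-nothing) and content (intervention − APC) effects as linear
combinations of coefficients, with classical homoskedastic standard errors
and t-reference p-values.  Effects are reported on the proportion scale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .schema import (ARMS, LIST_GROUPS, LIST_COLUMNS, N_LIST_EXPERIMENTS,
                     CONTROL_LIST_LEN, TREATMENT_LIST_LEN, ContractError,
                     TrialDataset, filter_complete)

EFFECT_KINDS = ("total", "attention", "content")
#: Arm contrast behind each effect kind (minuend, subtrahend).
EFFECT_CONTRASTS = {"total": ("covideo", "do_nothing"),
                    "attention": ("apc", "do_nothing"),
                    "content": ("covideo", "apc")}


# ---------------------------------------------------------------------------
# Cell summaries and the difference-in-means prevalence estimator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ListCellSummary:
    """Mean list counts for one arm in one experiment (both list groups)."""

    arm: str
    experiment_index: int    # 1..5
    control_mean: float      # C̄, in [0, 5]
    treatment_mean: float    # T̄, in [0, 6]
    control_n: int
    treatment_n: int
    control_var: float       # sample variances (ddof=1)
    treatment_var: float


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Estimated prevalence of the sensitive behavior, percentage points."""

    arm: str
    experiment_index: int
    prevalence: float
    se: float
    ci_low: float
    ci_high: float


def _check_experiment_index(experiment_index: int) -> str:
    if not 1 <= experiment_index <= N_LIST_EXPERIMENTS:
        raise ContractError(f"experiment_index must be in 1..{N_LIST_EXPERIMENTS}")
    return LIST_COLUMNS[experiment_index - 1]


def cell_summaries(dataset: TrialDataset,
                   experiment_index: int) -> dict[str, ListCellSummary]:
    """Per-arm count means/variances for one list experiment.

    Operates on the records as given (run :func:`listrct.schema.filter_complete`
    first for a complete-case analysis).  Raises :class:`ContractError`
    naming any empty arm × list cell.
    """
    col = _check_experiment_index(experiment_index)
    frame = dataset.frame
    out = {}
    for arm in ARMS:
        cells = {}
        for lg in LIST_GROUPS:
            vals = frame.loc[(frame["arm"] == arm) & (frame["list_group"] == lg),
                             col].to_numpy(dtype=float)
            if vals.size == 0:
                raise ContractError(f"empty design cell: arm={arm}, list_group={lg}")
            cells[lg] = vals
        out[arm] = ListCellSummary(
            arm=arm, experiment_index=experiment_index,
            control_mean=float(cells["control"].mean()),
            treatment_mean=float(cells["treatment"].mean()),
            control_n=cells["control"].size,
            treatment_n=cells["treatment"].size,
            control_var=float(np.var(cells["control"], ddof=1))
            if cells["control"].size > 1 else float("nan"),
            treatment_var=float(np.var(cells["treatment"], ddof=1))
            if cells["treatment"].size > 1 else float("nan"),
        )
    return out


def prevalence(summary: ListCellSummary, alpha: float = 0.05) -> PrevalenceEstimate:
    """Difference-in-means prevalence estimate with SE and normal CI.

    Point estimate: ``(T̄ − C̄) × 100``; SE from independent two-sample
    variance addition, ``100·sqrt(s_C²/n_C + s_T²/n_T)``.  Negative
    estimates are reported as-is (sampling noise can produce them).
    """
    point = (summary.treatment_mean - summary.control_mean) * 100.0
    se = 100.0 * float(np.sqrt(summary.control_var / summary.control_n
                               + summary.treatment_var / summary.treatment_n))
    z = stats.norm.ppf(1 - alpha / 2)
    return PrevalenceEstimate(arm=summary.arm,
                              experiment_index=summary.experiment_index,
                              prevalence=point, se=se,
                              ci_low=point - z * se, ci_high=point + z * se)


# ---------------------------------------------------------------------------
# Difference-in-difference OLS
# ---------------------------------------------------------------------------

@dataclass
class DiDModelFit:
    """Saturated two-arm × two-list OLS fit.

    Coefficients: b0 (intercept = reference-arm control-list mean),
    b1 (VideoArm), b2 (TreatList), b3 (VideoArm × TreatList).  b3 is the
    difference-in-difference, i.e. the prevalence contrast between the two
    arms on the proportion scale.
    """

    experiment_index: int
    arm_pair: tuple[str, str]       # (reference, comparison)
    params: np.ndarray              # b0..b3
    cov: np.ndarray                 # classical homoskedastic covariance
    df_resid: int
    param_names: tuple[str, ...] = ("b0", "b1_video_arm", "b2_treat_list",
                                    "b3_interaction")


@dataclass
class ThreeArmListFit:
    """Joint saturated OLS over all three arms for one experiment.

    Design: intercept, APC and intervention arm dummies (reference =
    do-nothing), treatment-list dummy, and both arm × list interactions.
    The interaction coefficients are the arm-vs-do-nothing
    difference-in-differences.
    """

    experiment_index: int
    params: np.ndarray
    cov: np.ndarray
    df_resid: int
    param_names: tuple[str, ...] = ("b0", "b_apc", "b_covideo", "b_treat_list",
                                    "b_apc_x_treat", "b_covideo_x_treat")


def _fit_ols(y: np.ndarray, design: np.ndarray):
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ContractError("design matrix is rank deficient "
                            "(an arm × list cell is empty or collinear)")
    res = sm.OLS(y, design).fit()
    return res.params, res.cov_params(), int(res.df_resid)


def fit_did(dataset: TrialDataset, experiment_index: int,
            arm_pair: tuple[str, str]) -> DiDModelFit:
    """Fit the two-arm difference-in-difference OLS for one experiment.

    ``arm_pair`` is (reference arm, comparison arm); the VideoArm indicator
    is 1 for the comparison arm.
    """
    col = _check_experiment_index(experiment_index)
    ref, cmp_arm = arm_pair
    for a in arm_pair:
        if a not in ARMS:
            raise ContractError(f"unknown arm {a!r}")
    if ref == cmp_arm:
        raise ContractError("arm_pair must name two distinct arms")
    frame = dataset.frame
    sub = frame[frame["arm"].isin(arm_pair)]
    y = sub[col].to_numpy(dtype=float)
    video = (sub["arm"] == cmp_arm).to_numpy(dtype=float)
    treat = (sub["list_group"] == "treatment").to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(y), video, treat, video * treat])
    params, cov, df = _fit_ols(y, design)
    return DiDModelFit(experiment_index=experiment_index, arm_pair=arm_pair,
                       params=np.asarray(params), cov=np.asarray(cov),
                       df_resid=df)


def fit_three_arm(dataset: TrialDataset, experiment_index: int) -> ThreeArmListFit:
    """Fit the joint three-arm saturated OLS for one experiment."""
    col = _check_experiment_index(experiment_index)
    frame = dataset.frame
    y = frame[col].to_numpy(dtype=float)
    apc = (frame["arm"] == "apc").to_numpy(dtype=float)
    cov_arm = (frame["arm"] == "covideo").to_numpy(dtype=float)
    treat = (frame["list_group"] == "treatment").to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(y), apc, cov_arm, treat,
                              apc * treat, cov_arm * treat])
    params, cov, df = _fit_ols(y, design)
    return ThreeArmListFit(experiment_index=experiment_index,
                           params=np.asarray(params), cov=np.asarray(cov),
                           df_resid=df)


@dataclass(frozen=True)
class LinearCombination:
    """wᵀb with classical SE, t-reference p-value and CI."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    df_resid: int


def linear_combination(fit: DiDModelFit | ThreeArmListFit,
                       weights: Sequence[float],
                       alpha: float = 0.05) -> LinearCombination:
    """Inference for a linear combination of OLS coefficients.

    ``estimate = wᵀb``, ``se = sqrt(wᵀ Σ w)``; the p-value is two-sided
    from the t distribution on the residual degrees of freedom.  A
    zero-weight combination returns estimate 0, SE 0 and an undefined (NaN)
    p-value.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != fit.params.shape:
        raise ContractError(f"weights length {w.size} != number of "
                            f"coefficients {fit.params.size}")
    est = float(w @ fit.params)
    var = float(w @ fit.cov @ w)
    se = float(np.sqrt(max(var, 0.0)))
    tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    if se == 0.0:
        p = float("nan") if est == 0.0 else 0.0
    else:
        p = 2 * float(stats.t.sf(abs(est) / se, fit.df_resid))
    return LinearCombination(estimate=est, se=se, ci_low=est - tcrit * se,
                             ci_high=est + tcrit * se, p_value=p,
                             df_resid=fit.df_resid)


# ---------------------------------------------------------------------------
# Effect decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectEstimate:
    """A total / attention / content contrast on the proportion scale."""

    experiment_index: int
    effect_kind: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


#: Weight vectors extracting each effect from the three-arm fit.
_EFFECT_WEIGHTS = {
    "total": np.array([0., 0., 0., 0., 0., 1.]),       # (T−C)_cov − (T−C)_no
    "attention": np.array([0., 0., 0., 0., 1., 0.]),   # (T−C)_apc − (T−C)_no
    "content": np.array([0., 0., 0., 0., -1., 1.]),    # total − attention
}


def effect_decomposition(dataset: TrialDataset, experiment_index: int,
                         alpha: float = 0.05,
                         fit: ThreeArmListFit | None = None,
                         ) -> dict[str, EffectEstimate]:
    """Total, attention and content effects for one list experiment.

    All three come from linear combinations in the single three-arm
    saturated OLS, so ``content + attention = total`` holds exactly.
    """
    if fit is None:
        fit = fit_three_arm(dataset, experiment_index)
    if fit.experiment_index != experiment_index:
        raise ContractError("fit and requested experiment indices disagree")
    out = {}
    for kind in EFFECT_KINDS:
        lc = linear_combination(fit, _EFFECT_WEIGHTS[kind], alpha=alpha)
        out[kind] = EffectEstimate(
            experiment_index=experiment_index, effect_kind=kind,
            estimate=lc.estimate, se=lc.se, ci_low=lc.ci_low,
            ci_high=lc.ci_high, p_value=lc.p_value)
    return out


# ---------------------------------------------------------------------------
# Endpoint driver
# ---------------------------------------------------------------------------

@dataclass
class ListExperimentSummary:
    """Full second-endpoint output bundle for all five experiments."""

    cells: dict[int, dict[str, ListCellSummary]]
    prevalences: dict[int, dict[str, PrevalenceEstimate]]
    effects: dict[int, dict[str, EffectEstimate]]

    def to_dict(self) -> dict:
        return {
            "cells": {i: {a: asdict(s) for a, s in by_arm.items()}
                      for i, by_arm in self.cells.items()},
            "prevalences": {i: {a: asdict(p) for a, p in by_arm.items()}
                            for i, by_arm in self.prevalences.items()},
            "effects": {i: {k: asdict(e) for k, e in by_kind.items()}
                        for i, by_kind in self.effects.items()},
        }


def analyze_lists(dataset: TrialDataset, alpha: float = 0.05) -> ListExperimentSummary:
    """Run the complete second-endpoint analysis on completers."""
    complete = filter_complete(dataset)
    complete.require_full_design()
    cells, prevs, effects = {}, {}, {}
    for i in range(1, N_LIST_EXPERIMENTS + 1):
        cells[i] = cell_summaries(complete, i)
        prevs[i] = {arm: prevalence(s, alpha=alpha) for arm, s in cells[i].items()}
        effects[i] = effect_decomposition(complete, i, alpha=alpha)
    return ListExperimentSummary(cells=cells, prevalences=prevs, effects=effects)
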