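"""First trial endpoint: knowledge of preventive behaviors.

Scoring sums correct answers over the 18 true/false items (min 0, max 18);
a timed-out item (code 9, the 30-second answer window expired) is recoded
as incorrect, since the participant could not answer in time.  Between-arm
differences are tested with a one-way ANOVA and Tukey's honestly
significant difference (Tukey–Kramer for the slightly unbalanced arms).

Because baseline knowledge sits near the 18-point ceiling, raw mean
differences understate the intervention's reach: the decomposition
therefore also reports each contrast relative to its *headroom*, the
maximum attainable gain ``18 − comparator mean``.  The three contrasts are

* total effect      = intervention − do-nothing
* attention effect  = APC − do-nothing   (the effect of watching any video)
* content effect    = intervention − APC (the message itself)

and satisfy ``content + attention = total`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (ARMS, CORRECT, INCORRECT, TIMEOUT, KNOWLEDGE_CODES,
                     KNOWLEDGE_COLUMNS, N_KNOWLEDGE_ITEMS, ContractError,
                     RecordValidationError, TrialDataset, filter_complete)

MAX_SCORE = N_KNOWLEDGE_ITEMS


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_knowledge(responses: Sequence[int]) -> int:
    """Knowledge score: number of correct answers out of 18.

    Timeout (code 9) contributes 0, identically to an incorrect answer.
    """
    responses = tuple(int(r) for r in responses)
    if len(responses) != N_KNOWLEDGE_ITEMS:
        raise RecordValidationError(
            f"expected {N_KNOWLEDGE_ITEMS} responses, got {len(responses)}")
    if any(r not in KNOWLEDGE_CODES for r in responses):
        raise RecordValidationError("responses must be coded 1/0/9")
    return sum(r == CORRECT for r in responses)


def correctness_matrix(dataset: TrialDataset) -> np.ndarray:
    """Participants × 18 binary correctness (timeout recoded to 0)."""
    return (dataset.frame[list(KNOWLEDGE_COLUMNS)].to_numpy() == CORRECT).astype(int)


def knowledge_scores(dataset: TrialDataset) -> pd.DataFrame:
    """Per-participant knowledge scores with arm labels."""
    return pd.DataFrame({
        "participant_id": dataset.frame["participant_id"].to_numpy(),
        "arm": dataset.frame["arm"].to_numpy(),
        "score": correctness_matrix(dataset).sum(axis=1),
    })


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitHalfReliability:
    """Split-half internal consistency of the knowledge instrument.

    ``raw`` is the Pearson correlation between the odd-item and even-item
    half scores; ``spearman_brown`` is the 2r/(1+r) step-up projecting that
    half-length correlation to the full 18-item instrument.  Both are
    reported because "split-half coefficient" is ambiguous between them.
    """

    raw: float
    spearman_brown: float


def split_half_reliability(matrix: np.ndarray) -> SplitHalfReliability:
    """Correlate odd-item and even-item half scores across participants.

    ``matrix`` is participants × 18 binary correctness.  Raises
    :class:`ContractError` when fewer than 3 participants are supplied or a
    half has zero variance (the coefficient is then undefined — this is
    never silently reported as 0).
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != N_KNOWLEDGE_ITEMS:
        raise ContractError(f"matrix must be participants x {N_KNOWLEDGE_ITEMS}")
    if matrix.shape[0] < 3:
        raise ContractError("split-half reliability needs at least 3 participants")
    odd_half = matrix[:, 0::2].sum(axis=1)   # items 1,3,...,17
    even_half = matrix[:, 1::2].sum(axis=1)  # items 2,4,...,18
    if np.var(odd_half) == 0 or np.var(even_half) == 0:
        raise ContractError("a half score has zero variance; "
                            "split-half reliability is undefined")
    r = float(np.corrcoef(odd_half, even_half)[0, 1])
    return SplitHalfReliability(raw=r, spearman_brown=2 * r / (1 + r))


# ---------------------------------------------------------------------------
# Between-arm inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmSummary:
    arm: str
    n: int
    mean: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class TukeyComparison:
    arm_a: str          # contrast is arm_b − arm_a
    arm_b: str
    mean_difference: float
    p_adjusted: float


def arm_summaries(scores: pd.DataFrame, alpha: float = 0.05) -> dict[str, ArmSummary]:
    """Per-arm n, mean score, SE and normal-approximation CI."""
    z = stats.norm.ppf(1 - alpha / 2)
    out = {}
    for arm, grp in scores.groupby("arm", observed=True):
        vals = grp["score"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ContractError(f"arm {arm}: need at least 2 participants")
        se = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
        mean = float(vals.mean())
        out[arm] = ArmSummary(arm, len(vals), mean, se,
                              mean - z * se, mean + z * se)
    return {arm: out[arm] for arm in ARMS if arm in out}


def anova_tukey(scores: Sequence[float], arms: Sequence[str],
                ) -> tuple[AnovaResult, list[TukeyComparison]]:
    """One-way ANOVA across arms plus Tukey HSD pairwise comparisons.

    Adjusted p-values use the studentized range distribution with the
    Tukey–Kramer allowance for unequal cell sizes.
    """
    scores = np.asarray(scores, dtype=float)
    arms = np.asarray(arms)
    present = [a for a in ARMS if a in arms]
    if len(present) < 2:
        raise ContractError("ANOVA needs at least 2 arms")
    groups = [scores[arms == a] for a in present]
    if any(len(g) < 2 for g in groups):
        raise ContractError("each arm needs at least 2 participants")

    f_stat, p = stats.f_oneway(*groups)
    anova = AnovaResult(float(f_stat), len(groups) - 1,
                        int(scores.size - len(groups)), float(p))

    hsd = stats.tukey_hsd(*groups)
    comparisons = []
    for ia in range(len(present)):
        for ib in range(ia + 1, len(present)):
            comparisons.append(TukeyComparison(
                arm_a=present[ia], arm_b=present[ib],
                mean_difference=float(groups[ib].mean() - groups[ia].mean()),
                p_adjusted=float(hsd.pvalue[ib, ia])))
    return anova, comparisons


# ---------------------------------------------------------------------------
# Effect decomposition with headroom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnowledgeEffects:
    """Arm contrasts on the knowledge score with ceiling-relative gains.

    ``headroom_vs_do_nothing`` (= 18 − do-nothing mean) is the maximum gain
    available over the do-nothing arm; total and attention effects are
    expressed relative to it.  The content effect is relative to the APC
    headroom.  SEs come from independent-arm variance addition.
    """

    total: float
    attention: float
    content: float
    total_se: float
    attention_se: float
    content_se: float
    headroom_vs_do_nothing: float
    headroom_vs_apc: float
    relative_total: float
    relative_attention: float
    relative_content: float


def knowledge_effects(means: Mapping[str, float],
                      ses: Mapping[str, float] | None = None) -> KnowledgeEffects:
    """Decompose arm mean differences into total/attention/content effects.

    ``means`` maps each arm to its mean score (each must lie in [0, 18]);
    ``ses`` optionally supplies standard errors for contrast SEs.
    """
    missing = [a for a in ARMS if a not in means]
    if missing:
        raise ContractError(f"missing arm mean(s): {', '.join(missing)}")
    for arm in ARMS:
        if not 0 <= means[arm] <= MAX_SCORE:
            raise ContractError(f"arm {arm} mean {means[arm]} outside [0, {MAX_SCORE}]")
    m_no, m_apc, m_cov = (float(means[a]) for a in ARMS)
    total = m_cov - m_no
    attention = m_apc - m_no
    content = m_cov - m_apc

    if ses is not None:
        s_no, s_apc, s_cov = (float(ses[a]) for a in ARMS)
        total_se = float(np.hypot(s_cov, s_no))
        attention_se = float(np.hypot(s_apc, s_no))
        content_se = float(np.hypot(s_cov, s_apc))
    else:
        total_se = attention_se = content_se = float("nan")

    head_no = MAX_SCORE - m_no
    head_apc = MAX_SCORE - m_apc
    return KnowledgeEffects(
        total=total, attention=attention, content=content,
        total_se=total_se, attention_se=attention_se, content_se=content_se,
        headroom_vs_do_nothing=head_no, headroom_vs_apc=head_apc,
        relative_total=total / head_no if head_no > 0 else float("nan"),
        relative_attention=attention / head_no if head_no > 0 else float("nan"),
        relative_content=content / head_apc if head_apc > 0 else float("nan"),
    )


def correct_response_rate(mean_score: float) -> float:
    """Mean score expressed as a percentage of the 18-item maximum."""
    return 100.0 * mean_score / MAX_SCORE


def per_item_correct(dataset: TrialDataset) -> pd.DataFrame:
    """18 × 3 table of per-item correct proportions by arm (timeout = wrong)."""
    frame = dataset.frame
    out = {}
    for arm in ARMS:
        sub = frame.loc[frame["arm"] == arm, list(KNOWLEDGE_COLUMNS)]
        if len(sub) == 0:
            raise ContractError(f"arm {arm} has no participants")
        out[arm] = (sub.to_numpy() == CORRECT).mean(axis=0)
    return pd.DataFrame(out, index=[f"item_{j:02d}" for j in range(1, MAX_SCORE + 1)])


# ---------------------------------------------------------------------------
# Endpoint driver
# ---------------------------------------------------------------------------

@dataclass
class KnowledgeSummary:
    """Full first-endpoint output bundle."""

    arms: dict[str, ArmSummary]
    anova: AnovaResult
    tukey: list[TukeyComparison]
    effects: KnowledgeEffects
    reliability: SplitHalfReliability
    per_item: pd.DataFrame
    correct_response_rate: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "arms": {a: asdict(s) for a, s in self.arms.items()},
            "anova": asdict(self.anova),
            "tukey": [asdict(c) for c in self.tukey],
            "effects": asdict(self.effects),
            "reliability": asdict(self.reliability),
            "correct_response_rate_pct": self.correct_response_rate,
            "per_item_correct": {a: self.per_item[a].round(10).tolist()
                                 for a in self.per_item.columns},
        }


def analyze_knowledge(dataset: TrialDataset, alpha: float = 0.05) -> KnowledgeSummary:
    """Run the complete first-endpoint analysis on completers.

    Filters to complete cases, scores, summarises arms, tests between-arm
    differences (ANOVA + Tukey HSD) and decomposes the effects with
    headroom-relative gains.
    """
    complete = filter_complete(dataset)
    complete.require_full_design()
    scores = knowledge_scores(complete)
    summaries = arm_summaries(scores, alpha=alpha)
    anova, tukey = anova_tukey(scores["score"], scores["arm"])
    effects = knowledge_effects({a: s.mean for a, s in summaries.items()},
                                {a: s.se for a, s in summaries.items()})
    reliability = split_half_reliability(correctness_matrix(complete))
    return KnowledgeSummary(
        arms=summaries, anova=anova, tukey=tukey, effects=effects,
        reliability=reliability, per_item=per_item_correct(complete),
        correct_response_rate={a: correct_response_rate(s.mean)
                               for a, s in summaries.items()})
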