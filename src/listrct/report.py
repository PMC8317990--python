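"""End-to-end pipeline: simulate/load → analyse both endpoints → report.

Produces a small report bundle in an output directory:

* ``knowledge.json`` — first endpoint (scores, ANOVA/Tukey, effects,
  reliability, per-item proportions)
* ``lists.json`` — second endpoint (cell means, prevalences, effect
  decomposition for the five list experiments)
* ``balance.json`` — baseline-characteristics balance table: for each
  demographic, counts per arm × list cell and the chi-square test of
  independence of the demographic against the six cells
* ``summary.txt`` — plain-text restatement of the headline effects with CIs

Regeneration from the same inputs is byte-identical; all randomness lives
in the synthetic generator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .schema import (ARMS, LIST_GROUPS, DEMOGRAPHIC_COLUMNS, ContractError,
                     TrialDataset, filter_complete, read_trial_csv)
from .simulate import SimulationConfig, generate_trial
from .knowledge import analyze_knowledge, KnowledgeSummary
from .lists import analyze_lists, ListExperimentSummary

logger = logging.getLogger("listrct")


@dataclass
class RunConfig:
    """Pipeline run configuration.

    Exactly one of ``input_csv`` or ``simulation`` must be supplied; ``alpha``
    is the two-sided significance level used for every CI in the bundle.
    """

    output_dir: str | Path
    input_csv: str | Path | None = None
    simulation: SimulationConfig | None = None
    alpha: float = 0.05
    spearman_brown: bool = True   # include the stepped-up reliability in text

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ContractError("alpha must lie in (0, 1)")
        if (self.input_csv is None) == (self.simulation is None):
            raise ContractError("provide exactly one of input_csv or simulation")


def balance_table(dataset: TrialDataset) -> dict:
    """Baseline-characteristics balance across the six arm × list cells.

    For each demographic, tabulates counts per cell and reports the
    chi-square test of independence of the demographic against the cells
    (the conventional randomization-balance check for categorical
    baseline variables).
    """
    frame = dataset.frame
    cell = frame["arm"] + "/" + frame["list_group"]
    cell_order = [f"{a}/{g}" for a in ARMS for g in LIST_GROUPS]
    out = {}
    for col in DEMOGRAPHIC_COLUMNS:
        table = pd.crosstab(frame[col], cell).reindex(columns=cell_order,
                                                      fill_value=0)
        table = table.loc[table.sum(axis=1) > 0]
        chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy())
        out[col] = {
            "counts": {str(level): [int(v) for v in row]
                       for level, row in table.iterrows()},
            "cells": cell_order,
            "chi2": float(chi2), "df": int(dof), "p_value": float(p),
        }
    return out


def _summary_text(knowledge: KnowledgeSummary, lists: ListExperimentSummary,
                  balance: dict, alpha: float, spearman_brown: bool) -> str:
    pct = 100 * (1 - alpha)
    lines = ["Three-arm trial analysis summary", "=" * 34, ""]
    lines.append(f"Knowledge score (0-18), {pct:g}% CIs:")
    for arm, s in knowledge.arms.items():
        lines.append(f"  {arm:>10}: n={s.n}, mean {s.mean:.2f} "
                     f"({s.ci_low:.2f}-{s.ci_high:.2f}), "
                     f"correct-response rate "
                     f"{knowledge.correct_response_rate[arm]:.1f}%")
    a = knowledge.anova
    lines.append(f"  ANOVA: F({a.df_between},{a.df_within}) = "
                 f"{a.f_statistic:.2f}, p = {a.p_value:.3g}")
    for c in knowledge.tukey:
        lines.append(f"  Tukey {c.arm_b} - {c.arm_a}: "
                     f"{c.mean_difference:+.3f}, adj. p = {c.p_adjusted:.3g}")
    e = knowledge.effects
    lines.append(f"  Effects: total {e.total:+.3f}, attention "
                 f"{e.attention:+.3f}, content {e.content:+.3f}")
    lines.append(f"  Headroom: {e.headroom_vs_do_nothing:.2f} vs do-nothing "
                 f"({100*e.relative_total:.1f}% relative total gain), "
                 f"{e.headroom_vs_apc:.2f} vs APC "
                 f"({100*e.relative_content:.1f}% relative content gain)")
    rel = knowledge.reliability
    rel_txt = f"  Split-half reliability: raw {rel.raw:.3f}"
    if spearman_brown:
        rel_txt += f", Spearman-Brown {rel.spearman_brown:.3f}"
    lines.append(rel_txt)
    lines.append("")
    lines.append(f"List experiments (prevalence in percentage points, {pct:g}% CIs):")
    for i, by_arm in lists.prevalences.items():
        lines.append(f"  Experiment {i}:")
        for arm, p in by_arm.items():
            lines.append(f"    {arm:>10}: {p.prevalence:6.1f} "
                         f"({p.ci_low:.1f} to {p.ci_high:.1f})")
        for kind, eff in lists.effects[i].items():
            lines.append(f"    {kind:>10} effect: {eff.estimate:+.3f} "
                         f"({eff.ci_low:+.3f} to {eff.ci_high:+.3f}), "
                         f"p = {eff.p_value:.3g}")
    lines.append("")
    lines.append("Balance (chi-square p by demographic):")
    for col, entry in balance.items():
        lines.append(f"  {col:>15}: p = {entry['p_value']:.3f}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write the report bundle.

    Returns a mapping of artifact name → path.  Any stage failure raises
    with a stage-named message (the CLI maps this to a nonzero exit code).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.input_csv is not None:
        dataset = read_trial_csv(config.input_csv)
    else:
        dataset = generate_trial(config.simulation)
    logger.info("run_pipeline: %d records enrolled (%s)", len(dataset),
                dataset.provenance)

    complete = filter_complete(dataset)
    for arm in ARMS:
        for lg in LIST_GROUPS:
            n_cell = int(((complete.frame["arm"] == arm)
                          & (complete.frame["list_group"] == lg)).sum())
            logger.info("run_pipeline: cell %s/%s n=%d", arm, lg, n_cell)

    knowledge = analyze_knowledge(dataset, alpha=config.alpha)
    lists = analyze_lists(dataset, alpha=config.alpha)
    balance = balance_table(complete)

    artifacts = {}

    def _write_json(name: str, payload: dict) -> None:
        path = outdir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                   allow_nan=True) + "\n")
        artifacts[name] = path

    _write_json("knowledge.json", knowledge.to_dict())
    _write_json("lists.json", lists.to_dict())
    _write_json("balance.json", balance)
    summary_path = outdir / "summary.txt"
    summary_path.write_text(_summary_text(knowledge, lists, balance,
                                          config.alpha, config.spearman_brown))
    artifacts["summary.txt"] = summary_path
    return artifacts
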