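"""End-to-end pipeline: spike sets -> unit table -> population code.

Chains the stages in their natural order — exclusion filtering, the
light-responsiveness shuffle test, step-response metrics, contrast and
temporal-frequency tuning fits, and (optionally, across conditions)
sparse-PC consensus clustering with community detection and the
between-condition distribution test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import code_structure as cs
from .config import AnalysisConfig
from .metrics import compute_unit_metrics
from .preprocess import bin_psth, exclusion_filter, lr_shuffle_test
from .synthetic import SpikeTrainSet
from .tuning import contrast_profile, fit_half_gaussian, fit_naka_rushton, temporal_profile

__all__ = ["PipelineResult", "unit_table", "run_pipeline"]


@dataclass
class PipelineResult:
    units: pd.DataFrame  # one row per unit: metrics + tuning + flags
    code: cs.CodeStructureResult | None = None
    filter_log: dict[str, int] = field(default_factory=dict)


def unit_table(
    spike_set: SpikeTrainSet,
    config: AnalysisConfig | None = None,
    n_shuffles_lr: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-unit metric table with exclusion and LR flags.

    Metrics and tuning fits are computed for units that pass the activity
    filter and the light-responsiveness test; all units appear in the table
    with their filter status.
    """
    cfg = config or AnalysisConfig()
    n_sh = n_shuffles_lr if n_shuffles_lr is not None else cfg.n_shuffles_lr
    stim = spike_set.stimulus
    duration = stim.total_duration_s
    lr_seed_root = np.random.SeedSequence(cfg.seed)
    unit_seeds = lr_seed_root.spawn(len(spike_set.units))

    rows = []
    log = {"n_input": len(spike_set.units), "n_pass_filter": 0, "n_lr": 0}
    for u, sseed in zip(spike_set.units, unit_seeds):
        psth25 = bin_psth(u.trials, cfg.bin_lr_s, (0.0, duration))
        dec = exclusion_filter(psth25)
        row: dict = {
            "unit_id": u.unit_id,
            "condition": u.condition,
            "tissue": u.tissue,
            "n_trials": len(u.trials),
            "frac_active_bins": dec.frac_active_bins,
            "n_active_trials": dec.n_active_trials,
            "keep": dec.keep,
            "is_lr": False,
        }
        if dec.keep:
            log["n_pass_filter"] += 1
            lr = lr_shuffle_test(psth25, n_shuffles=n_sh, seed=sseed, alpha=cfg.lr_alpha)
            row["lr_statistic"] = lr.statistic
            row["lr_p"] = lr.p_value
            row["is_lr"] = lr.is_lr
        if row["is_lr"]:
            log["n_lr"] += 1
            m = compute_unit_metrics(u.unit_id, u.trials, duration_s=duration)
            row.update(
                amplitude=m.amplitude,
                qi=m.qi,
                latency_s=m.latency_s,
                bias_index=m.bias_index,
                transience_index=m.transience_index,
                category=m.category,
                mean_rate=m.mean_rate,
            )
            cp = contrast_profile(psth25, stim)
            nr = fit_naka_rushton(cp, seed=cfg.seed)
            tp = temporal_profile(psth25, stim)
            hg = fit_half_gaussian(tp, seed=cfg.seed)
            row.update(
                c50=nr.c50,
                nr_slope=nr.slope,
                nr_r2=nr.r2,
                nr_included=nr.included,
                peak_tf=hg.peak_tf,
                spread=hg.spread,
                hg_r2=hg.r2,
                hg_included=hg.included,
            )
        rows.append(row)
    return pd.DataFrame(rows), log


def run_pipeline(
    spike_set: SpikeTrainSet,
    config: AnalysisConfig | None = None,
    n_shuffles_lr: int | None = None,
    with_code_structure: bool = True,
    balance_conditions: bool = True,
) -> PipelineResult:
    """Run the full analysis on one (possibly multi-condition) spike set."""
    cfg = config or AnalysisConfig()
    table, log = unit_table(spike_set, cfg, n_shuffles_lr=n_shuffles_lr)
    result = PipelineResult(units=table, filter_log=log)
    if not with_code_structure:
        return result

    lr_units = [u for u, ok in zip(spike_set.units, table["is_lr"]) if ok]
    if len(lr_units) < 2:
        return result
    duration = spike_set.stimulus.total_duration_s
    pop = np.stack(
        [
            bin_psth(u.trials, cfg.bin_features_s, (0.0, duration)).mean_rate()
            for u in lr_units
        ]
    )
    cond = np.array([u.condition for u in lr_units])
    idx = np.arange(len(lr_units))
    if balance_conditions and np.unique(cond).size >= 2:
        idx = cs.downsample_balanced(cond, seed=cfg.seed)
        pop, cond = pop[idx], cond[idx]

    segs = cs.segment_psth_features(pop, bin_s=cfg.bin_features_s)
    loadings, scores, varexp = cs.sparse_pca(segs)
    similarity, _, _ = cs.consensus_cluster(
        scores,
        n_repeats=cfg.n_cluster_repeats,
        k_max=cfg.k_max,
        seed=cfg.seed,
        bf_threshold=cfg.bayes_factor_threshold,
    )
    communities = cs.detect_communities(
        similarity, min_size=cfg.min_community_size, seed=cfg.seed
    )
    ids, sizes = np.unique(communities[communities >= 0], return_counts=True)
    code = cs.CodeStructureResult(
        spc_loadings=loadings,
        spc_scores=scores,
        variance_explained=varexp,
        similarity=similarity,
        communities=communities,
        community_sizes={int(i): int(s) for i, s in zip(ids, sizes)},
    )
    for c in np.unique(cond):
        m = (cond == c) & (communities >= 0)
        code.condition_distributions[str(c)] = np.bincount(
            communities[m], minlength=ids.size if ids.size else 1
        )
    if np.unique(cond[communities >= 0]).size >= 2:
        code.shuffle_p = cs.distribution_shuffle_test(
            communities, cond, n_shuffles=cfg.n_shuffles_distribution, seed=cfg.seed
        )
    result.code = code
    return result
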