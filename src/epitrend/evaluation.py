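"""Scoring pipeline output against the generator's planted truth.

Every metric here compares what the pipeline recovered with what the
synthetic-data generator planted: the developmental order, the per-gene
profile category, the switch ranks, and the multilevel calls.  These are
the quantities the package's acceptance checks report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .pipeline import PipelineResult
from .synthetic import SyntheticTruth
from .trends import FAMILY

SWITCH_KEYS = {
    "up_on": ("start_hpf", "start"),
    "up_start": ("start_hpf", "start"),
    "down_off": ("stop_hpf", "stop"),
    "down_stop": ("stop_hpf", "stop"),
}


def order_recovery_rho(result: PipelineResult, truth: SyntheticTruth) -> float:
    """Spearman correlation between recovered and true developmental order."""
    rank_true = {e: i for i, e in enumerate(truth.true_order) if e in set(result.order.ranks)}
    ids = result.order.ranks
    rec = np.arange(len(ids))
    tru = np.array([rank_true[e] for e in ids])
    return float(spearmanr(rec, tru).statistic)


def direction_agreement_rho(result: PipelineResult) -> float:
    """Spearman correlation between the increasing- and decreasing-trained
    orders (the reciprocal validation of the ordering)."""
    if result.order_decreasing is None:
        return float("nan")
    a = {e: i for i, e in enumerate(result.order.ranks)}
    ids = result.order.ranks
    b = {e: i for i, e in enumerate(result.order_decreasing.ranks)}
    return float(spearmanr([a[e] for e in ids], [b[e] for e in ids]).statistic)


def type_agreement(result: PipelineResult, truth: SyntheticTruth) -> dict[str, float]:
    """Exact and family-level agreement between planted and inferred
    profile categories, over planted genes present in the report."""
    rep = result.gene_report
    cat = pd.Series(truth.gene_category)
    both = rep.index.intersection(cat.index)
    inferred = rep.loc[both, "category"]
    planted = cat.loc[both]
    return {
        "exact": float((inferred == planted).mean()),
        "family": float((inferred.map(FAMILY) == planted.map(FAMILY)).mean()),
        "n": int(len(both)),
    }


def true_switch_rank(truth: SyntheticTruth, result: PipelineResult, hpf: float) -> int:
    """The planted switch time's position among the analysed embryos'
    true collection times (1-based)."""
    times = np.sort([truth.true_pseudotime[e] for e in result.order.ranks])
    return int(np.searchsorted(times, hpf)) + 1


def changepoint_errors(result: PipelineResult, truth: SyntheticTruth) -> np.ndarray:
    """Signed rank errors of every valid located change point of a planted
    switching gene (estimate minus planted switch rank)."""
    cat = truth.gene_category
    params = truth.gene_params
    table = result.changepoint_table
    errs = []
    for _, row in table.iterrows():
        g = row["gene_id"]
        c = cat.get(g)
        if c not in SWITCH_KEYS or not row["valid"]:
            continue
        key, kind = SWITCH_KEYS[c]
        if row["kind"] != kind:
            continue
        errs.append(float(row["rank"]) - true_switch_rank(truth, result, params[g][key]))
    return np.asarray(errs)


def multilevel_performance(result: PipelineResult, truth: SyntheticTruth) -> dict[str, float]:
    """Sensitivity on planted spawn-offset genes and the false-call rate
    on planted unimodal genes."""
    ml = result.multilevel_table.set_index("gene_id")
    planted = set(truth.multilevel_genes)
    called = set(ml.index[ml["n_levels"].notna()])
    unimodal = [g for g in truth.gene_category if g in ml.index and g not in planted]
    tp = called & planted
    return {
        "sensitivity": float(len(tp) / len(planted)) if planted else float("nan"),
        "false_call_rate": float(sum(g in called for g in unimodal) / len(unimodal)),
        "n_planted": int(len(planted)),
        "n_unimodal": int(len(unimodal)),
    }
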