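"""Data-driven developmental ordering of individual embryos.

Epiboly percentage is precise enough to identify the developmentally
youngest and oldest embryos but stalls mid-course, so the order itself is
derived from the expression data: transcripts that are low (mean log2
intensity below the low cutoff) in the lowest-epiboly samples and high
(above the high cutoff) in the highest-epiboly samples form a monotone
training set, and embryos are ranked by their mean intensity over that
set.  Reversing the criterion yields an independent decreasing-gene
order used for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trends import lowess_trend


@dataclass
class OrderingParams:
    n_extreme: int = 10
    low_intensity_cutoff: float = 12.0
    high_intensity_cutoff: float = 13.0

    def __post_init__(self) -> None:
        if self.low_intensity_cutoff >= self.high_intensity_cutoff:
            raise ValueError("low_intensity_cutoff must be below high_intensity_cutoff")
        if self.n_extreme < 1:
            raise ValueError("n_extreme must be positive")


@dataclass
class DevelopmentalOrder:
    ranks: list[str]  # embryo ids, rank 1 first
    pseudotime_hpf: np.ndarray  # hours per rank, linear over the stage window
    training_set: list[str]  # transcript ids used to order
    direction: str  # 'increasing' or 'decreasing'

    def rank_of(self) -> dict[str, int]:
        """Map embryo id -> 1-based developmental rank."""
        return {e: i + 1 for i, e in enumerate(self.ranks)}

    def to_frame(self, training_mean: pd.Series | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "embryo_id": self.ranks,
                "rank": np.arange(1, len(self.ranks) + 1),
                "pseudotime_hpf": self.pseudotime_hpf,
            }
        )
        if training_mean is not None:
            df["training_mean"] = training_mean.loc[self.ranks].to_numpy()
        return df


def _extreme_groups(epiboly: pd.Series, n_extreme: int) -> tuple[list[str], list[str]]:
    srt = epiboly.sort_values(kind="stable")
    return list(srt.index[:n_extreme]), list(srt.index[-n_extreme:])


def select_training_transcripts(
    transcript_matrix: pd.DataFrame,
    epiboly: pd.Series,
    params: OrderingParams | None = None,
    direction: str = "increasing",
) -> list[str]:
    """Transcripts monotone across the stage window, by the extreme-sample
    criterion.

    increasing: mean below ``low_intensity_cutoff`` over the ``n_extreme``
    lowest-epiboly embryos AND above ``high_intensity_cutoff`` over the
    ``n_extreme`` highest.  decreasing: the reversed criterion.
    """
    params = params or OrderingParams()
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    if 2 * params.n_extreme >= transcript_matrix.shape[1]:
        raise ValueError("n_extreme too large for the number of embryos")
    epiboly = epiboly.loc[transcript_matrix.columns]
    low_ids, high_ids = _extreme_groups(epiboly, params.n_extreme)
    mean_low = transcript_matrix[low_ids].mean(axis=1)
    mean_high = transcript_matrix[high_ids].mean(axis=1)
    if direction == "increasing":
        sel = (mean_low < params.low_intensity_cutoff) & (mean_high > params.high_intensity_cutoff)
    else:
        sel = (mean_low > params.high_intensity_cutoff) & (mean_high < params.low_intensity_cutoff)
    chosen = list(transcript_matrix.index[sel])
    if not chosen:
        raise ValueError(
            f"empty {direction} training set; relax the intensity cutoffs "
            f"(currently {params.low_intensity_cutoff}/{params.high_intensity_cutoff})"
        )
    return chosen


def order_samples(
    transcript_matrix: pd.DataFrame,
    training_set: list[str],
    direction: str = "increasing",
    epiboly: pd.Series | None = None,
    t_start: float = 5.0,
    t_end: float = 8.0,
) -> DevelopmentalOrder:
    """Rank embryos by their mean intensity over the training transcripts.

    Increasing training sets are sorted low-to-high, decreasing ones
    high-to-low, so developmental time always runs forward.  Ties break
    by measured epiboly (when given), then by embryo id.  Pseudotime maps
    rank linearly onto [t_start, t_end] hpf.
    """
    if not training_set:
        raise ValueError("training_set is empty")
    means = transcript_matrix.loc[training_set].mean(axis=0)
    key = means if direction == "increasing" else -means
    df = pd.DataFrame({"key": key})
    df["epiboly"] = epiboly.loc[df.index] if epiboly is not None else 0.0
    df["embryo_id"] = df.index
    df = df.sort_values(["key", "epiboly", "embryo_id"], kind="stable")
    ranks = list(df.index)
    n = len(ranks)
    pseudotime = np.linspace(t_start, t_end, n)
    return DevelopmentalOrder(
        ranks=ranks, pseudotime_hpf=pseudotime, training_set=list(training_set),
        direction=direction,
    )


def validate_order(
    gene_matrix: pd.DataFrame,
    candidate_order: list[str],
    baseline_order: list[str],
    test_genes: list[str],
) -> pd.DataFrame:
    """Residual variance of each test gene around its lowess trend under
    two orderings.

    Returns a per-gene frame with ``var_candidate``, ``var_baseline`` and
    a ``candidate_better`` flag; the fraction of True flags measures how
    much tighter the candidate order makes held-out genes.
    """
    rows = []
    for g in test_genes:
        vc = _lowess_residual_variance(gene_matrix.loc[g, candidate_order].to_numpy())
        vb = _lowess_residual_variance(gene_matrix.loc[g, baseline_order].to_numpy())
        rows.append((g, vc, vb, vc < vb))
    return pd.DataFrame(rows, columns=["gene_id", "var_candidate", "var_baseline",
                                       "candidate_better"]).set_index("gene_id")


def _lowess_residual_variance(y: np.ndarray) -> float:
    fitted = lowess_trend(y)
    r = y - fitted
    return float(np.var(r))
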