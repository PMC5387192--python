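"""Present/absent calling, expressed-probe filtering and normalisation.

Single-channel intensities are modelled per array as a two-component
mixture: a background component anchored on probes that vary little
across arrays and sit in the lower intensity mode, and an expressed
component fitted by EM.  A probe is called 'present' on an array when
its posterior probability of the expressed component reaches the
likelihood cutoff (default 20%, deliberately lenient to avoid false
negatives).  Truly expressed probes must then be 'present' in at least
``min_present_in_window`` samples within one moving window (default 6 of
30) with samples in epiboly order.  Retained probes are quantile
normalised and summarised probe -> transcript -> gene by the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class DetectionParams:
    log_variance_cutoff: float = -2.0  # log2 across-array variance separating low/high-variant probes
    presence_likelihood_cutoff: float = 0.20
    window: int = 30
    min_present_in_window: int = 6
    em_iterations: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.presence_likelihood_cutoff < 1:
            raise ValueError("presence_likelihood_cutoff must be in (0, 1)")
        if self.min_present_in_window > self.window:
            raise ValueError("min_present_in_window cannot exceed window")


def _lower_mode_split(values: np.ndarray) -> np.ndarray:
    """Boolean mask of the lower of two 1-D modes (exact 2-means split)."""
    order = np.argsort(values)
    x = values[order]
    n = x.size
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    k = np.arange(1, n)  # split after k points
    wss_left = cs2[k - 1] - cs[k - 1] ** 2 / k
    tot2, tot = cs2[-1], cs[-1]
    wss_right = (tot2 - cs2[k - 1]) - (tot - cs[k - 1]) ** 2 / (n - k)
    best = int(np.argmin(wss_left + wss_right)) + 1
    mask = np.zeros(n, dtype=bool)
    mask[order[:best]] = True
    return mask


def call_presence(probe_matrix: pd.DataFrame, params: DetectionParams | None = None) -> pd.DataFrame:
    """Call each probe 'present' or not on each array.

    Per array a two-Gaussian mixture is fitted: the background component
    is anchored (mean/sd held fixed) on probes whose across-array log2
    variance falls below ``log_variance_cutoff`` and whose mean intensity
    lies in the lower of the two intensity modes; the expressed component
    and the mixing weight are estimated by EM.  'Present' means the
    posterior probability of the expressed component is at least the
    likelihood cutoff (inclusive).

    Returns a boolean DataFrame with the same shape and labels.
    """
    params = params or DetectionParams()
    X = probe_matrix.to_numpy(dtype=float)
    n_probes, n_arrays = X.shape
    if n_arrays < 2:
        raise ValueError("presence calling needs at least 2 arrays")

    with np.errstate(divide="ignore"):
        logvar = np.log2(X.var(axis=1, ddof=1))
    low_var = logvar < params.log_variance_cutoff
    if low_var.sum() < 10:
        warnings.warn("too few low-variant probes to anchor a background model; all-absent")
        return pd.DataFrame(False, index=probe_matrix.index, columns=probe_matrix.columns)

    probe_means = X.mean(axis=1)
    lower = _lower_mode_split(probe_means[low_var])
    anchor = np.zeros(n_probes, dtype=bool)
    anchor[np.nonzero(low_var)[0][lower]] = True

    bg = X[anchor]  # anchors x arrays
    mu_b = bg.mean(axis=0)
    sd_b = bg.std(axis=0, ddof=1)
    if np.any(sd_b <= 0):
        warnings.warn("degenerate background distribution; all-absent")
        return pd.DataFrame(False, index=probe_matrix.index, columns=probe_matrix.columns)

    # EM per array (vectorised across arrays); background component fixed
    expressed_init = ~anchor
    mu_e = np.where(
        expressed_init.any(),
        X[expressed_init].mean(axis=0),
        mu_b + 1.0,
    )
    sd_e = np.maximum(X[expressed_init].std(axis=0, ddof=1), 1e-3)
    w_e = np.full(n_arrays, expressed_init.mean())

    def _norm_pdf(x, mu, sd):
        return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))

    post = np.zeros_like(X)
    for _ in range(params.em_iterations):
        pe = w_e * _norm_pdf(X, mu_e, sd_e)
        pb = (1.0 - w_e) * _norm_pdf(X, mu_b, sd_b)
        denom = pe + pb
        np.maximum(denom, 1e-300, out=denom)
        post = pe / denom
        tot = post.sum(axis=0)
        if np.any(tot < 1.0):
            break
        mu_e_new = (post * X).sum(axis=0) / tot
        sd_e_new = np.sqrt((post * (X - mu_e_new) ** 2).sum(axis=0) / tot)
        sd_e_new = np.maximum(sd_e_new, 1e-3)
        w_e_new = tot / n_probes
        shift = np.max(np.abs(mu_e_new - mu_e))
        mu_e, sd_e, w_e = mu_e_new, sd_e_new, np.clip(w_e_new, 1e-6, 1 - 1e-6)
        if shift < 1e-8:
            break

    degenerate = mu_e <= mu_b
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} array(s) show a single-mode intensity distribution; "
            "calling all probes absent there"
        )
        post[:, degenerate] = 0.0

    present = post >= params.presence_likelihood_cutoff
    return pd.DataFrame(present, index=probe_matrix.index, columns=probe_matrix.columns)


def expressed_probes(mask: pd.DataFrame, epiboly_order: list[str],
                     params: DetectionParams | None = None) -> list[str]:
    """Probes 'present' in >= ``min_present_in_window`` samples within at
    least one moving window of ``window`` consecutive epiboly-ordered
    embryos.  Returns retained probe ids in input row order."""
    params = params or DetectionParams()
    if set(epiboly_order) != set(mask.columns) or len(epiboly_order) != mask.shape[1]:
        raise ValueError("epiboly_order must be a permutation of the mask columns")
    n = len(epiboly_order)
    if params.window > n:
        raise ValueError(f"window ({params.window}) exceeds the number of embryos ({n})")
    M = mask.loc[:, epiboly_order].to_numpy(dtype=np.int32)
    # rolling window sums via cumulative sums along the ordered axis
    cs = np.concatenate([np.zeros((M.shape[0], 1), dtype=np.int64), np.cumsum(M, axis=1)], axis=1)
    win = cs[:, params.window:] - cs[:, :-params.window]
    keep = win.max(axis=1) >= params.min_present_in_window
    return [p for p, k in zip(mask.index, keep) if k]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of across-column
    mean order statistics; ties within a column receive the average of
    the reference values they span."""
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _collapse(matrix: pd.DataFrame, mapping: pd.Series) -> pd.DataFrame:
    common = matrix.index.intersection(mapping.index)
    sub = matrix.loc[common]
    return sub.groupby(mapping.loc[common]).mean()


def collapse_to_transcripts(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Transcript value per embryo = mean of its retained probes' values.
    Transcripts with no retained probes are omitted."""
    m = annotation.set_index("probe_id")["transcript_id"]
    return _collapse(matrix, m)


def collapse_to_genes(transcript_matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Gene value per embryo = mean over its transcripts (mirrors the
    transcript-level collapse)."""
    m = annotation.drop_duplicates("transcript_id").set_index("transcript_id")["gene_id"]
    return _collapse(transcript_matrix, m)
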