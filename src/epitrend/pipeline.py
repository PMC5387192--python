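"""End-to-end orchestration of the analysis chain.

``run_pipeline`` wires the stages together in their methodological
order: presence calling -> expressed-probe filter (epiboly order) ->
quantile normalisation -> transcript/gene summarisation -> data-driven
developmental ordering -> per-gene trend fitting, classification and
change-point location -> multilevel detection -> summary (type counts,
DTFL quantiles, PCA variance fractions).  Results are plain DataFrames
plus a JSON-serialisable summary so runs are easy to diff; everything is
deterministic for a fixed (input, config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import changepoints as cp
from . import detection, multilevel, ordering, trends
from .detection import DetectionParams
from .multilevel import MultilevelParams
from .ordering import OrderingParams
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset
from .trends import TYPE_NUMBER


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None  # directory of probe_matrix/annotation/sample_meta TSVs
    detection: DetectionParams = field(default_factory=DetectionParams)
    ordering: OrderingParams = field(default_factory=OrderingParams)
    multilevel: MultilevelParams = field(default_factory=MultilevelParams)
    changepoint_tolerance: float = cp.CLOSURE_TOLERANCE
    oscillation_threshold: float = 0.5
    oscillation_override: tuple[str, ...] = ()
    multilevel_override: tuple[str, ...] = ()
    type_map: dict = field(default_factory=lambda: dict(TYPE_NUMBER))
    direction: str = "increasing"
    qc_exclude: tuple[str, ...] = ()
    n_permutations: int = 499
    t_start: float = 5.0
    t_end: float = 8.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("synthetic", SyntheticConfig),
            ("detection", DetectionParams),
            ("ordering", OrderingParams),
            ("multilevel", MultilevelParams),
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = sub(**kwargs[key])
        for key in ("oscillation_override", "multilevel_override", "qc_exclude"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    presence_mask: pd.DataFrame
    expressed_probe_ids: list[str]
    gene_matrix: pd.DataFrame
    transcript_matrix: pd.DataFrame
    order: ordering.DevelopmentalOrder
    order_decreasing: ordering.DevelopmentalOrder | None
    gene_report: pd.DataFrame
    changepoint_table: pd.DataFrame
    multilevel_table: pd.DataFrame
    summary: dict
    dataset: SyntheticDataset | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.presence_mask.astype(int).to_csv(outdir / "presence_mask.tsv", sep="\t")
        self.gene_matrix.to_csv(outdir / "gene_matrix.tsv", sep="\t")
        self.transcript_matrix.to_csv(outdir / "transcript_matrix.tsv", sep="\t")
        self.order.to_frame().to_csv(outdir / "developmental_order.tsv", sep="\t", index=False)
        self.gene_report.to_csv(outdir / "gene_report.tsv", sep="\t")
        self.changepoint_table.to_csv(outdir / "changepoints.tsv", sep="\t", index=False)
        self.multilevel_table.to_csv(outdir / "multilevel.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(json.dumps(self.summary, indent=1, sort_keys=True))


def pca_variance(gene_matrix: pd.DataFrame) -> np.ndarray:
    """Fraction of variance per principal component of the gene x embryo
    matrix (genes centred, embryos as observations); fractions sum to 1,
    components in descending order."""
    X = gene_matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    s = np.linalg.svd(X, compute_uv=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("matrix has no variance")
    return var / total


def _representative_probes(gene_ids, transcript_matrix, annotation, presence_any) -> dict[str, str]:
    """gene -> reporting probe (most 3' probe with a present call on the
    highest-expressed transcript); vectorised over genes."""
    tx_mean = transcript_matrix.mean(axis=1)
    ann = annotation[annotation["transcript_id"].isin(transcript_matrix.index)]
    out: dict[str, str] = {}
    for g, sub in ann.groupby("gene_id", sort=False):
        if g not in gene_ids:
            continue
        best_tx = tx_mean.loc[sub["transcript_id"].unique()].idxmax()
        probes = sub[sub["transcript_id"] == best_tx].sort_values("three_prime_rank")
        called = probes[presence_any.reindex(probes["probe_id"]).fillna(False).to_numpy()]
        chosen = called if not called.empty else probes
        out[g] = str(chosen.iloc[0]["probe_id"])
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis chain; see the module docstring."""
    cfg = config
    dataset = _load_dataset(cfg)
    probe_matrix = dataset.probe_matrix
    sample_meta = dataset.sample_meta.set_index("embryo_id")

    drop = set(cfg.qc_exclude) | set(dataset.qc_fail_ids)
    keep_cols = [c for c in probe_matrix.columns if c not in drop]
    probe_matrix = probe_matrix[keep_cols]
    sample_meta = sample_meta.loc[keep_cols]
    n = len(keep_cols)

    # 1-2: presence calls, then the expressed filter in epiboly order
    mask = detection.call_presence(probe_matrix, cfg.detection)
    epiboly = sample_meta["epiboly_pct"]
    epiboly_order = list(epiboly.sort_values(kind="stable").index)
    expressed = detection.expressed_probes(mask, epiboly_order, cfg.detection)
    if not expressed:
        raise RuntimeError("detection stage retained no expressed probes")

    # 3: quantile normalisation and summarisation of the retained probes
    norm = detection.quantile_normalize(probe_matrix.loc[expressed])
    transcript_matrix = detection.collapse_to_transcripts(norm, dataset.annotation)
    gene_matrix = detection.collapse_to_genes(transcript_matrix, dataset.annotation)

    # 4: developmental ordering (increasing training set is the reference;
    # the decreasing one is kept for reciprocal validation)
    params = cfg.ordering
    train_inc = ordering.select_training_transcripts(transcript_matrix, epiboly, params, "increasing")
    order_inc = ordering.order_samples(transcript_matrix, train_inc, "increasing", epiboly,
                                       cfg.t_start, cfg.t_end)
    order_dec = None
    try:
        train_dec = ordering.select_training_transcripts(transcript_matrix, epiboly, params,
                                                         "decreasing")
        order_dec = ordering.order_samples(transcript_matrix, train_dec, "decreasing", epiboly,
                                           cfg.t_start, cfg.t_end)
    except ValueError as exc:
        warnings.warn(f"no decreasing-direction validation order: {exc}")
    primary = order_inc if cfg.direction == "increasing" else order_dec
    if primary is None:
        raise RuntimeError("requested ordering direction could not be established")
    ranks = primary.ranks

    # global off reference: median intensity of all not-present observations
    mask_np = mask.to_numpy()
    global_off = float(np.median(probe_matrix.to_numpy()[~mask_np])) if (~mask_np).any() else float("nan")

    presence_any = mask.any(axis=1)
    rep_probe = _representative_probes(set(gene_matrix.index), transcript_matrix,
                                       dataset.annotation, presence_any)
    probe_count = dataset.annotation[dataset.annotation["probe_id"].isin(expressed)] \
        .groupby("gene_id")["probe_id"].size()

    first15 = ranks[: trends.EDGE_WINDOW]
    last15 = ranks[-trends.EDGE_WINDOW:]

    # 5-6: per-gene fits, classification, change points
    rows = []
    cp_rows = []
    ordered = gene_matrix.loc[:, ranks]
    for g in gene_matrix.index:
        y = ordered.loc[g].to_numpy(dtype=float)
        trend = trends.fit_trend(y)
        osc_score, oscillatory = trends.oscillation_score(
            y, trend.lowess_values, threshold=cfg.oscillation_threshold,
            override=cfg.oscillation_override, gene=g,
        )
        probe = rep_probe.get(g)
        pm = mask.loc[probe] if probe is not None else None
        edge_on = edge_off = False
        if pm is not None:
            edge_on = int(pm.loc[first15].sum()) < trends.EDGE_MAX_PRESENT
            edge_off = int(pm.loc[last15].sum()) < trends.EDGE_MAX_PRESENT

        angle_label, _ = ("flat", 0.0)
        if trend.angle_deg > trends.ANGLE_THRESHOLD_DEG:
            angle_label = "increasing"
        elif trend.angle_deg < -trends.ANGLE_THRESHOLD_DEG:
            angle_label = "decreasing"

        point = None
        if angle_label != "flat" and probe is not None:
            kind = "start" if angle_label == "increasing" else "stop"
            try:
                point = cp.locate_changepoint_refined(
                    y, pm.loc[ranks].to_numpy(), kind, cfg.changepoint_tolerance,
                    t_start=cfg.t_start, t_end=cfg.t_end,
                )
            except ValueError:
                point = None  # probe present everywhere: no off level exists

        classification = trends.classify_gene(
            trend, edge_on, edge_off,
            start_valid=point.valid if point is not None and point.kind == "start" else False,
            stop_valid=point.valid if point is not None and point.kind == "stop" else False,
            oscillatory=oscillatory, n_samples=n,
            t_start=cfg.t_start, t_end=cfg.t_end, type_map=cfg.type_map,
        )

        # rate on the on-segment: between the located change point and the
        # window edge when a valid point exists, else the full range
        fc = classification.fc_per_hour
        if point is not None and point.valid and point.rank_estimate is not None:
            r = point.rank_estimate
            seg = np.arange(r - 1, n) if point.kind == "start" else np.arange(0, r)
            if seg.size >= 3:
                seg_slope = np.polyfit(seg + 1.0, y[seg], 1)[0]
                fc = trends.fc_per_hour(seg_slope, n, cfg.t_start, cfg.t_end)
                classification.fc_per_hour = fc

        rows.append({
            "gene_id": g,
            "probe_count": int(probe_count.get(g, 0)),
            "type": classification.type_number,
            "category": classification.category,
            "angle_deg": trend.angle_deg,
            "dtfl": trend.dtfl,
            "continuity_ratio": trend.continuity_ratio,
            "fc_per_hour": fc,
            "oscillation_score": osc_score,
            "starting_point_rank": point.rank_estimate if point is not None and point.valid and point.kind == "start" else np.nan,
            "stopping_point_rank": point.rank_estimate if point is not None and point.valid and point.kind == "stop" else np.nan,
            "first_level": float(trend.lowess_values[0]),
        })
        if point is not None:
            cp_rows.append({
                "gene_id": g, "kind": point.kind, "rank": point.rank_estimate,
                "hpf": point.hpf_estimate, "off_level": point.off_level,
                "closure_gap": point.closure_gap, "valid": point.valid,
                "off_level_fallback": point.off_level_fallback,
            })

    gene_report = pd.DataFrame(rows).set_index("gene_id")
    changepoint_table = pd.DataFrame(
        cp_rows, columns=["gene_id", "kind", "rank", "hpf", "off_level", "closure_gap",
                          "valid", "off_level_fallback"])

    # predicted onsets for genes already on at the window start: gradual-up
    # genes run their own rate backwards; constant genes borrow the
    # dataset's maximum positive rate
    up_cont = gene_report["category"] == "up_continuous"
    increasing = gene_report["category"].isin(["up_discontinuous", "up_continuous",
                                               "up_start", "up_on"])
    max_rate = float(gene_report.loc[increasing, "fc_per_hour"].max()) if increasing.any() else float("nan")
    predicted = np.full(len(gene_report), np.nan)
    if np.isfinite(global_off):
        for i, g in enumerate(gene_report.index):
            row = gene_report.iloc[i]
            if row["category"] == "up_continuous":
                rate = row["fc_per_hour"]
            elif row["category"] == "constant" and np.isfinite(max_rate):
                rate = max_rate
            else:
                continue
            if rate > 1.0:
                predicted[i] = cp.extrapolate_start(
                    row["first_level"], rate, global_off, cfg.t_start)
    gene_report["predicted_start_hpf"] = predicted

    # 7: multilevel detection and spawn association
    spawn = sample_meta.loc[ranks, "spawn"].to_numpy()
    ml_rows = []
    for g in gene_matrix.index:
        call = multilevel.call_multilevel(ordered.loc[g].to_numpy(dtype=float),
                                          cfg.multilevel, seed=cfg.seed, gene=g)
        if g in cfg.multilevel_override and call.n_levels is None:
            call.temporal_artifact = False
        if call.is_multilevel:
            ari, p = multilevel.spawn_association(call.assignments, spawn,
                                                  cfg.n_permutations, cfg.seed)
            call.spawn_ari, call.spawn_p = ari, p
        ml_rows.append({
            "gene_id": g, "n_levels": call.n_levels,
            "wss_bss_ratio": call.wss_bss_ratio,
            "log2_variance": call.log2_variance,
            "min_span": min(call.level_spans) if call.level_spans else np.nan,
            "temporal_artifact": call.temporal_artifact,
            "spawn_ari": call.spawn_ari, "spawn_p": call.spawn_p,
        })
    multilevel_table = pd.DataFrame(ml_rows)

    # 8: summary
    var_frac = pca_variance(gene_matrix)
    type_counts = gene_report["type"].value_counts().sort_index()
    dq = gene_report["dtfl"].quantile([0.5, 0.9, 0.95, 0.96, 0.99])
    summary = {
        "n_embryos": n,
        "n_probes": int(probe_matrix.shape[0]),
        "n_expressed_probes": len(expressed),
        "n_expressed_transcripts": int(transcript_matrix.shape[0]),
        "n_expressed_genes": int(gene_matrix.shape[0]),
        "n_training_transcripts_increasing": len(train_inc),
        "type_counts": {int(k): int(v) for k, v in type_counts.items()},
        "dtfl_quantiles": {str(k): float(v) for k, v in dq.items()},
        "dtfl_frac_below_0.4": float((gene_report["dtfl"] < 0.4).mean()),
        "pc_variance_fractions": [float(v) for v in var_frac[:5]],
        "n_multilevel": int(multilevel_table["n_levels"].notna().sum()),
        "n_two_level": int((multilevel_table["n_levels"] == 2).sum()),
        "n_three_level": int((multilevel_table["n_levels"] == 3).sum()),
        "thresholds": {
            "log_variance_cutoff": cfg.detection.log_variance_cutoff,
            "presence_likelihood_cutoff": cfg.detection.presence_likelihood_cutoff,
            "window": cfg.detection.window,
            "min_present_in_window": cfg.detection.min_present_in_window,
            "low_intensity_cutoff": cfg.ordering.low_intensity_cutoff,
            "high_intensity_cutoff": cfg.ordering.high_intensity_cutoff,
            "angle_threshold_deg": trends.ANGLE_THRESHOLD_DEG,
            "continuity_threshold": trends.CONTINUITY_THRESHOLD,
            "changepoint_tolerance": cfg.changepoint_tolerance,
            "multilevel_var_cutoff": cfg.multilevel.var_cutoff,
            "multilevel_ratio_cutoff": cfg.multilevel.ratio_cutoff,
            "oscillation_threshold": cfg.oscillation_threshold,
        },
        "seed": cfg.seed,
    }

    return PipelineResult(
        presence_mask=mask,
        expressed_probe_ids=list(expressed),
        gene_matrix=gene_matrix,
        transcript_matrix=transcript_matrix,
        order=primary,
        order_decreasing=order_dec,
        gene_report=gene_report,
        changepoint_table=changepoint_table,
        multilevel_table=multilevel_table,
        summary=summary,
        dataset=dataset,
    )


def _load_dataset(cfg: PipelineConfig) -> SyntheticDataset:
    if cfg.synthetic is not None:
        return generate_dataset(cfg.synthetic)
    if cfg.input_dir is None:
        raise ValueError("config needs either a synthetic config or an input_dir")
    d = Path(cfg.input_dir)
    probe_matrix = pd.read_csv(d / "probe_matrix.tsv", sep="\t", index_col=0)
    annotation = pd.read_csv(d / "annotation.tsv", sep="\t")
    sample_meta = pd.read_csv(d / "sample_meta.tsv", sep="\t")
    from .synthetic import SyntheticTruth

    truth = SyntheticTruth([], {}, {}, {}, {}, {}, [], {})
    return SyntheticDataset(probe_matrix, annotation, sample_meta, truth, [])
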