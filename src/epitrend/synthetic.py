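"""Synthetic individual-embryo expression time courses with planted truth.

The generator emulates the statistical structure of a single-channel
microarray time course over late blastula / gastrula stages: ~179 embryos
from 9 spawns collected across a 5-8 hpf window, probe-level log2
intensities in which only a minority of probes report expressed genes, a
noisy epiboly measurement that stalls near 50%, and per-gene dynamics
drawn from ten profile archetypes (constant, gradual up/down, piecewise
up/down, switch-on/off inside the window, near-edge start/stop with a
basal plateau, oscillatory).  Spawn-linked level offsets plant multilevel
genes.  Everything needed to score recovery (true order, category,
parameters, spawn levels) is returned as :class:`SyntheticTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .trends import CATEGORIES

_DEFAULT_TYPE_PROPORTIONS = {
    "down_off": 0.038,
    "down_stop": 0.040,
    "down_continuous": 0.210,
    "down_discontinuous": 0.050,
    "constant": 0.305,
    "up_discontinuous": 0.050,
    "up_continuous": 0.220,
    "up_start": 0.055,
    "up_on": 0.023,
    "oscillatory": 0.009,
}

_DEFAULT_PROBE_COUNTS = {1: 0.42, 2: 0.30, 3: 0.22, 4: 0.06}


@dataclass
class SyntheticConfig:
    """Study-design parameters of the generator.

    Defaults mirror the emulated experiment: 179 QC-passing embryos from
    9 spawns over 5-8 hpf, ~17% of probes reporting expressed genes, and
    probe-per-gene multiplicities of 42/30/22/6% for 1/2/3/4+ probes.
    Intensities are log2 units throughout.
    """

    n_embryos: int = 179
    n_genes: int = 2000
    n_spawns: int = 9
    t_start: float = 5.0
    t_end: float = 8.0
    type_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TYPE_PROPORTIONS)
    )
    noise_sd: float = 0.25
    noise_heterogeneity: float = 0.25  # sd of the per-gene lognormal noise factor
    spawn_offset_sd: float = 1.25
    multilevel_fraction: float = 0.015
    oscillator_count: int = 4
    oscillation_period: float = 0.5
    oscillation_amplitude: float = 0.5
    probe_count_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROBE_COUNTS)
    )
    background_mean: float = 8.0
    background_sd: float = 0.5
    # fraction of background probes with elevated means (cross-hybridising
    # or otherwise bright probes), uniform over bright_range
    background_bright_fraction: float = 0.08
    background_bright_range: tuple[float, float] = (8.4, 10.0)
    epiboly_noise_sd: float = 3.0
    collection_jitter_sd: float = 0.15  # hours; fertilization-time / speed spread
    expressed_probe_fraction: float = 0.17
    ramp_hours: float = 0.25
    probe_affinity_sd: float = 0.25
    defection_prob: float = 0.05
    include_failed_array: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        for name, m in (
            ("type_proportions", self.type_proportions),
            ("probe_count_distribution", self.probe_count_distribution),
        ):
            total = float(sum(m.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(v < 0 for v in m.values()):
                raise ValueError(f"{name} contains negative fractions")
        unknown = set(self.type_proportions) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in type_proportions: {sorted(unknown)}")
        for name in ("noise_sd", "spawn_offset_sd", "epiboly_noise_sd", "background_sd",
                     "probe_affinity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.multilevel_fraction <= 1:
            raise ValueError("multilevel_fraction must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth: the recovery target for every downstream test."""

    true_order: list[str]  # embryo ids, developmental order
    true_pseudotime: dict[str, float]  # embryo id -> hpf
    gene_category: dict[str, str]
    gene_params: dict[str, dict[str, float]]
    spawn_assignment: dict[str, int]
    spawn_levels: dict[str, dict[int, float]]  # gene -> spawn -> log2 offset
    multilevel_genes: list[str]
    embryo_level: dict[str, dict[str, float]]  # gene -> embryo -> realized offset


@dataclass
class SyntheticDataset:
    """Probe-level matrix plus annotation, sample metadata and truth."""

    probe_matrix: pd.DataFrame  # rows: probe ids, cols: embryo ids
    annotation: pd.DataFrame  # probe_id, transcript_id, gene_id, three_prime_rank
    sample_meta: pd.DataFrame  # embryo_id, spawn, epiboly_pct, collection_index
    truth: SyntheticTruth
    qc_fail_ids: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        """Write matrix/annotation/metadata as TSV and the truth as JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.probe_matrix.to_csv(outdir / "probe_matrix.tsv", sep="\t")
        self.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        self.sample_meta.to_csv(outdir / "sample_meta.tsv", sep="\t", index=False)
        t = self.truth
        payload = {
            "true_order": t.true_order,
            "true_pseudotime": t.true_pseudotime,
            "gene_category": t.gene_category,
            "gene_params": t.gene_params,
            "spawn_assignment": t.spawn_assignment,
            "spawn_levels": {g: {str(s): v for s, v in d.items()} for g, d in t.spawn_levels.items()},
            "multilevel_genes": t.multilevel_genes,
            "qc_fail_ids": self.qc_fail_ids,
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1))


def gene_trend(category: str, params: Mapping[str, float], t: np.ndarray | float,
               t_start: float = 5.0, t_end: float = 8.0) -> np.ndarray | float:
    """Noise-free expression of one gene at time ``t`` (hpf).

    ``params`` uses keys baseline, slope (log2/h), start_hpf, stop_hpf,
    amplitude, phase, period, off_level, ramp_h, slope2, break_hpf as the
    category requires.  Switching genes follow a quadratic ease-in over
    ``ramp_h``: the rate of change is smallest next to the switch point,
    giving onset/offset profiles their characteristic concave approach to
    the off level.
    """
    t = np.asarray(t, dtype=float)
    baseline = params.get("baseline", 0.0)
    slope = params.get("slope", 0.0)
    if category == "constant":
        out = np.full_like(t, baseline)
    elif category in ("up_continuous", "down_continuous"):
        out = baseline + slope * (t - t_start)
    elif category in ("up_discontinuous", "down_discontinuous"):
        b = params["break_hpf"]
        s2 = params["slope2"]
        out = np.where(
            t <= b,
            baseline + slope * (t - t_start),
            baseline + slope * (b - t_start) + s2 * (t - b),
        )
    elif category in ("up_on", "up_start"):
        out = _switch_on(t, params["start_hpf"], slope, params["off_level"], params["ramp_h"])
    elif category in ("down_off", "down_stop"):
        # time-mirror of the switch-on shape around the stop point
        out = _switch_on(2.0 * params["stop_hpf"] - t + 0.0, params["stop_hpf"], slope,
                         params["off_level"], params["ramp_h"])
    elif category == "oscillatory":
        out = baseline + params["amplitude"] * np.sin(
            2 * np.pi * (t - t_start) / params["period"] + params["phase"]
        )
    else:
        raise ValueError(f"unknown category: {category!r}")
    return out if out.shape else float(out)


def _switch_on(t: np.ndarray, start: float, slope: float, off: float, ramp: float) -> np.ndarray:
    """Quadratic ease-in from the off level, centred on ``start``: the
    profile leaves ``off`` at start - ramp/2 and joins the linear rise
    (slope-continuously) at start + ramp/2.  Centring makes ``start``
    the intersection of the off plateau with the extrapolated linear
    rise, i.e. the geometric switch point."""
    a = slope * ramp / 2.0  # level gained over the ramp
    s = t - (start - ramp / 2.0)
    out = np.where(
        s <= 0,
        off,
        np.where(s < ramp, off + a * (s / ramp) ** 2, off + a + slope * (s - ramp)),
    )
    return out


# epiboly calibration: 40% at 5 hpf, 80% at 8 hpf, with the characteristic
# slow-down of blastoderm spreading around 50% epiboly
_EPIBOLY_KNOTS_T = np.array([5.0, 5.8, 7.0, 8.0])
_EPIBOLY_KNOTS_PCT = np.array([40.0, 50.0, 55.0, 80.0])


def simulate_epiboly(true_pseudotime: np.ndarray, config: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Measured epiboly percentage per embryo.

    The expectation is a monotone piecewise-linear map of hpf to percent
    anchored at 40%/5 hpf and 80%/8 hpf with a reduced-slope plateau near
    50%; Gaussian measurement noise (``epiboly_noise_sd`` percentage
    points) is added and the result clipped to [30, 90].
    """
    t = np.asarray(true_pseudotime, dtype=float)
    pct = np.interp(t, _EPIBOLY_KNOTS_T, _EPIBOLY_KNOTS_PCT)
    if config.epiboly_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        pct = pct + rng.normal(0.0, config.epiboly_noise_sd, size=t.shape)
    return np.clip(pct, 30.0, 90.0)


def _draw_gene_params(category: str, cfg: SyntheticConfig, rng: np.random.Generator) -> dict:
    """Draw one gene's trend parameters from the study-condition priors."""
    t0, t1 = cfg.t_start, cfg.t_end
    t_mid = 0.5 * (t0 + t1)
    # Trends are anchored at the window midpoint so the cross-sectional
    # intensity distribution stays stationary over development (the
    # premise under which quantile normalization is applicable), and
    # levels span continuously from just above the detection boundary to
    # the top of the range, as expressed genes do on real arrays.
    floor = 10.0
    top = 14.5
    p: dict[str, float]
    if category == "constant":
        # constants extend below the trending floor, into the weakly
        # expressed regime straddling the detection boundary
        p = {"baseline": float(rng.uniform(9.4, top))}
    elif category in ("up_continuous", "down_continuous"):
        mag = rng.uniform(0.2, 0.8)
        slope = float(mag if category == "up_continuous" else -mag)
        # keep the whole path above the floor: |level at either edge| >= floor
        level_mid = float(rng.uniform(floor + 1.5 * mag, top))
        p = {"slope": slope, "baseline": level_mid - slope * (t_mid - t0)}
    elif category in ("up_discontinuous", "down_discontinuous"):
        sign = 1.0 if category == "up_discontinuous" else -1.0
        s1 = float(sign * rng.uniform(0.0, 0.2))
        s2 = float(sign * rng.uniform(0.8, 1.5))
        br = float(t0 + rng.uniform(0.35, 0.65) * (t1 - t0))
        # time-average and minimum of the two-slope shape (baseline 0)
        a1 = s1 * (br - t0) ** 2 / 2.0
        a2 = s1 * (br - t0) * (t1 - br) + s2 * (t1 - br) ** 2 / 2.0
        abar = (a1 + a2) / (t1 - t0)
        m0 = min(0.0, s1 * (br - t0) + s2 * (t1 - br))
        level_mid = float(rng.uniform(floor + abar - m0, top))
        p = {"slope": s1, "slope2": s2, "break_hpf": br, "baseline": level_mid - abar}
    elif category == "up_on":
        # onsets staggered across most of the window, as observed onsets
        # are; off levels spread from deep background up to just below
        # the detection boundary, as resting levels are on real arrays
        p = {
            "slope": float(rng.uniform(1.2, 2.0)),
            "start_hpf": float(rng.uniform(5.4, 7.0)),
            "off_level": float(rng.uniform(cfg.background_mean, 9.2)),
            "ramp_h": cfg.ramp_hours,
        }
    elif category == "down_off":
        # decay of a recently active transcript leaves residual signal:
        # switched-off genes rest above pristine background
        p = {
            "slope": float(rng.uniform(1.2, 2.0)),
            "stop_hpf": float(rng.uniform(6.0, 7.6)),
            "off_level": float(rng.uniform(cfg.background_mean + 0.6, 9.4)),
            "ramp_h": cfg.ramp_hours,
        }
    elif category == "up_start":
        # basal plateau near the presence boundary; onsets staggered like
        # the switch-on type's
        p = {
            "slope": float(rng.uniform(0.8, 1.6)),
            "start_hpf": float(rng.uniform(5.3, 7.0)),
            "off_level": float(rng.uniform(9.5, 9.9)),
            "ramp_h": cfg.ramp_hours,
        }
    elif category == "down_stop":
        p = {
            "slope": float(rng.uniform(0.8, 1.6)),
            "stop_hpf": float(rng.uniform(6.0, 7.7)),
            "off_level": float(rng.uniform(9.5, 9.9)),
            "ramp_h": cfg.ramp_hours,
        }
    elif category == "oscillatory":
        p = {
            "baseline": float(rng.uniform(10.5, top)),
            "amplitude": cfg.oscillation_amplitude,
            "period": cfg.oscillation_period,
            "phase": float(rng.uniform(0, 2 * np.pi)),
        }
    else:
        raise ValueError(f"unknown category: {category!r}")
    return p


def _assign_categories(cfg: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    """Category assignment with counts fixed by the proportions (largest
    remainder allocation) so the dataset's dynamic composition is a study
    condition rather than a multinomial draw; which genes carry which
    category is still random.  ``oscillator_count`` pins the number of
    oscillators exactly (the emulated study contains a known handful)."""
    names = [c for c in CATEGORIES if cfg.type_proportions.get(c, 0.0) > 0 or c == "constant"]
    probs = np.array([cfg.type_proportions.get(c, 0.0) for c in names], dtype=float)
    probs = probs / probs.sum()
    ideal = probs * cfg.n_genes
    counts = np.floor(ideal).astype(int)
    remainder = cfg.n_genes - counts.sum()
    for i in np.argsort(ideal - counts)[::-1][:remainder]:
        counts[i] += 1
    # pin the oscillator count, balancing against the constant pool
    if "oscillatory" in names:
        k = names.index("oscillatory")
        c = names.index("constant")
        want = min(cfg.oscillator_count, cfg.n_genes)
        counts[c] += counts[k] - want
        counts[k] = want
    cats = np.repeat(names, counts)
    return [str(c) for c in cats[rng.permutation(cfg.n_genes)]]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full probe-level dataset plus ground truth.

    Reproducible for a fixed ``config.seed``.  Embryo collection times are
    uniform over the window with a small jitter; expressed genes follow
    their category's trend over true pseudotime; non-expressed probes are
    drawn from the background distribution; multilevel genes receive
    spawn-linked level offsets from {-delta, 0, +delta}.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_total = cfg.n_embryos + (1 if cfg.include_failed_array else 0)
    embryo_ids = [f"E{i + 1:03d}" for i in range(n_total)]
    # one embryo per minute: an even clock-time grid across the window,
    # jittered by fertilization-time uncertainty and developmental-speed
    # differences between embryos
    t = np.linspace(cfg.t_start, cfg.t_end, n_total)
    t = t + rng.normal(0.0, cfg.collection_jitter_sd, size=n_total)
    t = np.clip(t, cfg.t_start, cfg.t_end)
    t = t[rng.permutation(n_total)]  # collection order is not embryo id order
    order_idx = np.argsort(t, kind="stable")
    true_order = [embryo_ids[i] for i in order_idx]
    spawn = rng.integers(0, cfg.n_spawns, size=n_total)
    epiboly = simulate_epiboly(t, cfg, rng)

    cats = _assign_categories(cfg, rng)
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    gene_params = {g: _draw_gene_params(c, cfg, rng) for g, c in zip(gene_ids, cats)}

    # multilevel planting: spawn-linked offsets on flat or mild-trend genes,
    # so the level structure (not the trend) dominates the profile variance
    eligible = [
        g for g, c in zip(gene_ids, cats)
        if c == "constant"
        or (c in ("up_continuous", "down_continuous") and abs(gene_params[g]["slope"]) <= 0.3)
    ]
    n_ml = int(round(cfg.multilevel_fraction * cfg.n_genes))
    ml_genes = sorted(rng.choice(eligible, size=min(n_ml, len(eligible)), replace=False))
    delta = cfg.spawn_offset_sd
    spawn_levels: dict[str, dict[int, float]] = {}
    embryo_level: dict[str, dict[str, float]] = {}
    for g in ml_genes:
        # mostly two-level genes (levels -delta/+delta, i.e. a gap of
        # 2*delta, which is what survives the variance filter), a few
        # three-level; every level carried by at least two spawns
        three = rng.random() < 0.06
        choices = (-delta, 0.0, delta) if three else (-delta, delta)
        while True:
            lv = rng.choice(choices, size=cfg.n_spawns)
            distinct, counts = np.unique(lv, return_counts=True)
            if len(distinct) == len(choices) and (counts >= 2).all():
                break
        spawn_levels[g] = {s: float(lv[s]) for s in range(cfg.n_spawns)}
        # per-embryo defection to a different level
        off = lv[spawn]
        defect = rng.random(n_total) < cfg.defection_prob
        for i in np.nonzero(defect)[0]:
            others = [v for v in choices if v != off[i]]
            off[i] = rng.choice(others)
        embryo_level[g] = {e: float(o) for e, o in zip(embryo_ids, off)}

    # probe / transcript structure for expressed genes
    counts = sorted(cfg.probe_count_distribution)
    cprobs = np.array([cfg.probe_count_distribution[k] for k in counts])
    n_probes_per_gene = rng.choice(counts, size=cfg.n_genes, p=cprobs / cprobs.sum())

    probe_rows = []  # (probe_id, transcript_id, gene_id, three_prime_rank)
    probe_gene: list[int] = []  # gene index per expressed probe
    pid = 0
    for gi, g in enumerate(gene_ids):
        k = int(n_probes_per_gene[gi])
        two_tx = k >= 2 and rng.random() < 0.3
        split = rng.integers(1, k) if two_tx else k
        for j in range(k):
            tx = f"{g}.T{1 if j < split else 2}"
            rank = (j + 1) if j < split else (j - split + 1)
            probe_rows.append((f"P{pid + 1:06d}", tx, g, int(rank)))
            probe_gene.append(gi)
            pid += 1
    n_expr_probes = pid

    # background (non-expressed) probes sized so expressed probes are the
    # configured fraction of the array
    f = cfg.expressed_probe_fraction
    n_bg = int(round(n_expr_probes * (1.0 - f) / f)) if f < 1 else 0
    bg_gene_ids = []
    bg_left = n_bg
    bi = 0
    while bg_left > 0:
        k = int(rng.choice(counts, p=cprobs / cprobs.sum()))
        k = min(k, bg_left)
        g = f"BG{bi + 1:05d}"
        bg_gene_ids.append(g)
        for j in range(k):
            probe_rows.append((f"P{pid + 1:06d}", f"{g}.T1", g, j + 1))
            pid += 1
        bg_left -= k
        bi += 1

    annotation = pd.DataFrame(
        probe_rows, columns=["probe_id", "transcript_id", "gene_id", "three_prime_rank"]
    )

    # expression values: gene trend + spawn offset + probe affinity + noise
    expr_gene_vals = np.empty((cfg.n_genes, n_total))
    for gi, (g, c) in enumerate(zip(gene_ids, cats)):
        v = gene_trend(c, gene_params[g], t, cfg.t_start, cfg.t_end)
        if g in embryo_level:
            v = v + np.array([embryo_level[g][e] for e in embryo_ids])
        expr_gene_vals[gi] = v

    values = np.empty((pid, n_total))
    affinity = rng.normal(0.0, cfg.probe_affinity_sd, size=n_expr_probes)
    # per-gene noise heterogeneity: real genes differ in how tightly they
    # are regulated/measured, giving the tightness statistic its tail
    gene_noise = cfg.noise_sd * np.exp(
        rng.normal(0.0, cfg.noise_heterogeneity, size=cfg.n_genes)
    )
    probe_noise_sd = gene_noise[np.asarray(probe_gene)]
    values[:n_expr_probes] = (
        expr_gene_vals[np.asarray(probe_gene)] + affinity[:, None]
        + probe_noise_sd[:, None] * rng.standard_normal((n_expr_probes, n_total))
    )
    n_bg_probes = pid - n_expr_probes
    bg_probe_mean = rng.normal(cfg.background_mean, cfg.background_sd, size=n_bg_probes)
    bright = rng.random(n_bg_probes) < cfg.background_bright_fraction
    bg_probe_mean[bright] = rng.uniform(*cfg.background_bright_range, size=int(bright.sum()))
    values[n_expr_probes:] = bg_probe_mean[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(n_bg_probes, n_total)
    )

    probe_matrix = pd.DataFrame(values, index=annotation["probe_id"].to_list(), columns=embryo_ids)

    collection = rng.permutation(n_total)
    sample_meta = pd.DataFrame(
        {
            "embryo_id": embryo_ids,
            "spawn": spawn,
            "epiboly_pct": epiboly,
            "collection_index": collection,
        }
    )

    qc_fail = [embryo_ids[int(rng.integers(0, n_total))]] if cfg.include_failed_array else []

    truth = SyntheticTruth(
        true_order=true_order,
        true_pseudotime={e: float(x) for e, x in zip(embryo_ids, t)},
        gene_category=dict(zip(gene_ids, cats)),
        gene_params=gene_params,
        spawn_assignment={e: int(s) for e, s in zip(embryo_ids, spawn)},
        spawn_levels=spawn_levels,
        multilevel_genes=list(ml_genes),
        embryo_level=embryo_level,
    )
    return SyntheticDataset(
        probe_matrix=probe_matrix,
        annotation=annotation,
        sample_meta=sample_meta,
        truth=truth,
        qc_fail_ids=qc_fail,
    )
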