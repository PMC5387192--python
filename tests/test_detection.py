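"""Presence calling, the moving-window expressed filter, normalisation
and probe -> transcript -> gene summarisation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from epitrend import detection
from epitrend.detection import (
    DetectionParams,
    call_presence,
    collapse_to_genes,
    collapse_to_transcripts,
    expressed_probes,
    quantile_normalize,
)


def _mask_from_rows(rows, n_embryos):
    cols = [f"E{i:03d}" for i in range(n_embryos)]
    return pd.DataFrame(rows, columns=cols,
                        index=[f"P{i}" for i in range(len(rows))]).astype(bool)


class TestExpressedProbes:
    def test_six_consecutive_present_is_retained(self):
        row = np.zeros(179, bool)
        row[9:15] = True  # embryos ranked 10-15
        mask = _mask_from_rows([row], 179)
        assert expressed_probes(mask, list(mask.columns)) == ["P0"]

    def test_five_present_total_is_discarded(self):
        row = np.zeros(179, bool)
        row[50:55] = True
        mask = _mask_from_rows([row], 179)
        assert expressed_probes(mask, list(mask.columns)) == []

    def test_six_spread_out_is_discarded(self):
        row = np.zeros(179, bool)
        row[[0, 39, 79, 119, 159, 178]] = True
        mask = _mask_from_rows([row], 179)
        assert expressed_probes(mask, list(mask.columns)) == []

    def test_window_larger_than_series_rejected(self):
        mask = _mask_from_rows([np.ones(10, bool)], 10)
        with pytest.raises(ValueError, match="window"):
            expressed_probes(mask, list(mask.columns))

    def test_equals_brute_force_window_scan(self, rng):
        """Oracle: explicit scan over every window of 30 on random masks."""
        n, w, k = 179, 30, 6
        rows = rng.random((200, n)) < rng.uniform(0.0, 0.1, size=(200, 1))
        mask = _mask_from_rows(list(rows), n)
        fast = set(expressed_probes(mask, list(mask.columns)))
        slow = {
            probe
            for probe, row in zip(mask.index, rows)
            if any(row[i:i + w].sum() >= k for i in range(n - w + 1))
        }
        assert fast == slow


class TestQuantileNormalize:
    def test_two_column_closed_form(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        col = np.array([5.0, 1.0, 3.0, 2.0])
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy())

    def test_columns_share_one_sorted_vector(self, rng):
        m = pd.DataFrame(rng.normal(10, 2, size=(50, 6)))
        out = quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)
        assert np.allclose(out.mean(axis=0), out[:, 0].mean())


class TestCollapse:
    annotation = pd.DataFrame(
        {
            "probe_id": ["p1", "p2", "p3", "p4"],
            "transcript_id": ["t1", "t2", "t2", "t3"],
            "gene_id": ["g1", "g1", "g1", "g2"],
            "three_prime_rank": [1, 1, 2, 1],
        }
    )

    def test_single_probe_transcript_passes_through(self):
        m = pd.DataFrame({"e1": [10.0], "e2": [11.0]}, index=["p1"])
        tx = collapse_to_transcripts(m, self.annotation)
        np.testing.assert_allclose(tx.loc["t1"], [10.0, 11.0])

    def test_mean_of_probes_and_filtered_probe_omitted(self):
        m = pd.DataFrame({"e1": [10.0, 12.0]}, index=["p2", "p3"])
        tx = collapse_to_transcripts(m, self.annotation)
        assert tx.loc["t2", "e1"] == pytest.approx(11.0)
        assert "t1" not in tx.index  # its probe was filtered out upstream

    def test_gene_collapse_is_mean_of_transcripts(self):
        tx = pd.DataFrame({"e1": [12.0, 14.0, 9.0]}, index=["t1", "t2", "t3"])
        genes = collapse_to_genes(tx, self.annotation)
        assert genes.loc["g1", "e1"] == pytest.approx(13.0)
        assert genes.loc["g2", "e1"] == pytest.approx(9.0)

    def test_matches_two_loop_oracle_on_synthetic_fixture(self, small_dataset):
        ds = small_dataset
        sub = ds.probe_matrix.iloc[:150, :10]
        ann = ds.annotation[ds.annotation["probe_id"].isin(sub.index)]
        tx = collapse_to_transcripts(sub, ann)
        genes = collapse_to_genes(tx, ann)
        # naive oracle: two explicit loops over transcripts then genes
        tx_oracle = {}
        for t in ann["transcript_id"].unique():
            probes = ann.loc[ann["transcript_id"] == t, "probe_id"]
            tx_oracle[t] = sub.loc[probes].to_numpy().mean(axis=0)
        gene_oracle = {}
        for g in ann["gene_id"].unique():
            ts = ann.loc[ann["gene_id"] == g, "transcript_id"].unique()
            gene_oracle[g] = np.mean([tx_oracle[t] for t in ts], axis=0)
        for g, vals in gene_oracle.items():
            np.testing.assert_allclose(genes.loc[g].to_numpy(), vals)


class TestCallPresence:
    def test_extreme_probe_present_everywhere(self, small_dataset):
        ds = small_dataset
        mask = call_presence(ds.probe_matrix)
        # a probe far above background in every array: pick a constant
        # expressed gene probe with high mean
        means = ds.probe_matrix.mean(axis=1)
        strong = means.idxmax()
        assert mask.loc[strong].all()

    def test_background_probes_called_absent(self, small_dataset):
        """Planted background probes (means >= 4 noise sd below expression)
        are called absent in at least 99% of cells."""
        ds = small_dataset
        mask = call_presence(ds.probe_matrix)
        bg = ds.annotation["gene_id"].str.startswith("BG").to_numpy()
        deep_bg = bg & (ds.probe_matrix.mean(axis=1).to_numpy() < 9.0)
        assert mask.to_numpy()[deep_bg].mean() <= 0.01

    def test_degenerate_single_mode_matrix_is_all_absent(self):
        m = pd.DataFrame(np.full((50, 5), 8.0) + np.arange(5) * 1e-6,
                         index=[f"p{i}" for i in range(50)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = call_presence(m)
        assert not mask.to_numpy().any()

    def test_inclusive_threshold_convention(self):
        assert DetectionParams().presence_likelihood_cutoff == 0.20
        with pytest.raises(ValueError):
            DetectionParams(presence_likelihood_cutoff=0.0)
        with pytest.raises(ValueError):
            DetectionParams(min_present_in_window=31)


def test_lower_mode_split_separates_two_clusters(rng):
    values = np.concatenate([rng.normal(8, 0.3, 100), rng.normal(12, 0.5, 60)])
    lower = detection._lower_mode_split(values)
    assert lower.sum() == 100
    assert values[lower].max() < values[~lower].min()
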