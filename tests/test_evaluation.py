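import numpy as np
import pandas as pd
import pytest

from deepgwas import evaluation as ev


def sig_df(positions, chrom="1", scores=None, keys=None):
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": [chrom] * n if isinstance(chrom, str) else chrom,
            "pos": positions,
            "key": keys or [f"k{i}" for i in range(n)],
            "score": scores if scores is not None else np.ones(n),
        }
    )


def brute_force_loci(positions, merge_bp):
    """Transitive-closure merge oracle: O(n²) union-find over pairs."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pos = sorted(positions)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(pos[i] - pos[j]) <= merge_bp:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(pos[i])
    return sorted((min(g), max(g)) for g in groups.values())


class TestCallLoci:
    def test_single_variant_single_locus(self):
        loci = ev.call_loci(sig_df([500]))
        assert len(loci) == 1 and loci[0].start == loci[0].end == 500

    def test_boundary_at_merge_distance_joins(self):
        one = ev.call_loci(sig_df([1_000, 251_000]), merge_bp=250_000)
        two = ev.call_loci(sig_df([1_000, 251_001]), merge_bp=250_000)
        assert len(one) == 1 and len(two) == 2

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(0)
        positions = sorted(rng.choice(np.arange(1, 50_000_000), 200, replace=False))
        loci = ev.call_loci(sig_df(positions), merge_bp=250_000)
        got = sorted((l.start, l.end) for l in loci)
        assert got == brute_force_loci(positions, 250_000)
        assert sum(len(l.members) for l in loci) == 200

    def test_index_variant_is_top_scorer(self):
        df = sig_df([100, 200, 300], scores=[1.0, 5.0, 2.0])
        locus = ev.call_loci(df)[0]
        assert locus.index_variant == "k1" and locus.index_score == 5.0

    def test_empty_input(self):
        assert ev.call_loci(sig_df([])) == []


class TestMatchLoci:
    def test_identical_all_matched_and_disjoint_chrom_none(self):
        a = ev.call_loci(sig_df([1_000, 600_000]))
        assert ev.match_loci(a, a).all()
        b = ev.call_loci(sig_df([1_000], chrom="2"))
        assert not ev.match_loci(b, a).any()

    def test_partial_overlaps_match_manual_enumeration(self):
        rng = np.random.default_rng(1)
        pa = sorted(rng.choice(np.arange(1, 20_000_000), 40, replace=False))
        pb = sorted(rng.choice(np.arange(1, 20_000_000), 40, replace=False))
        a = ev.call_loci(sig_df(pa))
        b = ev.call_loci(sig_df(pb))
        slack = 250_000
        got = ev.match_loci(a, b, slack_bp=slack)
        expected = [
            any(lb.start <= la.end + slack and lb.end >= la.start - slack for lb in b)
            for la in a
        ]
        assert got.tolist() == expected


class TestFindEnhanced:
    def _preds(self):
        return pd.DataFrame(
            {
                "chrom": ["1"] * 4,
                "pos": [1_000, 2_000, 2_000_000, 4_000_000],
                "key": ["k0", "k1", "k2", "k3"],
                "prob": [0.9, 0.2, 0.6, 0.1],
                "p_value": [1e-9, 0.5, 1e-5, 1e-9],
            }
        )

    def test_definitions(self):
        res = ev.find_enhanced(self._preds())
        # k0 predicted+input-significant: not enhanced; k2 predicted, p=1e-5: enhanced
        assert res.enhanced_variants.tolist() == [False, False, True, False]
        assert [l.members for l in res.enhanced_loci] == [["k2"]]
        # k3 locus is input-significant but predicted below threshold: anti-enhanced
        assert [l.members for l in res.anti_enhanced_loci] == [["k3"]]

    def test_matches_row_wise_filter_on_random_toy(self):
        rng = np.random.default_rng(2)
        n = 50
        preds = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.sort(rng.choice(np.arange(1, 10**8), n, replace=False)),
                "key": [f"k{i}" for i in range(n)],
                "prob": rng.uniform(0, 1, n),
                "p_value": 10.0 ** -rng.uniform(0, 10, n),
            }
        )
        res = ev.find_enhanced(preds)
        manual = (preds["prob"] >= 0.5) & (preds["p_value"] >= 5e-8)
        np.testing.assert_array_equal(res.enhanced_variants, manual)
        # enhanced and input-significant sets are disjoint by construction
        assert not (res.enhanced_variants & (preds["p_value"] < 5e-8)).any()


class TestVariantMetrics:
    def test_f1_printed_formula(self):
        prob = np.array([0.9, 0.9, 0.1, 0.1])
        truth = np.array([1, 0, 1, 0])
        m = ev.variant_metrics(prob, truth)
        assert m["tp"] == m["fp"] == m["fn"] == 1
        assert m["f1"] == pytest.approx(1 / (1 + 0.5 * 2))

    def test_perfect_predictor(self):
        truth = np.array([1, 1, 0, 0])
        m = ev.variant_metrics(np.array([0.9, 0.8, 0.2, 0.1]), truth)
        assert m["tpr"] == 1.0 and m["f1"] == 1.0 and m["auroc"] == 1.0

    def test_auroc_equals_concordance_pair_oracle(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 1, 500)
        scores[::5] = np.round(scores[::5], 1)  # force some ties
        truth = rng.integers(0, 2, 500)
        m = ev.variant_metrics(scores, truth)
        pos = scores[truth == 1]
        neg = scores[truth == 0]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
            pos[:, None] == neg[None, :]
        ).sum()
        oracle = wins / (len(pos) * len(neg))
        assert m["auroc"] == pytest.approx(oracle, abs=1e-12)

    def test_counts_partition_n(self):
        rng = np.random.default_rng(4)
        m = ev.variant_metrics(rng.uniform(0, 1, 100), rng.integers(0, 2, 100))
        assert m["tp"] + m["fp"] + m["fn"] + m["tn"] == 100

    def test_single_class_truth_reports_missing_curves(self):
        m = ev.variant_metrics(np.array([0.1, 0.9]), np.array([1, 1]))
        assert m["auroc"] is None and m["roc"] is None


class TestLocusMetrics:
    def test_identical_sets(self):
        loci = ev.call_loci(sig_df([1, 10**6, 5 * 10**6, 9 * 10**6, 20 * 10**6]))
        m = ev.locus_metrics(loci, loci)
        assert m["tpr"] == 1.0 and m["f1"] == 1.0

    def test_empty_predictions(self):
        truth = ev.call_loci(sig_df([1_000]))
        assert ev.locus_metrics([], truth)["tpr"] == 0.0

    def test_known_overlap_toy(self):
        truth = ev.call_loci(sig_df([10**6 * k for k in (1, 5, 9, 13, 17, 21, 25, 29)]))
        pred = ev.call_loci(sig_df([10**6 * k for k in (1, 5, 9, 13, 40, 44)]))
        m = ev.locus_metrics(pred, truth, slack_bp=250_000)
        assert (m["tp"], m["fn"], m["fp"]) == (4, 4, 2)
        assert m["tp"] + m["fn"] == len(truth)


class TestThresholdSweep:
    def _preds(self, n=200, seed=5):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.sort(rng.choice(np.arange(1, 10**8), n, replace=False)),
                "key": [f"k{i}" for i in range(n)],
                "prob": rng.uniform(0, 1, n),
                "p_value": 10.0 ** -rng.uniform(0, 12, n),
            }
        )

    def test_ten_thresholds_monotone_and_recomputable(self):
        table = ev.threshold_sweep(self._preds())
        assert len(table) == 10
        assert table["threshold"].tolist() == pytest.approx(
            [0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95]
        )
        counts = table["n_enhanced_loci"].to_numpy()
        assert (np.diff(counts) <= 0).all()
        # independent re-filter oracle: loci are the base-threshold (0.5) set,
        # counted at threshold t iff their peak probability clears t
        base = ev.find_enhanced(self._preds(), prob_threshold=0.5)
        preds = self._preds()
        manual_var = (preds["prob"].to_numpy() >= 0.5) & (
            preds["p_value"].to_numpy() >= 5e-8
        )
        assert table["n_enhanced_variants"].iloc[0] == manual_var.sum()
        for _, row in table.iterrows():
            survivors = [
                l for l in base.enhanced_loci if l.index_score >= row["threshold"]
            ]
            assert row["n_enhanced_loci"] == len(survivors)


class TestValidationBinning:
    def _enhanced(self, probs, spacing=10**6):
        return [
            ev.Locus("1", (i + 1) * spacing, (i + 1) * spacing, members=[f"k{i}"],
                     index_variant=f"k{i}", index_score=p)
            for i, p in enumerate(probs)
        ]

    def test_all_validated(self):
        enhanced = self._enhanced([0.55, 0.72, 0.93])
        validation = [self._enhanced([0.5] * 3)]  # same positions
        table = ev.validation_binning(enhanced, validation)
        nonempty = table[table["n_loci"] > 0]
        assert (nonempty["prop_validated"] == 1.0).all()

    def test_no_overlap_all_zero(self):
        enhanced = self._enhanced([0.55, 0.72])
        far = [ev.Locus("2", 10**6, 10**6)]
        table = ev.validation_binning(enhanced, [far])
        nonempty = table[table["n_loci"] > 0]
        assert (nonempty["prop_validated"] == 0.0).all()

    def test_monotone_when_validity_planted_monotone(self):
        """Higher-P̂ loci made truly causal more often ⇒ rising proportion."""
        from scipy.stats import spearmanr

        corrs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            probs = rng.uniform(0.5, 1.0, 300)
            valid = rng.random(300) < (probs - 0.4)  # planted monotone validity
            enhanced = self._enhanced(probs)
            validation = [[l for l, v in zip(self._enhanced(probs), valid) if v]]
            table = ev.validation_binning(enhanced, validation)
            ok = table["n_loci"] > 3
            rho = spearmanr(table.loc[ok, "bin_low"], table.loc[ok, "prop_validated"])[0]
            corrs.append(rho)
        assert np.median(corrs) > 0
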