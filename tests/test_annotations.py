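import itertools

import numpy as np
import pandas as pd
import pytest

from deepgwas import annotations as ann
from deepgwas.data_io import ConfigError
from deepgwas.schema import DEFAULT_SCHEMA


def track(name, triples):
    return ann.IntervalAnnotation.from_intervals(name, triples)


def variants_df(positions, chrom="1"):
    return pd.DataFrame(
        {
            "chrom": [chrom] * len(positions),
            "pos": positions,
            "variant_id": [f"v{i}" for i in range(len(positions))],
            "key": [f"{chrom}:{p}:A:G" for p in positions],
        }
    )


class TestOverlapIndicator:
    def test_boundary_convention(self):
        # 1-based pos p is inside [start, end) iff start < p <= end
        t = track("t", [("1", 99, 100)])
        assert ann.overlap_indicator(variants_df([100]), t).tolist() == [1]
        t2 = track("t2", [("1", 100, 200)])
        got = ann.overlap_indicator(variants_df([100, 101, 200, 201]), t2)
        assert got.tolist() == [0, 1, 1, 0]

    def test_matches_all_pairs_scan(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(np.arange(1, 100_000), size=1_000, replace=False))
        starts = rng.integers(0, 99_000, size=50)
        ends = starts + rng.integers(1, 2_000, size=50)
        t = track("t", [("1", s, e) for s, e in zip(starts, ends)])
        got = ann.overlap_indicator(variants_df(pos), t)
        expected = np.array([
            any(s < p <= e for s, e in zip(starts, ends)) for p in pos
        ], dtype=np.uint8)
        np.testing.assert_array_equal(got, expected)

    def test_unknown_chromosome_yields_zero_with_warning(self):
        t = track("t", [("1", 0, 100)])
        with pytest.warns(UserWarning, match="absent"):
            got = ann.overlap_indicator(variants_df([50], chrom="chrX"), t)
        assert got.tolist() == [0]


class TestScoreLookup:
    def test_present_absent_and_median_fill(self):
        trk = ann.ScoreTrack("s", pd.Series({"v0": 3.2, "v1": 1.0, "v2": 5.0}))
        vs = variants_df([100, 200, 300, 400])  # v3 absent
        got, n_filled = ann.score_lookup(vs, trk, fill="zero")
        assert got.tolist() == [3.2, 1.0, 5.0, 0.0] and n_filled == 1
        got_med, _ = ann.score_lookup(vs, trk, fill="median")
        assert got_med[3] == pytest.approx(np.median([3.2, 1.0, 5.0]))

    def test_bulk_median_fill_matches_independent_median(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=80), index=[f"v{i}" for i in range(80)])
        trk = ann.ScoreTrack("s", scores)
        vs = variants_df(np.arange(1, 101) * 10)  # 20 variants absent
        got, n_filled = ann.score_lookup(vs, trk, fill="median")
        assert n_filled == 20
        np.testing.assert_allclose(got[80:], np.median(scores.to_numpy()))


class TestFilterEqtls:
    def test_strict_threshold_and_set_semantics(self):
        table = pd.DataFrame(
            {
                "key": ["k1", "k1", "k2", "k3"],
                "gene": ["g1", "g2", "g1", "g3"],
                "p": [1e-7, 1e-9, 1e-6, 1e-5],  # k2 exactly at threshold: excluded
            }
        )
        assert ann.filter_eqtls(table) == {"k1"}

    def test_manual_filter_count(self):
        rng = np.random.default_rng(4)
        keys = [f"k{i % 5}" for i in range(20)]
        p = np.concatenate([np.full(7, 1e-8), rng.uniform(1e-5, 1, 13)])
        table = pd.DataFrame({"key": keys, "gene": "g", "p": p})
        expected = set(table.loc[table.p < 1e-6, "key"])
        assert ann.filter_eqtls(table) == expected
        assert len(expected) == 5


class TestJaccard:
    def test_closed_forms(self):
        a = track("a", [("1", 0, 100)])
        b = track("b", [("1", 50, 150)])
        assert ann.jaccard_index(a, a) == 1.0
        assert ann.jaccard_index(a, track("c", [("1", 500, 600)])) == 0.0
        assert ann.jaccard_index(a, b) == pytest.approx(1 / 3)

    def test_symmetric_and_fragmentation_invariant(self):
        rng = np.random.default_rng(8)
        a = track("a", [("1", int(s), int(s) + 500) for s in rng.integers(0, 50_000, 20)])
        b = track("b", [("1", int(s), int(s) + 300) for s in rng.integers(0, 50_000, 20)])
        assert ann.jaccard_index(a, b) == ann.jaccard_index(b, a)
        # splitting every interval of a in two changes nothing
        frag = track("a2", [
            piece
            for chrom, (ss, es) in a.intervals.items()
            for s, e in zip(ss, es)
            for piece in ((chrom, s, (s + e) // 2), (chrom, (s + e) // 2, e))
        ])
        assert ann.jaccard_index(frag, b) == pytest.approx(ann.jaccard_index(a, b))
        assert ann.jaccard_index(frag, a) == 1.0

    def test_agrees_with_bedtools(self, tmp_path):
        """Independent oracle: bedtools jaccard on the same two tracks."""
        import shutil
        import subprocess

        if shutil.which("bedtools") is None:
            pytest.skip("bedtools not on PATH")
        rng = np.random.default_rng(12)
        a = track("a", [("1", int(s), int(s) + 400) for s in rng.integers(0, 30_000, 15)])
        b = track("b", [("1", int(s), int(s) + 600) for s in rng.integers(0, 30_000, 15)])
        fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
        a.to_bed(fa)
        b.to_bed(fb)
        out = subprocess.run(["bedtools", "jaccard", "-a", fa, "-b", fb],
                             capture_output=True, text=True, check=True).stdout
        oracle = float(out.splitlines()[1].split("\t")[2])
        # bedtools prints ~7 significant digits
        assert ann.jaccard_index(a, b) == pytest.approx(oracle, abs=1e-6)


class TestClusterAnnotations:
    def test_identity_cut(self):
        tracks = [track(f"t{i}", [("1", i * 1000, i * 1000 + 500)]) for i in range(4)]
        metas = ann.cluster_annotations(tracks, n_groups=4)
        assert len(metas) == 4
        for meta, t in zip(metas, sorted(tracks, key=lambda x: x.name)):
            assert ann.jaccard_index(meta, t) == 1.0

    def test_identical_pair_merges_first(self):
        a = track("a", [("1", 0, 100)])
        b = track("b", [("1", 0, 100)])
        c = track("c", [("2", 0, 100)])
        metas = ann.cluster_annotations([c, a, b], n_groups=2)
        sizes = sorted(m.total_bp() for m in metas)
        assert len(metas) == 2
        assert sizes == [100, 100]  # a+b union is still 100 bp; c alone 100

    def test_recovers_planted_two_block_structure(self):
        """Exhaustive-search oracle: best 2-partition by within-cluster Jaccard."""
        rng = np.random.default_rng(6)
        base1 = [("1", int(s), int(s) + 300) for s in rng.integers(0, 20_000, 12)]
        base2 = [("2", int(s), int(s) + 300) for s in rng.integers(0, 20_000, 12)]
        tracks = []
        for i in range(3):
            tracks.append(track(f"x{i}", base1 + [("1", 30_000 + 100 * i, 30_050 + 100 * i)]))
            tracks.append(track(f"y{i}", base2 + [("2", 30_000 + 100 * i, 30_050 + 100 * i)]))
        metas = ann.cluster_annotations(tracks, n_groups=2)
        got = frozenset(
            frozenset(t.name for t in tracks if ann.jaccard_index(m, t) > 0.5)
            for m in metas
        )
        # brute-force best 2-partition of the 6 tracks by mean within-cluster Jaccard
        names = [t.name for t in tracks]
        by_name = {t.name: t for t in tracks}
        best, best_score = None, -1
        for size in range(1, 6):
            for combo in itertools.combinations(names, size):
                c1, c2 = set(combo), set(names) - set(combo)
                score = 0.0
                for grp in (c1, c2):
                    pairs = list(itertools.combinations(sorted(grp), 2))
                    if pairs:
                        score += np.mean([
                            ann.jaccard_index(by_name[u], by_name[v]) for u, v in pairs
                        ])
                if score > best_score:
                    best_score, best = score, frozenset((frozenset(c1), frozenset(c2)))
        assert got == best

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(10)
        tracks = [
            track(f"t{i}", [("1", int(s), int(s) + 200) for s in rng.integers(0, 10_000, 8)])
            for i in range(6)
        ]
        m1 = ann.cluster_annotations(tracks, n_groups=3)
        m2 = ann.cluster_annotations(tracks[::-1], n_groups=3)
        assert [m.name for m in m1] == [m.name for m in m2]
        for a, b in zip(m1, m2):
            assert ann.jaccard_index(a, b) == 1.0

    def test_too_many_groups_is_config_error(self):
        with pytest.raises(ConfigError):
            ann.cluster_annotations([track("a", [("1", 0, 1)])], n_groups=2)


class TestAssembleFeatures:
    def _inputs(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        pos = np.arange(1, n + 1) * 1_000
        stats = variants_df(pos)
        stats["p_value"] = rng.uniform(1e-10, 1, n)
        stats["odds_ratio"] = rng.lognormal(0, 0.1, n)
        maf = rng.uniform(0.01, 0.5, n)
        ld_o = 1 + rng.uniform(0, 5, n)
        ld_k = rng.uniform(0, 1, n) * ld_o
        tracks = {
            name: track(name, [("1", int(p) - 1, int(p)) for p in pos[rng.random(n) < 0.4]])
            for name in DEFAULT_SCHEMA
            if name not in ("neglog10_p", "odds_ratio", "maf", "ld_score_overall",
                            "ld_score_known", "eqtl", "phylop", "fathmm_xf",
                            "cadd_phred", "user_slot")
        }
        scores = {
            name: ann.ScoreTrack(name, pd.Series(rng.normal(size=n),
                                                 index=stats["variant_id"]))
            for name in ("phylop", "fathmm_xf", "cadd_phred")
        }
        eqtl = set(stats["key"][rng.random(n) < 0.3])
        return stats, maf, ld_o, ld_k, tracks, scores, eqtl

    def test_schema_order_and_cellwise_consistency(self):
        stats, maf, ld_o, ld_k, tracks, scores, eqtl = self._inputs()
        X = ann.assemble_features(stats, maf, ld_o, ld_k, tracks, scores, eqtl)
        assert list(X.columns) == DEFAULT_SCHEMA and X.shape == (10, 33)
        np.testing.assert_allclose(X["neglog10_p"], -np.log10(stats["p_value"]))
        np.testing.assert_allclose(X["maf"], maf)
        np.testing.assert_allclose(X["ld_score_known"], ld_k)
        for name, trk in tracks.items():
            np.testing.assert_array_equal(
                X[name].to_numpy(), ann.overlap_indicator(stats, trk).astype(float)
            )
        for name, trk in scores.items():
            np.testing.assert_allclose(X[name], ann.score_lookup(stats, trk)[0])
        np.testing.assert_array_equal(
            X["eqtl"].to_numpy(), stats["key"].isin(eqtl).to_numpy().astype(float)
        )
        np.testing.assert_array_equal(X["user_slot"], np.zeros(10))

    def test_neglog10_closed_form_and_cap(self):
        stats, maf, ld_o, ld_k, tracks, scores, eqtl = self._inputs()
        stats.loc[0, "p_value"] = 5e-8
        stats.loc[1, "p_value"] = 1e-400  # underflows to 0.0 in float
        assert stats.loc[1, "p_value"] == 0.0
        X = ann.assemble_features(stats, maf, ld_o, ld_k, tracks, scores, eqtl)
        assert X.iloc[0]["neglog10_p"] == pytest.approx(7.301, abs=1e-3)
        assert X.iloc[1]["neglog10_p"] == 320.0

    def test_unresolvable_name_lists_candidates(self):
        stats, maf, ld_o, ld_k, tracks, scores, eqtl = self._inputs()
        with pytest.raises(ConfigError, match="candidates"):
            ann.assemble_features(stats, maf, ld_o, ld_k, tracks, scores, eqtl,
                                  schema=["neglog10_p", "no_such_feature"])
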