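"""CPM filtering, FDR adjustment, twofold classification and summaries."""

import numpy as np
import pandas as pd
import pytest

from fluoribo import simulate as S
from fluoribo import translatome as T
from fluoribo.errors import DataError

from oracles import bh_oracle, cpm_keep_oracle


class TestCpmFilter:
    def test_counts_equal_cpm_at_unit_library(self):
        counts = pd.DataFrame(
            {"s1": [10, 0], "s2": [10, 10]}, index=["keep", "drop"]
        )
        m = T.CountMatrix(counts, library_size=pd.Series({"s1": 10**6, "s2": 10**6}))
        kept = T.cpm_filter(m, min_cpm=1.0)
        assert list(kept.counts.index) == ["keep"]

    def test_all_zero_matrix_drops_everything(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [0, 0]}, index=["a", "b"])
        m = T.CountMatrix(counts, library_size=pd.Series({"s1": 10, "s2": 10}))
        assert T.cpm_filter(m).counts.empty

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        m = T.CountMatrix(counts, library_size=pd.Series({"s1": 0}))
        with pytest.raises(DataError, match="library size"):
            T.cpm_filter(m)

    def test_min_samples_mode_keeps_more(self):
        m = S.simulate_count_matrix(n_genes=300, n_samples=4, seed=1)
        strict = set(T.cpm_filter(m).counts.index)
        relaxed = set(T.cpm_filter(m, min_samples=2).counts.index)
        assert strict <= relaxed

    def test_matches_per_gene_brute_force_on_simulated_matrix(self):
        m = S.simulate_count_matrix(n_genes=400, n_samples=5, seed=9)
        kept = set(T.cpm_filter(m, min_cpm=1.0).counts.index)
        libs = m.library_size.to_numpy()
        oracle = {
            gene
            for gene, row in m.counts.iterrows()
            if cpm_keep_oracle(row.to_numpy(), libs, 1.0)
        }
        assert kept == oracle

    def test_order_preserved(self):
        m = S.simulate_count_matrix(n_genes=100, n_samples=3, seed=2)
        kept = T.cpm_filter(m).counts.index
        original = [g for g in m.counts.index if g in set(kept)]
        assert list(kept) == original


class TestBenjaminiHochberg:
    def test_single_pvalue_unchanged(self):
        assert T.benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        # p(i)*n/i = (.04, .04, .04, .04) after right-to-left minimum
        assert T.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        assert T.benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            T.benjamini_hochberg([0.5, 1.5])

    def test_oracle_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(1, 60)
            p = rng.uniform(0, 1, n)
            np.testing.assert_allclose(
                T.benjamini_hochberg(p), bh_oracle(p), rtol=1e-12
            )

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(0, 1, 200))
        adj = T.benjamini_hochberg(p)
        assert np.all(np.diff(adj) >= -1e-15)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)


class TestClassifyTranslation:
    def _records(self, rows):
        return [T.DifferentialTranslationRecord(*r) for r in rows]

    def test_clear_positive(self):
        c = T.classify_translation(self._records([("g", 1.5, 0.01)]))
        assert c.up == {"g"}

    def test_fails_significance(self):
        c = T.classify_translation(self._records([("g", 1.5, 0.2)]))
        assert c.unchanged == {"g"}

    def test_exact_twofold_is_unchanged(self):
        # "more than twofold" is strict: |log2FC| == 1 does not qualify
        c = T.classify_translation(self._records([("g", 1.0, 0.001), ("h", -1.0, 0.001)]))
        assert c.up == set() and c.down == set()

    def test_planted_counts_recovered_exactly(self):
        df = S.simulate_de_table(n_genes=2000, n_up=50, n_down=20, seed=4)
        c = T.classify_translation(df)
        assert (len(c.up), len(c.down)) == (50, 20)

    def test_partition_property(self):
        df = S.simulate_de_table(n_genes=500, n_up=30, n_down=10, seed=6)
        c = T.classify_translation(df)
        assert c.up | c.down | c.unchanged == set(df["gene_id"])
        assert len(c.up) + len(c.down) + len(c.unchanged) == len(df)

    def test_threshold_monotonicity(self):
        df = S.simulate_de_table(n_genes=800, n_up=40, n_down=40,
                                 lfc_magnitude=1.5, seed=7)
        base = T.classify_translation(df, log2fc_threshold=1.0, alpha=0.05)
        stricter_lfc = T.classify_translation(df, log2fc_threshold=1.6, alpha=0.05)
        stricter_alpha = T.classify_translation(df, log2fc_threshold=1.0, alpha=0.001)
        assert stricter_lfc.up <= base.up and stricter_lfc.down <= base.down
        assert stricter_alpha.up <= base.up and stricter_alpha.down <= base.down

    def test_padj_computed_from_raw_pvalues_when_absent(self):
        records = self._records([])
        df = pd.DataFrame(
            {"gene": ["a", "b", "c", "d"], "log2fc": [2.0, 0.1, -2.0, 0.0],
             "pvalue": [0.001, 0.8, 0.002, 0.9]}
        )
        c = T.classify_translation(df)
        assert c.up == {"a"} and c.down == {"c"}

    def test_missing_both_p_columns_rejected(self):
        with pytest.raises(DataError, match="missing both"):
            T.classify_translation(self._records([("g", 1.5, None, None)]))

    def test_null_table_yields_essentially_no_calls(self):
        # uniform raw p, small log2fc noise: after BH at alpha 0.05 the
        # expected number of discoveries is ~0
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(5000)],
                "log2fc": rng.normal(0, 0.3, 5000),
                "pvalue": rng.uniform(0, 1, 5000),
            }
        )
        c = T.classify_translation(df)
        assert len(c.up) + len(c.down) <= 2


class TestSummaries:
    def test_low_dose_condition_counts(self):
        s = T.condition_summary(702, 275)
        assert s == {"n_up": 702, "n_down": 275, "n_total": 977, "pct_up": 72}

    def test_high_dose_condition_counts(self):
        s = T.condition_summary(937, 477)
        assert s == {"n_up": 937, "n_down": 477, "n_total": 1414, "pct_up": 66}

    def test_empty_classification_fraction_undefined(self):
        s = T.condition_summary(0, 0)
        assert s["pct_up"] is None and s["n_total"] == 0

    def test_two_condition_overlap(self):
        a = T.TranslationClassification(
            up=frozenset("abc"), down=frozenset("x"), unchanged=frozenset("q"),
            log2fc_threshold=1.0, alpha=0.05,
        )
        b = T.TranslationClassification(
            up=frozenset("bcd"), down=frozenset("xy"), unchanged=frozenset("p"),
            log2fc_threshold=1.0, alpha=0.05,
        )
        summary = T.summarize_classification(a, b, labels=("c10", "c50"))
        assert summary["overlap"]["up"] == {"only_c10": 1, "both": 2, "only_c50": 1}
        assert summary["overlap"]["down"] == {"only_c10": 0, "both": 1, "only_c50": 1}
        assert summary["conditions"]["c10"]["n_total"] == 4


class TestIo:
    def test_de_table_round_trip(self, tmp_path):
        df = S.simulate_de_table(n_genes=100, n_up=5, n_down=3, seed=0)
        path = tmp_path / "de.tsv"
        df.to_csv(path, sep="\t", index=False)
        reread = T.read_de_table(path)
        c = T.classify_translation(reread)
        assert (len(c.up), len(c.down)) == (5, 3)

    def test_classification_frame_is_partition(self):
        df = S.simulate_de_table(n_genes=50, n_up=4, n_down=2, seed=1)
        c = T.classify_translation(df)
        frame = T.classification_to_frame(c)
        assert len(frame) == 50
        assert set(frame["class"]) == {"up", "down", "unchanged"}
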