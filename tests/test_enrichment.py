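from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from thermoglyco.enrichment import (
    ContingencyTable,
    cluster_heatmap,
    enrich,
    fisher_two_tailed,
    localization_summary,
)
from thermoglyco.io_formats import AnnotationTable
from thermoglyco.simulate import SimulationConfig, generate


def fisher_oracle(k, K, n, N):
    """Exact two-sided Fisher p by rational hypergeometric enumeration."""
    denom = comb(N, K)
    lo, hi = max(0, K + n - N), min(K, n)
    pmf = {x: Fraction(comb(n, x) * comb(N - n, K - x), denom)
           for x in range(lo, hi + 1)}
    obs = pmf[k]
    return float(sum(p for p in pmf.values() if p <= obs))


class TestFisher:
    def test_worked_table_3113(self):
        # [[3,1],[1,3]]: foreground 4 with 3 in category; background-only 4 with 1
        tab = ContingencyTable(k=3, K=4, n=4, N=8)
        p = fisher_two_tailed(tab)
        assert p == pytest.approx(0.4857, abs=2e-4)
        assert p == pytest.approx(fisher_oracle(3, 4, 4, 8), abs=1e-10)

    def test_degenerate_margins_give_p_one(self):
        assert fisher_two_tailed(ContingencyTable(k=4, K=4, n=4, N=4)) == 1.0

    def test_transpose_symmetry(self, rng):
        # swapping the roles of the two margins leaves p unchanged
        for _ in range(100):
            N = int(rng.integers(4, 30))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            lo, hi = max(0, K + n - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            p1 = fisher_two_tailed(ContingencyTable(k, K, n, N))
            p2 = fisher_two_tailed(ContingencyTable(k, n, K, N))
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_margin_violation_errors(self):
        with pytest.raises(ValueError):
            ContingencyTable(k=5, K=4, n=5, N=10)
        with pytest.raises(ValueError):
            ContingencyTable(k=2, K=10, n=3, N=10)  # n-k exceeds N-K

    def test_matches_scipy_minimum_likelihood(self, rng):
        from scipy.stats import fisher_exact
        for _ in range(200):
            N = int(rng.integers(4, 40))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            lo, hi = max(0, K + n - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            if n - k > N - K:
                continue
            mine = fisher_two_tailed(ContingencyTable(k, K, n, N))
            ref = fisher_exact([[k, K - k], [n - k, N - K - (n - k)]]).pvalue
            assert mine == pytest.approx(ref, abs=1e-9)


def toy_annotations():
    ann = AnnotationTable()
    for i in range(20):
        acc = f"P{i}"
        if i < 10:
            ann.go.setdefault(acc, []).append(("BP", "GO:A"))
        if i % 2 == 0:
            ann.go.setdefault(acc, []).append(("BP", "GO:B"))
    return ann


class TestEnrich:
    def test_foreground_equals_background_p_one(self):
        ann = toy_annotations()
        bg = {f"P{i}" for i in range(20)}
        df = enrich(bg, bg, ann, "BP")
        assert (df["p_value"] == 1.0).all()

    def test_category_absent_from_foreground_not_emitted(self):
        ann = toy_annotations()
        bg = {f"P{i}" for i in range(20)}
        fg = {"P1", "P3"}  # odd indices: never in GO:B
        df = enrich(fg, bg, ann, "BP")
        assert set(df["category"]) == {"GO:A"}

    def test_foreground_not_subset_errors(self):
        ann = toy_annotations()
        with pytest.raises(ValueError, match="subset"):
            enrich({"X"}, {"P1"}, ann, "BP")

    def test_planted_category_top_ranked(self, rng):
        ann = AnnotationTable()
        bg = {f"P{i}" for i in range(200)}
        fg = {f"P{i}" for i in range(40)}
        for acc in bg:
            i = int(acc[1:])
            if (i < 40 and rng.random() < 0.5) or (i >= 40 and rng.random() < 0.05):
                ann.go.setdefault(acc, []).append(("BP", "GO:PLANTED"))
            if rng.random() < 0.2:
                ann.go.setdefault(acc, []).append(("BP", "GO:RANDOM"))
        df = enrich(fg, bg, ann, "BP")
        assert df.iloc[0]["category"] == "GO:PLANTED"
        assert df.iloc[0]["p_value"] < 0.05
        assert df.iloc[0]["fold_enrichment"] > 1

    def test_uniform_foreground_false_positive_rate(self, rng):
        # random foregrounds: ~5% of category tests come out p < 0.05
        bg = [f"P{i}" for i in range(400)]
        ann = AnnotationTable()
        for acc in bg:
            for c in range(10):
                if rng.random() < 0.25:
                    ann.go.setdefault(acc, []).append(("BP", f"GO:C{c}"))
        n_sig = n_tot = 0
        for _ in range(120):
            fg = set(rng.choice(bg, size=50, replace=False))
            df = enrich(fg, set(bg), ann, "BP")
            n_sig += int((df["p_value"] < 0.05).sum())
            n_tot += len(df)
        rate = n_sig / n_tot
        assert 0.01 <= rate <= 0.08   # exact test is conservative at small counts


class TestHeatmap:
    def make_rows(self):
        rows = []
        for cell in ("up@A", "down@A"):
            for cat, p in [("GO:1", 1e-6), ("GO:2", 1e-6), ("GO:3", 0.5)]:
                rows.append({"category": cat, "namespace": "BP", "k": 5, "K": 10,
                             "n": 8, "N": 100, "fold_enrichment": 5.0,
                             "p_value": p, "direction": cell, "significant": p < 0.05})
        return pd.DataFrame(rows)

    def test_identical_rows_adjacent_and_insignificant_excluded(self):
        heat = cluster_heatmap(self.make_rows())
        assert list(heat.matrix.index) == ["GO:1", "GO:2"]  # GO:3 never significant
        i1 = heat.row_order.index("GO:1")
        i2 = heat.row_order.index("GO:2")
        assert abs(i1 - i2) == 1

    def test_all_p_one_gives_zero_matrix(self):
        rows = self.make_rows()
        rows["p_value"] = 1.0
        heat = cluster_heatmap(rows, alpha=1.1)  # keep rows despite p = 1
        assert (heat.matrix.to_numpy() == 0).all()

    def test_permutation_invariance(self, rng):
        rows = self.make_rows()
        heat1 = cluster_heatmap(rows)
        heat2 = cluster_heatmap(rows.sample(frac=1.0, random_state=3))
        pd.testing.assert_frame_equal(heat1.matrix, heat2.matrix)
        assert heat1.row_order == heat2.row_order

    def test_single_row_no_dendrogram(self):
        rows = self.make_rows()
        rows = rows[rows["category"] == "GO:1"]
        heat = cluster_heatmap(rows)
        assert heat.row_linkage is None
        assert heat.row_order == ["GO:1"]

    def test_small_k_categories_excluded(self):
        rows = self.make_rows()
        rows.loc[rows["category"] == "GO:1", "k"] = 1
        heat = cluster_heatmap(rows)
        assert "GO:1" not in heat.matrix.index


class TestLocalization:
    def test_percent_split(self):
        ann = AnnotationTable()
        for acc in ("P1", "P2", "P3"):
            ann.location[acc] = "nucleus"
        ann.location["P4"] = "cytoplasm"
        df = localization_summary(["P1", "P2", "P3", "P4"], ann)
        assert df.at["nucleus", "percent"] == pytest.approx(75.0)
        assert df.at["cytoplasm", "percent"] == pytest.approx(25.0)

    def test_unlabeled_binned_unknown(self):
        ann = AnnotationTable()
        ann.location["P1"] = "nucleus"
        df = localization_summary(["P1", "P2"], ann)
        assert df.at["unknown", "count"] == 1

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            localization_summary([], AnnotationTable())

    def test_percent_sums_to_100_random(self, rng):
        ann = AnnotationTable()
        accs = [f"P{i}" for i in range(80)]
        for a in accs:
            ann.location[a] = str(rng.choice(["a", "b", "c", "d"]))
        df = localization_summary(accs, ann)
        assert df["percent"].sum() == pytest.approx(100.0, abs=0.1)
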