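import numpy as np
import pandas as pd
import pytest

from thermoglyco.io_formats import GlycoSiteRecord, PeptideRecord
from thermoglyco.quantification import (
    NormalizationError,
    NormalizedPeptideMatrix,
    correct_site_ratio,
    correct_site_ratios,
    normalize_by_median_ratio,
    rollup_protein,
)

from conftest import make_peptide


def random_peptides(design, rng, n=12, n_prot=4, missing_rate=0.0):
    """Random peptide set: log-normal intensities, some shared peptides."""
    peps = []
    for i in range(n):
        shared = rng.random() < 0.2 and n_prot >= 2
        if shared:
            a, b = rng.choice(n_prot, size=2, replace=False)
            accs = (f"P{a}", f"P{b}")
        else:
            accs = (f"P{rng.integers(n_prot)}",)
        intens = {}
        for ch in design.channels:
            if missing_rate and rng.random() < missing_rate:
                intens[ch] = None
            else:
                intens[ch] = float(np.exp(rng.normal(13, 1)))
        peps.append(PeptideRecord(f"PEP{i}K", accs, intens))
    return peps


class TestNormalization:
    def test_all_ratios_one_is_identity(self, design):
        peps = [make_peptide(design, f"P{i}K", [f"P{i}"], {"T30": 1, "T50": 1, "T55": 1})
                for i in range(3)]
        m = normalize_by_median_ratio(peps, design)
        for lab in ("T50/T30", "T55/T30", "T55/T50"):
            assert np.allclose(m.peptide_ratio(lab), 1.0)

    def test_median_two_normalizes_to_quarter_one_four(self, design):
        # raw T50/T30 ratios {0.5, 2, 8}: median 2 -> normalized {0.25, 1, 4}
        levels = [{"T30": 1, "T50": r, "T55": 1} for r in (0.5, 2.0, 8.0)]
        peps = [make_peptide(design, f"P{i}K", [f"P{i}"], lv) for i, lv in enumerate(levels)]
        m = normalize_by_median_ratio(peps, design)
        assert np.allclose(sorted(m.peptide_ratio("T50/T30")), [0.25, 1.0, 4.0])

    def test_single_channel_scale_invariance(self, design, rng):
        peps = random_peptides(design, rng, n=15)
        ref = normalize_by_median_ratio(peps, design)
        ch = design.channels[4]
        scaled = [
            PeptideRecord(p.peptide_seq, p.accessions,
                          {c: (v * 10.0 if c == ch and v is not None else v)
                           for c, v in p.intensities.items()})
            for p in peps
        ]
        m2 = normalize_by_median_ratio(scaled, design)
        for lab in ("T50/T30", "T55/T30", "T55/T50"):
            np.testing.assert_allclose(m2.log2_ratios[lab], ref.log2_ratios[lab],
                                       atol=1e-9)

    def test_grand_median_invariant(self, design, rng):
        for _ in range(25):
            peps = random_peptides(design, rng, n=int(rng.integers(5, 25)),
                                   missing_rate=0.1)
            try:
                m = normalize_by_median_ratio(peps, design)
            except NormalizationError:
                continue
            for lab in ("T50/T30", "T55/T30", "T55/T50"):
                r = m.peptide_ratio(lab)[m.unique_mask]
                r = r[np.isfinite(r)]
                assert abs(np.median(r) - 1.0) < 1e-9

    def test_shared_peptides_excluded_from_median(self, design):
        # one unique peptide at ratio 2 defines the normalizer; the shared
        # peptide at ratio 8 must not shift it
        peps = [
            make_peptide(design, "UNIQK", ["P1"], {"T30": 1, "T50": 2, "T55": 1}),
            make_peptide(design, "SHRDK", ["P1", "P2"], {"T30": 1, "T50": 8, "T55": 1}),
        ]
        m = normalize_by_median_ratio(peps, design)
        r = dict(zip(m.peptides["peptide_seq"], m.peptide_ratio("T50/T30")))
        assert r["UNIQK"] == pytest.approx(1.0)
        assert r["SHRDK"] == pytest.approx(4.0)

    def test_error_when_no_complete_unique_peptide(self, design):
        shared = make_peptide(design, "SHRDK", ["P1", "P2"], {"T30": 1, "T50": 2, "T55": 1})
        with pytest.raises(NormalizationError, match="T50/T30"):
            normalize_by_median_ratio([shared], design)


def matrix_from_ratios(design, ratios_by_protein):
    """Hand-built NormalizedPeptideMatrix with given linear peptide ratios
    (same value in all three replicates, all comparisons)."""
    rows, accs = [], []
    for acc, ratios in ratios_by_protein.items():
        for r in ratios:
            rows.append(r)
            accs.append(acc)
    n = len(rows)
    meta = pd.DataFrame({
        "peptide_seq": [f"PEP{i}K" for i in range(n)],
        "accessions": accs,
        "is_unique": [True] * n,
    })
    L = np.tile(np.log2(np.asarray(rows, dtype=float))[:, None], (1, 3))
    log2_ratios = {design.comparison_label(c): L.copy() for c in design.comparisons}
    rng = np.random.default_rng(0)
    logI = rng.normal(13, 1, size=(n, len(design.channels)))
    normalizers = {design.comparison_label(c): (np.zeros(3), 0.0)
                   for c in design.comparisons}
    return NormalizedPeptideMatrix(design, meta, log2_ratios, normalizers, logI)


class TestRollup:
    def test_single_peptide_ratio_passes_through(self, design):
        m = matrix_from_ratios(design, {"P1": [2.5]})
        prot = rollup_protein(m)
        assert prot.table.at["P1", "ratio T50/T30"] == pytest.approx(2.5)
        assert prot.table.at["P1", "n_unique_peptides"] == 1

    def test_even_median_is_mean_of_middle_values(self, design):
        m = matrix_from_ratios(design, {"P1": [1.0, 2.0, 4.0, 100.0]})
        prot = rollup_protein(m)
        assert prot.table.at["P1", "ratio T50/T30"] == pytest.approx(3.0)

    def test_duplicating_peptides_leaves_median_unchanged(self, design):
        vals = [0.5, 1.3, 2.0, 8.0, 11.0]
        a = rollup_protein(matrix_from_ratios(design, {"P1": vals}))
        b = rollup_protein(matrix_from_ratios(design, {"P1": vals + vals}))
        assert a.table.at["P1", "ratio T50/T30"] == pytest.approx(
            b.table.at["P1", "ratio T50/T30"])

    def test_matches_sort_based_median_oracle(self, design, rng):
        for _ in range(50):
            ratios = {f"P{j}": list(np.exp(rng.normal(0, 1, size=rng.integers(1, 9))))
                      for j in range(4)}
            prot = rollup_protein(matrix_from_ratios(design, ratios))
            for acc, vals in ratios.items():
                s = sorted(vals)
                k = len(s)
                oracle = s[k // 2] if k % 2 else 0.5 * (s[k // 2 - 1] + s[k // 2])
                assert prot.table.at[acc, "ratio T50/T30"] == pytest.approx(oracle)

    def test_proteins_without_unique_peptides_omitted(self, design):
        peps = [
            make_peptide(design, "UNIQK", ["P1"], {"T30": 1, "T50": 2, "T55": 1}),
            make_peptide(design, "SHRDK", ["P2", "P3"], {"T30": 1, "T50": 1, "T55": 1}),
        ]
        prot = rollup_protein(normalize_by_median_ratio(peps, design))
        assert list(prot.table.index) == ["P1"]


class TestSiteCorrection:
    def test_arithmetic(self):
        assert correct_site_ratio(3.0, 1.5) == pytest.approx(2.0)
        assert correct_site_ratio(1.5, 1.5) == pytest.approx(1.0)

    def test_absent_or_zero_protein_flagged(self):
        assert np.isnan(correct_site_ratio(3.0, float("nan")))
        assert np.isnan(correct_site_ratio(3.0, 0.0))

    def test_identity_raw_equals_corrected_times_protein(self, design, rng):
        peps = random_peptides(design, rng, n=20, n_prot=3)
        m = normalize_by_median_ratio(peps, design)
        prot = rollup_protein(m)
        sites = [
            GlycoSiteRecord(acc, 10 + i,
                            {ch: float(np.exp(rng.normal(12, 1)))
                             for ch in design.channels})
            for i, acc in enumerate(prot.table.index)
        ]
        sq = correct_site_ratios(sites, m, prot)
        for lab in ("T50/T30", "T55/T30", "T55/T50"):
            raw = sq.table[f"raw_ratio {lab}"].to_numpy()
            cor = sq.table[f"corrected_ratio {lab}"].to_numpy()
            pr = np.array([prot.ratio(a, lab) for a in sq.table["accession"]])
            ok = np.isfinite(cor)
            np.testing.assert_array_equal(cor[ok], raw[ok] / pr[ok])
            np.testing.assert_allclose(cor[ok] * pr[ok], raw[ok], rtol=1e-15)

    def test_unquantified_parent_flagged_not_raw(self, design, rng):
        peps = random_peptides(design, rng, n=10, n_prot=2)
        m = normalize_by_median_ratio(peps, design)
        prot = rollup_protein(m)
        orphan = GlycoSiteRecord("NOPE", 5, {ch: 100.0 for ch in design.channels})
        sq = correct_site_ratios([orphan], m, prot)
        row = sq.table.iloc[0]
        assert not row["parent_quantified"]
        assert np.isfinite(row["raw_ratio T50/T30"])
        assert np.isnan(row["corrected_ratio T50/T30"])

    def test_planted_occupancy_recovered_after_correction(self, design):
        # protein 4x up, site with an extra 2x occupancy change: corrected ~ 2
        peps = [make_peptide(design, f"P{i}K", ["PG"], {"T30": 1, "T50": 4, "T55": 1})
                for i in range(3)]
        # normalizer peptides at ratio 1 keep the grand median centered
        peps += [make_peptide(design, f"N{i}K", [f"N{i}"], {"T30": 1, "T50": 1, "T55": 1})
                 for i in range(4)]
        m = normalize_by_median_ratio(peps, design)
        prot = rollup_protein(m)
        site = GlycoSiteRecord(
            "PG", 7,
            {ch: 1e5 * {"T30": 1, "T50": 8, "T55": 1}[design.condition_of[ch]]
             for ch in design.channels})
        sq = correct_site_ratios([site], m, prot)
        assert sq.table.at[0, "raw_ratio T50/T30"] == pytest.approx(8.0, rel=1e-6)
        assert sq.table.at[0, "corrected_ratio T50/T30"] == pytest.approx(2.0, rel=1e-6)
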