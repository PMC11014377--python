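import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agingtx import (
    CountMatrix,
    SimConfig,
    SwitchPair,
    Transcript,
    TranscriptCatalog,
    classify_splicing_events,
    compute_isoform_fractions,
    consequence_summary,
    dtu_test,
    event_fraction_test,
    find_switch_pairs,
    generate_transcript_catalog,
    module_relative_isoform_ratio,
    nmd_sensitive,
    predict_orf,
    simulate_count_matrices,
)
from agingtx.splicing import Orf, assess_consequences, orf_similarity

from conftest import make_matrix, make_sheet


def _tx(tid, exons, strand="+", gene="g"):
    return Transcript(tid, gene, strand, exons)


def _types(a, b, **kw):
    return {e.event_type for e in classify_splicing_events(a, b, **kw)}


def _carrier(a, b, ev_type, **kw):
    return {e.carrier for e in classify_splicing_events(a, b, **kw)
            if e.event_type == ev_type}


HAND_CASES = [
    # (exons_a, exons_b, strand, expected type, expected carrier)
    ([(0, 100), (200, 300)], [(0, 100), (150, 300)], "+", "A3", "B"),
    ([(0, 100), (200, 300)], [(0, 120), (200, 300)], "+", "A5", "B"),
    ([(0, 100), (200, 300)], [(0, 100), (150, 300)], "-", "A5", "B"),
    ([(0, 100), (200, 300)], [(0, 120), (200, 300)], "-", "A3", "B"),
    ([(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)], "+", "ES", "B"),
    ([(0, 100), (200, 300), (350, 380), (400, 500)], [(0, 100), (400, 500)], "+", "MES", "B"),
    ([(0, 100), (200, 300)], [(0, 300)], "+", "IR", "B"),
    ([(0, 100), (200, 300), (400, 500)],
     [(0, 100), (320, 360), (400, 500)], "+", "MEE", "A"),
    ([(0, 100), (200, 300)], [(50, 100), (200, 300)], "+", "ATSS", "B"),
    ([(0, 100), (200, 300)], [(0, 100), (200, 250)], "+", "ATTS", "B"),
    ([(0, 100), (200, 300)], [(0, 100), (200, 250)], "-", "ATSS", "B"),
    ([(0, 100), (200, 300)], [(50, 100), (200, 300)], "-", "ATTS", "B"),
]


class TestEventClassifier:
    @pytest.mark.parametrize(
        "exons_a,exons_b,strand,expected,carrier",
        HAND_CASES,
        ids=[f"{c[3]}_{c[2]}" for c in HAND_CASES],
    )
    def test_hand_constructed_pairs(self, exons_a, exons_b, strand, expected, carrier):
        a = _tx("A", exons_a, strand)
        b = _tx("B", exons_b, strand)
        assert _types(a, b) == {expected}
        assert _carrier(a, b, expected) == {carrier}

    def test_pair_swap_preserves_types_and_swaps_carriers(self):
        for exons_a, exons_b, strand, expected, _ in HAND_CASES:
            a = _tx("A", exons_a, strand)
            b = _tx("B", exons_b, strand)
            fwd = classify_splicing_events(a, b)
            rev = classify_splicing_events(b, a)
            assert {e.event_type for e in fwd} == {e.event_type for e in rev}
            if expected != "MEE":  # MEE orientation is positional by convention
                assert {e.carrier for e in fwd} == {e.carrier for e in rev}

    def test_different_gene_or_strand_rejected(self):
        a = _tx("A", [(0, 100)])
        with pytest.raises(ValueError):
            classify_splicing_events(a, Transcript("B", "other", "+", [(0, 100)]))
        with pytest.raises(ValueError):
            classify_splicing_events(a, Transcript("B", "g", "-", [(0, 100)]))

    def test_end_shift_within_tolerance_ignored(self):
        a = _tx("A", [(0, 100), (200, 300)])
        b = _tx("B", [(8, 100), (200, 300)])
        assert _types(a, b) == set()
        assert _types(a, b, tss_tolerance=5) == {"ATSS"}

    def test_generator_round_trip_exact_over_200_genes(self):
        cfg = SimConfig(n_genes=200, isoforms_per_gene=(2, 4), n_modules=1,
                        module_size=1, seed=17)
        catalog, truth = generate_transcript_catalog(cfg)
        planted = truth[truth["event"] != "reference"]
        assert set(planted["event"]) == {"ATSS", "ATTS", "A5", "A3", "ES", "MES", "MEE", "IR"}
        for _, row in planted.iterrows():
            ref = catalog[f"{row.gene_id}.t1"]
            alt = catalog[row.transcript_id]
            assert _types(ref, alt) == {row.event}, row.transcript_id


class TestIsoformFractions:
    def _matrices(self, gene_counts, iso_counts, iso_genes):
        sheet = make_sheet(2, 2)
        gene_m = CountMatrix(
            pd.DataFrame(gene_counts, index=sorted(set(iso_genes.values())),
                         columns=sheet.index, dtype=float), sheet)
        iso_m = CountMatrix(
            pd.DataFrame(iso_counts, index=list(iso_genes), columns=sheet.index,
                         dtype=float), sheet)
        cat = TranscriptCatalog()
        for tid, gid in iso_genes.items():
            cat.add(Transcript(tid, gid, "+", [(0, 100)]))
        return gene_m, iso_m, cat

    def test_fraction_arithmetic(self):
        gene_m, iso_m, cat = self._matrices(
            [[100] * 4], [[60] * 4, [40] * 4], {"t1": "g1", "t2": "g1"})
        ift = compute_isoform_fractions(gene_m, iso_m, cat)
        assert np.allclose(ift.fractions.loc["t1"], 0.6)
        assert np.allclose(ift.fractions.loc["t2"], 0.4)
        assert np.allclose(ift.fractions.sum(axis=0), 1.0)

    def test_low_gene_expression_removes_gene(self):
        gene_m, iso_m, cat = self._matrices(
            [[4] * 4], [[3] * 4, [1] * 4], {"t1": "g1", "t2": "g1"})
        ift = compute_isoform_fractions(gene_m, iso_m, cat, gene_cutoff=5)
        assert ift.fractions.empty

    def test_single_remaining_isoform_removes_gene(self):
        gene_m, iso_m, cat = self._matrices(
            [[100] * 4], [[98] * 4, [2] * 4], {"t1": "g1", "t2": "g1"})
        ift = compute_isoform_fractions(gene_m, iso_m, cat, iso_cutoff=3)
        assert ift.fractions.empty

    def test_orphan_isoform_rejected(self):
        gene_m, iso_m, _ = self._matrices(
            [[100] * 4], [[60] * 4, [40] * 4], {"t1": "g1", "t2": "g1"})
        cat = TranscriptCatalog()
        cat.add(Transcript("t1", "g1", "+", [(0, 100)]))
        with pytest.raises(ValueError, match="t2"):
            compute_isoform_fractions(gene_m, iso_m, cat)


class TestDtuTest:
    def _ift_from_sim(self, seed, switch_fraction, n_genes=400):
        cfg = SimConfig(n_genes=n_genes, isoforms_per_gene=(2, 2), n_modules=1,
                        module_size=1, module_effect=0.0,
                        switch_fraction=switch_fraction, switch_lfc=1.5, seed=seed)
        catalog, _ = generate_transcript_catalog(cfg)
        gene_m, iso_m, _, switch_truth = simulate_count_matrices(catalog, cfg)
        ift = compute_isoform_fractions(gene_m, iso_m, catalog)
        return ift, switch_truth

    def test_identical_usage_is_ns(self):
        ift, _ = self._ift_from_sim(seed=3, switch_fraction=0.0, n_genes=100)
        dtu = dtu_test(ift)
        assert (dtu["padj"] > 0.05).mean() > 0.9

    def test_planted_usage_flip_detected(self):
        ift, truth = self._ift_from_sim(seed=4, switch_fraction=0.5)
        dtu = dtu_test(ift)
        planted = [t for t in truth.iso_up if t in dtu.index]
        assert (dtu.loc[planted, "padj"] <= 0.05).mean() >= 0.6
        assert (dtu.loc[planted, "dIF"] > 0).mean() >= 0.9

    def test_null_type_one_rate_controlled(self):
        ift, _ = self._ift_from_sim(seed=5, switch_fraction=0.0, n_genes=500)
        dtu = dtu_test(ift)
        rate = (dtu["p"] <= 0.05).mean()
        band = 2.576 * np.sqrt(0.05 * 0.95 / len(dtu))
        assert rate <= 0.05 + band

    def test_switch_pairs_have_opposite_signs(self):
        ift, truth = self._ift_from_sim(seed=6, switch_fraction=0.5)
        pairs = find_switch_pairs(dtu_test(ift))
        dtu = dtu_test(ift)
        for sp in pairs:
            assert dtu.loc[sp.up, "dIF"] > 0 > dtu.loc[sp.down, "dIF"]


class TestEventFractionTest:
    @staticmethod
    def _pairs(n_up, n_total, ev_type="ES"):
        from agingtx.splicing import SplicingEvent

        out = {}
        for i in range(n_total):
            sp = SwitchPair(f"g{i}", f"g{i}.u", f"g{i}.d")
            carrier = sp.up if i < n_up else sp.down
            out[sp] = {SplicingEvent(sp.gene_id, ev_type, carrier, (sp.up, sp.down))}
        return out

    def test_extreme_asymmetry_binomial_p(self):
        res = event_fraction_test(self._pairs(10, 10))
        row = res.loc["ES"]
        assert row["fraction_up"] == 1.0
        assert row["p"] == pytest.approx(2 * 0.5 ** 10, rel=1e-9)

    def test_balanced_fraction_is_null(self):
        res = event_fraction_test(self._pairs(5, 10))
        assert res.loc["ES", "fraction_up"] == 0.5
        assert res.loc["ES", "p"] == pytest.approx(1.0)

    def test_power_at_planted_asymmetry(self):
        rng = np.random.default_rng(19)
        hits = 0
        for _ in range(500):
            k = rng.binomial(30, 0.9)
            p = stats.binomtest(k, 30, 0.5).pvalue
            hits += p <= 0.05
        assert hits / 500 >= 0.8

    def test_uninformative_and_empty_types_omitted(self):
        res = event_fraction_test(self._pairs(3, 7, ev_type="IR"))
        assert list(res.index) == ["IR"]


class TestOrfAndNmd:
    def test_minimal_orf(self):
        orf = predict_orf("ATGAAATAG")
        assert orf is not None and orf.length == 9
        assert (orf.start, orf.end) == (0, 9)

    def test_no_start_codon(self):
        assert predict_orf("CCCCCCTAG") is None

    def test_longest_orf_wins(self):
        short = "ATG" + "AAA" + "AAC" + "TGA"        # 12 nt, no internal ATG
        long = "ATG" + "GGG" * 8 + "TAA"             # 30 nt
        seq = short + "CC" + long
        orf = predict_orf(seq)
        assert orf.length == 30
        assert seq[orf.start : orf.start + 3] == "ATG"

    def test_n_never_matches(self):
        assert predict_orf("NTGAAATAG") is None

    def test_nmd_50nt_rule_boundary(self):
        # + strand, junction at transcript coordinate 200
        tx = _tx("t", [(0, 200), (300, 400)])
        assert nmd_sensitive(tx, Orf(start=0, end=149, frame=0)) is True   # 51 nt upstream
        assert nmd_sensitive(tx, Orf(start=0, end=150, frame=0)) is False  # exactly 50
        assert nmd_sensitive(_tx("s", [(0, 400)]), Orf(0, 149, 0)) is None
        assert nmd_sensitive(tx, None) is None

    def test_identical_orfs_have_similarity_one(self):
        orf_seq = "ATG" + "GCT" * 20 + "TAA"
        assert orf_similarity(orf_seq, orf_seq) == pytest.approx(1.0)

    def test_consequence_gain_asymmetry_binomial(self):
        rows = []
        for i in range(10):
            rows.append({
                "gene_id": f"g{i}", "up": "u", "down": "d",
                "NMD_status_up": None, "NMD_status_down": None,
                "coding_potential_up": i < 9, "coding_potential_down": i >= 9,
                "intron_retention_up": False, "intron_retention_down": False,
                "ORF_seq_similarity": 1.0,
            })
        res = consequence_summary(pd.DataFrame(rows))
        row = res.loc["coding_potential"]
        assert row["gain_fraction"] == pytest.approx(0.9)
        assert row["p"] == pytest.approx(0.021484375, rel=1e-9)


class TestModuleRelativeRatio:
    def _setup(self):
        from agingtx.coexpr import ModuleAssignment
        from agingtx.splicing import SplicingEvent

        labels = pd.Series({"g1": "M1", "g2": "M2", "g3": "M0"})
        direction = pd.DataFrame(
            {"direction": ["up", "down"], "padj": [0.01, 0.01]},
            index=pd.Index(["M1", "M2"], name="module"),
        )
        asg = ModuleAssignment(labels, pd.DataFrame(), direction)
        iso_de = pd.DataFrame(
            {"direction": ["up", "down", "up", "down", "up", "down"]},
            index=["g1.u", "g1.d", "g2.u", "g2.d", "g3.u", "g3.d"],
        )
        pairs = {}
        for g in ("g1", "g2", "g3"):
            sp = SwitchPair(g, f"{g}.u", f"{g}.d")
            pairs[sp] = {SplicingEvent(g, "ES", sp.up, (sp.up, sp.down))}
        return iso_de, pairs, asg

    def test_mixed_pair_gives_half_and_m0_excluded(self):
        iso_de, pairs, asg = self._setup()
        per_gene, _, n_excluded = module_relative_isoform_ratio(iso_de, pairs, asg)
        assert n_excluded == 1  # g3 in M0
        g1 = per_gene[per_gene["gene_id"] == "g1"].iloc[0]
        assert g1["ratio"] == pytest.approx(0.5)  # one matches "up" module, one opposes

    def test_all_similar_gives_ratio_one(self):
        iso_de, pairs, asg = self._setup()
        iso_de.loc["g1.d", "direction"] = "up"
        per_gene, _, _ = module_relative_isoform_ratio(iso_de, pairs, asg)
        g1 = per_gene[per_gene["gene_id"] == "g1"].iloc[0]
        assert g1["ratio"] == 1.0


class TestConsequencePipeline:
    def test_assess_consequences_on_synthetic_pair(self):
        cat = TranscriptCatalog()
        cat.add(Transcript("u", "g", "+", [(0, 300), (400, 500)]))
        cat.add(Transcript("d", "g", "+", [(0, 300), (400, 500)]))
        orf = "ATG" + "GCA" * 98 + "TAA"  # 300 nt: coding by the heuristic
        seqs = {"u": orf + "T" * 100, "d": "TTTT" + orf + "T" * 96}
        res = assess_consequences([SwitchPair("g", "u", "d")], cat, seqs)
        row = res.iloc[0]
        assert row["coding_potential_up"] and row["coding_potential_down"]
        assert row["ORF_seq_similarity"] == pytest.approx(1.0)
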