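"""Pseudogene screening, NG86 Ka/Ks and Tajima's relative rate test."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2

from homeosort.alignment_io import (MultipleAlignment, Region, RegionMap)
from homeosort.coding_analysis import (CODON_TO_AA, STOP_CODONS,
                                       ka_ks_pairwise, pseudogene_screen,
                                       rrt_scan, tajima_rrt)
from homeosort.synthetic_data import (SimConfig, study_panel_config,
                                      study_representative_alignment,
                                      simulate_progenitors)

BASES = "ACGT"


class TestPseudogeneScreen:
    def test_internal_stop_detected(self):
        # TAA at codon 2 of a 4-codon ORF
        aln = MultipleAlignment(["x"], ["ATGTAAGGGTGA"])
        rm = RegionMap([Region("e", 1, 12, "exon")])
        scr = pseudogene_screen(aln, rm, "x")
        assert [(c, r) for c, r in scr.internal_stops] == [(2, "e")]
        assert scr.verdict == "putative pseudogene"

    def test_terminal_stop_is_not_internal(self):
        aln = MultipleAlignment(["x"], ["ATGAAATGA"])
        rm = RegionMap([Region("e", 1, 9, "exon")])
        scr = pseudogene_screen(aln, rm, "x")
        assert scr.internal_stops == []
        assert scr.verdict == "putatively functional"

    def test_frame_disrupting_deletion_flagged(self):
        aln = MultipleAlignment(["x", "y"],
                                ["ATGAAA----CCCGGG", "ATGAAATTTTCCCGGG"])
        rm = RegionMap([Region("e", 1, 16, "exon")], frame_offset=1)
        scr = pseudogene_screen(aln, rm, "x")
        assert ("e", 4) in scr.frameshift_indels
        assert scr.verdict == "putative pseudogene"

    def test_in_frame_deletion_not_flagged(self):
        aln = MultipleAlignment(["x", "y"],
                                ["ATGAAA---CCCGGG", "ATGAAATTTCCCGGG"])
        rm = RegionMap([Region("e", 1, 15, "exon")])
        scr = pseudogene_screen(aln, rm, "x")
        assert scr.frameshift_indels == []

    def test_simulated_pseudogene_flagged_and_functional_copies_clean(self):
        cfg = SimConfig(n_progenitors=4, pseudogene_lineage="P4", seed=9)
        rng = np.random.default_rng(cfg.seed)
        panel, _, rm = simulate_progenitors(cfg, rng)
        for sid in panel.ids:
            scr = pseudogene_screen(panel, rm, sid)
            if sid == "P4":
                assert scr.verdict == "putative pseudogene"
                assert ("exon11", 10) in scr.frameshift_indels
            else:
                assert scr.verdict == "putatively functional", sid

    def test_emulated_fm_clones_show_ten_bp_exon11_deletion(self):
        """Clone library from the pseudogenized direct-sequencing lineage:
        every clone carries the 10 bp frame-breaking deletion in the last
        exon plus an internal stop."""
        cfg = SimConfig(n_progenitors=4, pseudogene_lineage="P2",
                        clones_per_accession=4, chimera_fraction=0.0,
                        error_rate=1e-3, seed=3)
        rng = np.random.default_rng(cfg.seed)
        panel, nwk, rm = simulate_progenitors(cfg, rng)
        from homeosort.synthetic_data import simulate_clone_library
        clones, _ = simulate_clone_library(panel, cfg, rng,
                                           lineages=["P2"], tree_newick=nwk)
        assert clones.alignment.n_sequences == 4
        for cid in clones.alignment.ids:
            scr = pseudogene_screen(clones.alignment, rm, cid)
            assert ("exon11", 10) in scr.frameshift_indels
            assert scr.internal_stops
            assert scr.verdict == "putative pseudogene"


def brute_ng86_codon(c1, c2):
    """Independent oracle: enumerate every pathway permutation explicitly."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            syn = (nxt not in STOP_CODONS and cur not in STOP_CODONS
                   and CODON_TO_AA.get(nxt) == CODON_TO_AA.get(cur))
            sd, nd = sd + syn, nd + (not syn)
            cur = nxt
        results.append((sd, nd, blocked))
    ok = [(s, n) for s, n, b in results if not b] or \
        [(s, n) for s, n, _ in results]
    return (sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok))


class TestKaKs:
    def test_identical_sequences_undefined_ratio(self):
        res = ka_ks_pairwise("ATGGCTAAA", "ATGGCTAAA")
        assert res.ka == res.ks == 0.0
        assert math.isnan(res.ratio)
        assert res.classification == "undefined"

    def test_single_synonymous_change_gives_zero_ka(self):
        res = ka_ks_pairwise("GGAGGAGGA", "GGGGGAGGA")
        assert res.ka == 0.0
        assert res.ks > 0.0
        assert res.ratio == 0.0
        assert res.classification == "purifying"

    def test_single_nonsynonymous_change_gives_zero_ks(self):
        res = ka_ks_pairwise("ATGGCT", "ATGTCT")  # GCT(Ala)->TCT(Ser)
        assert res.ks == 0.0
        assert res.ka > 0.0
        assert math.isnan(res.ratio)

    def test_codons_with_gaps_skipped(self):
        full = ka_ks_pairwise("GGAGGA", "GGGGGA")
        padded = ka_ks_pairwise("GGAGGAG-A", "GGGGGAGGA")
        assert padded.n_codons == 2
        assert padded.ks == pytest.approx(full.ks)

    def test_site_and_difference_counts_match_pathway_oracle(self, rng):
        codons = [a + b + c for a in BASES for b in BASES for c in BASES
                  if a + b + c not in STOP_CODONS]
        pairs = rng.choice(len(codons), size=(120, 2))
        for i, j in pairs:
            c1, c2 = codons[i], codons[j]
            res = ka_ks_pairwise(c1, c2)
            sd, nd = brute_ng86_codon(c1, c2)
            assert res.diffs_syn == pytest.approx(sd), (c1, c2)
            assert res.diffs_nonsyn == pytest.approx(nd), (c1, c2)

    def test_third_position_only_changes_keep_ka_zero(self, rng):
        """Fourfold-degenerate third positions: any change is synonymous."""
        fourfold = ["GG", "GC", "CC", "CG", "TC", "CT", "GT", "AC"]
        for _ in range(30):
            stems = rng.choice(fourfold, size=10)
            third1 = rng.choice(list(BASES), size=10)
            third2 = rng.choice(list(BASES), size=10)
            a = "".join(s + t for s, t in zip(stems, third1))
            b = "".join(s + t for s, t in zip(stems, third2))
            res = ka_ks_pairwise(a, b)
            assert res.ka == 0.0


class TestTajimaRRT:
    def test_equal_unique_counts_not_significant(self):
        a = "AAAATTTT" + "C" * 20
        b = "TTTTAAAA" + "C" * 20
        o = "AAAAAAAA" + "C" * 20
        res = tajima_rrt(a, b, o)
        assert res.m1 == res.m2 == 4
        assert res.chi2 == 0.0
        assert not res.significant

    def test_closed_form_counts_10_vs_2(self):
        """m1=10, m2=2 -> chi2 = 64/12, p ~ 0.0209, significant."""
        L = 60
        a = list("A" * L)
        b = list("A" * L)
        o = list("A" * L)
        for i in range(10):
            a[i] = "G"
        for i in range(20, 22):
            b[i] = "C"
        res = tajima_rrt("".join(a), "".join(b), "".join(o))
        assert (res.m1, res.m2) == (10, 2)
        assert res.chi2 == pytest.approx(64 / 12)
        assert res.p_value == pytest.approx(chi2.sf(64 / 12, 1))
        assert res.p_value == pytest.approx(0.0209, abs=2e-4)
        assert res.significant

    def test_swapping_ingroups_swaps_counts_only(self):
        rng = np.random.default_rng(2)
        a, b, o = ("".join(rng.choice(list(BASES), 100)) for _ in range(3))
        r1, r2 = tajima_rrt(a, b, o), tajima_rrt(b, a, o)
        assert (r1.m1, r1.m2) == (r2.m2, r2.m1)
        assert r1.chi2 == pytest.approx(r2.chi2)
        assert r1.p_value == pytest.approx(r2.p_value, nan_ok=True)

    def test_complete_deletion_over_triple(self):
        res = tajima_rrt("ACG-", "ACGT", "ACGT")
        assert res.n_sites == 3

    def test_identical_ingroups_uncomputable(self):
        res = tajima_rrt("ACGT", "ACGT", "AAGT")
        assert not res.computable
        assert math.isnan(res.p_value)

    def test_sites_where_all_three_differ_count_for_neither(self):
        res = tajima_rrt("A" + "C" * 9, "G" + "C" * 9, "T" + "C" * 9)
        assert (res.m1, res.m2) == (0, 0)
        assert not res.computable


class TestRrtScan:
    def test_identical_pair_in_scan_is_uncomputable(self):
        aln = MultipleAlignment(
            ["a", "b", "out"], ["ACGTACGT", "ACGTACGT", "AAGTACGA"])
        table, summary = rrt_scan(aln, ["a", "b"], "out")
        assert summary == {"n_significant": 0, "n_nonsignificant": 0,
                           "n_uncomputable": 1}

    def test_emulation_pair_partition(self, study_panel):
        """91 pairs over the 14 representatives; the two identical pairs
        are uncomputable; the accelerated lineage pair is significant."""
        _, panel, _, rm = study_panel
        reps = study_representative_alignment(panel)
        ids = [i for i in reps.ids if i != "outgroup"]
        table, summary = rrt_scan(reps, ids, "outgroup", rm=rm)
        assert len(table) == 91
        assert summary["n_uncomputable"] == 2
        assert (summary["n_significant"] + summary["n_nonsignificant"]) == 89
        row = table[(table.id1 == "3f") & (table.id2 == "4c")].iloc[0]
        assert row.m1 > row.m2
        assert row.significant

    def test_type_i_error_near_alpha_under_clock(self, rng):
        """Clock-like triples: rejection rate ~ alpha (binomial CI,
        1000 replicates)."""
        n_rep, L, t = 1000, 400, 0.02
        from homeosort.synthetic_data import _evolve, _k2p_probs
        hits = computable = 0
        for _ in range(n_rep):
            root = rng.integers(0, 4, size=L)
            anc = _evolve(root, 0.05, 2.0, rng)  # ingroup ancestor
            a = _evolve(anc, t, 2.0, rng)
            b = _evolve(anc, t, 2.0, rng)
            bases = np.array(list("ACGT"))
            res = tajima_rrt("".join(bases[a]), "".join(bases[b]),
                             "".join(bases[root]))
            if res.computable:
                computable += 1
                hits += res.significant
        rate = hits / computable
        se = math.sqrt(0.05 * 0.95 / computable)
        assert abs(rate - 0.05) <= 3.5 * se
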