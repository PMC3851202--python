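import math

import pytest
from hypothesis import given, settings, strategies as st

from phosmet import (Proteome, ProteinRecord, SiteRecord, SiteWindow,
                     composition, enumerate_all_sty, extract_window, has_met,
                     hydropathy_score, met_proximity_table,
                     positional_distribution, window_size_scan, window_string)

from oracles import (brute_composition, brute_met_in_window,
                     brute_positional_counts)


def one_protein(seq):
    return Proteome(records=[ProteinRecord(id="p", sequence=seq)])


def site_of(seq, pos):
    return SiteRecord("p", pos, seq[pos - 1])


class TestExtractWindow:
    def test_interior_window(self):
        prot = ProteinRecord(id="p", sequence="MKSTMA")
        win = extract_window(prot, SiteRecord("p", 3, "S"), half_width=2)
        assert win.flank == {-2: "M", -1: "K", 1: "T", 2: "M"}

    def test_terminal_truncation(self):
        prot = ProteinRecord(id="p", sequence="SAAAA")
        win = extract_window(prot, SiteRecord("p", 1, "S"), half_width=6)
        assert all(win.flank[d] is None for d in range(-6, 0))
        assert [win.flank[d] for d in range(1, 7)] == \
            ["A", "A", "A", "A", None, None]

    def test_zero_half_width(self):
        prot = ProteinRecord(id="p", sequence="MKSTMA")
        win = extract_window(prot, SiteRecord("p", 3, "S"), half_width=0)
        assert win.flank == {}

    def test_mismatched_site_rejected(self):
        prot = ProteinRecord(id="p", sequence="MKSTMA")
        with pytest.raises(ValueError):
            extract_window(prot, SiteRecord("p", 4, "S"), 2)

    def test_window_string_pads_gaps(self):
        prot = ProteinRecord(id="p", sequence="SAAAA")
        win = extract_window(prot, SiteRecord("p", 1, "S"), half_width=3)
        assert window_string(win) == "---SAAA"


class TestHasMet:
    def test_nterm_met_discounted_but_other_met_counts(self):
        prot = ProteinRecord(id="p", sequence="MKSTMA")
        win = extract_window(prot, SiteRecord("p", 3, "S"), 2)
        assert has_met(win, discount_nterm=True)  # M at +2 still counts

    def test_only_initiator_met(self):
        prot = ProteinRecord(id="p", sequence="MKSAAA")
        win = extract_window(prot, SiteRecord("p", 3, "S"), 2)
        assert not has_met(win, discount_nterm=True)
        assert has_met(win, discount_nterm=False)

    @settings(derandomize=True, max_examples=150)
    @given(st.text(alphabet="ACDMSTYK", min_size=3, max_size=40),
           st.data())
    def test_matches_brute_force_scan(self, seq, data):
        sty = [i + 1 for i, aa in enumerate(seq) if aa in "STY"]
        if not sty:
            return
        pos = data.draw(st.sampled_from(sty))
        k = data.draw(st.integers(min_value=0, max_value=10))
        discount = data.draw(st.booleans())
        prot = ProteinRecord(id="p", sequence=seq)
        win = extract_window(prot, site_of(seq, pos), k)
        assert has_met(win, discount) == \
            brute_met_in_window(seq, pos, k, discount)


class TestMetProximity:
    def test_single_site_with_met(self):
        proteome = one_protein("AMSAA")
        res = met_proximity_table(proteome, [site_of("AMSAA", 3)], 6)
        assert len(res) == 1
        assert (res[0].n_sites, res[0].n_with_met) == (1, 1)
        assert res[0].proportion == 100.0

    def test_no_met_anywhere(self):
        proteome = one_protein("ASTYASTYA")
        sites = enumerate_all_sty(proteome)
        for r in met_proximity_table(proteome, sites, 6):
            assert r.proportion == 0.0

    def test_counts_match_brute_force_on_small_proteome(self,
                                                        small_synthetic):
        _, proteome, sites = small_synthetic
        few = Proteome(records=list(proteome)[:10],
                       taxon_label=proteome.taxon_label)
        few_sites = [s for s in sites if s.protein_id in few]
        res = met_proximity_table(few, few_sites, 6)
        expected = sum(
            brute_met_in_window(few[s.protein_id].sequence, s.position, 6)
            for s in few_sites)
        assert sum(r.n_with_met for r in res) == expected
        assert sum(r.n_sites for r in res) == len(few_sites)

    def test_discount_only_removes_counts(self, small_synthetic):
        _, proteome, sites = small_synthetic
        on = met_proximity_table(proteome, sites, 6, discount_nterm=True)
        off = met_proximity_table(proteome, sites, 6, discount_nterm=False)
        for a, b in zip(on, off):
            assert a.n_with_met <= b.n_with_met


class TestWindowSizeScan:
    def test_met_appears_at_half_width_two(self):
        proteome = one_protein("AAMASAA")
        sites = [site_of("AAMASAA", 5)]
        df = window_size_scan(proteome, sites, half_widths=[1, 2])
        by_k = dict(zip(df["half_width"], df["proportion_pct"]))
        assert by_k[1] == 0.0 and by_k[2] == 100.0

    def test_empty_sites_empty_table(self):
        assert window_size_scan(one_protein("MAAA"), [], [1, 2]).empty

    def test_monotone_in_half_width(self, small_synthetic):
        _, proteome, sites = small_synthetic
        df = window_size_scan(proteome, sites, half_widths=range(1, 11))
        for (_, _), grp in df.groupby(["residue", "evidence"]):
            props = grp.sort_values("half_width")["proportion_pct"].tolist()
            assert props == sorted(props)


class TestPositionalDistribution:
    def test_single_site(self):
        # flank of S at 3 in MKSTM: -2:M (position 1, discounted), +2:M
        proteome = one_protein("MKSTM")
        dist = positional_distribution(proteome, [site_of("MKSTM", 3)],
                                       "M", half_width=2)
        assert dist.percentages == {-2: 0.0, -1: 0.0, 1: 0.0, 2: 100.0}

    def test_missing_offsets_have_zero_denominator(self):
        proteome = one_protein("SAAAA")
        dist = positional_distribution(proteome, [site_of("SAAAA", 1)],
                                       "M", half_width=6)
        assert dist.denominators[-1] == 0
        assert dist.percentages[-1] is None

    def test_pooled_vilf_class(self):
        proteome = one_protein("AVSAA")
        dist = positional_distribution(proteome, [site_of("AVSAA", 3)],
                                       "VILF", half_width=1)
        assert dist.percentages == {-1: 100.0, 1: 0.0}

    def test_matches_brute_force(self, small_synthetic):
        _, proteome, sites = small_synthetic
        dist = positional_distribution(proteome, sites, "M", 6)
        seqs = {r.id: r.sequence for r in proteome}
        counts, denoms = brute_positional_counts(
            seqs, [(s.protein_id, s.position) for s in sites], "M", 6)
        assert dist.counts == counts
        assert dist.denominators == denoms

    def test_denominator_counts_in_range_positions(self, small_synthetic):
        _, proteome, sites = small_synthetic
        dist = positional_distribution(proteome, sites, "M", 6)
        for d, n in dist.denominators.items():
            expected = sum(
                1 <= s.position + d <= len(proteome[s.protein_id])
                for s in sites)
            assert n == expected


class TestComposition:
    def test_all_met_discounted(self):
        comp = composition(one_protein("MMMM"), discount_nterm=True)
        assert comp["M"] == 100.0
        assert comp.n_counted == 3

    def test_initiator_met_removed_entirely(self):
        comp = composition(one_protein("MA"), discount_nterm=True)
        assert comp["A"] == 100.0 and comp["M"] == 0.0

    def test_uniform_protein(self):
        comp = composition(one_protein("ACDEFGHIKLMNPQRSTVWY"),
                           discount_nterm=False)
        assert all(math.isclose(comp[aa], 5.0)
                   for aa in "ACDEFGHIKLMNPQRSTVWY")

    def test_sums_to_100(self, small_synthetic):
        _, proteome, _ = small_synthetic
        comp = composition(proteome)
        assert math.isclose(sum(comp.proportions.values()), 100.0)

    def test_matches_brute_force(self, small_synthetic):
        _, proteome, _ = small_synthetic
        few = list(proteome)[:10]
        comp = composition(Proteome(records=few))
        counts = brute_composition([r.sequence for r in few])
        total = sum(counts.values())
        for aa, pct in comp.proportions.items():
            assert math.isclose(pct, 100.0 * counts.get(aa, 0) / total)


class TestHydropathy:
    def test_twelve_glycines(self):
        win = SiteWindow(site=SiteRecord("p", 7, "S"), half_width=6,
                         flank={d: "G" for d in range(-6, 7) if d != 0})
        assert math.isclose(hydropathy_score(win), -0.4)

    def test_single_isoleucine(self):
        flank = {d: None for d in range(-6, 7) if d != 0}
        flank[1] = "I"
        win = SiteWindow(site=SiteRecord("p", 1, "S"), half_width=6,
                         flank=flank)
        assert hydropathy_score(win) == 4.5

    def test_arg_ile_cancel(self):
        win = SiteWindow(site=SiteRecord("p", 2, "S"), half_width=1,
                         flank={-1: "R", 1: "I"})
        assert hydropathy_score(win) == 0.0

    def test_all_missing_is_undefined(self):
        win = SiteWindow(site=SiteRecord("p", 1, "S"), half_width=1,
                         flank={-1: None, 1: None})
        assert hydropathy_score(win) is None

    def test_ambiguity_letters_excluded_from_mean(self):
        win = SiteWindow(site=SiteRecord("p", 2, "S"), half_width=1,
                         flank={-1: "X", 1: "I"})
        assert hydropathy_score(win) == 4.5
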