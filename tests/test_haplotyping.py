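"""Panel loading, consistency-set calling, phased resolution, functional collapse."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sirpa_allo.haplotyping import (
    CallMethod,
    CallStatus,
    FunctionalAllele,
    GenotypeCall,
    GenotypeInputError,
    Haplotype,
    HaplotypePanel,
    PanelError,
    SiteType,
    UnphasedGenotype,
    VariantSite,
    call_phased,
    collapse_functional,
    enumerate_consistent_pairs,
    genotype_summary,
    load_panel,
)
from conftest import make_random_panel


def brute_force_pairs(g: UnphasedGenotype, panel: HaplotypePanel) -> frozenset:
    """Independent oracle: test every unordered pair by direct multiset comparison."""
    hits = set()
    n = len(panel.haplotypes)
    for i in range(n):
        for j in range(i, n):
            h1, h2 = panel.haplotypes[i], panel.haplotypes[j]
            if all(
                call is None or sorted(call) == sorted((a, b))
                for call, a, b in zip(g.calls, h1.alleles, h2.alleles)
            ):
                hits.add(frozenset((h1.name, h2.name)))
    return frozenset(hits)


class TestPanelLoading:
    def test_packaged_default(self, panel):
        assert panel.n_sites == 16
        assert sum(s.site_type is SiteType.SNP for s in panel.sites) == 15
        assert sum(s.site_type is SiteType.DELETION for s in panel.sites) == 1
        assert panel.names == ("V1", "V2", "V9", "NV1", "NV2")

    def test_standin_structure(self, panel):
        """V1/V2 well separated; rare alleles cluster near V1."""
        assert panel["V1"].hamming(panel["V2"]) >= 6
        for name in ("V9", "NV1", "NV2"):
            assert panel["V1"].hamming(panel[name]) <= 2

    def test_duplicate_haplotype_vectors_rejected(self, tmp_path, panel):
        variants = tmp_path / "variant_sites.tsv"
        haps = tmp_path / "haplotypes.tsv"
        variants.write_text("site_id\tchrom\tposition\tref\talt\tsite_type\nrs1\t20\t100\tA\tG\tSNP\n")
        haps.write_text("name\trs1\nV1\tA\nV2\tA\n")
        with pytest.raises(PanelError, match="identical allele vector"):
            load_panel(variants, haps)

    def test_malformed_row_names_line(self, tmp_path):
        variants = tmp_path / "variant_sites.tsv"
        variants.write_text(
            "site_id\tchrom\tposition\tref\talt\tsite_type\n"
            "rs1\t20\t100\tA\tG\tSNP\n"
            "rs2\t20\tnot_a_number\tA\tG\tSNP\n"
        )
        haps = tmp_path / "haplotypes.tsv"
        haps.write_text("name\trs1\trs2\nV1\tA\tA\n")
        with pytest.raises(PanelError, match="line 3"):
            load_panel(variants, haps)

    def test_allele_outside_site_rejected(self, tmp_path):
        variants = tmp_path / "v.tsv"
        variants.write_text("site_id\tchrom\tposition\tref\talt\tsite_type\nrs1\t20\t100\tA\tG\tSNP\n")
        haps = tmp_path / "h.tsv"
        haps.write_text("name\trs1\nV1\tT\n")
        with pytest.raises(PanelError, match="rs1"):
            load_panel(variants, haps)


class TestUnphasedCalling:
    @pytest.mark.parametrize("name", ["V1", "V2", "V9", "NV1", "NV2"])
    def test_homozygote_is_unique(self, panel, name):
        g = UnphasedGenotype.from_pair("s", panel[name], panel[name])
        call = enumerate_consistent_pairs(g, panel)
        assert call.status is CallStatus.UNIQUE
        assert call.pairs == frozenset({frozenset({name})})

    def test_v1_v9_heterozygote_is_sanger_ambiguous(self, panel):
        """The rare-allele heterozygote is consistent with two distinct pairs."""
        g = UnphasedGenotype.from_pair("s", panel["V1"], panel["V9"])
        call = enumerate_consistent_pairs(g, panel)
        assert call.status is CallStatus.AMBIGUOUS
        assert call.pairs == frozenset(
            {frozenset({"V1", "V9"}), frozenset({"NV1", "NV2"})}
        )

    def test_v1_v2_heterozygote_resolves_uniquely(self, panel):
        g = UnphasedGenotype.from_pair("s", panel["V1"], panel["V2"])
        call = enumerate_consistent_pairs(g, panel)
        assert call.status is CallStatus.UNIQUE
        assert call.pairs == frozenset({frozenset({"V1", "V2"})})

    def test_unproducible_genotype_fails(self, panel):
        site0 = panel.sites[0]
        calls = list(UnphasedGenotype.from_pair("s", panel["V1"], panel["V1"]).calls)
        calls[0] = (site0.alt, site0.alt)  # no panel haplotype carries alt here
        call = enumerate_consistent_pairs(UnphasedGenotype("s", tuple(calls)), panel)
        assert call.status is CallStatus.FAILED
        assert call.pairs == frozenset()

    def test_missing_sites_only_enlarge_pair_set(self, panel):
        full = UnphasedGenotype.from_pair("s", panel["V1"], panel["V2"])
        masked = UnphasedGenotype(
            "s", tuple(None if i < 4 else c for i, c in enumerate(full.calls))
        )
        assert enumerate_consistent_pairs(full, panel).pairs <= enumerate_consistent_pairs(
            masked, panel
        ).pairs

    def test_length_mismatch_rejected(self, panel):
        with pytest.raises(GenotypeInputError):
            enumerate_consistent_pairs(UnphasedGenotype("s", (("A", "G"),)), panel)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        p = make_random_panel(rng, int(rng.integers(1, 21)), int(rng.integers(1, 9)))
        i, j = rng.integers(0, len(p.haplotypes), size=2)
        g = UnphasedGenotype.from_pair("s", p.haplotypes[i], p.haplotypes[j])
        call = enumerate_consistent_pairs(g, p)
        assert call.pairs == brute_force_pairs(g, p)
        # soundness: the generating pair is always in the consistent set
        assert frozenset({p.haplotypes[i].name, p.haplotypes[j].name}) in call.pairs


class TestPhasedCalling:
    def test_exact_match_pair(self, panel):
        call = call_phased("s", [panel["V1"].alleles, panel["V2"].alleles], panel)
        assert call.status is CallStatus.UNIQUE
        assert call.method is CallMethod.PHASED
        assert call.pairs == frozenset({frozenset({"V1", "V2"})})

    def test_homozygous_phased(self, panel):
        call = call_phased("s", [panel["V2"].alleles, panel["V2"].alleles], panel)
        assert call.pairs == frozenset({frozenset({"V2"})})

    def test_novel_vector_labelled_and_retained(self, panel):
        vec = list(panel["V2"].alleles)
        site = panel.sites[8]  # V1 and V2 agree here in the stand-in panel
        vec[8] = site.alt if vec[8] == site.ref else site.ref
        call = call_phased("s", [panel["V1"].alleles, tuple(vec)], panel)
        assert call.status is CallStatus.NOVEL
        assert call.novel_haplotypes == {"NOVEL-1": tuple(vec)}
        assert frozenset({"V1", "NOVEL-1"}) in call.pairs

    def test_max_mismatch_allows_near_match(self, panel):
        vec = list(panel["V2"].alleles)
        site = panel.sites[8]
        vec[8] = site.alt if vec[8] == site.ref else site.ref
        call = call_phased("s", [panel["V1"].alleles, tuple(vec)], panel, max_mismatch=1)
        assert call.status is CallStatus.UNIQUE
        assert call.pairs == frozenset({frozenset({"V1", "V2"})})

    def test_vector_length_mismatch_rejected(self, panel):
        with pytest.raises(GenotypeInputError):
            call_phased("s", [("A",), ("G",)], panel)


class TestFunctionalCollapse:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("V1", FunctionalAllele.V1LIKE),
            ("V2", FunctionalAllele.V2),
            ("V9", FunctionalAllele.V1LIKE),
            ("NV1", FunctionalAllele.V1LIKE),
            ("NV2", FunctionalAllele.V1LIKE),
        ],
    )
    def test_collapse_over_panel(self, panel, name, expected):
        assert collapse_functional(panel[name], panel).allele is expected

    def test_total_and_stable_over_panel(self, panel):
        for h in panel.haplotypes:
            first = collapse_functional(h, panel)
            assert first == collapse_functional(h, panel)
            assert first.allele in (FunctionalAllele.V1LIKE, FunctionalAllele.V2)

    def test_tie_goes_to_v1like_and_is_flagged(self):
        sites = tuple(
            VariantSite(f"rs{i}", "20", 100 + i, "A", "G", SiteType.SNP) for i in range(2)
        )
        p = HaplotypePanel(
            sites,
            (
                Haplotype("V1", ("A", "A")),
                Haplotype("V2", ("G", "G")),
                Haplotype("X", ("A", "G")),
            ),
        )
        res = collapse_functional(p["X"], p)
        assert res.tie and res.allele is FunctionalAllele.V1LIKE

    def test_novel_vectors_collapse_by_distance(self, panel):
        near_v2 = list(panel["V2"].alleles)
        site = panel.sites[8]
        near_v2[8] = site.alt if near_v2[8] == site.ref else site.ref
        res = collapse_functional(Haplotype("NOVEL-1", tuple(near_v2)), panel)
        assert res.allele is FunctionalAllele.V2


def _calls(category_counts):
    """Fabricate GenotypeCall lists per summary category."""
    out = []
    for (status, pair), n in category_counts.items():
        for k in range(n):
            out.append(
                GenotypeCall(f"s{len(out)}", status, frozenset(pair), CallMethod.SANGER_LIKE)
            )
    return out


class TestGenotypeSummary:
    def test_volunteer_cohort_percentages(self):
        """12 V1/V1 + 35 V2/V2 + 47 ambiguous of 94 report as 12.8/37.2/50.0%."""
        calls = _calls(
            {
                (CallStatus.UNIQUE, (frozenset({"V1"}),)): 12,
                (CallStatus.UNIQUE, (frozenset({"V2"}),)): 35,
                (CallStatus.AMBIGUOUS, (frozenset({"V1", "V2"}), frozenset({"V9", "NV1"}))): 47,
            }
        )
        table = genotype_summary(calls).set_index("category")
        assert table.loc["V1/V1", "percent"] == 12.8
        assert table.loc["V2/V2", "percent"] == 37.2
        assert table.loc["ambiguous-het", "percent"] == 50.0
        assert table.loc["other", "percent"] == 0.0
        assert table["count"].sum() == 94

    def test_transplant_cohort_ambiguous_fraction(self):
        calls = _calls(
            {
                (CallStatus.AMBIGUOUS, (frozenset({"V1", "V2"}), frozenset({"V9", "NV1"}))): 142,
                (CallStatus.UNIQUE, (frozenset({"V2"}),)): 166,
            }
        )
        table = genotype_summary(calls).set_index("category")
        assert table.loc["ambiguous-het", "percent"] == 46.1

    @given(st.lists(st.integers(0, 200), min_size=4, max_size=4).filter(lambda c: sum(c) > 0))
    def test_percentages_sum_to_100(self, counts):
        n1, n2, na, no = counts
        calls = _calls(
            {
                (CallStatus.UNIQUE, (frozenset({"V1"}),)): n1,
                (CallStatus.UNIQUE, (frozenset({"V2"}),)): n2,
                (CallStatus.AMBIGUOUS, (frozenset({"V1", "V2"}), frozenset({"V9", "NV1"}))): na,
                (CallStatus.FAILED, ()): no,
            }
        )
        table = genotype_summary(calls)
        assert abs(table["percent"].sum() - 100.0) <= 0.1 + 1e-9

    def test_empty_call_list_rejected(self):
        with pytest.raises(GenotypeInputError):
            genotype_summary([])
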