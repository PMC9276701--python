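import numpy as np
import pytest

from ddscan.genome import Genome, reverse_complement
from ddscan.reference import (
    naive_ddcbe_designs,
    naive_editable_sets,
    naive_mddcbe_designs,
    naive_tale_sites,
    naive_tc_motifs,
)
from ddscan.scan import (
    ScanParams,
    TCMotif,
    ddcbe_editable_motifs,
    editability_report,
    enumerate_tale_sites,
    find_ddcbe_designs,
    find_mddcbe_designs,
    find_tc_motifs,
    mddcbe_editable_motifs,
)

from conftest import DDCBE_CONSTRUCT, MDDCBE_CONSTRUCT, rotate


def random_genome(rng, min_len=50, max_len=300, circular=None) -> Genome:
    length = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list("ACGT"), size=length))
    if circular is None:
        circular = bool(rng.integers(0, 2))
    return Genome("g", seq, circular=circular)


def scan_sets(genome: Genome, params: ScanParams):
    """Scan output normalized to plain tuples for comparison with the oracle."""
    motifs = {(m.c_position, m.strand) for m in find_tc_motifs(genome)}
    sites = {
        (s.interval.start, s.interval.length, s.strand)
        for s in enumerate_tale_sites(genome, params)
    }
    dd = {
        (
            d.left_site.interval.start,
            d.left_site.interval.length,
            d.right_site.interval.start % genome.length,
            d.right_site.interval.length,
            frozenset((m.c_position, m.strand) for m in d.editable_motifs),
        )
        for d in find_ddcbe_designs(genome, params)
    }
    md = {
        (
            d.site.interval.start,
            d.site.interval.length,
            d.site.strand,
            frozenset((m.c_position, m.strand, o) for m, o in d.editable_motifs),
        )
        for d in find_mddcbe_designs(genome, params)
    }
    return motifs, sites, dd, md


class TestTCMotifs:
    def test_forward_motif(self):
        g = Genome("g", "TC", circular=False)
        assert find_tc_motifs(g) == [TCMotif(c_position=1, strand="+")]

    def test_reverse_motif(self):
        g = Genome("g", "GA", circular=False)
        assert find_tc_motifs(g) == [TCMotif(c_position=0, strand="-")]

    def test_junction_motif_circular_only(self):
        assert find_tc_motifs(Genome("g", "CT", circular=True)) == [
            TCMotif(c_position=0, strand="+")
        ]
        assert find_tc_motifs(Genome("g", "CT", circular=False)) == []

    def test_matches_naive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            g = random_genome(rng)
            assert {(m.c_position, m.strand) for m in find_tc_motifs(g)} == naive_tc_motifs(g)


class TestTALESites:
    def test_minimal_plus_site(self):
        g = Genome("g", "T" + "G" * 12 + "T", circular=False)
        sites = enumerate_tale_sites(g, ScanParams())
        assert [(s.interval.start, s.interval.end, s.strand) for s in sites] == [(0, 14, "+")]
        assert sites[0].bound_sequence == g.sequence

    def test_minimal_minus_site_strand_mirror(self):
        g = Genome("g", "A" + "C" * 12 + "A", circular=False)
        sites = enumerate_tale_sites(g, ScanParams())
        assert [(s.interval.start, s.interval.end, s.strand) for s in sites] == [(0, 14, "-")]
        assert sites[0].bound_sequence == "T" + "G" * 12 + "T"

    def test_too_long_window_rejected(self):
        g = Genome("g", "T" + "G" * 19 + "T", circular=False)
        assert enumerate_tale_sites(g, ScanParams()) == []

    def test_short_linear_genome_gives_empty_list(self):
        g = Genome("g", "TTTT", circular=False)
        assert enumerate_tale_sites(g, ScanParams()) == []


class TestDdCBEDesigns:
    def test_single_pair_construct(self, ddcbe_genome):
        designs = find_ddcbe_designs(ddcbe_genome, ScanParams())
        assert len(designs) == 1
        d = designs[0]
        assert (d.left_site.interval.start, d.left_site.interval.end) == (0, 14)
        assert (d.right_site.interval.start, d.right_site.interval.end) == (28, 42)
        assert (d.spacer.start, d.spacer.end) == (14, 28)
        assert TCMotif(c_position=21, strand="+") in d.editable_motifs

    def test_widened_spacer_invalidates_pair(self):
        seq = "TGGGGGGGGGGGGT" + "GGGGGGTCGGGGGG" + "GGGGG" + "AGGGGGGGGGGGGA"
        g = Genome("g", seq, circular=False)
        assert find_ddcbe_designs(g, ScanParams()) == []

    def test_all_g_genome(self):
        g = Genome("g", "G" * 60, circular=False)
        assert find_ddcbe_designs(g, ScanParams()) == []

    def test_spacer_containment_conventions(self):
        # motif straddling the left-site/spacer boundary: T is the site's
        # terminal T, C is the first spacer base
        seq = "TGGGGGGGGGGGGT" + "CGGGGGGGGGGGGG" + "AGGGGGGGGGGGGA"
        g = Genome("g", seq, circular=False)
        strict = find_ddcbe_designs(g, ScanParams(spacer_containment="dinucleotide"))
        loose = find_ddcbe_designs(g, ScanParams(spacer_containment="c"))
        straddler = TCMotif(c_position=14, strand="+")
        assert not any(straddler in d.editable_motifs for d in strict)
        assert any(straddler in d.editable_motifs for d in loose)


class TestMDdCBEDesigns:
    def test_planted_offset_recovered(self, mddcbe_genome):
        designs = find_mddcbe_designs(mddcbe_genome, ScanParams())
        wanted = [
            d for d in designs if (d.site.interval.start, d.site.interval.end) == (0, 14)
        ]
        assert len(wanted) == 1
        assert (TCMotif(c_position=18, strand="+"), 5) in wanted[0].editable_motifs

    def test_reverse_complement_symmetry(self, mddcbe_genome):
        rc = Genome("rc", reverse_complement(mddcbe_genome.sequence), circular=False)
        designs = find_mddcbe_designs(rc, ScanParams())
        L = rc.length
        wanted = [
            d
            for d in designs
            if (d.site.interval.start, d.site.interval.end, d.site.strand)
            == (L - 14, L, "-")
        ]
        assert len(wanted) == 1
        assert {o for _, o in wanted[0].editable_motifs} == {5}

    def test_window_anchor_boundary(self):
        # C sits 19 bp downstream of the intended site's 3' T, its own T 18 bp
        seq = "TGGGGGGGGGGGGT" + "G" * 17 + "TC" + "G"
        g = Genome("g", seq, circular=False)
        target = TCMotif(c_position=32, strand="+")

        def offsets_for_site(params):
            for d in find_mddcbe_designs(g, params):
                if (d.site.interval.start, d.site.interval.end) == (0, 14):
                    return {o for m, o in d.editable_motifs if m == target}
            return set()

        assert offsets_for_site(ScanParams(window_anchor="c")) == set()
        assert offsets_for_site(ScanParams(window_anchor="t")) == {18}


class TestOracleEquivalence:
    @pytest.mark.parametrize("anchor", ["c", "t"])
    @pytest.mark.parametrize("containment", ["dinucleotide", "c"])
    def test_random_genomes_match_naive(self, anchor, containment):
        params = ScanParams(window_anchor=anchor, spacer_containment=containment)
        rng = np.random.default_rng(101)
        for _ in range(10):
            g = random_genome(rng, min_len=60, max_len=200)
            motifs, sites, dd, md = scan_sets(g, params)
            assert motifs == naive_tc_motifs(g)
            assert sites == naive_tale_sites(g, params)
            assert dd == naive_ddcbe_designs(g, params)
            assert md == naive_mddcbe_designs(g, params)

    def test_fixture_constructs_match_naive(self, ddcbe_genome, mddcbe_genome):
        params = ScanParams()
        for g in (ddcbe_genome, mddcbe_genome):
            _, _, dd, md = scan_sets(g, params)
            assert dd == naive_ddcbe_designs(g, params)
            assert md == naive_mddcbe_designs(g, params)


class TestEditabilityReport:
    def test_no_t_genome_all_zero(self):
        g = Genome("g", "GGGCCCGGGCCC", circular=True)
        with pytest.warns(UserWarning):
            r = editability_report(g)
        assert (r.total_motifs, r.ddcbe_editable, r.mddcbe_editable, r.mddcbe_only) == (
            0,
            0,
            0,
            0,
        )
        assert r.mddcbe_only_fraction == 0.0

    def test_report_matches_design_unions(self, ddcbe_genome):
        params = ScanParams()
        r = editability_report(ddcbe_genome, params)
        dd = ddcbe_editable_motifs(find_ddcbe_designs(ddcbe_genome, params))
        md = mddcbe_editable_motifs(find_mddcbe_designs(ddcbe_genome, params))
        assert r.ddcbe_editable == len(dd)
        assert r.mddcbe_editable == len(md)
        assert r.mddcbe_only == len(md - dd)
        flagged = {m for m, tag in r.motif_annotations.items() if tag != "none"}
        assert flagged == dd | md

    def test_set_algebra(self):
        rng = np.random.default_rng(7)
        params = ScanParams()
        for _ in range(10):
            g = random_genome(rng)
            dd = ddcbe_editable_motifs(find_ddcbe_designs(g, params))
            md = mddcbe_editable_motifs(find_mddcbe_designs(g, params))
            r = editability_report(g, params)
            assert r.mddcbe_only + len(md & dd) == r.mddcbe_editable
            assert r.mddcbe_only <= r.mddcbe_editable <= r.total_motifs
            assert r.ddcbe_editable <= r.total_motifs

    def test_rotation_invariance(self):
        rng = np.random.default_rng(17)
        params = ScanParams()
        for _ in range(3):
            g = random_genome(rng, min_len=150, max_len=220, circular=True)
            base = editability_report(g, params)
            for k in rng.integers(1, g.length, size=5):
                rotated = Genome("g", rotate(g.sequence, int(k)), circular=True)
                r = editability_report(rotated, params)
                assert (
                    r.total_motifs,
                    r.ddcbe_editable,
                    r.mddcbe_editable,
                    r.mddcbe_only,
                ) == (
                    base.total_motifs,
                    base.ddcbe_editable,
                    base.mddcbe_editable,
                    base.mddcbe_only,
                )

    def test_strand_symmetry(self):
        rng = np.random.default_rng(23)
        params = ScanParams()
        for _ in range(10):
            g = random_genome(rng)
            rc = Genome("g", reverse_complement(g.sequence), circular=g.circular)
            a, b = editability_report(g, params), editability_report(rc, params)
            assert (a.total_motifs, a.ddcbe_editable, a.mddcbe_editable, a.mddcbe_only) == (
                b.total_motifs,
                b.ddcbe_editable,
                b.mddcbe_editable,
                b.mddcbe_only,
            )

    def test_monotonicity_in_window_and_spacer(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            g = random_genome(rng)
            base = editability_report(g, ScanParams())
            wider_mono = editability_report(g, ScanParams(mono_window=24))
            wider_spacer = editability_report(g, ScanParams(spacer_len_min=12, spacer_len_max=20))
            assert wider_mono.mddcbe_editable >= base.mddcbe_editable
            assert wider_spacer.ddcbe_editable >= base.ddcbe_editable


class TestNaiveEditableSets:
    def test_union_helpers_agree_with_naive(self):
        rng = np.random.default_rng(41)
        params = ScanParams()
        for _ in range(5):
            g = random_genome(rng, min_len=80, max_len=160)
            dd, md = naive_editable_sets(g, params)
            assert {(m.c_position, m.strand) for m in ddcbe_editable_motifs(find_ddcbe_designs(g, params))} == dd
            assert {(m.c_position, m.strand) for m in mddcbe_editable_motifs(find_mddcbe_designs(g, params))} == md
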