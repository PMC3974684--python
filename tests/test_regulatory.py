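"""Peak-to-TSS assignment, E-box scanning, Venn counts, GO enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2 as chi2_dist

import replilife as rl
from _oracles import assign_targets_bruteforce, chi2_hand

REVCOMP = str.maketrans("ACGTN", "TGCAN")


def _random_instance(rng, n_genes=40, n_peaks=120, chrom_length=100_000):
    genes = [
        rl.Gene(
            f"g{i}",
            f"chr{rng.integers(1, 3)}",
            int(rng.integers(0, chrom_length)),
            "+" if rng.uniform() < 0.5 else "-",
        )
        for i in range(n_genes)
    ]
    peaks = []
    for j in range(n_peaks):
        start = int(rng.integers(0, chrom_length - 500))
        peaks.append(
            rl.Peak(
                f"chr{rng.integers(1, 3)}",
                start,
                start + int(rng.integers(50, 500)),
                factor=f"F{rng.integers(1, 4)}",
                name=f"p{j}",
            )
        )
    return peaks, genes


class TestPeakMidpoint:
    def test_single_base_and_even_length(self):
        assert rl.peak_midpoint(rl.Peak("chr1", 100, 101)) == 100
        assert rl.peak_midpoint(rl.Peak("chr1", 100, 200)) == 149

    @given(start=st.integers(0, 10**6), length=st.integers(1, 10**4))
    @settings(deadline=None)
    def test_midpoint_inside_interval(self, start, length):
        mid = rl.peak_midpoint(rl.Peak("chr1", start, start + length))
        assert start <= mid < start + length


class TestTssOffsetProfile:
    def test_plus_strand_offset(self):
        genes = [rl.Gene("g", "chr1", 1000, "+")]
        peaks = [rl.Peak("chr1", 700, 701)]
        edges, counts = rl.tss_offset_profile(peaks, genes, bin_width=50)
        assert counts.sum() == 1
        bin_lo = edges[:-1][counts > 0][0]
        assert bin_lo == -300

    def test_minus_strand_flip(self):
        genes = [rl.Gene("g", "chr1", 1000, "-")]
        peaks = [rl.Peak("chr1", 1300, 1301)]
        edges, counts = rl.tss_offset_profile(peaks, genes, bin_width=50)
        assert edges[:-1][counts > 0][0] == -300  # downstream-looking = upstream

    def test_planted_offsets_land_in_promoter_band(self):
        data = rl.simulate_genome(
            rl.GenomeScenario(
                planted_target_fraction=1.0,
                n_peaks_per_factor=1000,
                offset_range=(-400, -400),
                seed=3,
            )
        )
        edges, counts = rl.tss_offset_profile(data.peaks, data.genes, bin_width=50)
        lo = edges[:-1]
        in_band = counts[(lo >= -700) & (lo < 100)].sum()
        assert in_band == counts.sum() == len(data.peaks)

    def test_chrom_without_genes_warns_and_skips(self):
        genes = [rl.Gene("g", "chr1", 1000, "+")]
        peaks = [rl.Peak("chr1", 900, 901), rl.Peak("chrX", 10, 11)]
        with pytest.warns(UserWarning, match="chrX"):
            _, counts = rl.tss_offset_profile(peaks, genes)
        assert counts.sum() == 1


class TestAssignTargets:
    @pytest.mark.parametrize(
        "offset, expected",
        [(0, True), (-700, True), (-701, False), (100, True), (101, False)],
    )
    def test_window_boundaries_inclusive(self, offset, expected):
        genes = [rl.Gene("g", "chr1", 5000, "+")]
        mid = 5000 + offset
        peaks = [rl.Peak("chr1", mid, mid + 1, factor="F")]
        out = rl.assign_targets(peaks, genes)
        assert ("g" in out.get("F", set())) is expected

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            peaks, genes = _random_instance(rng)
            assert rl.assign_targets(peaks, genes) == assign_targets_bruteforce(
                peaks, genes
            )

    def test_nearest_only_subset_of_all_in_window(self):
        rng = np.random.default_rng(23)
        peaks, genes = _random_instance(rng, chrom_length=20_000)
        near = rl.assign_targets(peaks, genes, nearest_only=True)
        full = rl.assign_targets(peaks, genes)
        for f, gs in near.items():
            assert gs <= full[f]


class TestEbox:
    @pytest.mark.parametrize(
        "seq, n",
        [
            ("CACGTG", 1),
            ("AAAAAA", 0),
            ("CATATGCACGTG", 2),
            ("CACATGCACATG", 2),
            ("CACANTG", 0),       # 7-mer, no window matches
            ("CANNTG", 1),        # ambiguity code in the middle is any-base
            ("cacgtg", 1),        # case-insensitive
            ("CACACGTGTG", 1),
        ],
    )
    def test_counts(self, seq, n):
        assert rl.scan_ebox(seq) == n

    def test_overlapping_matches_counted(self):
        # CACATGTG holds CACATG at 0 and the overlapping CATGTG at 2
        assert rl.scan_ebox("CACATGTG") == 2
        assert rl.scan_ebox("CAATTG") == 1  # AT core is a legitimate E-box
        assert rl.scan_ebox("CCGGTGACGT") == 0

    def test_alphabet_error(self):
        with pytest.raises(rl.AlphabetError):
            rl.scan_ebox("CACGUG")

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=60))
    @settings(deadline=None, max_examples=300)
    def test_reverse_complement_invariance(self, seq):
        """The CANNTG motif class is closed under reverse complement."""
        rc = seq.translate(REVCOMP)[::-1]
        assert rl.scan_ebox(seq) == rl.scan_ebox(rc)

    def test_fraction_reported_percent(self):
        peaks = [rl.Peak("chr1", i, i + 10, name=f"p{i}") for i in range(0, 46050, 10)]
        peaks = peaks[:4605]
        seqs = {p.name: ("CACGTGAAAA" if i < 3555 else "AAAAAAAAAA")
                for i, p in enumerate(peaks)}
        frac, pct = rl.ebox_fraction(peaks, seqs)
        assert pct == 77.2
        assert frac == pytest.approx(3555 / 4605)

    def test_zero_and_missing(self):
        peaks = [rl.Peak("chr1", 0, 10, name="p0")]
        assert rl.ebox_fraction(peaks, {"p0": "AAAAAAAAAA"}) == (0.0, 0.0)
        with pytest.raises(rl.MissingSequenceError):
            rl.ebox_fraction(peaks, {})


class TestVenn3:
    def test_identical_sets(self):
        s = {1, 2, 3}
        counts = rl.venn3(s, s, s, set(range(10)))
        assert counts.abc == 3
        assert counts.a == counts.ab == 0
        assert counts.outside == 7

    def test_disjoint_sets(self):
        counts = rl.venn3({1}, {2, 3}, {4, 5, 6}, set(range(10)))
        assert (counts.a, counts.b, counts.c) == (1, 2, 3)
        assert counts.ab == counts.ac == counts.bc == counts.abc == 0

    def test_not_in_universe(self):
        with pytest.raises(rl.NotInUniverseError):
            rl.venn3({1}, set(), set(), {2, 3})

    @given(st.data())
    @settings(deadline=None, max_examples=100)
    def test_conservation_and_elementwise_oracle(self, data):
        universe = set(range(30))
        sets = [
            data.draw(st.sets(st.integers(0, 29), max_size=30)) for _ in range(3)
        ]
        counts = rl.venn3(*sets, universe)
        assert counts.total() == len(universe)
        # element-wise membership enumeration
        regions = dict(a=0, b=0, c=0, ab=0, ac=0, bc=0, abc=0, outside=0)
        for x in universe:
            key = "".join(n for n, s in zip("abc", sets) if x in s) or "outside"
            regions[key] += 1
        for k, v in regions.items():
            assert getattr(counts, k) == v


class TestChisqEnrichment:
    def _genes(self, layout):
        """layout: list of (n, in_target, has_term); returns genes, targets."""
        genes, targets = [], set()
        i = 0
        for n, in_t, has in layout:
            for _ in range(n):
                gid = f"g{i}"
                genes.append(
                    rl.Gene(gid, "chr1", i * 10, "+",
                            frozenset({"GO:1"} if has else set()))
                )
                if in_t:
                    targets.add(gid)
                i += 1
        return genes, targets

    def test_equal_frequencies_null(self):
        genes, targets = self._genes(
            [(10, True, True), (40, True, False), (10, False, True), (40, False, False)]
        )
        row = rl.chisq_enrichment(targets, genes)[0]
        assert row.chi2 == pytest.approx(0.0, abs=1e-12)
        assert row.p == pytest.approx(1.0)
        assert row.fold == pytest.approx(1.0)

    def test_textbook_table(self):
        """2x2 (20,30;980,1970) against the hand-expanded formula."""
        genes, targets = self._genes(
            [(20, True, True), (30, True, False), (980, False, True), (1970, False, False)]
        )
        row = rl.chisq_enrichment(targets, genes)[0]
        ref = chi2_hand(20, 50, 980, 2950)
        assert row.chi2 == pytest.approx(ref, abs=1e-9)
        assert row.p == pytest.approx(chi2_dist.sf(ref, 1), rel=1e-9)
        assert row.fold == pytest.approx((20 / 50) / (1000 / 3000))

    def test_degenerate_margin_flagged(self):
        genes, targets = self._genes([(5, True, False), (5, False, False)])
        row = rl.chisq_enrichment(targets, genes, terms=["GO:1"])[0]
        assert row.degenerate
        assert row.p == 1.0

    def test_target_outside_gene_table_raises(self):
        genes, _ = self._genes([(3, False, False)])
        with pytest.raises(rl.NotInUniverseError):
            rl.chisq_enrichment({"nope"}, genes)

    def test_planted_term_ranks_first(self):
        data = rl.simulate_genome(rl.GenomeScenario(seed=0))
        targets = rl.assign_targets(data.peaks, data.genes)["MDL-1"]
        rows = rl.chisq_enrichment(targets, data.genes)
        assert rows[0].term == "GO:0000001"
        assert rows[0].fold > 1.0


class TestPeakOverlapFraction:
    def test_identical_and_disjoint(self):
        p = rl.Peak("chr1", 0, 100)
        assert rl.peak_overlap_fraction(p, [rl.Peak("chr1", 0, 100)]) == 1.0
        assert rl.peak_overlap_fraction(p, [rl.Peak("chr1", 200, 300)]) == 0.0
        assert rl.peak_overlap_fraction(p, [rl.Peak("chr2", 0, 100)]) == 0.0

    def test_union_of_overlapping_segments(self):
        p = rl.Peak("chr1", 0, 100)
        others = [rl.Peak("chr1", 0, 30), rl.Peak("chr1", 20, 60)]
        assert rl.peak_overlap_fraction(p, others) == pytest.approx(0.60)

    @given(st.data())
    @settings(deadline=None, max_examples=100)
    def test_matches_basewise_count(self, data):
        start = data.draw(st.integers(0, 50))
        end = data.draw(st.integers(51, 120))
        p = rl.Peak("chr1", start, end)
        others = [
            rl.Peak("chr1", s, s + w)
            for s, w in data.draw(
                st.lists(
                    st.tuples(st.integers(0, 150), st.integers(1, 60)), max_size=6
                )
            )
        ]
        base = np.zeros(200, bool)
        for o in others:
            base[o.start:o.end] = True
        expected = base[start:end].sum() / (end - start)
        assert rl.peak_overlap_fraction(p, others) == pytest.approx(expected)
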