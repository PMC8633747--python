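import numpy as np
import pytest

from recombikit import complexity as cx
from recombikit.genome_io import revcomp

from conftest import make_toy_genome
from oracles import brute_inverted, brute_tandem

PARAMS = cx.RepeatParams()
SMALL = cx.RepeatParams(max_period=4)


def random_test_string(rng, n: int, style: int) -> str:
    """Mixed alphabet: uniform, two-letter, mutated tandem, planted inverted."""
    bases = np.array(list("ACGT"))
    if style == 0:
        return "".join(rng.choice(bases, n))
    if style == 1:
        return "".join(rng.choice(np.array(list("AC")), n))
    if style == 2:
        unit = "".join(rng.choice(bases, int(rng.integers(1, 5))))
        rep = list((unit * 40)[:int(rng.integers(8, max(9, n - 10)))])
        for _ in range(int(rng.integers(0, 3))):
            rep[int(rng.integers(len(rep)))] = str(rng.choice(bases))
        pad = "".join(rng.choice(bases, 5))
        return (pad + "".join(rep) + pad)[:max(n, 12)]
    stem = "".join(rng.choice(bases, int(rng.integers(8, 16))))
    gap = "".join(rng.choice(bases, int(rng.integers(0, 13))))
    pad = "".join(rng.choice(bases, 4))
    return pad + stem + gap + revcomp(stem) + pad


def assert_matches_oracles(seq: str, params: cx.RepeatParams) -> None:
    got = [(h.kind, h.start, h.end, h.period, round(h.identity, 9))
           for h in cx.find_tandem_repeats(seq, params)]
    exp = [(k, a, b, p, round(i, 9)) for k, a, b, p, i in brute_tandem(seq, params)]
    assert got == exp, f"tandem mismatch on {seq!r}"
    got_i = [(h.start, h.end, h.period, h.spacer, round(h.identity, 9))
             for h in cx.find_inverted_repeats(seq, params)]
    exp_i = [(a, b, L, g, round(i, 9)) for a, b, L, g, i in brute_inverted(seq, params)]
    assert got_i == exp_i, f"inverted mismatch on {seq!r}"


class TestTandemExamples:
    def test_ten_base_mononucleotide_run_reported(self):
        (hit,) = cx.find_tandem_repeats("A" * 10, PARAMS)
        assert (hit.kind, hit.length, hit.identity) == ("mono", 10, 1.0)

    def test_nine_base_run_below_cutoff(self):
        assert cx.find_tandem_repeats("A" * 9, PARAMS) == []

    def test_imperfect_run_at_90_percent_identity(self):
        (hit,) = cx.find_tandem_repeats("GGGGGTGGGG", PARAMS)
        assert (hit.kind, hit.length) == ("mono", 10)
        assert hit.identity == pytest.approx(0.9)

    def test_dinucleotide_20bp_cutoff(self):
        (hit,) = cx.find_tandem_repeats("AC" * 10, PARAMS)
        assert (hit.kind, hit.length) == ("di", 20)
        assert cx.find_tandem_repeats("AC" * 9, PARAMS) == []

    def test_embedded_repeat_coordinates(self):
        s = "GCTGCTAGCT" + "TA" * 11 + "CGATCGGATC"
        hits = cx.find_tandem_repeats(s, PARAMS)
        di = [h for h in hits if h.kind == "di"]
        assert len(di) == 1
        assert s[di[0].start:di[0].end].count("TA") >= 10


class TestInvertedExamples:
    STEM = "GACTTCGGATCC"

    def test_perfect_palindrome(self):
        (hit,) = cx.find_inverted_repeats(self.STEM + revcomp(self.STEM), PARAMS)
        assert (hit.start, hit.end, hit.period, hit.spacer) == (0, 24, 12, 0)
        assert hit.identity == 1.0

    def test_spacer_over_ten_bases_rejected(self):
        s = self.STEM + "A" * 11 + revcomp(self.STEM)
        assert cx.find_inverted_repeats(s, PARAMS) == []

    def test_spacer_of_ten_accepted(self):
        s = self.STEM + "A" * 10 + revcomp(self.STEM)
        (hit,) = cx.find_inverted_repeats(s, PARAMS)
        assert hit.spacer == 10

    def test_two_mismatches_in_stem_rejected(self):
        rc = list(revcomp(self.STEM))
        # corrupt positions 3 and 8: every >= 10-bp substem keeps both
        rc[3] = "A" if rc[3] != "A" else "C"
        rc[8] = "A" if rc[8] != "A" else "C"
        assert cx.find_inverted_repeats(self.STEM + "".join(rc), PARAMS) == []

    def test_total_length_cap(self):
        stem = "ACGGTCAAGGTCCAGTTCAGGACTGGACCGTATTGACCGGTCAACCTGGACAAGGTCCAGGTACCGGTCAAGGACCAGGTCCGGTACTGGTCAAGGTACCAGGACCGGTACAG"[:106]
        s = stem + revcomp(stem)  # total 212 > 210
        hits = cx.find_inverted_repeats(s, PARAMS)
        assert all(h.length <= PARAMS.inv_max_total for h in hits)


class TestOracleEquivalence:
    def test_finders_match_brute_force(self):
        rng = np.random.default_rng(11)
        for trial in range(250):
            n = int(rng.integers(15, 49))
            seq = random_test_string(rng, n, trial % 4)
            assert_matches_oracles(seq, SMALL)


class TestProperties:
    def test_inverted_reverse_complement_symmetry(self):
        rng = np.random.default_rng(3)
        for trial in range(60):
            seq = random_test_string(rng, int(rng.integers(20, 60)), trial % 4)
            fwd = cx.find_inverted_repeats(seq, PARAMS)
            rev = cx.find_inverted_repeats(revcomp(seq), PARAMS)
            assert len(fwd) == len(rev)
            n = len(seq)
            mirrored = sorted((n - h.end, n - h.start) for h in fwd)
            assert mirrored == sorted((h.start, h.end) for h in rev)

    def test_threshold_relaxation_never_shrinks_coverage(self):
        """Lowering identity/length thresholds never uncovers a detected
        position (counts may merge, coverage is monotone)."""
        rng = np.random.default_rng(4)
        strict = cx.RepeatParams()
        loose = cx.RepeatParams(min_mono_len=8, min_ditri_len=14,
                                min_tetraplus_len=14, min_identity=0.85)
        for trial in range(40):
            seq = random_test_string(rng, int(rng.integers(25, 70)), trial % 4)
            for finder in (cx.find_tandem_repeats, cx.find_inverted_repeats):
                cov_strict = {i for h in finder(seq, strict)
                              for i in range(h.start, h.end)}
                cov_loose = {i for h in finder(seq, loose)
                             for i in range(h.start, h.end)}
                assert cov_strict <= cov_loose

    def test_duplication_roughly_preserves_density(self):
        base = "GCTAGCTAAC" + "AG" * 12 + "CGATCCGGAT" + "T" * 11 + "GCACTGCAAC"
        single = cx.find_tandem_repeats(base, PARAMS)
        double = cx.find_tandem_repeats(base + base, PARAMS)
        assert len(double) >= 2 * len(single) - 2  # boundary-spanning merges
        d1 = len(single) / (len(base) / 1000)
        d2 = len(double) / (2 * len(base) / 1000)
        assert d2 == pytest.approx(d1, rel=0.10)


class TestProfiles:
    def _gene_with(self, utr5, cds, utr3):
        genome, gene = make_toy_genome("T" * 5, utr5, cds, utr3, "G" * 5)
        from recombikit.genome_io import extract_regions
        return gene, extract_regions(gene, genome)

    def test_repeat_in_utr3_counted_in_utr3_and_whole(self):
        cds = "ATG" + "GCT" * 30 + "TAA"
        utr3 = "CGATC" + "A" * 12 + "GCTAG" + "CCGGATTACG"
        gene, regions = self._gene_with("CCTCGGAAGG", cds, utr3)
        prof = cx.profile_gene(gene, regions, PARAMS)
        assert prof.whole_counts["mono"] == 1
        assert prof.utr3_counts["mono"] == 1
        assert prof.atg_stop_counts["mono"] == 0

    def test_repeat_across_start_codon_counts_whole_only(self):
        # TG tiling across the boundary; the A of ATG is the one mismatch
        utr5 = "CCGATCCGGA" + "TGTGTGTGTGTGT"
        cds = "ATG" + "TGTGTGTGTGTGTG" + "GCT" * 25 + "TAA"
        gene, regions = self._gene_with(utr5, cds, "CGATCGATCG")
        prof = cx.profile_gene(gene, regions, PARAMS)
        assert prof.whole_counts["di"] == 1
        assert prof.utr5_counts["di"] == 0
        assert prof.atg_stop_counts["di"] == 0

    def test_repeat_free_gene_zero_densities(self):
        cds = "ATG" + "GCTAGACTCGATCCGGATCGCATCGACTGACGTACGAGCATGCATCGCATGCCATGACTACG" * 3 + "TAA"
        gene, regions = self._gene_with("CCGATCCGGA", cds, "CGATCGGATC")
        prof = cx.profile_gene(gene, regions, PARAMS)
        assert all(v == 0 for v in prof.whole_counts.values())
        assert all(v == 0.0 for v in prof.density_per_kbp.values())


class TestDatasetSummary:
    def test_planted_gene_counts(self, study):
        from recombikit.genome_io import extract_regions
        profiles = [cx.profile_gene(g, extract_regions(g, study.genome), PARAMS)
                    for g in study.genes]
        summary = cx.dataset_summary(profiles)
        expected_mdt = sum(
            1 for info in study.manifest["genes"].values()
            if any(info["repeat_counts"][k]["whole"] > 0
                   for k in ("mono", "di", "tri")))
        assert summary["totals"]["genes_with_mono_di_tri"] == expected_mdt
        per_kind = summary["per_kind"].set_index("kind")
        for kind in ("mono", "di", "tri", "tetra_plus", "inverted"):
            expected = sum(1 for info in study.manifest["genes"].values()
                           if info["repeat_counts"][kind]["whole"] > 0)
            assert per_kind.loc[kind, "genes_with_hit"] == expected

    def test_identical_profiles_mean_density(self):
        prof = cx.ComplexityProfile(
            gene_id="x", gene_length=2000, gc=0.6,
            whole_counts={k: (2 if k == "mono" else 0) for k in cx.KINDS},
            utr5_counts={k: 0 for k in cx.KINDS},
            atg_stop_counts={k: 0 for k in cx.KINDS},
            utr3_counts={k: 0 for k in cx.KINDS})
        summary = cx.dataset_summary([prof, prof, prof])
        per_kind = summary["per_kind"].set_index("kind")
        assert per_kind.loc["mono", "aggregate_density_per_kbp"] == pytest.approx(1.0)
        assert per_kind.loc["mono", "mean_per_gene_density_per_kbp"] == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cx.dataset_summary([])


def test_masked_bed_counts(tmp_path, study):
    gene = study.genes[0]
    s, e = gene.gene_span
    bed = tmp_path / "mask.bed"
    bed.write_text(f"{gene.chromosome}\t{s + 10}\t{s + 60}\n"
                   f"{gene.chromosome}\t{e - 30}\t{e + 30}\n")  # spans the end
    masked = cx.load_masked_bed(bed)
    counts = cx.masked_repeat_counts(study.genes, masked)
    assert counts[gene.gene_id] == 1  # only the fully-contained interval
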