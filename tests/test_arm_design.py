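import pytest

from recombikit import arm_design as ad
from recombikit import construct
from recombikit.genome_io import revcomp

from conftest import make_toy_genome

PARAMS = ad.ArmParams()


def toy_gene(strand="+", upstream=None, cds=None):
    upstream = upstream or ("ACGGTCTTAT" * 350)       # 3500 bp, repeat-lite
    cds = cds or ("ATG" + "GCA" * 80 + "TAA")
    return make_toy_genome(upstream, "CCGAC" * 10, cds, "GGATC" * 10,
                           "ACGGT" * 20, strand=strand)


class TestCandidateWindows:
    def test_951_candidates_on_clean_template(self):
        genome, gene = toy_gene()
        cands = ad.candidate_5prime_windows(gene, genome, PARAMS)
        assert len(cands) == (PARAMS.window_max - PARAMS.window_min
                              - PARAMS.arm_len + 1) == 951

    def test_candidates_lie_strictly_beyond_window_min(self):
        genome, gene = toy_gene()
        for arm in ad.candidate_5prime_windows(gene, genome, PARAMS):
            assert -PARAMS.window_max <= arm.offset_from_atg
            assert arm.offset_from_atg + PARAMS.arm_len <= -PARAMS.window_min

    def test_insufficient_upstream_reports_feasible_window(self):
        genome, gene = make_toy_genome("A" * 1500, "CCGAC", "ATG" + "GCA" * 20 + "TAA",
                                       "GGATC", "ACGGT")
        with pytest.raises(ad.ArmDesignError, match="feasible window"):
            ad.candidate_5prime_windows(gene, genome, PARAMS)

    def test_minus_strand_intervals_above_atg(self):
        genome, gene = toy_gene(strand="-")
        atg = gene.atg_position
        for arm in ad.candidate_5prime_windows(gene, genome, PARAMS):
            assert arm.genomic_interval[0] > atg

    def test_sequences_match_slice_oracle_on_both_strands(self):
        for strand in "+-":
            genome, gene = toy_gene(strand=strand)
            for arm in ad.candidate_5prime_windows(gene, genome, PARAMS)[::97]:
                s, e = arm.genomic_interval
                raw = genome.records[gene.chromosome][s:e]
                expect = raw if strand == "+" else revcomp(raw)
                assert arm.sequence == expect.upper()

    def test_candidates_containing_n_dropped(self):
        up = list("ACGGTCTTAT" * 350)
        up[3500 - 2500] = "N"
        genome, gene = toy_gene(upstream="".join(up))
        cands = ad.candidate_5prime_windows(gene, genome, PARAMS)
        assert all("N" not in a.sequence for a in cands)
        assert len(cands) < 951

    def test_no_arm_contains_iscei_site(self):
        up = "ACGGTCTTAT" * 350
        pos = 3500 - 2500
        up = up[:pos] + ad.ISCEI_SITE + up[pos + 18:]
        genome, gene = toy_gene(upstream=up)
        cands = ad.candidate_5prime_windows(gene, genome, PARAMS)
        for arm in cands:
            assert ad.ISCEI_SITE not in arm.sequence


class TestRankAndSelect:
    def _mk(self, seq, offset, gc, run, dint):
        # genomic interval consistent with a + strand gene whose ATG is at 5000
        return ad.HomologyArm(gene_id="g", side="5prime", sequence=seq,
                              genomic_interval=(5000 + offset, 5050 + offset),
                              offset_from_atg=offset,
                              gc=gc, longest_run=run, longest_dint=dint)

    def test_homopolymer_run_filtered(self):
        good = self._mk("G" * 50, -2500, 0.60, 2, 1)
        bad = self._mk("A" * 50, -2400, 0.60, 6, 1)
        out = ad.rank_and_select([good, bad] * 3, ad.ArmParams(top_k=2))
        assert all(a.longest_run <= PARAMS.max_homopolymer_run for a in out)

    def test_tie_break_prefers_target_offset_then_coordinate(self):
        a = self._mk("G" * 50, -2100, 0.60, 2, 1)
        b = self._mk("G" * 50, -2500, 0.60, 2, 1)
        c = self._mk("G" * 50, -2900, 0.60, 2, 1)
        out = ad.rank_and_select([a, b, c], ad.ArmParams(top_k=3))
        # equal scores: target offset wins, then the equidistant pair orders
        # by ascending genomic coordinate
        assert [x.offset_from_atg for x in out] == [-2500, -2900, -2100]

    def test_relaxation_flagged_when_filters_exhaust(self):
        bads = [self._mk("A" * 50, -2500 + i, 0.95, 8, 6) for i in range(6)]
        out = ad.rank_and_select(bads, ad.ArmParams(top_k=5))
        assert out and set(out[0].relaxed_filters) == set(
            ("gc_bounds", "max_dint_tandem_units", "max_homopolymer_run"))

    def test_planted_clean_window_ranks_first(self, study):
        for gene in study.genes:
            info = study.manifest["genes"][gene.gene_id]
            arms = ad.design_5prime_arms(gene, study.genome)
            assert arms[0].sequence == info["best_arm_sequence"]
            assert arms[0].offset_from_atg == info["best_arm_offset"]
            assert arms[0].relaxed_filters == ()
            assert len(arms) == 5

    def test_selection_deterministic(self, study):
        gene = study.genes[0]
        first = ad.design_5prime_arms(gene, study.genome)
        second = ad.design_5prime_arms(gene, study.genome)
        assert [(a.sequence, a.score) for a in first] == \
               [(a.sequence, a.score) for a in second]


class TestThreePrimeArm:
    def test_arm_abuts_stop_codon(self):
        genome, gene = toy_gene()
        arm = ad.three_prime_arm(gene, genome, PARAMS)
        stop_s, stop_e = gene.stop_span
        assert arm.genomic_interval == (stop_s - 50, stop_s)
        assert len(arm.sequence) == 50

    def test_minus_strand_arm(self):
        genome, gene = toy_gene(strand="-")
        arm = ad.three_prime_arm(gene, genome, PARAMS)
        stop_s, stop_e = gene.stop_span
        assert arm.genomic_interval == (stop_e, stop_e + 50)
        raw = genome.records[gene.chromosome][stop_e:stop_e + 50]
        assert arm.sequence == revcomp(raw).upper()

    def test_annotation_drift_detected(self):
        cds_bad = "ATG" + "GCA" * 80 + "TAC"      # not a stop codon
        genome, gene = toy_gene(cds=cds_bad)
        with pytest.raises(ad.ArmDesignError, match="TAC"):
            ad.three_prime_arm(gene, genome, PARAMS)

    def test_arm_is_genomic_contiguous_across_intron(self):
        """Homology is to the clone, so an intron in the last 50 bp stays."""
        from recombikit import genome_io
        exon1 = "ATG" + "GCA" * 30
        intron = "GT" + "CCTTACCTAGCCTTAC" + "AG"
        exon2 = "GAC" * 10 + "TAA"
        sense = "T" * 3500 + "CCGAC" + exon1 + intron + exon2 + "GGATC" + "A" * 50
        genome = genome_io.GenomeSequences({"c": sense})
        off = 3505
        cds1 = (off, off + len(exon1))
        cds2 = (cds1[1] + len(intron), cds1[1] + len(intron) + len(exon2))
        gene = genome_io.GeneModel("gi", "c", "+", (off - 5, cds2[1] + 5),
                                   utr5_segments=[(off - 5, off)],
                                   cds_segments=[cds1, cds2],
                                   utr3_segments=[(cds2[1], cds2[1] + 5)])
        arm = ad.three_prime_arm(gene, genome, PARAMS)
        stop_s = cds2[1] - 3
        assert arm.sequence == sense[stop_s - 50:stop_s]
        assert intron[-10:] in arm.sequence  # intron bases retained


class TestCloningPrimers:
    def test_primer_composition_and_length(self, study):
        gene = study.genes[0]
        arm5 = ad.design_5prime_arms(gene, study.genome)[0]
        arm3 = ad.three_prime_arm(gene, study.genome)
        pair = ad.build_cloning_primers(arm5, arm3, study.vector)
        anneal = len(study.vector.forward_anneal)
        assert len(pair.forward) == 50 + anneal
        assert pair.forward.startswith(arm5.sequence)
        assert pair.reverse.startswith(revcomp(arm3.sequence))
        assert pair.expected_amplicon_len == study.vector.cassette_length + 100

    def test_amplicon_excludes_ccdb(self, study):
        gene = study.genes[0]
        arm5 = ad.design_5prime_arms(gene, study.genome)[0]
        arm3 = ad.three_prime_arm(gene, study.genome)
        pair = ad.build_cloning_primers(arm5, arm3, study.vector)
        product = construct.simulate_cassette_pcr(study.vector, pair)
        ccdb = study.vector.feature_seq("ccdB")
        assert ccdb not in product and revcomp(ccdb) not in product


class TestCheckPrimers:
    def test_four_clean_pairs_in_bounds(self, study):
        from recombikit import primer_qc
        gene = study.genes[0]
        design = ad.design_check_primers(gene, study.genome)
        assert len(design.pairs) == 4
        for pair in design.pairs:
            assert 200 <= pair.expected_amplicon_len <= 800
            verdict = primer_qc.screen_pair(pair.forward, pair.reverse)
            assert not verdict.pair_breach

    def test_zero_pairs_requested(self, study):
        design = ad.design_check_primers(study.genes[0], study.genome, n_pairs=0)
        assert design.pairs == []

    def test_unprimable_region_reported(self):
        # an upstream window of pure AT homopolymer alternation defeats QC
        genome, gene = toy_gene(upstream="AAAAATTTTT" * 350)
        design = ad.design_check_primers(gene, genome)
        assert "upstream_window" in design.unprimable_regions


def test_utr5_override_arm(study):
    gene = study.genes[0]
    arm = ad.utr5_override_arm(gene, study.genome)
    s, e = gene.gene_span
    expect = (study.genome.records[gene.chromosome][s:s + 50]
              if gene.strand == "+"
              else revcomp(study.genome.records[gene.chromosome][e - 50:e]))
    assert arm.sequence == expect.upper()
    assert arm.relaxed_filters == ("utr5_override",)
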