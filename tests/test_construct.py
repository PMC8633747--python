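import numpy as np
import pytest

from recombikit import arm_design, construct
from recombikit.construct import (ConstructError, ConstructModel,
                                  digest_fragments, enzyme_sites, find_isce1,
                                  suggest_diagnostic_enzymes)
from recombikit.genome_io import revcomp


def retrieval(study, gene_index=0):
    """Design arms and simulate the full retrieval for one fixture gene."""
    gene = study.genes[gene_index]
    arm5 = arm_design.design_5prime_arms(gene, study.genome)[0]
    arm3 = arm_design.three_prime_arm(gene, study.genome)
    pair = arm_design.build_cloning_primers(arm5, arm3, study.vector)
    cassette = construct.simulate_cassette_pcr(study.vector, pair)
    lo = min(arm5.genomic_interval[0], arm3.genomic_interval[0])
    hi = max(arm5.genomic_interval[1], arm3.genomic_interval[1])
    region = study.genome.slice(gene.chromosome, lo, hi)
    if gene.strand == "-":
        region = revcomp(region)
    cds_len = sum(e - s for s, e in gene.cds_segments) - 3
    product = construct.assemble_product(region, arm5, arm3, cassette,
                                         cds_len_before_stop=cds_len)
    return gene, arm5, arm3, cassette, region, product


class TestVectorModel:
    def test_fixture_vector_loads_with_all_roles(self, study, tmp_path):
        p = tmp_path / "v.gb"
        construct.vector_to_genbank(study.vector, p)
        v = construct.load_vector(p)
        assert v.sequence == study.vector.sequence
        roles = {name for name, _, _ in v.features}
        assert set(construct.REQUIRED_FEATURES) <= roles

    def test_two_iscei_sites_rejected(self, study):
        seq = study.vector.sequence
        pos = seq.find(construct.ISCEI_SITE)
        doubled = seq[:pos - 40] + construct.ISCEI_SITE + seq[pos - 22:]
        with pytest.raises(ConstructError, match="I-SceI"):
            construct.VectorModel("bad", doubled, list(study.vector.features))

    def test_missing_feature_listed(self, study):
        feats = [f for f in study.vector.features if f[0] != "ccdB"]
        with pytest.raises(ConstructError, match="ccdB"):
            construct.VectorModel("nofeat", study.vector.sequence, feats)


class TestCassettePCR:
    def test_product_length_is_cassette_plus_arms(self, study):
        _, _, _, cassette, _, _ = retrieval(study)
        assert len(cassette) == study.vector.cassette_length + 100

    def test_product_is_ccdb_free_with_one_iscei(self, study):
        _, _, _, cassette, _, _ = retrieval(study)
        ccdb = study.vector.feature_seq("ccdB")
        assert ccdb not in cassette and revcomp(ccdb) not in cassette
        assert len(find_isce1(cassette)) == 1

    def test_zero_length_arms_give_bare_cassette(self, study):
        v = study.vector
        pair = arm_design.PrimerPair(
            name="bare", forward=v.forward_anneal, reverse=v.reverse_anneal,
            purpose="cloning", expected_amplicon_len=v.cassette_length)
        product = construct.simulate_cassette_pcr(v, pair)
        assert product == v.cassette_core

    def test_mismatched_anneal_rejected(self, study):
        pair = arm_design.PrimerPair(
            name="bad", forward="ACGT" * 10, reverse=study.vector.reverse_anneal,
            purpose="cloning", expected_amplicon_len=1)
        with pytest.raises(ConstructError, match="forward"):
            construct.simulate_cassette_pcr(study.vector, pair)


class TestAssembly:
    def test_circular_length_counts_shared_arms_once(self, study):
        _, _, _, cassette, region, product = retrieval(study)
        assert product.length == len(region) + len(cassette) - 100

    def test_round_trip_recovers_retrieved_region(self, study):
        _, arm5, arm3, _, region, product = retrieval(study)
        s = product.sequence
        i5 = s.find(arm5.sequence)
        i3 = s.find(arm3.sequence)
        assert s[i5:i3 + 50] == region

    def test_junction_translates_linker_then_fluorophore_start(self, study):
        from Bio.Seq import Seq
        _, _, _, _, _, product = retrieval(study)
        seam = dict((n, iv) for n, iv, _ in product.features)["cassette_core"][0]
        aa = str(Seq(product.sequence[seam:seam + 33]).translate())
        assert aa.startswith("GGLGGSGGR") and aa[9] == "M"

    def test_frame_displacement_detected(self, study):
        gene, arm5, arm3, cassette, region, _ = retrieval(study)
        cds_len = sum(e - s for s, e in gene.cds_segments) - 3
        product = construct.assemble_product(region, arm5, arm3, cassette,
                                             cds_len_before_stop=cds_len + 1)
        assert not product.fusion_frame_ok

    def test_duplicated_arm_is_ambiguous(self, study):
        _, arm5, arm3, cassette, region, _ = retrieval(study)
        doubled = region + arm5.sequence
        with pytest.raises(ConstructError, match="ambig|times"):
            construct.assemble_product(doubled, arm5, arm3, cassette)


class TestFindISceI:
    def test_exactly_one_in_fixture_construct(self, study):
        _, _, _, _, _, product = retrieval(study)
        assert len(product.isce1_positions) == 1

    def test_both_strands_detected(self):
        s = "ACGT" * 10 + revcomp(construct.ISCEI_SITE) + "ACGT" * 10
        assert len(find_isce1(s)) == 1

    def test_absent_from_random_10kb(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        hits = sum(len(find_isce1("".join(rng.choice(bases, 10_000))))
                   for _ in range(200))
        assert hits == 0  # expected rate (1/4)^18 per position

    def test_absent_from_fixture_genome(self, study):
        for seq in study.genome.records.values():
            assert find_isce1(seq) == []


class TestDigest:
    def test_single_site_yields_full_length(self):
        res = digest_fragments(10_000, [137])
        assert res.cut and res.fragments == [10_000]

    def test_two_sites_on_kb_circle(self):
        res = digest_fragments(1000, [100, 600])
        assert sorted(res.fragments) == [500, 500]

    def test_uncut_flagged(self):
        res = digest_fragments(5000, [])
        assert not res.cut and res.fragments == [5000]

    def test_conservation_and_rotation_invariance(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(100, 20_000))
            k = int(rng.integers(1, 8))
            sites = sorted(set(int(x) for x in rng.integers(0, n, k)))
            frags = digest_fragments(n, sites).fragments
            assert sum(frags) == n
            shift = int(rng.integers(0, n))
            rotated = [(p + shift) % n for p in sites]
            assert sorted(digest_fragments(n, rotated).fragments) == sorted(frags)


class TestEnzymeSuggestions:
    def test_planted_single_cutter_ranked_first(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        body = "".join(rng.choice(bases, 6000)).replace("GAATTC", "GAATAC")
        seq = body[:2000] + "GAATTC" + body[2000:]
        model = ConstructModel(sequence=seq)
        table = {"EcoRI": "GAATTC", "Missing": "GCGGCCGC"}
        rows = suggest_diagnostic_enzymes(model, table)
        assert rows and rows[0]["enzyme"] == "EcoRI"
        assert all(r["enzyme"] != "Missing" for r in rows)

    def test_palindromic_site_counted_once(self):
        seq = "A" * 100 + "GAATTC" + "C" * 100
        assert enzyme_sites(seq, "GAATTC", circular=False) == [100]

    def test_non_palindromic_site_counted_on_both_strands(self):
        site = "GGTCTC"  # BsaI-like, not its own revcomp
        seq = "A" * 50 + site + "C" * 50 + revcomp(site) + "T" * 50
        assert len(enzyme_sites(seq, site, circular=False)) == 2

    def test_empty_table_rejected(self):
        with pytest.raises(ConstructError):
            suggest_diagnostic_enzymes(ConstructModel(sequence="ACGT" * 100), {})


def test_construct_genbank_round_trip(study, tmp_path):
    from Bio import SeqIO
    _, _, _, _, _, product = retrieval(study)
    p = tmp_path / "construct.gb"
    construct.construct_to_genbank(product, p, name="toyproduct")
    rec = SeqIO.read(str(p), "genbank")
    assert str(rec.seq) == product.sequence
    assert rec.annotations["topology"] == "circular"
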