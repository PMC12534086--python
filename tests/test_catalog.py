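"""Consensus acceptance, mapping, CDS extraction, SNP calling, variant ids."""

import subprocess
import textwrap

import pytest

from beemas.catalog import (
    CdsIndelError,
    InsufficientCoverageError,
    MixedSampleError,
    UnexpectedHeterozygosityError,
    UnmappableSampleError,
    assign_variant_ids,
    build_catalog_from_consensus,
    call_snps_and_classify,
    enforce_single_haplotype,
    extract_cds,
    map_to_gene,
)
from beemas.simulate import S1110_PROTEIN_POS, make_reads
from beemas.snp import apply_snps, snp_at


class TestEnforceSingleHaplotype:
    def test_pure_sample_accepted(self, pool):
        seq = pool[2].sequence
        reads = [seq] * 10
        assert enforce_single_haplotype(reads) == seq

    def test_pure_noisy_sample_accepted(self, pool):
        seq = pool[2].sequence
        reads = make_reads(seq, (1, len(seq)), 0.02, 20, seed=3)
        assert enforce_single_haplotype(reads) == seq

    def test_even_mixture_rejected(self, pool, vg_model):
        # two haplotypes differing at 3 sites
        a = vg_model.sequence
        b = apply_snps(vg_model, sorted(pool[9].snps)[:3])
        with pytest.raises(MixedSampleError):
            enforce_single_haplotype([a] * 5 + [b] * 5)

    def test_mixture_tolerated_when_threshold_raised(self, pool, vg_model):
        a, b = vg_model.sequence, pool[9].sequence
        consensus = enforce_single_haplotype([a] * 8 + [b] * 2, max_minor_fraction=0.25)
        assert consensus == a

    def test_batch_of_ten_with_two_mixtures(self, pool, vg_model):
        accepted = 0
        for i in range(10):
            if i < 2:
                reads = [pool[1].sequence] * 5 + [pool[5].sequence] * 5
            else:
                reads = [pool[2].sequence] * 10
            try:
                enforce_single_haplotype(reads)
                accepted += 1
            except MixedSampleError:
                pass
        assert accepted == 8

    def test_insufficient_coverage(self, pool):
        with pytest.raises(InsufficientCoverageError):
            enforce_single_haplotype([pool[1].sequence] * 2)


class TestMapToGene:
    def test_identity_mapping(self, vg_model):
        assert map_to_gene(vg_model.sequence, vg_model) == vg_model.sequence

    def test_planted_substitutions_flagged_nowhere_else(self, vg_model, pool):
        mutant = pool[9].sequence  # 4 planted substitutions
        mapped = map_to_gene(mutant, vg_model)
        mismatches = {
            i + 1 for i, (a, b) in enumerate(zip(mapped, vg_model.sequence)) if a != b
        }
        assert mismatches == {s.gene_pos for s in pool[9].snps}

    def test_random_sequence_unmappable(self, vg_model):
        import numpy as np

        # a seed far from the model's own, so the sequence is truly unrelated
        rng = np.random.default_rng(987654321)
        junk = "".join(rng.choice(list("ACGT"), size=len(vg_model)))
        with pytest.raises(UnmappableSampleError):
            map_to_gene(junk, vg_model)

    def test_length_out_of_range_rejected(self, vg_model):
        with pytest.raises(UnmappableSampleError):
            map_to_gene("ACGT" * 10, vg_model)

    def test_deletion_produces_gap_at_correct_position(self, vg_model):
        seq = vg_model.sequence
        deleted = seq[:999] + seq[1005:]  # drop 6 bases inside exon 2
        mapped = map_to_gene(deleted, vg_model)
        assert len(mapped) == len(seq)
        assert "-" in mapped[995:1010]
        assert mapped[:900] == seq[:900]

    def test_mafft_cross_check_on_planted_substitutions(self, vg_model, pool, tmp_path):
        """Independent aligner (MAFFT) sees the same mismatch columns."""
        mutant = pool[15].sequence
        fasta = tmp_path / "pair.fasta"
        fasta.write_text(f">ref\n{vg_model.sequence}\n>mut\n{mutant}\n")
        out = subprocess.run(
            ["mafft", "--retree", "1", "--quiet", str(fasta)],
            capture_output=True, text=True, check=True,
        ).stdout
        seqs = {}
        for block in out.split(">")[1:]:
            name, _, body = block.partition("\n")
            seqs[name.split()[0]] = body.replace("\n", "").upper()
        mafft_mismatches = {
            i + 1
            for i, (a, b) in enumerate(zip(seqs["ref"], seqs["mut"]))
            if a != b
        }
        ours = {s.gene_pos for s in pool[15].snps}
        assert mafft_mismatches == ours


class TestExtractCds:
    def test_reference_round_trip(self, vg_model):
        cds = extract_cds(vg_model.sequence, vg_model)
        assert cds.startswith("ATG") and len(cds) % 3 == 0

    def test_toy_hand_spliced_oracle(self, toy_model):
        assert extract_cds(toy_model.sequence, toy_model) == "ATGGCTGAATAA"

    def test_intronic_snps_leave_cds_unchanged(self, toy_model):
        mutated = toy_model.sequence[:12] + "AAAA" + toy_model.sequence[16:]
        assert extract_cds(mutated, toy_model) == "ATGGCTGAATAA"

    def test_gap_in_cds_excludes_sample(self, toy_model):
        mapped = toy_model.sequence[:5] + "-" + toy_model.sequence[6:]
        with pytest.raises(CdsIndelError):
            extract_cds(mapped, toy_model)


class TestCallSnps:
    def test_s1110t_annotation(self, vg_model, pool):
        snps = call_snps_and_classify(pool[15].sequence, vg_model)
        changes = {s.aa_change for s in snps if s.aa_change}
        assert ("S", S1110_PROTEIN_POS, "T") in changes
        named = next(s for s in snps if s.aa_change == ("S", 1110, "T"))
        assert named.hgvs_p == "p.S1110T"
        assert named.synonymous is False

    def test_wobble_change_is_synonymous(self, vg_model):
        # CCA -> CCG at a planted proline codon (fourfold degenerate)
        pos = vg_model.codon_gene_positions(240)[2]
        snp = snp_at(vg_model, pos, "G")
        assert snp.synonymous is True and snp.aa_change is None
        mutated = apply_snps(vg_model, [snp])
        called = call_snps_and_classify(mutated, vg_model)
        assert {s.gene_pos for s in called} == {pos}
        assert next(iter(called)).synonymous is True

    def test_reference_sample_yields_empty_set(self, vg_model):
        assert call_snps_and_classify(vg_model.sequence, vg_model) == frozenset()

    def test_ambiguity_in_haploid_flagged(self, vg_model):
        seq = vg_model.sequence[:100] + "R" + vg_model.sequence[101:]
        with pytest.raises(UnexpectedHeterozygosityError):
            call_snps_and_classify(seq, vg_model, ploidy=1)

    def test_intronic_snp_has_no_synonymy(self, vg_model):
        intron_pos = vg_model.exons[0][1] + 5  # inside intron 1
        alt = "A" if vg_model.sequence[intron_pos - 1] != "A" else "G"
        snp = snp_at(vg_model, intron_pos, alt)
        assert snp.in_exon is None and snp.synonymous is None


class TestVariantIds:
    def test_same_nssnps_different_ssnps_share_id(self, vg_model, records):
        from beemas.catalog import AlleleRecord
        from beemas.simulate import syn_snp

        ns = next(r for r in records if len(r.nssnps) == 1).nssnps
        syn = syn_snp(vg_model, 240)
        a = AlleleRecord("a", "c1", "s", "drone", 1, apply_snps(vg_model, ns), ns)
        b = AlleleRecord(
            "b", "c1", "s", "drone", 1, apply_snps(vg_model, ns | {syn}), ns | {syn}
        )
        recs, catalog = assign_variant_ids([a, b])
        assert recs[0].variant_id == recs[1].variant_id
        assert catalog.n_variants == 1

    def test_reference_gets_variant_one(self, vg_model):
        from beemas.catalog import AlleleRecord

        rec = AlleleRecord("r", "c", "s", "drone", 1, vg_model.sequence)
        recs, _ = assign_variant_ids([rec])
        assert recs[0].variant_id == 1

    def test_counts_sum_to_accepted_samples(self, catalog_result):
        assert catalog_result.catalog.total_samples() == catalog_result.n_accepted


class TestRoundTrip:
    def test_noiseless_catalog_matches_truth_table(self, catalog_result, records):
        """Catalogue partition == generator truth partition, sample by sample."""
        truth = {r.sample_id: r.variant_id for r in records}
        called = {r.sample_id: r.variant_id for r in catalog_result.records}
        assert set(truth) == set(called)
        mapping = {}
        for sid, true_vid in truth.items():
            mapping.setdefault(true_vid, set()).add(called[sid])
        # bijection between truth ids and catalogue ids
        assert all(len(v) == 1 for v in mapping.values())
        assigned = [next(iter(v)) for v in mapping.values()]
        assert len(set(assigned)) == len(assigned)
        assert catalog_result.catalog.n_variants == 26
        assert len(catalog_result.catalog.nssnp_union) == 34

    def test_rejected_samples_reported(self, vg_model):
        samples = [
            ("ok", "c", "s", "drone", vg_model.sequence, 1),
            ("bad", "c", "s", "drone", "A" * len(vg_model), 1),
        ]
        result = build_catalog_from_consensus(samples, vg_model)
        assert result.n_accepted == 1
        assert "bad" in result.rejected
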