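"""Signature discovery: haplotype collapsing, the exon-window search vs a
brute-force oracle, confounder handling by colony exclusion, minimality."""

import pytest

from beemas.catalog import AlleleRecord
from beemas.signature import (
    NoSignatureError,
    collapse_haplotypes,
    find_signature,
    validate_signature,
)
from beemas.simulate import (
    PRIMER_PAIRS,
    SimScenario,
    make_allele_pool,
    sample_population,
    truth_records,
)


# --------------------------------------------------------------------------
# independent oracle: enumerate exons straight from the raw sequences
# --------------------------------------------------------------------------


def brute_force_signature(records, target_variant, model, max_window_bp=700):
    """Exhaustive exon-region search working directly on sequences."""
    best = None
    for exon_no, (es, ee) in enumerate(model.exons, start=1):
        sites = [
            p
            for p in range(es, ee + 1)
            if len({r.sequence[p - 1] for r in records}) > 1
            and {r.sequence[p - 1] for r in records} <= set("ACGT")
        ]
        if not sites:
            continue
        window = (sites[0], sites[-1])
        if window[1] - window[0] + 1 > max_window_bp:
            continue
        targets = [r for r in records if r.variant_id == target_variant]
        tuples = {tuple(r.sequence[p - 1] for p in sites) for r in targets}
        if len(tuples) != 1:
            continue
        tt = next(iter(tuples))
        conflicting_colonies = {
            r.colony
            for r in records
            if r.variant_id != target_variant
            and tuple(r.sequence[p - 1] for p in sites) == tt
        }
        excluded = tuple(sorted(conflicting_colonies))
        if not any(r.colony not in excluded for r in targets):
            continue
        score = (len(excluded), len(sites), window[1] - window[0] + 1, window[0])
        if best is None or score < best[0]:
            best = (score, exon_no, window, tuple(sites), tt, excluded)
    return best


def _records_for(pool, scenario):
    drones, _ = sample_population(pool, scenario)
    return [
        AlleleRecord(
            r.sample_id, r.colony, r.stock, r.caste, 1,
            pool[r.variant_id].sequence, pool[r.variant_id].snps, r.variant_id,
        )
        for r in drones.itertuples(index=False)
    ]


class TestCollapseHaplotypes:
    def test_enumerated_tuples(self, vg_model, pol_records):
        """AA, AG, GA, AA over 2 sites -> 3 haplotypes with counts 2, 1, 1."""
        base = pol_records[0]
        seqs = {}
        template = vg_model.sequence
        pos1, pos2 = 873, 918  # two exon-2 sites
        for name, (a, b) in {"h1": "AA", "h2": "AG", "h3": "GA", "h4": "AA"}.items():
            s = list(template)
            s[pos1 - 1], s[pos2 - 1] = a, b
            seqs[name] = "".join(s)
        recs = [
            AlleleRecord(n, "c", "s", "drone", 1, seq, variant_id=i)
            for i, (n, seq) in enumerate(seqs.items())
        ]
        table = collapse_haplotypes(recs, (860, 930))
        assert table.sites == (pos1, pos2)
        assert [r.count for r in table.rows] == [2, 1, 1]
        assert table.total() == 4

    def test_identical_records_collapse_to_one(self, vg_model):
        recs = [
            AlleleRecord(f"r{i}", "c", "s", "drone", 1, vg_model.sequence, variant_id=1)
            for i in range(5)
        ]
        table = collapse_haplotypes(recs, (1, len(vg_model)))
        assert table.n_haplotypes == 1

    def test_counts_conserved_on_study_population(self, pol_records, vg_model):
        window = vg_model.exons[1]
        table = collapse_haplotypes(pol_records, window)
        assert table.total() == len(pol_records)
        assert len({r.alleles for r in table.rows}) == table.n_haplotypes


class TestFindSignature:
    def test_reference_signature_is_exon2(self, pol_records, vg_model):
        sig = find_signature(pol_records, 1, vg_model, primers=PRIMER_PAIRS)
        assert sig.exon == 2
        assert len(sig.sites) == 9
        assert sig.excluded_colonies == ()
        assert sig.amplicon is not None and sig.amplicon.length == 620
        table = collapse_haplotypes(pol_records, sig.window)
        assert table.n_haplotypes == 7

    def test_lipid_variant_needs_colony_exclusion(self, pol_records, vg_model):
        sig = find_signature(pol_records, 15, vg_model, primers=PRIMER_PAIRS)
        assert sig.exon == 4
        assert len(sig.sites) == 6
        assert sig.excluded_colonies == ("P7",)
        report = validate_signature(sig, pol_records)
        assert report.n_false_positives == 0

    def test_confounder_flagged_without_exclusion(self, pol_records, vg_model):
        sig = find_signature(pol_records, 15, vg_model)
        report = validate_signature(sig, pol_records, apply_exclusions=False)
        assert report.n_false_positives == 2
        assert {c for _, _, c in report.false_positives} == {"P7"}
        assert {v for _, v, _ in report.false_positives} == {7}

    def test_indiscriminable_twin_raises(self, vg_model, pool):
        # a non-target record genome-identical to the target, same colony
        recs = [
            AlleleRecord("t", "c1", "s", "drone", 1, pool[2].sequence, variant_id=2),
            AlleleRecord("x", "c1", "s", "drone", 1, pool[2].sequence, variant_id=99),
            AlleleRecord("r", "c1", "s", "drone", 1, pool[1].sequence, variant_id=1),
        ]
        with pytest.raises(NoSignatureError) as exc:
            find_signature(recs, 2, vg_model)
        assert exc.value.near_misses

    def test_absent_target_rejected(self, pol_records, vg_model):
        with pytest.raises(ValueError, match="absent"):
            find_signature(pol_records, 999, vg_model)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_brute_force_on_random_pools(self, vg_model, seed):
        """Exhaustive search over exon regions agrees with the implementation
        on random <=30-SNP pools, for every variant as target."""
        scenario = SimScenario(
            n_colonies=4, n_variants=5, n_nssnps=12, n_ssnps=4,
            drones_per_colony=8, target_variant=2, seed=seed,
        )
        pool = make_allele_pool(vg_model, scenario)
        records = _records_for(pool, scenario)
        present = sorted({r.variant_id for r in records})
        for target in present:
            expected = brute_force_signature(records, target, vg_model)
            if expected is None:
                with pytest.raises(NoSignatureError):
                    find_signature(records, target, vg_model)
                continue
            sig = find_signature(records, target, vg_model)
            _, exon_no, window, sites, tt, excluded = expected
            assert sig.exon == exon_no
            assert sig.window == window
            assert sig.positions == sites
            assert tuple(b for _, b in sig.sites) == tt
            assert sig.excluded_colonies == excluded

    def test_exclusions_can_be_disallowed(self, pol_records, vg_model):
        with pytest.raises(NoSignatureError):
            find_signature(pol_records, 15, vg_model, allow_exclusions=False)


class TestMinimality:
    def test_minimized_sites_discriminate_and_are_minimal(self, pol_records, vg_model):
        sig = find_signature(pol_records, 1, vg_model, minimize_sites=True)
        assert len(sig.sites) <= 9
        assert validate_signature(sig, pol_records).n_false_positives == 0
        # dropping any single site breaks discrimination
        from dataclasses import replace

        for i in range(len(sig.sites)):
            reduced_sites = sig.sites[:i] + sig.sites[i + 1 :]
            if not reduced_sites:
                continue
            reduced = replace(
                sig,
                sites=reduced_sites,
                site_alleles=sig.site_alleles[:i] + sig.site_alleles[i + 1 :],
                window=(reduced_sites[0][0], reduced_sites[-1][0]),
            )
            assert validate_signature(reduced, pol_records).n_false_positives >= 1

    def test_wider_windows_never_need_more_sites(self, pol_records, vg_model):
        narrow = find_signature(pol_records, 1, vg_model, max_window_bp=700,
                                minimize_sites=True)
        wide = find_signature(pol_records, 1, vg_model, max_window_bp=1200,
                              minimize_sites=True)
        assert len(wide.sites) <= len(narrow.sites)

    def test_stability_same_inputs_same_signature(self, pol_records, vg_model):
        a = find_signature(pol_records, 15, vg_model)
        b = find_signature(pol_records, 15, vg_model)
        assert a == b
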