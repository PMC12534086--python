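"""Haplodiploid inheritance, csd accounting, and the breeding-scheme gates."""

from collections import Counter

import numpy as np
import pytest

from beemas.breeding import (
    OTHER,
    TARGET,
    DroneGenotype,
    LineageExtinctError,
    QueenGenotype,
    SchemeConfig,
    daughter_distribution,
    diploid_male_fraction,
    drone_from_queen,
    heterozygote_detection_prob,
    mate,
    n_distinct_diploid_genotypes,
    run_scheme,
)


def _queen(markers, csd=(0, 1)):
    return QueenGenotype(tuple(tuple(m) for m in markers), csd)


class TestDroneFromQueen:
    def test_homozygous_queen_transmits_always(self):
        rng = np.random.default_rng(0)
        q = _queen([(TARGET, TARGET)])
        assert all(drone_from_queen(q, rng).is_carrier() for _ in range(200))

    def test_heterozygous_queen_transmits_half(self):
        rng = np.random.default_rng(1)
        q = _queen([(OTHER, TARGET)])
        n = 10_000
        carriers = sum(drone_from_queen(q, rng).is_carrier() for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(carriers / n - 0.5) <= 3 * se

    def test_two_locus_double_heterozygote_equal_quarters(self):
        rng = np.random.default_rng(2)
        q = _queen([(OTHER, TARGET), (OTHER, TARGET)])
        n = 20_000
        counts = Counter(drone_from_queen(q, rng).markers for _ in range(n))
        assert set(counts) == {
            (TARGET, TARGET), (TARGET, OTHER), (OTHER, TARGET), (OTHER, OTHER)
        }
        se = np.sqrt(0.25 * 0.75 / n)
        for hap in counts:
            assert abs(counts[hap] / n - 0.25) <= 3 * se


class TestMate:
    def test_het_queen_target_drone_exact_distribution(self):
        q = _queen([(OTHER, TARGET)])
        d = DroneGenotype((TARGET,), csd=5)
        dist = daughter_distribution(q, d)
        het = (tuple(sorted((OTHER, TARGET))),)
        assert dist == {((TARGET, TARGET),): 0.5, het: 0.5}
        assert abs(sum(dist.values()) - 1.0) < 1e-12

    def test_non_carrier_cross_yields_no_carriers(self):
        q = _queen([(OTHER, OTHER)])
        d = DroneGenotype((OTHER,), csd=5)
        (geno, p), = daughter_distribution(q, d).items()
        assert geno == ((OTHER, OTHER),) and p == 1.0

    def test_two_locus_distribution_sums_to_one(self):
        q = _queen([(OTHER, TARGET), (TARGET, TARGET)])
        d = DroneGenotype((OTHER, TARGET), csd=0)
        dist = daughter_distribution(q, d)
        assert abs(sum(dist.values()) - 1.0) < 1e-12
        assert len(dist) == 2  # locus 2 is fixed

    def test_csd_matched_drone_halves_viable_brood(self):
        rng = np.random.default_rng(3)
        q = _queen([(TARGET, TARGET)], csd=(1, 2))
        d = DroneGenotype((TARGET,), csd=1)
        n = 10_000
        diploid_males = sum(mate(q, d, rng) is None for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(diploid_males / n - 0.5) <= 3 * se

    def test_daughters_have_two_alleles_per_locus_drones_one(self):
        rng = np.random.default_rng(4)
        q = _queen([(OTHER, TARGET), (OTHER, TARGET)])
        d = DroneGenotype((TARGET, OTHER), csd=7)
        daughter = None
        while daughter is None:
            daughter = mate(q, d, rng)
        assert all(len(locus) == 2 for locus in daughter.markers)
        son = drone_from_queen(q, rng)
        assert len(son.markers) == q.n_loci


class TestClosedForms:
    def test_heterozygote_detection_probability(self):
        assert heterozygote_detection_prob(9) == 1 - 2**-9
        rng = np.random.default_rng(5)
        q = _queen([(OTHER, TARGET)])
        n = 5000
        detected = sum(
            any(drone_from_queen(q, rng).is_carrier() for _ in range(9))
            for _ in range(n)
        )
        p = heterozygote_detection_prob(9)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(detected / n - p) <= max(3 * se, 1e-3)

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_diploid_male_fraction_closed_form_and_monte_carlo(self, k):
        exact = diploid_male_fraction(k)
        assert exact == pytest.approx(1 / k)
        mc = diploid_male_fraction(
            k, "monte_carlo", n_matings=40_000, rng=np.random.default_rng(k)
        )
        se = np.sqrt(exact * (1 - exact) / 40_000) * 2  # brood halving widens SE
        assert abs(mc - exact) <= 3 * max(se, 1e-3)

    def test_diploid_male_fraction_decreases_with_allele_count(self):
        values = [diploid_male_fraction(k) for k in (2, 4, 8, 16, 64, 1024)]
        assert values == sorted(values, reverse=True)
        assert values[-1] < 0.001

    def test_genotype_space_grows_exponentially(self):
        assert [n_distinct_diploid_genotypes(k) for k in (1, 2, 3)] == [3, 9, 27]


class TestRunScheme:
    def test_het_founders_reach_full_homozygosity_by_f4(self):
        cfg = SchemeConfig(seed=0)
        trajectory = run_scheme(cfg)
        final = trajectory[-1]
        assert final.generation == 4
        assert final.queens and final.n_homozygous == len(final.queens)
        assert final.target_allele_freq == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_allele_frequency_non_decreasing_with_gates_active(self, seed):
        cfg = SchemeConfig(seed=seed, n_founder_queens=10,
                           queens_grafted_per_generation=30, daughters_screened=30)
        try:
            trajectory = run_scheme(cfg)
        except LineageExtinctError as exc:
            trajectory = exc.trajectory
        freqs = [st.target_allele_freq for st in trajectory if st.queens]
        assert all(b >= a - 1e-12 for a, b in zip(freqs, freqs[1:]))

    def test_neutral_scheme_is_a_martingale(self):
        """No selection gates: mean final allele frequency equals the founder
        frequency within 3 SE over many replicates."""
        reps = 10_000
        finals = []
        for rep in range(reps):
            cfg = SchemeConfig(
                n_founder_queens=4,
                queens_grafted_per_generation=8,
                daughters_screened=8,
                generations=2,
                n_csd_alleles=50,
                screen_virgin_queens=False,
                cull_on_drone_genotype=False,
                graft_from_homozygous_when_available=False,
                founder_mate_carrier_prob=0.5,
                seed=rep,
            )
            try:
                trajectory = run_scheme(cfg)
            except LineageExtinctError as exc:
                trajectory = exc.trajectory
            finals.append(trajectory[-1].target_allele_freq)
        mean = np.mean(finals)
        se = np.std(finals) / np.sqrt(reps)
        assert abs(mean - 0.5) <= 3 * se

    def test_trajectories_reproducible_from_seed(self):
        a = run_scheme(SchemeConfig(seed=33))
        b = run_scheme(SchemeConfig(seed=33))
        assert [(s.n_carriers, s.n_homozygous, s.target_allele_freq) for s in a] == [
            (s.n_carriers, s.n_homozygous, s.target_allele_freq) for s in b
        ]

    def test_non_carrier_founders_go_extinct(self):
        cfg = SchemeConfig(founders={"none": 1.0}, seed=1)
        with pytest.raises(LineageExtinctError) as exc:
            run_scheme(cfg)
        assert exc.value.trajectory

    def test_multilocus_fixation_is_slower(self):
        """Fixing k unlinked loci needs at least as many generations as one."""

        def generations_to_fix(n_loci, seed):
            cfg = SchemeConfig(
                n_loci=n_loci, generations=10, seed=seed,
                n_founder_queens=30, queens_grafted_per_generation=60,
                daughters_screened=60,
            )
            try:
                trajectory = run_scheme(cfg)
            except LineageExtinctError:
                return 11
            for st in trajectory:
                if st.queens and st.n_homozygous == len(st.queens):
                    return st.generation
            return 11

        for seed in range(3):
            assert generations_to_fix(2, seed) >= generations_to_fix(1, seed)

    def test_diploid_male_fraction_tracked(self):
        cfg = SchemeConfig(seed=2, n_csd_alleles=4, generations=3)
        trajectory = run_scheme(cfg)
        fractions = [st.diploid_male_brood_fraction for st in trajectory[1:]]
        assert all(0 <= f <= 1 for f in fractions)
        assert np.mean(fractions) == pytest.approx(1 / 4, abs=0.15)

    def test_pooled_insemination_mode_runs(self):
        trajectory = run_scheme(SchemeConfig(insemination="pooled", seed=6))
        assert trajectory[-1].queens

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SchemeConfig(founders={"het": 0.5})
        with pytest.raises(ValueError):
            SchemeConfig(n_csd_alleles=1)
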