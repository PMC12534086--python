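"""Stochastic simulator of the marker-assisted breeding scheme.

Honey bees are haplodiploid: drones develop from unfertilized eggs and carry
a single maternal chromosome set, queens and workers are diploid. The
scheme drives a target marker allele to homozygosity through four screening
gates per generation:

* G1 — founder queens are genotyped through their haploid drone sons (a
  heterozygote is detected by ``n`` sons with probability ``1 - 2**-n``);
* G2 — daughters are grafted only from carrier queens (from homozygous
  queens once any exist, mirroring the final generations of the field
  scheme);
* G3 — virgin daughter queens are genotyped and non-carriers culled;
* G4 — each queen is instrumentally inseminated with semen from a single
  drone; the drone is genotyped post hoc and queens inseminated by a
  non-carrier drone are culled.

Inbreeding is tracked through the single-locus complementary sex determiner
(csd): fertilized eggs homozygous at csd develop into inviable diploid
males, so each generation's diploid-male brood fraction is recorded. Under
random mating with ``k`` equifrequent csd alleles the expected fraction is
``1/k`` (probability ``2/k`` that the drone matches one of the queen's two
alleles, times the 1/2 of the brood that inherits the matching one).

Loci are unlinked and segregate independently; generations are discrete and
non-overlapping. Time is measured in generations, not calendar units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Literal, Optional

import numpy as np

TARGET = "T"  #: the selected marker allele
OTHER = "o"  #: any non-target allele


class LineageExtinctError(RuntimeError):
    """Every carrier queen was lost; carries the trajectory so far."""

    def __init__(self, message: str, trajectory: list["BreedingState"]):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass(frozen=True)
class QueenGenotype:
    """Diploid queen: one allele pair per marker locus plus a csd pair."""

    markers: tuple[tuple[str, str], ...]
    csd: tuple[int, int]
    id: int = 0
    generation: int = 0
    sire: Optional["DroneGenotype"] = None

    def __post_init__(self):
        if self.csd[0] == self.csd[1]:
            raise ValueError("csd-homozygous diploids are diploid males, not queens")

    @property
    def n_loci(self) -> int:
        return len(self.markers)

    def is_carrier(self, locus: int = 0) -> bool:
        return TARGET in self.markers[locus]

    def is_homozygous(self, locus: int = 0) -> bool:
        return self.markers[locus] == (TARGET, TARGET)

    def carries_all(self) -> bool:
        return all(self.is_carrier(l) for l in range(self.n_loci))

    def homozygous_all(self) -> bool:
        return all(self.is_homozygous(l) for l in range(self.n_loci))


@dataclass(frozen=True)
class DroneGenotype:
    """Haploid drone: one allele per marker locus plus one csd allele."""

    markers: tuple[str, ...]
    csd: int

    def is_carrier(self, locus: int = 0) -> bool:
        return self.markers[locus] == TARGET

    def carries_all(self) -> bool:
        return all(m == TARGET for m in self.markers)


@dataclass(frozen=True)
class SchemeConfig:
    """Parameters of the breeding scheme.

    ``founders`` maps single-locus genotype labels (``"hom"``, ``"het"``,
    ``"none"``) to frequencies among founder queens (applied independently
    per locus for multilocus runs).
    """

    n_loci: int = 1
    n_csd_alleles: int = 16
    founders: dict = field(default_factory=lambda: {"het": 1.0})
    n_founder_queens: int = 20
    founder_mate_carrier_prob: float = 0.5
    queens_grafted_per_generation: int = 100
    daughters_screened: int = 100
    drone_sons_for_genotyping: int = 9
    insemination: Literal["single_drone", "pooled"] = "single_drone"
    pooled_drones: int = 8
    screen_virgin_queens: bool = True
    cull_on_drone_genotype: bool = True
    graft_from_homozygous_when_available: bool = True
    colony_survival: float = 1.0
    generations: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1 or self.n_csd_alleles < 2 or self.generations < 1:
            raise ValueError("counts must be positive (csd needs >= 2 alleles)")
        if min(self.n_founder_queens, self.queens_grafted_per_generation,
               self.daughters_screened, self.drone_sons_for_genotyping) < 1:
            raise ValueError("population sizes must be positive")
        total = sum(self.founders.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"founder frequencies sum to {total}, not 1")
        if not set(self.founders) <= {"hom", "het", "none"}:
            raise ValueError("founder genotypes must be hom/het/none")


@dataclass
class BreedingState:
    """Census of one generation after all gates."""

    generation: int
    queens: list[QueenGenotype]
    n_grafted: int = 0
    n_screened: int = 0
    n_carriers: int = 0
    n_homozygous: int = 0
    n_culled_screen: int = 0
    n_culled_drone: int = 0
    diploid_male_brood_fraction: float = 0.0

    @property
    def target_allele_freq(self) -> float:
        if not self.queens:
            return 0.0
        alleles = [
            a
            for q in self.queens
            for locus in q.markers
            for a in locus
        ]
        return alleles.count(TARGET) / len(alleles)


# --------------------------------------------------------------------------
# Mendelian primitives
# --------------------------------------------------------------------------


def drone_from_queen(queen: QueenGenotype, rng: np.random.Generator) -> DroneGenotype:
    """One unfertilized-egg son: an independent maternal allele per locus."""
    markers = tuple(locus[rng.integers(2)] for locus in queen.markers)
    return DroneGenotype(markers, csd=int(queen.csd[rng.integers(2)]))


def daughter_distribution(
    queen: QueenGenotype, drone: DroneGenotype
) -> dict[tuple[tuple[str, str], ...], float]:
    """Exact genotype distribution of fertilized daughters (markers only).

    Per locus the daughter receives one random maternal allele and the
    paternal allele; loci segregate independently. Allele pairs are stored
    sorted so reciprocal heterozygotes coincide. Probabilities sum to 1.
    """
    per_locus: list[dict[tuple[str, str], float]] = []
    for locus, paternal in zip(queen.markers, drone.markers):
        d: dict[tuple[str, str], float] = {}
        for maternal in locus:
            pair = tuple(sorted((maternal, paternal)))
            d[pair] = d.get(pair, 0.0) + 0.5
        per_locus.append(d)
    dist: dict[tuple[tuple[str, str], ...], float] = {}
    for combo in product(*(d.items() for d in per_locus)):
        geno = tuple(pair for pair, _ in combo)
        p = float(np.prod([pr for _, pr in combo]))
        dist[geno] = dist.get(geno, 0.0) + p
    return dist


def mate(
    queen: QueenGenotype,
    drone: DroneGenotype,
    rng: np.random.Generator,
    *,
    id: int = 0,
    generation: int = 0,
) -> Optional[QueenGenotype]:
    """Sample one fertilized daughter; None if she is a diploid male (csd).

    The csd locus follows the same rule as the markers: one random maternal
    allele plus the paternal allele; homozygotes are inviable as females.
    """
    markers = tuple(
        tuple(sorted((locus[rng.integers(2)], paternal)))
        for locus, paternal in zip(queen.markers, drone.markers)
    )
    csd = (int(queen.csd[rng.integers(2)]), drone.csd)
    if csd[0] == csd[1]:
        return None
    return QueenGenotype(markers, csd, id=id, generation=generation, sire=drone)


def heterozygote_detection_prob(n_sons: int) -> float:
    """Probability that >=1 of ``n_sons`` drone sons carries the target allele
    when the mother is heterozygous: ``1 - 2**-n``."""
    return 1.0 - 0.5**n_sons


def diploid_male_fraction(
    n_csd_alleles: int,
    mode: Literal["exact", "monte_carlo"] = "exact",
    *,
    n_matings: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Expected diploid-male brood fraction under random single-drone mating.

    With ``k`` equifrequent csd alleles the closed form is ``1/k``; the
    Monte-Carlo mode simulates matings and agrees within sampling error.
    """
    k = n_csd_alleles
    if k < 2:
        raise ValueError("csd needs at least 2 alleles")
    if mode == "exact":
        return 1.0 / k
    rng = rng or np.random.default_rng(0)
    queens_a = rng.integers(k, size=n_matings)
    shift = rng.integers(1, k, size=n_matings)
    queens_b = (queens_a + shift) % k  # two distinct alleles, uniform pairs
    drones = rng.integers(k, size=n_matings)
    matched = (drones == queens_a) | (drones == queens_b)
    # in matched matings half the fertilized brood is csd-homozygous
    return float(matched.mean() * 0.5)


# --------------------------------------------------------------------------
# the full scheme
# --------------------------------------------------------------------------


def _founder_queens(cfg: SchemeConfig, rng: np.random.Generator) -> list[QueenGenotype]:
    labels = list(cfg.founders)
    probs = [cfg.founders[l] for l in labels]
    pair = {"hom": (TARGET, TARGET), "het": (OTHER, TARGET), "none": (OTHER, OTHER)}
    queens = []
    for i in range(cfg.n_founder_queens):
        markers = tuple(
            tuple(sorted(pair[labels[rng.choice(len(labels), p=probs)]]))
            for _ in range(cfg.n_loci)
        )
        a = int(rng.integers(cfg.n_csd_alleles))
        csd = (a, int((a + rng.integers(1, cfg.n_csd_alleles)) % cfg.n_csd_alleles))
        sire = DroneGenotype(
            tuple(
                TARGET if rng.random() < cfg.founder_mate_carrier_prob else OTHER
                for _ in range(cfg.n_loci)
            ),
            csd=int(rng.integers(cfg.n_csd_alleles)),
        )
        queens.append(QueenGenotype(markers, csd, id=i, generation=0, sire=sire))
    return queens


def run_scheme(cfg: SchemeConfig) -> list[BreedingState]:
    """Run the breeding scheme for ``cfg.generations`` generations.

    Returns one :class:`BreedingState` per generation (generation 0 holds
    the founder queens that passed drone-son genotyping). Raises
    :class:`LineageExtinctError` if the carrier pool empties, with the
    trajectory so far attached.
    """
    rng = np.random.default_rng(cfg.seed)
    founders = _founder_queens(cfg, rng)

    # G1: call founder carriers through their drone sons
    breeders = []
    for q in founders:
        sons = [drone_from_queen(q, rng) for _ in range(cfg.drone_sons_for_genotyping)]
        if any(s.carries_all() for s in sons):
            breeders.append(q)
    state0 = BreedingState(
        0,
        breeders,
        n_screened=len(founders),
        n_carriers=len(breeders),
        n_homozygous=sum(q.homozygous_all() for q in breeders),
    )
    trajectory = [state0]
    if not breeders:
        raise LineageExtinctError("no founder queen passed drone-son genotyping", trajectory)

    for gen in range(1, cfg.generations + 1):
        # G2: graft from homozygous breeders once any exist
        graft_pool = breeders
        if cfg.graft_from_homozygous_when_available:
            homs = [q for q in breeders if q.homozygous_all()]
            if homs:
                graft_pool = homs

        daughters: list[QueenGenotype] = []
        brood = diploid_males = 0
        for i in range(cfg.queens_grafted_per_generation):
            mother = graft_pool[rng.integers(len(graft_pool))]
            sire = mother.sire or drone_from_queen(
                breeders[rng.integers(len(breeders))], rng
            )
            brood += 1
            daughter = mate(mother, sire, rng, id=i, generation=gen)
            if daughter is None:
                diploid_males += 1
                continue
            daughters.append(daughter)

        # G3: screen virgin queens, cull non-carriers
        screened = daughters[: cfg.daughters_screened]
        if cfg.screen_virgin_queens:
            kept = [q for q in screened if q.carries_all()]
        else:
            kept = list(screened)
        culled_screen = len(screened) - len(kept)

        # G4: single-drone insemination; drone genotyped post hoc
        next_queens: list[QueenGenotype] = []
        culled_drone = 0
        for q in kept:
            if cfg.insemination == "single_drone":
                sire_mother = breeders[rng.integers(len(breeders))]
                drone = drone_from_queen(sire_mother, rng)
                if cfg.cull_on_drone_genotype and not drone.carries_all():
                    culled_drone += 1
                    continue
            else:  # pooled semen: effective sire drawn per brood from the pool
                pool = [
                    drone_from_queen(breeders[rng.integers(len(breeders))], rng)
                    for _ in range(cfg.pooled_drones)
                ]
                if cfg.cull_on_drone_genotype:
                    pool = [d for d in pool if d.carries_all()]
                    if not pool:
                        culled_drone += 1
                        continue
                drone = pool[rng.integers(len(pool))]
            if cfg.colony_survival < 1.0 and rng.random() > cfg.colony_survival:
                continue
            next_queens.append(replace(q, sire=drone))

        trajectory.append(
            BreedingState(
                gen,
                next_queens,
                n_grafted=cfg.queens_grafted_per_generation,
                n_screened=len(screened),
                n_carriers=sum(q.carries_all() for q in next_queens),
                n_homozygous=sum(q.homozygous_all() for q in next_queens),
                n_culled_screen=culled_screen,
                n_culled_drone=culled_drone,
                diploid_male_brood_fraction=diploid_males / brood if brood else 0.0,
            )
        )
        carriers = [q for q in next_queens if q.carries_all()]
        if cfg.screen_virgin_queens and not carriers:
            raise LineageExtinctError(f"carrier pool exhausted at generation {gen}", trajectory)
        breeders = carriers if cfg.screen_virgin_queens else next_queens
        if not breeders:
            raise LineageExtinctError(f"population empty at generation {gen}", trajectory)

    return trajectory


def n_distinct_diploid_genotypes(n_loci: int) -> int:
    """Unlinked biallelic markers: ``3**k`` diploid genotypes — the
    exponential growth that limits multilocus schemes."""
    return 3**n_loci
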