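"""Synthetic data generator for the marker-assisted-selection pipeline.

Everything downstream (variant cataloguing, signature discovery, Sanger
screening, breeding simulation) is exercised on data produced here, so the
generator emulates the statistical structure of the study system:

* a multi-exon Vitellogenin-like gene of ~6.1 kb whose spliced CDS encodes a
  ~1770-residue protein;
* an allele pool of a few dozen protein variants, each defined by a unique
  combination of nonsynonymous SNPs (synonymous SNPs ride along on
  haplotypes but do not define variants);
* colony-structured populations of haploid drones and diploid queens;
* substitution-noise reads standing in for amplicon sequencing, and
  IUPAC-coded base calls standing in for Sanger electropherograms.

The module also ships a fixed "Pol-line" scenario — a synthetic stand-in for
the study's breeding-stock survey (the per-variant allele tables of that
survey are not redistributable) — that reproduces its structural facts: 26
variants from 34 nsSNPs, an exon-2 region with 9 SNPs forming 7 haplotypes
that isolate the reference allele, an exon-4 region with 6 SNPs forming 3
haplotypes that isolate the lipid-binding-cavity variant (p.S1110T), and a
rare confounder variant confined to a single colony.

All randomness flows through explicit seeds; no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genemodel import STOP_CODONS, CoordinateError, GeneModel
from .snp import BASES, Snp, apply_snps, snp_at


class ConfigurationError(ValueError):
    """A scenario or gene-model request is internally inconsistent."""


# --------------------------------------------------------------------------
# scenario description
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimScenario:
    """Parameters of a synthetic study population.

    ``target_variant_freq`` is the per-colony frequency of the selection
    target; the remaining probability mass is spread uniformly over the other
    variants. ``confounder`` optionally confines one variant to a single
    colony and makes it match the target over one exon (the situation that
    forces colony exclusion during signature discovery).
    """

    n_colonies: int = 25
    n_variants: int = 26
    n_nssnps: int = 34
    n_ssnps: int = 3
    target_variant: int = 2
    target_variant_freq: float = 0.3
    confounder: Optional[tuple[int, str]] = None
    confounder_exon: Optional[int] = None
    read_error_rate: float = 0.02
    n_reads_per_sample: int = 20
    drones_per_colony: int = 9
    queens_per_colony: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 1:
            raise ConfigurationError("need at least one variant")
        if self.n_nssnps < self.n_variants - 1:
            raise ConfigurationError(
                "need at least one nsSNP per non-reference variant "
                f"({self.n_nssnps} nsSNPs for {self.n_variants} variants)"
            )
        for name in ("n_colonies", "n_ssnps", "n_reads_per_sample",
                     "drones_per_colony", "queens_per_colony"):
            if getattr(self, name) < 0 or (name == "n_colonies" and self.n_colonies < 1):
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.target_variant_freq <= 1.0:
            raise ConfigurationError("target_variant_freq must be in [0, 1]")
        if not 0.0 <= self.read_error_rate <= 0.2:
            raise ConfigurationError("read_error_rate must be in [0, 0.2]")


@dataclass(frozen=True)
class VariantTemplate:
    """One full-gene haplotype of the allele pool."""

    variant_id: int
    sequence: str
    nssnps: frozenset[Snp]
    ssnps: frozenset[Snp]

    @property
    def snps(self) -> frozenset[Snp]:
        return self.nssnps | self.ssnps


# --------------------------------------------------------------------------
# gene-model construction
# --------------------------------------------------------------------------


def make_gene_model(
    n_exons: int,
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
    seed: int,
    *,
    name: str = "synthetic_gene",
    utr5: int = 0,
    utr3: int = 0,
) -> GeneModel:
    """Generate a random multi-exon gene with a clean open reading frame.

    The spliced exonic sequence is ``utr5`` bases of 5' UTR, the CDS, and
    ``utr3`` bases of 3' UTR. The CDS starts ATG, ends TAA, and contains no
    internal in-frame stop codon.
    """
    if n_exons < 2:
        raise ConfigurationError("need at least 2 exons")
    if len(exon_lengths) != n_exons or len(intron_lengths) != n_exons - 1:
        raise ConfigurationError("exon/intron length lists do not match n_exons")
    if any(l <= 0 for l in (*exon_lengths, *intron_lengths)):
        raise ConfigurationError("exon and intron lengths must be positive")
    cds_len = sum(exon_lengths) - utr5 - utr3
    if cds_len < 6 or cds_len % 3 != 0:
        raise ConfigurationError(
            f"spliced CDS length {cds_len} is not a positive multiple of 3"
        )

    exons = []
    pos = 1
    for i, length in enumerate(exon_lengths):
        exons.append((pos, pos + length - 1))
        pos += length
        if i < n_exons - 1:
            pos += intron_lengths[i]
    gene_len = exons[-1][1]

    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(BASES), size=gene_len))

    # gene coordinates of each spliced exonic base, in splice order
    spliced = [g for start, end in exons for g in range(start, end + 1)]
    cds_positions = spliced[utr5 : utr5 + cds_len]
    _write_codon(seq, cds_positions[:3], "ATG")
    _write_codon(seq, cds_positions[-3:], "TAA")
    _remove_internal_stops(seq, cds_positions, protected=set())

    return GeneModel(
        name=name,
        sequence="".join(seq),
        exons=tuple(exons),
        cds_start=cds_positions[0],
        cds_end=cds_positions[-1],
    )


def _write_codon(seq: list, positions: Sequence[int], codon: str) -> None:
    for g, base in zip(positions, codon):
        seq[g - 1] = base


def _remove_internal_stops(seq: list, cds_positions: Sequence[int], protected: set) -> None:
    """Mutate unprotected bases so no internal in-frame stop codon remains."""
    for i in range(3, len(cds_positions) - 3, 3):
        triplet = cds_positions[i : i + 3]
        codon = "".join(seq[g - 1] for g in triplet)
        if codon not in STOP_CODONS:
            continue
        # a 'C' at any codon position breaks TAA/TAG/TGA
        for g in (triplet[1], triplet[0], triplet[2]):
            if g not in protected:
                seq[g - 1] = "C"
                break
        else:
            raise ConfigurationError(
                f"in-frame stop codon at gene {triplet[0]} lies entirely in a "
                "protected (planted) region"
            )


# --------------------------------------------------------------------------
# the Vitellogenin-like reference gene
# --------------------------------------------------------------------------

#: Screening primer pairs (forward, reverse; 5'->3') and the product size
#: each amplifies from the reference gene. The exon-2 pair brackets the
#: reference-allele signature region, the exon-4 pair the p.S1110T variant
#: signature region, and the exon-5 pair a third screening window.
PRIMER_PAIRS: dict[int, tuple[str, str]] = {
    2: ("GGGACAGTTTCAGCCGACTT", "TCTTGATCACCTCCATGTGGC"),
    4: ("AGTTTGATGAAGCTGAAGAGCC", "TTCCTTCCAGAGGAACGAGC"),
    5: ("TGGACCAGAAGCCGAAGATG", "TTAATCCTCGTAGAATACGTTGTTA"),
}
PRODUCT_LENGTHS: dict[int, int] = {2: 620, 4: 542, 5: 400}

_VG_EXON_LENGTHS = (700, 900, 900, 1100, 800, 600, 509)
_VG_INTRON_LENGTHS = (100,) * 6
_VG_UTR5, _VG_UTR3 = 100, 99
#: gene coordinate at which each forward primer's 5' end is planted
_FWD_PRIMER_START = {2: 840, 4: 3209, 5: 4201}
#: protein position of the serine whose loss defines the lipid-cavity variant
S1110_PROTEIN_POS = 1110


def vitellogenin_like_model(seed: int = 0, name: str = "Vg_synthetic") -> GeneModel:
    """A 6109-bp, 7-exon gene emulating honey bee Vitellogenin.

    The spliced CDS is 5310 bp (1769 residues + stop). The three screening
    primer pairs are planted so that in-silico PCR yields the same product
    sizes as on the real gene (620, 542 and 400 bp), and codon 1110 encodes
    serine via TCA so the T>A first-base change produces p.S1110T.
    """
    model = make_gene_model(
        7,
        _VG_EXON_LENGTHS,
        _VG_INTRON_LENGTHS,
        seed,
        name=name,
        utr5=_VG_UTR5,
        utr3=_VG_UTR3,
    )
    seq = list(model.sequence)
    protected: set[int] = set()

    for exon, (fwd, rev) in PRIMER_PAIRS.items():
        start = _FWD_PRIMER_START[exon]
        rc_rev = str(Seq(rev).reverse_complement())
        rc_start = start + PRODUCT_LENGTHS[exon] - len(rc_rev)
        _plant(seq, start, fwd, protected)
        _plant(seq, rc_start, rc_rev, protected)

    # serine codon for the p.S1110T site; proline codons at the synonymous
    # signature sites (CCN is fourfold degenerate, so any third-base change
    # is synonymous)
    _plant_codon(model, seq, S1110_PROTEIN_POS, "TCA", protected)
    for ppos in _SYN_SITE_PROTEIN_POSITIONS:
        _plant_codon(model, seq, ppos, "CCA", protected)

    spliced = [g for s, e in model.exons for g in range(s, e + 1)]
    cds_positions = spliced[_VG_UTR5 : _VG_UTR5 + 5310]
    _remove_internal_stops(seq, cds_positions, protected)
    _scrub_spurious_primer_hits(seq, cds_positions, protected)

    out = GeneModel(
        name=name,
        sequence="".join(seq),
        exons=model.exons,
        cds_start=model.cds_start,
        cds_end=model.cds_end,
    )
    assert out.protein()[S1110_PROTEIN_POS - 1] == "S"
    return out


def _plant(seq: list, start1: int, segment: str, protected: set) -> None:
    for i, base in enumerate(segment):
        seq[start1 - 1 + i] = base
        protected.add(start1 + i)


def _plant_codon(model: GeneModel, seq: list, protein_pos: int, codon: str, protected: set) -> None:
    for g, base in zip(model.codon_gene_positions(protein_pos), codon):
        seq[g - 1] = base
        protected.add(g)


def _scrub_spurious_primer_hits(seq: list, cds_positions, protected: set) -> None:
    """Mutate the random background until each primer matches the gene once."""
    needles = []
    for fwd, rev in PRIMER_PAIRS.values():
        needles.append(fwd)
        needles.append(str(Seq(rev).reverse_complement()))
    for _ in range(20):
        text = "".join(seq)
        dirty = False
        for needle in needles:
            start = 0
            hits = []
            while (idx := text.find(needle, start)) != -1:
                hits.append(idx + 1)
                start = idx + 1
            for hit in hits[1:] if len(hits) > 1 else []:
                mid = hit + len(needle) // 2
                if mid in protected:  # overlapping planted copy: shift target
                    mid = hit
                seq[mid - 1] = "C" if seq[mid - 1] != "C" else "G"
                dirty = True
        if not dirty:
            break
        _remove_internal_stops(seq, cds_positions, protected)
    else:  # pragma: no cover - 20 passes always suffice on random sequence
        raise ConfigurationError("could not scrub spurious primer matches")


# --------------------------------------------------------------------------
# SNP site helpers
# --------------------------------------------------------------------------


def nonsyn_snp(model: GeneModel, protein_pos: int) -> Snp:
    """A first-codon-base substitution changing the residue at ``protein_pos``."""
    gene_pos = model.codon_gene_positions(protein_pos)[0]
    ref = model.sequence[gene_pos - 1]
    for alt in BASES:
        if alt == ref:
            continue
        snp = snp_at(model, gene_pos, alt)
        if snp.synonymous is False and snp.aa_change[2] != "*":
            return snp
    raise ConfigurationError(f"no nonsynonymous substitution at codon {protein_pos}")


def syn_snp(model: GeneModel, protein_pos: int) -> Snp:
    """A third-codon-base substitution leaving the residue unchanged."""
    gene_pos = model.codon_gene_positions(protein_pos)[2]
    ref = model.sequence[gene_pos - 1]
    for alt in BASES:
        if alt == ref:
            continue
        snp = snp_at(model, gene_pos, alt)
        if snp.synonymous is True:
            return snp
    raise ConfigurationError(f"no synonymous substitution at codon {protein_pos}")


# --------------------------------------------------------------------------
# the Pol-line allele pool (synthetic stand-in for the breeding-stock survey)
# --------------------------------------------------------------------------

# protein positions hosting each named site; letters: s* = exon-2 signature
# sites, q* = exon-4 signature sites, u1 = the confounder's private site,
# f* = variant-distinguishing sites scattered over the other exons.
_EXON2_SITES = {
    "s1": 225, "s2": 240, "s3": 255, "s4": 270, "s5": 285,
    "s6": 300, "s7": 315, "s8": 330, "s9": 345,
}
_EXON4_SITES = {"q1": 950, "q2": 965, "q3": 980, "q4": 995, "q5": 1010, "q6": S1110_PROTEIN_POS}
_FRESH_SITES = {
    # exon 1
    "f1": 20, "f2": 40, "f3": 60, "f4": 80, "f5": 100,
    # exon 3
    "f6": 520, "f7": 550, "f8": 580, "f9": 610, "f10": 640, "f11": 670,
    # exon 5
    "f12": 1180, "f13": 1200, "f14": 1220, "f15": 1250,
    # exon 6
    "f16": 1550, "f17": 1580, "f18": 1610,
    # exon 7
    "f19": 1640, "f20": 1660, "f21": 1680,
}
_CONFOUNDER_SITE = {"u1": 1500}  # exon 6
_SYN_SITE_NAMES = ("s2", "s8", "q2")
_SYN_SITE_PROTEIN_POSITIONS = (240, 330, 965)

#: truth variant id -> site names carried (nonsynonymous and synonymous)
POLLINE_VARIANT_SITES: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("s1",),
    3: ("s2", "s3"),
    4: ("s2", "s7", "q1", "q2", "q3"),
    5: ("s9",),
    6: ("s3", "s8", "f6"),
    7: ("s4", "s5", "s6", "s7", "q3", "q4", "q5", "q6", "u1"),
    8: ("s2", "s3", "f1"),
    9: ("s2", "s3", "f2", "f3"),
    10: ("s2", "s7", "f4"),
    11: ("s2", "s7", "f5"),
    12: ("s9", "f7"),
    13: ("s9", "f8"),
    14: ("s3", "s8", "f9"),
    15: ("s4", "s5", "s6", "s7", "q3", "q4", "q5", "q6"),
    16: ("s3", "s8", "f10"),
    17: ("s2", "s3", "f11"),
    18: ("s2", "s7", "f12"),
    19: ("s9", "f13"),
    20: ("s4", "s5", "s6", "s7", "f14"),
    21: ("s3", "s8", "f15"),
    22: ("s2", "s3", "f16"),
    23: ("s2", "s7", "f17"),
    24: ("s9", "f18"),
    25: ("s3", "s8", "f19"),
    26: ("s2", "s3", "f20", "f21"),
}

POLLINE_TARGET_REFERENCE = 1  #: the reference allele (empty nsSNP set)
POLLINE_TARGET_LIPID = 15  #: the p.S1110T lipid-cavity variant
POLLINE_CONFOUNDER = (7, "P7")  #: rare variant confined to one colony


def polline_sites(model: GeneModel) -> dict[str, Snp]:
    """Classified SNPs for every named Pol-line site."""
    sites: dict[str, Snp] = {}
    for table in (_EXON2_SITES, _EXON4_SITES, _FRESH_SITES, _CONFOUNDER_SITE):
        for name, ppos in table.items():
            if name in _SYN_SITE_NAMES:
                sites[name] = syn_snp(model, ppos)
            else:
                sites[name] = nonsyn_snp(model, ppos)
    return sites


def polline_pool(model: GeneModel) -> dict[int, VariantTemplate]:
    """The 26-variant allele pool behind the Pol-line scenario.

    Synthetic stand-in for the study's supplementary allele table; it
    reproduces the table's structure (26 variants from 34 nsSNPs; variant 1
    identical to the reference; variant 15 carrying p.S1110T plus seven other
    nsSNPs; variant 7 matching variant 15 across exon 4 but not elsewhere)
    without its unpublished per-sample content.
    """
    sites = polline_sites(model)
    pool: dict[int, VariantTemplate] = {}
    for vid, names in POLLINE_VARIANT_SITES.items():
        snps = [sites[n] for n in names]
        ns = frozenset(s for s in snps if s.synonymous is False)
        ss = frozenset(s for s in snps if s.synonymous is True)
        pool[vid] = VariantTemplate(vid, apply_snps(model, snps), ns, ss)

    ns_union = frozenset().union(*(t.nssnps for t in pool.values()))
    assert len(ns_union) == 34, len(ns_union)
    assert len({t.nssnps for t in pool.values()}) == len(pool)
    assert pool[1].nssnps == frozenset()
    assert any(s.aa_change == ("S", S1110_PROTEIN_POS, "T") for s in pool[15].nssnps)
    assert len(pool[15].nssnps) == 8
    return pool


# Pol-line population layout: 416 drones sampled from three stocks; 86 are
# two-haplotype (mixed) samples that the single-haplotype consensus rule
# must reject, leaving 330 clean sequences of which 161 are Pol-line
# (20 reference) — the generator's defaults mirror the screening effort.
_POL_COLONIES = [f"P{i}" for i in range(1, 26)]
_MH_COLONIES = [f"M{i}" for i in range(1, 13)]
_RU_COLONIES = [f"R{i}" for i in range(1, 16)]
_MH_VARIANTS = (2, 3, 5, 12, 13, 17, 19)
_RU_VARIANTS = (3, 4, 6, 9, 18, 22, 25)
_N_MIXED = {"Pol-line": 40, "MN-Hygienic": 24, "Russian": 22}


def polline_population(seed: int = 0) -> pd.DataFrame:
    """Sample sheet of the default screening effort (416 drone samples).

    Columns: sample_id, stock, colony, caste, ploidy, variant_id (truth),
    variant_id_2 (second haplotype for mixed samples, <NA> otherwise).
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, int, Optional[int]]] = []  # stock, colony, v1, v2

    def add(stock: str, colony: str, vid: int, n: int = 1, vid2: Optional[int] = None):
        rows.extend([(stock, colony, vid, vid2)] * n)

    # Pol-line: 161 clean drones over 25 colonies
    for i in range(20):
        add("Pol-line", _POL_COLONIES[i % 5], 1)
    for i in range(48):
        add("Pol-line", _POL_COLONIES[i % 16], 15)
    add("Pol-line", "P7", 7, n=2)
    others = [v for v in POLLINE_VARIANT_SITES if v not in (1, 7, 15)]
    remaining = 161 - 20 - 48 - 2
    counts = {v: remaining // len(others) for v in others}
    for v in others[: remaining - sum(counts.values())]:
        counts[v] += 1
    colony_cycle = [c for c in _POL_COLONIES if c != "P7"]
    ci = 0
    for v in others:
        for k in range(counts[v]):
            add("Pol-line", colony_cycle[(ci + k // 2) % len(colony_cycle)], v)
        ci += 2
    # sister stocks: 85 + 84 clean drones, reference rare outside Pol-line
    add("MN-Hygienic", "M1", 1, n=3)
    for i in range(82):
        add("MN-Hygienic", _MH_COLONIES[i % 12], _MH_VARIANTS[i % len(_MH_VARIANTS)])
    add("Russian", "R1", 1, n=1)
    for i in range(83):
        add("Russian", _RU_COLONIES[i % 15], _RU_VARIANTS[i % len(_RU_VARIANTS)])
    # mixed (two-haplotype) samples, to be rejected by the consensus rule
    all_variants = list(POLLINE_VARIANT_SITES)
    for stock, colonies in (
        ("Pol-line", colony_cycle),
        ("MN-Hygienic", _MH_COLONIES),
        ("Russian", _RU_COLONIES),
    ):
        for i in range(_N_MIXED[stock]):
            va, vb = rng.choice(all_variants, size=2, replace=False)
            add(stock, colonies[i % len(colonies)], int(va), vid2=int(vb))

    order = rng.permutation(len(rows))
    data = [rows[i] for i in order]
    return pd.DataFrame(
        {
            "sample_id": [f"D{i + 1:04d}" for i in range(len(data))],
            "stock": [r[0] for r in data],
            "colony": [r[1] for r in data],
            "caste": "drone",
            "ploidy": 1,
            "variant_id": [r[2] for r in data],
            "variant_id_2": pd.array([r[3] for r in data], dtype="Int64"),
        }
    )


# --------------------------------------------------------------------------
# generic allele pools and populations
# --------------------------------------------------------------------------


def make_allele_pool(model: GeneModel, scenario: SimScenario) -> dict[int, VariantTemplate]:
    """Random allele pool: ``n_variants`` haplotypes over ``n_nssnps`` nsSNPs.

    Variant 1 is the reference (empty nsSNP set). Every requested nsSNP is
    carried by at least one variant, every variant's nsSNP set is distinct,
    and synonymous SNPs are sprinkled over variants without affecting their
    identity. If ``scenario.confounder`` is set, that variant is rebuilt to
    match the target variant across one exon while differing elsewhere.
    """
    if scenario.n_variants == 1:  # degenerate pool: reference only
        return {1: VariantTemplate(1, model.sequence, frozenset(), frozenset())}
    rng = np.random.default_rng(scenario.seed)
    n_internal = len(model.spliced_cds()) // 3 - 2  # exclude start and stop codons
    candidates = list(range(2, n_internal + 1))
    if len(candidates) < scenario.n_nssnps + scenario.n_ssnps:
        raise ConfigurationError("gene too short for requested SNP count")
    chosen = rng.choice(candidates, size=scenario.n_nssnps + scenario.n_ssnps, replace=False)
    ns_sites: list[Snp] = []
    ss_sites: list[Snp] = []
    for ppos in sorted(int(p) for p in chosen[: scenario.n_nssnps]):
        ns_sites.append(nonsyn_snp(model, ppos))
    for ppos in sorted(int(p) for p in chosen[scenario.n_nssnps :]):
        try:
            ss_sites.append(syn_snp(model, ppos))
        except ConfigurationError:  # ATG/TGG codons have no synonymous partner
            continue

    n_var = scenario.n_variants
    assignments: dict[int, set[Snp]] = {v: set() for v in range(1, n_var + 1)}
    order = rng.permutation(len(ns_sites))
    for k, idx in enumerate(order):  # round-robin: coverage + distinctness
        assignments[2 + k % (n_var - 1)].add(ns_sites[idx])

    if scenario.confounder is not None:
        conf_id, _colony = scenario.confounder
        target = scenario.target_variant
        if conf_id in (1, target) or target == 1:
            raise ConfigurationError("confounder and target must be distinct non-reference variants")
        exon = scenario.confounder_exon
        if exon is None:
            exon_counts = [0] * len(model.exons)
            for s in assignments[target]:
                exon_counts[s.in_exon] += 1
            exon = int(np.argmax(exon_counts))
        displaced = {s for s in assignments[conf_id] if s.in_exon == exon}
        kept_outside = {s for s in assignments[conf_id] if s.in_exon != exon}
        assignments[conf_id] = {s for s in assignments[target] if s.in_exon == exon} | kept_outside
        if assignments[conf_id] == assignments[target]:  # must differ outside the exon
            spare = sorted(s for s in ns_sites if s.in_exon != exon and s not in assignments[target])
            if not spare:
                raise ConfigurationError("cannot distinguish confounder outside the shared exon")
            assignments[conf_id].add(spare[0])
        for s in displaced:  # keep the union at n_nssnps members
            if not any(s in a for a in assignments.values()):
                others = [v for v in range(2, n_var + 1) if v not in (conf_id, target)]
                assignments[int(rng.choice(others))].add(s)

    seen: dict[frozenset, int] = {}
    for v in range(1, n_var + 1):
        key = frozenset(assignments[v])
        if key in seen:  # collision repair: add an unused-by-this-variant site
            spare = sorted(s for s in ns_sites if s not in assignments[v])
            if not spare:
                raise ConfigurationError("cannot make variant nsSNP sets distinct")
            assignments[v].add(spare[0])
            key = frozenset(assignments[v])
        seen[key] = v

    syn_assignments: dict[int, set[Snp]] = {v: set() for v in range(1, n_var + 1)}
    for s in ss_sites:
        syn_assignments[int(rng.integers(2, n_var + 1))].add(s)
    if scenario.confounder is not None:
        # the confounder must match the target base-for-base over the shared
        # exon, synonymous sites included
        conf_id, _ = scenario.confounder
        target = scenario.target_variant
        exon = scenario.confounder_exon
        if exon is None:
            exon_counts = [0] * len(model.exons)
            for s in assignments[target]:
                exon_counts[s.in_exon] += 1
            exon = int(np.argmax(exon_counts))
        syn_assignments[conf_id] = {
            s for s in syn_assignments[conf_id] if s.in_exon != exon
        } | {s for s in syn_assignments[target] if s.in_exon == exon}

    pool = {}
    for v in range(1, n_var + 1):
        snps = assignments[v] | syn_assignments[v]
        pool[v] = VariantTemplate(
            v, apply_snps(model, snps), frozenset(assignments[v]), frozenset(syn_assignments[v])
        )
    return pool


def sample_population(
    pool: dict[int, VariantTemplate], scenario: SimScenario, *, model: GeneModel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a colony-structured population from an allele pool.

    Returns ``(drones, queens)`` sample sheets. Drones are haploid (one
    variant each); queens carry two independent draws. The target variant
    has frequency ``target_variant_freq`` in every colony; a confounder
    variant appears only in its own colony.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    variant_ids = sorted(pool)
    conf_id, conf_colony = scenario.confounder if scenario.confounder else (None, None)
    colonies = [f"C{i}" for i in range(1, scenario.n_colonies + 1)]
    if conf_colony is not None and conf_colony not in colonies:
        colonies[-1] = conf_colony

    def colony_probs(colony: str) -> np.ndarray:
        probs = np.zeros(len(variant_ids))
        others = [
            i
            for i, v in enumerate(variant_ids)
            if v != scenario.target_variant and (v != conf_id or colony == conf_colony)
        ]
        ti = variant_ids.index(scenario.target_variant)
        probs[ti] = scenario.target_variant_freq
        if others:
            probs[others] = (1.0 - scenario.target_variant_freq) / len(others)
        elif scenario.target_variant_freq < 1.0:
            raise ConfigurationError(
                "per-colony frequencies do not sum to 1: no variant carries "
                f"the remaining {1.0 - scenario.target_variant_freq:.2f}"
            )
        return probs

    drone_rows, queen_rows = [], []
    for colony in colonies:
        probs = colony_probs(colony)
        for _ in range(scenario.drones_per_colony):
            vid = int(rng.choice(variant_ids, p=probs))
            drone_rows.append((colony, vid))
        for _ in range(scenario.queens_per_colony):
            va = int(rng.choice(variant_ids, p=probs))
            vb = int(rng.choice(variant_ids, p=probs))
            queen_rows.append((colony, va, vb))

    drones = pd.DataFrame(
        {
            "sample_id": [f"d{i + 1:04d}" for i in range(len(drone_rows))],
            "stock": "synthetic",
            "colony": [r[0] for r in drone_rows],
            "caste": "drone",
            "ploidy": 1,
            "variant_id": [r[1] for r in drone_rows],
        }
    )
    queens = pd.DataFrame(
        {
            "sample_id": [f"q{i + 1:04d}" for i in range(len(queen_rows))],
            "stock": "synthetic",
            "colony": [r[0] for r in queen_rows],
            "caste": "queen",
            "ploidy": 2,
            "variant_id": [r[1] for r in queen_rows],
            "variant_id_2": [r[2] for r in queen_rows],
        }
    )
    return drones, queens


# --------------------------------------------------------------------------
# reads and Sanger-style base calls
# --------------------------------------------------------------------------


def make_reads(
    sequence: str,
    region: tuple[int, int],
    error_rate: float,
    n_reads: int,
    seed: int | np.random.Generator,
) -> list[str]:
    """Substitution-corrupted copies of ``sequence[region]`` (1-based inclusive)."""
    start, end = region
    if not (1 <= start <= end <= len(sequence)):
        raise CoordinateError(f"region {region} outside sequence of length {len(sequence)}")
    if not 0.0 <= error_rate <= 0.2:
        raise ConfigurationError("error_rate must be in [0, 0.2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    template = np.frombuffer(sequence[start - 1 : end].encode(), dtype=np.uint8)
    reads = np.tile(template, (n_reads, 1))
    if error_rate > 0 and reads.size:
        mask = rng.random(reads.shape) < error_rate
        # shift each erroneous base by 1..3 within the ACGT alphabet
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(BASES):
            lut[ord(b)] = i
        shifted = (lut[reads] + rng.integers(1, 4, size=reads.shape)) % 4
        alphabet = np.frombuffer(BASES.encode(), dtype=np.uint8)
        reads = np.where(mask, alphabet[shifted], reads)
    return [bytes(row).decode() for row in reads]


#: unordered base pair -> IUPAC two-base ambiguity code
IUPAC_PAIR_CODES = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


def make_sanger_seq(genotype: tuple[str, str], region: tuple[int, int]) -> str:
    """Base-called Sanger read of a (possibly heterozygous) genotype.

    ``genotype`` holds the two full-gene haplotype sequences (identical for a
    homozygote; pass the same sequence twice for a haploid). Positions where
    the haplotypes differ become two-base IUPAC ambiguity codes.
    """
    a, b = genotype
    if len(a) != len(b):
        raise CoordinateError("haplotypes of a genotype must have equal length")
    start, end = region
    if not (1 <= start <= end <= len(a)):
        raise CoordinateError(f"region {region} outside gene of length {len(a)}")
    out = []
    for x, y in zip(a[start - 1 : end], b[start - 1 : end]):
        out.append(x if x == y else IUPAC_PAIR_CODES[frozenset((x, y))])
    return "".join(out)


def truth_records(
    pool: dict[int, VariantTemplate], population: pd.DataFrame
) -> list:
    """Noiseless :class:`~beemas.catalog.AlleleRecord` objects for the clean
    (single-haplotype) samples of a population sheet, with truth variant ids.

    The ground truth the catalogue stage must recover exactly.
    """
    from .catalog import AlleleRecord

    records = []
    for row in population.itertuples(index=False):
        vid2 = getattr(row, "variant_id_2", None)
        if vid2 is not None and not pd.isna(vid2):
            continue
        tpl = pool[row.variant_id]
        records.append(
            AlleleRecord(
                row.sample_id, row.colony, row.stock, row.caste,
                int(row.ploidy), tpl.sequence, tpl.snps, variant_id=tpl.variant_id,
            )
        )
    return records


def population_reads(
    model: GeneModel,
    pool: dict[int, VariantTemplate],
    population: pd.DataFrame,
    scenario: SimScenario,
) -> Iterator[tuple[str, list[str]]]:
    """Yield ``(sample_id, reads)`` for every sample of a population sheet.

    Mixed samples (``variant_id_2`` set) contribute an even split of reads
    from both haplotypes — the situation the single-haplotype consensus rule
    exists to reject.
    """
    rng = np.random.default_rng(scenario.seed + 2)
    region = (1, len(model))
    n = scenario.n_reads_per_sample
    for row in population.itertuples(index=False):
        vid2 = getattr(row, "variant_id_2", None)
        if pd.isna(vid2) if vid2 is not None else True:
            vid2 = None
        if vid2 is None:
            reads = make_reads(pool[row.variant_id].sequence, region, scenario.read_error_rate, n, rng)
        else:
            half = n // 2
            reads = make_reads(pool[row.variant_id].sequence, region, scenario.read_error_rate, n - half, rng)
            reads += make_reads(pool[int(vid2)].sequence, region, scenario.read_error_rate, half, rng)
        yield row.sample_id, reads
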