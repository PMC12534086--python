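"""Variant cataloguing: from per-sample consensus sequences to protein variants.

The stages mirror an amplicon-sequencing workflow for a single gene:

1. :func:`enforce_single_haplotype` — accept a sample's read stack only if it
   represents one haplotype (haploid drones must not look mixed);
2. :func:`map_to_gene` — place the consensus onto gene coordinates;
3. :func:`extract_cds` — splice out the coding sequence;
4. :func:`call_snps_and_classify` — call substitutions and annotate synonymy
   and amino-acid changes by codon translation;
5. :func:`assign_variant_ids` — group samples into protein variants keyed on
   their nonsynonymous SNP set (synonymous SNPs are retained on the
   haplotype but do not define the variant).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align

from .genemodel import GeneModel
from .snp import BASES, Snp, snp_at

GAP = "-"


class UnmappableSampleError(ValueError):
    """Consensus too diverged (or wrong length) to map onto the gene."""


class InsufficientCoverageError(ValueError):
    """Fewer reads than the single-haplotype rule needs."""


class MixedSampleError(ValueError):
    """The read stack contains more than one haplotype."""


class CdsIndelError(ValueError):
    """A gap interrupts the coding sequence; the sample is excluded."""


class UnexpectedHeterozygosityError(ValueError):
    """Ambiguity codes in a haploid consensus."""


@dataclass(frozen=True)
class AlleleRecord:
    """One sample's full-gene haplotype with its metadata and called SNPs."""

    sample_id: str
    colony: str
    stock: str
    caste: str
    ploidy: int
    sequence: str
    snps: frozenset[Snp] = frozenset()
    variant_id: Optional[int] = None

    def __post_init__(self):
        if self.caste == "drone" and self.ploidy != 1:
            raise ValueError(f"{self.sample_id}: drones are haploid")
        if self.ploidy not in (1, 2):
            raise ValueError(f"{self.sample_id}: ploidy must be 1 or 2")

    @property
    def nssnps(self) -> frozenset[Snp]:
        return frozenset(s for s in self.snps if s.synonymous is False)


@dataclass
class VariantCatalog:
    """Protein variants (nsSNP sets) with per-stock sample counts."""

    variants: dict[int, frozenset[Snp]]
    counts: Counter = field(default_factory=Counter)  # (variant_id, stock) -> n

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def nssnp_union(self) -> frozenset[Snp]:
        return frozenset().union(*self.variants.values()) if self.variants else frozenset()

    def total_samples(self) -> int:
        return sum(self.counts.values())


# --------------------------------------------------------------------------
# consensus acceptance
# --------------------------------------------------------------------------


def enforce_single_haplotype(
    reads: Sequence[str],
    model: GeneModel | None = None,
    max_minor_fraction: float = 0.0,
    *,
    min_reads: int = 3,
    site_minor_fraction: float = 0.3,
) -> str:
    """Majority consensus of a read stack, accepted only if single-haplotype.

    Reads are clustered by their allele pattern at candidate biallelic sites
    (positions where the minor base reaches ``site_minor_fraction`` of the
    stack — well above what substitution noise produces, well below what a
    second haplotype produces). If the reads outside the largest cluster
    exceed ``max_minor_fraction`` (default 0: *only one type of read per
    sample*), the sample is rejected.

    Raises
    ------
    InsufficientCoverageError
        fewer than ``min_reads`` reads.
    MixedSampleError
        minor cluster fraction above the threshold.
    """
    if len(reads) < min_reads:
        raise InsufficientCoverageError(f"{len(reads)} reads < required {min_reads}")
    lengths = {len(r) for r in reads}
    if len(lengths) != 1:
        raise MixedSampleError("reads of unequal length (indel or mixed amplicons)")

    stack = np.frombuffer("".join(reads).encode(), dtype=np.uint8).reshape(len(reads), -1)
    alphabet = np.frombuffer(BASES.encode(), dtype=np.uint8)
    counts = np.stack([(stack == b).sum(axis=0) for b in alphabet])  # 4 x L
    consensus_idx = counts.argmax(axis=0)
    consensus = bytes(alphabet[consensus_idx]).decode()

    # candidate biallelic sites: minor-base support at or above threshold
    order = np.sort(counts, axis=0)
    minor = order[-2]
    candidate = np.nonzero(minor >= max(2, int(np.ceil(site_minor_fraction * len(reads)))))[0]
    if candidate.size:
        patterns = [tuple(row) for row in stack[:, candidate]]
        cluster_sizes = Counter(patterns)
        major = cluster_sizes.most_common(1)[0][1]
        minor_fraction = (len(reads) - major) / len(reads)
        if minor_fraction > max_minor_fraction:
            raise MixedSampleError(
                f"minor read cluster fraction {minor_fraction:.2f} > "
                f"{max_minor_fraction} at {candidate.size} split site(s)"
            )
    return consensus


# --------------------------------------------------------------------------
# mapping
# --------------------------------------------------------------------------

# deterministic pairwise global alignment; ties resolved toward leftmost gaps
_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 2
_ALIGNER.mismatch_score = -1
_ALIGNER.open_gap_score = -5
_ALIGNER.extend_gap_score = -1


def map_to_gene(consensus: str, model: GeneModel, min_identity: float = 0.7) -> str:
    """Assign every consensus base a gene coordinate.

    Returns a string of gene length where position ``i`` holds the consensus
    base aligned to gene coordinate ``i+1``, or ``-`` where the consensus has
    a deletion. Equal-length, high-identity consensus (the usual case for
    substitution-only amplicon data) maps positionally; otherwise a global
    pairwise alignment (match +2, mismatch -1, gap open -5, extend -1) is
    used.
    """
    consensus = consensus.upper()
    ref = model.sequence
    if not 0.5 * len(ref) <= len(consensus) <= 1.5 * len(ref):
        raise UnmappableSampleError(
            f"consensus length {len(consensus)} outside 50%-150% of gene length {len(ref)}"
        )
    if len(consensus) == len(ref):
        matches = sum(a == b for a, b in zip(consensus, ref))
        identity = matches / len(ref)
        if identity >= min_identity:
            return consensus
    alignment = _ALIGNER.align(ref, consensus)[0]
    mapped = [GAP] * len(ref)
    matches = 0
    for (rs, re), (cs, ce) in zip(*alignment.aligned):
        for k in range(re - rs):
            mapped[rs + k] = consensus[cs + k]
            matches += consensus[cs + k] == ref[rs + k]
    # identity over alignment columns, so gap-riddled alignments of unrelated
    # sequences score low even when many scattered bases coincide
    identity = matches / alignment.length
    if identity < min_identity:
        raise UnmappableSampleError(
            f"alignment identity {identity:.2f} below {min_identity}"
        )
    return "".join(mapped)


# --------------------------------------------------------------------------
# CDS extraction and SNP calling
# --------------------------------------------------------------------------


def extract_cds(mapped: str, model: GeneModel) -> str:
    """Spliced CDS of a position-mapped sequence (non-coding regions removed)."""
    cds = model.spliced_cds(mapped)
    if GAP in cds:
        raise CdsIndelError(
            f"gap inside CDS at spliced position {cds.index(GAP) + 1}; sample excluded"
        )
    return cds


def call_snps_and_classify(mapped: str, model: GeneModel, *, ploidy: int = 1) -> frozenset[Snp]:
    """Every substitution of the mapped sequence vs the reference, classified.

    Positions where the consensus has a gap are skipped (CDS gaps have
    already been rejected by :func:`extract_cds`). Ambiguity codes in a
    haploid sample raise :class:`UnexpectedHeterozygosityError`.
    """
    snps = []
    for i, (obs, ref) in enumerate(zip(mapped, model.sequence)):
        if obs == ref or obs == GAP:
            continue
        if obs not in BASES:
            if ploidy == 1:
                raise UnexpectedHeterozygosityError(
                    f"ambiguity code {obs!r} at gene position {i + 1} in a haploid sample"
                )
            continue  # diploid consensus heterozygosity is handled by the screen stage
        snps.append(snp_at(model, i + 1, obs))
    return frozenset(snps)


# --------------------------------------------------------------------------
# variant identity
# --------------------------------------------------------------------------


def assign_variant_ids(records: Iterable[AlleleRecord]) -> tuple[list[AlleleRecord], VariantCatalog]:
    """Group records into protein variants keyed on their nsSNP sets.

    Two records share a variant id iff their nonsynonymous SNP sets are
    identical; the reference (empty set) is always variant 1. Non-reference
    ids are assigned deterministically by (set size, positions).
    """
    records = list(records)
    keys = {rec.nssnps for rec in records}
    keys.add(frozenset())
    ordered = sorted(
        (k for k in keys if k),
        key=lambda k: (len(k), sorted(s.gene_pos for s in k), sorted((s.gene_pos, s.alt_base) for s in k)),
    )
    ids: dict[frozenset, int] = {frozenset(): 1}
    for i, k in enumerate(ordered, start=2):
        ids[k] = i

    catalog = VariantCatalog(variants={})
    out = []
    for rec in records:
        vid = ids[rec.nssnps]
        catalog.variants[vid] = rec.nssnps
        catalog.counts[(vid, rec.stock)] += 1
        out.append(
            AlleleRecord(
                rec.sample_id, rec.colony, rec.stock, rec.caste, rec.ploidy,
                rec.sequence, rec.snps, variant_id=vid,
            )
        )
    return out, catalog


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


@dataclass
class CatalogResult:
    """Outcome of cataloguing a cohort of samples."""

    records: list[AlleleRecord]
    catalog: VariantCatalog
    rejected: dict[str, str]  # sample_id -> reason

    @property
    def n_accepted(self) -> int:
        return len(self.records)


def build_catalog_from_consensus(
    samples: Iterable[tuple[str, str, str, str, str, int]],
    model: GeneModel,
    *,
    min_identity: float = 0.7,
) -> CatalogResult:
    """Catalogue pre-computed consensus sequences.

    ``samples`` yields ``(sample_id, colony, stock, caste, sequence, ploidy)``.
    Samples that fail mapping, CDS integrity, or haploid-purity checks are
    excluded and reported, not repaired.
    """
    accepted, rejected = [], {}
    for sample_id, colony, stock, caste, sequence, ploidy in samples:
        try:
            mapped = map_to_gene(sequence, model, min_identity)
            extract_cds(mapped, model)
            snps = call_snps_and_classify(mapped, model, ploidy=ploidy)
        except (UnmappableSampleError, CdsIndelError, UnexpectedHeterozygosityError) as exc:
            rejected[sample_id] = str(exc)
            continue
        accepted.append(
            AlleleRecord(sample_id, colony, stock, caste, ploidy, mapped, snps)
        )
    records, catalog = assign_variant_ids(accepted)
    return CatalogResult(records, catalog, rejected)


def build_catalog_from_reads(
    read_sets: Iterable[tuple[str, Sequence[str]]],
    sheet,
    model: GeneModel,
    *,
    max_minor_fraction: float = 0.0,
    min_identity: float = 0.7,
) -> CatalogResult:
    """Full pipeline from raw read stacks: consensus rule, then cataloguing.

    ``sheet`` is a sample-sheet DataFrame indexed by ``sample_id`` (or with a
    ``sample_id`` column) providing colony/stock/caste/ploidy.
    """
    if "sample_id" in getattr(sheet, "columns", ()):
        sheet = sheet.set_index("sample_id")
    consensus_samples = []
    rejected = {}
    for sample_id, reads in read_sets:
        meta = sheet.loc[sample_id]
        try:
            consensus = enforce_single_haplotype(reads, model, max_minor_fraction)
        except (InsufficientCoverageError, MixedSampleError) as exc:
            rejected[sample_id] = str(exc)
            continue
        consensus_samples.append(
            (sample_id, meta["colony"], meta["stock"], meta["caste"], consensus, int(meta["ploidy"]))
        )
    result = build_catalog_from_consensus(consensus_samples, model, min_identity=min_identity)
    result.rejected.update(rejected)
    return result
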