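"""Single-nucleotide polymorphisms in gene coordinates.

A :class:`Snp` records one substitution relative to the reference gene:
its 1-based gene position, reference and alternative base, the exon it
falls in (if any), whether it is synonymous, and — for nonsynonymous
coding changes — the amino-acid change in p.S1110T style (ref residue,
1-based protein position, alt residue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Seq import Seq

from .genemodel import GeneModel

BASES = "ACGT"


@dataclass(frozen=True, order=True)
class Snp:
    gene_pos: int
    ref_base: str
    alt_base: str
    in_exon: Optional[int] = None
    synonymous: Optional[bool] = None
    aa_change: Optional[tuple[str, int, str]] = None

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError(f"SNP at {self.gene_pos}: ref equals alt ({self.ref_base})")
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ValueError(f"SNP at {self.gene_pos}: non-ACGT allele")
        if (self.aa_change is not None) != (self.synonymous is False):
            raise ValueError(
                f"SNP at {self.gene_pos}: aa_change must be present exactly for "
                "nonsynonymous coding SNPs"
            )

    @property
    def hgvs_p(self) -> Optional[str]:
        """Protein-level name like ``p.S1110T`` (None for non-coding/synonymous)."""
        if self.aa_change is None:
            return None
        ref_aa, pos, alt_aa = self.aa_change
        return f"p.{ref_aa}{pos}{alt_aa}"


def snp_at(model: GeneModel, gene_pos: int, alt_base: str) -> Snp:
    """Build a fully classified :class:`Snp` for a substitution at ``gene_pos``.

    Synonymy is decided by translating the mutated codon against the
    reference codon; positions outside the CDS get ``synonymous=None``.
    """
    ref_base = model.sequence[gene_pos - 1]
    in_exon = model.exon_index(gene_pos)
    cds_pos = model.gene_to_cds(gene_pos)
    if cds_pos is None:
        return Snp(gene_pos, ref_base, alt_base, in_exon=in_exon)
    protein_pos = (cds_pos - 1) // 3 + 1
    codon_positions = model.codon_gene_positions(protein_pos)
    ref_codon = "".join(model.sequence[g - 1] for g in codon_positions)
    offset = codon_positions.index(gene_pos)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return Snp(gene_pos, ref_base, alt_base, in_exon=in_exon, synonymous=True)
    return Snp(
        gene_pos,
        ref_base,
        alt_base,
        in_exon=in_exon,
        synonymous=False,
        aa_change=(ref_aa, protein_pos, alt_aa),
    )


def apply_snps(model: GeneModel, snps: Iterable[Snp]) -> str:
    """Return the gene sequence with every SNP's alternative allele applied."""
    seq = bytearray(model.sequence, "ascii")
    for snp in snps:
        if seq[snp.gene_pos - 1 : snp.gene_pos] != bytes(snp.ref_base, "ascii"):
            raise ValueError(
                f"SNP at {snp.gene_pos}: reference base mismatch "
                f"({chr(seq[snp.gene_pos - 1])} != {snp.ref_base})"
            )
        seq[snp.gene_pos - 1] = ord(snp.alt_base)
    return seq.decode("ascii")
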