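"""Gene model: reference sequence plus exon/CDS coordinates.

All coordinates are 1-based inclusive gene coordinates (the frame used for
p.S1110T-style protein numbering). Conversion to 0-based half-open happens
only at BED export (see :mod:`beemas.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class CoordinateError(ValueError):
    """A position falls outside the gene or the requested frame."""


class GeneModelError(ValueError):
    """The gene model violates one of its structural invariants."""


@dataclass(frozen=True)
class GeneModel:
    """A single gene on its coding strand with exon and CDS annotation.

    Parameters
    ----------
    name : str
        Gene/contig name; used as the CHROM field in exports.
    sequence : str
        Nucleotide sequence of the full gene (coding strand, uppercase).
    exons : tuple of (int, int)
        Non-overlapping, ascending (start, end) pairs, 1-based inclusive.
    cds_start : int
        Gene coordinate of the 'A' of the initiator ATG.
    cds_end : int
        Gene coordinate of the last base of the stop codon.
    """

    name: str
    sequence: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    _cds_index: dict = field(init=False, repr=False, compare=False, hash=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "exons", tuple((int(a), int(b)) for a, b in self.exons))
        n = len(self.sequence)
        prev_end = 0
        for start, end in self.exons:
            if not (1 <= start <= end <= n):
                raise GeneModelError(f"exon ({start},{end}) outside gene of length {n}")
            if start <= prev_end:
                raise GeneModelError("exons overlap or are unsorted")
            prev_end = end
        if not self.cds_start < self.cds_end:
            raise GeneModelError("cds_start must precede cds_end")
        if self.exon_index(self.cds_start) is None or self.exon_index(self.cds_end) is None:
            raise GeneModelError("CDS boundaries must fall inside exons")
        cds = self.spliced_cds()
        if len(cds) % 3 != 0:
            raise GeneModelError(f"spliced CDS length {len(cds)} not divisible by 3")
        if not cds.startswith("ATG"):
            raise GeneModelError("spliced CDS does not begin with ATG")
        if cds[-3:] not in STOP_CODONS:
            raise GeneModelError("spliced CDS does not end with a stop codon")
        # genewise position -> CDS offset lookup (0-based CDS offsets)
        idx = {}
        off = 0
        for start, end in self.cds_segments():
            for g in range(start, end + 1):
                idx[g] = off
                off += 1
        object.__setattr__(self, "_cds_index", idx)

    # -- basic geometry -------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequence)

    def exon_index(self, gene_pos: int) -> Optional[int]:
        """0-based index of the exon containing ``gene_pos``, or None."""
        for i, (start, end) in enumerate(self.exons):
            if start <= gene_pos <= end:
                return i
        return None

    def cds_segments(self) -> list[tuple[int, int]]:
        """Exonic segments of the CDS as 1-based inclusive gene intervals."""
        segs = []
        for start, end in self.exons:
            lo, hi = max(start, self.cds_start), min(end, self.cds_end)
            if lo <= hi:
                segs.append((lo, hi))
        return segs

    def spliced_cds(self, sequence: str | None = None) -> str:
        """Concatenate exonic CDS segments (of ``sequence`` if given)."""
        seq = self.sequence if sequence is None else sequence
        if len(seq) != len(self.sequence):
            raise CoordinateError("sequence length differs from gene length")
        return "".join(seq[lo - 1 : hi] for lo, hi in self.cds_segments())

    # -- coordinate conversions -----------------------------------------

    def gene_to_cds(self, gene_pos: int) -> Optional[int]:
        """1-based CDS coordinate of a gene position, or None outside the CDS."""
        off = self._cds_index.get(gene_pos)
        return None if off is None else off + 1

    def cds_to_gene(self, cds_pos: int) -> int:
        """Gene coordinate of a 1-based CDS position."""
        off = cds_pos - 1
        for lo, hi in self.cds_segments():
            seg = hi - lo + 1
            if off < seg:
                return lo + off
            off -= seg
        raise CoordinateError(f"CDS position {cds_pos} beyond spliced CDS")

    def protein_position(self, gene_pos: int) -> Optional[int]:
        """1-based residue number encoded at ``gene_pos``, or None if non-coding."""
        cds = self.gene_to_cds(gene_pos)
        return None if cds is None else (cds - 1) // 3 + 1

    def codon_gene_positions(self, protein_pos: int) -> tuple[int, int, int]:
        """Gene coordinates of the three bases of codon ``protein_pos``."""
        first = (protein_pos - 1) * 3 + 1
        return tuple(self.cds_to_gene(first + k) for k in range(3))

    # -- translation ----------------------------------------------------

    def protein(self, sequence: str | None = None) -> str:
        """Translate the (spliced) CDS, stop codon trimmed."""
        cds = self.spliced_cds(sequence)
        return str(Seq(cds).translate())[:-1]
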