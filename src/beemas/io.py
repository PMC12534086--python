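"""File formats and provenance.

Conventions: VCF positions are 1-based (per the VCF spec), BED intervals are
0-based half-open, and everything internal is 1-based inclusive gene
coordinates — conversions live in :func:`to_bed_interval` /
:func:`from_bed_interval` only. Every writer has a reader that round-trips
losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import AlleleRecord
from .genemodel import GeneModel
from .signature import Amplicon, Signature
from .snp import Snp


class GffParseError(ValueError):
    """Malformed GFF3 with the offending line number."""


# --------------------------------------------------------------------------
# coordinates
# --------------------------------------------------------------------------


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(header, sequence)`` pairs (header may contain description)."""
    seq_records = []
    for header, seq in records:
        name, _, desc = header.partition(" ")
        seq_records.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id if not rec.description.partition(" ")[2] else rec.description
        out.append((header, str(rec.seq)))
    return out


def write_consensus_fasta(path, records: Iterable[AlleleRecord]) -> None:
    """Per-sample consensus with ``sample|colony|stock|caste|ploidy`` headers."""
    write_fasta(
        path,
        (
            (f"{r.sample_id}|{r.colony}|{r.stock}|{r.caste}|{r.ploidy}", r.sequence)
            for r in records
        ),
    )


def read_consensus_fasta(path) -> list[tuple[str, str, str, str, str, int]]:
    """Yield ``(sample_id, colony, stock, caste, sequence, ploidy)`` tuples."""
    out = []
    for header, seq in read_fasta(path):
        fields = header.split("|")
        if len(fields) != 5:
            raise ValueError(
                f"consensus header {header!r} is not sample|colony|stock|caste|ploidy"
            )
        sample_id, colony, stock, caste, ploidy = fields
        out.append((sample_id, colony, stock, caste, seq, int(ploidy)))
    return out


# --------------------------------------------------------------------------
# GFF3 gene model (+ TSV mirror)
# --------------------------------------------------------------------------


def write_gff3(path, model: GeneModel) -> None:
    lines = [
        "##gff-version 3",
        f"##sequence-region {model.name} 1 {len(model)}",
        _gff_line(model.name, "gene", 1, len(model), ".", ID=model.name),
    ]
    for start, end in model.exons:
        lines.append(_gff_line(model.name, "exon", start, end, ".", Parent=model.name))
    phase_carry = 0
    for start, end in model.cds_segments():
        lines.append(_gff_line(model.name, "CDS", start, end, str(phase_carry), Parent=model.name))
        phase_carry = (3 - ((end - start + 1 - phase_carry) % 3)) % 3
    Path(path).write_text("\n".join(lines) + "\n")


def _gff_line(seqid: str, feature: str, start: int, end: int, phase: str, **attrs) -> str:
    attr = ";".join(f"{k}={v}" for k, v in attrs.items())
    return "\t".join([seqid, "beemas", feature, str(start), str(end), ".", "+", phase, attr])


def read_gff3(path, sequence: str) -> GeneModel:
    """Rebuild a :class:`GeneModel` from a GFF3 file plus its sequence."""
    name: Optional[str] = None
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GffParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        seqid, _source, feature, start, end, _score, strand, _phase, _attrs = fields
        try:
            interval = (int(start), int(end))
        except ValueError as exc:
            raise GffParseError(f"line {lineno}: non-integer coordinates") from exc
        if interval[0] > interval[1] or interval[0] < 1:
            raise GffParseError(f"line {lineno}: invalid interval {interval}")
        if strand not in "+-.":
            raise GffParseError(f"line {lineno}: invalid strand {strand!r}")
        if feature == "gene":
            name = seqid
        elif feature == "exon":
            exons.append(interval)
        elif feature == "CDS":
            cds.append(interval)
    if name is None or not exons or not cds:
        raise GffParseError("missing gene/exon/CDS features")
    return GeneModel(
        name=name,
        sequence=sequence,
        exons=tuple(sorted(exons)),
        cds_start=min(s for s, _ in cds),
        cds_end=max(e for _, e in cds),
    )


def write_gene_model_tsv(path, model: GeneModel) -> None:
    rows = [{"feature": "gene", "start": 1, "end": len(model)}]
    rows += [{"feature": "exon", "start": s, "end": e} for s, e in model.exons]
    rows.append({"feature": "CDS", "start": model.cds_start, "end": model.cds_end})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# sample sheets and tables
# --------------------------------------------------------------------------


def write_sample_sheet(path, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "colony": str, "stock": str})


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=beemas
##contig=<ID={name},length={length}>
##INFO=<ID=SYN,Number=1,Type=Integer,Description="1 synonymous, 0 nonsynonymous; absent outside the CDS">
##INFO=<ID=AA,Number=1,Type=String,Description="Amino-acid change, e.g. p.S1110T">
##INFO=<ID=EXON,Number=1,Type=Integer,Description="1-based exon number">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(path, model: GeneModel, snps: Iterable[Snp]) -> None:
    """One record per SNP, 1-based positions, synonymy and p.-notation in INFO."""
    lines = [_VCF_HEADER.format(name=model.name, length=len(model))]
    for snp in sorted(snps):
        info = []
        if snp.synonymous is not None:
            info.append(f"SYN={int(snp.synonymous)}")
        if snp.aa_change is not None:
            info.append(f"AA={snp.hgvs_p}")
        if snp.in_exon is not None:
            info.append(f"EXON={snp.in_exon + 1}")
        lines.append(
            "\t".join(
                [
                    model.name,
                    str(snp.gene_pos),
                    ".",
                    snp.ref_base,
                    snp.alt_base,
                    ".",
                    "PASS",
                    ";".join(info) or ".",
                ]
            )
            + "\n"
        )
    Path(path).write_text("".join(lines))


def read_vcf(path) -> list[Snp]:
    """Read a SNP VCF back (via pysam) into classified :class:`Snp` objects."""
    snps = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            syn = rec.info.get("SYN")
            aa = rec.info.get("AA")
            exon = rec.info.get("EXON")
            aa_change = None
            if aa is not None:
                body = aa[2:]  # strip "p."
                k = len(body)
                while not body[k - 1].isdigit():
                    k -= 1
                aa_change = (body[0], int(body[1:k]), body[k:])
            snps.append(
                Snp(
                    gene_pos=rec.pos,
                    ref_base=rec.ref,
                    alt_base=rec.alts[0],
                    in_exon=None if exon is None else int(exon) - 1,
                    synonymous=None if syn is None else bool(syn),
                    aa_change=aa_change,
                )
            )
    return snps


# --------------------------------------------------------------------------
# signature JSON and BED
# --------------------------------------------------------------------------


def write_signature_json(path, sig: Signature, provenance: Optional[dict] = None) -> None:
    payload = {
        "target_variant": sig.target_variant,
        "exon": sig.exon,
        "window": list(sig.window),
        "sites": [[pos, base] for pos, base in sig.sites],
        "discriminated_against": sig.discriminated_against,
        "excluded_colonies": list(sig.excluded_colonies),
        "site_alleles": [list(a) for a in sig.site_alleles],
        "amplicon": None
        if sig.amplicon is None
        else {
            "fwd_primer": sig.amplicon.fwd_primer,
            "rev_primer": sig.amplicon.rev_primer,
            "start": sig.amplicon.start,
            "end": sig.amplicon.end,
        },
        "provenance": provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_signature_json(path) -> Signature:
    payload = json.loads(Path(path).read_text())
    amp = payload.get("amplicon")
    return Signature(
        target_variant=payload["target_variant"],
        exon=payload["exon"],
        window=tuple(payload["window"]),
        sites=tuple((pos, base) for pos, base in payload["sites"]),
        discriminated_against=payload["discriminated_against"],
        excluded_colonies=tuple(payload["excluded_colonies"]),
        site_alleles=tuple(tuple(a) for a in payload.get("site_alleles", ())),
        amplicon=None if amp is None else Amplicon(**amp),
    )


def write_signature_bed(path, model: GeneModel, sig: Signature) -> None:
    start, end = to_bed_interval(*sig.window)
    Path(path).write_text(
        f"{model.name}\t{start}\t{end}\tsignature_v{sig.target_variant}_exon{sig.exon}\n"
    )


# --------------------------------------------------------------------------
# provenance
# --------------------------------------------------------------------------


def provenance_block(config: dict, seed: int) -> dict:
    """Deterministic run fingerprint: config hash, seed, package version."""
    from . import __version__

    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {"config_sha256": digest, "seed": seed, "beemas_version": __version__}


def record_provenance_hash(records: Iterable[AlleleRecord]) -> str:
    h = hashlib.sha256()
    for r in sorted(records, key=lambda r: r.sample_id):
        h.update(f"{r.sample_id}|{r.colony}|{r.variant_id}|{r.sequence}\n".encode())
    return h.hexdigest()
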