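"""Sanger-style genotype screening against a signature.

Queens are diploid: a Sanger base call over the screening amplicon shows
two-base IUPAC ambiguity codes at heterozygous positions. Drones are
haploid, so any ambiguity is a failure. :func:`in_silico_pcr` locates the
screening amplicon on a template, :func:`call_genotype` reads a sample's
bases at the signature sites, and :func:`screen_cohort` applies the caller
to a whole cohort and tallies the outcome per caste.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import pandas as pd
from Bio.Seq import Seq

from .signature import Signature
from .snp import BASES


class NoProductError(ValueError):
    """Neither primer orientation yields a product."""


class NonSpecificPrimersError(ValueError):
    """The primer pair amplifies more than one product."""


@dataclass(frozen=True)
class PcrProduct:
    sequence: str
    start: int  # 1-based template coordinate of the product's first base
    end: int  # 1-based template coordinate of the product's last base

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _find_all(text: str, needle: str) -> list[int]:
    hits, start = [], 0
    while (idx := text.find(needle, start)) != -1:
        hits.append(idx)
        start = idx + 1
    return hits


def in_silico_pcr(template: str, fwd_primer: str, rev_primer: str) -> PcrProduct:
    """Exact-match PCR product of a primer pair on a template.

    The product spans from the 5' end of the forward-primer match to the 5'
    end of the reverse-primer match on the opposite strand, inclusive. Both
    orientations of the pair are searched, so swapping primer roles finds
    the same product. Matching is exact: the study validated primer
    specificity on a gel, not computationally.
    """
    template = template.upper()
    fwd, rev = fwd_primer.upper(), rev_primer.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    products = set()
    for up, down in ((fwd, rev), (rev, fwd)):
        down_rc = str(Seq(down).reverse_complement())
        for i in _find_all(template, up):
            for j in _find_all(template, down_rc):
                if i + len(up) <= j:  # primer footprints must not overlap
                    products.add((i + 1, j + len(down_rc)))
    if not products:
        raise NoProductError("no primer pair orientation matches the template")
    if len(products) > 1:
        raise NonSpecificPrimersError(f"{len(products)} distinct products")
    start, end = products.pop()
    return PcrProduct(template[start - 1 : end], start, end)


# --------------------------------------------------------------------------
# genotype calling
# --------------------------------------------------------------------------

#: IUPAC decoding used by the caller: the 4 bases plus the 6 two-base codes.
#: Three/four-base codes and N mean an unreadable site (fail), matching a
#: clean-double-peak model of Sanger heterozygotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    **{b: frozenset(b) for b in BASES},
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
}

Call = Literal["hom_target", "het_target", "hom_other", "fail"]


@dataclass
class GenotypeCall:
    sample_id: str
    call: Call
    evidence: list[tuple[int, str, str]] = field(default_factory=list)
    # (gene_pos, observed symbol, expected target base)
    failed_sites: list[tuple[int, str]] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)


def call_genotype(
    observed: str,
    sig: Signature,
    ploidy: int,
    *,
    start: Optional[int] = None,
    sample_id: str = "",
) -> GenotypeCall:
    """Call a sample's genotype at the signature sites.

    ``observed`` is the base-called sequence of the screening amplicon (or
    any region covering all signature sites); ``start`` is the gene
    coordinate of its first base (defaults to the signature's amplicon
    start). Decision, after decoding IUPAC codes to per-site base sets and
    checking each set against the alleles the discovery population actually
    showed at that site (``sig.site_alleles``):

    * ``hom_target`` — every site's set is exactly the target base;
    * ``het_target`` — every site's set contains the target and at least one
      site is a two-base set with a non-target base (diploids only);
    * ``hom_other`` — some site's set excludes the target (no chromosome can
      carry the full target haplotype);
    * ``fail`` — unreadable codes, missing coverage, a base matching neither
      expected allele, or apparent heterozygosity in a haploid.

    A diploid call is per-site and unphased: a pair of non-target
    haplotypes whose differences happen to complement each other across the
    sites is indistinguishable from a true heterozygous carrier — the
    reason the breeding scheme re-checks queens through their drone sons.
    """
    if start is None:
        if sig.amplicon is None:
            raise ValueError("need `start` when the signature has no amplicon")
        start = sig.amplicon.start
    evidence, failed, reasons = [], [], []
    sets: list[Optional[frozenset]] = []
    for pos, target_base in sig.sites:
        idx = pos - start
        if not 0 <= idx < len(observed):
            failed.append((pos, "."))
            reasons.append(f"no coverage at site {pos}")
            sets.append(None)
            continue
        symbol = observed[idx].upper()
        evidence.append((pos, symbol, target_base))
        base_set = IUPAC_SETS.get(symbol)
        if base_set is None:
            failed.append((pos, symbol))
            reasons.append(f"unreadable base {symbol!r} at site {pos}")
        sets.append(base_set)

    def done(call: Call) -> GenotypeCall:
        return GenotypeCall(sample_id, call, evidence, failed, reasons)

    if any(s is None for s in sets):
        return done("fail")
    targets = [base for _, base in sig.sites]
    expected = (
        [frozenset(a) for a in sig.site_alleles]
        if sig.site_alleles
        else [frozenset(BASES)] * len(sets)
    )
    bad = [
        (pos, s, e)
        for s, e, (pos, _) in zip(sets, expected, sig.sites)
        if not s <= e
    ]
    if bad:
        for pos, s, e in bad:
            failed.append((pos, "".join(sorted(s))))
            reasons.append(
                f"base matching neither expected allele at site {pos} "
                f"(saw {'/'.join(sorted(s))}, expected {'/'.join(sorted(e))})"
            )
        return done("fail")
    if ploidy == 1 and any(len(s) > 1 for s in sets):
        reasons.append("ambiguity code in a haploid sample")
        return done("fail")
    if all(s == frozenset(t) for s, t in zip(sets, targets)):
        return done("hom_target")
    if (
        ploidy == 2
        and all(t in s for s, t in zip(sets, targets))
        and any(len(s) == 2 for s in sets)
    ):
        return done("het_target")
    if any(t not in s for s, t in zip(sets, targets)):
        return done("hom_other")
    reasons.append("ambiguous genotype not classifiable from unphased base calls")
    return done("fail")


# --------------------------------------------------------------------------
# cohort screening
# --------------------------------------------------------------------------


@dataclass
class ScreenSample:
    """One individual submitted for Sanger screening."""

    sample_id: str
    caste: str  # drone | queen | worker
    ploidy: int
    sequence: str  # base-called amplicon sequence (IUPAC codes allowed)
    start: Optional[int] = None  # gene coordinate of sequence[0]


def screen_cohort(
    samples: Iterable[ScreenSample], sig: Signature
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype every sample against a signature.

    Returns ``(calls, summary)``: one call per sample, and call-class counts
    per caste.
    """
    rows = []
    for s in samples:
        call = call_genotype(s.sequence, sig, s.ploidy, start=s.start, sample_id=s.sample_id)
        rows.append(
            {
                "sample_id": s.sample_id,
                "caste": s.caste,
                "ploidy": s.ploidy,
                "call": call.call,
                "failed_sites": ";".join(f"{p}:{o}" for p, o in call.failed_sites),
                "reasons": ";".join(call.reasons),
            }
        )
    calls = pd.DataFrame(
        rows, columns=["sample_id", "caste", "ploidy", "call", "failed_sites", "reasons"]
    )
    if calls.empty:
        summary = pd.DataFrame(columns=["caste", "call", "n"])
    else:
        summary = (
            calls.groupby(["caste", "call"]).size().reset_index(name="n").sort_values(
                ["caste", "call"], ignore_index=True
            )
        )
    return calls, summary


def carrier_counts(summary: pd.DataFrame) -> Counter:
    """Convenience tally: call class -> n across castes."""
    out: Counter = Counter()
    for row in summary.itertuples(index=False):
        out[row.call] += row.n
    return out
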