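"""End-to-end pipeline: simulate -> catalogue -> signature -> screen -> breed.

Chains the stages on the default Pol-line-like scenario and writes every
artifact (reference FASTA, gene model GFF3/TSV, sample sheet, consensus
FASTA, VCF, catalogue and assignment tables, signature JSON/BED, screening
calls, breeding trajectory) plus a machine-readable run manifest with a
provenance block. Outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import breeding, io, simulate
from .catalog import CatalogResult, build_catalog_from_reads
from .genemodel import GeneModel
from .screen import ScreenSample, screen_cohort
from .signature import Signature, collapse_haplotypes, find_signature, validate_signature
from .simulate import PRIMER_PAIRS, VariantTemplate

log = logging.getLogger("beemas")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[beemas:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage(name: str, message: str) -> None:
    log.info(message, extra={"stage": name})


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, with study-scale defaults."""

    seed: int = 0
    max_window_bp: int = 700
    max_minor_fraction: float = 0.0
    n_screen_queens: int = 347
    n_screen_drones: int = 497
    scheme: breeding.SchemeConfig = field(default_factory=breeding.SchemeConfig)

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# screening-cohort simulation
# --------------------------------------------------------------------------


def simulate_screen_cohort(
    model: GeneModel,
    pool: dict[int, VariantTemplate],
    sig: Signature,
    n_queens: int,
    n_drones: int,
    seed: int,
    *,
    exclude_variants: tuple[int, ...] = (),
) -> tuple[list[ScreenSample], pd.DataFrame]:
    """Sanger-screening cohort drawn from an allele pool.

    Queens are diploid (two independent variant draws) and their amplicon
    sequence carries IUPAC codes at heterozygous sites; drones are haploid.
    Returns the samples plus a truth table with the expected call per
    sample.
    """
    if sig.amplicon is None:
        raise ValueError("signature needs an attached amplicon to build Sanger samples")
    rng = np.random.default_rng(seed)
    region = (sig.amplicon.start, sig.amplicon.end)
    variant_ids = [v for v in sorted(pool) if v not in exclude_variants]

    def expected_call(va: int, vb: int) -> str:
        # unphased per-site truth: what a clean Sanger trace can support
        site_sets = [
            {pool[va].sequence[pos - 1], pool[vb].sequence[pos - 1]}
            for pos, _ in sig.sites
        ]
        targets = [base for _, base in sig.sites]
        if all(s == {t} for s, t in zip(site_sets, targets)):
            return "hom_target"
        if all(t in s for s, t in zip(site_sets, targets)):
            return "het_target"
        return "hom_other"

    samples, truth_rows = [], []
    for i in range(n_queens + n_drones):
        queen = i < n_queens
        if queen:
            va, vb = (int(v) for v in rng.choice(variant_ids, size=2))
            seq = simulate.make_sanger_seq(
                (pool[va].sequence, pool[vb].sequence), region
            )
            expected = expected_call(va, vb)
            sid = f"Q{i + 1:04d}"
            samples.append(ScreenSample(sid, "queen", 2, seq, start=region[0]))
        else:
            va = vb = int(rng.choice(variant_ids))
            seq = simulate.make_sanger_seq((pool[va].sequence, pool[va].sequence), region)
            expected = expected_call(va, va)
            sid = f"D{i - n_queens + 1:04d}"
            samples.append(ScreenSample(sid, "drone", 1, seq, start=region[0]))
        truth_rows.append(
            {"sample_id": sid, "variant_id": va, "variant_id_2": vb if queen else pd.NA,
             "expected_call": expected}
        )
    return samples, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# the full run
# --------------------------------------------------------------------------


def run_default_pipeline(outdir, cfg: PipelineConfig | None = None) -> dict:
    """Run every stage on the default scenario; write artifacts; return summary."""
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed

    _stage("simulate", "building reference gene and Pol-line-like population")
    model = simulate.vitellogenin_like_model(seed)
    pool = simulate.polline_pool(model)
    population = simulate.polline_population(seed)
    scenario = simulate.SimScenario(seed=seed)
    io.write_fasta(outdir / "reference.fasta", [(model.name, model.sequence)])
    io.write_gff3(outdir / "gene_model.gff3", model)
    io.write_gene_model_tsv(outdir / "gene_model.tsv", model)
    io.write_sample_sheet(outdir / "samples.tsv", population)
    truth = population[["sample_id", "variant_id", "variant_id_2"]]
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    _stage("catalog", f"consensus + SNP calling on {len(population)} read stacks")
    reads = simulate.population_reads(model, pool, population, scenario)
    result: CatalogResult = build_catalog_from_reads(
        reads, population, model, max_minor_fraction=cfg.max_minor_fraction
    )
    io.write_consensus_fasta(outdir / "consensus.fasta", result.records)
    all_snps = frozenset().union(*(r.snps for r in result.records)) if result.records else frozenset()
    io.write_vcf(outdir / "variants.vcf", model, all_snps)
    _write_catalog_tables(outdir, result)

    _stage("signature", "discovering reference and lipid-variant signatures")
    pol_records = [r for r in result.records if r.stock == "Pol-line"]
    ref_id = next(v for v, s in result.catalog.variants.items() if not s)
    lipid_candidates = [
        v
        for v, s in result.catalog.variants.items()
        if any(snp.aa_change == ("S", simulate.S1110_PROTEIN_POS, "T") for snp in s)
    ]
    lipid_id = max(
        lipid_candidates,
        key=lambda v: sum(n for (vid, _), n in result.catalog.counts.items() if vid == v),
    )
    prov = io.provenance_block(cfg.to_dict(), seed)
    sig_ref = find_signature(
        pol_records, ref_id, model, cfg.max_window_bp, primers=PRIMER_PAIRS
    )
    sig_lipid = find_signature(
        pol_records, lipid_id, model, cfg.max_window_bp, primers=PRIMER_PAIRS
    )
    io.write_signature_json(outdir / "signature_reference.json", sig_ref, prov)
    io.write_signature_json(outdir / "signature_lipid.json", sig_lipid, prov)
    io.write_signature_bed(outdir / "signature_reference.bed", model, sig_ref)
    io.write_signature_bed(outdir / "signature_lipid.bed", model, sig_lipid)

    _stage("screen", f"genotyping {cfg.n_screen_queens} queens and {cfg.n_screen_drones} drones")
    confounder_id = simulate.POLLINE_CONFOUNDER[0]
    samples, truth_calls = simulate_screen_cohort(
        model, pool, sig_ref, cfg.n_screen_queens, cfg.n_screen_drones,
        seed + 10, exclude_variants=(confounder_id,),
    )
    calls, summary = screen_cohort(samples, sig_ref)
    calls.to_csv(outdir / "screen_calls.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "screen_summary.tsv", sep="\t", index=False)
    merged = calls.merge(truth_calls, on="sample_id")
    concordance = float((merged["call"] == merged["expected_call"]).mean())

    _stage("breed", f"{cfg.scheme.generations}-generation breeding scheme")
    scheme = breeding.SchemeConfig(**{**asdict(cfg.scheme), "seed": seed + 20})
    trajectory = breeding.run_scheme(scheme)
    traj_rows = [
        {
            "generation": st.generation,
            "queens": len(st.queens),
            "screened": st.n_screened,
            "carriers": st.n_carriers,
            "homozygous": st.n_homozygous,
            "culled_screen": st.n_culled_screen,
            "culled_drone": st.n_culled_drone,
            "diploid_male_brood_fraction": st.diploid_male_brood_fraction,
            "target_allele_freq": st.target_allele_freq,
        }
        for st in trajectory
    ]
    pd.DataFrame(traj_rows).to_csv(outdir / "breeding_trajectory.tsv", sep="\t", index=False)

    final = trajectory[-1]
    exon2_table = collapse_haplotypes(pol_records, sig_ref.window)
    exon4_table = collapse_haplotypes(pol_records, sig_lipid.window)
    lipid_unexcluded = validate_signature(sig_lipid, pol_records, apply_exclusions=False)
    summary_dict = {
        "samples_total": int(len(population)),
        "consensus_accepted": result.n_accepted,
        "consensus_rejected": len(result.rejected),
        "n_variants": result.catalog.n_variants,
        "n_nssnps": len(result.catalog.nssnp_union),
        "reference_drones_polline": int(result.catalog.counts.get((ref_id, "Pol-line"), 0)),
        "reference_signature": {
            "exon": sig_ref.exon,
            "n_sites": len(sig_ref.sites),
            "n_haplotypes": exon2_table.n_haplotypes,
            "excluded_colonies": list(sig_ref.excluded_colonies),
            "amplicon_bp": sig_ref.amplicon.length if sig_ref.amplicon else None,
        },
        "lipid_signature": {
            "exon": sig_lipid.exon,
            "n_sites": len(sig_lipid.sites),
            "n_haplotypes": exon4_table.n_haplotypes,
            "excluded_colonies": list(sig_lipid.excluded_colonies),
            "amplicon_bp": sig_lipid.amplicon.length if sig_lipid.amplicon else None,
            "window_matching_drones": len(lipid_unexcluded.true_positives)
            + lipid_unexcluded.n_false_positives,
        },
        "screen_concordance": concordance,
        "breeding_final_homozygous_fraction": (
            final.n_homozygous / len(final.queens) if final.queens else 0.0
        ),
        "provenance": prov,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(summary_dict, indent=2, sort_keys=True) + "\n"
    )
    return summary_dict


def _write_catalog_tables(outdir: Path, result: CatalogResult) -> None:
    cat_rows = []
    for vid in sorted(result.catalog.variants):
        snps = result.catalog.variants[vid]
        stocks = {
            stock: n for (v, stock), n in sorted(result.catalog.counts.items()) if v == vid
        }
        cat_rows.append(
            {
                "variant_id": vid,
                "n_nssnps": len(snps),
                "nssnps": ";".join(
                    f"{s.gene_pos}{s.ref_base}>{s.alt_base}({s.hgvs_p})" for s in sorted(snps)
                ),
                "counts": ";".join(f"{k}={v}" for k, v in stocks.items()),
            }
        )
    pd.DataFrame(cat_rows).to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    assign = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in result.records],
            "colony": [r.colony for r in result.records],
            "stock": [r.stock for r in result.records],
            "variant_id": [r.variant_id for r in result.records],
        }
    )
    assign.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    rej = pd.DataFrame(
        sorted(result.rejected.items()), columns=["sample_id", "reason"]
    )
    rej.to_csv(outdir / "rejected.tsv", sep="\t", index=False)
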