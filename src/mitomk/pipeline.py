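"""End-to-end analysis pipeline.

``run_pipeline`` takes an aligned population FASTA plus a gene annotation and
produces per-gene diversity summaries, per-gene MK statistics, gene-set
summaries, a recombination (LD / four-gamete) report and synonymous-vs-
nonsynonymous heterogeneity tests, all as TSV files with a JSON run manifest.
``mk_from_counts`` is the stats-only entry point for pre-tabulated MK counts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    GeneAnnotation,
    extract_gene,
    read_alignment,
    read_annotation,
    write_results_table,
)
from .codons import MKTable, MORE_INCLUSIVE, build_mk_table, polarize_with_two_outgroups
from .coalescent import heterogeneity_test, stat_null_pvalue
from .diversity import gene_diversity
from .ld import four_gamete_test, ld_distance_correlation, pairwise_ld
from .mkstats import mk_table_records, summarize_gene_set

logger = logging.getLogger("mitomk")


@dataclass
class PipelineConfig:
    fasta: str
    annotation: str
    outgroup_labels: list[str]
    method: str = MORE_INCLUSIVE
    polarize: bool = False
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    n_boot: int = 5000
    n_reps: int = 10000
    maf_cutoffs: tuple[float, ...] = (0.0, 0.05, 0.1)
    circular: bool = False
    seed: int | None = None
    out_dir: str | None = None


@dataclass
class PipelineResult:
    mk_tables: list[MKTable]
    mk_records: list[dict]
    diversity_records: list[dict]
    set_records: list[dict]
    ld_records: list[dict]
    heterogeneity_records: list[dict]
    manifest: dict


def _diversity_records(summaries) -> list[dict]:
    return [
        {
            "gene": s.gene_name,
            "site_class": s.site_class,
            "n_sites": s.n_sites,
            "S": s.S,
            "pi": s.pi,
            "theta_w": s.theta_w,
            "tajima_d": s.tajima_d,
            "fu_li_d": s.fu_li_d,
            "fay_wu_h": s.fay_wu_h,
        }
        for s in summaries
    ]


def _set_record(summary) -> dict:
    ci = summary.NI_TG_CI
    return {
        "set": summary.set_name,
        "n_genes": len(summary.genes),
        "PN": summary.summed.P_N,
        "PS": summary.summed.P_S,
        "DN": summary.summed.D_N,
        "DS": summary.summed.D_S,
        "NI": summary.NI_summed,
        "Z": summary.Z_summed,
        "p_fet": summary.p_fet,
        "NI_TG": summary.NI_TG,
        "NI_TG_ci_low": ci[0] if ci else float("nan"),
        "NI_TG_ci_high": ci[1] if ci else float("nan"),
        "woolf_p": summary.woolf_p,
        "NI_median": summary.NI_median,
        "NI_mean": summary.NI_mean,
        "NI_sd": summary.NI_sd,
        "Zstar_median": summary.Zstar_median,
        "Zstar_mean": summary.Zstar_mean,
        "Zstar_sd": summary.Zstar_sd,
    }


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    aln = read_alignment(cfg.fasta, cfg.outgroup_labels)
    annotations = read_annotation(cfg.annotation)
    n_in = len(aln.ingroup_ids)

    mk_tables: list[MKTable] = []
    diversity_records: list[dict] = []
    het_records: list[dict] = []
    per_gene_delta: dict[str, tuple[int, int, float]] = {}

    for ann in annotations:
        gene = extract_gene(aln, ann)
        if cfg.polarize:
            if len(cfg.outgroup_labels) != 2:
                raise ValueError("polarized divergence needs exactly two outgroups")
            table = polarize_with_two_outgroups(
                gene, cfg.outgroup_labels[0], cfg.outgroup_labels[1], cfg.method
            )
        else:
            table = build_mk_table(gene, method=cfg.method)
        mk_tables.append(table)

        summaries = gene_diversity(gene)
        diversity_records.extend(_diversity_records(summaries))
        by_class = {s.site_class: s for s in summaries}
        syn, nonsyn = by_class["synonymous"], by_class["nonsynonymous"]
        if syn.S >= 1 and nonsyn.S >= 1:
            per_gene_delta[ann.gene_name] = (
                syn.S,
                nonsyn.S,
                nonsyn.tajima_d - syn.tajima_d,
            )

    # heterogeneity tests per gene (and pooled)
    seed_seq = np.random.SeedSequence(cfg.seed)
    het_seeds = seed_seq.generate_state(len(per_gene_delta) + 1)
    for (gene_name, (s_syn, s_nonsyn, delta)), hseed in zip(
        per_gene_delta.items(), het_seeds
    ):
        p = heterogeneity_test(
            n_in, s_syn, s_nonsyn, delta, n_reps=cfg.n_reps, seed=int(hseed) % 2**31
        )
        het_records.append(
            {
                "gene": gene_name,
                "S_syn": s_syn,
                "S_nonsyn": s_nonsyn,
                "delta_tajima_d": delta,
                "p": p,
                "n_reps": cfg.n_reps,
            }
        )

    # gene-set summaries
    by_gene = {t.gene_name: t for t in mk_tables}
    set_records = []
    boot_seeds = seed_seq.generate_state(len(cfg.gene_sets) + 1)[1:]
    for (set_name, genes), bseed in zip(cfg.gene_sets.items(), boot_seeds):
        missing = [g for g in genes if g not in by_gene]
        if missing:
            raise LookupError(f"gene set {set_name!r} references unknown genes {missing}")
        summary = summarize_gene_set(
            [by_gene[g] for g in genes],
            set_name,
            n_boot=cfg.n_boot,
            seed=int(bseed) % 2**31,
        )
        set_records.append(_set_record(summary))

    # recombination report on the whole ingroup alignment
    ld_records = []
    in_matrix = aln.ingroup_matrix
    circular_length = float(aln.length) if cfg.circular else None
    n_fgt, _ = four_gamete_test(in_matrix)
    perm_seeds = seed_seq.generate_state(2 * len(cfg.maf_cutoffs) + 10)[10:]
    si = 0
    for maf in cfg.maf_cutoffs:
        pairs = pairwise_ld(in_matrix, maf_cutoff=maf, circular_length=circular_length)
        for measure in ("d_prime_abs", "r2"):
            if len(pairs) >= 3:
                rho, p = ld_distance_correlation(
                    pairs,
                    measure,
                    n_perm=1000,
                    seed=int(perm_seeds[si]) % 2**31,
                    circular_length=circular_length,
                )
            else:
                rho, p = float("nan"), float("nan")
            si += 1
            ld_records.append(
                {
                    "maf_cutoff": maf,
                    "measure": measure,
                    "n_pairs": len(pairs),
                    "rho": rho,
                    "p_one_sided": p,
                    "four_gamete_violations": n_fgt,
                }
            )

    manifest = {
        "mitomk_version": __version__,
        "seed": cfg.seed,
        "method": cfg.method,
        "polarized": cfg.polarize,
        "n_ingroup": n_in,
        "outgroups": list(cfg.outgroup_labels),
        "n_genes": len(annotations),
        "n_boot": cfg.n_boot,
        "n_reps": cfg.n_reps,
    }

    result = PipelineResult(
        mk_tables=mk_tables,
        mk_records=mk_table_records(mk_tables),
        diversity_records=diversity_records,
        set_records=set_records,
        ld_records=ld_records,
        heterogeneity_records=het_records,
        manifest=manifest,
    )
    if cfg.out_dir:
        _write_bundle(result, cfg.out_dir)
    return result


def _write_bundle(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results_table(result.mk_records, out / "mk_per_gene.tsv")
    write_results_table(result.diversity_records, out / "diversity_per_gene.tsv")
    write_results_table(result.set_records, out / "gene_set_summary.tsv")
    write_results_table(result.ld_records, out / "ld_report.tsv")
    write_results_table(result.heterogeneity_records, out / "heterogeneity.tsv")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))


def mk_from_counts(
    path,
    gene_sets: dict[str, list[str]] | None = None,
    n_boot: int = 5000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stats-only entry point: per-gene and gene-set statistics from a
    pre-tabulated MK count TSV (gene, PN, PS, DN, DS)."""
    from .mkstats import read_mk_counts

    tables = read_mk_counts(path)
    per_gene = pd.DataFrame.from_records(mk_table_records(tables))
    if gene_sets is None:
        gene_sets = {"all": [t.gene_name for t in tables]}
    by_gene = {t.gene_name: t for t in tables}
    seeds = np.random.SeedSequence(seed).generate_state(len(gene_sets))
    set_rows = []
    for (set_name, genes), s in zip(gene_sets.items(), seeds):
        missing = [g for g in genes if g not in by_gene]
        if missing:
            raise LookupError(f"gene set {set_name!r} references unknown genes {missing}")
        summary = summarize_gene_set(
            [by_gene[g] for g in genes], set_name, n_boot=n_boot, seed=int(s) % 2**31
        )
        set_rows.append(_set_record(summary))
    return per_gene, pd.DataFrame.from_records(set_rows)
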