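"""Summary statistics of McDonald-Kreitman contingency tables.

The neutrality index NI = (P_N/P_S)/(D_N/D_S) summarises the departure from
the neutral expectation NI = 1.  Per-gene NI applies a +1 pseudocount to all
four cells whenever any raw cell is zero; the log-scale Z* statistic embeds
the +1 pseudocount in its definition; gene-set statistics computed on summed
counts use the raw sums without pseudocounts.  NI_TG is the Tarone-style
combined estimator that weights each gene by P_S + D_S, avoiding the bias of
averaging per-gene ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codons import MKTable

logger = logging.getLogger("mitomk")


@dataclass
class MKStatistics:
    gene_name: str
    NI: float
    Z_star: float
    Z: float
    p_fet: float
    pseudocount_applied: bool


@dataclass
class GeneSetSummary:
    set_name: str
    genes: list[str]
    summed: MKTable
    NI_summed: float
    Z_summed: float
    p_fet: float
    NI_TG: float
    NI_TG_CI: tuple[float, float] | None
    woolf_chi2: float
    woolf_df: int
    woolf_p: float
    NI_median: float
    NI_mean: float
    NI_sd: float
    Zstar_median: float
    Zstar_mean: float
    Zstar_sd: float


def neutrality_index(t: MKTable) -> tuple[float, bool]:
    """NI = (D_S * P_N) / (D_N * P_S); +1 to all cells if any cell is zero."""
    pn, ps, dn, ds = t.counts()
    pseudo = min(pn, ps, dn, ds) == 0
    if pseudo:
        pn, ps, dn, ds = pn + 1, ps + 1, dn + 1, ds + 1
    return (ds * pn) / (dn * ps), pseudo


def z_star(t: MKTable) -> float:
    """Z* = log10(((D_N+1)(P_S+1)) / ((D_S+1)(P_N+1))).

    Negative values indicate an excess of (weakly deleterious) nonsynonymous
    polymorphism; positive values an excess of nonsynonymous divergence.
    """
    pn, ps, dn, ds = t.counts()
    return math.log10(((dn + 1) * (ps + 1)) / ((ds + 1) * (pn + 1)))


def z_plain(t: MKTable) -> float:
    """Z = log10((D_N * P_S) / (D_S * P_N)) on raw counts; NaN on zero cells."""
    pn, ps, dn, ds = t.counts()
    if min(pn, ps, dn, ds) == 0:
        return float("nan")
    return math.log10((dn * ps) / (ds * pn))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fisher_exact_mk(t: MKTable) -> float:
    """Two-sided Fisher's exact p of the 2x2 MK table.

    Fractional counts are rounded half-away-from-zero first (exact tests need
    integers); NI/Z/Z* elsewhere keep the unrounded values.
    """
    cells = [_round_half_away(x) for x in t.counts()]
    if cells != list(t.counts()):
        logger.info("%s: fractional counts rounded for Fisher's exact test", t.gene_name)
    pn, ps, dn, ds = cells
    return float(stats.fisher_exact([[pn, ps], [dn, ds]], alternative="two-sided")[1])


def mk_statistics(t: MKTable) -> MKStatistics:
    ni, pseudo = neutrality_index(t)
    return MKStatistics(
        gene_name=t.gene_name,
        NI=ni,
        Z_star=z_star(t),
        Z=z_plain(t),
        p_fet=fisher_exact_mk(t),
        pseudocount_applied=pseudo,
    )


def ni_tg(tables: list[MKTable]) -> float:
    """Combined neutrality index sum(D_Si P_Ni/(P_Si+D_Si)) / sum(P_Si D_Ni/(P_Si+D_Si)).

    Raw counts, no pseudocounts; genes with P_S + D_S = 0 are skipped; NaN
    when the denominator sum is zero.
    """
    if not tables:
        raise ValueError("ni_tg requires at least one MK table")
    num = den = 0.0
    for t in tables:
        pn, ps, dn, ds = t.counts()
        w = ps + ds
        if w == 0:
            continue
        num += ds * pn / w
        den += ps * dn / w
    if den == 0:
        return float("nan")
    return num / den


def ni_tg_bootstrap_ci(
    tables: list[MKTable],
    n_boot: int = 5000,
    seed: int | None = None,
    level: float = 0.95,
    max_undefined_frac: float = 0.0,
) -> tuple[float, float] | None:
    """Percentile bootstrap CI of NI_TG, resampling genes with replacement.

    Returns None (undefined) when the fraction of resamples with an undefined
    estimator exceeds ``max_undefined_frac`` (by default any undefined
    resample voids the interval, since dropping them conditions on the
    resample composition).  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    k = len(tables)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, k, size=k)
        estimates[b] = ni_tg([tables[i] for i in idx])
    defined = estimates[~np.isnan(estimates)]
    if n_boot - len(defined) > max_undefined_frac * n_boot or len(defined) == 0:
        return None
    alpha = (1 - level) / 2
    lo, hi = np.quantile(defined, [alpha, 1 - alpha])
    return float(lo), float(hi)


def woolf_homogeneity(tables: list[MKTable]) -> tuple[float, int, float]:
    """Woolf's test of homogeneity of the MK odds ratios across genes.

    Haldane-Anscombe +0.5 is added to every cell; each gene is weighted by
    the inverse variance of its log odds ratio; the statistic is the weighted
    sum of squared deviations of per-gene log ORs from their weighted mean,
    chi-square distributed with (k-1) df under homogeneity.
    """
    if len(tables) < 2:
        raise ValueError("woolf_homogeneity requires >= 2 tables")
    log_or = np.empty(len(tables))
    w = np.empty(len(tables))
    for i, t in enumerate(tables):
        a, b, c, d = (x + 0.5 for x in t.counts())
        log_or[i] = math.log((a * d) / (b * c))
        w[i] = 1.0 / (1 / a + 1 / b + 1 / c + 1 / d)
    mean = float((w * log_or).sum() / w.sum())
    chi2 = float((w * (log_or - mean) ** 2).sum())
    df = len(tables) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def summarize_gene_set(
    tables: list[MKTable],
    set_name: str,
    n_boot: int = 5000,
    seed: int | None = None,
) -> GeneSetSummary:
    """Gene-set summary: summed-count NI/Z/FET, NI_TG with bootstrap CI,
    Woolf homogeneity, and per-gene NI and Z* distribution summaries."""
    if not tables:
        raise ValueError(f"{set_name}: empty gene set")
    summed = MKTable(
        gene_name=set_name,
        P_N=sum(t.P_N for t in tables),
        P_S=sum(t.P_S for t in tables),
        D_N=sum(t.D_N for t in tables),
        D_S=sum(t.D_S for t in tables),
        method=tables[0].method,
        outgroup=tables[0].outgroup,
        polarized=tables[0].polarized,
    )
    nis = np.array([neutrality_index(t)[0] for t in tables])
    zstars = np.array([z_star(t) for t in tables])
    if len(tables) > 1:
        ci = ni_tg_bootstrap_ci(tables, n_boot=n_boot, seed=seed)
        chi2, df, woolf_p = woolf_homogeneity(tables)
    else:
        point = ni_tg(tables)
        ci = (point, point)
        chi2, df, woolf_p = float("nan"), 0, float("nan")
    return GeneSetSummary(
        set_name=set_name,
        genes=[t.gene_name for t in tables],
        summed=summed,
        NI_summed=(summed.D_S * summed.P_N) / (summed.D_N * summed.P_S)
        if summed.D_N * summed.P_S > 0
        else float("nan"),
        Z_summed=z_plain(summed),
        p_fet=fisher_exact_mk(summed),
        NI_TG=ni_tg(tables),
        NI_TG_CI=ci,
        woolf_chi2=chi2,
        woolf_df=df,
        woolf_p=woolf_p,
        NI_median=float(np.median(nis)),
        NI_mean=float(np.mean(nis)),
        NI_sd=float(np.std(nis, ddof=1)) if len(nis) > 1 else 0.0,
        Zstar_median=float(np.median(zstars)),
        Zstar_mean=float(np.mean(zstars)),
        Zstar_sd=float(np.std(zstars, ddof=1)) if len(zstars) > 1 else 0.0,
    )


def rank_sum_compare(values_a, values_b) -> tuple[float, float]:
    """Mann-Whitney U comparison of two samples (two-sided).

    Exact p for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's automatic policy).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if np.array_equal(a, b):
        return float(len(a) * len(b) / 2), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def effect_size(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """|mean_a - mean_b| divided by the root-mean-square of the two SDs."""
    return abs(mean_a - mean_b) / math.sqrt((sd_a**2 + sd_b**2) / 2)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


# ---------------------------------------------------------------------------
# MK table TSV I/O


def read_mk_counts(path) -> list[MKTable]:
    """Read pre-tabulated MK counts (TSV with gene, PN, PS, DN, DS)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().upper().replace("_", "") for c in df.columns]
    required = ["GENE", "PN", "PS", "DN", "DS"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"MK counts file missing columns: {missing}")
    if df.empty:
        raise ValueError(f"MK counts file {path} has no rows")
    return [
        MKTable(
            gene_name=str(r.GENE),
            P_N=float(r.PN),
            P_S=float(r.PS),
            D_N=float(r.DN),
            D_S=float(r.DS),
        )
        for r in df.itertuples()
    ]


def mk_table_records(tables: list[MKTable]) -> list[dict]:
    """Rows for the per-gene MK results table (gene,PN,PS,DN,DS,NI,Zstar,p_fet)."""
    records = []
    for t in tables:
        s = mk_statistics(t)
        records.append(
            {
                "gene": t.gene_name,
                "PN": t.P_N,
                "PS": t.P_S,
                "DN": t.D_N,
                "DS": t.D_S,
                "NI": s.NI,
                "Zstar": s.Z_star,
                "p_fet": s.p_fet,
            }
        )
    return records
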