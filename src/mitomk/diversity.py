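"""Nucleotide diversity, site-frequency spectra and SFS-based neutrality
statistics (Tajima's D, Fu & Li's D, Fay & Wu's H).

Statistics are reported in count units by default (per-gene totals); per-site
values divide by the number of analysable sites.  Missing data is handled
per column: a column needs at least two non-missing ingroup bases to count,
and the pairwise-heterozygosity correction uses that column's own sample
size.  The normalising constants of Tajima's D use the full ingroup sample
size, which is the convention for samples with scattered missing data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import MISSING
from .codons import CodonGeneAlignment, count_site_classes, _consensus

logger = logging.getLogger("mitomk")


def harmonic(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i."""
    return float(sum(1.0 / i for i in range(1, k + 1)))


def harmonic2(k: int) -> float:
    """b_k = sum_{i=1}^{k} 1/i^2."""
    return float(sum(1.0 / (i * i) for i in range(1, k + 1)))


# ---------------------------------------------------------------------------
# column helpers


def _column_allele_counts(col: np.ndarray) -> np.ndarray:
    """Counts of the four bases among non-missing entries of one column."""
    return np.bincount(col[col != MISSING], minlength=4)


def segregating_sites(matrix: np.ndarray) -> int:
    """Number of columns with >=2 distinct bases among >=2 non-missing rows."""
    S = 0
    for j in range(matrix.shape[1]):
        counts = _column_allele_counts(matrix[:, j])
        if counts.sum() >= 2 and (counts > 0).sum() >= 2:
            S += 1
    return S


def pi(matrix: np.ndarray, per_site: bool = False) -> float:
    """Expected pairwise differences (sum over columns, count units).

    Each column contributes (n_c/(n_c-1)) * (1 - sum p_a^2) where n_c is the
    column's non-missing sample size; ``per_site`` divides by the number of
    columns with n_c >= 2.
    """
    total = 0.0
    n_sites = 0
    for j in range(matrix.shape[1]):
        counts = _column_allele_counts(matrix[:, j])
        n_c = counts.sum()
        if n_c < 2:
            continue
        n_sites += 1
        p = counts / n_c
        total += (n_c / (n_c - 1)) * (1.0 - float(p @ p))
    if per_site:
        return total / n_sites if n_sites else 0.0
    return total


def watterson_theta(S: float, n: int) -> float:
    """Watterson's moment estimator S / a_{n-1} (count units)."""
    if n < 2:
        raise ValueError("watterson_theta requires n >= 2")
    return S / harmonic(n - 1)


def tajimas_d(pi_value: float, S: int, n: int) -> float:
    """Tajima's D; NaN (undefined) when S = 0."""
    if S == 0:
        return float("nan")
    a1 = harmonic(n - 1)
    a2 = harmonic2(n - 1)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_value - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fu_li_d_from_counts(S: int, eta_e: int, n: int) -> float:
    """Fu & Li's polarized D from total mutations and derived singletons."""
    if S == 0:
        return float("nan")
    a_n = harmonic(n - 1)
    b_n = harmonic2(n - 1)
    c_n = 2 * (n * a_n - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1 + (a_n * a_n / (b_n + a_n * a_n)) * (c_n - (n + 1) / (n - 1))
    u_d = a_n - 1 - v_d
    return (S - a_n * eta_e) / math.sqrt(u_d * S + v_d * S * S)


def fu_li_d(matrix: np.ndarray, outgroup_row: np.ndarray) -> float:
    """Fu & Li's D polarized with an outgroup.

    Derived singletons are counted at biallelic columns where the outgroup
    carries one of the two ingroup alleles; other columns still contribute
    to S but cannot be polarized.
    """
    if outgroup_row is None:
        raise LookupError("fu_li_d requires an outgroup row")
    n = matrix.shape[0]
    S = 0
    eta_e = 0
    for j in range(matrix.shape[1]):
        counts = _column_allele_counts(matrix[:, j])
        if counts.sum() < 2 or (counts > 0).sum() < 2:
            continue
        S += 1
        alleles = np.flatnonzero(counts)
        if len(alleles) != 2:
            continue
        anc = outgroup_row[j]
        if anc not in alleles:
            continue
        derived = alleles[0] if alleles[1] == anc else alleles[1]
        if counts[derived] == 1:
            eta_e += 1
    return fu_li_d_from_counts(S, eta_e, n)


def fu_li_d_star(matrix: np.ndarray) -> float:
    """Fu & Li's D* (no outgroup): singletons counted on the folded spectrum."""
    n = matrix.shape[0]
    S = 0
    eta_s = 0
    for j in range(matrix.shape[1]):
        counts = _column_allele_counts(matrix[:, j])
        if counts.sum() < 2 or (counts > 0).sum() < 2:
            continue
        S += 1
        if (counts == 1).any():
            eta_s += 1
    if S == 0:
        return float("nan")
    a_n = harmonic(n - 1)
    b_n = harmonic2(n - 1)
    a_np1 = harmonic(n)
    d_n = c_n = 2 * (n * a_n - 2 * (n - 1)) / ((n - 1) * (n - 2))
    d_n = c_n + (n - 2) / ((n - 1) ** 2) + (2 / (n - 1)) * (1.5 - (2 * a_np1 - 3) / (n - 2) - 1 / n)
    v = (
        (n / (n - 1)) ** 2 * b_n
        + a_n * a_n * d_n
        - 2 * n * a_n * (a_n + 1) / ((n - 1) ** 2)
    ) / (a_n * a_n + b_n)
    u = (n / (n - 1)) * (a_n - n / (n - 1)) - v
    return ((n / (n - 1)) * S - a_n * eta_s) / math.sqrt(u * S + v * S * S)


# ---------------------------------------------------------------------------
# site-frequency spectra


@dataclass
class SiteFrequencySpectrum:
    """Counts of segregating sites per allele-frequency class.

    Folded spectra bin minor-allele counts (classes 1..floor(n/2)); unfolded
    spectra bin derived-allele counts (classes 1..n-1) and require an
    outgroup.  ``omitted_sites`` counts sites dropped from the unfolded
    spectrum because the outgroup base matched neither ingroup allele.
    """

    n: int
    counts: np.ndarray
    polarized: bool
    omitted_sites: int = 0

    @classmethod
    def empty(cls, n: int, polarized: bool) -> "SiteFrequencySpectrum":
        size = (n - 1) if polarized else (n // 2)
        return cls(n, np.zeros(size, dtype=float), polarized)

    def add(self, freq_class: int, weight: float = 1.0) -> None:
        self.counts[freq_class - 1] += weight

    def fold(self) -> "SiteFrequencySpectrum":
        if not self.polarized:
            return self
        n = self.n
        folded = np.zeros(n // 2, dtype=float)
        for i in range(1, n):
            folded[min(i, n - i) - 1] += self.counts[i - 1]
        return SiteFrequencySpectrum(n, folded, polarized=False)

    @property
    def total_sites(self) -> float:
        return float(self.counts.sum())


def sfs(
    matrix: np.ndarray,
    mode: str = "folded",
    outgroup_row: np.ndarray | None = None,
) -> SiteFrequencySpectrum:
    """Site-frequency spectrum of biallelic columns.

    Columns with more than two ingroup alleles are skipped with a log entry.
    In unfolded mode the derived allele is the ingroup allele that does not
    match the outgroup base; sites where the outgroup matches neither allele
    are recorded in ``omitted_sites``.
    """
    if mode not in ("folded", "unfolded"):
        raise ValueError("mode must be 'folded' or 'unfolded'")
    polarized = mode == "unfolded"
    if polarized and outgroup_row is None:
        raise LookupError("unfolded SFS requires an outgroup row")
    n = matrix.shape[0]
    spec = SiteFrequencySpectrum.empty(n, polarized)
    n_multi = 0
    for j in range(matrix.shape[1]):
        counts = _column_allele_counts(matrix[:, j])
        alleles = np.flatnonzero(counts)
        if counts.sum() < 2 or len(alleles) < 2:
            continue
        if len(alleles) > 2:
            n_multi += 1
            continue
        if polarized:
            anc = outgroup_row[j]  # type: ignore[index]
            if anc not in alleles:
                spec.omitted_sites += 1
                continue
            derived = alleles[0] if alleles[1] == anc else alleles[1]
            spec.add(int(counts[derived]))
        else:
            spec.add(int(counts[alleles].min()))
    if n_multi:
        logger.info("sfs: skipped %d columns with >2 alleles", n_multi)
    return spec


def fay_wu_h(spectrum: SiteFrequencySpectrum) -> float:
    """Fay & Wu's H = pi - theta_H from an unfolded spectrum."""
    if not spectrum.polarized:
        raise ValueError("fay_wu_h requires a polarized (unfolded) spectrum")
    n = spectrum.n
    i = np.arange(1, n)
    denom = n * (n - 1)
    pi_val = float((spectrum.counts * 2 * i * (n - i)).sum()) / denom
    theta_h = float((spectrum.counts * 2 * i * i).sum()) / denom
    return pi_val - theta_h


# ---------------------------------------------------------------------------
# per-gene summaries


@dataclass
class DiversitySummary:
    gene_name: str
    site_class: str  # synonymous | nonsynonymous | all
    n_sites: float
    S: int
    pi: float
    theta_w: float
    tajima_d: float
    fu_li_d: float = field(default=float("nan"))
    fay_wu_h: float = field(default=float("nan"))


def _site_class_labels(gene: CodonGeneAlignment, in_idx: list[int]) -> dict[int, str]:
    """Class label (synonymous/nonsynonymous) for each variable nucleotide
    column of a gene, judged against the majority-codon background.

    A multi-allelic or multi-position-linked site is synonymous only if every
    non-majority allele substitution is synonymous.
    """
    labels: dict[int, str] = {}
    code = gene.genetic_code
    for j in range(gene.n_codons):
        observed = [gene.codons[i][j] for i in in_idx]
        observed = [c for c in observed if c is not None]
        if len(observed) < 2 or len(set(observed)) < 2:
            continue
        cons = _consensus(observed)
        for pos in range(3):
            bases = sorted({c[pos] for c in observed})
            if len(bases) < 2:
                continue
            classes = set()
            for base in bases:
                if base == cons[pos]:
                    continue
                mutant = cons[:pos] + base + cons[pos + 1 :]
                classes.add(
                    "synonymous"
                    if code.translate(mutant) == code.translate(cons)
                    else "nonsynonymous"
                )
            labels[3 * j + pos] = (
                "synonymous" if classes == {"synonymous"} else "nonsynonymous"
            )
    return labels


def gene_diversity(
    gene: CodonGeneAlignment,
    outgroup_label: str | None = None,
) -> list[DiversitySummary]:
    """Per-gene diversity summaries for synonymous, nonsynonymous and all sites.

    Fractional site totals (bp) come from the per-codon site-class counts of
    the ingroup consensus codon.  Statistics are in count units.
    """
    in_idx = [gene.row_index(s) for s in gene.ingroup_ids]
    mat = gene.matrix[in_idx]
    n = len(in_idx)
    out_row = None
    if gene.outgroup_ids:
        out_row = gene.outgroup_nuc_row(outgroup_label)

    labels = _site_class_labels(gene, in_idx)

    # fractional site totals from consensus codons
    syn_sites = nonsyn_sites = 0.0
    for j in range(gene.n_codons):
        observed = [gene.codons[i][j] for i in in_idx if gene.codons[i][j] is not None]
        if not observed:
            continue
        cons = _consensus(observed)
        if gene.genetic_code.is_stop(cons):
            continue
        s, ns = count_site_classes(cons, gene.genetic_code)
        syn_sites += s
        nonsyn_sites += ns

    out: list[DiversitySummary] = []
    for site_class, n_sites in (
        ("synonymous", syn_sites),
        ("nonsynonymous", nonsyn_sites),
        ("all", syn_sites + nonsyn_sites),
    ):
        if site_class == "all":
            cols = sorted(labels)
        else:
            cols = sorted(c for c, lab in labels.items() if lab == site_class)
        sub = mat[:, cols] if cols else mat[:, :0]
        S = segregating_sites(sub)
        pi_val = pi(sub)
        theta = watterson_theta(S, n)
        summary = DiversitySummary(
            gene_name=gene.gene_name,
            site_class=site_class,
            n_sites=n_sites,
            S=S,
            pi=pi_val,
            theta_w=theta,
            tajima_d=tajimas_d(pi_val, S, n),
        )
        if out_row is not None and S > 0:
            sub_out = out_row[cols]
            summary.fu_li_d = fu_li_d(sub, sub_out)
            spec = sfs(sub, "unfolded", sub_out)
            summary.fay_wu_h = fay_wu_h(spec)
        out.append(summary)
    return out
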