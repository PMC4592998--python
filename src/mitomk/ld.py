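"""Pairwise linkage disequilibrium, LD-decay correlation and four-gamete tests.

All measures are defined for biallelic haploid sites; columns with more than
two alleles are excluded with a log entry.  Distances are linear
alignment-column distances by default; circular (minimum-arc) distances for
circular genomes are available by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alignment import MISSING

logger = logging.getLogger("mitomk")


@dataclass
class LDPair:
    site_i: int
    site_j: int
    distance: float
    d_prime_abs: float
    r2: float
    n_informative: int
    four_gametes: bool


def _biallelic_sites(matrix: np.ndarray, maf_cutoff: float = 0.0):
    """Indices and 0/1/-1 recoding of biallelic columns passing the MAF cutoff."""
    sites = []
    coded = []
    n_multi = 0
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        counts = np.bincount(col[col != MISSING], minlength=4)
        alleles = np.flatnonzero(counts)
        if len(alleles) < 2 or counts.sum() < 2:
            continue
        if len(alleles) > 2:
            n_multi += 1
            continue
        maf = counts[alleles].min() / counts.sum()
        if maf < maf_cutoff:
            continue
        # allele 0 = lexicographically smaller base; |D'| and r2 are invariant
        recoded = np.full(len(col), -1, dtype=np.int8)
        recoded[col == alleles[0]] = 0
        recoded[col == alleles[1]] = 1
        sites.append(j)
        coded.append(recoded)
    if n_multi:
        logger.info("ld: skipped %d columns with >2 alleles", n_multi)
    return sites, np.array(coded).T if coded else np.empty((matrix.shape[0], 0), np.int8)


def _pair_distance(pos_i: float, pos_j: float, circular_length: float | None) -> float:
    d = abs(pos_j - pos_i)
    if circular_length is not None:
        d = min(d, circular_length - d)
    return d


def pairwise_ld(
    matrix: np.ndarray,
    maf_cutoff: float = 0.0,
    positions: np.ndarray | None = None,
    circular_length: float | None = None,
) -> list[LDPair]:
    """|D'| and r^2 for every pair of biallelic sites.

    D = p_AB - p_A p_B; D' = D / D_max with the usual sign-dependent D_max;
    r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)).  Each pair is computed over the
    sequences non-missing at both sites; pairs monomorphic after that
    filtering are skipped.
    """
    sites, coded = _biallelic_sites(matrix, maf_cutoff)
    if positions is None:
        positions = np.asarray(sites, dtype=float)
    else:
        positions = np.asarray(positions, dtype=float)[sites]
    pairs: list[LDPair] = []
    m = len(sites)
    for a in range(m):
        xa = coded[:, a]
        for b in range(a + 1, m):
            xb = coded[:, b]
            ok = (xa >= 0) & (xb >= 0)
            n_inf = int(ok.sum())
            if n_inf < 2:
                continue
            va, vb = xa[ok], xb[ok]
            p_a = va.mean()
            p_b = vb.mean()
            if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
                continue  # monomorphic after missing-data filtering
            p_ab = float((va & vb).mean())
            D = p_ab - p_a * p_b
            if D > 0:
                d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
            else:
                d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
            d_prime = abs(D) / d_max if d_max > 0 else 0.0
            r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
            hap = {(int(x), int(y)) for x, y in zip(va, vb)}
            pairs.append(
                LDPair(
                    site_i=sites[a],
                    site_j=sites[b],
                    distance=_pair_distance(positions[a], positions[b], circular_length),
                    d_prime_abs=float(min(d_prime, 1.0)),
                    r2=float(min(r2, 1.0)),
                    n_informative=n_inf,
                    four_gametes=len(hap) == 4,
                )
            )
    return pairs


def ld_distance_correlation(
    pairs: list[LDPair],
    measure: str = "d_prime_abs",
    n_perm: int = 1000,
    seed: int | None = None,
    circular_length: float | None = None,
    positions: dict[int, float] | None = None,
) -> tuple[float, float]:
    """Spearman correlation between an LD measure and pair distance, with a
    one-sided (negative-direction) permutation p-value.

    Because the pairs sharing a site are not independent, the null is built
    by permuting the site positions and recomputing every pair's distance;
    the LD values stay attached to their site pairs.  ``positions`` maps site
    index to coordinate (defaults to the site index itself, matching
    ``pairwise_ld`` run without explicit positions).
    """
    if len(pairs) < 3:
        raise ValueError("ld_distance_correlation requires >= 3 pairs")
    if measure not in ("d_prime_abs", "r2"):
        raise ValueError("measure must be 'd_prime_abs' or 'r2'")
    values = np.array([getattr(p, measure) for p in pairs])
    sites = sorted({p.site_i for p in pairs} | {p.site_j for p in pairs})
    site_pos = positions or {s: float(s) for s in sites}
    idx_i = np.array([sites.index(p.site_i) for p in pairs])
    idx_j = np.array([sites.index(p.site_j) for p in pairs])

    def rho_for(pos: np.ndarray) -> float:
        d = np.abs(pos[idx_j] - pos[idx_i])
        if circular_length is not None:
            d = np.minimum(d, circular_length - d)
        if np.all(values == values[0]) or np.all(d == d[0]):
            return 0.0
        r = stats.spearmanr(d, values).statistic
        return 0.0 if np.isnan(r) else float(r)

    pos0 = np.array([site_pos[s] for s in sites])
    rho_obs = rho_for(pos0)
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(n_perm):
        if rho_for(rng.permutation(pos0)) <= rho_obs:
            n_le += 1
    p = (1 + n_le) / (n_perm + 1)
    return rho_obs, float(p)


def four_gamete_test(matrix: np.ndarray) -> tuple[int, list[tuple[int, int]]]:
    """Count site pairs at which all four haplotypes occur.

    Under a single genealogy with at most one mutation per site, no pair can
    show all four gametes; violations indicate recombination or recurrent
    mutation.
    """
    sites, coded = _biallelic_sites(matrix)
    violations: list[tuple[int, int]] = []
    m = len(sites)
    for a in range(m):
        xa = coded[:, a]
        for b in range(a + 1, m):
            xb = coded[:, b]
            ok = (xa >= 0) & (xb >= 0)
            va, vb = xa[ok], xb[ok]
            combos = np.unique(va * 2 + vb)
            if len(combos) == 4:
                violations.append((sites[a], sites[b]))
    return len(violations), violations
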