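"""Codon-aware counting of polymorphism and divergence for MK tables.

Codon pairs that differ at k positions are connected by k! single-base
mutational pathways.  The *more-inclusive* counting method averages the
synonymous/nonsynonymous step counts over all pathways (excluding pathways
that traverse a stop codon); the *less-inclusive* method takes the single
pathway that minimises the nonsynonymous count.  Fixed differences are only
counted at positions where the outgroup allele is absent from the ingroup
sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

from .alignment import BASES, CodonGeneAlignment, GeneticCode

logger = logging.getLogger("mitomk")

MORE_INCLUSIVE = "more_inclusive"
LESS_INCLUSIVE = "less_inclusive"


@dataclass(frozen=True)
class Pathway:
    """One ordering of the single-base steps between two codons."""

    position_order: tuple[int, ...]
    steps: tuple[tuple[str, str, str], ...]  # (codon_from, codon_to, class)
    n_syn: int
    n_nonsyn: int
    hits_stop: bool  # traverses a stop codon at an intermediate step


@dataclass
class PathwaySet:
    codon_from: str
    codon_to: str
    pathways: list[Pathway] = field(default_factory=list)

    @property
    def k(self) -> int:
        return sum(a != b for a, b in zip(self.codon_from, self.codon_to))

    def usable(self) -> list[Pathway]:
        """Pathways used for counting: stop-traversing ones are excluded
        unless every pathway hits a stop (then all are kept, with a warning)."""
        clean = [p for p in self.pathways if not p.hits_stop]
        if clean:
            return clean
        if self.pathways:
            logger.warning(
                "all pathways %s->%s traverse a stop; including all",
                self.codon_from,
                self.codon_to,
            )
        return self.pathways

    def averaged_counts(self) -> tuple[float, float]:
        """Mean (syn, nonsyn) step counts over usable pathways."""
        paths = self.usable()
        if not paths:
            return 0.0, 0.0
        m = len(paths)
        return (
            sum(p.n_syn for p in paths) / m,
            sum(p.n_nonsyn for p in paths) / m,
        )

    def min_dn_counts(self) -> tuple[int, int]:
        """(syn, nonsyn) of the pathway minimising the nonsynonymous count.

        Ties are broken by lexicographic position order (pathways are
        enumerated in that order, and ``min`` keeps the first).
        """
        paths = self.usable()
        if not paths:
            return 0, 0
        best = min(paths, key=lambda p: (p.n_nonsyn, p.position_order))
        return best.n_syn, best.n_nonsyn


def enumerate_pathways(codon_from: str, codon_to: str, code: GeneticCode) -> PathwaySet:
    """Enumerate all k! mutational pathways between two resolved codons."""
    diff = tuple(i for i in range(3) if codon_from[i] != codon_to[i])
    out = PathwaySet(codon_from, codon_to)
    if not diff:
        return out
    for order in permutations(diff):
        current = codon_from
        steps = []
        n_syn = n_nonsyn = 0
        hits_stop = False
        for step_idx, pos in enumerate(order):
            nxt = current[:pos] + codon_to[pos] + current[pos + 1 :]
            if step_idx < len(order) - 1 and code.is_stop(nxt):
                hits_stop = True
            cls = "synonymous" if code.translate(current) == code.translate(nxt) else "nonsynonymous"
            if cls == "synonymous":
                n_syn += 1
            else:
                n_nonsyn += 1
            steps.append((current, nxt, cls))
            current = nxt
        out.pathways.append(Pathway(order, tuple(steps), n_syn, n_nonsyn, hits_stop))
    return out


def count_site_classes(codon: str, code: GeneticCode) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    Each position contributes the fraction of its non-stop single-base
    changes that are synonymous; mutations to stop codons are excluded from
    the denominator (so syn + nonsyn = 3 only when no stop neighbours exist).
    """
    if code.is_stop(codon):
        raise ValueError(f"site counts undefined for stop codon {codon}")
    aa = code.translate(codon)
    syn = nonsyn = 0.0
    for pos in range(3):
        n_syn = n_total = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if code.is_stop(mutant):
                continue
            n_total += 1
            if code.translate(mutant) == aa:
                n_syn += 1
        if n_total:
            syn += n_syn / n_total
            nonsyn += 1 - n_syn / n_total
    return syn, nonsyn


@dataclass
class MKTable:
    """Gene-level MK contingency counts (fractional values permitted)."""

    gene_name: str
    P_N: float = 0.0
    P_S: float = 0.0
    D_N: float = 0.0
    D_S: float = 0.0
    method: str = MORE_INCLUSIVE
    outgroup: str = ""
    polarized: bool = False

    def counts(self) -> tuple[float, float, float, float]:
        return self.P_N, self.P_S, self.D_N, self.D_S

    def __post_init__(self) -> None:
        if min(self.counts()) < 0:
            raise ValueError("MK counts must be non-negative")

    def __add__(self, other: "MKTable") -> "MKTable":
        return MKTable(
            gene_name=f"{self.gene_name}+{other.gene_name}",
            P_N=self.P_N + other.P_N,
            P_S=self.P_S + other.P_S,
            D_N=self.D_N + other.D_N,
            D_S=self.D_S + other.D_S,
            method=self.method,
            outgroup=self.outgroup,
            polarized=self.polarized,
        )


def _majority_base(bases: list[str]) -> str:
    # majority with lexicographic tie-break for reproducibility
    return max(sorted(set(bases)), key=bases.count)


def _consensus(codons: list[str]) -> str:
    return "".join(_majority_base([c[pos] for c in codons]) for pos in range(3))


def _effective_outgroup(outgroup_codons) -> list[str | None]:
    """Per-position outgroup base; None where outgroups disagree/missing."""
    if outgroup_codons is None:
        return [None, None, None]
    if isinstance(outgroup_codons, str):
        outgroup_codons = [outgroup_codons]
    resolved = [c for c in outgroup_codons if c is not None]
    if len(resolved) < len(outgroup_codons) or not resolved:
        # any missing outgroup codon: divergence cannot be assessed
        return [None, None, None]
    out: list[str | None] = []
    for pos in range(3):
        bases = {c[pos] for c in resolved}
        out.append(bases.pop() if len(bases) == 1 else None)
    return out


def classify_codon_column(
    ingroup_codons: list[str | None],
    outgroup_codon,
    code: GeneticCode,
    method: str = MORE_INCLUSIVE,
) -> list[tuple[str, float]]:
    """Classify one codon column into weighted P_S/P_N/D_S/D_N contributions.

    ``outgroup_codon`` may be a codon string, ``None``, or a list of codons
    (two-outgroup polarization: only positions where the outgroups agree can
    contribute divergence).

    Rules, applied per nucleotide position within the codon:
      * ingroup-variable positions contribute polymorphism;
      * positions fixed in the ingroup but different from the outgroup, and
        ingroup-variable positions where the outgroup allele is absent from
        the ingroup, contribute fixed differences;
      * an ingroup-variable position whose outgroup allele is present in the
        ingroup contributes polymorphism only.
    """
    observed = [c for c in ingroup_codons if c is not None]
    if len(observed) < 2:
        return []
    states = sorted(set(observed))
    cons = _consensus(observed)
    out_bases = _effective_outgroup(outgroup_codon)

    contributions: list[tuple[str, float]] = []

    # -- polymorphism ------------------------------------------------------
    if len(states) == 2:
        ps = enumerate_pathways(states[0], states[1], code)
        syn_w, nonsyn_w = ps.averaged_counts()
        if syn_w:
            contributions.append(("P_S", syn_w))
        if nonsyn_w:
            contributions.append(("P_N", nonsyn_w))
    elif len(states) > 2:
        # >=3 segregating codon states: count per variable position against
        # the majority-codon background
        for pos in range(3):
            pos_bases = [c[pos] for c in observed]
            major = _majority_base(pos_bases)
            for base in sorted(set(pos_bases) - {major}):
                mutant = cons[:pos] + base + cons[pos + 1 :]
                cls = (
                    "P_S"
                    if code.translate(mutant) == code.translate(cons)
                    else "P_N"
                )
                contributions.append((cls, 1.0))

    # -- divergence --------------------------------------------------------
    div_positions = []
    for pos in range(3):
        ob = out_bases[pos]
        if ob is None:
            continue
        ingroup_pos = {c[pos] for c in observed}
        if ob not in ingroup_pos:
            div_positions.append(pos)
    if div_positions:
        target = list(cons)
        for pos in div_positions:
            target[pos] = out_bases[pos]  # type: ignore[assignment]
        ps = enumerate_pathways(cons, "".join(target), code)
        if method == LESS_INCLUSIVE:
            syn_w, nonsyn_w = ps.min_dn_counts()
        else:
            syn_w, nonsyn_w = ps.averaged_counts()
        if syn_w:
            contributions.append(("D_S", syn_w))
        if nonsyn_w:
            contributions.append(("D_N", nonsyn_w))
    return contributions


def build_mk_table(
    gene: CodonGeneAlignment,
    method: str = MORE_INCLUSIVE,
    outgroup_choice: str | None = None,
    min_ingroup: int = 2,
    drop_sequences: tuple[str, ...] = (),
) -> MKTable:
    """Assemble a gene's MK contingency table from its codon alignment.

    ``more_inclusive`` keeps codon columns with partial missing data
    (classifying over the non-missing rows); ``less_inclusive`` drops any
    column with missing data and supports dropping designated high-missing
    sequences first via ``drop_sequences``.
    """
    if method not in (MORE_INCLUSIVE, LESS_INCLUSIVE):
        raise ValueError(f"unknown method {method!r}")
    out_label = outgroup_choice or (gene.outgroup_ids[0] if gene.outgroup_ids else None)
    out_idx = gene.row_index(out_label) if out_label is not None else None
    in_ids = [s for s in gene.ingroup_ids if s not in set(drop_sequences)]
    in_idx = [gene.row_index(s) for s in in_ids]

    table = MKTable(gene.gene_name, method=method, outgroup=out_label or "")
    n_used = 0
    n_skipped = 0
    for j in range(gene.n_codons):
        ingroup = [gene.codons[i][j] for i in in_idx]
        out_codon = gene.codons[out_idx][j] if out_idx is not None else None
        if method == LESS_INCLUSIVE:
            if any(c is None for c in ingroup) or (
                out_idx is not None and out_codon is None
            ):
                n_skipped += 1
                continue
        else:
            if sum(c is not None for c in ingroup) < min_ingroup:
                n_skipped += 1
                continue
        # fast path: invariant, fully consistent column
        col_states = {c for c in ingroup if c is not None}
        if len(col_states) == 1 and (out_codon is None or out_codon in col_states):
            n_used += 1
            continue
        for cls, w in classify_codon_column(ingroup, out_codon, gene.genetic_code, method):
            setattr(table, cls, getattr(table, cls) + w)
        n_used += 1
    if n_used == 0:
        raise ValueError(f"{gene.gene_name}: no codon columns pass the {method} filter")
    if n_skipped:
        logger.info("%s: %d codon columns skipped (%s)", gene.gene_name, n_skipped, method)
    return table


def polarize_with_two_outgroups(
    gene: CodonGeneAlignment,
    outgroup1: str,
    outgroup2: str,
    method: str = MORE_INCLUSIVE,
    min_ingroup: int = 2,
) -> MKTable:
    """MK table with divergence polarized to the ingroup branch.

    Fixed differences are counted only where both outgroups agree with each
    other and differ from the ingroup; positions with discordant outgroups
    are excluded from divergence.
    """
    i1, i2 = gene.row_index(outgroup1), gene.row_index(outgroup2)
    out_set = {outgroup1, outgroup2}
    in_idx = [gene.row_index(s) for s in gene.sequence_ids if s not in out_set]

    table = MKTable(
        gene.gene_name,
        method=method,
        outgroup=f"{outgroup1}+{outgroup2}",
        polarized=True,
    )
    n_used = 0
    for j in range(gene.n_codons):
        ingroup = [gene.codons[i][j] for i in in_idx]
        outs = [gene.codons[i1][j], gene.codons[i2][j]]
        if method == LESS_INCLUSIVE:
            if any(c is None for c in ingroup) or any(c is None for c in outs):
                continue
        elif sum(c is not None for c in ingroup) < min_ingroup:
            continue
        for cls, w in classify_codon_column(ingroup, outs, gene.genetic_code, method):
            setattr(table, cls, getattr(table, cls) + w)
        n_used += 1
    if n_used == 0:
        raise ValueError(f"{gene.gene_name}: no codon columns pass the {method} filter")
    return table
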