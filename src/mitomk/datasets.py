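"""Packaged reference data.

``load_dmel_mt_mk_counts`` returns published more-inclusive McDonald-Kreitman
counts for the 13 protein-coding genes of the D. melanogaster mitochondrial
genome (38 haplotypes from a single North American population, divergence to
D. yakuba).  ``DMEL_MT_GENE_SETS`` groups those genes into the
mitochondrially encoded OXPHOS complexes.
"""

from __future__ import annotations

from importlib import resources

from .codons import MKTable
from .mkstats import read_mk_counts

#: OXPHOS complex membership of the 13 mtDNA protein-coding genes.
#: Complex II is nuclear encoded; Complex III has the single locus Cyt-b;
#: the two ATPase loci of Complex V overlap on the chromosome.
DMEL_MT_GENE_SETS: dict[str, list[str]] = {
    "Complex I": ["ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6"],
    "Complex III": ["Cyt-b"],
    "Complex IV": ["COI", "COII", "COIII"],
    "Complex V": ["ATPase6", "ATPase8"],
    "All coding": [
        "ATPase6", "ATPase8", "COI", "COII", "COIII", "Cyt-b",
        "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    ],
}


def load_dmel_mt_mk_counts() -> list[MKTable]:
    """The packaged 13-gene mitochondrial MK count table."""
    ref = resources.files("mitomk.data") / "dmel_mtdna_mk_counts.tsv"
    with resources.as_file(ref) as path:
        return read_mk_counts(path)
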