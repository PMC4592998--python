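"""Alignment and annotation I/O.

Population samples are handled as haploid multiple-sequence alignments with
one or two outgroup sequences.  Nucleotides are stored as small integer codes;
every gap, ``N`` and IUPAC ambiguity code is collapsed to a single missing
state, because downstream counting filters ambiguous data rather than
interpreting it.

Annotation coordinates are 1-based inclusive (GenBank convention) in files;
all internal indexing is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger("mitomk")

# nucleotide integer codes
A, C, G, T, MISSING = 0, 1, 2, 3, 4
BASES = "ACGT"
_CHAR2CODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CHAR2CODE[ord(_b)] = _i
    _CHAR2CODE[ord(_b.lower())] = _i
_CODE2CHAR = np.array(list(BASES + "N"))
# complement: A<->T, C<->G, missing stays missing
_COMPLEMENT = np.array([T, G, C, A, MISSING], dtype=np.uint8)


class AlignmentError(ValueError):
    """Malformed or inconsistent alignment input."""


class AnnotationError(ValueError):
    """Malformed gene annotation input."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string into integer codes (non-ACGT -> missing)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CHAR2CODE[raw]


def decode_row(row: np.ndarray) -> str:
    return "".join(_CODE2CHAR[row])


@dataclass
class GeneticCode:
    """A 64-codon translation table; stop codons translate to ``'*'``."""

    table_id: int
    codon_to_aa: dict[str, str] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.codon_to_aa:
            tbl = CodonTable.unambiguous_dna_by_id[self.table_id]
            mapping = dict(tbl.forward_table)
            for stop in tbl.stop_codons:
                mapping[stop] = "*"
            self.codon_to_aa = mapping
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map all 64 codons")

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == "*"

    @property
    def stop_codons(self) -> set[str]:
        return {c for c, aa in self.codon_to_aa.items() if aa == "*"}


#: codes shipped by default: 1 standard, 2 vertebrate mito, 5 invertebrate mito
def get_code(table_id: int) -> GeneticCode:
    return GeneticCode(table_id)


@dataclass
class PopulationAlignment:
    """Aligned haploid sample: ingroup haplotypes plus outgroup sequence(s)."""

    sequence_ids: list[str]
    matrix: np.ndarray  # (n_sequences, L) uint8 codes
    outgroup_ids: list[str]

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or len(self.sequence_ids) != self.matrix.shape[0]:
            raise AlignmentError("matrix shape does not match sequence ids")
        missing = set(self.outgroup_ids) - set(self.sequence_ids)
        if missing:
            raise LookupError(f"outgroup labels not in alignment: {sorted(missing)}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def ingroup_ids(self) -> list[str]:
        out = set(self.outgroup_ids)
        return [s for s in self.sequence_ids if s not in out]

    def row_index(self, label: str) -> int:
        try:
            return self.sequence_ids.index(label)
        except ValueError:
            raise LookupError(f"sequence label not found: {label}") from None

    @property
    def ingroup_matrix(self) -> np.ndarray:
        idx = [self.row_index(s) for s in self.ingroup_ids]
        return self.matrix[idx]

    def outgroup_row(self, label: str | None = None) -> np.ndarray:
        if label is None:
            if not self.outgroup_ids:
                raise LookupError("alignment has no outgroup")
            label = self.outgroup_ids[0]
        return self.matrix[self.row_index(label)]

    def reverse_complement(self) -> "PopulationAlignment":
        return PopulationAlignment(
            list(self.sequence_ids),
            _COMPLEMENT[self.matrix[:, ::-1]],
            list(self.outgroup_ids),
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene on the alignment coordinate system (1-based inclusive)."""

    gene_name: str
    start: int
    end: int
    strand: str
    frame_offset: int = 0
    genetic_code_id: int = 5

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"{self.gene_name}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.gene_name}: bad strand {self.strand!r}")
        if self.frame_offset not in (0, 1, 2):
            raise AnnotationError(f"{self.gene_name}: frame must be 0-2")


@dataclass
class CodonGeneAlignment:
    """One gene sliced into codon columns on the coding strand.

    ``codons[i][j]`` is a 3-letter string, or ``None`` when the codon contains
    any missing base for that sequence.  ``matrix`` holds the underlying
    coding-strand nucleotides (used by the nucleotide-level diversity
    statistics).
    """

    gene_name: str
    sequence_ids: list[str]
    outgroup_ids: list[str]
    codons: list[list[str | None]]
    matrix: np.ndarray
    genetic_code: GeneticCode

    @property
    def n_codons(self) -> int:
        return len(self.codons[0]) if self.codons else 0

    @property
    def ingroup_ids(self) -> list[str]:
        out = set(self.outgroup_ids)
        return [s for s in self.sequence_ids if s not in out]

    def row_index(self, label: str) -> int:
        try:
            return self.sequence_ids.index(label)
        except ValueError:
            raise LookupError(f"sequence label not found: {label}") from None

    def codon_column(self, j: int) -> list[str | None]:
        return [row[j] for row in self.codons]

    @property
    def ingroup_matrix(self) -> np.ndarray:
        idx = [self.row_index(s) for s in self.ingroup_ids]
        return self.matrix[idx]

    def outgroup_nuc_row(self, label: str | None = None) -> np.ndarray:
        if label is None:
            label = self.outgroup_ids[0]
        return self.matrix[self.row_index(label)]


def read_alignment(path, outgroup_labels) -> PopulationAlignment:
    """Read an aligned FASTA file; ``outgroup_labels`` name the outgroup rows."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise AlignmentError(f"duplicate sequence label: {rec.id}")
        ids.append(rec.id)
        rows.append(encode_sequence(str(rec.seq)))
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal record lengths: {sorted(lengths)}")
    return PopulationAlignment(ids, np.vstack(rows), list(outgroup_labels))


def write_alignment(aln: PopulationAlignment, path) -> None:
    """Write the alignment back to FASTA; missing cells are emitted as ``N``."""
    with open(path, "w") as fh:
        for label in aln.sequence_ids:
            fh.write(f">{label}\n{decode_row(aln.matrix[aln.row_index(label)])}\n")


def read_annotation(path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV with columns gene,start,end,strand,frame,code."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "strand": str})
    required = ["gene", "start", "end", "strand", "frame", "code"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation file missing columns: {missing}")
    anns = [
        GeneAnnotation(
            gene_name=r.gene,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            frame_offset=int(r.frame),
            genetic_code_id=int(r.code),
        )
        for r in df.itertuples()
    ]
    names = [a.gene_name for a in anns]
    dupes = {g for g in names if names.count(g) > 1}
    if dupes:
        raise AnnotationError(f"duplicated gene names: {sorted(dupes)}")
    return anns


def write_annotation(anns: list[GeneAnnotation], path) -> None:
    df = pd.DataFrame(
        {
            "gene": [a.gene_name for a in anns],
            "start": [a.start for a in anns],
            "end": [a.end for a in anns],
            "strand": [a.strand for a in anns],
            "frame": [a.frame_offset for a in anns],
            "code": [a.genetic_code_id for a in anns],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def extract_gene(
    aln: PopulationAlignment,
    ann: GeneAnnotation,
    code: GeneticCode | None = None,
) -> CodonGeneAlignment:
    """Slice one annotated gene into codon columns on the coding strand.

    Minus-strand genes are reverse-complemented; ``frame_offset`` leading
    bases and any trailing partial codon are trimmed.  A codon containing any
    missing base is recorded as missing for that sequence.
    """
    if ann.end > aln.length:
        raise AnnotationError(
            f"{ann.gene_name}: end {ann.end} beyond alignment length {aln.length}"
        )
    code = code or get_code(ann.genetic_code_id)
    sub = aln.matrix[:, ann.start - 1 : ann.end]
    if ann.strand == "-":
        sub = _COMPLEMENT[sub[:, ::-1]]
    sub = sub[:, ann.frame_offset :]
    n_codons = sub.shape[1] // 3
    if n_codons == 0:
        raise AnnotationError(f"{ann.gene_name}: extracted region shorter than a codon")
    sub = sub[:, : 3 * n_codons]

    codons: list[list[str | None]] = []
    n_internal_stops = 0
    for row in sub:
        row_codons: list[str | None] = []
        chars = _CODE2CHAR[row]
        for j in range(n_codons):
            triplet = row[3 * j : 3 * j + 3]
            if (triplet == MISSING).any():
                row_codons.append(None)
            else:
                cdn = "".join(chars[3 * j : 3 * j + 3])
                if j < n_codons - 1 and code.is_stop(cdn):
                    n_internal_stops += 1
                row_codons.append(cdn)
        codons.append(row_codons)
    if n_internal_stops:
        logger.warning(
            "%s: %d internal stop codon(s) in trimmed coding region",
            ann.gene_name,
            n_internal_stops,
        )
    return CodonGeneAlignment(
        gene_name=ann.gene_name,
        sequence_ids=list(aln.sequence_ids),
        outgroup_ids=list(aln.outgroup_ids),
        codons=codons,
        matrix=sub,
        genetic_code=code,
    )


def write_results_table(records, path, float_precision: int = 3, columns=None) -> None:
    """Write a list of record dicts as a TSV with fixed float precision."""
    if records:
        if columns is None:
            columns = list(records[0].keys())
        df = pd.DataFrame.from_records(records, columns=columns)
    else:
        df = pd.DataFrame(columns=columns or [])
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}f")
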