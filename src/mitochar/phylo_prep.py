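"""13-PCG supermatrix construction and a lightweight distance tree.

The supermatrix concatenates the 13 protein-coding genes (ND5 joined from
its two exons) in canonical circle order, with terminal stop codons
stripped; the amino-acid level translates each gene under the configured
genetic code.  Per-gene lengths must be identical across taxa: unequal
lengths raise an error instructing external alignment rather than silently
padding (no internal aligner is provided).

The neighbor-joining tree is pipeline plumbing for sanity checks, not a
substitute for model-based phylogenetics.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .codon_usage import CodonTable, DEFAULT_TABLE, codons_of, translate
from .errors import AlignmentError, FeatureError
from .genome_io import FeatureTable, MitoGenome, extract_feature, nd5_joined
from .presets import PCG_CONCAT_ORDER

Level = Literal["nt", "aa"]


@dataclass(frozen=True)
class Supermatrix:
    """A concatenated multi-gene matrix with 1-based column partitions."""

    taxa: tuple[str, ...]
    partitions: tuple[tuple[str, int, int], ...]
    matrix: dict[str, str]
    level: str

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.matrix.values())))


def _taxon_label(genome: MitoGenome) -> str:
    label = genome.organism or genome.accession
    return label.replace(" ", "_")


def _gene_sequences(genome: MitoGenome, table: FeatureTable,
                    code: CodonTable, level: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for gene in PCG_CONCAT_ORDER:
        try:
            feat = nd5_joined(table) if gene == "ND5" else table.get(gene)
        except KeyError as exc:
            raise FeatureError(
                f"{table.genome_ref}: missing PCG {gene}"
            ) from exc
        cds = extract_feature(genome, feat)
        codon_list = codons_of(cds)
        if codon_list and code.is_stop(codon_list[-1]):
            cds = cds[:-3]  # exclude the stop codon
        out[gene] = translate(cds, code) if level == "aa" else cds
    return out


def build_supermatrix(genomes: Sequence[tuple[MitoGenome, FeatureTable]],
                      level: Level = "nt",
                      code: CodonTable = DEFAULT_TABLE) -> Supermatrix:
    """Concatenate the 13 PCGs of every genome into one supermatrix.

    Genes are concatenated in canonical circle order; a per-gene length
    mismatch across taxa is an error (align externally, then retry).
    """
    if level not in ("nt", "aa"):
        raise ValueError(f"level must be 'nt' or 'aa', got {level!r}")
    if not genomes:
        raise AlignmentError("no genomes supplied")
    per_taxon: dict[str, dict[str, str]] = {}
    labels: list[str] = []
    for genome, table in genomes:
        label = _taxon_label(genome)
        if label in per_taxon:
            label = f"{label}_{genome.accession}"
        labels.append(label)
        per_taxon[label] = _gene_sequences(genome, table, code, level)
    # validate per-gene length agreement
    for gene in PCG_CONCAT_ORDER:
        lengths = {label: len(per_taxon[label][gene]) for label in labels}
        if len(set(lengths.values())) > 1:
            raise AlignmentError(
                f"per-gene length mismatch for {gene}: {lengths}; "
                f"align orthologs externally before concatenation"
            )
    partitions: list[tuple[str, int, int]] = []
    col = 1
    for gene in PCG_CONCAT_ORDER:
        glen = len(per_taxon[labels[0]][gene])
        partitions.append((gene, col, col + glen - 1))
        col += glen
    matrix = {label: "".join(per_taxon[label][g] for g in PCG_CONCAT_ORDER)
              for label in labels}
    return Supermatrix(taxa=tuple(labels), partitions=tuple(partitions),
                       matrix=matrix, level=level)


def _alignment(sm: Supermatrix) -> MultipleSeqAlignment:
    mol = "protein" if sm.level == "aa" else "DNA"
    records = [
        SeqRecord(Seq(sm.matrix[t]), id=t, description="",
                  annotations={"molecule_type": mol})
        for t in sm.taxa
    ]
    return MultipleSeqAlignment(records)


def write_supermatrix(sm: Supermatrix, path: str | Path,
                      fmt: Literal["fasta", "phylip", "nexus"] = "nexus",
                      ) -> None:
    """Write FASTA, relaxed PHYLIP, or NEXUS (with a partition sets block)."""
    path = Path(path)
    aln = _alignment(sm)
    bio_fmt = {"fasta": "fasta", "phylip": "phylip-relaxed",
               "nexus": "nexus"}[fmt]
    with open(path, "w", newline="\n") as fh:
        AlignIO.write(aln, fh, bio_fmt)
        if fmt == "nexus":
            fh.write("begin sets;\n")
            for gene, start, end in sm.partitions:
                fh.write(f"    charset {gene} = {start}-{end};\n")
            fh.write("end;\n")


def p_distance(s1: str, s2: str) -> float:
    """Proportion of differing columns between two equal-length rows."""
    if len(s1) != len(s2):
        raise AlignmentError("rows differ in length")
    if not s1:
        raise AlignmentError("empty rows")
    return sum(a != b for a, b in zip(s1, s2)) / len(s1)


def corrected_distance(s1: str, s2: str, level: str = "nt") -> float:
    """Jukes-Cantor-type correction (alphabet size 4 for nt, 20 for aa)."""
    p = p_distance(s1, s2)
    b = 4 if level == "nt" else 20
    factor = (b - 1) / b
    if p >= factor:
        raise AlignmentError(
            f"distance saturated (p = {p:.4f} >= {factor:.4f})"
        )
    return -factor * math.log(1 - p / factor)


def nj_tree(sm: Supermatrix,
            distance: Literal["p", "jc"] = "p") -> str:
    """Neighbor-joining Newick tree (with branch lengths) from a supermatrix.

    Taxa are processed in sorted label order so the result is invariant to
    input order; ties break deterministically.
    """
    if len(sm.taxa) < 3:
        raise AlignmentError("neighbor joining requires at least 3 taxa")
    ids = sorted(sm.taxa)
    dist = (p_distance if distance == "p"
            else lambda a, b: corrected_distance(a, b, sm.level))
    data = [[0.0 if i == j else dist(sm.matrix[ids[i]], sm.matrix[ids[j]])
             for j in range(len(ids))] for i in range(len(ids))]
    dm = DistanceMatrix(data, ids)
    tree = _skbio_nj(dm)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
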