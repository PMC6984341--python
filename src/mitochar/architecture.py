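"""Per-gene summary table: sizes, GC%, protein lengths, codons, spacers.

One row per feature in circle order.  The signed intergenic column gives
the gap to the NEXT feature on the circle: positive = spacer, negative =
overlap; the wrap-around gap (last feature back to the first) is attributed
to the last feature.  The whole table is invariant under rotation of the
genome's origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .codon_usage import CodonTable, DEFAULT_TABLE, detect_start_stop, translate
from .composition import base_composition, round_report
from .errors import FeatureError
from .genome_io import FeatureTable, GeneFeature, MitoGenome, extract_feature

#: Anchor gene at which the canonical circle presentation starts.
CANONICAL_ANCHOR = "tRNA-Met"


@dataclass(frozen=True)
class GeneSummaryRow:
    """One gene/element row of the architecture summary."""

    gene: str
    strand: str
    size_bp: int
    gc_pct: float
    aa: int | None
    start_codon: str | None
    stop_codon: str | None
    intergenic_bp: int


def _circle_sorted(table: FeatureTable) -> list[GeneFeature]:
    return sorted(table.features, key=lambda f: f.start)


def summarize(genome: MitoGenome, table: FeatureTable,
              code: CodonTable = DEFAULT_TABLE,
              pct_decimals: int = 2) -> list[GeneSummaryRow]:
    """Per-feature summary rows in circle order.

    ``intergenic_bp`` = next.start - this.end - 1 on the circle.  Protein
    lengths (aa) are reported for PCGs only: len/3 - 1 when the CDS is
    stop-terminated, len/3 otherwise (the intron-interrupted ND5 5' exon).
    """
    if not table.features:
        raise FeatureError(f"{table.genome_ref}: no features to summarize")
    feats = _circle_sorted(table)
    length = genome.length_bp
    rows: list[GeneSummaryRow] = []
    for i, feat in enumerate(feats):
        seq = extract_feature(genome, feat)
        if i + 1 < len(feats):
            next_start = feats[i + 1].start
        else:
            next_start = feats[0].start + length  # wrap to the first feature
        gap = next_start - feat.end - 1
        aa: int | None = None
        start_codon = stop_codon = None
        if feat.ftype == "PCG":
            info = detect_start_stop(seq, code)
            start_codon = info.start_codon
            stop_codon = info.stop_codon
            protein = translate(seq, code)
            aa = len(protein)
        rows.append(GeneSummaryRow(
            gene=feat.name,
            strand=feat.strand,
            size_bp=feat.span_length,
            gc_pct=round_report(base_composition(seq).gc_pct, pct_decimals),
            aa=aa,
            start_codon=start_codon,
            stop_codon=stop_codon,
            intergenic_bp=gap,
        ))
    return rows


def summary_dataframe(rows: list[GeneSummaryRow]) -> pd.DataFrame:
    """Summary rows as a DataFrame in the published column layout."""
    df = pd.DataFrame([{
        "gene": r.gene, "strand": r.strand, "size_bp": r.size_bp,
        "gc_pct": r.gc_pct, "aa": r.aa,
        "start_codon": r.start_codon, "stop_codon": r.stop_codon,
        "intergenic_bp": r.intergenic_bp,
    } for r in rows])
    df["aa"] = df["aa"].astype("Int64")
    return df


def gene_order_string(table: FeatureTable,
                      anchor: str = CANONICAL_ANCHOR) -> tuple[str, ...]:
    """Canonical gene order around the circle, rotated to start at ``anchor``.

    Any rotation of the same circle yields the same tuple, making gene
    orders equality-comparable across genomes (a rearrangement check).  When
    the anchor gene is absent, rotation starts at the lexicographically
    smallest gene name.
    """
    names = [f.name for f in _circle_sorted(table)]
    if not names:
        return ()
    if anchor in names:
        k = names.index(anchor)
    else:
        k = names.index(min(names))
    return tuple(names[k:] + names[:k])
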