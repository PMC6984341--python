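"""Scleractinian (stony coral) mitogenome preset and published reference data.

Scleractinian mitochondrial genomes are circular molecules of roughly
16.5-18 kb carrying 13 protein-coding genes (PCGs), two tRNAs (Met, Trp) and
two rRNAs, all encoded on the heavy (H) strand.  ND5 is split by a large
group-I-type intron: its 5' exon sits early on the circle, the 3' exon near
the end, and ten PCGs plus the 12S rRNA lie inside the intron.

The preset below encodes the gene order, sizes, start/stop codons and
intergenic spacers reported for the deposited Merulinidae accessions
MH119077 (*Dipsastraea rotumana*), KY247139 (*Favites pentagona*) and
MH086217 (*Hydnophora exesa*); where the published annotation gives a range
across the three species a single representative value is used.  The
published whole-genome base compositions of these and eleven related
scleractinians are kept here as a reference dataset for validating the skew
statistics.
"""

from __future__ import annotations

from types import MappingProxyType

#: Canonical gene order around the circle, anchored at tRNA-Met.
GENE_ORDER: tuple[str, ...] = (
    "tRNA-Met",
    "16S rRNA",
    "ND5-5prime",
    "ND1",
    "CYTB",
    "ND2",
    "ND6",
    "ATP6",
    "ND4",
    "12S rRNA",
    "COIII",
    "COII",
    "ND4L",
    "ND3",
    "ND5-3prime",
    "tRNA-Trp",
    "ATP8",
    "COI",
)

#: Feature class of every preset gene.
GENE_TYPES: MappingProxyType[str, str] = MappingProxyType({
    "tRNA-Met": "tRNA",
    "16S rRNA": "rRNA",
    "ND5-5prime": "PCG",
    "ND1": "PCG",
    "CYTB": "PCG",
    "ND2": "PCG",
    "ND6": "PCG",
    "ATP6": "PCG",
    "ND4": "PCG",
    "12S rRNA": "rRNA",
    "COIII": "PCG",
    "COII": "PCG",
    "ND4L": "PCG",
    "ND3": "PCG",
    "ND5-3prime": "PCG",
    "tRNA-Trp": "tRNA",
    "ATP8": "PCG",
    "COI": "PCG",
})

#: Gene sizes in bp.  Ranges in the published annotation are collapsed to a
#: representative value (16S rRNA 1698-1699 -> 1699; tRNA-Trp 70-71 -> 71).
GENE_SIZES: MappingProxyType[str, int] = MappingProxyType({
    "tRNA-Met": 72,
    "16S rRNA": 1699,
    "ND5-5prime": 711,
    "ND1": 948,
    "CYTB": 1140,
    "ND2": 1287,
    "ND6": 561,
    "ATP6": 678,
    "ND4": 1440,
    "12S rRNA": 911,
    "COIII": 780,
    "COII": 708,
    "ND4L": 300,
    "ND3": 342,
    "ND5-3prime": 1104,
    "tRNA-Trp": 71,
    "ATP8": 198,
    "COI": 1590,
})

#: Signed intergenic gap (bp) from each gene to the NEXT gene on the circle;
#: negative values are overlaps.  Ranges are collapsed to their (rounded)
#: midpoints; the COI -> tRNA-Met wrap gap uses the nonnegative midpoint.
INTERGENIC_AFTER: MappingProxyType[str, int] = MappingProxyType({
    "tRNA-Met": 1061,
    "16S rRNA": 96,
    "ND5-5prime": 24,
    "ND1": 110,
    "CYTB": 2,
    "ND2": 25,
    "ND6": 1,
    "ATP6": -1,
    "ND4": -1,
    "12S rRNA": 123,
    "COIII": 96,
    "COII": 670,
    "ND4L": -19,
    "ND3": 2,
    "ND5-3prime": 56,
    "tRNA-Trp": -2,
    "ATP8": 3,
    "COI": 362,
})

#: Start codon of each PCG (COIII uses GTG, ND2 uses ATA, the rest ATG;
#: the ND5 3' exon continues an upstream reading frame and has none).
START_CODONS: MappingProxyType[str, str] = MappingProxyType({
    "ND5-5prime": "ATG",
    "ND1": "ATG",
    "CYTB": "ATG",
    "ND2": "ATA",
    "ND6": "ATG",
    "ATP6": "ATG",
    "ND4": "ATG",
    "COIII": "GTG",
    "COII": "ATG",
    "ND4L": "ATG",
    "ND3": "ATG",
    "ATP8": "ATG",
    "COI": "ATG",
})

#: Stop codon terminating each PCG (the ND5 5' exon is interrupted by the
#: intron and has none; ND1, ND4 and ND5 use TAG, the other ten use TAA).
STOP_CODONS: MappingProxyType[str, str] = MappingProxyType({
    "ND1": "TAG",
    "CYTB": "TAA",
    "ND2": "TAA",
    "ND6": "TAA",
    "ATP6": "TAA",
    "ND4": "TAG",
    "COIII": "TAA",
    "COII": "TAA",
    "ND4L": "TAA",
    "ND3": "TAA",
    "ND5-3prime": "TAG",
    "ATP8": "TAA",
    "COI": "TAA",
})

#: Whole-genome base-composition target (percent), matching the reported
#: *D. rotumana* composition: T-rich, A second, C least common.
TARGET_PCT: MappingProxyType[str, float] = MappingProxyType({
    "A": 25.2,
    "T": 41.6,
    "G": 20.3,
    "C": 12.9,
})

#: Published protein lengths (aa) for the PCG rows of the deposited
#: annotations; None marks non-coding rows.  Note the published ND5 5' row
#: (711 bp, 236 aa) is arithmetically inconsistent: 711/3 = 237 codons.
PUBLISHED_AA: MappingProxyType[str, int | None] = MappingProxyType({
    "tRNA-Met": None,
    "16S rRNA": None,
    "ND5-5prime": 236,
    "ND1": 315,
    "CYTB": 379,
    "ND2": 428,
    "ND6": 186,
    "ATP6": 225,
    "ND4": 479,
    "12S rRNA": None,
    "COIII": 259,
    "COII": 235,
    "ND4L": 99,
    "ND3": 113,
    "ND5-3prime": 367,
    "tRNA-Trp": None,
    "ATP8": 65,
    "COI": 529,
})

#: Published concatenated 13-PCG protein length (aa) for the three focal
#: accessions (sum of the published per-gene aa column above).
PUBLISHED_CONCAT_AA: int = 3915

#: Published whole-genome compositions of 14 scleractinian mitogenomes:
#: accession -> (species, length_bp, A%, T%, C%, G%, AT-skew, GC-skew).
PUBLISHED_COMPOSITIONS: MappingProxyType[str, tuple] = MappingProxyType({
    "NC_008161": ("Astrangia poculata", 14853, 25.2, 42.9, 12.2, 19.7, -0.259, 0.233),
    "NC_008162": ("Colpophyllia natans", 16906, 24.9, 41.5, 13.2, 20.3, -0.250, 0.211),
    "KY094484": ("Cyphastrea serailia", 17138, 25.0, 41.4, 13.0, 20.5, -0.247, 0.225),
    "MG792550": ("Echinophyllia aspera", 17697, 25.3, 40.6, 13.4, 20.7, -0.231, 0.212),
    "NC_035879": ("Favites abdita", 17825, 25.0, 41.2, 13.3, 20.5, -0.245, 0.213),
    "KY247139": ("Favites pentagona", 18006, 25.3, 41.1, 13.3, 20.2, -0.238, 0.206),
    "MH119077": ("Dipsastraea rotumana", 16466, 25.2, 41.6, 12.9, 20.3, -0.246, 0.221),
    "MH086217": ("Hydnophora exesa", 17790, 25.0, 41.7, 13.0, 20.4, -0.251, 0.224),
    "NC_008163": ("Mussa angulosa", 17245, 25.1, 41.2, 13.4, 20.3, -0.242, 0.203),
    "NC_007224": ("Orbicella annularis", 16138, 24.9, 41.5, 13.1, 20.4, -0.251, 0.217),
    "NC_007226": ("Orbicella faveolata", 16138, 24.9, 41.5, 13.2, 20.4, -0.250, 0.217),
    "NC_007225": ("Orbicella franksi", 16137, 24.9, 41.5, 13.2, 20.4, -0.250, 0.215),
    "NC_020049": ("Platygyra carnosa", 16463, 25.6, 41.4, 12.8, 20.1, -0.236, 0.222),
    "FO904931": ("Sclerophyllia maxima", 18168, 25.3, 41.0, 13.1, 20.6, -0.237, 0.221),
})

#: The three newly deposited focal accessions and their genome lengths (bp).
FOCAL_ACCESSIONS: MappingProxyType[str, tuple[str, int]] = MappingProxyType({
    "MH119077": ("Dipsastraea rotumana", 16466),
    "KY247139": ("Favites pentagona", 18006),
    "MH086217": ("Hydnophora exesa", 17790),
})

#: Accessions whose printed skews are exactly reproducible from their printed
#: percentages at 3 decimals (rounding-consistent rows of the reference set).
ROUNDING_CONSISTENT_ACCESSIONS: tuple[str, ...] = (
    "KY247139",   # Favites pentagona
    "NC_035879",  # Favites abdita
    "NC_020049",  # Platygyra carnosa
)

#: The 13 PCGs in circle order with the two ND5 exons joined, used for
#: supermatrix concatenation and per-gene Ka/Ks.
PCG_CONCAT_ORDER: tuple[str, ...] = (
    "ND5",
    "ND1",
    "CYTB",
    "ND2",
    "ND6",
    "ATP6",
    "ND4",
    "COIII",
    "COII",
    "ND4L",
    "ND3",
    "ATP8",
    "COI",
)
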