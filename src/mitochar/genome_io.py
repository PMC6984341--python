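"""Annotated mitogenome I/O and circular coordinate handling.

Coordinates follow the GenBank convention: 1-based, inclusive.  Because the
molecule is circular, a segment may run through the origin; this is encoded
as ``end > length_bp`` (e.g. segment ``(16400, 16500)`` on a 16,466 bp
genome covers the last 67 bases and the first 34).  Multi-segment features
(the intron-split ND5) list their exons in biological order and are joined
in that order when the coding sequence is extracted.

Reading and writing of GenBank flat files is delegated to Biopython; this
module maps GenBank features onto the standardized gene names used
throughout the package and preserves join coordinates as multi-segment
features.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import FeatureError, GenomeParseError

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")

FEATURE_TYPES = ("PCG", "tRNA", "rRNA")

#: Standardized gene names recognized by the pipeline.
CANONICAL_NAMES = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND5-5prime", "ND5-3prime",
    "ND6", "COI", "COII", "COIII", "ATP6", "ATP8", "CYTB",
    "tRNA-Met", "tRNA-Trp", "12S rRNA", "16S rRNA",
)

_ALIASES = {
    "nd1": "ND1", "nad1": "ND1", "nd2": "ND2", "nad2": "ND2",
    "nd3": "ND3", "nad3": "ND3", "nd4": "ND4", "nad4": "ND4",
    "nd4l": "ND4L", "nad4l": "ND4L", "nd5": "ND5", "nad5": "ND5",
    "nd6": "ND6", "nad6": "ND6",
    "nd55prime": "ND5-5prime", "nd55": "ND5-5prime",
    "nd53prime": "ND5-3prime", "nd53": "ND5-3prime",
    "coi": "COI", "co1": "COI", "cox1": "COI", "coxi": "COI",
    "coii": "COII", "co2": "COII", "cox2": "COII", "coxii": "COII",
    "coiii": "COIII", "co3": "COIII", "cox3": "COIII", "coxiii": "COIII",
    "atp6": "ATP6", "atpase6": "ATP6", "atp8": "ATP8", "atpase8": "ATP8",
    "cytb": "CYTB", "cob": "CYTB", "cytochromeb": "CYTB",
    "trnm": "tRNA-Met", "trnamet": "tRNA-Met", "trnmcat": "tRNA-Met",
    "trnw": "tRNA-Trp", "trnatrp": "tRNA-Trp", "trnwtca": "tRNA-Trp",
    "rrns": "12S rRNA", "12srrna": "12S rRNA", "12sribosomalrna": "12S rRNA",
    "srrna": "12S rRNA", "smallsubunitribosomalrna": "12S rRNA",
    "rrnl": "16S rRNA", "16srrna": "16S rRNA", "16sribosomalrna": "16S rRNA",
    "lrrna": "16S rRNA", "largesubunitribosomalrna": "16S rRNA",
}


def standardize_name(raw: str) -> str | None:
    """Map a free-form gene/product label onto a canonical name.

    Returns ``None`` when the label is not recognized.
    """
    key = re.sub(r"[\s_\-'.()]", "", raw).lower()
    key = key.replace("′", "prime").replace("prime", "prime")
    if key in _ALIASES:
        return _ALIASES[key]
    # already canonical?
    for name in CANONICAL_NAMES:
        if key == re.sub(r"[\s_\-]", "", name).lower():
            return name
    return None


@dataclass(frozen=True)
class MitoGenome:
    """A circular mitochondrial genome sequence with minimal metadata."""

    sequence: str
    accession: str = "SYNMITO"
    organism: str = ""
    is_circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise GenomeParseError("genome sequence is empty")
        bad = set(seq) - _ALPHABET
        if bad:
            raise GenomeParseError(
                f"sequence of {self.accession} contains non-ACGTN characters: "
                f"{sorted(bad)}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A named, typed, possibly multi-segment annotation on the circle.

    ``segments`` are (start, end) pairs, 1-based inclusive; an end beyond the
    genome length wraps through the origin.  Segments are joined in list
    order to form the coding sequence.
    """

    name: str
    ftype: str
    strand: str = "H"
    segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise FeatureError(
                f"{self.name}: feature type must be one of {FEATURE_TYPES}, "
                f"got {self.ftype!r}"
            )
        if self.strand not in ("H", "L"):
            raise FeatureError(f"{self.name}: strand must be 'H' or 'L'")
        segs = tuple((int(s), int(e)) for s, e in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise FeatureError(f"{self.name}: feature has no segments")
        for s, e in segs:
            if s < 1:
                raise FeatureError(f"{self.name}: segment start {s} < 1")
            if e < s:
                raise FeatureError(
                    f"{self.name}: segment end {e} precedes start {s}"
                )

    @property
    def start(self) -> int:
        """Start of the first segment (circle-order sort key)."""
        return self.segments[0][0]

    @property
    def end(self) -> int:
        """End of the last segment (may exceed the genome length)."""
        return self.segments[-1][1]

    @property
    def span_length(self) -> int:
        """Total extracted length: sum of segment lengths."""
        return sum(e - s + 1 for s, e in self.segments)


@dataclass
class FeatureTable:
    """Ordered gene annotations of one genome, sorted by circle position."""

    genome_ref: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise FeatureError(
                f"{self.genome_ref}: duplicate feature names {sorted(dupes)}"
            )
        self.features = sorted(self.features, key=lambda f: f.start)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]


def nd5_joined(table: FeatureTable) -> GeneFeature:
    """Derive the virtual joined ND5 feature from its two exon features.

    The intron itself is never a stored feature; translation of ND5 uses
    this joined feature.  If the table already carries a single (possibly
    multi-segment) ``ND5`` feature it is returned as-is.
    """
    try:
        return table.get("ND5")
    except KeyError:
        pass
    try:
        five = table.get("ND5-5prime")
        three = table.get("ND5-3prime")
    except KeyError as exc:
        raise FeatureError(
            f"{table.genome_ref}: no ND5 annotation (need ND5 or "
            f"ND5-5prime + ND5-3prime)"
        ) from exc
    return GeneFeature(
        name="ND5", ftype="PCG", strand=five.strand,
        segments=five.segments + three.segments,
    )


def _validate_segment(genome: MitoGenome, name: str, s: int, e: int) -> None:
    if e > 2 * genome.length_bp:
        raise FeatureError(
            f"{name}: coordinate {e} beyond twice the genome length "
            f"({genome.length_bp} bp)"
        )


def extract_feature(genome: MitoGenome, feature: GeneFeature) -> str:
    """Extract a feature's sequence, joining segments and wrapping the origin.

    Strand L features are reverse-complemented after joining.
    """
    length = genome.length_bp
    parts: list[str] = []
    for s, e in feature.segments:
        _validate_segment(genome, feature.name, s, e)
        if e <= length:
            parts.append(genome.sequence[s - 1:e])
        else:
            parts.append(genome.sequence[s - 1:] + genome.sequence[:e - length])
    joined = "".join(parts)
    if feature.strand == "L":
        joined = str(Seq(joined).reverse_complement())
    return joined


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

def _merge_wrap(segments: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    """Merge an (x..length),(1..y) split back into the end>length encoding."""
    merged: list[tuple[int, int]] = []
    i = 0
    while i < len(segments):
        s, e = segments[i]
        if (e == length and i + 1 < len(segments)
                and segments[i + 1][0] == 1 and s != 1):
            merged.append((s, length + segments[i + 1][1]))
            i += 2
        else:
            merged.append((s, e))
            i += 1
    return merged


def read_genbank(path: str | Path) -> tuple[MitoGenome, FeatureTable]:
    """Read a single-record GenBank flat file into pipeline types.

    CDS/tRNA/rRNA features are mapped onto standardized names; features with
    unrecognizable names are skipped with a logged warning.  Join
    coordinates are preserved as multi-segment features.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise GenomeParseError(f"{path}: not a single-record GenBank file: {exc}") from exc
    try:
        seq = str(record.seq)
    except Exception as exc:  # undefined sequence (no ORIGIN block)
        raise GenomeParseError(f"{path}: record has no ORIGIN sequence") from exc
    if not seq:
        raise GenomeParseError(f"{path}: record has an empty ORIGIN sequence")
    genome = MitoGenome(
        sequence=seq,
        accession=record.id if record.id != "<unknown id>" else record.name,
        organism=record.annotations.get("organism", ""),
        is_circular=record.annotations.get("topology", "circular") == "circular",
    )
    gb_type_map = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}
    feats: list[GeneFeature] = []
    for f in record.features:
        if f.type not in gb_type_map:
            continue
        label = (f.qualifiers.get("gene") or f.qualifiers.get("product") or [""])[0]
        name = standardize_name(label) if label else None
        if name is None:
            logger.warning(
                "%s: skipping %s feature with unrecognized gene name %r",
                path.name, f.type, label,
            )
            continue
        segs = [(int(p.start) + 1, int(p.end)) for p in f.location.parts]
        segs = _merge_wrap(segs, genome.length_bp)
        strand = "L" if f.location.strand == -1 else "H"
        feats.append(GeneFeature(name=name, ftype=gb_type_map[f.type],
                                 strand=strand, segments=tuple(segs)))
    if not feats:
        logger.warning("%s: no annotated gene features found", path.name)
    return genome, FeatureTable(genome_ref=genome.accession, features=feats)


def write_genbank(genome: MitoGenome, table: FeatureTable,
                  path: str | Path) -> None:
    """Write a minimally valid single-record GenBank flat file.

    The output round-trips through :func:`read_genbank` identically at the
    feature level.  Wrap-around segments are emitted as GenBank joins.
    """
    gb_type_map = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession,
        name=genome.accession[:16].replace(" ", "_"),
        description=f"{genome.organism} mitochondrion, complete genome".strip(),
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.is_circular else "linear"
    record.annotations["organism"] = genome.organism
    record.annotations["source"] = genome.organism
    length = genome.length_bp
    for feat in table:
        locs: list[SimpleLocation] = []
        strand = -1 if feat.strand == "L" else 1
        for s, e in feat.segments:
            if e <= length:
                locs.append(SimpleLocation(s - 1, e, strand=strand))
            else:  # split a wrap-around segment into a GenBank join
                locs.append(SimpleLocation(s - 1, length, strand=strand))
                locs.append(SimpleLocation(0, e - length, strand=strand))
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [feat.name]}
        if feat.ftype == "PCG":
            qualifiers["transl_table"] = ["4"]
        record.features.append(
            SeqFeature(location, type=gb_type_map[feat.ftype],
                       qualifiers=qualifiers)
        )
    SeqIO.write([record], str(path), "genbank")


def write_fasta(genome: MitoGenome, path: str | Path) -> None:
    """Write the bare genome sequence as FASTA."""
    record = SeqRecord(Seq(genome.sequence), id=genome.accession,
                       description=genome.organism)
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path: str | Path, is_circular: bool = True) -> MitoGenome:
    """Read a bare genome sequence from a single-record FASTA."""
    record = SeqIO.read(str(path), "fasta")
    return MitoGenome(sequence=str(record.seq), accession=record.id,
                      organism=record.description.partition(" ")[2],
                      is_circular=is_circular)


# ---------------------------------------------------------------------------
# Feature TSV dialect
# ---------------------------------------------------------------------------

_SEGMENT_RE = re.compile(r"^(\d+)\.\.(\d+)$")


def read_feature_tsv(genome: MitoGenome, path: str | Path) -> FeatureTable:
    """Read a tab-separated feature table.

    Columns: ``name``, ``ftype``, ``strand``, ``segments`` where segments are
    encoded ``start..end[,start..end]`` (1-based inclusive; an end beyond the
    genome length wraps through the origin).  Lines starting with ``#`` and
    an optional header line are skipped.
    """
    path = Path(path)
    feats: list[GeneFeature] = []
    with open(path, encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("name\t"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FeatureError(
                    f"{path.name}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(cols)}"
                )
            name, ftype, strand, segstr = (c.strip() for c in cols)
            segments: list[tuple[int, int]] = []
            for token in segstr.split(","):
                m = _SEGMENT_RE.match(token.strip())
                if not m:
                    raise FeatureError(
                        f"{path.name}:{lineno}: malformed segment {token!r} "
                        f"(expected 'start..end')"
                    )
                s, e = int(m.group(1)), int(m.group(2))
                if e > 2 * genome.length_bp:
                    raise FeatureError(
                        f"{path.name}:{lineno}: coordinate {e} beyond twice "
                        f"the genome length ({genome.length_bp} bp)"
                    )
                segments.append((s, e))
            try:
                feats.append(GeneFeature(name=name, ftype=ftype, strand=strand,
                                         segments=tuple(segments)))
            except FeatureError as exc:
                raise FeatureError(f"{path.name}:{lineno}: {exc}") from exc
    return FeatureTable(genome_ref=genome.accession, features=feats)


def write_feature_tsv(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table in the TSV dialect read by :func:`read_feature_tsv`."""
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("name\tftype\tstrand\tsegments\n")
        for f in table:
            segs = ",".join(f"{s}..{e}" for s, e in f.segments)
            fh.write(f"{f.name}\t{f.ftype}\t{f.strand}\t{segs}\n")
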