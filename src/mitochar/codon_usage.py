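"""Translation and codon-usage statistics under the coelenterate mt code.

The default genetic code is NCBI translation table 4 (mold / protozoan /
coelenterate mitochondrial), under which TGA encodes Trp rather than STOP
and only TAA/TAG terminate.  Scleractinian PCGs initiate at ATG, ATA or
GTG; other table-4 starts are flagged as non-canonical.

RSCU (relative synonymous codon usage) of a codon is its observed count
divided by the mean count of its synonymous family:

    RSCU(c) = count(c) * k / sum(counts over the k synonymous codons)

so RSCU = 1 means no bias.  Six-fold degenerate families (Leu, Ser, Arg)
are treated as single families of size six.  Stop codons are excluded;
codons of families never observed are reported as NA to distinguish
"unused" from "impossible".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable as _NCBICodonTable

from .errors import TranslationError

STOP = "*"

#: Start codons observed in scleractinian mitogenomes.
CANONICAL_START_CODONS = frozenset({"ATG", "ATA", "GTG"})

_BASES = "TCAG"
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)


@dataclass(frozen=True)
class CodonTable:
    """A genetic code: 64 codon->amino-acid assignments plus start codons."""

    table_id: int
    codon_to_aa: Mapping[str, str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise TranslationError(
                f"genetic code must map 64 codons, got {len(self.codon_to_aa)}"
            )

    @classmethod
    def from_ncbi(cls, table_id: int = 4) -> "CodonTable":
        ncbi = _NCBICodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(ncbi.forward_table)
        for stop in ncbi.stop_codons:
            mapping[stop] = STOP
        return cls(table_id=table_id,
                   codon_to_aa=mapping,
                   start_codons=frozenset(ncbi.start_codons))

    def aa(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, a in self.codon_to_aa.items() if a == STOP)

    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families: amino acid -> codons (stops excluded)."""
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = self.codon_to_aa[codon]
            if aa == STOP:
                continue
            fams.setdefault(aa, []).append(codon)
        return {aa: tuple(cs) for aa, cs in fams.items()}


DEFAULT_TABLE = CodonTable.from_ncbi(4)


def codons_of(cds: str) -> list[str]:
    """Split a CDS into codons, requiring length divisible by 3."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise TranslationError(
            f"CDS length {len(cds)} is not a multiple of 3"
        )
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def translate(cds: str, table: CodonTable = DEFAULT_TABLE,
              require_terminal_stop: bool = False) -> str:
    """Translate a CDS, excluding the terminal stop codon if present.

    For a stop-terminated CDS the protein length is len/3 - 1.  An internal
    stop raises :class:`TranslationError` naming the codon index (1-based).
    """
    codon_list = codons_of(cds)
    if not codon_list:
        raise TranslationError("empty CDS")
    protein: list[str] = []
    for i, codon in enumerate(codon_list):
        aa = table.aa(codon)
        if aa == STOP:
            if i == len(codon_list) - 1:
                return "".join(protein)
            raise TranslationError(
                f"internal stop codon {codon} at codon {i + 1}"
            )
        protein.append(aa)
    if require_terminal_stop:
        raise TranslationError(
            f"CDS does not end in a stop codon (last codon {codon_list[-1]})"
        )
    return "".join(protein)


@dataclass(frozen=True)
class StartStopInfo:
    """Literal first/last codons of a CDS with convention flags."""

    start_codon: str
    stop_codon: str | None
    canonical_start: bool


def detect_start_stop(cds: str, table: CodonTable = DEFAULT_TABLE,
                      ) -> StartStopInfo:
    """Report a CDS's start codon and terminal stop (None when absent).

    Non-canonical starts and absent stops are flagged, not failed: the ND5
    5' exon legitimately ends without a stop (the intron interrupts it).
    """
    if len(cds) < 6:
        raise TranslationError("CDS shorter than two codons")
    codon_list = codons_of(cds)
    start = codon_list[0]
    last = codon_list[-1]
    return StartStopInfo(
        start_codon=start,
        stop_codon=last if table.is_stop(last) else None,
        canonical_start=start in CANONICAL_START_CODONS,
    )


@dataclass(frozen=True)
class CodonCounts:
    """Per-codon tallies over one or more CDSs (terminal stops excluded)."""

    counts: Mapping[str, int]
    n_codons: int

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = Counter(self.counts) + Counter(other.counts)
        return CodonCounts(counts=dict(merged),
                           n_codons=self.n_codons + other.n_codons)


def count_codons(cds: str, table: CodonTable = DEFAULT_TABLE) -> CodonCounts:
    """Tally the codons of one CDS, excluding its terminal stop."""
    codon_list = codons_of(cds)
    translate(cds, table)  # validates internal stops
    if codon_list and table.is_stop(codon_list[-1]):
        codon_list = codon_list[:-1]
    counts = Counter(codon_list)
    return CodonCounts(counts=dict(counts), n_codons=sum(counts.values()))


def pooled_codon_counts(cds_list: Sequence[str],
                        table: CodonTable = DEFAULT_TABLE) -> CodonCounts:
    """Pool codon tallies over a gene set (terminal stops excluded)."""
    if not cds_list:
        raise TranslationError("no coding sequences to pool")
    total = CodonCounts(counts={}, n_codons=0)
    for cds in cds_list:
        total = total + count_codons(cds, table)
    return total


@dataclass(frozen=True)
class RSCUTable:
    """RSCU per codon (None = NA for zero-count families)."""

    rscu: Mapping[str, float | None]
    family_of: Mapping[str, str]

    def to_dataframe(self, counts: CodonCounts | None = None) -> pd.DataFrame:
        rows = []
        for codon in sorted(self.family_of, key=lambda c: (self.family_of[c], c)):
            row = {"codon": codon, "aa": self.family_of[codon],
                   "RSCU": self.rscu[codon]}
            if counts is not None:
                row["count"] = counts.counts.get(codon, 0)
            rows.append(row)
        cols = ["codon", "aa"] + (["count"] if counts is not None else []) + ["RSCU"]
        return pd.DataFrame(rows)[cols]


def rscu(counts: CodonCounts, table: CodonTable = DEFAULT_TABLE) -> RSCUTable:
    """Relative synonymous codon usage from pooled codon counts.

    Within every family with a non-zero total, the mean RSCU is 1 and the
    RSCU values sum to the family size.
    """
    if counts.n_codons <= 0:
        raise TranslationError("RSCU requires at least one counted codon")
    values: dict[str, float | None] = {}
    family_of: dict[str, str] = {}
    for aa, codons in table.families().items():
        total = sum(counts.counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            family_of[c] = aa
            values[c] = None if total == 0 else counts.counts.get(c, 0) * k / total
    return RSCUTable(rscu=values, family_of=family_of)
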