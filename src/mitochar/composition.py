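"""Base composition and strand-asymmetry (skew) statistics.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C), computed on
counts; both lie in [-1, 1] and are undefined (``None``) when the
denominator is zero.  Ambiguity code N is excluded from both numerators and
denominators, so percentages are over known bases only.

Reported tables round percentages to 1 decimal and skews to 3 decimals
(half away from zero); full precision is retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .errors import CompositionError, TranslationError
from .genome_io import FeatureTable, MitoGenome

Region = Literal["whole", "PCG", "tRNA", "rRNA", "intergenic"]

REGIONS: tuple[str, ...] = ("whole", "PCG", "tRNA", "rRNA", "intergenic")


def round_report(x: float, decimals: int) -> float:
    """Round half away from zero, as printed tables conventionally do."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _skew(x: int | float, y: int | float) -> float | None:
    denom = x + y
    if denom == 0:
        return None
    return (x - y) / denom


@dataclass(frozen=True)
class CompositionProfile:
    """Base counts, percentages and skews for one sequence region."""

    counts: Mapping[str, int]
    n_effective: int
    pct: Mapping[str, float]
    at_skew: float | None
    gc_skew: float | None

    def rounded(self, pct_decimals: int = 1,
                skew_decimals: int = 3) -> "CompositionProfile":
        """Profile with percentages/skews rounded to report precision."""
        return CompositionProfile(
            counts=dict(self.counts),
            n_effective=self.n_effective,
            pct={b: round_report(p, pct_decimals) for b, p in self.pct.items()},
            at_skew=None if self.at_skew is None
            else round_report(self.at_skew, skew_decimals),
            gc_skew=None if self.gc_skew is None
            else round_report(self.gc_skew, skew_decimals),
        )

    @property
    def at_pct(self) -> float:
        return self.pct["A"] + self.pct["T"]

    @property
    def gc_pct(self) -> float:
        return self.pct["G"] + self.pct["C"]


def base_composition(seq: str) -> CompositionProfile:
    """Composition profile of a nucleotide sequence (N excluded)."""
    if not seq:
        raise CompositionError("cannot profile an empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    n_eff = sum(counts.values())
    if n_eff == 0:
        raise CompositionError(
            "composition undefined: sequence contains no unambiguous bases"
        )
    pct = {b: 100.0 * c / n_eff for b, c in counts.items()}
    return CompositionProfile(
        counts=counts,
        n_effective=n_eff,
        pct=pct,
        at_skew=_skew(counts["A"], counts["T"]),
        gc_skew=_skew(counts["G"], counts["C"]),
    )


def skew_from_percentages(a_pct: float, t_pct: float, g_pct: float,
                          c_pct: float) -> tuple[float | None, float | None]:
    """Skews computed directly from four base percentages.

    Utility for validating published composition tables; agrees with
    :func:`base_composition` exactly when the percentages are exact.
    """
    for p in (a_pct, t_pct, g_pct, c_pct):
        if p < 0:
            raise CompositionError("percentages must be non-negative")
    return _skew(a_pct, t_pct), _skew(g_pct, c_pct)


def _class_positions(genome: MitoGenome, table: FeatureTable,
                     ftype: str) -> set[int]:
    """Genomic positions (1-based, wrapped onto the circle) covered by a class.

    Positions shared by overlapping same-class features are counted once.
    """
    length = genome.length_bp
    positions: set[int] = set()
    for feat in table.of_type(ftype):
        for s, e in feat.segments:
            for i in range(s, e + 1):
                positions.add((i - 1) % length + 1)
    return positions


def region_sequence(genome: MitoGenome, table: FeatureTable,
                    region: str) -> str:
    """Concatenated (position-deduplicated) sequence of a region class."""
    region_l = region.lower()
    if region_l == "whole":
        return genome.sequence
    if region_l in ("pcg", "trna", "rrna"):
        ftype = {"pcg": "PCG", "trna": "tRNA", "rrna": "rRNA"}[region_l]
        positions = _class_positions(genome, table, ftype)
        if not positions:
            raise CompositionError(f"no features of class {ftype} annotated")
        return "".join(genome.sequence[i - 1] for i in sorted(positions))
    if region_l == "intergenic":
        covered: set[int] = set()
        for ftype in ("PCG", "tRNA", "rRNA"):
            covered |= _class_positions(genome, table, ftype)
        positions = [i for i in range(1, genome.length_bp + 1)
                     if i not in covered]
        if not positions:
            raise CompositionError("no intergenic positions on this genome")
        return "".join(genome.sequence[i - 1] for i in positions)
    raise CompositionError(f"unknown region class {region!r}")


def region_composition(genome: MitoGenome, table: FeatureTable,
                       region: str) -> CompositionProfile:
    """Composition of a whole genome or one annotation class.

    Class sequences are concatenated (each genomic position once) before
    counting; ``intergenic`` is the whole genome minus all annotated spans.
    """
    return base_composition(region_sequence(genome, table, region))


def codon_position_composition(
    cds_list: Sequence[str],
) -> tuple[CompositionProfile, CompositionProfile, CompositionProfile]:
    """Per-codon-position composition pooled over a list of CDSs."""
    if not cds_list:
        raise CompositionError("no coding sequences supplied")
    pooled = ["", "", ""]
    for idx, cds in enumerate(cds_list):
        if len(cds) % 3 != 0:
            raise TranslationError(
                f"CDS #{idx + 1} length {len(cds)} is not a multiple of 3"
            )
        for pos in range(3):
            pooled[pos] += cds[pos::3]
    return tuple(base_composition(p) for p in pooled)  # type: ignore[return-value]


def gc_content_windows(genome: MitoGenome, window: int = 200,
                       step: int = 50) -> pd.DataFrame:
    """Sliding-window GC% around the circle (wrap-aware), as a DataFrame."""
    seq = genome.sequence
    length = len(seq)
    rows = []
    for start in range(0, length, step):
        chunk = seq[start:start + window]
        if len(chunk) < window:
            chunk += seq[:window - len(chunk)]
        prof = base_composition(chunk)
        rows.append({"start": start + 1, "gc_pct": prof.gc_pct})
    return pd.DataFrame(rows)


def composition_table(genome: MitoGenome, table: FeatureTable,
                      regions: Iterable[str] = REGIONS,
                      pct_decimals: int = 1,
                      skew_decimals: int = 3) -> pd.DataFrame:
    """Tabulate composition per region in the published layout."""
    rows = []
    for region in regions:
        prof = region_composition(genome, table, region).rounded(
            pct_decimals, skew_decimals)
        rows.append({
            "region": region,
            "A_pct": prof.pct["A"], "T_pct": prof.pct["T"],
            "C_pct": prof.pct["C"], "G_pct": prof.pct["G"],
            "AT_skew": prof.at_skew, "GC_skew": prof.gc_skew,
        })
    return pd.DataFrame(rows)
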