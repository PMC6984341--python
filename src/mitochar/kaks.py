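"""Pairwise Ka/Ks by the Nei-Gojobori (1986) counting method.

For each codon, every nucleotide position contributes the fraction of its
three possible single-base changes that are synonymous; summing gives the
synonymous site count S, with N = 3*codons - S (changes creating a stop
codon count as nonsynonymous).  Differences between two codons are
classified directly when they differ at one position; codons differing at
two or three positions are averaged over all mutational pathways (2 or 6
orderings), with pathways passing through a stop codon excluded and the
remainder reweighted (if every pathway crosses a stop, all are kept).

Proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits with
the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p); a proportion >= 3/4 is
flagged as saturated.  The ratio Ka/Ks is reported only when Ks > 0.

Gene pairs are compared ungapped: a length mismatch is an error, not an
alignment trigger (the three focal mitogenomes have length-identical PCGs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import pandas as pd

from .codon_usage import STOP, CodonTable, DEFAULT_TABLE, codons_of
from .errors import AlignmentError, TranslationError
from .genome_io import FeatureTable, MitoGenome, extract_feature, nd5_joined
from .presets import PCG_CONCAT_ORDER

_NT = "ACGT"


@lru_cache(maxsize=None)
def _syn_fraction_by_position(codon: str, table_id: int) -> tuple[float, ...]:
    """Fraction of the 3 single-base changes at each position that are
    synonymous (changes to stop codons are nonsynonymous)."""
    table = CodonTable.from_ncbi(table_id)
    aa = table.aa(codon)
    if aa == STOP:
        raise TranslationError(f"cannot count sites of stop codon {codon}")
    fracs = []
    for pos in range(3):
        syn = 0
        for base in _NT:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if table.aa(mutant) == aa:  # stop maps to '*', never equal
                syn += 1
        fracs.append(syn / 3)
    return tuple(fracs)


def count_sites(cds: str, table: CodonTable = DEFAULT_TABLE,
                ) -> tuple[float, float]:
    """Synonymous (S) and nonsynonymous (N) site counts of one CDS.

    The terminal stop codon must be removed beforehand; S + N = 3 * codons.
    """
    codon_list = codons_of(cds)
    s_total = 0.0
    for i, codon in enumerate(codon_list):
        if table.is_stop(codon):
            raise TranslationError(f"stop codon {codon} at codon {i + 1}")
        s_total += sum(_syn_fraction_by_position(codon, table.table_id))
    return s_total, 3 * len(codon_list) - s_total


@lru_cache(maxsize=None)
def _codon_pair_differences(c1: str, c2: str, table_id: int,
                            ) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) difference counts for one codon pair."""
    table = CodonTable.from_ncbi(table_id)
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0
    paths: list[tuple[int, int, bool]] = []  # (syn steps, nonsyn steps, crosses stop)
    for order in permutations(diff_positions):
        current = c1
        syn = nonsyn = 0
        crosses_stop = False
        for step, pos in enumerate(order):
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if table.is_stop(nxt) and step < len(order) - 1:
                crosses_stop = True  # intermediate codon is a stop
            if (not table.is_stop(current) and not table.is_stop(nxt)
                    and table.aa(current) == table.aa(nxt)):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        paths.append((syn, nonsyn, crosses_stop))
    valid = [p for p in paths if not p[2]]
    if not valid:  # all pathways cross stops: keep all
        valid = paths
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def count_differences(cds1: str, cds2: str,
                      table: CodonTable = DEFAULT_TABLE,
                      ) -> tuple[float, float]:
    """Pathway-averaged synonymous (Sd) and nonsynonymous (Nd) differences."""
    if len(cds1) != len(cds2):
        raise AlignmentError(
            f"sequence lengths differ ({len(cds1)} vs {len(cds2)}); "
            f"align externally before comparing"
        )
    sd_total = nd_total = 0.0
    for c1, c2 in zip(codons_of(cds1), codons_of(cds2)):
        sd, nd = _codon_pair_differences(c1, c2, table.table_id)
        sd_total += sd
        nd_total += nd
    return sd_total, nd_total


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - (4.0 / 3.0) * p)


@dataclass(frozen=True)
class KaKsResult:
    """Site counts, difference counts and corrected rates for one gene pair.

    ``ratio`` is Ka/Ks, defined only when Ks > 0; ``saturated_s`` /
    ``saturated_n`` flag a Jukes-Cantor saturation (p >= 3/4) on the
    corresponding rate, which is then None.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    saturated_s: bool = False
    saturated_n: bool = False


def _strip_terminal_stop(cds: str, table: CodonTable) -> str:
    codon_list = codons_of(cds)
    if codon_list and table.is_stop(codon_list[-1]):
        return cds[:-3]
    return cds


def ng86(cds1: str, cds2: str, table: CodonTable = DEFAULT_TABLE,
         strip_stop: bool = True) -> KaKsResult:
    """Nei-Gojobori Ka/Ks with Jukes-Cantor correction for one gene pair.

    Terminal stop codons are stripped (when present on both) before
    analysis; site counts are averaged over the two sequences.  The result
    is symmetric in its arguments.
    """
    if len(cds1) != len(cds2):
        raise AlignmentError(
            f"sequence lengths differ ({len(cds1)} vs {len(cds2)})"
        )
    if strip_stop:
        cds1 = _strip_terminal_stop(cds1, table)
        cds2 = _strip_terminal_stop(cds2, table)
        if len(cds1) != len(cds2):
            raise AlignmentError(
                "one sequence is stop-terminated and the other is not"
            )
    s1, _ = count_sites(cds1, table)
    s2, _ = count_sites(cds2, table)
    n_codons = len(cds1) // 3
    s_avg = (s1 + s2) / 2
    n_avg = 3 * n_codons - s_avg
    sd, nd = count_differences(cds1, cds2, table)
    ps = sd / s_avg if s_avg > 0 else 0.0
    pn = nd / n_avg if n_avg > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    ratio = None
    if ks is not None and ka is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(
        S=s_avg, N=n_avg, Sd=sd, Nd=nd, pS=ps, pN=pn,
        Ks=ks, Ka=ka, ratio=ratio,
        saturated_s=ks is None, saturated_n=ka is None,
    )


def _pcg_cds(genome: MitoGenome, table: FeatureTable, gene: str) -> str:
    feat = nd5_joined(table) if gene == "ND5" else table.get(gene)
    return extract_feature(genome, feat)


def kaks_table(a: tuple[MitoGenome, FeatureTable],
               b: tuple[MitoGenome, FeatureTable],
               genes: tuple[str, ...] = PCG_CONCAT_ORDER,
               code: CodonTable = DEFAULT_TABLE) -> pd.DataFrame:
    """Per-gene NG86 results for one genome pair, in concatenation order.

    Undefined rates/ratios appear as NaN (written "NA" by the CLI).
    """
    genome_a, feats_a = a
    genome_b, feats_b = b
    rows = []
    for gene in genes:
        res = ng86(_pcg_cds(genome_a, feats_a, gene),
                   _pcg_cds(genome_b, feats_b, gene), code)
        rows.append({
            "gene": gene, "S": res.S, "N": res.N, "Sd": res.Sd, "Nd": res.Nd,
            "Ka": res.Ka, "Ks": res.Ks, "ratio": res.ratio,
        })
    return pd.DataFrame(rows)
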