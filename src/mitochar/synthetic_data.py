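"""Seeded generator of scleractinian-style annotated mitogenomes.

The generator emulates the architecture shared by Merulinidae (and most
scleractinian) mitochondrial genomes: a circular molecule with 13 PCGs, two
tRNAs and two rRNAs all on the H strand, gene order anchored at tRNA-Met,
ND5 split into a 5' and a 3' exon by a group-I-type intron that contains
ten PCGs and the 12S rRNA, canonical start codons (ATG everywhere except
GTG for COIII and ATA for ND2), TAA/TAG stops, and a T-rich, C-poor base
composition (negative AT-skew, positive GC-skew).

Composition is steered, not imposed: codons are drawn with weights built
from per-position target base probabilities (with an extra T bias at
synonymous third positions), free (tRNA/rRNA/intergenic) bases are drawn to
make up the remaining target counts, and a short multiplicative calibration
loop repeats generation until the whole-genome composition is within half a
percentage point of the target (error if it cannot get within one point).
All randomness flows from one explicit seed; no global generator state.

Also provided: controlled mutation of a CDS with exact synonymous /
nonsynonymous counts (for Ka/Ks recovery experiments) and Jukes-Cantor
sequence evolution along a Newick tree (for tree-recovery experiments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np

from . import presets
from .codon_usage import ALL_CODONS, CodonTable, DEFAULT_TABLE, codons_of
from .errors import GenerationError, MitocharError
from .genome_io import FeatureTable, GeneFeature, MitoGenome, nd5_joined

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic mitogenome.

    Defaults reproduce the deposited Merulinidae annotations: gene sizes and
    signed intergenic spacers from the published summary table and the
    published *D. rotumana* whole-genome composition as the target.
    ``third_pos_t_bias`` multiplies the weight of T at synonymous third
    codon positions, reproducing the stronger T bias real mitogenomes show
    at third positions.
    """

    seed: int = 0
    gene_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(presets.GENE_SIZES))
    intergenic: Mapping[str, int] = field(
        default_factory=lambda: dict(presets.INTERGENIC_AFTER))
    target_pct: Mapping[str, float] = field(
        default_factory=lambda: dict(presets.TARGET_PCT))
    code_table: int = 4
    third_pos_t_bias: float = 1.6
    accession: str = "SYNMITO"
    organism: str = "synthetic scleractinian"
    max_rounds: int = 15

    def __post_init__(self) -> None:
        total = sum(self.target_pct.values())
        if abs(total - 100.0) > 1e-6:
            raise GenerationError(
                f"target percentages must sum to 100, got {total}")
        for gene, size in self.gene_sizes.items():
            if presets.GENE_TYPES.get(gene) == "PCG" and size % 3 != 0:
                raise GenerationError(
                    f"PCG size must be divisible by 3: {gene} = {size}")


@dataclass(frozen=True)
class MutationSpec:
    """Controlled substitution counts for :func:`mutate_cds`."""

    seed: int = 0
    k_syn: int = 0
    k_nonsyn: int = 0
    disjoint_sites: bool = True


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _layout(spec: GenomeSpec) -> tuple[list[GeneFeature], int]:
    """Place the preset gene order on the circle; return features + length."""
    feats: list[GeneFeature] = []
    pos = 1
    for gene in presets.GENE_ORDER:
        size = spec.gene_sizes[gene]
        feats.append(GeneFeature(
            name=gene, ftype=presets.GENE_TYPES[gene], strand="H",
            segments=((pos, pos + size - 1),),
        ))
        pos = pos + size + spec.intergenic[gene]
    length = pos - 1  # the last gap wraps back to position 1
    if length < max(f.end for f in feats):
        raise GenerationError("intergenic defaults fold the circle onto itself")
    return feats, length


def _coding_units(feats: list[GeneFeature]) -> list[tuple[str, np.ndarray]]:
    """0-based genomic positions of every coding unit, ND5 joined first."""
    by_name = {f.name: f for f in feats}
    units: list[tuple[str, np.ndarray]] = []
    order: list[tuple[str, tuple[tuple[int, int], ...]]] = []
    if "ND5-5prime" in by_name:
        order.append(("ND5", by_name["ND5-5prime"].segments
                      + by_name["ND5-3prime"].segments))
    for f in feats:
        if f.ftype == "PCG" and not f.name.startswith("ND5-"):
            order.append((f.name, f.segments))
    order.sort(key=lambda item: item[1][0][0])
    for name, segments in order:
        positions = np.concatenate([
            np.arange(s - 1, e) for s, e in segments
        ])
        units.append((name, positions))
    return units


def _fix_codon(seq: np.ndarray, positions: np.ndarray, codon: str,
               context: str) -> None:
    for p, base in zip(positions, codon):
        idx = _BASE_IDX[base]
        if seq[p] >= 0 and seq[p] != idx:
            raise GenerationError(
                f"conflicting fixed bases at position {p + 1} ({context})")
        seq[p] = idx


# ---------------------------------------------------------------------------
# codon sampling machinery
# ---------------------------------------------------------------------------

_CODON_ARRAY = np.array(
    [[_BASE_IDX[b] for b in codon] for codon in ALL_CODONS], dtype=np.int8)


def _codon_weights(target: np.ndarray, factors: np.ndarray,
                   t_bias: float, stops: set[int]) -> np.ndarray:
    """Weight per codon = product of per-position base probabilities."""
    pos_probs = []
    for pos in range(3):
        p = target * factors
        if pos == 2:
            p = p.copy()
            p[_BASE_IDX["T"]] *= t_bias
        pos_probs.append(p / p.sum())
    w = np.ones(64)
    for pos in range(3):
        w *= pos_probs[pos][_CODON_ARRAY[:, pos]]
    for s in stops:
        w[s] = 0.0
    return w


class _CodonSampler:
    """Draws codons matching fixed-base patterns, weighted, cached per pattern."""

    def __init__(self, weights: np.ndarray, stops: set[int]) -> None:
        self._weights = weights
        self._stops = stops
        self._cache: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]] = {}

    def draw(self, rng: np.random.Generator,
             pattern: tuple[int, int, int]) -> int:
        entry = self._cache.get(pattern)
        if entry is None:
            mask = np.ones(64, dtype=bool)
            for pos, want in enumerate(pattern):
                if want >= 0:
                    mask &= _CODON_ARRAY[:, pos] == want
            for s in self._stops:
                mask[s] = False
            cands = np.flatnonzero(mask)
            if cands.size == 0:
                raise GenerationError(
                    f"no stop-free codon matches fixed pattern {pattern}")
            w = self._weights[cands]
            if w.sum() <= 0:
                w = np.ones_like(w)
            entry = (cands, np.cumsum(w))
            self._cache[pattern] = entry
        cands, cumw = entry
        u = rng.random() * cumw[-1]
        return int(cands[np.searchsorted(cumw, u, side="right")])


def _generate_once(spec: GenomeSpec, feats: list[GeneFeature], length: int,
                   rng: np.random.Generator, factors: np.ndarray,
                   code: CodonTable) -> np.ndarray:
    """One generation pass; returns the base-index array."""
    stops = {ALL_CODONS.index(c) for c in code.stop_codons}
    seq = np.full(length, -1, dtype=np.int8)

    by_name = {f.name: f for f in feats}
    units = _coding_units(feats)
    # pre-fix start and stop codons so overlapping genes see them as constraints
    for name, positions in units:
        start_gene = "ND5-5prime" if name == "ND5" else name
        stop_gene = "ND5-3prime" if name == "ND5" else name
        if start_gene in presets.START_CODONS and start_gene in by_name:
            _fix_codon(seq, positions[:3], presets.START_CODONS[start_gene],
                       f"start of {name}")
        if stop_gene in presets.STOP_CODONS and stop_gene in by_name:
            _fix_codon(seq, positions[-3:], presets.STOP_CODONS[stop_gene],
                       f"stop of {name}")

    target = np.array([spec.target_pct[b] / 100.0 for b in _BASES])
    sampler = _CodonSampler(
        _codon_weights(target, factors, spec.third_pos_t_bias, stops), stops)

    for name, positions in units:
        n_codons = len(positions) // 3
        has_stop = ("ND5-3prime" if name == "ND5" else name) in presets.STOP_CODONS
        for ci in range(n_codons):
            tri = positions[3 * ci:3 * ci + 3]
            fixed = tuple(int(seq[p]) for p in tri)
            if all(f >= 0 for f in fixed):
                # fully constrained (start/stop or an overlapping gene)
                codon = "".join(_BASES[f] for f in fixed)
                terminal = has_stop and ci == n_codons - 1
                if code.is_stop(codon) and not terminal:
                    raise GenerationError(
                        f"overlap constraints force internal stop {codon} "
                        f"in {name} at codon {ci + 1}")
                continue
            if has_stop and ci == n_codons - 1:
                continue  # terminal stop already fixed
            codon_idx = sampler.draw(rng, fixed)
            for p, b in zip(tri, _CODON_ARRAY[codon_idx]):
                seq[p] = b

    # free (tRNA / rRNA / intergenic) positions top up the target counts
    free = np.flatnonzero(seq < 0)
    if free.size:
        counts = np.bincount(seq[seq >= 0], minlength=4).astype(float)
        needed = np.maximum(target * length - counts, 1e-9)
        q = needed / needed.sum()
        seq[free] = rng.choice(4, size=free.size, p=q)
    return seq


def _achieved_pct(seq: np.ndarray) -> np.ndarray:
    counts = np.bincount(seq, minlength=4).astype(float)
    return 100.0 * counts / counts.sum()


def generate_genome(spec: GenomeSpec) -> tuple[MitoGenome, FeatureTable]:
    """Generate one annotated synthetic mitogenome, reproducible from seed.

    Post-conditions: circular genome in preset gene order, every PCG starts
    ATG/ATA/GTG and ends TAA/TAG with no internal stop under the configured
    code (ND5 as two exon features forming one reading frame), and the
    whole-genome composition within one percentage point of the target
    (the calibration loop aims for half a point).
    """
    feats, length = _layout(spec)
    code = CodonTable.from_ncbi(spec.code_table)
    rng = np.random.default_rng(spec.seed)
    target = np.array([spec.target_pct[b] / 100.0 for b in _BASES])

    factors = np.ones(4)
    best: tuple[float, np.ndarray] | None = None
    cds_mask = np.zeros(length, dtype=bool)
    for _, positions in _coding_units(feats):
        cds_mask[positions] = True

    for _ in range(spec.max_rounds):
        # overlapping reading frames (ND4L/ND3) can force a stop in the
        # downstream frame; those draws are rejected and resampled
        seq = None
        last_error: GenerationError | None = None
        for _attempt in range(40):
            try:
                seq = _generate_once(spec, feats, length, rng, factors, code)
                break
            except GenerationError as exc:
                last_error = exc
        if seq is None:
            raise GenerationError(
                f"could not satisfy overlap constraints after 40 draws: "
                f"{last_error}")
        pct = _achieved_pct(seq)
        dev = float(np.max(np.abs(pct - 100.0 * target)))
        if best is None or dev < best[0]:
            best = (dev, seq)
        cds_pct = _achieved_pct(seq[cds_mask])
        at_dev = abs((cds_pct[0] + cds_pct[3]) - 100.0 * (target[0] + target[3]))
        if dev <= 0.5 and at_dev <= 0.4:
            best = (dev, seq)
            break
        cds_counts = np.bincount(seq[cds_mask], minlength=4).astype(float)
        cds_frac = cds_counts / cds_counts.sum()
        factors *= np.clip(target / np.maximum(cds_frac, 1e-9), 0.5, 2.0)

    assert best is not None
    dev, seq = best
    if dev > 1.0:
        raise GenerationError(
            f"composition targets infeasible: best deviation {dev:.2f} "
            f"percentage points after {spec.max_rounds} rounds")
    sequence = "".join(_BASES[i] for i in seq)
    genome = MitoGenome(sequence=sequence, accession=spec.accession,
                        organism=spec.organism, is_circular=True)
    table = FeatureTable(genome_ref=spec.accession, features=feats)
    return genome, table


# ---------------------------------------------------------------------------
# controlled CDS mutation
# ---------------------------------------------------------------------------

def _codon_changes(codon: str, code: CodonTable) -> tuple[list, list]:
    """Single-base changes of one codon, split into (syn, nonsyn) lists.

    Each entry is (position, new_base); changes creating a stop codon are
    never offered.
    """
    aa = code.aa(codon)
    syn, nonsyn = [], []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if code.is_stop(mutant):
                continue
            (syn if code.aa(mutant) == aa else nonsyn).append((pos, base))
    return syn, nonsyn


def mutate_cds(cds: str, mspec: MutationSpec,
               code: CodonTable = DEFAULT_TABLE) -> str:
    """Apply exactly k_syn synonymous and k_nonsyn nonsynonymous substitutions.

    With ``disjoint_sites`` at most one substitution lands in any codon, so
    an NG86 comparison of (original, mutant) recovers Sd = k_syn and
    Nd = k_nonsyn exactly.  The start codon and terminal stop are never
    touched, and no substitution ever creates a stop codon.
    """
    rng = np.random.default_rng(mspec.seed)
    codon_list = codons_of(cds)
    protected = {0}
    if codon_list and code.is_stop(codon_list[-1]):
        protected.add(len(codon_list) - 1)
    eligible = [i for i in range(len(codon_list)) if i not in protected]

    if mspec.disjoint_sites:
        order = list(rng.permutation(len(eligible)))
        chosen: list[tuple[int, str]] = []  # (codon index, kind)
        need = {"nonsyn": mspec.k_nonsyn, "syn": mspec.k_syn}
        for kind in ("nonsyn", "syn"):
            for oi in list(order):
                if need[kind] == 0:
                    break
                ci = eligible[oi]
                options = _codon_changes(codon_list[ci], code)
                opts = options[0] if kind == "syn" else options[1]
                if opts:
                    chosen.append((ci, kind))
                    order.remove(oi)
                    need[kind] -= 1
            if need[kind] > 0:
                raise GenerationError(
                    f"not enough codons with eligible {kind} changes: "
                    f"short by {need[kind]}")
        for ci, kind in chosen:
            syn, nonsyn = _codon_changes(codon_list[ci], code)
            opts = syn if kind == "syn" else nonsyn
            pos, base = opts[rng.integers(len(opts))]
            codon = codon_list[ci]
            codon_list[ci] = codon[:pos] + base + codon[pos + 1:]
    else:
        for kind, k in (("nonsyn", mspec.k_nonsyn), ("syn", mspec.k_syn)):
            for _ in range(k):
                candidates = []
                for ci in eligible:
                    syn, nonsyn = _codon_changes(codon_list[ci], code)
                    opts = syn if kind == "syn" else nonsyn
                    candidates.extend((ci, pos, base) for pos, base in opts)
                if not candidates:
                    raise GenerationError(
                        f"no eligible {kind} change left to apply")
                ci, pos, base = candidates[rng.integers(len(candidates))]
                codon = codon_list[ci]
                codon_list[ci] = codon[:pos] + base + codon[pos + 1:]
    return "".join(codon_list)


# ---------------------------------------------------------------------------
# sequence evolution along a tree
# ---------------------------------------------------------------------------

def _codon_triples(genome: MitoGenome, table: FeatureTable,
                   code: CodonTable = DEFAULT_TABLE,
                   ) -> tuple[dict[int, list[tuple[int, int, int]]], set[int]]:
    """Map 0-based genomic position -> codon triples containing it, plus the
    frozen positions (start codons and terminal stops, kept under absolute
    purifying constraint during evolution)."""
    triples: dict[int, list[tuple[int, int, int]]] = {}
    frozen: set[int] = set()
    units: list[GeneFeature] = []
    names = set(table.names())
    if {"ND5-5prime", "ND5-3prime"} & names:
        units.append(nd5_joined(table))
    for f in table:
        if f.ftype == "PCG" and not f.name.startswith("ND5-") and f.name != "ND5":
            units.append(f)
    length = genome.length_bp
    for feat in units:
        positions: list[int] = []
        for s, e in feat.segments:
            positions.extend((p - 1) % length for p in range(s, e + 1))
        for ci in range(len(positions) // 3):
            tri = tuple(positions[3 * ci:3 * ci + 3])
            for p in tri:
                triples.setdefault(p, []).append(tri)  # type: ignore[arg-type]
        frozen.update(positions[:3])
        last = "".join(genome.sequence[p] for p in positions[-3:])
        if code.is_stop(last):
            frozen.update(positions[-3:])
    return triples, frozen


def _evolve_branch(seq: list[str], mu: float, rng: np.random.Generator,
                   triples: dict[int, list[tuple[int, int, int]]],
                   frozen: set[int], code: CodonTable) -> list[str]:
    """Jukes-Cantor evolution of one branch, CDS-aware (no stops created)."""
    if mu <= 0:
        return list(seq)
    p_sub = 0.75 * (1.0 - math.exp(-4.0 * mu / 3.0))
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < p_sub)
    for pos in hits:
        if int(pos) in frozen:
            continue  # start / terminal stop codons are immutable
        current = out[pos]
        choices = [b for b in _BASES if b != current]
        for j in rng.permutation(3):
            base = choices[j]
            ok = True
            for tri in triples.get(int(pos), ()):
                codon = "".join(base if q == pos else out[q] for q in tri)
                if code.is_stop(codon):
                    ok = False
                    break
            if ok:
                out[pos] = base
                break
        # if every base change creates a stop, the site is left unchanged
    return out


def evolve_on_tree(genome: MitoGenome, table: FeatureTable, tree: str,
                   rate: float, seed: int = 0,
                   code: CodonTable = DEFAULT_TABLE,
                   ) -> dict[str, MitoGenome]:
    """Evolve a genome along a Newick tree; returns leaf-label -> genome.

    ``rate`` scales branch lengths into expected substitutions per site
    (Jukes-Cantor model).  Substitutions inside PCGs are resampled so no
    stop codon is ever created; annotation coordinates are unchanged (no
    indels), so the input FeatureTable applies to every leaf genome.
    """
    if rate < 0:
        raise GenerationError("substitution rate must be non-negative")
    try:
        dtree = dendropy.Tree.get(data=tree, schema="newick")
    except Exception as exc:
        raise MitocharError(f"malformed Newick tree: {exc}") from exc
    rng = np.random.default_rng(seed)
    triples, frozen = _codon_triples(genome, table, code)
    root_seq = list(genome.sequence)
    seqs: dict[int, list[str]] = {id(dtree.seed_node): root_seq}
    leaves: dict[str, MitoGenome] = {}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            node_seq = root_seq
        else:
            parent_seq = seqs[id(node.parent_node)]
            mu = rate * (node.edge.length or 0.0)
            node_seq = _evolve_branch(parent_seq, mu, rng, triples, frozen,
                                      code)
        seqs[id(node)] = node_seq
        if node.is_leaf():
            label = (node.taxon.label if node.taxon else None) or "leaf"
            label = label.replace(" ", "_")
            leaves[label] = MitoGenome(
                sequence="".join(node_seq),
                accession=label, organism=label, is_circular=True)
    return leaves
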