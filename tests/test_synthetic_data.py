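"""Synthetic mitogenome generator: structure, composition, mutation, evolution."""

import numpy as np
import pytest

from mitochar import (
    GenomeSpec,
    MutationSpec,
    evolve_on_tree,
    generate_genome,
    mutate_cds,
    ng86,
    translate,
)
from mitochar.codon_usage import DEFAULT_TABLE, detect_start_stop
from mitochar.composition import base_composition, region_composition
from mitochar.errors import GenerationError, MitocharError
from mitochar.genome_io import extract_feature, nd5_joined
from mitochar import presets


def test_default_genome_structure(genome, ftable):
    expected_length = (sum(presets.GENE_SIZES.values())
                       + sum(presets.INTERGENIC_AFTER.values()))
    assert genome.length_bp == expected_length == 17148
    assert 16500 <= genome.length_bp <= 18000
    assert len(ftable) == 18
    assert all(f.strand == "H" for f in ftable)


def test_same_seed_identical_bytes():
    a, _ = generate_genome(GenomeSpec(seed=42))
    b, _ = generate_genome(GenomeSpec(seed=42))
    assert a.sequence == b.sequence
    c, _ = generate_genome(GenomeSpec(seed=43))
    assert c.sequence != a.sequence


def test_generated_skew_signs(genome):
    prof = base_composition(genome.sequence)
    assert prof.at_skew < 0  # T favored over A
    assert prof.gc_skew > 0  # G favored over C


def test_whole_genome_composition_within_one_point(genome):
    prof = base_composition(genome.sequence)
    for base, target in presets.TARGET_PCT.items():
        assert abs(prof.pct[base] - target) <= 1.0


def test_composition_targeting_over_seeds():
    """Mean absolute deviation of achieved percentages < 1 point (20 seeds)."""
    devs = []
    for seed in range(20):
        g, _ = generate_genome(GenomeSpec(seed=seed))
        prof = base_composition(g.sequence)
        devs.extend(abs(prof.pct[b] - t) for b, t in presets.TARGET_PCT.items())
    assert float(np.mean(devs)) < 1.0


def test_pcg_region_tracks_custom_at_target(genome, ftable):
    """A genome built to 66.5% AT yields a PCG region within half a point."""
    spec = GenomeSpec(seed=11, target_pct={"A": 25.2, "T": 41.3,
                                           "G": 20.4, "C": 13.1})
    g, ft = generate_genome(spec)
    pcg = region_composition(g, ft, "PCG")
    assert pcg.at_pct == pytest.approx(66.5, abs=0.5)


def test_every_pcg_translates_with_published_codons(genome, ftable):
    for gene in presets.PCG_CONCAT_ORDER:
        feat = nd5_joined(ftable) if gene == "ND5" else ftable.get(gene)
        cds = extract_feature(genome, feat)
        translate(cds)  # raises on internal stops
        info = detect_start_stop(cds)
        assert info.canonical_start
        start_gene = "ND5-5prime" if gene == "ND5" else gene
        assert info.start_codon == presets.START_CODONS[start_gene]
        stop_gene = "ND5-3prime" if gene == "ND5" else gene
        assert info.stop_codon == presets.STOP_CODONS[stop_gene]


def test_nd5_emitted_as_two_exons(ftable):
    five = ftable.get("ND5-5prime")
    three = ftable.get("ND5-3prime")
    assert five.span_length == 711
    assert three.span_length == 1104
    between = [f.name for f in ftable
               if five.end < f.start < three.start]
    # ten PCGs and one rRNA nest inside the ND5 intron
    assert sum(presets.GENE_TYPES[n] == "PCG" for n in between) == 10
    assert sum(presets.GENE_TYPES[n] == "rRNA" for n in between) == 1


def test_extreme_targets_still_steerable():
    """Almost any target is feasible on a 17-kb genome: only ~80 bases are
    pinned by start/stop codons, and homopolymer codons are sense codons."""
    g, _ = generate_genome(GenomeSpec(seed=0, target_pct={"A": 80.0, "T": 10.0,
                                                          "G": 5.0, "C": 5.0}))
    prof = base_composition(g.sequence)
    assert prof.pct["A"] == pytest.approx(80.0, abs=1.0)


def test_infeasible_layout_errors():
    with pytest.raises(GenerationError):
        generate_genome(GenomeSpec(
            seed=0, intergenic={**presets.INTERGENIC_AFTER, "COI": -17000}))


def test_target_percentages_must_sum_to_100():
    with pytest.raises(GenerationError):
        GenomeSpec(target_pct={"A": 30, "T": 30, "G": 30, "C": 30})


def test_pcg_sizes_must_be_codon_multiples():
    with pytest.raises(GenerationError):
        GenomeSpec(gene_sizes={**presets.GENE_SIZES, "COI": 1591})


# ---------------------------------------------------------------------------
# mutate_cds
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def coi(genome, ftable):
    return extract_feature(genome, ftable.get("COI"))


def test_mutation_counts_recovered_exactly(coi):
    mut = mutate_cds(coi, MutationSpec(seed=1, k_syn=10, k_nonsyn=2))
    res = ng86(coi, mut)
    assert (res.Sd, res.Nd) == (10.0, 2.0)


def test_zero_mutations_is_identity(coi):
    assert mutate_cds(coi, MutationSpec(seed=1)) == coi


def test_synonymous_only_preserves_protein(coi):
    mut = mutate_cds(coi, MutationSpec(seed=3, k_syn=25, k_nonsyn=0))
    assert translate(mut) == translate(coi)
    assert mut != coi


def test_mutations_never_create_stops_and_spare_ends(coi):
    mut = mutate_cds(coi, MutationSpec(seed=5, k_syn=40, k_nonsyn=40,
                                       disjoint_sites=False))
    translate(mut)  # no internal stop
    assert mut[:3] == coi[:3]
    assert mut[-3:] == coi[-3:]


def test_disjoint_mutations_invertible_by_complement(coi):
    """Re-applying the observed substitutions restores the original."""
    mut = mutate_cds(coi, MutationSpec(seed=8, k_syn=12, k_nonsyn=3))
    back = list(mut)
    for i, (a, b) in enumerate(zip(coi, mut)):
        if a != b:
            back[i] = a
    assert "".join(back) == coi
    changed_codons = {i // 3 for i, (a, b) in enumerate(zip(coi, mut)) if a != b}
    changed_sites = [i for i, (a, b) in enumerate(zip(coi, mut)) if a != b]
    assert len(changed_sites) == 15
    assert len(changed_codons) == 15  # one site per codon


def test_insufficient_eligible_sites_errors():
    with pytest.raises(GenerationError):
        mutate_cds("ATGAAATAA", MutationSpec(seed=0, k_syn=50, k_nonsyn=0))


# ---------------------------------------------------------------------------
# evolve_on_tree
# ---------------------------------------------------------------------------

TREE = "((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05,E:0.1);"


def test_rate_zero_yields_identical_taxa(genome, ftable):
    leaves = evolve_on_tree(genome, ftable, TREE, rate=0.0, seed=1)
    assert set(leaves) == set("ABCDE")
    assert all(g.sequence == genome.sequence for g in leaves.values())


def test_evolution_deterministic_by_seed(genome, ftable):
    a = evolve_on_tree(genome, ftable, TREE, rate=0.5, seed=7)
    b = evolve_on_tree(genome, ftable, TREE, rate=0.5, seed=7)
    assert all(a[k].sequence == b[k].sequence for k in a)


def test_evolved_genomes_keep_valid_reading_frames(genome, ftable):
    leaves = evolve_on_tree(genome, ftable, TREE, rate=2.0, seed=2)
    for g in leaves.values():
        for gene in presets.PCG_CONCAT_ORDER:
            feat = nd5_joined(ftable) if gene == "ND5" else ftable.get(gene)
            cds = extract_feature(g, feat)
            translate(cds)  # no internal stop introduced
            assert DEFAULT_TABLE.is_stop(cds[-3:])


def test_p_distance_grows_with_branch_length_jc(genome, ftable):
    """Observed divergence tracks the Jukes-Cantor expectation."""
    import math
    expected = {}
    observed = {}
    for bl in (0.02, 0.1, 0.3):
        tree = f"(A:{bl},B:0.0,C:0.0);"
        leaves = evolve_on_tree(genome, ftable, tree, rate=1.0, seed=4)
        p = sum(a != b for a, b in zip(leaves["A"].sequence,
                                       leaves["B"].sequence))
        p /= genome.length_bp
        observed[bl] = p
        expected[bl] = 0.75 * (1 - math.exp(-4 * bl / 3))
    assert observed[0.02] < observed[0.1] < observed[0.3]
    for bl in expected:
        # CDS stop-avoidance and frozen start/stop codons slightly depress
        # the realized rate, so compare with a generous Monte-Carlo margin
        assert observed[bl] == pytest.approx(expected[bl], rel=0.15)


def test_malformed_newick_errors(genome, ftable):
    with pytest.raises(MitocharError):
        evolve_on_tree(genome, ftable, "((A:0.1,B", rate=0.1, seed=0)


def test_negative_rate_rejected(genome, ftable):
    with pytest.raises(GenerationError):
        evolve_on_tree(genome, ftable, TREE, rate=-1.0, seed=0)
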