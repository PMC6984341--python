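# Methods and design notes

## Scope and model of the data

mitochar treats a mitogenome as a circular nucleotide sequence over
{A,C,G,T,N} with an ordered table of named gene features.  Coordinates are
1-based and inclusive (the GenBank convention); circularity is encoded by
letting a segment's end exceed the genome length rather than by splitting
segments, which keeps the arithmetic of wrap-around extraction unambiguous
(GenBank joins that straddle the origin are normalized to this encoding on
read and re-split on write).  Multi-segment features are joined in list
order; the intron-split ND5 is stored as two exon features (`ND5-5prime`,
`ND5-3prime`) with a derived joined virtual feature for translation — the
intron itself is never a stored feature, matching how deposited coral
annotations report the two exons separately.

The canonical circle presentation starts at the first base of tRNA-Met,
which is where published coral gene maps begin; `gene_order_string`
rotates any annotation to that anchor so gene orders compare equal across
genomes regardless of where a submitter placed the origin.

## Composition and skew statistics

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C) are computed on counts.
N bases are excluded from numerators and denominators, so percentages
describe known bases only; a zero denominator yields an explicit
undefined flag (`None`), never a NaN that silently propagates.  Reported
tables round percentages to 1 decimal and skews to 3 decimals, rounding
half away from zero as printed tables conventionally do; full precision is
kept internally.  `skew_from_percentages` exists to validate published
composition tables: it agrees with the count-based skews exactly whenever
the input percentages are exact, and reproduces a published skew at print
precision only when the published row was itself internally consistent —
for a minority of published rows the authors evidently rounded from
unrounded counts, and those rows cannot be reproduced from their printed
percentages at the third decimal.

Region classes (PCG/tRNA/rRNA/intergenic) are counted over the set of
genomic positions each class covers, so bases shared by overlapping genes
of the same class are counted once; `intergenic` is the complement of all
annotated spans.  This makes the class counts add up to the genome length
plus exactly the cross-class overlap.

## Translation and codon usage

The genetic code defaults to NCBI translation table 4 (mold / protozoan /
coelenterate mitochondrial): TGA encodes Trp, only TAA/TAG terminate.
The code table is a configuration knob (`code_table`), but coral
mitogenomes force table 4: the observed start codons are ATG/ATA/GTG and
TGA read-through is required for the annotated protein lengths to hold.
Starts outside {ATG, ATA, GTG} and missing terminal stops are flags, not
errors — the ND5 5′ exon legitimately ends without a stop.

RSCU follows the standard definition (count × family size / family
total).  Six-fold degenerate families (Leu, Ser, Arg) are treated as
single families of size six rather than 2+4 sub-families, matching how
coral codon-usage figures group them.  Families never observed report NA
rather than 0, distinguishing "unused" from "impossible".  RSCU is pooled
over all 13 PCGs by default (per-gene tables via `--per-gene`); published
coral RSCU figures do not state the pooling level, and pooled is the
conservative default because per-gene families are small.

## Ka/Ks (Nei–Gojobori 1986, Jukes–Cantor corrected)

The counting method is implemented in full rather than delegated, since
it is the analytical core of the package.  Per codon, each position
contributes the fraction of its three single-base changes that are
synonymous (changes creating stops count as nonsynonymous — the
conventional choice); S is the sum, N = 3·codons − S, and the pair uses
the average of the two sequences' S.  Codons differing at 2–3 positions
are averaged over all 2 or 6 mutational orderings; orderings that pass
through a stop codon are excluded and the remainder reweighted, and if
every ordering crosses a stop all are kept (the fallback avoids undefined
results on adversarial toy inputs).  Proportions are corrected with
d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is reported as a saturation flag, and
ω = Ka/Ks is defined only when Ks > 0 (identical sequences therefore give
ω = undefined, not 0/0).  NG86-with-JC is the classic default of DnaSP's
Ka/Ks output, which is why it is the method of record here; the
implementation is cross-checked in the test suite against Biopython's
independent NG86 and against a brute-force pathway enumerator on all
sense-codon pairs.

Gene pairs are compared ungapped.  For the coral trio the orthologous
PCGs are length-identical, so no aligner is needed; a length mismatch is
an explicit error telling the user to align externally, because a silent
internal alignment would fabricate methodology the published protocol
never stated.

## Supermatrix and distance tree

The 13 PCGs are concatenated in circle order (ND5 first, joined across
its exons) with terminal stop codons stripped; the amino-acid level
translates each gene before concatenation.  Partitions are recorded as
1-based column spans and written as a NEXUS `sets` block.  Both
nucleotide and amino-acid levels are supported because published coral
phylogenies have used either.  The neighbor-joining tree (scikit-bio NJ
on p- or JC-corrected distances, taxa pre-sorted for input-order
invariance) is deliberately minimal pipeline plumbing: it verifies that a
supermatrix carries the expected signal, and is not a substitute for
model-based inference, which is out of scope.

## Synthetic genome generator

The generator's defaults are the study conditions: gene sizes, gene
order, start/stop codon assignments and signed intergenic spacers follow
the deposited Merulinidae annotations (ranges collapsed to representative
values: 16S rRNA 1699 bp, tRNA-Trp 71 bp, 12S rRNA 911 bp; intergenic
midpoints with the fixed printed overlaps −1, −1, −19, −2 kept; the
COI→tRNA-Met wrap gap 362 bp), giving a 17,148 bp circle — inside the
published 16,466–18,006 bp span.  The composition target defaults to the
published *D. rotumana* whole-genome percentages (A 25.2, T 41.6, G 20.3,
C 12.9).

Sequence is generated constraint-first: start and stop codons are fixed
up front (so overlapping genes see them), each CDS is then filled
codon-by-codon from a weighted distribution over sense codons that
matches any already-fixed bases, and remaining tRNA/rRNA/intergenic
positions are drawn to top up the target base counts.  Codon weights are
products of per-position target probabilities with an extra T bias at
third positions (`third_pos_t_bias`, default 1.6), reflecting the
stronger third-position T bias of real mitogenomes; a short
multiplicative calibration loop regenerates until the whole-genome
composition is within 0.5 percentage points of target (hard failure
beyond 1.0).  Overlapping reading frames (ND4L/ND3 share 19 bp) can
occasionally force a stop in the downstream frame; such draws are
rejected and resampled, with a bounded number of attempts.  All
randomness flows from the single spec seed.

What the generator does **not** emulate: tRNA/rRNA secondary structure,
per-gene GC% heterogeneity, indels, realistic intergenic repeat content,
or between-species composition differences.  Tests that pass on these
genomes therefore demonstrate the correctness of the statistics and the
coordinate handling, not the biological realism of any sequence.

`mutate_cds` applies exactly k synonymous and k′ nonsynonymous
single-base changes (never touching the start codon or terminal stop,
never creating a stop); with disjoint sites at most one change lands per
codon, which makes NG86 recovery exact (Sd = k, Nd = k′) and the mutation
set invertible.  `evolve_on_tree` applies Jukes–Cantor substitutions
along Newick branches; inside PCGs a substitution that would create a
stop is redrawn among the remaining bases (or skipped if all three create
stops), and start/terminal-stop codons are frozen — an absolute
purifying constraint that slightly depresses the realized rate relative
to the JC expectation, which the calibration tests account for.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated data:
one 17.1 kb default genome shared across tests, 6-taxon evolution
experiments at 20 seeds, and exhaustive codon-pair checks (62×62).  The
full suite completes in well under a minute on one CPU.  Ties in NJ are
broken by sorted taxon labels; report rounding is half-away-from-zero;
composition calibration tolerances are 0.5 points (aim) and 1.0 points
(failure); saturation thresholds follow the JC domain bound p < 3/4.

## Known limitations

* The published per-gene table prints the ND5 5′ exon as 711 bp / 236 aa;
  711/3 = 237, so any arithmetic route gives a joined ND5 product of
  604 aa and a 13-PCG total of 3,916 aa, one more than the printed
  concatenated total of 3,915.  The toolkit reports the arithmetic value
  and leaves reconciling the deposited annotation to the user.
* De novo annotation (gene finding, tRNA structure prediction) is out of
  scope; the toolkit consumes existing annotations.
* Ka/Ks is NG86 only — no maximum-likelihood (GY94-style) dN/dS, no
  codon-frequency corrections, no sliding windows.
* The NJ tree has no support values and should not be published as a
  phylogeny.
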