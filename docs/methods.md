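# Methods

`rasprok` reimplements, at desk scale, a phylogenomic census procedure for
prokaryotic Ras-superfamily small GTPases: iterative homolog harvesting,
domain-architecture resolution, length-band delineation, MglB
gene-neighborhood coupling, G-motif catalytic-mechanism typing,
distance-tree phylogenetics, and coupled-tree coevolution analysis. This
note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## The census procedure

**Harvest.** Candidate small GTPases are collected by the union of three
routes: (i) hits of a seed protein in an all-vs-all local-alignment
search at an E-value cutoff of 1e-4; (ii) every protein whose resolved
domain architecture contains one of the most frequent domains among the
seed hits (default: the top four of the census table); (iii) hits of
expansion queries, which are the extracted regions of those collection
domains. Domain architectures are resolved greedily: the highest-scoring
hit is kept and every hit sharing at least one residue with it is
discarded, repeating until no hits remain; score ties break by lower
E-value, then longer interval, then domain name, for determinism. After
the union, exclusion rules apply in a fixed order of precedence: an
architecture containing an ABC-transporter-like domain (`ABC_tran`,
`ABC_tran_2`, `AAA_21`) excludes the protein outright
("decoy-architecture"); a length below 150 aa excludes it ("short");
length above 240 aa keeps the protein for tree context but flags it as
not small. MglB (Roadblock/LC7) harvesting reuses the same machinery
with the `Robl_LC7` collection domain; its 129-179 aa band is an
annotation, not an exclusion, because genuine fusion proteins exist.

Expansion queries are deduplicated and capped (default 40 per round,
one round): on the synthetic censuses used here the planted families are
recovered exactly well below the cap, and the cap keeps the all-vs-all
Smith-Waterman expansion tractable on one CPU.

**Search backend.** Pairwise search is optimal Smith-Waterman under
affine gaps (BLOSUM62, open 11, extend 1), with an expectation value of
Karlin-Altschul form, E = K m n exp(-lambda S), using fixed ungapped
BLOSUM62 constants (lambda = 0.3176, K = 0.134) and n equal to the total
residue count of the database. The statistic is a monotone ranking
surrogate that preserves the semantics of the 1e-4 cutoff; parity with
any particular BLAST release is a non-goal, and externally computed hit
tables in the 12-column dialect are interchangeable with the built-in
backend.

**Coupling.** A GTPase and an mglB gene are coupled when they lie on the
same replicon within four ordinal gene positions (at most three
intervening genes), strand-agnostic; on circular replicons the distance
wraps, d = min(|i-j|, N-|i-j|). Whether "within four genes" counts index
offset or intervening genes is ambiguous in the field's usage; we chose
index offset <= 4 and expose the window as a parameter. Family members
with no qualifying partner are orphans; a GTPase with two partners in the
window is a 1:2 system (larger k is reported verbatim, not an error).
Couplings never cross replicons.

**Motifs and mechanisms.** The five G-motif windows (G1 P-loop
GxxxxGK[T/S]; G2 with its conserved threonine; G3/switch II; G4
[NT]KxD; G5) are defined once as residue ranges on a reference protein
and projected onto every sequence through the columns of a multiple
alignment; a window whose columns are more than half gaps for a sequence
is recorded as absent, never guessed. The catalytic-mechanism call
applies ordered rules: (1) arginine immediately after the G2 threonine
plus a TxPGQ switch II -> intrinsic-arginine type (MglA Group 1);
(2) GTPGQ-like switch II plus a threonine in the arginine's place ->
the shared Groups 2-5 type; (3) DxxGQ -> eukaryote-like Ras type with
the catalytic glutamine; (4) DxxG without the +4 glutamine -> Ras-like
without the glutamine (Rup Group 1 type); otherwise uncalled. The
MglA-specific rules run first because the Ras-like patterns are
supersets. G4/G5 signatures (NxFD, DAR, SA[KL], [NT]KxD) are recorded as
evidence, never as call criteria. The bacterial-MglA insertion between
G1 and G2 is measured as the ungapped G1-to-G2 spacing minus the
insertion-free reference spacing, flagged at >= 5 residues.

Conservation profiles report per-column residue frequencies and
information content (log2 20 - H, bits). The consensus letter is the
residue with frequency >= 0.5, else a residue class (ILVM / FYW / KR /
DE / ST / NQ / AG) whose joint frequency reaches 0.8, else `x`. The two
thresholds are conventions, exposed as parameters.

**Trees.** Distances are Poisson-corrected p-distances, d = -ln(1-p),
over columns where both sequences are ungapped, capped at d(0.95) =
-ln 0.05 ~ 3.0. Tree inference is canonical neighbor joining
(Saitou-Nei), delegated to scikit-bio and verified exact on additive
matrices; taxon order is canonicalized first so topology does not
depend on input order, and negative branch lengths are clamped to zero.
Bootstrap support resamples alignment columns with replacement, builds
one NJ tree per replicate, and retains exactly the bipartitions present
in more than half of the replicates (strict majority rule); zero-length
internal edges in a replicate are treated as unresolved rather than as
evidence, so an alignment of identical sequences yields a star. The
default is 100 replicates — a deliberate desk-scale reduction of the
thousand-replicate convention, sufficient for the support contrasts the
package tests.

**Classification.** Family assignment is reference-anchored: a leaf is
MglA when it falls in the minimal clade containing every MglA reference
and no Rup reference (rooting on the opposite family's first reference),
and symmetrically for Rup. Where the tree is ambiguous the call falls
back to a vote: coupling to mglB and a G1-G2 insertion each argue for
MglA, a Ras-like mechanism argues for Rup; ties are reported as `none`
with "ambiguous" evidence. Groups are maximal monophyletic clades whose
references carry exactly one group label; leaves outside any labeled
clade stay unclassified. The "small" band is inclusive at both ends
(150-240 aa): where a table header and the text disagree about the upper
bound, the report follows the inclusive text reading and the divergence
is noted here rather than silently resolved. Orphans keep their family
assignment through tree and motif evidence even without coupling. The
census report tallies, per family and group, all sequences / small
sequences / coupled / small coupled; the invariants small <= all and
small-coupled <= min(small, coupled) hold by construction and are
asserted in tests.

**Coevolution congruence.** The congruence statistic restricts the
GTPase tree and the MglB tree to coupled leaves and reports the fraction
of the GTPase tree's internal bipartitions {S, S'} for which some
partner-tree bipartition {T, T'} lets every GTPase in S choose a partner
in T and every GTPase in S' a partner in T'. For 1:2 systems either
partner may satisfy a split and the chosen partner is recorded. The
statistic is invariant to rerooting of either tree. It is an
operationalization of visual clade matching between coupled trees — a
defined artifact statistic of this package, not a field-standard formula
— and reports label it as such.

## The synthetic-data generator

The generator emulates the composition of a real prokaryotic census at
desk scale, with complete ground truth. Defaults (one instance of the
study conditions; all configurable):

- 30 genomes, one circular replicon of 84 genes each.
- Five MglA groups (16, 14, 12, 10, 10 systems) with group-specific
  motif sets: Group 1 G2 `TR` + G3 `TVPGQ`; Groups 2-5 G2 threonine pair
  + G3 `GTPGQ`; Group 2 G4 `NxFD` and G5 `DAR` (Group 3 likewise
  deviates from [NT]KxD — realized as `NxxD`, a modeling choice, since
  only its lysine loss is established); Groups 1, 2, 3, 5 carry a
  10-14 aa insertion between G1 and G2; Group 4 (the archaeal-style
  group) does not. Two Rup groups (12, 8 systems), eukaryote-like:
  Group 1 `DTAGE` (no catalytic glutamine), Group 2 `DTAGQ`.
- Each MglA gene has an MglB partner within a planted gene-index
  distance drawn from weights (0.4, 0.3, 0.2, 0.1) over distances 1-4;
  10% of systems carry a second, nearly identical MglB (1:2). Group-2
  systems sit in a four-gene conservon block (kinase, MglB, unknown,
  MglA). Orphan MglBs (40% of the family) and all Rup genes are placed
  with at least 5 ordinal positions of clearance from any partner-family
  gene, so orphanhood is unambiguous under the window-4 rule. Placement
  uses per-genome 12-gene segments, one planted item per segment, which
  enforces the clearance including across the circular wrap.
- Decoys: 8 ABC-transporter-like proteins (architecture `ABC_tran` +
  `AAA_21`-style plus a spurious GTPase-domain match, in-band length, so
  only the architecture rule can exclude them); 6 truncations cut before
  G4 (< 150 aa, missing motifs); 6 Roco-like proteins (> 240 aa,
  N-terminal LRR repeats in front of a Rup-derived G domain).
- Sequence model: fixed background amino-acid frequency table
  (uniform-ish with realistic skew, shipped as data); hierarchical
  divergence — 0.7 substitutions/site between the MglA and Rup family
  backgrounds (derived from one superfamily background), 0.3 between
  group roots within a family, 0.2 from a group root to each member,
  with MglB partners ticking 1.5x faster. Substitutions are applied as
  fixed counts at the branch expectation (1 - exp(-t) of the free sites)
  and never inside motif windows; members of a group differ by
  substitutions only (no indels). The G2 window is realized as a
  5-residue anchored block so that alignment gap placement around the
  G1-G2 insertion cannot slide into the window.
- True trees are random balanced ultrametric trees (node heights scale
  with log2 of subtree size), so every internal edge carries a
  resolvable number of substitutions; coupled MglB partners evolve along
  the same tree shape, and the MglB group backgrounds evolve along the
  same group-level tree as the MglA groups, so the deep structure of the
  two families coevolves as well. These choices are what make the
  planted coevolution signal recoverable from 150-180 aa proteins; with
  exponential join heights the shortest edges fall below the p-distance
  noise floor and no inference method could be expected to find them.
- One master seed; per-genome and per-purpose substreams are derived by
  fixed key splitting, so changing the genome count does not reshuffle
  earlier genomes.

What the generator does **not** emulate: nucleotide-level sequences and
codon usage, indel evolution within families, horizontal transfer,
rate heterogeneity across sites, low-complexity and compositionally
biased regions, Pfam model mis-annotation beyond the planted decoy
classes, and the database-scale redundancy of real genome sets. Passing
recovery tests on these censuses therefore demonstrates the pipeline's
internal correctness — the algorithms compute what they claim on inputs
whose truth is known — not field performance on RefSeq-scale data, which
depends on search sensitivity and alignment quality far outside this
model.

## Multiple alignment

The built-in aligner is center-star: the center is the sequence with the
highest total pairwise score (deterministic subsampling above 60
sequences; ties by id), every sequence is aligned to it semi-globally
(end gaps free) with BLOSUM45 (open 13, extend 1), and the pairwise
alignments merge under "once a gap, always a gap". BLOSUM45 is used
because cross-family pairs sit near 20-25% identity, where BLOSUM62
favours staggered, nearly disjoint paths that leave sequence pairs
without comparable columns. Externally computed alignments can be
supplied wherever the built-in aligner's output is accepted. Trees for
classification are built from the core-region columns (the reference's
G1-through-G5 span), mirroring the usual practice of trimming ragged
termini before phylogenetics.

## Numerical and degenerate-input conventions

Coordinates on sequences are 1-based inclusive everywhere; gene indices
are 0-based consecutive ordinals. Readers reject malformed input with
file and line rather than repairing it. The distance cap (p >= 0.95),
the consensus thresholds (0.5 / 0.8), the insertion flag minimum (5 aa),
and the bootstrap majority rule (> 0.5, strict) are the package's
defaults, all overridable. Empty inputs return empty results where that
is meaningful (an empty hit list resolves to an empty architecture; an
empty census yields an all-zero report); fewer than three taxa is an
error for neighbor joining, and a pair of aligned sequences with no
mutually ungapped column is an error for distance computation.

## Known limitations

- The congruence statistic depends on both trees being inferable; on
  very short or very slowly evolving families it under-reports
  coevolution even when the planted histories are identical.
- Center-star alignment is O(n) pairwise alignments against one center
  and degrades for families with long, variable insertions; the package
  accepts external alignments for such cases.
- The E-value surrogate shares only monotonicity with database-search
  statistics; absolute E-values are not comparable to BLAST output.
- Family assignment requires at least one reference per family in the
  tree; with none present it refuses rather than guessing.
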