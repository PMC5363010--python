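# Methods

## Reference coordinate system

All positions are 1-based in a single reference numbering (the
*T. zostericola* convention). The model fixes the signature residues
{26:H, 56:H, 60:E, 75:H, 79:H, 108:H, 113:D}, the helix intervals
A=[19,38], B=[43,65], C=[72,88], D=[98,118] (closed; where published
residue counts and intervals disagree, the intervals are taken as
authoritative, since they are the operational object), and the
inter-helix window [89,97] that carries the five-residue ncHr
insertion, placed at positions 93–97, immediately before the D helix.
Numbering follows the insertion-bearing (myo-type) form.

The packaged reference templates are **synthetic**: a random
125-residue protein drawn once from a fixed seed, with Met at position
1 and the signature residues overwritten; the cHr-form template is the
same protein with positions 93–97 deleted, and its CDS is the myo CDS
minus those codons. Only the templates' structural properties matter
(signatures present, insertion length/location, identity outside the
window); nothing downstream depends on the specific random residues. A
real reference can be substituted through the YAML serialization.

## Discovery

ORFs are extracted from all six frames: reading frames are segmented
at stop codons; every stop-to-stop (or edge-bounded) fragment of ≥100
residues is kept, and fragments not beginning with Met additionally
yield their Met-initiated sub-ORF. Non-Met fragments are retained,
flagged, to accommodate 5'-incomplete transcripts. Codons containing N
translate to X.

Screening is explicit Smith-Waterman (BLOSUM62, gap open 11 / extend
1; the X row of the matrix is zeroed so unknown residues are neutral).
Scores are normalized by the panel sequence's self-score, giving a
[0,1] similarity; the default acceptance threshold of 0.35 was chosen
once to separate planted genes (≈0.5–1.0 at ≤30% divergence) from
dinucleotide-matched decoys (≈0.1–0.25) on seeded fixtures, and a hit
must span >300 nt of coding sequence. This replaces database-calibrated
E-values: the decisive specificity filter is the downstream
signature gate, which requires all seven iron-binding residues (the
minimum is configurable). Overlapping-frame hits are deduplicated per
contig by best normalized score, ties broken by longer protein, then
lower start coordinate.

## Annotation and classification

Candidates are globally aligned to the insertion-bearing template with
affine gaps and free end gaps (so terminal extensions cost nothing),
yielding a monotone candidate↔reference position map. The observed
insertion length is the number of candidate residues strictly between
the two conserved signature residues flanking the window (His79 and
His108 by default) minus the cHr-template count between the same
positions. Anchoring at exactly conserved residues makes the statistic
independent of where the aligner places gaps among mutable residues
near the window; for candidates missing those anchors the helix
boundary positions (C.end / D.start) are used instead. Insertion 5 →
ncHr, 0 → cHr; any other value is reported as *ambiguous* rather than
forced into the dichotomy, and ambiguous calls are excluded from
downstream statistics by default.

Trimming retains [initiator Met … residue mapped to D.end+7]; the
initiator is the first mapped Met near the reference N-terminus
(reference position ≤ 5), falling back to the first mapped residue for
5'-incomplete candidates, which are accepted when reference coverage
is ≥ 0.8. The CDS is cut to the exact corresponding codons, so trimmed
CDSs always re-translate to trimmed proteins.

## Alignment

The multiple alignment is a reference-anchored star alignment: each
reference position is one shared column, and residues a row inserts
relative to the reference get private columns (insertions from
different rows are **not** aligned to each other — conservative for
per-site statistics, since it never fabricates homology between
independent insertions). An externally computed protein MSA can be
supplied instead. Back-translation replaces each residue cell by its
source codon and each gap by `---`; it validates per-cell
codon/residue agreement and errors on any disagreement, so degapping a
nucleotide row always reproduces the input CDS.

## Phylogenetics

Distances are proportions of differing sites over pairwise-ungapped
columns (optional Jukes-Cantor correction). Neighbor joining is
implemented directly with a deterministic tie-break (lexicographically
smallest pair of representative tip labels) so trees are
byte-reproducible; it is validated against brute-force additive-matrix
recovery and cross-checked against an independent NJ implementation.
Bootstrap support is the frequency of each point-estimate bipartition
among column-resampled NJ replicates (default 100). Rooting requires
the outgroup to be a clade of the unrooted tree and places the root at
the midpoint of the separating branch; monophyly of a tip set means it
is exactly the leaf set of some node of the rooted tree.

## Rate-shift statistic

Per-site substitution counts per clade are minimum change counts from
unweighted small parsimony, computed by a unit-cost Sankoff dynamic
program (exact on any tree shape, including the multifurcations that
arise when a clade is extracted from a larger tree); gaps and
non-standard residues are missing data. With normalizers λi = Σk ci[k]:

    r[k] = |c1[k]/λ1 − c2[k]/λ2|,  Q[k] = r[k]/max_j r[j] ∈ [0,1]

Sites with Q ≥ 0.7 (default) are flagged. The coefficient of
divergence is θ_D = clip(1 − ρ, 0, 1) with ρ the Pearson correlation
of (c1, c2) across sites; a constant count vector is defined to have
ρ = 1 (θ_D = 0), and a clade with zero total changes yields a warning
and all-zero scores. Note that the cutoff applies to the normalized
score Q — a *relative* criterion ("within 70% of the strongest shift
signal") — not to a posterior probability of functional divergence;
likelihood-based type-I divergence machinery is intentionally not
reimplemented. Flagged alignment columns are assigned to helix
A/B/C/D, inter-helix, or unmapped via the star alignment's reference
anchoring.

## Synthetic data

**Transcriptomes.** Planted genes descend from the two subtype
templates hierarchically: a per-subtype founder is mutated away from
its template at half the requested divergence, and each gene mutates
independently from its founder at the other half (`founder_share`
controls the split). This emulates paralog lineages older than the
sampled species — members of a subtype resemble each other more than
the other subtype, the regime in which the subtypes form two clades.
Substitutions are uniform over the 19 alternative residues, never
touch signature positions, and introduce no indels; protein-level
divergence control is what the tests require, so no substitution
matrix bias is modelled. CDSs inherit founder codons, with codons
redrawn uniformly among synonyms at substituted residues and silently
substituted at the same rate elsewhere — synonymous sites therefore
carry phylogenetic signal, as in real transcripts. Genes are embedded
between random UTRs (30–300 nt) with an explicit stop codon, on a
random strand. Decoys are first-order Markov resamples of the planted
coding pool (preserving dinucleotide composition, hence hard negatives
for the similarity screen) interleaved with uniform-random sequence.
Two outgroup sequences for rooting are generated as a third, deeply
diverged (40%) lineage. Defaults (10 cHr + 10 ncHr at 25% divergence
among 200 decoys) are the package's standard study conditions.

Not modelled: read-level sequencing noise, expression levels, assembly
artifacts, chimeric contigs, codon-usage bias, indel evolution within
genes. Passing tests therefore demonstrate correctness of the pipeline
logic under controlled divergence, not robustness to assembly
pathology.

**Two-clade simulations.** Protein alignments evolve down two random
bifurcating clades by per-site Poisson substitution. Background sites
share a discrete-gamma site rate (4 equal-probability categories,
shape 0.5, mean 1) between the clades — shared among-site rate
heterogeneity is what makes the clades' count profiles correlated, so
θ̂_D is small when nothing has shifted; without it two homogeneous
Poisson profiles would be uncorrelated and θ̂_D would sit near 1 even
under the null. Shifted sites abandon the shared rate and evolve at
exactly `base_rate` in clade 1 and `base_rate × rate_ratio` in clade
2, modelling a change of functional constraint after duplication.
Clade trees are terminal-branch-dominated (80% of the total branch
length on terminal branches, total within-clade length 1.0, stem
0.25), a radiation-like shape in which most substitutions arise
independently on tip lineages. `base_rate` defaults to 6.0 expected
substitutions per unit site rate, placing background sites at ~5
changes per clade and shifted clade-2 sites near the parsimony
saturation plateau; these defaults were fixed once by a design
experiment and are reported with every simulation.

**Calibration at the standard conditions** (clades of 20, 132 columns,
10% of sites shifted five-fold, cutoff 0.7): flagging precision is
~0.85–0.9, recall ~0.35–0.4, and mean θ̂_D rises from ~0.12 (no shift)
through ~0.25 (10% shifted) to ~0.37 (30% shifted) — the numbers
`scripts/acceptance.py` recomputes. Recall is structurally limited at
these sizes: Q normalizes by the maximum per-site difference, so a
site is flagged only if its signal is within 70% of the strongest
site's, which requires the coefficient of variation of r among truly
shifted sites to be ≲0.25, while Poisson counting noise at ~5 expected
clade-1 changes and the parsimony ceiling (~13–14 distinguishable
changes per column on 20 tips) floor that CV near 0.33. Detecting a
larger share of shifted sites at the 0.7 relative cutoff requires
either more taxa per clade or a cutoff on an absolute (e.g.
model-based posterior) scale.

## Numerical and degenerate-input conventions

Alignment parameters (BLOSUM62, open 11, extend 1) are fixed and
echoed in run metadata. NJ Q-matrix ties break lexicographically;
bootstrap replicates that produce an incomparable pair (no shared
ungapped column) are skipped. p-distance raises on a pair with zero
comparable columns. An empty contig set yields a zero-count report and
exit 0; fewer than two classified candidates skips the tree stage, and
a subtype with fewer than three members skips the divergence stage,
with notes recorded in the report.
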