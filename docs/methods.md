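# Methods

## Screening model

The screen operates on unrooted single-partition trees. Because an
outgroup is often absent from individual gene trees, "clade" is
implemented as *either side of a bipartition*: every internal edge with
bootstrap support at or above the threshold contributes both of its
sides, which share the edge's support and length. The a-priori filter and
the downstream classifiers operate per side; complement sides are in
practice removed by the filter or come out of assessment as clean or as
implying the same prune action as their counterpart. Edges whose support
is absent from the input tree never qualify — absence of evidence is not
a support value of 0.

The default support threshold is BP ≥ 95, configurable. It encodes the
assumption that single-gene bootstrap support for deep relationships is
ordinarily low, so high support in one gene is itself a red flag. The
screen is deliberately conservative in the other direction as well: the
a-priori group filter removes clades whose monophyly is independently
established (they are *expected* to be well supported), at the accepted
cost of missing artifacts hiding inside those groups.

## Contamination criteria

Two criteria, jointly required: a terminal branch ≤ ε within the clade,
and a member pair with identity ≥ θ over ≥ `min_overlap` shared columns
(columns where neither sequence is `-` or `X`). Defaults ε = 10⁻⁶
substitutions/site, θ = 0.99, `min_overlap` = 20. The source study states
only "very short branch, ideally zero" and "identical or nearly
identical"; the defaults here are deliberately strict so that conserved
genes with genuinely similar sequences do not trip the classifier, and
every verdict records the extremal values used (minimum terminal branch,
best pair identity, overlap) so reports are auditable against different
thresholds. Since the direction of transfer cannot be decided from the
data, both members of the implicated pair are pruned.

## Paralogy decision rule

Gene labels are compared after whitespace collapsing and case folding;
synonym resolution is the job of the curated accession→label map. A
member with no hit is ignored in the comparison and noted — a missing hit
is not evidence of a different gene. If no label at all is available the
record is *indeterminate* and triggers no action.

The prune-vs-exclude decision distinguishes whether the core ortholog set
itself is compromised. Pooling every available primer-taxon label
(a primer taxon may sit inside the flagged clade; its label then comes
from the clade side of the evidence): if the primer labels disagree among
themselves, or a primer taxon is itself among the label-deviating
sequences, the partition's seed gene was already a paralog mixture and
the whole partition is excluded. Otherwise only the clade members whose
label deviates from the primer consensus are pruned. A primer taxon
sitting inside a flagged clade with a *conforming* label does not trigger
exclusion — this matters on unrooted trees, where the complement side of
a genuine artifact edge can contain all primer taxa.

With several reference transcriptomes, labels are compared per reference
and any single reference showing a split decides (a single reference can
miss a paralogy case when both paralogs hit the same reference gene).

## Branch diagnostics

For a flagged clade, the leading branch length is that of the internal
edge defining it; the branch ratio divides it by the mean of **all**
internal branch lengths, the leading edge included (hence ratios below 1
are possible and a tree with a single internal edge has ratio exactly 1).
The diagnostic is scale-invariant. It is reported, not thresholded: in
the bundled case study the ratio ranges of clean clades (0.98–3.70) and
paralog clades (0.77–13.40) overlap, which is precisely why an automatic
branch-length-only screen is not offered.

## Supermatrix bookkeeping

Internally all coordinates are 0-based half-open; emitted partition files
use the conventional 1-based inclusive ranges. Sequence-level pruning
removes rows but never columns, even if a column becomes all-gap: this
keeps the all-data and contamination-pruned matrices the same length and
keeps the coordinate chart stable across dataset variants. Partition
exclusion removes the partition's columns. Taxa left with no data at all
are retained in the matrix but flagged in the report, since downstream
tree software differs in its tolerance of empty rows. Redundant
partitions (identical taxon set, per-taxon byte-identical sequences) are
collapsed to the lexicographically first ID.

## Likelihood engine

`site_log_likelihoods` is an *evaluator*: topology, branch lengths, the
gamma shape α and the invariant proportion `pinv` are inputs, never
optimized — the intended workflow estimates them with standard ML
software and uses this module for the per-site diagnostic. The model is a
reversible amino-acid exchangeability matrix (LG bundled as published
constants; any PAML-format matrix loadable) with rate matrix
q<sub>ij</sub> = s<sub>ij</sub>π<sub>j</sub>, scaled to one expected
substitution per site at equilibrium. Transition matrices come from a
symmetrized eigendecomposition (exact for reversible models), partial
likelihoods are computed by Felsenstein pruning vectorized across sites
with per-node rescaling against underflow, and totals are assembled in
log space.

Discrete-gamma rates use K equal-probability categories represented by
their conditional means under Γ(α, α), renormalized to mean exactly 1.
The +I mixture is

L<sub>site</sub> = pinv·π<sub>x</sub>·[site constant with residue x] + (1 − pinv)·(1/K)·Σ<sub>k</sub> L(rate<sub>k</sub>),

with gamma rates *not* rescaled by 1/(1 − pinv) — conventions differ
between programs; this one is stated and tested. "Constant" means all
non-missing residues identical; gaps and `X` are uninformative (partial
vector of ones) and an all-missing site has lnL = 0. ΔpsL is the per-site
difference lnL(H1) − lnL(H2) on a fixed alignment, aggregated per
partition through the coordinate chart; its sites sum to the total
log-likelihood difference by construction, and the per-partition sums
identify genes whose signal drives a clade's support.

## Leaf stability

The triplet "maximum" variant: for focal taxon t and each pair {i, j} of
co-occurring taxa, the three resolutions (t,i)|j, (t,j)|i, (i,j)|t are
counted over the tree set and the pair contributes the modal resolution's
relative frequency; LSI(t) is the mean over pairs. Trees missing any of
the three taxa — or leaving the triplet unresolved, as happens for
triplets spanning the trifurcating base of an unrooted tree — are
excluded from that pair's denominator, so a set of identical trees yields
exactly 1 for every taxon. Which variant of the index the original
Phyutility-based analyses used is not documented; results are therefore
labelled with the variant name, and the table writer emits deltas between
consecutive tree sets (changes above ~0.05 are the conventionally
interesting ones).

## Synthetic data

The generator reproduces the mechanism the screen targets, not any
particular empirical dataset. A gene family carries paralogs A and B from
a duplication at the species-tree root; each copy mirrors the species
tree and the copies are joined by an inter-paralog stem. Defaults, chosen
once as plausible study conditions and fixed:

| parameter | default | units | rationale |
|---|---|---|---|
| species tree | 8-taxon balanced, 0.1/branch | subst/site | small enough for exhaustive checks |
| inter-paralog divergence | 1.5 | subst/site | deep pre-speciation duplication; guarantees score separation |
| per-branch loss probability | 0.2 | — | losses common enough to create reciprocal-lack patterns |
| per-taxon detection probability | 0.5 | — | shallow EST libraries miss half their transcripts |
| sites | 300 | aa columns | typical masked partition length |
| model | LG, α = 0.8, pinv = 0.1, K = 4 | — | matches the evaluator's model family |
| contaminant transfer | 0.05 | fraction of donor | the magnitude reported for real library cross-contamination |

Sequence evolution reuses the same substitution-model engine as the
likelihood module (single code path: the simulator and the evaluator
cannot drift apart). Libraries sample each genome-present transcript
independently with the detection probability; contamination copies
⌈fraction·|donor|⌉ transcripts verbatim.

The orthology-assignment emulator approximates a profile-HMM search by
the maximum pairwise global-alignment score (BLOSUM62, affine gaps)
against the core-set members, followed by the reciprocal back-check
against each reference library. Generation validates *score separation*
(minimum same-paralog score > maximum cross-paralog score) and errors
otherwise; under that condition "misassigned iff reciprocal lack holds
under all references" is provable, which is what makes the closed-form
truth set an exact oracle for the emulator. The representative-option
behavior of concatenating non-overlapping hits into chimeras is
deliberately not emulated.

Simulated partitions get neighbor-joining trees on uncorrected
p-distances with column-resampling bootstrap supports (negative NJ
branches clamped to zero). These trees are deliberately cruder than ML
trees; they suffice because the induced artifacts (zero-branch duplicate
pairs, deeply divergent paralog clades) produce saturated support under
any reasonable reconstruction.

What passing synthetic tests does **not** show: robustness to alignment
error and masking, to within-library assembly chimeras, to rate
heterogeneity across lineages, or to paralogs so recently diverged that
score separation fails — real data have all of these, and the classifier
thresholds (ε, θ, BP) may need adjustment there.

## Problem sizes

Test and acceptance computations are sized for quick desk validation:
exhaustive-likelihood oracles run on ≤ 5-taxon trees with 50 sites,
stability oracles on ≤ 8 taxa × ≤ 50 trees, end-to-end synthetic runs on
8-taxon, 3–6-partition bundles with 50–100 bootstrap replicates, and the
redundancy benchmark on a 231-partition set. These sizes exercise every
code path; the algorithms themselves scale to realistic datasets
(hundreds of partitions, tens of taxa) without modification.

## Known limitations

- The screen inherits the blind spots of its inputs: paralogy invisible
  at BP < threshold, or hidden inside a-priori groups, passes through.
- Gene-label comparison is exact string matching after normalization;
  inconsistent curation in the accession→label map produces spurious
  splits.
- The ΔpsL evaluator uses the supplied branch lengths for both
  hypotheses; it does not re-optimize per hypothesis, so hypotheses
  should come with comparably estimated lengths.
- Contamination *source* attribution (handling, gut content, parasitism)
  is not computable from these data and is out of scope.
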