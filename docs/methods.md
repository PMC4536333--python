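# Methods

`balaena` reimplements, as a tested library, the comparative-genomics
workflow used to search a newly sequenced mammal genome (the motivating
case is the bowhead whale, with minke whale, orca, dolphin, cow and other
mammals as comparators) for lineage-specific adaptive evolution. This note
records the models, the conventions and tunable parameters, what the
synthetic data do and do not emulate, and the design choices made where the
procedure was genuinely open.

## Orthology and single-gene ortholog (SGO) families

Cross-species similarity hits (12-column tabular format) are reduced to
best hits per query at an e-value cutoff (default 1e-7 for family building;
1e-5 is the conventional choice when annotating against a single reference
proteome — both are config keys). Ties on bit score break to the lower
e-value and then the lexicographically smaller subject id, making results
independent of input row order. Reciprocal best hits (RBH) define an
undirected graph whose connected components are the gene families — the
minimal reading of RBH-based clustering; no within-species self-hits are
used, since within-species paralogy is the expansion module's job.

A family is kept as an SGO when it has at most one member per species
(one-to-zero orthology allowed), spans **more than seven** species (i.e. at
least eight), and no member CDS translates with an internal stop codon
(internal stops indicate annotation or assembly error). Every rejection is
logged with a reason code.

## Alignment quality control

Two filters gate codon alignments before selection testing:

1. **Unique-insertion filter** — fails if a maximal run of alignment
   columns longer than 12 bp (codon gaps come in multiples of three, so a
   failing run is at least 15 bp in practice) contains residues in exactly
   one focal taxon while every other taxon is gapped. An insertion shared
   by the two focal taxa, or by a focal and any background taxon, is not
   unique and passes. A run of exactly 12 bp passes.
2. **Focal-length filter** — fails if a focal sequence's ungapped length is
   below half the alignment length (exactly half passes).

Pairwise comparisons additionally drop a pair when the shorter CDS is under
half the length of the longer (exactly half is kept). All three thresholds
are config keys (`qc.*`).

## Codon substitution model

The engine implements the Goldman–Yang Markov model on the 61 sense codons:
instantaneous change only between codons differing at one nucleotide, with
rate `kappa` multiplying transitions, `omega` (dN/dS) multiplying
nonsynonymous changes, and target-codon frequency `pi_j`. Codon frequencies
default to F3×4 (per-position nucleotide frequencies with a 0.5
pseudocount and a 1e-9 floor so every sense codon stays reachable on short
alignments); F61 and uniform are options. Columns containing a gap or an
ambiguous codon are removed before likelihood computation.

**Normalization.** Each per-omega matrix is scaled to one expected
substitution per codon per unit time, and in site-class mixtures every
class's branch lengths are further scaled by `mu(omega_c) / mu_mix`, where
`mu_mix` is the proportion-weighted flux of the **background** classes.
One unit of branch length is therefore one expected substitution per codon
under the background site-class mixture, and a positively selected
foreground class is genuinely accelerated. The alternative convention
(normalizing foreground branches by their own mixture) was tried and
rejected: it lets branch-length rescaling absorb the foreground
acceleration, leaving `omega2` nearly unidentifiable in profile-likelihood
checks on simulated data.

Likelihoods use Felsenstein pruning over compressed site patterns with
per-node rescaling; transition matrices come from a symmetric
eigendecomposition of the reversible generator. An internal memoization
layer caches eigensystems, `P(t)` matrices, and whole per-class site
likelihood vectors keyed on the exact parameter values — finite-difference
optimizers revisit most of these unchanged.

### Models and fits

| model     | site classes (background / foreground omega)       | free parameters |
|-----------|----------------------------------------------------|-----------------|
| M0        | one ratio everywhere                               | kappa, omega    |
| M1        | 0 / 0 and 1 / 1                                    | kappa, p0       |
| M1a       | omega0 in [0,1] and 1                              | kappa, p0, omega0 |
| M2        | 0, 1, omega2 (free)                                | kappa, p0, p1, omega2 |
| A         | omega0, 1, plus foreground classes at omega2 >= 1  | kappa, p0, p1, omega0, omega2 |
| A_null    | model A with omega2 = 1                            | kappa, p0, p1, omega0 |

Two dialects of the two-class site model ship: the literal two-class form
with omegas fixed at 0 and 1 (`M1`) and the modern `M1a` with an
estimated omega0, which is the standard null for model A; `M1a` is the
default (`selection.site_dialect`).

Optimization is bounded L-BFGS-B on (kappa in [0.1, 20], omega in
[1e-4, 50], omega0 in [1e-4, 1], omega2 in [1, 50], proportions on the
closed simplex — zero-mass classes are legal, which makes the nestings
M0 ⊆ M1a ⊆ A and A_null ⊆ A exact), with branch lengths log-transformed,
convergence at ~1e-7 in log-likelihood, and several omega starting values
(default 0.5, 1.0, 2.0); the best converged start wins.

**Branch lengths and kappa.** M0 estimates branch lengths jointly
(initialized from the input tree). Richer models reuse the M0 branch
lengths — with one deliberate exception: branch-site models re-estimate
the **foreground** branch length(s). The M0 estimate of a foreground
branch absorbs any foreground acceleration, which would otherwise bias
omega2 toward 1; recovery simulations confirmed the bias and its removal.
The bundled `branch_site_test` suite additionally holds kappa at the M0
estimate in the site and branch-site fits (identical treatment in null and
alternative, so LRTs compare like with like) and warm-starts model A from
the fitted null parameters, which guarantees the alternative's optimum
dominates its nulls.

### Tests, sites, and calls

LRTs use the chi-square upper tail of `max(0, 2 * delta lnL)` with df equal
to the free-parameter difference: A vs M1a df 2, A vs A_null df 1, M2 vs
M1 df 2, and M0-vs-branch-site comparisons at their parameter
difference. No boundary mixture correction is applied at the A vs A_null
boundary — the plain chi-square(1) is conservative there, which the type-I
calibration study quantifies. Per-site identification is naive empirical
Bayes: `PP(c | site) = p_c L_c / sum_k p_k L_k`, flagging sites whose
posterior mass on foreground classes with omega > 1 reaches the threshold
(default 0.95), reported in 1-based alignment columns and ungapped focal
coordinates. Bayes empirical Bayes is out of scope.

A gene is called positively selected only when (1) both LRTs are
significant at `alpha` (default 0.05), (2) the fitted parameters indicate
selection (omega2 > 1 with positive class mass), and (3) the alignment
passed QC; negative calls name the failed criterion.

### Pairwise dN/dS and the acceleration ratio

Pairwise rates fit M0 on a two-leaf tree and decompose dN and dS from
(kappa, omega, t) using mutational-opportunity site fractions computed at
omega = 1, so dN/dS equals the fitted omega exactly. Identical sequences
or dS = 0 yield an undefined, flagged ratio. The independent
Nei–Gojobori counting estimator (equal-weight pathway averaging for
multi-difference codons, pathways through stops excluded when avoidable,
changes to stops counted as nonsynonymous, Jukes–Cantor correction)
cross-checks the ML estimates; the two agree in rank order on simulated
gene sets. The lineage-acceleration screen divides the focal-pair omega by
the larger of two reference-pair omegas and flags the top 5% (config).

## Lineage-unique residues

A column of a focal-vs-mammals protein alignment is focal-unique when no
taxon is gapped there, at most one non-focal residue is unknown (X), and
the focal residue does not occur among the known non-focal residues. The
non-focal residues need *not* agree with each other — the minimal reading
of uniqueness; a strict mode requiring agreement is a config switch, as is
ignoring (rather than disqualifying on) gapped taxa. Proteins are ranked
by unique-residue count over focal length, ties by count then id, with the
top 5% flagged.

## Gene-family expansions

Gene trees are reconciled against the species tree by standard LCA
mapping; a node mapping to the same species-tree node as one of its
children is a duplication, attributed to the branch above the mapped node.
Unrooted gene trees are rooted to minimize the duplication count (ties:
fewer deep duplications, then first edge in postorder). The species tree
defaults to the eight-taxon mammal topology shipped in
`balaena/data/species_tree_8taxa.nwk`.

Candidate focal duplicates then pass an identity band: percent difference
over aligned non-gap positions of a BLOSUM62 global alignment (gap open
-10, extend -0.5) must satisfy 1% <= d <= 10%, boundaries inclusive — the
lower bound removes assembly artifacts and dead-recent copies, the upper
bound anciently diverged copies. Expression is checked from read counts:
a gene is expressed when its summed count across tissues reaches
`min_reads` (default 10); genes missing from the table are flagged.

## Genome summaries

Shannon's index `H = -sum p_i ln p_i` over repeat classes (natural log by
default, base configurable; counts or base-pair mass per class both work —
the statistic is defined relative to the granularity of the supplied
table). Coverage tables divide per-library totals (Gb) by the genome size
(default 2.91 Gb), rounding to one decimal as sequencing reports print it.

## Synthetic data

Every generator is a pure function of its spec and seed. Codon alignments
are simulated by drawing root codons from pi, assigning each site a class
(kept across the tree; foreground branches use the class's foreground
omega — the generative reading of the branch-site model), and sampling
per-branch transitions from the same matrices the likelihood uses. Family
simulation clones the species tree, splices duplication nodes onto the
requested branches (ancestral events planted first so each plant is
exactly one reconciliation event), and tunes the duplicate subtree's rate
scale by bisection until the closest duplicate protein pair falls in the
requested divergence band. Emitted hit tables score bit = 2 x length x
identity from realized protein identity, so best hits are nearest
relatives and RBH clustering recovers planted families exactly on
noise-free input. Residue fixtures plant columns that satisfy the
uniqueness rule exactly, with decoy columns (double-unknown, gapped)
violating it by construction. TE tables are multinomial draws.

The default study bundle (`balaena simulate`) uses the eight-taxon mammal
tree with smooth branch lengths, 150-codon genes, five purifying
background families (omega 0.2), one family with a planted branch-site
signal on the focal terminal branch (10% of sites at omega2 = 4), two
focal duplications inside the identity band, and one duplication on the
human branch. Calibration studies use a six-taxon tree with ~0.3
substitutions/codon background branches and a deep (1.0) foreground
branch — the scale of the ancestral lineages such tests target; the
type-I study runs 200 replicates of 200 codons, the power study 25
replicates of 500 codons. These sizes keep the full suite in the tens of
minutes on one CPU while leaving the binomial error on a 5%-level test
rate around one point.

**What the simulator does not emulate:** indels (alignments are generated
aligned, so QC filters are exercised on constructed fixtures, not on
simulator output), alignment error, sequencing noise in hit tables,
among-site rate variation beyond the defined classes, codon-usage bias
(uniform pi by default), and real expression structure (Poisson counts
with a silent fraction). Passing tests therefore demonstrate correctness
of the algorithms under the model's own assumptions, not robustness to
real-data artifacts.

## Known limitations

- Site identification under the branch-site model is information-limited:
  with 10% of sites at omega2 = 4 and a single foreground branch, even the
  posterior computed at the *true* parameters rarely exceeds 0.95 for a
  truly selected site (a calibrated posterior cannot concentrate harder
  than the per-site evidence allows). The site-recovery half of the power
  study documents this honestly rather than relaxing the threshold.
- NEB (not BEB) posteriors: parameter uncertainty is ignored, which can
  overstate confidence when estimates sit on ridges (small p2, large
  omega2).
- The chi-square reference for A vs A_null is conservative at the
  boundary; no mixture correction is applied.
- Reconciliation assumes duplication-only histories (no losses or
  incomplete lineage sorting) and rooted-or-rootable gene trees.
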