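# Methods

## Background and scope

Synaptonemal-complex (SC) central-region proteins are a canonical case of
"unconventional conservation": their amino-acid sequences diverge close
to neutrally within a clade, yet their overall length and the position
and extent of their coiled-coil domains are tightly preserved, because
the ~100-nm SC ladder is built from head-to-head coiled-coil transverse
filaments whose physical dimensions matter more than their residues.
`coilsig` turns that observation into a reusable, testable pipeline:
score coiled-coil character per residue, thread scores onto a multiple
sequence alignment, quantify three signature metrics per orthogroup,
test for depletion of indels inside coiled-coils on a phylogeny, and
screen whole proteomes for families carrying the signature.  A simulator
with full ground truth makes every stage verifiable without external
sequence resources.

## The three signature metrics

For an orthogroup alignment with one member per species:

* **Substitutions per site** `d` — the unweighted mean over all
  unordered member pairs of the gamma-corrected Poisson amino-acid
  distance `d = a[(1 − p)^(−1/a) − 1]`, where `p` is the pairwise
  proportion of differing residues and `a` is the gamma shape parameter
  of among-site rate variation (default `a = 2.0`).  `p` uses pairwise
  deletion by default (columns gapped in either member of the pair are
  excluded); complete deletion is available behind the
  `deletion="complete"` switch.  Pairwise deletion is the default
  because these alignments contain many lineage-specific indels that
  complete deletion would discard wholesale.
* **Coefficient of variation of protein length** — sample standard
  deviation (n − 1) of the members' ungapped lengths divided by their
  mean.  Sample SD is used throughout the package, matching the default
  of the statistical environments these analyses are usually run in.
* **Coiled-coil conservation score** — per-residue coiled-coil scores
  (1 − Paircoil2-style p-score, in [0, 1]) are placed at their alignment
  columns; columns with coverage below 80% of species (or 7-of-8 in the
  small-proteome mode) are removed; the score is the mean over retained
  columns of the per-column **minimum** across species.  The minimum is
  taken over non-missing entries only: the coverage filter already
  bounds missingness, and scoring a gap as 0 would conflate indels with
  loss of coiled-coil character.  The score is high only where all
  species place a coiled-coil at the same aligned position, which is why
  it outperforms presence/absence calls of coiled-coil domains.

The score machinery is agnostic to the score's meaning; disorder
profiles (PONDR-style, high = disordered) flow through alignment,
coverage filtering and conserved-domain calling unchanged.

Conserved domains are maximal runs of at least 21 retained columns with
cross-species mean score > 0.8 and SD < 0.1 (sample SD; a column with a
single residue is given SD 0).  Run length is counted in retained
columns; the reported `start`/`end` are original alignment coordinates.

## Per-residue scoring

The built-in predictor is a windowed heptad-composition score, a
deliberately simple stand-in for pairwise-frequency predictors such as
Paircoil2 (whose residue-pair tables are out of scope here).  For every
window of 28 residues and each of the 7 register phases it computes
`0.7 · (fraction of a/d positions occupied by A I L M F V W Y C) + 0.3 ·
(fraction of e/g positions occupied by D E K R N Q S T H)`; a residue's
score is the maximum over all windows containing it.  Sequences shorter
than the window score 0.  The alphabets and weights are configurable;
all downstream operations accept externally computed profiles, so any
predictor can be substituted.

The longest coiled-coil domain of a profile is the longest run of
residues with p-score below 0.1 (coiled-coil score above 0.9), where an
interruption of at most 2 *consecutive* non-qualifying residues does not
end the run.  The tolerance is applied per interruption, with no bound
on the number of interruptions — the most literal reading of the
"one or two residues may exceed the threshold" convention; a
total-per-domain budget is the plausible alternative and would call
shorter domains on noisy profiles.  Edge interruptions are trimmed.
Physical length uses 0.1485 nm of coiled-coil axial rise per residue
(configurable; the constant is a design choice consistent with the
~51–55 nm scale reported for ~360-residue SC coiled-coils).

## Indel census

Indel events are inferred from gap patterns on a rooted binary tree
(polytomies are resolved deterministically by ladderising children in
input order with zero-length branches):

1. Columns gapped in every species are excluded.  The remaining columns
   are grouped into **region blocks** — maximal column intervals over
   which the species' gap presence/absence pattern is constant.
2. Each block's binary gap character is reconstructed with Fitch small
   parsimony.  Descending from the root, a node takes its parent's state
   whenever its Fitch set allows, which yields a minimum-change
   reconstruction.  An ambiguous root state is resolved by (a)
   minimising changes on terminal branches, then (b) taking the majority
   tip state — so a lineage-specific gain or loss is placed on the
   deviating lineage's own stem rather than its sibling's — then (c)
   preferring the ungapped state.  All three steps are deterministic.
3. One event is emitted per state change, on the changing branch.
   Events on the same branch in column-adjacent blocks with the same
   change direction are merged into one spanning event; identical gap
   patterns separated by non-gap columns remain distinct events.

Events are **unpolarised**: calling insertion vs. deletion needs an
outgroup assumption, and the census only counts positions with indels.
Parsimony under-counts by construction (convergent events collapse onto
a stem); on simulated ground truth the inferred count never exceeds the
true count and ~86% of sparse events are recovered on their exact
branch.

Every alignment column (outside all-gap columns) is then labelled
indel-containing (covered by ≥ 1 event) or indel-lacking, and
inside/outside the coiled-coil of one designated **reference species**
(the analysis exposes `reference_species` because a paralog-bearing
species cannot serve as its own reference).  Columns where the reference
is gapped inherit the label of the nearest reference residue (ties to
the left flank).  Coiled-coil membership uses the reference's called
domains rather than a raw per-column score cutoff, matching how domain
extents are normally drawn on gene models.  The resulting 2×2 table
(positions with indels / total, inside vs. outside) is tested with a
two-sided Fisher exact test by the point-probability method (all tables
with the observed margins whose probability does not exceed the observed
table's, within a ~1e−7 relative tie tolerance); any zero margin returns
p = 1 by convention with a logged warning.  A multi-protein report sums
the four cells across proteins into a pooled "Total" row before a single
pooled test.

## Screening

Orthogroups are prepared by removing every species represented more than
once (dropping the species entirely avoids choosing among paralogs) and
keeping groups with members from at least half of the possible species.
The default minimum is `ceil(fraction × n)`; an explicit `min_species`
override exists because published conventions round this boundary both
ways (13-of-25 rounds up, 7-of-15 rounds down).  A coiled-coil
comparison set can be formed by keeping groups in which ≥ 90% of members
have a longest domain of ≥ 21 residues.

The screen passes orthogroups with `substitutions_per_site ≥ min_subs`,
`cv_length ≤ max_cv` and `cc_conservation_score ≥ min_ccscore`, each
intersected with optional externally supplied ID sets (single-copy
status, absence of cross-clade BLAST hits, expression enrichment —
computing those is out of scope by design).  No published numeric
thresholds exist for the three metrics, so defaults are expressed as
background percentiles (divergence and conservation at the background's
90th percentile, CV at its 10th); passers are ranked by conservation
score, then divergence, then ID, making output independent of input
order.  The homolog-free search needs no orthology at all: it keeps
proteins by longest-domain and total-length windows (long-filament mode:
domain ≥ 150 aa, length 300–1300 aa; short-protein mode: domain
21–150 aa, length 175–225 aa; bounds inclusive).

For visualisation-style clustering, the three metrics are used as raw
Euclidean coordinates (no scaling, matching direct clustering of the raw
dissimilarities; a `standardize` flag z-scores them) under complete
linkage, cut to k = 15 leaves.  The top 0.1% of divergence and CV values
can be trimmed for display only.  Group comparisons use the two-sided
Wilcoxon rank-sum test (exact for min(n, m) ≤ 8 without ties, normal
approximation with tie and continuity corrections otherwise).  A motif
scan reports all, possibly overlapping, S-[S/T]-P Polo-box docking
motifs in 1-based coordinates.

## Simulator

`simulate_tree` draws a pure-birth topology and rescales depths so every
root-to-tip path equals the requested height; `target_mean_pairwise`
instead rescales branches so the *mean pairwise tip distance* equals a
chosen expected divergence, which pins the quantity the estimator is
asked to recover.  Families evolve by Poisson substitutions (uniform
over the 19 alternative residues — exactly the model the gamma-Poisson
estimator assumes, which keeps parameter recovery well-posed) with
per-site gamma rates (shape 2.0, mean 1, drawn once per site), and by a
Poisson indel process with separate rates inside/outside planted
segments and geometric lengths.  Substitutions inside planted segments
are redrawn from the register-appropriate heptad class with probability
0.9, so segments keep coiled-coil character while diverging in sequence.
Deletions never straddle a segment boundary unless allowed.  All
randomness flows from one integer seed through `numpy`'s PCG64;
identical configs give byte-identical output.

Every indel is threaded through a master column registry, so the emitted
alignment is the *true* alignment; the per-branch event log replays from
the ancestor to every tip exactly (checked in the suite on every run).
Oracle profiles score `1 − ε` inside planted segments and `ε` outside
(`ε` = |N(0, 0.05)|, clipped), which separates testing of the metrics
from testing of the predictor.

Default study conditions (chosen once, before the suite was frozen, to
match the magnitudes the analysis is designed for): 12 taxa, 500-residue
ancestor, two segments covering half the protein, indel rates 0.04
events/site/branch-length outside vs. 0.008 inside (5× suppression,
~50 events per family), geometric mean length 3.  The SC-like screening
preset rescales true mean pairwise divergence to 1.5 substitutions/site
with segments covering ~2/3 of a 450-residue ancestor and low indel
rates (0.02/0.004).  Background families draw divergence from
U(0.15, 0.7) (median ≈ 0.43, the scale typical of a nematode proteome),
are 70% segment-free (otherwise one short, weakly preserved segment),
and have unsuppressed indels with geometric mean length 10 at rates
0.08–0.2, giving a length CV around 0.1 — proteome-like; with SC-like
short indels the background length CV came out ~0.03, i.e. unrealistically
length-conserved backgrounds.

What the simulator does **not** emulate: alignment error (it emits true
alignments; real pipelines inherit ClustalW/MAFFT artefacts), empirical
substitution matrices, codon structure, annotation errors (a major real
source of spurious length variation), orthology-inference mistakes, and
correlated indel/substitution processes.  Passing tests therefore show
the estimators and filters are correct under their own model
assumptions, not that real proteomes satisfy those assumptions.

## Numerical and interface conventions

Internal coordinates are 0-based half-open; all human-facing reports are
1-based inclusive.  Only `-` is a gap; `.` is rejected.  Raw p-score
profiles are converted to coiled-coil scores (1 − p) on read, making the
read–write–read cycle idempotent.  Column identity defaults to mean
pairwise identity over non-gap residue pairs (a consensus-fraction mode
is provided, since GUI tools differ and the convention is rarely
stated); smoothing is a centred moving average ignoring missing values
and shrinking at the edges.  Fisher tables with a zero margin return
p = 1; saturated pairwise distances (p ≥ 1) raise rather than clamp;
pairs with no comparable columns are skipped with a warning and an
orthogroup where all pairs are skipped is an error, not a zero.

## Problem sizes used by the test suite

Oracle comparisons run on 1,000 random score matrices (≤ 20 × 50), 500
binary characters on ≤ 8-tip trees, 200 Fisher tables (N ≤ 200) and 100
point sets (≤ 12 points).  Parameter recovery uses 50 two-taxon
replicates at 2,000 sites, 100 depletion replicates at the default
conditions, and 20 screening replicates of 205 families each.  These
sizes keep the whole suite at a few minutes on one CPU while leaving the
Monte-Carlo assertions comfortably away from their thresholds.

## Known limitations

* Parsimony event counts are a lower bound and cannot separate events on
  the two root-adjacent branches of an unrooted-equivalent pattern.
* The heptad scorer has no notion of pairwise residue correlations and
  will over-score low-complexity hydrophobic/polar alternations; it is a
  stand-in, not a Paircoil2 replacement.
* The gamma-Poisson estimator assumes the substitution model the
  simulator implements; on real data with empirical exchangeabilities it
  inherits the usual ~5% downward bias at high divergence.
* Published per-protein indel counts depend on manual event judgement and
  alignment-uncertainty masking and are not exactly reproducible from
  parsimony alone; the package reproduces the published contingency
  *tables* and their p-values exactly, and automates the census for new
  data.  An optional column mask can be supplied to exclude regions of
  uncertain alignment.
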