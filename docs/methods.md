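# Methods

This note documents the models and procedures implemented in `qsvar`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not emulate.

## The quaternary-structure character

A protein's quaternary structure (QS) is its subunit count plus the
identity of the interface holding the homomer together. Two homomers with
the same subunit count are the same QS only if their interfaces overlap by
at least 0.5 — the fraction of the smaller interface whose residues are
structurally aligned onto the other interface. Topology classes are formed
by single-linkage over the overlap ≥ 0.5 relation within each subunit-count
stratum. Overlap is pairwise and not transitive, so some clustering rule is
unavoidable; single linkage was chosen because it is deterministic,
order-independent, and the closest closure of a pairwise "different if
overlap < 0.5" rule. A consequence (documented, intended): a chain
A–B–C with overlaps 0.6, 0.6, 0.3 forms one class. Class labels are
`"<n_subunits>:<lexicographically smallest member id>"`, so runs are
reproducible. All monomers share the single monomer topology of their
stratum; between homomers of equal count a *missing* overlap conservatively
means different topologies (flag `missing_overlap_as_same` inverts this).

## Interface classification

Per residue, with SASA of the complex and of the isolated chain:

- RSA = SASA / maxASA, with the theoretical maximum allowed accessibilities
  of Tien et al. (2013) as denominators (packaged in
  `qsvar/data/max_areas.tsv`). RSA is not clamped at 1.
- interface ⇔ RSA_monomer ≥ 0.2 **and** (SASA_monomer − SASA_complex) /
  SASA_monomer ≥ 0.10;
- surface ⇔ not interface and RSA > 0.2 (strict, per the definitions);
- buried otherwise.

Open choices, resolved as follows: the exposure gate uses the
*monomer-context* SASA, because a residue buried by oligomerisation would
otherwise fail the gate — defeating the purpose of detecting assembly
burial (`rsa_context="complex"` restores the alternative). The 10% change
criterion is relative to the monomer SASA, not to the maximum area.
Negative burial (complex SASA above monomer SASA, numerical noise from the
SASA engine) counts as zero burial; residues with zero monomer SASA are
never interface. Nonstandard residue codes are rejected with an explicit
error rather than silently skipped. Boundary semantics: "0.2 or above" and
"minimum 10%" are ≥, "above 0.2" is strict.

Per-subunit interface area is max(0, ΣSASA_monomers − SASA_complex) /
n_subunits; a monomer has area 0 by definition. An optional sensitivity
mode (`small_interface_as_monomer`) relabels homomers burying less than
1000 Å² per subunit as monomers, for probing weak, possibly
crystal-contact, interfaces.

## Orthogroup diversity metrics

Four metrics per orthogroup, computed from one representative structure per
protein (the fourth also uses all of a protein's entries): mean subunit
count (monomers included); number of distinct topologies; Shannon index
−Σ pᵢ ln pᵢ over topology frequencies (0 for a single class, ln k for k
equally frequent classes, so an even 5:5 monomer/dimer split scores above a
skewed 1:9 one); and the mean number of distinct QSs per protein across
its entries. Frequencies are over proteins — each protein's representative
QS counts once. Group comparisons use orthogroups with ≥ 3 members; smaller
orthogroups still get metrics but are flagged non-comparable.

## Phylogenetic reconstruction

**Tree hygiene.** Tips whose mean cophenetic (path-length) distance to all
other tips exceeds the grand mean of tip means + 3 sample standard
deviations are excluded, in a single pass. Note an arithmetic bound: a
single outlier among n tip means cannot exceed (n−1)/√n SDs, which is below
3 for n ≤ 10, so on the smallest analyzable trees this filter can never
fire — it is a guard against gross long-branch artifacts on larger trees,
not a per-tree outlier test.

**MAD rooting.** The root is the point ρ on any branch minimizing the
root-mean-square over tip pairs (b, c) of |2·d(ρ∧bc, b)/d(b, c) − 1|, where
ρ∧bc is the point of the b–c path closest to ρ. For pairs straddling the
candidate branch that point is ρ itself and the contribution is quadratic
in the offset, so the per-branch minimizer is analytic (clamped to the
branch); pairs on one side contribute a branch-constant term. Ties break by
the deterministic branch enumeration order, then smaller offset. Tip pairs
at zero distance are skipped (their relative deviation is undefined); a
tree whose branches are all zero-length cannot be rooted and is an error.
The implementation is validated against a 10⁻⁴-resolution grid scan.

**Equal-rates Mk ML.** One transition rate r between every ordered state
pair; the state space is the states observed at the tips of that tree
(unobserved QS classes are not imputed). For this model the transition
matrix has the closed form P(t) = e^(−krt) I + (1 − e^(−krt)) J/k (J the
all-ones matrix), implemented directly — so zero-length branches get an
exact identity transition and no branch-length floor or matrix exponential
is needed. The likelihood uses
Felsenstein pruning with per-node rescaling; r is fitted by bounded scalar
minimization of −log L on the log-rate scale (bounds e^(−20.7)…e^(11.5),
tolerance 1e-8). Marginal node probabilities come from the standard
inside–outside computation with a **uniform root prior** (the equal-rates
spirit; an explicit prior vector can be supplied). Multifurcations are
resolved to binary left-to-right with zero-length branches before any
reconstruction.

**Parsimony.** Fitch downpass (unordered, equal cost) gives state sets and
the parsimony score; the uppass assigns the root the smallest state of its
set and keeps the parent's state whenever it lies in the child's downpass
set, otherwise the change is placed on that edge — as rootward as forced
placements allow — taking the smallest state of the child's set. The
resulting assignment always realises the Fitch-minimum change count
(verified exhaustively in the tests); the exact placement of changes inside
regions that admit several equally parsimonious resolutions follows this
deterministic rule rather than replicating any particular legacy
implementation.

**Resolution and change rate.** A node is resolved when its best state's
probability strictly exceeds 0.51; tips are always resolved. The change
rate iterates every parent–child pair including tip edges; pairs with an
unresolved endpoint are skipped from both numerator and denominator. The
per-node point state is the argmax, with ties broken toward the parent's
state to avoid manufacturing changes. A change is a gain/loss when the
child has more/fewer subunits, lateral when counts agree but the topology
class differs; lateral changes are reported separately from gains and
losses. Trees are stratified by root type (homomer / monomer); roots not
resolved above 0.51 put the tree in an excluded "unresolved" stratum.
Only trees with ≥ 10 tips after filtering enter this stage. The denominator
is the number of usable parent–child *pairs* (not nodes) — the two
formulations disagree only by the root's missing parent, and the pair
formulation is the one that makes the skipped-pair rule coherent.

## Annotation richness

OBO ontologies are read with obonet; obsolete terms are dropped with a
warning. Ancestry uses is_a and part_of edges within one namespace;
cross-namespace pairs never eliminate each other. A term set is reduced by
removing every term that is a proper ancestor of another term in the set —
an antichain results, the operation is idempotent, and of "mitochondrion"
and "mitochondrial inner membrane" only the latter survives. The Reactome
hierarchy is treated as the same kind of DAG built from parent–child
relation rows. GO evidence subsets: `all`, `drop_IEA`, and
`experimental_only` with the standard experimental code set
{EXP, IDA, IPI, IMP, IGI, IEP, HTP, HDA, HMP, HGI, HEP} (configurable).
Richness is the mean number of (filtered) terms per protein in a group,
zero-annotation proteins included.

## Statistics

All tests are two-sided. Wilcoxon rank-sum uses the exact null when the
smaller sample has ≤ 8 observations and the pooled data are tie-free,
otherwise the normal approximation with continuity and tie corrections.
The two-proportion test is the continuity-corrected chi-square;
per-group 95% CIs are Wilson score intervals (the CI family was not
dictated by anything upstream; Wilson behaves well at boundaries). ANCOVA
is OLS of the response on a binary group indicator plus one covariate,
without interaction; residual skewness and a normality p-value are attached
for diagnostics rather than auto-remediation. Spearman partial correlation
rank-transforms all three variables and applies the first-order partial
formula with a t-approximation on n − 3 df. Every p-value produced in a run
is collected and adjusted in one Benjamini–Hochberg pass at the end, so the
FDR is controlled across the whole study, not per table. BH is monotone in
the raw p-values but *not* idempotent — adjusted values fed back in will
generally change again — so only single-pass adjusted values are reported.

## Synthetic data: what it emulates, and what it does not

Trees are pure-birth (Yule) with exponential waiting times; branch lengths
share the arbitrary "substitutions/site" unit of the transition rates.
Orthogroup sizes are 3 + geometric(p = 0.15) capped at 48, reproducing the
empirical pattern that most orthogroups are small while a minority reach
the ≥ 10 tips needed for tree analysis. The QS character walks a one-step
ladder 1↔2↔4↔8 subunits with gain and loss rates of 0.25 events per unit
branch length each (a regime where roughly half the simulated trees keep a
resolvable root state); an equal-rates variant is provided for model-match
calibration, where a true rate of 0.5 is the reference recovery condition.
Root states are drawn uniformly. Toy complexes plant interface residues
strictly beyond both classification thresholds (RSA 0.3–0.9, burial
20–80%) and non-interface residues strictly below (surface burial < 5%,
buried RSA < 0.15), with multiplicative complex-SASA noise of ±2% — small
enough never to cross the 10% burial threshold, so planted recovery is
exact by construction. Same-count homomers within an orthogroup share one
planted interface and identity alignment maps, so lateral changes are
absent from the generated studies unless configured otherwise. Annotation
counts are negative-binomial (dispersion 5) with a non-MO mean of 4 terms
per protein and an MO multiplier of 1.5; sampled leaves carry a redundant
ancestor with probability 0.5 so the hierarchy filter has real work.

Consequently, passing tests demonstrate correctness of the machinery under
a model-true world: real data add misrooted gene trees, alignment and
biounit errors, heteromers, non-ladder QS jumps, phylogenetically
correlated annotations and database biases that the generator deliberately
does not model (a configurable wrong-QS error rate is the only pathology
stub). Agreement with the planted truth is a necessary, not sufficient,
condition for correct inference on real structures.

## Problem sizes and numerics

The test suite validates the pruning likelihood and marginals against
exhaustive enumeration (200 random trees ≤ 6 tips, ≤ 3 states, 1e-8),
parsimony against the exhaustive minimum (200 trees ≤ 7 tips), MAD rooting
against a 10⁴-point grid per branch (100 trees, 8 tips), rate recovery
(200 Yule trees × 64 tips, true rate 0.5, median within 15%), planted
interface recovery (500 complexes), type-I calibration (2,000 null
batteries of 5 tests), and null/effect behaviour of the MO change-rate
comparison (100 replicates × 100 trees/arm × 32 tips). The acceptance
script repeats these at reduced replicate counts (100 trees for recovery,
500 batteries, 30 replicates per arm condition) to keep a full from-scratch
rerun within a few minutes; sizes are recorded in its JSON output alongside
each value. Change-rate monotonicity in the true rate is checked with a
binary monomer/dimer character: with more states, saturation pushes
marginal probabilities below the 0.51 resolution threshold and the
filtered statistic stops rising — a property of the resolution rule, not a
numerical artifact.

## Known limitations

- The ACCTRAN uppass is a deterministic rootward-preferring Fitch
  refinement; it guarantees minimality but not bit-compatibility with other
  parsimony implementations in ambiguous regions.
- The ER model is the only substitution model; all-rates-different and
  covarion-style models are out of scope.
- Interface overlap assumes a one-to-one residue alignment per protein pair
  over the representative subunit's chains; multi-chain correspondence
  beyond that convention is the caller's responsibility.
- The pipeline consumes SASA tables and alignment maps produced elsewhere;
  it never computes SASA from coordinates nor superposes structures.
- `qs_per_protein` inherits the upstream caveat that spurious monomeric
  database entries inflate per-protein QS counts.
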