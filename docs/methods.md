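# Methods

## Problem setting

An enzyme's catalytic residues are its least substitutable positions: a
nonsynonymous variant that changes an active-site residue is expected to
abolish or strongly perturb catalysis and, through it, the pathway the
enzyme serves. Human cells have no practical genome-scale flux model in
which such a loss can be simulated directly, but *S. cerevisiae* does. The
pipeline therefore (i) finds the yeast protein orthologous to a human
candidate enzyme, (ii) verifies that the variant's catalytic position is
conserved between the two sequences and that the pair catalyses the same
reaction within the same pathway, and (iii) simulates a total
loss-of-function knockout of the yeast gene in a constraint-based
metabolic model, reading the predicted growth phenotype as a proxy for the
metabolic consequence of the human variant.

## Orthology by reciprocal best hits

Orthology is operationalised as mutual best hits: human protein *a* and
yeast protein *b* are paired when *b* is a's highest-scoring significant
hit against the yeast proteome and *a* is b's against the human proteome.
Significance is `E < 1e-5` by default (configurable; `1e-4` is a common
alternative). Best hits are chosen by bit score, ties broken by lower
E-value and then lexicographic subject accession, so reruns are
byte-identical.

Every query gets exactly one label. A many-to-one collision — several
queries sharing one best subject — is resolved in favour of the
highest-scoring query; the losers are labelled `PARALOGOUS`. This is an
explicit operationalisation of what is usually a manual call; the margin
thresholds of the later paralog screen (second-best hit within 50 bits or
above 0.9 of the best bit score disqualifies a candidate) are likewise
configurable approximations of manual alignment inspection, not measured
constants.

The built-in aligner is an optimal dynamic-programming alignment
(Biopython's `PairwiseAligner`) under BLOSUM62 with affine gap cost
`11 + 1·L`. Raw scores are placed on a bit scale with fixed gapped
Karlin–Altschul-style constants (λ = 0.267, K = 0.041) and E-values as
`m·n·2^(−bits)`. These statistics are intentionally simple: they give a
deterministic, monotone transform of the raw score for thresholding and
ranking. Agreement with any particular external search tool's E-values is
a non-goal; when an external tool's tabular output (12-column, optionally
extended with the gapped alignment strings) is supplied, its scores are
used as-is.

## Active-site conservation

Positions are 1-based in sequences and 0-based over alignment columns; all
TSV output is 1-based. A human site maps through its alignment column to
the partner position; a gap in the partner column maps to `GAP` (distinct
from "outside the aligned span", which is an error for bare mapping but a
recorded non-conserved outcome in the conservation call). Conservation
requires residue identity at the mapped position and, when the yeast
protein carries its own curated site annotation, agreement between the
mapped and annotated positions (disagreements are flagged). When the
yeast annotation is absent, identity alone decides and the mapping is
marked `annotation-absent`.

The conservation block is the maximal run of gap-free alignment columns
with positive BLOSUM62 score containing the site column; identical columns
render as the residue letter and positive non-identical columns as `+`
(the alignment-midline convention). Gap columns and non-positive scores
both terminate the block. Published block strings were produced by an
unstated rule, so bit-exact regeneration of any particular printed block
is not claimed; on identical inputs the rule here is deterministic.

## Candidate filter cascade

Five stages in a fixed order, each strictly narrowing the previous
survivor set, each dropout recorded with its first failing stage:

1. **1:1:1** — exactly one annotated pathway and one reaction (one
   substrate/product compound set). This confines the knockout's effect to
   a single annotated conversion.
2. **Reciprocal ortholog** — intersection with the RBH pair set.
3. **Active-site conservation** — the verdict above; a missing
   conservation result for a survivor is a hard error, never a silent
   skip.
4. **Unique ortholog** — the paralog screen (bit-margin / ratio rule).
5. **Pathway match** — at least one shared pathway with identical
   substrate/product compound-ID sets and no shared-pathway mismatch.
   Compound identity is exact ID equality within the CID:/SID: namespaces;
   no chemical-similarity matching. A pathway annotated only in yeast with
   matching chemistry is tolerated (recorded, not disqualifying), since
   annotation coverage differs between species.

Stages can be omitted but never reordered; survivor sets are sorted, so
input order cannot change any result.

## Constraint-based modelling

FBA is the LP: maximize `c·v` subject to `S·v = 0`, `lb ≤ v ≤ ub`, with
`c` selecting the biomass pseudo-reaction (flux in hr⁻¹; other fluxes in
mmol·gCDW⁻¹·hr⁻¹). The solver is scipy's HiGHS, which is deterministic
for fixed input ordering; reaction order is the model's declared order. A
least-squares polish step projects the returned vertex onto the equality
system, giving mass-balance residuals `max|S·v| ≤ 1e-9·max(1, max|v|)` on
the model scales used here (random toy models validate this bound in the
suite).

**Taxicab (parsimonious) stage.** Among optima, the reported flux vector
minimizes `Σ|v|` via the split formulation `v = v⁺ − v⁻`, `v⁺, v⁻ ≥ 0`,
with the first-stage objective fixed as an equality row and polished with
it. At an L1 optimum a futile cycle (a loop carrying flux with no effect
on the objective) always collapses to zero, which is why panel fluxes are
reported from this stage. The objective drifts by at most 1e-9 (asserted).

**Knockouts.** Gene-level knockouts evaluate each reaction's GPR with the
deleted genes set to false (AND = complex subunits, OR = isozymes; empty
rule = always active) and force the bounds of inactive reactions to
[0, 0] — a total loss of function. Reaction-level targets are zeroed
directly; both entry points exist because a curated "reaction tested" may
not coincide with a gene deletion's GPR footprint. The input model is
never mutated (copy-on-write).

**Growth classification.** `NO_GROWTH` below ε = 1e-6 hr⁻¹ (an infeasible
LP also classifies as no growth). The threshold is a package default, far
below any biologically meaningful growth rate and far above solver noise.

**Biomass augmentation.** Stock biomass functions omit many cofactors, so
a knockout upstream of, e.g., heme or a charged mitochondrial tRNA can
look silent. Augmentation adds a small requirement (default 0.0005 per
metabolite) in one of two modes: *coefficient* (decrement the metabolite's
biomass coefficient — the default, treating the printed value as a
per-growth requirement) and *demand* (a sink reaction whose lower bound
forces the flux, treating it as an absolute rate). Both are exposed
because the two readings differ in units (mmol/gCDW vs mmol/gCDW/hr) and
the literature is not always explicit; on the fixture models both modes
give the same qualitative knockout contrast. Coefficient-mode augmentation
can only lower growth (extra requirement at fixed machinery), which the
suite asserts.

## Synthetic data

**Proteomes.** Each planted pair is an i.i.d. random ancestor (uniform
over the 20 residues, length 80–160 by default) plus a diverged copy.
Substitutions occur per site with probability `1 − target_identity`
(default 0.6) and the replacement is drawn with probability ∝
`exp(BLOSUM62[a,b]/2)`, so diverged copies still score positively;
insertions/deletions are geometric with rate 0.01. Random unrelated
sequences share ≈ 5–6% identity, so planted pairs are mutually nearest by
a wide margin at identity ≥ 0.35 (enforced as a config floor). One active
site is planted per pair with a configurable fate: `preserve` (never
substituted), `mutate` (forced substitution), or `delete_column`. Decoy
paralogs are within-species duplicates at 0.95 identity, which creates
exactly the many-to-one collisions the classifier must resolve. Default
sizes (5–6 pairs, 0–3 decoys) keep the all-vs-all alignment step
sub-second while exercising every code path.

What the simulator does **not** emulate: domain architecture, repeats and
low-complexity regions, compositional bias, and realistic divergence-time
structure. Passing recovery tests therefore demonstrates the correctness
of the RBH/conservation machinery, not its performance on hard real
proteomes, where best-hit ties and domain shuffling make orthology
genuinely ambiguous.

**Toy metabolic models.** Parallel carbon branches (uptake capped at
`capacity_i`, conversion to precursor at `yield_i` behind one gene each)
feeding a biomass that consumes one precursor per unit growth; wild-type
growth has the closed form `Σ capacity_i·yield_i`, min-ed against
`ribose_capacity / ribose_coefficient` when the optional ribose branch is
enabled (its single "isomerase" reaction is then essential under every
biomass variant). The optional cofactor branch produces a mitochondrial
cofactor behind a two-gene complex (AND; OR makes them isozymes) that
nothing consumes until the biomass is augmented — reproducing the design
in which a knockout is silent under the stock biomass and lethal under the
augmented one. Every generated model passes validation and matches its
closed form to 1e-9 (asserted for a battery of configs).

**Random LP models.** For oracle tests, random sparse stoichiometries with
finite bounds straddling zero: the zero vector is always feasible and the
polytope is bounded, so exhaustive vertex enumeration (fixing every subset
of `n − rank(S)` variables at a bound and solving the reduced system) is a
complete, independent reference for the LP optimum.

## Numerical and design choices

- LP feasibility/optimality: HiGHS defaults plus the least-squares polish;
  comparisons against the enumeration oracle use 1e-7, mass balance 1e-9
  relative, taxicab objective drift 1e-9 absolute.
- Best-hit and owner tie-breaks are total orders (bit, E-value,
  accession), making every report byte-stable.
- The curated-table loader verifies SHA-256 checksums so packaging
  corruption fails loudly; tables are transcribed exactly as printed
  (including historical spellings and lowercase variant residues).
- The filter cascade's planted dropout identities in tests (which pair
  fails conservation, which four fail the paralog screen) are fixture
  choices: the curated tables record the cascade's shape
  (34 → 11 → 10 → 6) but not which accession fell at which of two adjacent
  stages, and the fixtures do not assert otherwise.
- Pipeline reports carry the config hash, never timestamps; the manifest
  records checksums and allows skipping a stage whose recorded outputs are
  intact.

## Problem sizes

Default test and acceptance runs use 5–6 planted pairs with up to 3
decoys, toy models with ≤ 12 reactions, 100 random LP models of ≤ 8
reactions, and GPR truth tables over ≤ 4 genes (all deletion subsets) —
sizes at which every oracle is exact and the full battery completes in
seconds.

## Known limitations

- RBH is a one-to-one criterion: lineage-specific duplications,
  co-orthology groups and domain-level homology are out of scope.
- Paralog exclusion approximates a manual judgement with two thresholds;
  the defaults are documented but not calibrated against curated sets.
- Pathway matching requires exact compound-ID equality; tautomers,
  protonation states or alternative database IDs for the same chemical
  will read as mismatches.
- The FBA layer implements plain FBA + L1 minimization only: no flux
  variability analysis, MOMA/ROOM, thermodynamic constraints, or
  kinetics.
- A knockout prediction in yeast transfers to human only under the
  pipeline's conservation assumptions (site, reaction chemistry, pathway
  context) and says nothing about dominance, dosage, or heterozygous
  states.
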