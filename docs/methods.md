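# Methods

This note records the model assumptions, algorithmic choices and numerical
conventions behind `topomod`, and what the synthetic benchmarks do and do
not demonstrate.

## Model representation

A model is a sparse stoichiometric matrix `S` (metabolites × reactions)
with per-reaction bounds `[lb, ub]` in arbitrary but consistent flux
units. A reaction is *reversible* iff `lb < 0 < ub`; a reaction clamped to
one direction (including a backward-only clamp `lb < 0, ub <= 0`) is
treated as irreversible with a fixed sign. Boundary metabolites — those
tagged with the external compartment `[e]`, declared unbalanced in the
source file, or participating only in single-metabolite exchange columns —
are excluded from the steady-state constraint. Compartments are encoded as
bracket suffixes (`agm[p]`); SBML species identifiers are normalised to
this form on load. GPR rules are stored verbatim and as flat gene sets;
only the gene sets are used downstream (the correlation analysis needs
genes, not boolean structure).

## Reduction and compression

1. **FVA** (two LPs per reaction, HiGHS) finds each reaction's flux range.
   Reactions with `|min|, |max| <= tol` are blocked and removed; reversible
   reactions whose range is one-sided get the corresponding bound set to 0.
   A single global FVA suffices: removing identically-zero columns leaves
   the flux polytope unchanged, so no new blocked reactions can appear and
   the fixpoint is reached after one pass.
2. **Duplicate merging** collapses columns identical up to sign and
   positive scaling; an opposite irreversible pair becomes one reversible
   reaction. Capacities add; GPRs are unioned.
3. **Linear-pathway compression** eliminates internal metabolites with
   exactly one producer and one consumer by substituting their balance
   into the surviving column; the chain members are fully coupled, so the
   flux cone projected on retained reactions is unchanged (verified by FVA
   equality within 1e-8 in the tests). A lump is irreversible as soon as
   any member is. Degree-2 status is evaluated on the full stoichiometry,
   currency metabolites included, so compression never merges across
   cofactor hubs. Chains whose net stoichiometry cancels are reported and
   left alone.

Provenance (`ReductionRecord`) maps every compressed reaction to its
members with multipliers. Chain expansion is exact; for merged duplicates
the expansion routes flux through the first member, which is exact only up
to that member's capacity — the linear map cannot represent a capacity
split, and the conservation property is therefore validated on chains.

Defaults: `tol = 1e-9`, default bounds ±1000 (standard constraint-based
practice; results are insensitive to the bound magnitude as long as it
dominates realistic fluxes).

## Clustering

Currency metabolites are removed *for clustering only*, according to a
role table: a currency metabolite stays in reactions that synthesise or
degrade it or use it as a building block, and reactions flagged ambiguous
keep everything. Reactions sharing a retained, non-boundary metabolite are
linked; modules are the connected components of this graph restricted to
reversible reactions. A bordering irreversible reaction is *internal* to a
module when all of its retained metabolites occur among the module's
reversible reactions, otherwise *external* — the only reading consistent
with modules being "insulated by" irreversible reactions while those
reactions still border several modules. Boundary metabolites never act as
connectors; reversible exchange reactions therefore enter modules through
their internal metabolite only.

`module_subnetwork` restores the original stoichiometry (currency
included) for a module's reversible + internal + external reactions, and
marks as boundary every metabolite also touched by reactions outside the
subnetwork — currency metabolites become boundary automatically because
their other consumers are elsewhere in the network.

Antiporter handling: reversible 1:1 two-species cross-compartment
exchanges are detected structurally; the keep-list is greedy in reaction-id
order, dropping an antiporter only when every movement it provides remains
available. The goal (transportability preserved) is fixed; the greedy
order is a deterministic implementation choice.

## Directed-topology enumeration

A DT orients every reversible reaction of a module; it is feasible when
all module reactions can carry flux simultaneously at steady state and no
internal cycle is consistently oriented. Counting is exact over
arbitrary-precision integers; DoF is reported to one decimal.

Pattern classes:

* **Mass balance.** For each internal metabolite, if the incident
  irreversible reactions do not already guarantee a producer (consumer),
  the orientation sending all reversible neighbours the other way is
  infeasible — at most two patterns per metabolite.
* **Pooled pairs.** Whenever a reaction's internal support is exactly two
  metabolites with opposite-sign coefficients, the pair is conserved as a
  weighted pool and the same balance argument applies to the pool's
  external neighbours. This captures infeasibilities that single-metabolite
  balances cannot see when each metabolite keeps a connector as private
  escape (two parallel cofactor-coupled interconversions are the canonical
  case). Pools are emitted for every qualifying pair; they are sound in
  general and simply redundant when a single-metabolite pattern subsumes
  them (a subsumption filter removes such duplicates). Chains of three or
  more pooled metabolites are not pooled further: only pairwise pools are
  generated, and the sampling validators flag any resulting
  incompleteness as unexplained infeasible samples.
* **Loop law.** `S_int` collects columns whose metabolites are all
  internal (boundary-touching and single-metabolite exchange columns are
  exchange-like and excluded) over internal rows, converted exactly to
  rationals (binary floats are exact rationals; no denominator limit).
  Support-minimal null vectors are enumerated by solving for the
  one-dimensional solution spaces over all (d−1)-subsets of coordinates —
  every elementary vector vanishes on d−1 independent coordinates, so the
  enumeration is complete — then filtered to minimal supports. Each
  orientation compatible with the irreversible members yields one pattern.
  Above null-space dimension 12 (or past a 300k-subset budget) the exact
  elementary enumeration is replaced by the reduced basis itself, flagged
  incomplete; the heuristic generator and the sampling validators are the
  safety net there. Fixture modules never reach that regime.

**DFS.** Patterns become (support, sign) bitmasks over the module's
reversible reactions. Reactions appearing in no pattern are free and each
doubles the count; the search runs over the constrained reactions ordered
by descending pattern participation (maximises early pruning; ties broken
by id, so the traversal is deterministic), rejecting a branch the moment
the partial assignment contains a full pattern. Per-pattern rejection
counts are first-match attributions. A configurable cap (default 40
constrained reactions) guards against un-prunable searches.

**Heuristic patterns.** For each known pattern with ≥3 fixed directions,
one constraint is relocated onto each unconstrained reaction (both signs).
A candidate is kept only when clamping its directions leaves some module
reaction unable to carry any flux (checked by opportunistic flux
consistency, a handful of LPs), which certifies that every matching DT is
infeasible. The oracle is sound, not complete, so emitted patterns never
over-prune; on the default synthetic archetypes the base rules are already
complete and the heuristic adds nothing, which the tests assert.

## Feasibility verdict (the oracle)

The brute-force and sampling validators decide feasibility of a single DT
independently of the pattern machinery: (1) the orientation is checked
against every exact elementary cycle — a match in either direction is a
second-law violation; (2) one LP maximises the sum of per-reaction
activity slacks `t_j <= eps` subject to `sign_j · v_j >= t_j`; if all
slacks reach `eps = 1e-4` the DT is feasible. Reactions whose slack falls
short are re-checked individually (`tol = 1e-6`): if each reaction can be
active alone, the convex average of those solutions activates all of them,
so the per-reaction fallback is decisive and the single-LP fast path is
only an optimisation. Checking conformal elementary cycles suffices
because any sign-consistent null vector decomposes conformally into
elementary ones.

Random sampling reports the feasible fraction with a 95% Clopper–Pearson
interval and cross-checks every infeasible sample against the known
patterns, reporting unexplained ones. Targeted sampling covers the full
`2^k` combinatorial of every k-subset with random completions. The
directionality-clique analysis computes Pearson correlations of signs
across sampled feasible DTs and enumerates maximal cliques
(Bron–Kerbosch) above an absolute-correlation cutoff (default 0.85);
constant-direction reactions are excluded with a warning.

## Expression validation

Distance-2 pairs (exactly one intermediate reaction in the shared-
metabolite graph) are the closest pairs that can span two modules, making
intra vs extra comparable at equal proximity. Genes with standard
deviation ≤ 0.6 (constitutive, on log2(TPM+1)-scale data) or present in
the GPRs of more than 50 reactions (promiscuous, artificially correlated)
are removed. Pearson correlations are recorded per gene pair, not
aggregated per reaction pair; signed values are kept, absolute values are
summarised. Two-sample KS and Wilcoxon rank-sum tests compare the
intra/extra |r| distributions, with summary fractions (|r|>0.8, |r|<0.1)
and 20-bin histograms.

## Synthetic data: what it emulates, what it does not

The generator plants modules of five archetypes — single interconversions
(70% of modules by default, matching the predominance of single-pathway
modules in real reconstructions), chains (3–6 reactions), rings (3–5),
diamonds and cofactor-coupled mixed pairs — joined only by irreversible
connectors (two per neighbouring module pair) and optionally decorated
with shared currency pairs (probability 0.3). Expression draws one latent
factor per module: intra-module gene pairs correlate at `rho_intra`,
cross-module pairs at `rho_extra`, noise makes unit variance; defaults
are the null (`rho = 0`), with 150 samples and two genes per reaction.
All randomness flows from one seed; identical spec + seed gives
byte-identical outputs.

On chains, rings, diamonds and pairwise-pooled motifs the three pattern
classes are provably complete (on trees, local producer/consumer
conditions imply a positive circulation; the only cycles are planted rings
caught by the loop law; pool violations are caught pairwise), so
DFS-vs-brute-force equality on these fixtures certifies the search and the
pattern generators, not an absence of harder cases. A `random_sparse`
archetype (random spanning tree plus a chord) exists as an opt-in stress
test precisely because completeness is not guaranteed on arbitrary
topologies — real networks can require the heuristic class, and counts on
them are upper bounds unless confirmed by sampling. The generator makes no
attempt to match real-organism degree distributions, stoichiometric
coefficients beyond ±1, compartment structure, or GPR complexity; passing
tests demonstrate correctness of the algorithms under modular conditions,
not performance claims about any particular reconstruction.

Benchmark sizes used by the test suite and acceptance script (chosen to
keep every run deterministic and desk-scale): ≥200 generated modules with
n ≤ 12 for the DFS/brute-force equivalence, 1000 audited rejections for
pattern soundness, 50 networks for compression invariance, 100 for
partition recovery, 500 null replicates and 100 planted replicates
(`rho_intra = 0.6`, 200 samples) for the expression calibration.

## Known limitations

* Pooled balances are pairwise only; a module needing a 3-metabolite pool
  rule would show up as unexplained infeasible samples rather than being
  pruned.
* Duplicate-merge provenance cannot express capacity splits (see above).
* The DFS count is exact only as far as the pattern set is sound — which
  is guaranteed — and its *equality* with the true DT count is certified
  only where an oracle (brute force or exhaustive sampling) has been run.
* Directionality constraints and currency roles are inputs; the package
  assigns no directions from thermodynamic data.
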