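# Methods

## Model

`logicnem` infers small signaling networks from binary perturbation-effect
screens.  The model has three parts:

1. **A signaling graph** `G`: a DAG over the perturbed genes (S-genes).
   Perturbation effects propagate downstream along the edges.
2. **Hidden attachments** `Θ = {θ_1, …, θ_m}`: each effect reporter
   (E-gene, typically a differentially expressed downstream gene) is
   linked to exactly one S-gene.  The attachment is unobserved and is
   marginalized during scoring.
3. **Logic gates**: every S-gene with exactly two parents carries one of
   five gates — AND, OR, XOR, NOT-A, NOT-B — that states how the parents'
   disruption signals combine into the child's disruption.

Gates are defined on *disruption* indicators (1 = the incoming signal is
cut), not on activity states.  With this convention the classic nested
effects model, in which any upstream perturbation propagates, is exactly
the all-OR special case; no double negation is needed anywhere.  The full
truth tables are in `logicnem.graph`; the per-child response to (A knocked
out, B knocked out, both) is:

| structure   | d₁₀ | d₀₁ | d₁₁ | reading                        |
|-------------|-----|-----|-----|--------------------------------|
| AND         | 0   | 0   | 1   | complete redundancy            |
| OR          | 1   | 1   | 1   | no interaction (classic NEM)   |
| XOR         | 1   | 1   | 0   | mutual prevention              |
| NOT-A       | 0   | 1   | 0   | A masks the effect of B        |
| NOT-B       | 1   | 0   | 0   | B masks the effect of A        |
| A-only      | 1   | 0   | 1   | edge from A only               |
| B-only      | 0   | 1   | 1   | edge from B only               |
| unconnected | 0   | 0   | 0   | no edges                       |

These are exactly the 2³ = 8 binary triples with the wild-type response
fixed at 0; five are irreducible gates and three reduce to edge-deleted
graphs, which is why only five gates are modeled.

**Masking orientation.** The labels NOT-A/NOT-B are not self-explanatory
and the orientation had to be fixed by convention: here NOT-A means
*knocking out A silences B's effect* ("A masks B"), i.e. the masked
partner's single-knockout effect vanishes in the double knockout.  The
convention lives in one place (`graph._GATE_FUNCS`) and everything else —
classification, accuracy scoring, orientation normalization — derives from
it.  A mirrored convention would relabel NOT-A ↔ NOT-B consistently
without changing any likelihood; results produced by other tools may use
the mirror image.

**Propagation.** Expected effects are computed by evaluating nodes in
topological order: directly knocked-out genes are disrupted irreversibly,
one-parent children inherit the parent's bit, two-parent children apply
their gate.  Stacking the resulting row vectors over all experiments gives
the design matrix Φ.  Irreversibility plus acyclicity guarantee a unique
steady state, so no fixed-point iteration is needed on the model class
actually searched.  A separate synchronous evaluator
(`steady_state_general`) handles arbitrary Boolean networks, including
cyclic ones: it iterates the synchronous update from the all-active state
with knockouts clamped and reports the fixed point or the limit cycle.  On
acyclic graphs it provably agrees with the propagation rule (tested
exhaustively over all knockout sets of small graphs).

## Likelihood

A data cell `e` with expected effect `f` contributes `1−α` (e=0,f=0), `α`
(1,0), `β` (0,1), `1−β` (1,1), with false-positive rate α and
false-negative rate β supplied by the user (defaults 0.1/0.1; they are
treated as known experiment properties, not estimated).  Reporters and
replicates are independent given the model, so the marginal likelihood
factorizes over reporters:

    P(D | Φ) = (1/nᵐ) ∏ᵢ Σⱼ ∏ₖ P(eᵢₖ | Φ, θᵢ = j)

All computation is in log space with log-sum-exp; products over a hundred
reporters underflow otherwise.  There is no "unattached" null target by
default (the sum runs over the n S-genes only); `include_null=True` adds an
all-zero expected column for reporters explained by noise alone.  The
implementation reduces each reporter×gene term to four agreement counts and
evaluates the whole model space with batched matrix products; a brute-force
sum over all nᵐ joint attachments is kept in the test suite as the
independent oracle (they agree to 1e−9 in log space on hundreds of random
instances — exact, because the reporters factorize).

## Search and identifiability

The model space is every labeled DAG with in-degree ≤ 2, each two-parent
node expanded into one hypothesis per gate: 61 hypotheses over 3 genes,
3,515 over 4.  Up to five genes the space is scored exhaustively (batched,
with design matrices cached per gene set and experiment panel).  Beyond
that a seeded greedy hill climber is provided: single-edge insertions,
deletions, reversals and gate swaps, accepting the best strictly improving
move, best of `restarts` random starts.  The neighborhood can reach any
DAG in the space (delete to empty, insert in topological order), and on
3-gene instances best-of-10-restarts attains the exhaustive optimum in
≥ 95% of seeded trials.

Hypotheses with identical design matrices over the measured experiments
have identical likelihoods.  Searches therefore annotate every hypothesis
with an equivalence-class id (byte-identical design matrices) and report
the whole top class; a canonical representative — fewest edges, then
lexicographic — is used only where a single model is required.  Two
structural causes are flagged: identical transitive closures (the classic
NEM equivalence), and the parent-chain collapse — when one gated parent
regulates the other, knocking out the upstream parent acts like the double
knockout, which collapses AND with A-only, OR with B-only, XOR with NOT-A,
and NOT-B with the unconnected child.

## Modulator screening

For a genetic-interaction pair (X, Y) with an X:Y double knockout measured,
every gene whose single knockout shows at least one effect is a candidate
modulator Z.  Per candidate, the data are restricted to the *common effect
set* — reporters with an effect in any of the X, Y, Z singles or the X:Y
double — and to those four experiments, so the marginal likelihoods of all
3-gene hypotheses are comparable; the space deliberately contains models
with and without gates.  The top equivalence class decides the category:
the gate label (oriented to the pair order) when the class contains a model
with X and Y gating Z; `no-epistasis` when it does not but Z shares effect
reporters with the pair; `no-information` when Z shares no reporters —
decided from overlap alone, before any likelihood is computed.  Ambiguous
top classes (several gate labels) report all labels.  A pair whose
significant modulators span ≥ 2 gate categories is labeled *mixed
epistasis*.

The common set is built per triple from the four relevant columns.  An
alternative reading — union over *all* single perturbations in the screen,
giving one set per pair — would make the set independent of Z; the
per-triple construction is used because it keeps candidates with disjoint
downstream programs comparable on their own support.

**Significance.** The screen itself has no built-in threshold.  The filter
keeps a candidate when its best gated model leads the best non-gated model
by more than a margin (default 0 log-units).  Optionally an empirical null
is built by permuting the modulator's single-knockout column across
reporters, which destroys exactly the modulator–pair coherence a gated
triple needs while preserving every column's effect frequency.  Two
rejected alternatives are instructive: permuting whole reporter rows leaves
the marginal likelihood invariant (reporters are exchangeable), and
permuting all columns independently inflates the null, because gated models
generically fit incoherent reporters better than gateless ones.  The
chosen null is conservative on truly unrelated modulators (p-values
concentrate near 1 rather than being uniform, since reassigning the
modulator column can only create pair coherence, not remove absent
coherence); planted modulators reach the minimal attainable p-value.

## Synthetic data and the benchmark

`random_network` draws a ground truth with exactly one planted gate: a
uniformly chosen child, two uniformly chosen parents, a uniformly chosen
gate label.  Remaining ordered pairs are added independently with
probability 0.25 subject to acyclicity and two constraints:

* extra edges only target nodes of in-degree 0, so the truth has exactly
  one gated node (the object the benchmark scores);
* no edge is ever placed between the two gated parents.  With a
  parent-parent edge the planted gate is unidentifiable *in principle*
  (the collapse above), and the benchmark would measure that
  identifiability gap rather than inference accuracy.

Reporters (default 100) attach uniformly at random; data are simulated for
all single knockouts plus the gated pair's double knockout — the minimal
panel distinguishing all 8 structures — and each cell flips independently
(0→1 with α, 1→0 with β).  The defaults (4 genes, 100 reporters, α = 0.1,
β swept over {0.01, …, 0.5}, 100 networks per β) are the benchmark's study
conditions.  What the generator does *not* emulate: correlated noise across
reporters, reporter-specific noise rates, partial or quantitative effects,
batch structure, and unmeasured S-genes; passing benchmarks therefore
demonstrate correctness of the inference machinery under the stated noise
model, not robustness to everything real expression screens do.

Three accuracies are recorded per network, with inference scored at the
true noise rates and the best-scoring hypothesis (canonical tie-break)
taken as the point estimate:

* **edge** — agreement of transitively closed adjacencies over ordered
  off-diagonal pairs, insensitive to shortcut edges within an equivalence
  class;
* **logic** — fraction of the truth's gated triples recovered with the same
  parents and the same orientation-normalized label (NOT-A vs NOT-B
  confusion counts as wrong);
* **expected data** — cellwise agreement of the reporter-level expected
  effect matrices, the inferred side expanded through its MAP attachments.

Medians per β are the headline summary.  Per-network seeds derive from the
master seed as `SeedSequence([seed, beta_index, network_index])`, so any
single run is reproducible in isolation.  Restricting the search space to
OR-only (`gates=("OR",)`) gives the no-logic nested-effects baseline.

## Numerical and degenerate-case choices

* Rates are validated to `0 ≤ α, β < 1` and `α + β < 1`; zero rates are
  allowed and produce −∞ cells handled explicitly (no NaNs from `0·−∞`).
* Attachment ties (identical design columns) resolve to the lowest gene
  index and are reported as ties with the full posterior.
* Score ties in searches are broken by the canonical key (fewest edges,
  then lexicographic edges, then gates), making all rankings deterministic.
* The empty experiment list, the wild-type experiment (all-zero Φ row) and
  an all-zero dataset are all legal inputs with defined outputs.
* Exhaustive enumeration refuses > 5 genes and points to the greedy
  search; in-degree > 2 is rejected at graph construction.

## Scales used in the shipped checks

The test suite runs the benchmark at 30 networks per β over
β ∈ {0.01, 0.025, 0.05, 0.1, 0.2} and the screening recovery at 100 seeded
trials; `scripts/acceptance.py` reruns the benchmark at the full 100
networks per β.  These sizes were chosen so the complete suite stays in the
tens of seconds while keeping the medians and rates stable across seeds.

## Known limitations

* Gates over more than two parents are out of scope (rejected, not
  approximated).
* α and β are user inputs; there is no estimation from data.
* Binarization of continuous expression data is a thresholding hook
  (|value| ≥ t), not a reproduction of any particular screen's pipeline.
* Quantitative (partial) redundancy cannot be represented in binary data;
  only complete redundancy and masking-type epistasis are addressed.
* The NOT-A/NOT-B orientation is a declared convention that may be
  mirrored relative to other implementations.
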