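# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic data do and
do not emulate, and the numerical choices that matter.

## Character model

The character is a single unordered 3-state trait: 0 = uncinate
process absent, 1 = cartilaginous (or calcified) process,
2 = ossified process.  Partial ambiguity is representable everywhere —
a taxon's coding is a non-empty subset of {0,1,2}, with the full set
written `?` — although typical datasets use only singletons and `?`.

Evolution is modeled as a continuous-time Markov (Mk) process.  The
default parameterization is equal rates (ER): one free rate q in
events/Myr per ordered state pair, giving the closed-form transition
probabilities

    P_same(t) = 1/3 + (2/3)·exp(−3qt)
    P_diff(t) = 1/3 − (1/3)·exp(−3qt).

SYM and ARD parameterizations are available (transition matrices via
`scipy.linalg.expm`), but with ~20 informative taxa anything richer
than ER is practically unidentifiable, so ER is the default.  The root
prior is flat by default (identical to the ER stationary distribution);
a stationary or user-supplied prior can be configured, and the choice
is echoed in result metadata.

## Inference

**Parsimony.**  Sankoff's algorithm with a unit cost matrix.  The
down-pass gives the minimum change count; an up-pass combining each
node's subtree cost with the "outside" cost yields the MPR set — the
states a node takes in at least one most-parsimonious reconstruction.
Ambiguous tips contribute zero cost for any state in their set.
Branch lengths are ignored, so parsimony results are computed once per
coding and are identical between branch-length modes.

**Maximum likelihood.**  Felsenstein pruning with per-node rescaling
(log-scale accumulation) to avoid underflow.  The ER rate is fitted by
bounded 1-D optimization on log q (bounds 1e-8 to 1e3 events/Myr);
SYM/ARD use L-BFGS-B on log rates.  Non-convergence is flagged in the
result, never silent.  Marginal node probabilities are exact, via an
up–down pass equivalent to re-rooting at every node: the marginal at a
node is the normalized product of its subtree conditional likelihood
and the likelihood of the rest of the tree given its state.  A profile
likelihood-ratio interval for q (drop of 1.92 log units for 95%) is
available for simulation calibration.

When the likelihood is maximized on the fast-rate plateau (all
P → 1/3), the rate estimate is reported as-is and the marginals go
flat; this is the correct statistical answer for saturated or
conflicting data, not an error state.

**Bayesian.**  Metropolis–Hastings on log q.  The prior on q is
exponential with mean 100/(tree depth in Myr), i.e. q scaled by
tree-depth/100 has prior mean 1; for unit-branch-length trees the same
rule applies to the unit depth.  The proposal is Gaussian on log q,
its scale adapted every 100 iterations during burn-in toward a 20–40%
acceptance rate and frozen afterwards (so the retained chain is a
valid fixed-kernel sampler).  Defaults: 100,000 iterations, 20%
burn-in, thinning 50.  Node posteriors are Rao–Blackwellized: the
exact marginal conditional is computed at each retained sampled rate
and averaged, which converges far faster than sampling ancestral
states.  ESS (via arviz) and the acceptance rate are reported; ESS
below 100 sets a warning flag.  A given seed yields bit-identical
output.  The MH loop uses a flattened ER pruning engine (vectorized
per-branch exponentials, no matrix materialization) that agrees with
the reference pruning to ~1e-14.

## Supertree assembly

Sources are grafted sequentially onto a backbone.  For each source, a
named landmark taxon shared with the backbone is replaced in situ by
the smallest source clade containing the landmark and all source-only
taxa.  Shared taxa other than the landmark stay at their backbone
positions: if one falls inside the grafted clade it is pruned with a
topology-conflict warning (informal supertrees tolerate this); a
strict mode raises instead.  A source that re-introduces a taxon added
by an *earlier* source is always a hard conflict naming the source.
The invariant — the result restricted to backbone taxa is isomorphic
to the backbone — is property-tested.  Grafting order is user-supplied
configuration, since no principled order exists for informal
supertrees.

## Timescaling

"Basic" timescaling: tip age = first appearance datum by default (LAD
and midpoint as options), internal node age = maximum FAD over
descendant tips.  Zero or short branches are corrected by processing
nodes postorder and lifting each internal node to
max(raw age, oldest child + mbl) — the minimal rootward shift, since
every lifted node sits exactly at its binding constraint; tips never
move.  Default mbl = 1 Myr: small against stage-level stratigraphic
uncertainty, large enough to keep ML non-degenerate.  Ultrametricity
is *not* enforced — fossil tips terminate at their own ages.  The
"no branch length" analysis mode sets every branch to exactly 1 and
clears ages.  The mbl, tip-age policy and branch mode are carried in
output metadata.

## Coding rules

Evidence classes map to states through a configurable table; by
default ossified → 2, cartilaginous or calcified → 1, scar → 1,
reflecting scars being the attachment correlate of unossified
processes (calcified plates are grouped with the cartilaginous grade).
A preserved process outranks scar counts.  Multiple rows per taxon are
aggregated by summing rib counts and keeping the strongest process
class ("at least one specimen" semantics).  Expert overrides (e.g. an
outgroup with many well-preserved scar-free ribs) always win.  The
alternate approach's threshold (≥5 scar-free ribs → absent) refines
the preferred coding: its state sets are always subsets, and the two
never disagree on positive evidence — both facts are property-tested.

## Synthetic data and the study fixture

The generator produces: birth–death trees conditioned on a tip count
(forward simulation; when the extant count first reaches n the tree is
extended by the waiting time to the next event, so Yule root ages have
expectation Σ_{i=2..n} 1/(λi), which the tests exploit as a
closed-form oracle); ER characters sampled branchwise from exp(Qt)
rows; stratigraphic ranges as true tip age ± uniform offsets (FAD ≥
LAD by construction); and an observation layer where each rib of a
process-bearing taxon shows a scar with a detection probability and
ossified processes fossilize with a preservation probability.
Defaults (40 tips, birth 0.06/Myr, death 0.03/Myr, q = 0.005
events/Myr, Poisson(4) ribs, 40% scar detection, 50% process
preservation) were chosen once to match the scale of a real
uncinate-process dataset: a few-hundred-Myr tree and ~20 taxa with
positive evidence.

The packaged study fixture is *constructed*, not simulated: 40
synthetic taxa (an outgroup, a pseudosuchian-grade clade, and nested
ornithischian/sauropodomorph/theropod/maniraptoran/pennaraptoran-like
clades, assembled by grafting six source trees onto a seven-tip
backbone), hand-assigned Triassic–Cretaceous ranges, 22 taxa with
positive evidence (ossified confined to the pennaraptoran-like clade),
and exactly nine taxa codeable absent under the alternate approach
(the overridden outgroup with 13 scar-free ribs plus eight ingroup
taxa with ≥5).  Everything is deterministic: fixture files are
byte-identical across runs.

What the synthetic layer does **not** emulate: real topological
conflict among source phylogenies, non-uniform fossil recovery through
time, correlated preservation between neighboring taxa, state-dependent
diversification, and observer error in scar identification.  Passing
tests therefore demonstrate the machinery's correctness and the
method's behavior under its own assumptions, not the robustness of any
real-data conclusion to those complications.

## Calibration results the tests compute

Under the simulation defaults the suite verifies: pruning equals
exhaustive enumeration to 1e-10 on trees of ≤6 tips; Sankoff costs and
MPR sets equal exhaustive minimal labelings; ER rate recovery at 200
tips and q·depth ≈ 1 has mean relative bias of a few percent with
likelihood-ratio 95% intervals covering ≥90/100 replicates; and with a
planted root state and ~0.3 expected changes per root-to-tip lineage,
marginal ML ranks the true root state first in ≥90% of replicates (at
roughly triple that rate the proportion drops toward ~75% — the root
signal genuinely decays, which bounds what any method can promise on
slow characters).  ML rate estimates and marginal node probabilities
agree with an independent reference implementation (R/phytools fitMk
and rerootingMethod) to ~1e-7 on a frozen five-tip example.

## Problem sizes

Default test and acceptance runs use the 40-tip fixture with the
study-scale sampler (100,000 iterations) in the acceptance script, and
reduced chains (2,000–50,000 iterations) inside the test suite where
only determinism, flatness, or ML-agreement is being measured;
simulation studies use 100 replicates at 60–200 tips.  These sizes
were chosen so that each statistical claim is measured at the smallest
scale where it is stable.

## Known limitations

- Bayesian inference fixes the ER model; rate-model uncertainty is not
  integrated over (SYM/ARD are ML-only in practice).
- Timescaling is the basic max-FAD + mbl rule; no sampling-rate-based
  (cal3-style) or tip-dating methods.
- One character at a time; no hidden-rate or covarion extensions, no
  stochastic character mapping.
- The supertree grafting rule cannot detect, only warn about,
  topological conflict among sources sharing several taxa.
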