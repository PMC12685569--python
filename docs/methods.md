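# Methods

## Model

A community of S species, each with K life-cycle stages, has stage densities
N_ik governed by dN_ik/dt = g_ik(N_11, ..., N_SK).  Local asymptotic
stability at a feasible equilibrium (all N_ik > 0) is decided by the spectrum
of the Jacobian: stable iff every eigenvalue has negative real part.

To compare against the unstructured theory, the system is rewritten in
totals N_i = Σ_k N_ik and stage fractions Z_ik = N_ik / N_i (k = 1..K−1; the
K-th fraction is implicit).  The Jacobian of the rewritten system at the
equilibrium is the *structured community matrix* M_S, an SK×SK block matrix
in stage-major layout (flat index (k−1)·S + i is stage block k of species i):
block row/column 1 holds the totals, so block (1,1) is exactly the
traditional S×S community matrix of the aggregated model.  The transformed
growth rates follow from the chain rule:

    dN_i/dt  = Σ_k g_ik
    dZ_ik/dt = (g_ik − Z_ik · Σ_l g_il) / N_i .

This identity is not assumed: the `dynamics` module integrates both
representations of a concrete system and checks they agree (see Oracle).

## Random-matrix layer

Rather than specifying g_ik, each block of M_S is drawn from a random
ensemble parametrised by

| parameter | meaning | default / convention |
|---|---|---|
| S | species count | ≥ 2; study conditions use 200–250 |
| K | stages per species | 2 (juvenile/adult) unless stated |
| C | probability a species pair interacts | study conditions use 1 |
| d | self-regulation magnitude | 1; every on-diagonal block carries −d on its diagonal, off-diagonal blocks a zero diagonal |
| σ | standard deviation of the underlying normal for coefficient magnitudes | per block |
| γ | scaled strength κ(type, S, C)·σ, compared against d | per block |

σ is deliberately read as a **standard deviation** (the literature sometimes
says "variance σ"); only under this reading does the classical criterion
take the form σ√(SC) < d, and the simulated transition indeed sits at
γ = 1.00–1.02 for S = 250 (test suite).

Interaction types fix the joint sign of each off-diagonal pair: competition
(−/−), mutualism (+/+), predation (+/−, orientation random or supplied),
commensalism (0/+), amensalism (0/−), or unconstrained ("random").  Typed
magnitudes are folded-normal |N(0, σ²)| (a truncated-normal sampling route is
available; at zero mean the two laws coincide).  For the random type each
*entry* is independently present with probability C (the classical
construction); typed pairs are present jointly.

### Scaled-strength coefficients

γ = κ·σ with κ(random) = √(SC) and κ(predation) = ((π−2)/π)√(SC).  The
mutualistic and competitive coefficients are derived from the elliptic law
with folded-normal moments:

* mutualism: the positive mean E = √(2/π)σ of every present entry creates a
  rank-one outlier eigenvalue ≈ −d + C(S−1)E, which dominates; hence
  κ = √(2/π)·C·(S−1).
* competition: present entries −|N(0, σ²)| have mean −CE, per-entry variance
  σ²C(1 − 2C/π) and transpose correlation 2(1−C)/(π−2C); the bulk edge sits
  at −d + CE + σ√(SC(1−2C/π))·(π+2−4C)/(π−2C), giving
  κ = √(SC(1−2C/π))·(π+2−4C)/(π−2C) + C√(2/π).

Both are validated by simulation: the Monte-Carlo 0.5-crossing lies within
0.03 of γ = d for S = 250 at C ∈ {0.5, 1}.

### Cross-stage sign convention

One predation orientation is drawn per interacting species pair and shared
by every predation-type block.  If i predates j, each such block receives
+|draw| at (i, j) and −|draw| at (j, i) — the *same positional pattern in
every block*.  Consequently transpose-paired entries of the full matrix that
straddle an upper/lower cross-block pair (M_S[i, S+j] against M_S[S+j, i])
carry opposite signs: every two-cycle between a total density and a stage
fraction is a negative feedback loop.  This is the construction under which
cross-stage predation stabilises; flipping the positional signs of the lower
cross block turns every such loop positive and destabilises instead (both
behaviours were measured during development; the stabilising convention is
the one consistent with the ecology: more juvenile prey raises the
predator's total, more predators depress the prey's juvenile fraction).
Cross-stage competition/mutualism blocks are sign-uniform, so their
two-cycles are positive and their nonzero means add a rank-one destabilising
outlier — which is why cross-stage competition destabilises even at small γ.

### Randomness

Every generator is driven by `numpy.random.default_rng`.  An assembly spawns
`SeedSequence(seed)` into 2 + K² child streams (topology, orientations, then
one per block in row-major order), so block (1,1) is bit-identical to the
unstructured builder fed the same stream and topology.  Ensembles and grid
cells derive independent 31-bit child seeds from the top-level seed, making
results reproducible and independent of evaluation order.

## Stability classification and ensembles

The full spectrum is computed densely (`numpy.linalg.eigvals`; the matrices
are ≤ 500×500 at study scale, milliseconds each).  Stable means
max Re λ < −10⁻¹⁰; marginal eigenvalues within the tolerance window count as
*not* stable (the conservative reading of "all real parts negative").
Species with fewer than K stages are handled by zeroing the rows and columns
of their non-existing stages; each padded stage leaves one structural zero
eigenvalue which classification discounts (it refuses to discount anything
with modulus above 10⁻⁸).

The proportion of stable communities is the exact fraction of stable
replicates (default 1000 per ensemble; grids expose a fast mode at 100).
The stability transition is located as the 0.5-crossing of that proportion
along an ascending γ scan, linearly interpolated between the bracketing
points — 0.5 is the symmetric choice for a sharp transition and the
estimator is exact in the deterministic limit.

## Dynamics oracle

The random-matrix layer is cross-checked against a concrete generalised
Lotka–Volterra system with juvenile/adult structure: reproduction b_i A_i,
maturation m_i J_i, logistic self-regulation s_i on the total, and pairwise
terms whose stage placement (adult–adult, adult–juvenile, stage-symmetric)
is switchable.  The bundled 2-species fixture is synthetic — designed
in-repo, not fitted to data.  Its equilibrium is constructed by the
target-equilibrium method: fix strictly positive stage densities first,
solve the intrinsic rates r_ik from g_ik = 0, so feasibility is guaranteed
and root-finding (`scipy.optimize.root`, hybrid Powell) must recover the
construction point.

Checks performed (tests and `stagecomm oracle-check`):

* aggregate/disaggregate round-trip to 1e−14 on well-conditioned states
  (for states whose smallest stage is tiny relative to the total, the
  implicit last fraction cancels and the achievable error scales with N_i —
  asserted at 1e−13·N_i);
* trajectory equivalence of the raw and transformed systems over 100 time
  units (LSODA, rtol 1e−9) to 1e−6 relative;
* finite-difference Jacobian (central differences, step √ε·max(1, |x_i|))
  against a symbolic (sympy) Jacobian of the same fixture to 1e−6;
* stability verdicts of M_S and of the raw stage-space Jacobian agree (the
  change of variables is a smooth bijection on the positive orthant);
* stage-symmetric interactions cancel out of the fraction rows (chain rule),
  so the corresponding cross-block species entries vanish.

## Food-web adapter

Webs are directed predator→prey link sets over labelled species, read from
square 0/1 adjacency CSV (row predates column) or predator-TAB-prey edge
lists; self-links are dropped with a logged warning.  The synthetic
generator draws each ordered non-self pair independently with probability C
— it emulates the size and connectance of empirical webs but none of their
degree heterogeneity, trophic coherence, nestedness or modularity, so
passing tests demonstrate the machinery on realistic (S, C) ranges, not that
real topologies behave identically.

Web-constrained structured matrices use: random-signed within-stage block
M1 over linked pairs, predator–prey cross blocks M2 and M3 oriented by the
link direction (mutual links resolve to one orientation chosen uniformly at
random), and M4 = −d·I (no juvenile–juvenile interactions).  Two deliberate
choices:

* **Connectance for scaling.**  The descriptive connectance is the directed
  C = L/(S(S−1)).  But both coefficients of a pair are filled whenever the
  pair is linked in either direction, so the per-entry fill probability is
  the *pairwise* connectance 2·n_pairs/(S(S−1)).  γ→σ conversion uses the
  pairwise value; with the directed value a nominal γ₁ = 1.2 would produce a
  spectral radius near 1.56 and γ would no longer mean what the criteria
  compare to d.
* **Cross-block treatment.**  Replacing either cross block by random-signed
  draws (a literal reading of treating one cross direction "as random")
  eliminates the stabilising negative loops entirely — measured: no
  stabilisation at any scanned γ.  The default is therefore predation
  pairing in both cross blocks; `cross_mode="m2_random"` / `"m3_random"`
  remain available for sensitivity analysis.

With these choices a complete web at C = 1 is statistically
indistinguishable (in leading-eigenvalue location) from the
Bernoulli-topology assembler, which the suite asserts.

## Problem sizes

Ensembles in the test and acceptance suites use S = 200–250 with 20–200
replicates per point and 50-seed medians for the two-stage grids — the
package's chosen desk-scale study conditions; the transition estimates are
sharp enough at these sizes that the analytic criteria are resolved to a few
hundredths in γ.

## Known limitations

* The random-matrix layer abstracts away mechanistic functional responses
  (Holling types etc.); blocks are statistically, not mechanistically,
  parametrised.
* Feasibility of the underlying equilibria is not analysed — stability only.
* The elliptic-law competition coefficient includes finite-size mean
  corrections but is still an asymptotic statement; at small S (≲ 50) the
  transition visibly widens.
* Transient amplification (reactivity, pseudospectra) is out of scope.
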