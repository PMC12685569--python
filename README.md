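# stagecomm

Local asymptotic stability of ecological communities whose populations are
**stage-structured** — split into juveniles and adults (or any number K of
life-cycle classes) — analysed with random-matrix ensembles and verified
against explicit stage-structured dynamics.

## The problem and the model

Classical community-stability theory summarises a community of S species by
its community matrix M (the Jacobian of the population dynamics at a feasible
equilibrium) and draws M at random: diagonal entries −d (self-regulation),
off-diagonal pairs (m<sub>ij</sub>, m<sub>ji</sub>) present with probability
C and drawn with a sign pattern set by the interaction type.  The community is
stable with probability approaching one when the scaled interaction strength
γ is below d:

- random interactions (circular law): γ = σ√(SC)
- predator–prey (elliptic law): γ<sub>p</sub> = ((π−2)/π)·σ√(SC)
- mutualism: γ<sub>m</sub> = √(2/π)·σ·C·(S−1)
- competition: γ<sub>c</sub> = σ·[√(SC(1−2C/π))·(π+2−4C)/(π−2C) + C√(2/π)]

where σ is the standard deviation of the underlying normal distribution of
coefficient magnitudes.

This package extends that machinery to structured populations.  Writing
N<sub>ik</sub> for the density of stage k of species i, the change of
variables to totals N<sub>i</sub> = Σ<sub>k</sub> N<sub>ik</sub> and stage
fractions Z<sub>ik</sub> = N<sub>ik</sub>/N<sub>i</sub> turns the SK-equation
system into one whose Jacobian — the **structured community matrix**
M<sub>S</sub>, an SK×SK block matrix — has the traditional community matrix
as its top-left S×S block.  The remaining blocks carry within- and
cross-stage interactions and are drawn from the same family of random
ensembles, one interaction type and strength (σ or γ) per block.

The headline phenomenon: with strong within-stage interactions
(γ<sub>1</sub> > d) the unstructured model is unstable, yet intermediate
cross-stage **predator–prey** coupling (adults of one species preying on
juveniles of another) restores stability — every feedback loop between a
total density and a stage fraction is negative, which pushes the spectrum
left.  Cross-stage **competition** does the opposite.  The same construction
runs on food-web topologies (read from adjacency CSV / edge-list TSV, or
generated synthetically), with the predation orientation taken from the
species-level link directions.

## Worked example

```python
import stagecomm as sc

# Two-stage community: 200 species, full connectance, d = 1,
# within-stage strength gamma1 = 1.2 (> d), cross-stage predation at 0.5.
cfg = sc.two_stage_config(200, 1.0, 1.0, gamma1=1.2,
                          gamma2=0.5, gamma3=0.5, seed=1)
ms = sc.assemble_two_stage(cfg)

lam_u = sc.classify_stability(sc.extract_unstructured(ms)).lambda_max_real
full = sc.classify_stability(ms)
print(f"unstructured lambda_max = {lam_u:+.3f}")
print(f"structured   lambda_max = {full.lambda_max_real:+.3f}")

res = sc.ensemble_stability(cfg, n_reps=100, seed=42)
print(f"proportion stable = {res.proportion_stable:.2f}")
```

prints

```
unstructured lambda_max = +0.175
structured   lambda_max = -0.104
proportion stable = 0.94
```

The unstructured block alone has an eigenvalue with positive real part
(unstable, as γ<sub>1</sub> = 1.2 > d = 1), while the full structured matrix
is stable — and remains so for 94 of 100 independent draws.  The same
analyses are available from the shell:

```bash
stagecomm criteria --sigma 0.05 --s 100 --c 0.5
# may: gamma = 0.353553 vs d = 1 -> predicted stable
stagecomm make-web --s 50 --c 0.2 --seed 1 --out web.csv
stagecomm foodweb --web web.csv --gamma2 0,0.5 --gamma3 0,0.5 --out-dir out/
```

Every run writes a JSON manifest alongside its CSV outputs; re-running a
command with the manifest as its config reproduces the outputs byte-for-byte.

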