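# nwatch — neighbourhood-watch positioning of the primitive streak

`nwatch` models how cells in the early chick embryo decide *where*
gastrulation starts. The marginal zone — the extraembryonic ring of
epiblast surrounding the area pellucida — is represented as a periodic
ring of 600 cells. Each cell `i` carries proxies for a streak **inducer**
`V_i` (cVG1/ACTIVIN/NODAL signalling through SMAD2/3; a posterior
Gaussian crescent) and an **inhibitor** `B_i` (BMP signalling through
SMAD1/5/8; a shallow anterior-high parabola). Because the two SMAD
classes compete for a fixed pool of SMAD4, the cell's decision variable
is the proportion of inducer-linked complex, the *SMAD-value*

```
F_i = a_V V_i / (1 + a_V V_i + a_B B_i)        0 ≤ F_i < 1
```

Two rival decision rules call streak initiation (cBRA expression) per
cell:

* **Model A (threshold-only):** streak iff `F_i > α` — a cell-autonomous
  reading of the morphogen field.
* **Model B (neighbourhood watch):** streak iff `F_i > β · F_nbhd(i)`,
  where `F_nbhd(i)` is the mean SMAD-value over the `(2n+1)`-cell window
  centred on `i` — cells compare themselves with their neighbourhood.

Bead and cell-pellet grafting experiments (ACTIVIN or BMP4-soaked beads,
dorsomorphin, cVG1- or BMP4-expressing pellets placed in the anterior
marginal zone) are encoded as additive perturbations with a constant
core and exponential spatial decay, together with the binary per-cell
outcome each experiment produced. A smoothed step-function likelihood

```
L_i(θ) = 1 / (1 + exp(−D_i f_i(θ) / Δ)),     Δ = 0.05
```

scores a parameter vector θ against the target labels `D_i = ±1`, where
`f_i` is the signed distance of `F_i` to its threshold (`F_i − α` for
Model A, `F_i − β·F_nbhd` for Model B). Posteriors are sampled with a
multi-chain differential-evolution MCMC (five chains, ≥5000 iterations,
Gelman–Rubin convergence checks), and every sampled vector is verified
for *success*: the predicted number and location of streak sites must
match the target. The package reproduces the central comparison: the
neighbourhood model accounts for all five encoded bead experiments —
including the counterintuitive ones, where a broad inducer domain fails
to make a streak and a low-dose inhibitor rescues one — while the
cell-autonomous model cannot.

It also implements the one-sided Boschloo exact test used for the
embryo-count comparisons.

## Worked example

```python
import numpy as np
from nwatch import (design_groups, PriorSpec, InferenceConfig,
                    run_mcmc, summarize, posterior_mode)

designs = design_groups()["microbead"]        # the five encoded bead experiments
config = InferenceConfig(seed=42, min_iterations=5000, n_chains=5)
chains = run_mcmc(designs, "B", PriorSpec.for_model("B"), config)
summary = summarize(chains, designs, config, success_subsample=4000)
print("success:", summary.success_flags)
print("modal n:", posterior_mode(chains, "n")[0])
```

prints

```
success: {'C-A-C': True, 'A-A-A': True, 'A-C-A': True, 'A-B-A-low': True, 'A-B-A-high': True}
modal n: 79
```

i.e. at its best verified parameters the neighbourhood model matches
all five experiments (one ectopic streak from a single inducer bead,
none from three adjacent ones, two when the row is interrupted by a
control or a low-dose inhibitor bead, none at high inhibitor dose), and
the marginal posterior of the neighbourhood half-width peaks around
`n ≈ 79` cells under the default priors (a sensing neighbourhood of
`2n+1 ≈ 159` cells; see `docs/methods.md` for why this lands above
the 50–65 cell half-width estimated for this system, and what it is
sensitive to). The same fit for Model A
(`run_mcmc(designs, "A", ...)`) never exceeds 3 of 5.

The Boschloo test of the key count comparison (7/56 embryos with
ectopic cBRA for a sub-threshold ACTIVIN bead flanked by BMP4 beads,
against 1/37 with control flanks):

```python
from nwatch import ContingencyTable2x2, boschloo_one_sided
boschloo_one_sided(ContingencyTable2x2(7, 56, 1, 37))   # 0.0678
```

A thin CLI wraps the same calls:

```bash
nwatch simulate --design C-A-C --model B --out out/
nwatch compare --group microbead --seed 42 --out out/
nwatch boschloo --x1 7 --n1 56 --x2 1 --n2 37
nwatch run-all --seed 42 --out run/
```

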