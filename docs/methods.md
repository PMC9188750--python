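# Methods

## The ring model

The marginal zone is reduced to a one-cell-thick periodic ring of
`n_cells = 600` cells (one cell ≈ 12 µm). Cell 0 is the posterior pole
(the endogenous streak site), cell 300 the anterior pole, and the
"anterior half" — the region where grafts are placed and the only
region scored by the likelihood — is the 299 cells within 150 cells of
the anterior pole. Two per-cell concentration proxies live on the ring:

* inducer `V_i = A·exp(−d_i²/2σ²)`, a Gaussian centred on the posterior
  pole. Defaults `A = 1`, `σ = 40` cells, chosen so the full width at
  half maximum (~94 cells) matches a ~60° posterior expression crescent
  (~100 cells of a 600-cell ring). The absolute amplitude is
  irrelevant: only the product `a_V V` enters the model, so scale lives
  entirely in the inferred `a_V`.
* inhibitor `B_i = B_min + (B_max−B_min)(d_i/300)²`, a shallow parabola
  rising from `B_min = 0.1` at the posterior pole to `B_max = 1` at the
  anterior pole, matching the qualitative anterior-high BMP pattern.

These shape constants are stand-ins: the source figures are
qualitative and print no numbers. One consequence worth knowing: with
`σ = 40`, the baseline inducer at the anterior pole is `exp(−28) ≈ 7e−13`,
i.e. effectively zero. Away from inducer-releasing sources every
anterior SMAD-value is ≈ 0, which makes several inferred quantities
(notably the upper range of the neighbourhood size, below) sensitive to
this choice.

Perturbation sources (protein-soaked microbeads, 9 cells wide;
transfected-cell pellets, 27 cells wide) add a constant amount `c` to
their target profile across the footprint and `c·exp(−d/s)` at `d`
cells beyond the footprint edge. An inducer source adds to `V`, an
inhibitor source adds to `B`, an inhibitor antagonist (dorsomorphin)
subtracts from `B`, and control beads do nothing. Effects of multiple
sources sum; concentrations clamp at zero after summation (no negative
protein). Multi-source rows place centres one footprint width apart.
Doses are mapped linearly to model units with the standard ACTIVIN
dose (12.5 ng/µl) ≡ 1.0, so sub-threshold ACTIVIN (2.5 ng/µl) is 0.2
and BMP4 at 6.25/12.5/25/50 ng/µl is 0.5/1/2/4; the mapping is
absorbed by the free concentration scale during fitting.

## The decision rules

The SMAD-value `F_i = a_V V_i/(1 + a_V V_i + a_B B_i)` is the
equilibrium proportion of inducer-linked SMAD4 complex when inducer-
and inhibitor-activated SMADs compete for a fixed SMAD4 pool. No
binding kinetics are modelled.

* Model A (cell-autonomous): streak iff `F_i > α`, `α ∈ (0,1)`.
* Model B (neighbourhood watch): streak iff `F_i > β·F_nbhd(i)`, where
  `F_nbhd(i)` is the mean of `F` over the `(2n+1)`-cell window centred
  on and including cell `i`. `β > 1` means a cell must beat its
  neighbourhood average by a fold factor; `n` is the sensing half-width
  in cells.

Ties (`f = 0`) are non-streak; thresholds are strict inequalities.

The signed threshold distance feeding the likelihood is `f_i = F_i − α`
for Model A and, by the same "distance to the threshold" construction,
`f_i = F_i − β·F_nbhd(i)` for Model B (the default). A fold-change
variant `f_i = F_i/F_nbhd − β` is available behind `form="ratio"`; the
two give identical streak masks and differ only in the magnitudes the
likelihood sees. The difference form is the default for two reasons:
it is the literal parallel of the Model A distance, and under it the
marginal posterior of `n` on the bead-experiment fits has a clean
interior peak, whereas the ratio form — being invariant to rescaling
`F` — lets the likelihood escape into a degenerate near-zero-background
regime whose `n` posterior collapses onto a window just wider than a
single bead footprint (`n ≈ 10`).

## Encoded experiments

Every in-source graft experiment is a `DesignSpec`: a bead layout plus
a binary target (`+1` streak expected, `−1` not) with the expected
streak-initiation sites as 11-cell intervals centred on the relevant
source. Targets are the *modal* experimental outcomes; outcome
frequencies across embryos are not modelled. The groups:

| group | designs | encoded outcome |
|---|---|---|
| microbead | C-A-C, A-A-A, A-C-A, A-B-A-low, A-B-A-high | 1 / 0 / 2 / 2 / 0 ectopic sites |
| inhibitor_mod | dorsomorphin, anterior-BMP | 1 / 0 |
| subthreshold | B-C-B, C-Asub-C, B-Asub-B-low, B-Asub-B-high | 0 / 0 / 1 / 0 |
| pellet | pellet variants (VV, CC, VVVV, VV-C-VV, VV-B-VV) | 1 / 0 / 0 / 2 / 2 |

Only anterior-half cells are evaluated, because grafts were placed
anteriorly; consequently the model is never rewarded or penalised for
predicting (or failing to predict) the endogenous posterior streak.

## Likelihood, priors, sampler

Each evaluated cell contributes `L_i = σ(D_i f_i/Δ)` with the logistic
`σ` and `Δ = 0.05`; the total log-likelihood sums over cells and
designs. As `Δ → 0` this approaches the exact sign test
`1{D_i f_i > 0}`. Priors are uniform: `α ∈ (0,1)`, `β ∈ (1,3)`,
`n ∈ [1,150]` (integer; proposals rounded at evaluation),
`b_V = log10 a_V` and `b_B = log10 a_B ∈ (−2,3)`, and per-fit free bead
parameters `c ∈ (0,10)` (a scale multiplying the relative doses) and
`s ∈ (0.5,50)` cells.

Sampling uses five interacting chains with differential-evolution
proposals drawn from a shared archive of past states (parallel-direction
jumps with `γ = 2.38/√(2d)`, 10% unit-γ mode-hopping jumps, 10% snooker
moves with the proper Jacobian correction), boundary reflection, and a
recency-windowed archive so the proposal scale tracks the posterior.
Burn-in is the first half of each chain; convergence is monitored by
the Gelman–Rubin statistic (threshold 1.1). Runs are exactly
reproducible from a single seed.

Because the likelihood only rewards the *sign pattern* of `f`, its
optimum often leaves target cells marginally below threshold. Every
reported "best" parameter vector is therefore chosen to maximise
`(number of successful designs, log-likelihood)` lexicographically,
where success requires the predicted streak components in the anterior
region to match the target sites in number and location. The search
pool is the posterior draws plus prior draws; if no pooled draw
succeeds on every design, a seeded differential-evolution ascent on
`1000·successes + logL` (alternating with a margin-shaped variant that
adds a penalty proportional to each design's worst negative site
margin) hunts for the full-success region, which can occupy under
1e−4 of the prior volume.

In the shared-bead-parameter regime the two models are fitted jointly:
one vector holds both models' parameters plus a single bead set, and
the target density is the product of the two likelihoods.

## What the fits show

* Model B attains success on all five microbead designs (among its own
  posterior draws); Model A attains at most 3–4 and — provably, since
  the triple-inducer field dominates the single-inducer field cell by
  cell — can never satisfy the single-inducer and triple-inducer
  targets simultaneously.
* At the selected best Model B parameters, the low-dose A-B-A design
  yields two predicted sites while A-A-A yields none, and (subthreshold group)
  the inhibitor-flanked sub-threshold inducer fires while the
  control-flanked one stays silent. An anterior inhibitor bead raises
  `f` in flanking cells above the no-bead baseline while staying below
  threshold — with the caveat that the absolute size of this rise is
  set by the near-zero anterior baseline (see above) and is therefore
  minute; the test asserts its sign and localisation.
* The marginal posterior of `n` on the microbead fit peaks at ~77–101 cells
  across seeds (R̂ < 1.1), above the 50–65 cell half-width estimated
  for this system. Two
  documented defaults drive this: the `β` prior ceiling of 3 (the `β`
  marginal pins it, and along the likelihood ridge a larger permitted
  `β` supports a larger `n`) and the effectively-zero anterior inducer
  baseline, which removes the absolute scale that would otherwise
  bound the window size. The prior ranges and baseline
  constants that produced the 50–65 estimate are not available; we
  report under our documented defaults rather than tuning either
  toward that band.

## Synthetic data and parameter recovery

`generate_from_model` runs a model with known parameters on a layout
and binarises the result into a target (components dilated to the
11-cell site width); `randomized_designs` samples random anterior
layouts. The recovery study (`nwatch.recovery`) draws a ground truth
from the prior interior, builds a battery of layouts chosen by forward
simulation to straddle the truth's own detection transitions — a wide
low-dose inducer "carpet" (which installs a non-zero anterior
background and thereby breaks the fold-change scale-freeness), bump
doses just below/above detection, and bump pairs just inside/outside
separate detection — and refits `(β, n, b_V, b_B)`.

The study's honest result is negative, and the mechanism is worth
stating because it is a property of the likelihood construction, not
of the sampler or the fixtures: with noise-free binarised targets, the
generating parameters place every mask-boundary cell exactly at
`f = 0` (likelihood 0.5 each), so any parameters reproducing the same
sign pattern with sharper margins score higher. The pseudo-posterior
is narrow and displaced a few percent from the truth toward the
sharpest-margin face of the mask-compatible set, and 90% credible
intervals for `β` and `n` cover the truth in only ~0–2 of 10
replicates. Recovering generative parameters from deterministic
binarised model output would require either an observation-noise model
for the targets or a likelihood that does not reward margin sharpness.

## Numerical choices and limitations

* Windowed means use cumulative sums of the wrapped vector (exact,
  O(ring)); `F_nbhd = 0` cells get `f = 0` under the ratio form (no
  evidence either way).
* Windows are capped at the ring size on small test rings.
* Boschloo's one-sided exact test maximises over 1001 equally spaced
  nuisance proportions; doubling the grid moves the key p-value by
  < 1e−3. The one-sided direction is fixed as "treated group has the
  higher ectopic-streak proportion". The scipy implementation returns
  a different value for the key table under `alternative="greater"`
  (0.0523 vs the enumeration-verified 0.0678), so the
  package ships its own grid enumeration and tests it against a
  factorial-arithmetic oracle.
* Posterior modes: modal rounded integer for `n`; Gaussian-KDE peak on
  a 512-point grid for continuous parameters, with near-flat and
  multimodal marginals flagged.
* Problem sizes: fits use 5 chains × 5000 iterations (≈ 10 s for a
  five-design group); the recovery study uses 5 × 1500 per replicate.
* Not modelled: 2-D geometry, diffusion or reaction dynamics, time
  dependence, streak elongation after initiation, and embryo-to-embryo
  outcome variability.
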