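# Methods

This note documents the modelling choices behind `circuitgen`: the
reaction model and its assumptions, the functional metrics, the
generative model and its training protocol, what the synthetic data does
and does not emulate, and the numerical conventions adopted where the
design was genuinely open.

## Circuit representation

A circuit is `n = 3` RNA species; its topology is the symmetric matrix of
pairwise minimum free binding energies, packed canonically as the upper
triangle in row-major order, `[k11, k12, k13, k22, k23, k33]`
(kcal/mol). All modules index interactions only through this packing —
it is the single source of truth that prevents silent permutation bugs.

Circuits originate two ways:

* **Parameter-sampled** (default): each of the 6 energies is drawn
  independently and uniformly on `[-30, 0]` kcal/mol, the plausible
  range for 20-nt RNAs. This is the fast path used throughout testing.
* **Sequence-sampled**: three 20-nt RNAs drawn position-wise from the
  E. coli nucleotide proportions `[A: 0.2451, C: 0.2458, G: 0.2622,
  U: 0.2469]`, scored pairwise by a pluggable energy engine. Adapters
  are provided for IntaRNA (subprocess, CSV mode, default settings) and
  ViennaRNA's RNAduplex, plus two deterministic stub engines (constant
  and hash-of-pair) so the contract is testable without external tools.
  A pair with no predicted interaction scores 0 kcal/mol (inert).

Sequences are stored uppercase RNA; `T` is rejected, never converted.

## From energies to rates

The per-copy equilibrium constant uses an empirical calibration of
sRNA/mRNA repression measurements rather than the raw Gibbs relation
(which badly overestimates binding for cellular RNA):

```
K = exp(-0.8 (ΔG + 10)) / x0          [copies⁻¹],  x0 = 100 copies
k_f = 1.50958097e-3 copies⁻¹ s⁻¹      (fixed; fast association)
k_r = k_f / K                         [s⁻¹]
```

The constants 0.8 and 10 are taken as given by the calibration. The two
published association rates (1e6 M⁻¹s⁻¹ and 1.50958097e-3 per-copy
s⁻¹) are mutually consistent with an effective cell volume of ≈1.1 fL
via Avogadro scaling — a documented sanity check, not a pipeline input.
The textbook `K = exp(-ΔG/RT)` (R = 1.987e-3 kcal/mol/K, T = 310 K) is
exposed for reference only.

## Reaction model and signal protocol

State: 3 free RNAs + 6 complexes = 9 species, in copies per cell.

* production of each free RNA at `p = d·x0 = 1.175` copies/s — chosen so
  the unbound steady state is exactly the 100 copies used for
  initialisation (the source material states no production rate);
* first-order degradation of **all** species at `d = 0.01175` s⁻¹
  (complexes are degraded but not produced, keeping the system bounded);
* reversible binding `RNAᵢ + RNAⱼ ⇌ Cᵢⱼ`; self-binding consumes and
  releases two copies (`k_f·xᵢ²` propensity).

The published parameter table also lists a 1200 s doubling time, which
contradicts the explicit degradation rate (ln2/1200 ≈ 5.8e-4 s⁻¹); the
explicit rate is used.

The two-phase protocol: (1) relax from all-free-at-100 to steady state —
bookmarks I₁, O₁; (2) apply the signal to node 1 and simulate until the
system settles — bookmarks I_peak, O_peak (largest |deviation| from the
phase-2 initial value, handling down-going responses), I₂, O₂.

**Signal convention.** The source material calls the input both a "step"
and an "impulse added to steady state". The default is a *step* that
multiplies the input node's production rate by 2: a pure impulse in this
production/degradation system returns the input exactly to its
pre-signal level, making `I₂ − I₁ = 0` and hence precision universally
NaN. Impulse mode (add `magnitude ×` steady-state copies to the free
input) is retained as a configuration option; results sensitive to the
choice carry the mode.

**Numerics.** LSODA with an analytic Jacobian (both JIT-compiled),
rtol = 1e-6, atol = 1e-9, t_max = 1e5 s per phase. Steady state is
declared when `max |ẋᵢ| / (atol + rtol·xᵢ) ≤ 1`, checked at geometric
chunk boundaries (2e3 s, ×10 growth) — the integrator takes huge steps
near equilibrium, so chunking costs little and avoids per-step event
overhead. Solver failures flag the record instead of raising, so batch
runs continue. A solver-independence test checks LSODA against BDF to
1e-4 relative on O_peak/O₂ over 50 random circuits.

## Functional metrics

Sensitivity `S` and precision `P` are the standard relative-excursion
definitions (see README). Any division by zero propagates NaN — this is
the contract, not an error. The scalar adaptation objective

```
a = −(3 (log₁₀S − 7)² + (log₁₀P − 7.5)²) + 1000
```

peaks at `a = 1000` (S = 1e7, P = 1e7.5) and is positive on the whole
operational box `log₁₀S ∈ [−7, 2], log₁₀P ∈ [−2, 7]` (minimum 321.75 at
the corner). The centres intentionally lie outside the box so the
gradient always points toward better adaptation. Binary adaptability
defaults to `S > 10, P > 1`; the alternative printed convention
(`S > 1, P > 10`) is supported and reports name the convention used.

Timing features use control-theory conventions (unstated in the source):
settling band 2 % of the terminal deviation, response time at 50 % of
peak deviation.

**Ruggedness.** Each interaction is perturbed by `+ε` (ε = 1 kcal/mol,
toward weaker binding; the sign is configurable since only "≈1 kcal/mol"
is stated), the full protocol re-run, and `r = Σ dkᵢ²` with
`dk = (a_ε − a₀)/ε`. Any NaN adaptation makes `r` NaN with a reason
code. A separate exploratory operation perturbs all interactions at once
with zero-mean noise (SD = 10 % of the strongest training energy); it is
not part of `r`.

## Dataset construction

Filtering drops records with NaN S/P, exact duplicate energy vectors
(rounded to 1e-9 kcal/mol, first kept), and slow responders (unsettled,
or settling time > 0.8 × the phase-2 horizon — the threshold is a
package choice, configurable). An empty result raises with per-rule
removal counts.

Features are negated (strong binding → high value), robust-scaled
(median/IQR; zero-IQR features fall back to min-max with a log message),
then min-max scaled to [0, 1]. The fitted state is JSON-serialised and
exactly invertible, so generated circuits map back to kcal/mol.
Feature scaling is fitted jointly on all filtered circuits (the
sequence/parameter datasets are normalised after concatenation); label
scaling is fitted on the training split only to avoid leakage, and rows
whose labels fall outside the fitted [0, 1] range are excluded.

Label objectives: scalar adaptation (c_n = 1); `[log₁₀S, log₁₀P]`;
the binary pair `[log₁₀S > 0, log₁₀P > 1]`; the 3-metric variant with
overshoot/initial; and joint adaptation + log₁₀-ruggedness (c_n = 2).
The default split is 80/20 by circuit, seed-reproducible.

## The CVAE

Encoder and decoder are stacks of 3 linear layers of width 32 with
leaky-ReLU (slope 0.01) and He-normal initialisation; the μ/logvar heads
and the decoder output layer are extra linear layers (heads are linear —
unstated in the source, linear assumed). Encoder input is `[x, c]`
(6 + c_n wide), the decoder consumes `[z, c]` (32 + c_n) and emits the
6-vector reconstruction.

Loss: `MSE + w_KL · KL` with the Gaussian KL
`(−logvar − 1 + e^logvar + μ²)/2` **summed over latent dimensions and
averaged over samples** — the standard VAE aggregation. This choice is
load-bearing: averaging over dimensions as well weakens the KL by the
latent width (32×) and the decoder then learns to ignore the condition
entirely, destroying prompt adherence while reconstruction stays
excellent. Default `w_KL = 1e-4`, inside the reported high-adherence
band; a warning fires outside [1e-6, 1e-2]. The optional contrastive
term (off by default; it did not improve outcomes in the source study)
compares dot-product label similarity against a threshold d = 0.9,
scaled by a temperature, with self-similarities removed.

Training: Adam (conventional moments), batch size 256 (unstated;
package default), per-epoch shuffling, linear warmup 0 → 1e-3 over 20
epochs then cosine decay to epoch 2000. Early stopping when validation
accuracy exceeds 0.98 — a sample counts as reconstructed if **all six**
coordinates deviate ≤ 0.1 in normalised units (strict reading;
a mean-absolute-error mode is available) — or after 500 epochs without
improvement. A NaN loss aborts and returns the last best parameters.
The whole network is NumPy with hand-derived gradients (verified against
central finite differences in the test suite) and is bitwise
reproducible for a fixed seed.

Generation decodes `[ε, c]` with `ε ~ N(0, I₃₂)` and the prompt `c`,
which may extrapolate beyond [0, 1] (the standard grid spans
[−0.2, 1.2]); outputs are inverse-normalised to kcal/mol. Because prompt
adherence varies notably with the initialisation seed, the
`train_multi_seed` helper trains several seeds and selects the best —
the mitigation used throughout the evaluation.

## Evaluation

* **Reconstruction R²** is pooled over all 6 entries of all held-out
  circuits, with evaluation noise set to zero.
* **KDE prompt adherence**: a Gaussian KDE (Scott bandwidth) is fitted
  per prompt group to the realised metric, all curves are evaluated on a
  shared 1000-point grid spanning the pooled range padded by 3
  bandwidths, unit-normalised on the grid, and overlap(A, B) is the
  discrete area of the pointwise minimum. This is the only reading of
  "summing the overlapping points" consistent with a [0, 1] scale
  (1 = identical distributions); relative comparisons are unaffected by
  the convention. Zero-variance groups fall back to an ε bandwidth.
* **Precision/recall/F1**: a circuit fulfils a prompt iff
  |realised − prompt| ≤ 0.1 in normalised units (the bound mirrors the
  training error bound and is configurable; results are sensitive to
  it, which is why the KDE metric exists).
* **Motif clustering**: Ward-linkage agglomerative clustering on raw
  6-vectors of circuits classified adaptable, tree cut at k = 5;
  identical inputs collapse to fewer groups. Linkage choice is a package
  default (unstated in the source).
* **Embedding export**: encoder means μ with attached labels, for
  downstream projection; projections themselves (UMAP etc.) are plotting
  convenience and untested surface.

## Problem sizes

The reference study simulated up to ~1e6 circuits. This package
reproduces the pipeline at a scale chosen to keep a complete run in the
order of a minute on one CPU: the reconstruction experiment uses 5,000
parameter-sampled circuits (4,000/1,000 split) trained over 5 seeds, and
prompt-adherence evaluation generates 10,000 circuits (1,000 per prompt
over the 10-prompt grid) which are all re-simulated. At this scale the
held-out pooled R² is ≥ 0.97 and the per-prompt medians of realised
adaptation increase with the prompt (Spearman ρ > 0.8, best of 5 seeds)
— both recomputed, not asserted, by `scripts/acceptance.py` and the
acceptance tests.

## What the synthetic data does not show

The generator reproduces the study's stated conditions (uniform energies
on [−30, 0], 3-node circuits, fixed kinetic constants), not real RNA
biology: no secondary-structure constraints, no transcription bursting
or growth dilution, no stochastic kinetics (the ODE model is
deterministic mass action), and binding energetics reduced to a single
empirical calibration. Adaptation labels in a uniformly sampled energy
space concentrate in a narrow high band, so low-adaptation prompts
extrapolate — generated distributions there are broad, exactly as the
reference study observed. Passing tests therefore demonstrate fidelity
of the pipeline, not predictive accuracy for wet-lab circuits.

## Known limitations

* The IntaRNA adapter is exercised against its documented CLI contract
  but, in environments without the tool, only its error path runs live;
  the RNAduplex adapter covers the real-subprocess path.
* Sequence-sampled datasets route through the same normalisation and
  training code but the headline experiments use the parameter-sampled
  path throughout (the study's own fast path).
* With 9 species the stiff solver is fast but circuits generated far
  outside the training energy range can carry extreme dissociation
  rates; such rows are flagged, never fatal.
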