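# Methods

## Model

`afsim` implements a synchronous three-state cellular automaton for
activation wavefronts on an anisotropic lattice mimicking the branching
cable structure of atrial muscle. Cells occupy an L × L grid (cylinder:
periodic vertically, open horizontally). Each cell is permanently coupled
to its longitudinal (horizontal) neighbours; each of the L² candidate
transverse (vertical) edges is present independently with probability ν,
the single structural control parameter (fibrosis reduces ν). A Bernoulli
fraction δ of cells is *dysfunctional*: when stimulated, such a cell
fails to excite with probability ε (one independent trial per cell per
step, however many neighbours are excited). The column x = 0 contains
pacemaker cells that self-excite every T steps when resting, bypassing ε.
The substrate is fixed for the lifetime of a simulation; the only
permitted modification is lesioning (ablation), which returns a copy with
a rectangle of permanently unexcitable cells.

### State convention

A cell's counter lies in [0, τ+1]: excited at τ+1 (exactly one step),
refractory while in [1, τ], resting at 0. An excitation therefore makes
a cell unexcitable for τ+1 consecutive steps — one excited step followed
by a refractory period of exactly τ. We adopted this convention, rather
than folding the excited step into τ, because it is the one under which
the dynamics reproduce the analytic criticality cutoff exactly: in the
two-cable reentry motif (below), brute-force simulation shows the circuit
sustains **iff ℓ ≥ τ/2** for τ = 4, 6, 8 under this convention, while the
alternative (total window τ) shifts the cutoff to ℓ ≥ τ/2 − 1 and breaks
the correspondence with the closed-form risk. The refractory period
proper — the time a cell spends unexcitable *after* its excited step —
is exactly τ, which is also what the per-cell bookkeeping tests assert.

All neighbour reads use the pre-update state (fully parallel update), so
no update-order tie-breaking exists. Random draws are consumed in a fixed
order — one uniform per stimulated dysfunctional resting cell, row-major,
per step — making every trace bit-reproducible from the seed. The
dynamics stream is spawned from the substrate seed on a separate spawn
key so that it cannot collide with the substrate-generation stream or
with the streams of neighbouring realisation seeds (sweeps use seeds
base, base+1, …).

## Physical ↔ dimensionless translation

Tissue defaults: cells of 100 μm × 20 μm, depolarisation time 0.6 ms,
sheet area 20 cm², refractory period 150 ms, pacing period 660 ms,
coarse-graining factor b = 5. The L × L grid tiles the sheet with cells
of pitch b·Δx longitudinally and b·Δy transversally, so the side length
in lattice units uses the geometric-mean pitch:

    L = round(L′ / (b·√(Δx·Δy)))  →  200 (b = 5),  1000 (b = 1)

which preserves the cell count L² = L′²/(b²ΔxΔy) — hence δL² = 2000
dysfunctional cells at δ = 0.05 — and makes the dimensional risk formula
(below) agree exactly with the dimensionless one. Times rescale by bΔt:
τ = 150/(5·0.6) = 50, T = 660/(5·0.6) = 220. Rounding is
half-away-from-zero. Coarse-graining the couplings maps
ν → 1 − (1−ν)^b (probability that a block of b cells has ≥ 1 vertical
connection).

## Analytic risk and threshold

A cell has ≥ 1 transverse coupling with probability p_ν = 1 − (1−ν)².
For a dysfunctional cell, let ℓ be the distance (offset 0 = the cell
itself) to the first transversely coupled cell at or to its right; ℓ is
geometric in p_ν. The circuit around the uncoupled stretch is too short
to reenter when ℓ < τ/2:

    P(ℓ < τ/2) = Σ_{ℓ=0}^{τ/2−1} (1−p_ν)^ℓ p_ν = 1 − (1−ν)^τ   (τ even)

With δL² dysfunctional cells on average, the risk of ≥ 1
fibrillation-inducing structure is

    P_risk = 1 − [1 − (1−ν)^τ]^{δL²}
           = 1 − [1 − (1−ν)^{θ_x τ′/(bΔx)}]^{δL′²/(b²ΔxΔy)}

and the point of steepest slope defines the threshold
ν★ ≈ 1 − (δL²)^{−1/τ} ≈ 0.14103 for δ = 0.05, L = 200, τ = 50 (valid for
τ ≫ 1, δL²τ ≫ 1). Probability arithmetic is done in log space
(log1p/expm1) so exponents ≫ 10³ do not underflow; the identity tests
hold to 1e−12. For odd τ the closed form 1 − (1−ν)^τ is used directly
and the criticality cutoff ℓ ≥ τ/2 is evaluated as a real comparison
(the boundary then falls on a half-integer, so no tie exists).

## Critical-region scanner

A cell is critical iff it is dysfunctional, not ablated, its ℓ is
defined, and ℓ ≥ τ/2 (ties critical). Cells whose uncoupled stretch runs
into the open right boundary (ℓ undefined) are **not** critical: without
a transverse coupling the retrograde circuit cannot close. This is the
physically correct reading but introduces a finite-size deficit relative
to P_risk, which assumes unbounded cables. Exactly, the expected number
of critical cells per substrate is

    m_eff = δ·L·Σ_x Σ_{k=τ/2}^{L−1−x} (1−p_ν)^k p_ν  <  m = δL²(1−ν)^τ

At L = 200, τ = 50 the corresponding substrate-level risk is ≈ 0.944 /
0.599 / 0.246 at ν = 0.12 / 0.14 / 0.16 versus P_risk = 0.965 / 0.654 /
0.279: a systematic ≈ 0.02–0.06 deficit concentrated around ν★. The
Monte-Carlo estimator (`mc_risk_estimate`) therefore tracks the shape of
the analytic curve but sits slightly below it near the threshold — at
400 substrates the deviation at ν = 0.12 (~6 SE) exceeds a 3-SE band,
which the acceptance suite reports rather than hides. At ν = 0 the
estimator returns 0 (no circuit can close), outside the validity of the
formula, which gives 1. The `ell=None` convention also leaves a one-cell
band untested dynamically: the scanner is exact for the ℓ ≥ τ/2 cutoff
that the risk formula uses.

## AF activity measurement

A single planar front excites at most one cell per row per step, so
n_excited ≤ L during regular rhythm — up to conduction-lag blips: a
dysfunctional cell that fails ε-trials twice is later re-excited
retrogradely by its healed right neighbour, transiently putting two
excited cells in one row (measured excess ≤ 5 cells at δ ≤ 0.3, ν = 1).
The experiments therefore classify a step as fibrillatory when
n_excited > 1.1·L (`threshold_factor = 1.1`, configurable); during actual
fibrillation the count reaches several hundred at L = 200, so the margin
is immaterial there. `af_activity` keeps the strict factor 1.0 default
for callers who want the raw criterion.

A second, threshold-free detector propagates pacemaker-beat labels with
the excitation: a reentry is flagged when a cell is re-excited within one
pacing interval by a wave carrying the label of its own previous
excitation — no pacemaker firing can have reached it in between, so the
activation travelled a closed path. Waves from prepared initial states
carry an "unknown" label and are detected on their second lap.

## Experiments and study conditions

**Phase diagram.** ν ∈ {0.10, …, 0.20} (step 0.01), 5 realizations ×
2×10⁴ steps at L = 200, τ = 50, δ = ε = 0.05, T = 220; seed schedule
base+realization. These scaled-down sizes keep the full sweep at a few
minutes on one CPU while resolving the transition; the full-scale
protocol (50 realizations × 10⁶ steps) is available by passing the
corresponding arguments to `phase_sweep` / `afsim sweep`. Mean time in
AF is ≈ 0 in the planar regime (ν ≳ 0.2), rises steeply through
ν★ ≈ 0.14, and approaches 1 by ν = 0.10.

**Ablation.** The `critical_one` fixture embeds exactly one engineered
critical region (ℓ = 30, τ = 50, within an otherwise fully coupled
L = 60 sheet, T = 120, ε = 0.008) whose location the scanner must
recover. ε controls two competing failure rates chosen once: expected
onset of the rotor (~ε⁻¹ pacing beats until the dysfunctional cell blocks
a front) versus the chance that the control rotor self-terminates within
the post-lesion observation window (~(1−ε)^(window/period), the
retrograde wave re-crosses the dysfunctional cell each ~2(ℓ+2)-step
lap). With ε = 0.008 and max_wait = 1.5×10⁵ both failure modes are ≲ 2%.
A 20×20 lesion centred on the scanned critical cell terminates the rotor
(no post-lesion reentry detections; no AF activity over the final two
pacing cycles) and planar pacing resumes; the same lesion placed far from
the circuit leaves the rotor detectable (outcome "persisted").

## What the synthetic substrates do and do not capture

Generated substrates are statistically homogeneous: independent Bernoulli
edges and dysfunction, uniform ν and δ, uniform τ, a rigid square
geometry, and a deterministic full-column pacemaker. Real atrial tissue
has spatially clustered fibrosis, dispersed refractoriness, restitution,
curved anatomy with orifices, and a compact sinus node — none are
modelled, so passing tests demonstrate the structural mechanism
(uncoupling → microreentry → AF) and the analytic risk on this idealised
substrate, not quantitative agreement with clinical AF. Ionic currents
and action-potential morphology are likewise outside the model's scope.

## Numerical choices and degenerate inputs

* Counters are int16; traces store per-step excited counts as int64.
* ν = 0 or 1 and δ = 0 or 1 are exact degenerate cases (no/all edges,
  no/all cells dysfunctional).
* Lesions must fit horizontally (open boundaries) and wrap vertically;
  zero-area lesions are rejected; lesioning zeroes the counters of
  covered cells so ablated tissue is inert from the moment of ablation.
* A pacemaker cell may be dysfunctional (no exclusion); self-excitation
  bypasses ε. A refractory pacemaker skips the beat.
* Pacing occurs at t ≡ 0 (mod T) starting at t = 0.
* Probabilities are validated to [0, 1] with errors naming the offending
  field.

## Known limitations

* The finite-size deficit of the scanned risk near ν★ (quantified above)
  is inherent to open boundaries; periodic-x substrates would remove it
  but change the topology the model argues from.
* The label-based reentry detector can miss circuits whose period
  exceeds the pacing interval (none arise at the parameters used, since
  2(ℓ+2) ≤ 2(τ+2) < T) and treats wave-collision label merges
  conservatively (max label wins).
* `phase_sweep` rows at the same realization index share seeds across ν
  values (the documented schedule), which correlates substrates across
  columns of the sweep table; rows within a column are independent.
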