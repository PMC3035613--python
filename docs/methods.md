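# Methods

## Model

The network couples five genes (*hes1*, *rbpj*, *notch1*, *mash1*,
*hes6*) through transcriptional repression and activation, two
heterodimer pools and the Notch intracellular domain (NICD) branch; the
state has 25 components (per gene: nuclear/cytoplasmic mRNA and protein;
plus Hes1–Hes6 and Mash1–E47 dimers, cytoplasmic/nuclear NICD, and the
nuclear NICD–RBPJ complex NRB). Each gene follows a two-compartment
Goodwin-type chain with first-order transfer (`a_mRNA`, `b_prot`, both
0.05 min⁻¹) and first-order degradation in both compartments; the
compartmental structure supplies the transcription→translation delay
that the oscillation requires.

Transcription of gene *i* is

    k_i = k_i,0 · Π_j  H_j^(n·h) / (H_j^(n·h) + x_j^(n·h))
              · (1 + s_i·[NRB]) · ebox_i ,

where the product runs over the gene's repressors (`h` = number of
binding sites, `n` = 2 when the repressor binds as a dimer, so three
N boxes bound by Hes1 dimers give exponent 6), `s_i` is the gene's RBPJ
site count (2 for *hes1*, 3 for *rbpj*, 2 for *notch1*), and `ebox_i` is
the Mash1–E47 E-box activation of the proneural genes. RBPJ represses
through its free nuclear pool; the NRB complex activates.

### Reconstruction choices

The source equations for this pathway are only available as prose, so
several compositional choices were genuinely open. Each is data-driven
configuration (the wiring document), not code, and each default was
selected to reproduce the qualitative behaviour the pathway is known
for: a sustained ~2 h limit cycle with Hes1 dominance and antiphase
Mash1 peaks at the calibrated parameter values, and a ~2.4 h cycle at
the initial values.

* **Hill-constant assignment.** The calibrated table names five
  constants for more regulator–gene edges than five. Default map:
  `H_HES1` — Hes1-dimer repression at the N boxes of every target gene
  (*hes1*, *rbpj*, *notch1*, *mash1*); `K_HES1` — RBPJ binding at the
  *hes1* gene's two RBPJ sites; `H_RBP-J` — RBPJ sites on *rbpj* and
  *notch1*; `H_MASH1`/`H_HES6` — the E boxes of *mash1*/*hes6*. The
  alternative (one constant per repressor everywhere) leaves the hes1
  loop barely past its Hopf bifurcation and the initial parameter table
  without any oscillation.
* **E-box composition.** *mash1* uses `1 + D/(H+D)` (basal transcription
  retained, the activator up to doubles it); *hes6* uses the pure
  saturating factor `D/(H+D)`. A pure factor on *mash1* makes the
  Mash1→dimer→*mash1* loop subcritical (Mash1 collapses to zero); a
  basal term on *hes6* drives nuclear Hes6 to ~500 concentration units,
  whose heterodimer exchange with Hes1 buffers the oscillator to death.
* **Hes1–Hes6 dimerisation** drains the *cytoplasmic* protein pools
  (dimerisation upon synthesis) and returns both monomers on
  dissociation; Mash1–E47 formation is attenuated by the Hes1
  dominant-negative factor `k_dom,neg/(k_dom,neg + [Hes1])` and Mash1 is
  *not* returned (phosphorylated in the dimer). Nuclear-pool
  dimerisation is available as a configuration switch but damps the
  nuclear delay stage enough to abolish the initial-table oscillation.
* **NICD branch.** Delta contact gates NICD generation
  (`delp · k_NICD · [Notch_cyt]/(K + [Notch_cyt])`, `k_NICD` = 0.1
  min⁻¹); nuclear import saturates with constant `K_NICD` and Vmax
  `k_NICD,import` = 0.1 min⁻¹ (neither rate has a literature value; both
  are set to the order of the complex-formation constant and are
  overridable). The NRB complex activates transcription for as long as
  it exists — the delta signal controls its production, not its
  activity. Since NRB is the slowest pool (dissociation 0.0028 min⁻¹,
  ~6 h), this is what makes the post-signal recovery lag grow with
  signal duration.
* **Initial state and burn-in.** All components start at 0.1
  concentration units; analyses use the final 1,000 min of a 3,000 min
  run. Limit-cycle features are insensitive to scaling the initial state
  by 10 in either direction (tested).

## Integration

Stiff-capable LSODA (scipy) with rtol 1e-8 / atol 1e-10 and a 1-min
output grid; integration is segmented at every protocol discontinuity
(delta-window and pulse edges, ramp endpoints) so the right-hand side is
smooth within each solver segment. The right-hand side is JIT-compiled
(numba); a readable reference implementation is part of the public API
and a unit test pins the two to 1e-12 relative agreement. Negative
excursions beyond 1e-6 abort the run; smaller ones (solver tolerance
noise) are clamped to zero.

## Protocols

* **Delta window**: `delp(t)` = 1 inside the window.
* **Pulses**: a constant source on a cytoplasmic protein pool; the ×1
  reference rate is the baseline time-averaged production rate of the
  target protein (`c_gene` × mean cytoplasmic mRNA over the unperturbed
  limit cycle), so ×1 roughly doubles supply. Absolute rates can be
  given instead.
* **Ramps**: linear in time across a window (default 1,000–2,000 min,
  i.e. starting from the settled cycle), holding the final value; the
  batch-of-constant-runs reading ("parameter sweep") can be expressed by
  running the model at fixed parameter sets.

## Feature extraction and fate rule

Peaks are local maxima with prominence ≥ 0.1 × series range
(scipy.signal.find_peaks). Period = mean inter-peak interval; amplitude
= mean peak-to-trough; relative amplitude = amplitude / mean. Antiphase
holds when every full Hes1 inter-peak interval contains exactly one
Mash1 peak strictly inside it. Fate labels (thresholds configurable;
the biology is verbal, the defaults quantify it):

* `differentiated` — Hes1 and Mash1 relative amplitudes < ε_amp = 0.05,
  mean Mash1 > mean Hes1, and mean Hes1 < θ_low = 0.5 × its baseline;
* `oscillatory_progenitor` — period defined with CV < 0.2, Hes1
  relative amplitude ≥ ε_amp, mean Hes1 > mean Mash1;
* `dampened_transition` — relative amplitudes of both proteins shrink
  by > 10% between the two halves of the window without reaching the
  floor; `other` — anything else.

Recovery lag: the first time after protocol end at which a 600-min
sliding window (30-min stride) of Mash1 matches the baseline features
(period within 5%, mean within 10%).

## Calibration cost

Five non-negative terms over the trailing 1,000 min: Hes1
relative-amplitude shortfall below 0.05 (sustained oscillation);
|period − 120 min| / 120; positive part of (mean Mash1 − mean Hes1)
normalised by the sum; fraction of Hes1 inter-peak intervals without an
interleaved Mash1 peak; and a validity penalty of 100 for failed or
non-finite runs. Weights default to 1 and are configurable. The search
evaluates the cost on an unscrambled Sobol sequence (first, degenerate
point skipped) mapped to the ±90% hypercube; the running minimum is
non-increasing and the scan is bit-reproducible for a fixed (m, skip).
The calibrated table scores ≈0.04 under this cost; the initial table
≈1.4 (no sustained oscillation at the target amplitude, Mash1
dominance). These shipped terms are this package's own reconstruction
of a qualitative-agreement cost; a rerun of the scan is not expected to
reproduce the shipped calibrated table exactly, and no test asserts it.

## Sensitivity analysis

DGSM: ν_i = mean over Sobol base points of the squared central
finite-difference derivative (relative step 1e-3 of each parameter's
range) of each output; scaled index S_i = range_i²·ν_i / Σ_j range_j²·ν_j,
which sums to 1 per output and reduces to the exact closed form on
additive-linear test functions. Outputs: nuclear Hes1/Mash1/Hes6 protein
averaged over the 120-min window ending at 2,000 min (a strict point
value aliases oscillation phase; the mode is switchable). Default 256
base points; solver tolerances rtol 1e-6 / atol 1e-9 for this stage —
the finite-difference signal is ~3 orders of magnitude above solver
error, and the ranking is unchanged against rtol 1e-8. Parameters with
S ≥ 0.1 on any output are significant.

## Problem sizes

Default analysis sizes keep a full pipeline run on one CPU at around ten
minutes: 3,000-min baselines, 6,000-min perturbation runs, 256 DGSM base
points (15,872 simulations of 2,000 min each), calibration scans of 2^10
points by default with full-scale 2^14 scans available from the CLI.

## What the synthetic traces do and do not show

The fixture generator produces damped cosines with seeded noise —
analytic period, amplitude, envelope and phase offsets. They validate
the feature extraction and the cost terms exactly, but they are
deliberately simpler than the model's waveforms (no harmonics, no
asymmetric peaks, no amplitude–period coupling), so passing fixture
tests demonstrates correctness of the measurement code, not fidelity of
the model itself; the model-level claims are tested on integrated
trajectories.

## Known limitations

* The source equations are reconstructed from prose; all compositional
  choices above are explicit configuration, but quantitative agreement
  with the reported behaviour of this pathway is limited where it
  depends on details the prose does not pin down. In particular: the
  Mash1 fold-change under tenfold-slower Mash1 mRNA degradation reaches
  ≈28× here against the reported ≈50× (with the basal E-box form the
  activation term can at most double, and Hes1's steep self-repression
  holds its own level within ~10% under Mash1/Hes6-branch
  perturbations); the sensitivity cutoff admits H_HES1 alongside four of
  the five reported degradation/dissociation rates while the Mash1–E47
  dissociation rate falls just below it; and pair ramps under delta
  cannot distinguish Hes1 mRNA- from protein-degradation routes, so the
  reported potent-pair set differs.
* The initial (literature) parameter table yields a small-amplitude
  (~1% of mean) but period-stable cycle at ~2.27 h rather than a
  full-blown oscillation.
* Single cell only: the delta signal is an external binary input; no
  lateral-inhibition coupling, no stochasticity, no downstream
  differentiation genes.
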