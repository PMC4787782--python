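# Methods

This note documents the models behind `hairpinfs`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user auditing results will want to
know.  Units throughout: forces pN, lengths nm, molar energies kJ/mol
(1 kJ/mol = 1.6606 pN·nm per molecule), times s.  The working temperature
is 302.15 K (29 °C, the measured in-chamber value), so k_BT ≈ 4.172 pN·nm;
`constants.py` is the single source of both numbers.

## Two-state Bell–Evans kinetics

The hairpin is reduced to two states separated by one barrier.  The
parameters (`TwoStateParams`) are the folded-to-unfolded distance L along
the pulling coordinate, the folded-to-barrier distance x_→, the zero-force
free-energy difference ΔG (total, i.e. including the elastic free energy
of the released strand — this is what makes the coexistence force
F\* = ΔG/L land at the measured transition forces), and the zero-force
unfolding rate k₀.  An attempt frequency ν₀ and barrier height E with
k₀ = ν₀·e^(−E/k_BT) can be carried as metadata but are never separately
identifiable from ramp data, so they are only validated for consistency.

Force tilts the landscape linearly: the unfolding barrier drops by F·x_→,
the folding barrier grows by F·x_←.  This assumes a force-independent
barrier position, valid for F ≪ E/x_→; it is the same regime in which the
linear-ramp first-passage densities have their closed form.  The folding
rate k₁ = k₀·e^(ΔG/k_BT) is astronomically large at zero force
(ΔG ≈ 20–30 k_BT), so all folding-rate arithmetic is done in log space.

Under a linear ramp F(t) = F₀ + r·t the first-transition force density is
p(F) = (k(F)/r)·exp(−(1/r)∫k), with the Bell integral in closed form.
`ramp_density` evaluates it on a uniform force grid (default 0.01 pN step)
and records the survival probability at ramp end as an explicit
`escape_mass`, so density mass + escape = 1 is an enforced invariant.
An independent oracle (`ode_survival_density`) integrates the survival
ODE dS/dF = ∓k(F)/r·S with LSODA at rtol 1e-10; the closed form agrees to
a sup-norm of ~5·10⁻⁹ for all four benchmark parameter sets.  The ODE
span is clipped where the hazard exceeds 10⁵·r — beyond that point the
survival is identically zero in double precision and the problem is
needlessly stiff.

The hysteresis ΔF = F_unfold − F_fold of independent stretch and release
first events is distributed as the cross-correlation
h(Δ) = ∫p_→(F)·p_←(F−Δ)dF, computed by FFT on the common grid.

## Construct elasticity and the loading rate

The construct is a mechanical series: two traps (lumped into one linear
spring, default combined stiffness 0.08 pN/nm), two ~0.5 μm (DNA/DNA) or
~0.4 μm (RNA/DNA hybrid) handles, and the hairpin.  Handles follow the
Marko–Siggia worm-like-chain interpolation with an enthalpic stretch
modulus (defaults: dsDNA L_p 45 nm, K 1200 pN, L_c 500 nm; hybrid L_p
50 nm, K 1000 pN, L_c 400 nm).  The folded hairpin contributes a rigid
2 nm (helix width); unfolded, the released strand (2·stem + loop
nucleotides) is a freely jointed chain (Kuhn length 1.5 nm; 0.56 nm/nt
ssDNA, 0.59 nm/nt ssRNA).  These are literature-style values, all
overridable in config; the original instrument's trap stiffnesses are not
published, so the absolute simulated forces are internally consistent
rather than a reproduction of the measured force scale.

The trap stiffness default (0.08 pN/nm combined) was chosen so that
(a) the loading rates k_eff·v for 50–450 nm/s fall in the few-to-20 pN/s
range characteristic of these experiments, and (b) the force drop on
unfolding near 6 pN is ~0.5 pN, comfortably above the 0.2 pN noise floor
so that event detection on synthetic traces is meaningful.

`solve_force_balance` finds the common tension at a given trap separation
by bracketed root finding (scipy brentq on [0, 200] pN, residual < 1e-6
nm); below the slack length the tension is zero.  `effective_stiffness`
sums the series compliances analytically; it matches the numerical
derivative dF/d(separation) of the force balance to < 1 %.  The loading
rate used by both the simulator and the fit is r = k_eff·v with k_eff
frozen on the folded branch at the coexistence force ΔG/L — freezing is
what makes the ramp linear in force and the closed-form densities exact,
and evaluating at the centre of the transition region minimises the
linearisation error where events actually happen.

## Free-energy landscapes

`build_landscape` opens the stem base pair by base pair from the bottom.
Pair i carries the nearest-neighbour stack free energy between pairs i
and i+1 (unified DNA set; Turner/Xia RNA set, both ΔH/ΔS so the 29 °C
values are temperature-corrected); the final step releases the loop
(Jacobson–Stockmayer extrapolation from a 9-nt reference penalty, treated
as entropic) and removes the duplex-end initiation term.  A single
additive per-stack buffer offset per chemistry (−0.17 kcal/mol DNA,
−0.35 kcal/mol RNA) absorbs the difference between the 1 M reference
tables and the working buffer (50 mM K⁺, 5 mM Mg²⁺); it was calibrated
once so that the default 13-bp ~50 % GC stem reproduces the
structure-prediction unfolding energies of the four benchmarks
(63/60/89/87 kJ/mol) within ±1 kJ/mol, and is not otherwise adjusted.
The default stem (5'-GCGATACTAGTAC-3', bottom to top) is a placeholder
with the benchmark hairpins' ~50 % GC content and three G·C pairs at the
bottom; the exact published sequences are only available graphically.

Under force, each opened pair releases two nucleotides whose
freely-jointed-chain stretching free energy ∫₀^F x_ss(f)df (closed form
n·l·(k_BT/b)·ln(sinh u/u)) is subtracted; full opening also releases the
loop.  At the measured transition forces the resulting landscapes peak at
the top of the stem for all four benchmarks — the signature of the
non-cooperative model, in contrast to the fitted x_→ values which place
the kinetic barrier only 5–11 nucleotides into the stem.  A
frozen-extension mode (per-nucleotide extension pinned at a reference
force) makes the tilt exactly linear in F for analysis purposes.

`total_free_energy` reports ΔG_mfold, ΔG_stretch and their exact sum.
The default model for ΔG_stretch is the elastic energy stored in the
released strand at the transition force, ∫F dx = F·x(F) − ∫x dF.  For the
DNA benchmarks this lands within ~1–2 kJ/mol of the published stretch
terms (19.3 vs 20, 16.1 vs 18); for RNA it overshoots (39 vs 32, 42 vs
35), because the published values come from an unpublished elasticity
treatment.  A measured/published stretch value can therefore be passed in
directly, which is what the bookkeeping checks do.

`x_to_nucleotides` converts x_→ to a count of unfolded nucleotides as the
smallest n whose extension at the transition force covers x_→ (ceiling;
exact multiples resolve to the smaller n).  The per-nucleotide extension
is a knob: the FJC value at F_t (~0.33 nm/nt for ssDNA at 6.3 pN) is the
model route, while the calibrated value 0.49 nm/nt reproduces the
published 9-nucleotide assignment for a 4.4 nm transition-state distance.
The discrepancy is documented rather than hidden: the conversion
procedure used originally is not fully specified.

## Synthetic data

The generator reproduces the statistical structure the inference assumes,
at the published study conditions: triangular ramps at 50/150/300/450
nm/s up to relative extension 1.4, molecule/cycle counts of the benchmark
data sets, Gaussian force noise (default 0.2 pN, applied post hoc to the
recorded force only), 1 kHz sampling.

Event tables are sampled *exactly*: under a linear ramp the integrated
Bell hazard inverts in closed form, so transition forces are drawn by
inverse-transform sampling of the alternating jump chain with no
time-step bias; first-unfolding forces from 10⁴ simulated ramps match the
analytic density with a Kolmogorov–Smirnov distance < 0.01.  Per cycle
the first unfolding force on stretch and the first folding force on
release are recorded (the convention for flipping traces), along with the
total number of transitions.  Full traces (`simulate_ramp_cycle`) instead
evolve the latent state along the actual separation protocol, with rates
driven by the state-dependent branch forces (precomputed force-separation
tables, cumulative-hazard inversion on a 10× oversampled time grid) — at
the price of the mild nonlinearity of the true loading rate.  Hopping at
constant extension uses exponential dwells with the branch-force rates.

One RNG stream per molecule is derived from the master seed by a
counter-based split (`SeedSequence((seed, molecule))`), so per-molecule
reproducibility survives reordering; identical configs give bit-identical
outputs.

What is *not* emulated: bead Brownian dynamics, detector transfer
functions, drift, calibration errors, and the instrument's actual
(unpublished) trap stiffnesses.  Passing tests therefore demonstrate the
correctness and statistical consistency of the analysis chain under the
stated model, not the absolute force scale of any particular instrument.

## Trace analysis

Event detection median-filters the force (5 samples), flags changes of at
least `min_jump` (default 0.5 pN, set by the ~1 pN published jumps)
within a window, clusters candidates and confirms each against medians
over 3 windows on either side; drops are unfoldings, rises are foldings.
On simulator output with latent truth retained, recall and precision are
≥ 0.95 at default settings.  Transition lengths come either from
ΔF/k_eff (default) or from the separation distance between the folded and
unfolded branches at the event force.  Most probable forces are the means
of least-squares Gaussian fits to binned counts (0.5 pN bins, zero bins
included), mirroring how the published values were obtained, and
F_t is the arithmetic mean of the unfold and fold values at 50 nm/s.
Dwell analysis locates the two force levels by a 1-d two-means split,
requires separation ≥ 2·deadband (default 0.3 pN), assigns states with a
Schmitt trigger, absorbs runs shorter than 3 samples, and excludes the
censored first and last dwells from the means.

## Hysteresis inference

For each molecule all unfolding forces are paired with all folding forces
(u_m·f_m pairs); each pair carries weight c_m/(u_m·f_m), so a molecule's
total weight is proportional to its number of performed cycles c_m, and
weights are normalised to one.  This is one reading of "weighted by the
number of force cycles"; per-pair and per-molecule strategies are
implemented as alternatives and give indistinguishable fits on synthetic
data at study scale.  Bin width defaults to 0.5 pN (≥ 5 bins across the
~2.5 pN FWHM of the force distributions).

The fit minimises Σ_speeds √(mean over bins (model − data)²) over a
60×60 grid of x_→ (1–10 nm) × log₁₀k₀ (−7…−1), followed by Nelder–Mead
refinement; the grid scan uses a 0.05 pN force grid (adequate for 0.5 pN
bins) and the refinement the full 0.01 pN grid, exploiting that both Bell
hazard integrals are linear in k₀ to evaluate a whole k₀ column at once.
L and ΔG are fixed inputs (measured transition length; total free-energy
bookkeeping), as are the per-speed k_eff values.  Intervals are profile
cuts at 1.1× the minimum rmse; a minimum on the search boundary sets a
warning flag.  On model-generated histograms the fit recovers the truth
exactly (rmse ~10⁻⁸); on simulated studies at the published data sizes
the estimator is unbiased with a per-replicate spread of ~0.15–0.3 nm in
x_→ and ~0.3 decades in k₀ — the medians over 20 replicates reproduce
the generating values within their published uncertainties, while
single replicates at these sample sizes frequently do not.  rmse values
at study scale are ~0.02–0.05 per speed, the multinomial noise floor of
~100-cycle histograms.

## Known limitations

- Single-barrier, two-state kinetics only: no intermediates, no
  Dudko–Hummer–Szabo shape corrections, no multi-barrier landscapes.
- The absolute simulated force scale depends on stand-in elasticity
  defaults; quantitative comparisons should be made on hysteresis and
  recovery statistics, which are invariant to it through k_eff.
- The nearest-neighbour tables use a single calibrated buffer offset, not
  a full salt model; non-Watson-Crick loop energetics are not included.
- With the benchmark RNA18 parameters the model predicts observable
  hopping (mean dwell ~25 s) near coexistence within 2-minute windows;
  the original experiment reported none, suggesting its holds were
  shorter or the true barrier higher than the fitted effective one.
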