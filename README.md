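# hairpinfs

Two-state analysis of DNA and RNA hairpin folding under force, as measured
in dual-trap optical-tweezers experiments.

A nucleic-acid hairpin (a base-paired stem closed by a single-stranded
loop) held between two handles and two optical traps unfolds and refolds
as the trap separation — and with it the tension — is ramped up and down.
`hairpinfs` is a library plus CLI for everyone who works with such data:
it implements the complete analysis chain from raw force/extension traces
to fitted kinetic parameters, together with a synthetic-data generator
that stands in for the instrument so every step can be validated against
known ground truth.

## The model

The hairpin is a two-state system on a single-barrier landscape: folded at
reaction coordinate x = 0, unfolded at x = L, barrier at x_→ (with
x_← = L − x_→).  Force tilts the landscape linearly:

    k_→(F) = k₀ · exp(+F·x_→ / k_BT)          (unfolding)
    k_←(F) = k₁ · exp(−F·x_← / k_BT),   k₁ = k₀ · exp(ΔG / k_BT)

where k₀ is the zero-force unfolding rate and ΔG the zero-force
free-energy difference (unfolded − folded, elastic contributions
included).  Under a linear force ramp with loading rate r = k_eff·v the
distribution of the first unfolding (or refolding) force has the
closed Bell–Evans form

    p_→(F) = (k_→(F)/r) · exp[ −(k₀·k_BT)/(r·x_→) · (e^{F·x_→/k_BT} − e^{F₀·x_→/k_BT}) ]

and the force **hysteresis** ΔF = F_unfold − F_fold is distributed as the
cross-correlation of the stretch and release densities.  Fitting measured
hysteresis histograms — globally across pulling speeds — recovers x_→ and
k₀, the two parameters not fixed by independent measurements.

Around this core the package provides:

- **`elasticity`** — Marko–Siggia worm-like-chain handles, freely-jointed
  released strand, the series force balance and the effective stiffness
  k_eff that converts pulling speed into loading rate;
- **`kinetics`** — rates, analytic ramp densities (with an independent
  survival-ODE oracle), hysteresis convolution, constant-extension
  hopping rates;
- **`landscape`** — nearest-neighbour free-energy landscapes G(n_open),
  the bookkeeping ΔG_tot = ΔG_mfold + ΔG_stretch, the equilibrium force
  estimate F = ΔG_tot/L, and the conversion of x_→ into a number of
  unfolded nucleotides;
- **`simulate`** — exact (inverse-hazard) event sampling and full sampled
  traces for triangular ramps and constant-extension hopping, with
  Gaussian measurement noise and per-molecule reproducible RNG streams;
- **`traces`** — event detection on noisy traces, transition lengths,
  Gaussian force histograms (most probable forces, F_t), Schmitt-trigger
  dwell-time analysis;
- **`inference`** — cycle-weighted hysteresis histograms and the global
  (x_→, k₀) fit with rmse objective and profile intervals;
- **`datasets`** — the published summary values of the four benchmark
  hairpins (DNA10, DNA18, RNA10, RNA18: a shared 13-bp stem with 10- or
  18-nt loops) used as simulation ground truth and fixed fit inputs.

## Worked example

Simulate a full RNA10-style study (four speeds 50/150/300/450 nm/s,
44 molecules, published cycle counts, 0.2 pN force noise), build the
cycle-weighted hysteresis histograms, and recover the kinetic parameters:

```python
import hairpinfs as h
from hairpinfs import datasets as ds
from hairpinfs.simulate import generate_event_tables, loading_rate_pn_s

cfg = ds.study_simulation_config("RNA10", seed=1)
events = generate_event_tables(cfg)
hists = [h.build_hysteresis_histogram(events, v) for v in cfg.speeds_nm_s]
k_eff = {v: loading_rate_pn_s(cfg.params, cfg.construct, v) / v
         for v in cfg.speeds_nm_s}
rec = ds.PUBLISHED["RNA10"]
fit = h.global_fit(hists, rec.transition_length_nm, rec.dG_total_kj_mol,
                   k_eff, f_max_pn=rec.ramp_F_max_pn)
print(f"x_fwd = {fit.x_fwd_hat_nm:.2f} nm")
print(f"k0    = {fit.k0_hat_per_s:.2e} 1/s")
```

prints

```
x_fwd = 3.09 nm
k0    = 2.79e-05 1/s
```

The generating truth was x_→ = 3.0 nm, k₀ = 4.0·10⁻⁵ 1/s: one replicate
of this size recovers the transition-state distance to ~0.1 nm and the
rate to within a factor ~1.5 (k₀ is only log-scale identifiable from ramp
data).  The same simulated study shows the expected non-equilibrium
signature — the mean hysteresis grows from 4.3 pN at 50 nm/s to 8.1 pN at
450 nm/s.

The CLI exposes the same pipeline:

```sh
hairpinfs pipeline --config my_run.yaml        # simulate → histogram → fit → landscape → dwell
hairpinfs fit events.tsv --config my_run.yaml  # fit an existing event table
hairpinfs landscape --stem-fasta stem.fa       # free-energy profile G(n_open)
```

Configs are flat key-value YAML with units in the key names
(`trap.stiffness_total_pN_nm: 0.08`); see `hairpinfs.config.DEFAULTS` for
every key.

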