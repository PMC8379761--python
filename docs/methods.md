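# Methods

## The model

Neuromuscular transmission is initiated when a nerve impulse releases a
bolus of acetylcholine (ACh, `A`) into the synaptic cleft, where it
competes with any nondepolarizing blocker (`D`) present for the two agonist
binding sites of the muscle nicotinic receptor (`R`). The package
integrates the mass-action kinetics of the ten coupled species

    A, ARA*, ARA, DRD, ARD, DRA, ARO, ORA, DRO, ORD

where three-letter symbols name site-1/receptor/site-2 occupancy (`O` =
empty) and `ARA*` is the diliganded open state, reached from `ARA` with
gating rates `k_open`/`k_close`. Free ACh decays at rate `k_decay`
(esterase hydrolysis plus diffusion out of the cleft); each
binding/unbinding step carries its own site- and ligand-specific
association and dissociation rate constant. The free receptor `ORO` is
never integrated — it is reconstructed from receptor conservation, so
total receptor mass is exact by construction.

A synaptic event is modelled as an instantaneous step of `[A]` to `A_init`
at t = 0 on top of the pre-event steady state of the blocker-binding
equilibrium, with `[D]` clamped throughout (no pharmacokinetics on the
millisecond scale). With independent sites, the pre-event occupancies have
the closed form

    O_DRD = mu_D d^2 / W,  O_ORD = mu_D d / W,  O_DRO = d / W,
    W = (1 + d)(1 + mu_D d),   d = [D]/K_D1,   mu_D = K_D1/K_D2,

and `O_total` is their sum. The response measure is the peak of `[ARA*]`
relative to the drug-free peak under otherwise identical parameters; under
the proportionality of end-plate conductance to open-channel count this is
the relative current I_antag/I_0 of patch-clamp work. The scientific
question the package answers is when that relative current equals the
occupancy complement `1 - O_total` (the assumption behind the two-site
receptor-binding model) and when it does not.

## Default parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| `R_total` | receptor concentration in the cleft | 7.75e-5 | M |
| `A_init` | free ACh immediately after release | 7.75e-6 | M |
| `k_decay` | free-ACh decay | 1.2e4 | 1/s |
| `k_dissA1`, `k_dissA2` | ACh off-rates | 1.8e4 | 1/s |
| `k_assocA1`, `k_assocA2` | ACh on-rates | 1.1e8 | 1/(M s) |
| `k_dissD1`, `k_dissD2` | blocker off-rates | 10 | 1/s |
| `k_assocD1`, `k_assocD2` | blocker on-rates | 1.0e8 | 1/(M s) |
| `k_open` / `k_close` | channel gating | 5.0e4 / 1.2e3 | 1/s |

`R_total` derives from 2.1e7 receptors at a human deltoid end plate in a
cleft volume of 4.5e-13 L (this volume has been printed elsewhere with a
positive exponent, which is physically impossible and inconsistent with
the concentration above; `parameters.derived_constants` documents the sign
choice). `A_init` corresponds to 300 vesicles of 7000 ACh molecules — one
tenth of the receptor count, so in vivo only a small fraction of receptors
can ever be activated. `k_decay` gives a free-ACh half-life of 58 µs. The
ACh binding constants are from mouse adult receptors and the blocker
constants are representative of slowly dissociating clinical blockers;
both are meant to be swept, not trusted to a digit.

Sweep rules are fixed: `K_A` moves both ACh on-rates with off-rates held
(so K_A1 = K_A2, mu_A = 1); `mu_D` moves `k_assocD2` only (K_D1 fixed);
the initial-ACh sweep scales `A_init` as a multiple of `R_total`; the
`k_dissD` sweep sets both off-rates equal and rescales both on-rates to
hold K_D1, K_D2 — hence the occupancy axis — fixed, isolating the pure
kinetic effect. The ACh-concentration and off-rate sweeps default to
K_A = 1e-5 M, the setting where the nonlinearity is most pronounced.

## Dimensionless form and reduction

Scaling time by `k_decay`, free ACh by `K_A1` and every receptor state by
`R_total` leaves eleven dimensionless groups (`kappa_*` normalized rates,
`lambda_A*` affinities, `mu_A`, `mu_D`, `delta`). For clinical blockers
`kappa_D1, kappa_D2 ~ 1e-3` while the ACh groups are order one, so blocker
exchange is frozen on the synaptic timescale. In the limit
`kappa_D -> 0`, `x_DRD`, `x_ORD + x_ARD` and `x_DRO + x_DRA` are constants
of motion fixed by the pre-event occupancies, and the model collapses to
seven states in which the blocker appears only through `mu_D` and `delta`
— which is why a slowly dissociating blocker is fully characterized by its
site selectivity.

The reduced right-hand side implemented here is the exact `kappa_D -> 0`
limit of the full dimensionless system under the substitutions
`x_ORD = O_ORD - x_ARD`, `x_DRO = O_DRO - x_DRA`, with the free-receptor
fraction reconstructed from full conservation **including the open state**.
Transcriptions of this reduction sometimes drop the open-state term from
the conservation sum and conflate `lambda_A1`/`lambda_A2` in the ACh
balance; both shortcuts are harmless at `mu_A = 1` and low activation but
break the exact correspondence with the full model, so this package
derives the reduced system from the change of variables and verifies it —
and the full dimensionless system — against the dimensional right-hand
side in the test suite rather than trusting any printed form.

## Numerics

* Integrator: LSODA (`scipy.integrate.solve_ivp`), rtol 1e-8, atol
  1e-14 M. State magnitudes span ~1e-14–1e-4 M across the drug grid, which
  rules out a purely relative criterion.
* Horizon: 5 ms (peaks occur below 0.5 ms in the base case); doubled up to
  three times automatically if the open-state trace has not turned over,
  after which a "peak not bracketed" error is raised.
* Output grid: 2001 evenly spaced samples per horizon; the peak value and
  time are refined by the vertex of the parabola through the three samples
  around the discrete maximum, so reported peak times are not grid-limited.
* Degenerate inputs: an identically zero open-state trace has no peak and
  raises; on exact grid ties the first maximum wins. Solver undershoot
  below zero within the absolute tolerance is treated as zero for
  reporting; anything larger is an error.
* Hill regression: ordinary least squares on the response scale (no
  weighting), optimized over (log IC50, log n_H) to enforce positivity
  without constraints; IC50 seeded at the model-free log-linear 0.5
  crossing, n_H at 1. Zero-drug points enter as exact response-1
  constraints. Data that never cross 0.5 are fitted but flagged ill-posed.
* "Slow enough" blocker exchange: `kappa_D <= 1e-3` is the documented
  threshold below which equal-`mu_D` configurations produce overlapping
  inhibition–occupancy curves (within 1e-3); chosen from the convergence
  study in the tests, not a literature constant.

## What the numerical experiments emulate — and what they do not

All inputs are synthetic by design: the package's subject *is* the
mechanistic model, and every experiment is a deterministic ODE study (no
random seeds exist anywhere in the pipeline). The base case emulates an
adult human neuromuscular junction at in vivo ACh release (one tenth of
the receptor pool); high-`A_init` settings emulate the saturating ACh
applications of in vitro patch-clamp protocols. Passing tests therefore
demonstrate internal consistency of the model and reproduction of its
qualitative and anchored quantitative behaviour — not agreement with any
particular experimental recording. In particular the model omits receptor
desensitization (the dominant cause of current decay in long in vitro
applications), presynaptic dynamics and vesicle depletion, diffusion
gradients within the cleft (well-mixed assumption), and the
muscle-twitch margin of safety downstream of receptor activation.

Problem sizes: library defaults use the standard 101-point drug grid
(zero plus 100 log-spaced values over 1e-14–1e-5 M). The test suite runs
its sweep batteries on a 13-point grid spanning the occupancy transition
(delta ~ 3e-3 to 1e2), which preserves every monotone trend and overlap
property while keeping the default `pytest` run near ten seconds; the
grids are a package choice and can be widened freely.

## Known limitations

* The equilibrium occupancy formula assumes the two sites load
  independently before the event; cooperative blocker binding would need a
  different pre-event state.
* The clamped-`[D]` assumption means onset/offset pharmacokinetics of the
  blocker are out of scope; only the within-event competition is modelled.
* `relative_current` compares single-event peaks; train-of-four and other
  repetitive-stimulation phenomena involve presynaptic rundown that the
  model cannot represent.
* The Hill fit reports asymptotic covariance from the Jacobian at the
  optimum; for strongly ill-posed data (responses never crossing 0.5) the
  IC50 is an extrapolation and is flagged as such rather than suppressed.
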