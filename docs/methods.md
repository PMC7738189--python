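# Methods

`hbaccess` models the onset of *hunchback* P2 transcription in nuclear cycle 13
of the early *Drosophila* embryo, driven by the Bicoid gradient and the
pioneer-like factor Zelda, and asks which classes of promoter model can
reproduce the dynamics of transcription onset along the anterior-posterior
(AP) axis.  This note records the models, the synthetic study conditions, the
numerical choices, and what the tests do and do not establish.

## Models

All models obey the occupancy hypothesis: the RNAP loading rate is
`R * p_bound(t)`, with `p_bound` the probability of the RNAP-bound promoter
states.

**Thermodynamic MWC model.**  Chromatin thermally fluctuates between an
inaccessible state, with statistical weight `exp(delta_eps_chrom)` (k_BT
units) relative to the bare accessible state, and accessible states in which
`n_b` Bicoid sites (default 6), `n_z` Zelda sites (default 10) and RNAP bind.
With reduced activities `b = [Bcd]/K_b`, `z = [Zld]/K_z`, `p = [RNAP]/K_p`,
an accessible state with `i` Bicoid, `k` Zelda and `j` RNAP molecules bound
has weight `C(n_b,i) b^i w_b^{max(i-1,0)} C(n_z,k) z^k p^j w_bp^{i j}`:
Bicoid-Bicoid cooperativity is chain-like (`w_b` per additional Bicoid),
Bicoid contacts RNAP through `w_bp`, and Zelda contacts nothing, so its factor
`(1+z)^{n_z}` multiplies every accessible state.  `p_bound` is the RNAP-bound
weight fraction; a brute-force state enumeration serves as the oracle for the
closed form.  Transcription is additionally gated by a mitotic repression
window `t_mitrep` after anaphase.  Because the equilibrium responds
instantaneously to its inputs, onset timing is slaved to nuclear import and
to `t_mitrep`, both position-independent — the structural reason this class
cannot produce AP-dependent onset delays.

**Generalized thermodynamic model.**  Arbitrary non-negative weights
`P_{r,i}` for `r` RNAP and `i` of up to 12 Bicoid molecules bound, plus an
inaccessible weight that may be polynomial in [Bicoid] (Bicoid binding to
inaccessible chromatin).  It contains the MWC model by an exact embedding
(`mwc_to_generalized`), verified to 1e-12.

**Non-equilibrium MWC model.**  The same state space (`n_b <= 5`), with free
transition rates and no detailed-balance constraint, solved as coupled linear
ODEs from an all-inaccessible initial condition.  Concentration dependence
enters only through binding edges; chromatin opening/closing is
concentration-independent.  Two mitotic-repression variants: transcription
clamped to zero before `t_mitrep` while the states evolve (default), or state
evolution frozen until `t_mitrep`.  With rates chosen in detailed balance
with the thermodynamic weights and scaled up, the model converges to the
thermodynamic `p_bound` — the equilibrium-limit oracle.

**Transcription-factor-driven accessibility.**  The locus traverses `m`
silent states via irreversible transitions catalyzed at the shared rate
`pi(t) = c_b [Bcd](t) + c_z [Zld](t)`; once open it stays open and
equilibrates instantly to an accessible-only thermodynamic sub-model (whose
Zelda factor provably cancels — asserted in tests, not assumed).  The silent
chain with a shared time-varying rate is an inhomogeneous Poisson process:
with cumulative hazard `L(t)` the opening probability is the regularized
incomplete gamma `P(m, L(t))` — the exact solution of the chain ODEs and the
Erlang CDF for constant `pi`.  Tests integrate the chain with an independent
ODE solver as the oracle.  The population-mean loading rate is
`P_open(t) * R * p_bound_acc(t)`; the predicted fraction of active nuclei is
`P_open(nc_duration)` (a nucleus that has not opened by the next mitosis
never transcribes).  No mitotic-repression window is applied: the chain
itself produces the post-anaphase quiet period.

## From loading rate to the MS2 observable

The number of actively transcribing RNAP molecules is the convolution of the
loading rate with a trapezoid-shaped single-polymerase fluorescence kernel:
linear ramp while the polymerase crosses the 5' MS2 cassette
(`ms2_position` = 0.1 kb), full signal until termination, cleavage at the
residence time `tau = gene_length / elongation_rate` (5.2 kb / 1.54 kb/min
≈ 3.4 min).  Trapezoidal quadrature on a uniform grid (default 0.5 min);
linearity and causality are property-tested.

## Features and onset metrics

`init_rate` and `t_on` come from a least-squares line through the initial
rise of a trace: the window opens where the trace first exceeds 10% of its
cycle maximum and closes at the earliest of the 60%-of-maximum crossing, the
maximum itself, and 2 min after opening.  The 60% ceiling and the 2-min cap
keep the fit on the quasi-linear part of the rise; windows that extend to the
trace maximum systematically drag the x-intercept early on saturating traces
(about 2 min for a thermodynamic trace with `t_mitrep` = 3), and windows tied
only to a fraction of the maximum mix the fast rise with slow late creep in
mixed-timescale kinetic traces, manufacturing spurious position-dependent
delays.  The rule is exact on piecewise-linear traces.  Fits with
`t_on` more than 1 min before anaphase or beyond the cycle end are rejected
as inactive: they arise from undetectable late creeps, not measurable onsets.
Traces whose maximum never reaches `min_signal` (1 RNAP) are inactive.

The two discrimination signatures are the onset offset, `t_on` at 20 %EL,
and the average onset delay: the trapezoidal integral of
`t_on(x) - t_on(20%)` over 20-37.5 %EL divided by the 17.5 %EL span.  When
activity ends before 37.5 %EL the integral runs over the contiguous active
sub-interval and normalizes by its length.  Positions where fewer than 30% of
nuclei ever show a detectable spot are masked before any metric.

## Synthetic study conditions

The generator emulates the structure of the live-imaging measurements, not
the images: an exponential Bicoid gradient (decay length 20 %EL, anterior
amplitude 1 in arbitrary units, so only ratios to dissociation constants
matter), spatially uniform Zelda, both imported into nuclei as
`1 - exp(-t/tau)` with `tau` = 1 min (saturating by ~3 min after anaphase);
2.5 %EL position bins from 20 to 60 %EL; a 17-min cycle sampled at 0.5 min;
per-nucleus traces equal to the model mean plus additive Gaussian noise
truncated at zero; cohorts of embryos synchronized at anaphase and averaged
within bins, then across embryos (SEM per time point); and a zelda-null
genotype that zeroes the Zelda channel.  The default data-generating model is
the TF-driven class with `m` = 3, `c_b` = 1.0 and `c_z` = 3.0 (per minute per
concentration unit): `c_b` places the zelda-null 30%-activity cutoff at
40 %EL and `c_z` makes wild-type opening Zelda-dominated, hence a flat
wild-type onset profile — the phenotypes the analysis is built around.
Recovery experiments use 11 wild-type and 12 zelda-null embryos with 8 nuclei
per bin and trace noise of 5% of the full signal; smaller cohorts leave the
number of silent steps weakly identified because adjacent `m` values
compensate through the catalytic constants.

What the generator does **not** emulate: nuclear movement and division,
spot-detection noise structure (real imaging noise is not additive Gaussian),
bursting, single-nucleus onset-time dispersion (traces share the bin mean),
or Bicoid gradient establishment.  Passing tests therefore show that the
analysis machinery is correct and that the discrimination logic works under
these idealized conditions — not that real embryos satisfy them.

## Parameter-space exploration

Each model class is sampled log-uniformly: dissociation constants
1e-2..1e2 (input units), cooperativity/interaction factors 1e-2..1e3,
`delta_eps_chrom` -10..10 k_BT, `t_mitrep` 0..4 min, catalytic constants
1e-4..1e1, `m` in 1..6, kinetic rate constants 1e-2..1e2 /min (occupancy-mode
graphs, `n_b` 1..5).  Every draw runs the full chain to a position profile
over 20-37.5 %EL.  A plateau constraint then rescales each draw's `R` so its
largest initial rate matches a reference plateau of 15 RNAP/min (onset times
are invariant under this rescaling) and masks positions whose rescaled trace
peak stays below the 1-RNAP detection floor.  The (offset, delay) cloud is
rasterized on a 0.1 x 0.1 min grid; a signature point is inside a region if
its cell is occupied, on the boundary if its SEM ellipse touches an occupied
cell.  Containment at single-cell resolution needs a dense cloud — the
TF-driven class is sampled at 8000 draws where containment is asserted;
region areas are compared at matched draw counts (500) because occupied area
grows with sampling depth.

## Fitting

`ProfileFit` minimizes the SEM-weighted sum of squared residuals of
`init_rate` and `t_on` over all datasets simultaneously with one shared
parameter set; zelda-null datasets zero the Zelda channel.  The residual
vector has fixed length: data-active positions where the model predicts no
activity (or vice versa) contribute a constant mismatch penalty (default 10)
instead of a data term.  Optimization is bounded trust-region least squares
in log space for scale parameters, with seeded multi-starts (default 8; the
objective is non-convex in the interaction and chromatin-energy parameters).
Standard errors come from the Gauss-Newton curvature `(J^T J)^{-1}` at the
optimum, mapped through the log transform.  `select_m` fits each `m` and
returns the smallest whose reduced objective is within 1.2x the minimum —
preferring the simplest chain compatible with the data.

## Numerical choices

* Equilibrium closed forms are evaluated with log-sum-exp throughout; no
  overflow up to `n_b` = 12 at extreme concentrations.
* Master equations: BDF with rtol 1e-8 / atol 1e-10 (default), or
  matrix-exponential stepping with the generator frozen at substep midpoints
  (0.1 min substeps) — exact for constant inputs and arbitrarily stiff rates;
  the two agree to ~5e-4 on random stiff graphs, and the sweeps use the
  exponential path for speed.  State vectors are clipped at zero and
  renormalized; conservation holds to 1e-8 before renormalization.
* The opening chain uses the analytic incomplete-gamma solution; its only
  error is the trapezoidal cumulative hazard (exact for constant rates).
* Degenerate line-fit windows (2 points) fall back to an exact line with zero
  covariance; ties in the rise window resolve to the earlier time point.

## Known limitations

* Fraction-active for MWC-class models is detectability of the deterministic
  mean trace, not a per-nucleus probability; only the TF-driven class
  predicts a graded fraction of active nuclei.
* `select_m` discriminates adjacent `m` only with cohort sizes near the
  defaults; single-embryo data will not identify `m`.
* The non-equilibrium sweep uses occupancy-resolved graphs; full
  configuration-resolved sweeps are exposed but combinatorially heavier.
* Absolute fluorescence calibration (RNAP per intensity unit) is outside the
  model; one trace unit is one fully loaded polymerase.
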