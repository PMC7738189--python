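# hbaccess

Models of transcription onset and chromatin accessibility at the *hunchback*
P2 enhancer in the early *Drosophila* embryo.

## The scientific problem

During nuclear cycle 13, *hunchback* switches on in a step-like pattern along
the anterior-posterior axis, activated by the exponential Bicoid gradient and
licensed by the spatially uniform pioneer-like factor Zelda.  Live MS2
imaging gives the number of actively transcribing RNA polymerases per nucleus
over time, and fluorescent protein fusions give the instantaneous nuclear
concentrations of both inputs — so the input-output function of the enhancer
can be interrogated dynamically rather than at steady state.

`hbaccess` implements three classes of promoter model for this system and the
machinery to discriminate between them:

* **Thermodynamic MWC** — chromatin thermally fluctuates between an
  inaccessible state (weight `e^{Δε_chrom}`, k_BT units) and accessible states
  in which `n_b` Bicoid and `n_z` Zelda sites plus RNAP bind in equilibrium;
  the RNAP loading rate is `R·p_bound` (occupancy hypothesis), gated by a
  mitotic-repression window `t_MitRep`.  A generalized variant allows
  arbitrary state weights `P_{r,i}` for up to 12 Bicoid sites.
* **Non-equilibrium MWC** — the same state space with free kinetic rates,
  solved as a master equation `dP/dt = M(t)P` from an all-inaccessible start;
  no detailed balance is imposed.
* **Transcription-factor-driven accessibility** — Bicoid and Zelda actively
  catalyze `m` irreversible silent transitions at rate
  `π = c_b[Bcd] + c_z[Zld]`; once open, the locus follows an accessible-only
  equilibrium model.  Opening probability is the inhomogeneous-Poisson
  (Erlang-type) closed form `P(m, ∫π dt)`.

Each model maps measured (or synthetic) input dynamics to a predicted MS2
trace per position, from which two features are extracted: the initial RNAP
loading rate and the onset time `t_on` (x-intercept of a line fitted to the
initial rise).  Two scalar signatures summarize a genotype — the `t_on`
*offset* (onset at 20 %EL) and the *average onset delay* (normalized integral
of `t_on(x) − t_on(20%)` over 20–37.5 %EL).  Equilibrium and kinetic MWC
models respond on the timescale of nuclear import, which is the same at every
position, so they cannot produce position-dependent onset delays; TF-driven
opening, paced by the local Bicoid concentration, can.  Sampling each class's
parameter space and rasterizing the attainable (offset, delay) region makes
this discrimination quantitative.

The package is exercised end-to-end on synthetic data with the statistical
structure of the measurements (embryo cohorts synchronized at anaphase,
2.5 %EL position bins, additive trace noise, a zelda-null genotype); see
`docs/methods.md` for the models, study conditions and numerical choices.

## Worked example

```python
import numpy as np
from hbaccess import (default_input_field, TFDrivenModel, gen_embryo,
                      average_embryos, profile_from_embryo, signature_point,
                      ProfileFit)

field = default_input_field()           # Bicoid gradient + uniform Zelda
model = TFDrivenModel()                 # m=3, c_b=1.0, c_z=3.0

datasets = []
for genotype, n in (("wild-type", 11), ("zelda-null", 12)):
    embryos = [gen_embryo(model, field, n_nuclei_per_bin=8, noise_sd=2.5,
                          seed=i + (100 if genotype == "zelda-null" else 0),
                          genotype=genotype)
               for i in range(n)]
    profile = profile_from_embryo(average_embryos(embryos), embryos)
    pt = signature_point(profile)
    print(f"{genotype:>10}: t_on offset {pt.offset:5.2f} min, "
          f"average delay {pt.avg_delay:5.2f} min, "
          f"active bins {profile.active_mask.sum()}/{profile.positions.size}")
    datasets.append((profile, field, genotype))

res = ProfileFit("tf_driven", datasets, fixed={"m": 3}).fit(n_starts=6, seed=0)
print(res.summary())
```

prints

```
 wild-type: t_on offset  1.83 min, average delay  0.03 min, active bins 17/17
zelda-null: t_on offset  4.36 min, average delay  0.20 min, active bins 9/17
                     Promoter model fit
============================================================
model class:        tf_driven
datasets:           2 (wild-type, zelda-null)
residuals:          60
objective (SSR):    878.06
reduced objective:  15.6796
multi-starts:       6 (0 failed)
converged:          True
------------------------------------------------------------
parameter               estimate       std err
------------------------------------------------------------
c_b                      0.91826        0.0146
c_z                       3.0544        0.0287
K_b                      0.10221       0.00196
R                         14.949        0.0725
m                              3 (fixed)
============================================================
```

Read: the wild-type onset profile is flat (delay ≈ 0) while removing Zelda
delays onset posteriorly and abolishes activity behind ~40 %EL (only the
anterior 9 of 17 bins pass the 30%-active filter).  The joint fit to both
genotypes recovers the generating catalytic constants (`c_b` = 1.0,
`c_z` = 3.0) within a few percent, with curvature-based standard errors.

A command-line interface wraps the same functions:

```bash
hbaccess simulate --genotype zelda-null --n-embryos 3 --seed 1 --out traces.csv
hbaccess features --traces traces.csv --out profile.csv
hbaccess explore --model-class thermo_mwc --model-class tf_driven \
    --n-samples 500 --seed 1 --out regions.csv
```

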