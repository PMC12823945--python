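# itdispersion

Quantitative analysis of solute dispersion after intrathecal (IT) drug
administration. Drugs injected into the cerebrospinal fluid (CSF) of the
spinal subarachnoid space do not spread by molecular diffusion alone:
cardiac-driven CSF oscillations and micro-anatomical mixing around nerve
roots make the tracer disperse like an *effective* diffusion process with
a coefficient D several orders of magnitude above molecular, in the
cm²/min range. This package provides the computational tools to

* **estimate D from tracer records** by inverting the 1D parabolic
  diffusion equation against moment time series (the *moment inversion
  process*, MIP), with the classical method of moments (MoM) as a
  baseline;
* **relate D to CSF pulsation** through dimensional and dimensionless
  (Womersley/Peclet, scale-analysis) correlations, plus linear laws for
  the caudocranial drift velocity (CCV) of the tracer centroid;
* **model downstream pharmacokinetics** with a distributed
  six-compartment model (spinal CSF PDE with convection, effective
  diffusion, first-order loss and partition-driven mass transfer,
  coupled to lumped compartments) supporting multi-dose schedules;
* **generate synthetic tracer experiments** with the statistical
  structure of benchtop phantom recordings (bounded asymmetric domain,
  injection phase, caudocranial drift, optical noise), so every stage is
  testable without bench data.

It is aimed at researchers in biotransport and IT therapy design who
work with axial tracer-intensity profiles (e.g. from optical phantom
recordings) or need fast, mass-conservative compartmental simulations of
dosing scenarios.

## The core method

Each frame of a record gives an intensity profile C(x, t) along the
neuraxis. Its centroid and left-sided spread are

    M1(t) = ∫ x C dx / ∫ C dx ≡ x̄(t)
    M2,left(t) = ∫_{x ≤ x̄} (x − x̄)² C dx / ∫_{x ≤ x̄} C dx

The left-sided second moment stays meaningful on the bounded, asymmetric
spinal domain, where the closed sacral end makes profiles skew. MIP
estimates D by minimising

    ε(D) = Σ_i [ M2,left(t_i) − φ(D, t_i) ]²

where φ(D, t) is the left-sided second moment of a finite-volume
solution of ∂C/∂t = D ∂²C/∂x² started from the first observed frame on
the closed domain. Because the forward model honours the boundary, MIP
remains accurate when the moment trajectory tapers off at the sacral
wall — the regime where MoM (D = slope of M2,left vs t divided by 2) is
biased low.

## Worked example

```python
import itdispersion as itd
from itdispersion.synthetic import NoiseSpec

# a synthetic lumbar-bolus experiment: 2 mL over 1 min, 10 min observed
# at 1-min frames, D_true = 7.4 cm²/min, 5% lighting noise
record = itd.simulate_tracer_experiment(
    d_true=7.4, noise=NoiseSpec(multiplicative=0.05, additive=0.0), seed=1
)

series = itd.moment_series(record)
ccv, stderr = itd.caudocranial_velocity(series)
mip = itd.mip_estimate(record)
mom = itd.mom_estimate(series)
print(f"MIP: D = {mip.d:.3f} cm^2/min   MoM: D = {mom.d:.3f} cm^2/min")
print(f"centroid drift = {ccv:.3f} +/- {stderr:.3f} cm/min")
```

prints

```
MIP: D = 7.371 cm^2/min   MoM: D = 1.770 cm^2/min
centroid drift = 0.517 +/- 0.008 cm/min
```

MIP recovers the true coefficient to 0.4% while MoM, reading a slope off
the tapering moment curve, underestimates it fourfold — the bounded
domain in action. (The drift reported here is not injected advection but
the centroid's genuine cranial motion as diffusing tracer reflects off
the nearby closed sacral end.) The same objects drive the correlations: the CSF state
at 72 bpm and 1 mL/beat gives a Womersley number α ≈ 6.86, and the
packaged dimensional correlation predicts D ≈ 8.1 cm²/min there.

The same workflow is available from the shell:

```
itdispersion simulate --d-true 7.4 --seed 1 --out record.csv
itdispersion invert --record record.csv --method mip --out estimate.json
itdispersion pipeline --seed 0 --out cohort_run/
```

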