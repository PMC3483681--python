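# cflung

A stochastic simulator of mucus creation, growth, propagation, scarring,
treatment and airway remodeling in a cystic-fibrosis (CF) lung, with the
calibration machinery to fit its parameters to spirometric (FVC) data.

CF airway disease is driven by thick mucus that normal clearance cannot
remove: colonized airways fill, plug everything distal to them, and
prolonged mucus contact scars the airway wall until it is irreversibly
remodeled. `cflung` models the lung as Weibel's symmetric binary tree of
24 generations (trachea = generation 0, alveolar level = generation 23,
`2^24 − 1` airways, `2^23` alveolar units) and follows each colonized
airway's mucus volume `M_i` and scarring `S_i` through monthly steps.

## Model

For each infected site `i` with airway volume `V_i` and infection time
`t_i`:

```
F_i = H(M_i − V_i)          filled (reversibly nonfunctional)
O_i = H(Σ F/R ancestors)    shut by a plugged ancestor
R_i = H(S_i − S*)           remodeled (irreversible)

dM_i/dt = (1 − F_i) · H(t − t_i) · v_c
dS_i/dt = (1 − R_i) · H(t − (t_i + T_s)) · v_s
```

with `H` the Heaviside step (1 at 0, so reaching a threshold counts).
New colonizations arrive on bronchiolar surfaces as independent Poisson
events with per-airway intensity `λ_i = P_c · A_i · Δt`; a filled airway
seeds infection in its parent and children (overflow). Treatment fires
when the functional lung volume `V_L` drops to `α · V_L*` of its last
post-treatment baseline: it clears all undamaged colonizations, but
airways whose scarring has begun are reinfected instantaneously and stay
plugged, so damaged coverage is never recovered. The fraction of alveoli
still reachable through unplugged airways is the model's FVC proxy.

Default constants: `P_c = 6.0e-6 mm⁻²/month`, `v_c = 11.0 mm³/month`,
`T_s = 7.0 months`, `v_s = 0.023 scars/month`, `S* = 1`, `α = 0.94`,
monthly steps over 600 months (ages 0–50).

The package also provides spirometric normalization (raw FVC in litres →
percent-of-predicted via NHANES III reference equations), a synthetic
patient-registry generator, an MSPE (mean squared percent error)
Nelder–Mead calibration over ages 18–50, and one-at-a-time sensitivity
analysis.

## Worked example

```python
from cflung import load_default_tree, SimParams, simulate

tree = load_default_tree()
params = SimParams(seed=1)
print(f"airways: {tree.total_airways:,}; alveolar units: {tree.n_alveoli:,}")
print(f"expected colonizations/month: {params.P_c * tree.total_surface_area():.1f}")

traj = simulate(params, tree, n_replicates=8)
for age in (18, 30, 40, 50):
    print(f"age {age}: {traj.mean[age * 12]:.1f}% of healthy FVC "
          f"(SE {traj.se[age * 12]:.1f})")
```

prints

```
airways: 16,777,215; alveolar units: 8,388,608
expected colonizations/month: 65.4
age 18: 86.4% of healthy FVC (SE 0.9)
age 30: 77.5% of healthy FVC (SE 1.0)
age 40: 72.3% of healthy FVC (SE 1.0)
age 50: 66.3% of healthy FVC (SE 1.3)
```

i.e. roughly 65 airway sites are newly colonized per month in a healthy
lung, and the replicate-averaged disease course declines to about
two-thirds of healthy FVC by age 50. Each replicate is an independent
patient-level disease course; the dispersion shown is the
root-mean-square deviation across replicates.

The same runs are available from the shell:

```
cflung simulate --replicates 20 --seed 1 --out trajectory.csv
cflung make-cohort --patients 200 --seed 1 --out cohort.csv
cflung average-cohort --cohort cohort.csv --out observed.csv
cflung fit --observed observed.csv --out fit.json
cflung sensitivity --observed observed.csv --out sensitivity.csv
```

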