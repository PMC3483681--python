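# Methods

## The model

The lung is an idealized symmetric dichotomous tree after Weibel's
"model A": 24 generations of cylindrical airways, generation 0 the
trachea and generation 23 the alveolar level. Airway `k` (1-based heap
indexing) has parent `k // 2` and children `2k, 2k + 1`; its generation
is `⌊log2 k⌋`. One alveolar unit hangs off each generation-23 airway, so
a healthy lung has `2^23` units; the fraction of units whose root-to-leaf
path contains no plugged or remodeled airway is the FVC proxy ("percent
functional volume"). Only per-generation aggregate geometry is stored;
dynamic state lives in sparse per-site arrays plus a dense boolean
infection mask, and blocked coverage is maintained as a merged union of
leaf-index intervals, so a 16.7-million-airway lung simulates in a few
seconds per 600-month course.

### Geometry fixture

`cflung/data/weibel_model_a.csv` holds the classical model-A diameters
and lengths rescaled isotropically from their ~4800 cm³ inflation to a
reference adult functional residual capacity of 3300 cm³ (linear factor
`(3300/4800)^(1/3) ≈ 0.8826`), the standard volume normalization in
airway-deposition modelling. The resulting total luminal surface is
1.09×10⁷ mm², so the default colonization density `P_c = 6.0×10⁻⁶
mm⁻²/month` implies ≈65 newly colonized sites per month over a healthy
lung. Note the well-known quirk of the model-A table: length (and hence
airway volume) increases from generation 3 to 4, so single-airway fill
times are strictly decreasing with generation only from generation 4
outward.

### Disease dynamics

Each monthly step applies, in order: colonization → mucus growth with
fill detection → overflow → scarring → remodeling → treatment check.

* **Colonization.** Every uninfected *bronchiolar* airway (generation
  ≥ `bronchiole_gen_min`, default 10 — the cartilage-free airways of
  ~1 mm diameter and below, which carry >99.5% of the total surface)
  independently becomes colonized with probability
  `1 − exp(−P_c·A_i·Δt)`. Sampling is aggregated per generation as a
  Binomial total placed uniformly among the uninfected airways, which is
  distributionally identical to the per-airway draw (verified by
  chi-square against naive sampling, and by a placement-uniformity
  test). Restricting direct colonization to bronchioles matters: a
  directly colonized trachea never fills (its fill time is ~1900 months)
  but can scar, and a remodeled trachea is whole-lung death — an
  artifact that would dominate the population mean.
* **Growth and overflow.** Mucus grows linearly at `v_c`, capped at the
  airway volume; volumes are integrated in closed form per step (the
  dynamics are piecewise-linear ramps, so no ODE solver is used). An
  airway that fills infects its parent and children once, at the step it
  fills; overflow is not chained within a step, so an infection front
  climbs at most one generation per month even where fill times are
  sub-month.
* **Scarring and remodeling.** Scarring follows the exact ramp
  `S_i = v_s · max(0, t − t_i − T_s)` and freezes when the airway
  remodels (`S_i ≥ S*`). Remodeled airways and their subtrees are
  permanently nonfunctional. Thresholds count as crossed when reached
  (Heaviside taken as 1 at 0).
* **Treatment.** When `V_L ≤ α·V_L*` (with `V_L*` the functional volume
  right after the previous treatment, initialized to 1 at birth),
  treatment clears every airway whose wall is still undamaged — mucus
  removed, infection gone. Airways in which scarring has begun (mucus
  continuously present for at least `T_s` months, and `v_s > 0`) cannot
  be cleared: they are reinfected instantaneously, keeping their
  infection time, mucus load and plugged status. A plugged damaged
  airway therefore never re-triggers overflow (its filled state never
  transitions) and the post-treatment baseline excludes all damaged
  coverage. This "ratchet" is what lets the disease progress: each
  treatment cycle lasts longer than `T_s`, its oldest cohort of
  colonizations becomes permanent, and the baseline erodes steadily. The
  alternative reading — treatment clearing damaged airways' mucus too —
  makes the emergent treatment cycle self-tune to `T_s`, after which no
  new airway ever scars and every parameter choice yields a frozen
  plateau; we rejected it on that ground.

### Choice of α

The exacerbation threshold α is the one constant with no established
value; it controls how much functional volume may be lost before a
treatment and thereby the scarring accrued per cycle. The package
default α = 0.94 was calibrated once against the registry-derived
anchors of the average adult disease course (≈95% of healthy FVC at age
18 falling to ≈65% at 50): it reproduces the age-50 level (≈66–67%
across seeds at 20 replicates) and yields ≈86–87% at age 18. No α
reproduces both anchors: the simulated decline is close to linear from
early childhood on, whereas the anchors imply a slow childhood phase
followed by a three-fold faster adult decline. We found no reading of
the treatment/overflow rules that adds the missing late-life
acceleration without either freezing the disease or destroying the lung
by mid-life, and document the age-18 discrepancy as a model limitation
rather than force it.

### Identifiability under monthly quantization

Fills happen at month boundaries, so the objective surface of the
calibration is piecewise constant in `v_c`: a perturbation changes
nothing until it flips some generation's ceiling `⌈V_g/(v_c·Δt)⌉`. On
the vendored geometry the plateau containing the default `v_c = 11`
spans roughly (−1.4%, +9%), so `v_c` is identifiable only to a few
percent, and a 1% one-at-a-time perturbation changes the MSPE by exactly
zero. By the same token `T_s` is the stiffest direction (a 1% shift
moves the integer-age survival boundary of a whole monthly cohort), and
`v_s` only sets the delay between scarring onset and remodeling, which
is functionally invisible under the ratchet (scarred airways already
block). Fits therefore use Nelder–Mead on log-parameters with an initial
simplex step large enough (5%) to straddle plateaus, and with common
random numbers — fixed replicate seeds across objective evaluations — so
the stochastic objective is quasi-deterministic and exactly zero at the
generating parameters in self-consistency experiments.

## Spirometry and the synthetic registry

Raw FVC (litres) is normalized to percent-of-predicted with the NHANES
III adult Caucasian reference polynomials (per sex:
`b0 + b1·age + b2·age² + b3·height²`; fixture
`cflung/data/fvc_reference_coefficients.json`, declared support ages
18–80 and heights 130–210 cm; the male equation is applied from age 18,
a <2-year extrapolation of its nominal ≥20 range). Cohort averaging is
cross-sectional by completed year of age; ages without observations are
flagged, never imputed.

The synthetic registry emulates an adult-CF clinic cross-section: 200
patients by default, sex balanced, heights normal per sex (176±7 cm
male, 163±6.5 cm female), ages uniform over 18–50, each patient's true
percent-predicted FVC read from one of 20 independent simulated disease
courses at the ground-truth parameters, plus Gaussian observation noise
(SD 5 percentage points, truncated to [0, 100]) — a generic figure for
spirometry repeatability, not an estimate of any particular registry.
Raw litres are back-computed through the reference equations so the full
normalization path is exercised. What passing tests show is therefore
internal consistency of the pipeline and recoverability of parameters
from data the model itself generated; they cannot show that real
registry data follow the model.

## Numerical conventions

* Heaviside at 0 is 1: `M_i = V_i` counts as filled, `S_i = S*` as
  remodeled, age exactly `T_s` as damaged.
* Replicate `r` uses an independent generator seeded `seed + r`; equal
  seeds give bit-identical trajectories.
* The replicate dispersion is the root-mean-square deviation from the
  pointwise mean with divisor `n` (not `n − 1`).
* MSPE is the mean of squared percent errors on the 33 integer ages
  18–50; observed values of zero are rejected.
* Degenerate inputs: non-positive geometry rows, α outside (0, 1),
  unknown cohort columns and out-of-support ages/heights are rejected
  with diagnostics naming the offending row or value.

## Problem sizes

Test and acceptance runs use 20 replicates of the 600-month full-tree
course (a few seconds each), a 14-generation miniature world for
calibration unit tests, and 3-replicate common-random-number objectives
with ≤16 simplex iterations for the recovery experiment.

## Known limitations

* The adult Weibel geometry is used from birth; no airway growth.
* One microbial community with constant rates; no immune response, no
  healing, no community succession.
* Decline is near-linear in time, lacking the slow-childhood /
  fast-adult curvature of observed average FVC trajectories (see
  "Choice of α").
* `v_c` and `v_s` are weakly identifiable at monthly resolution (see
  above); sensitivity rankings at 1% perturbations reflect the
  quantization, with `T_s` dominating.
* Remodeling timing does not affect the FVC proxy under the ratchet;
  it matters only for bookkeeping of irreversibility.
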