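# Methods

This note documents the models, the numerical choices, and the design
decisions behind `cgmgp`, in the spirit of the methods documentation of
simulation packages such as msprime or statsmodels.

## 1. The growth model

### Model structure

The simulator is a sink-driven model of sorghum vegetative growth in the
Ecomeristem tradition: the plant is a set of axes (main stem plus
tillers), each axis a sequence of phytomers (leaf blade + internode)
whose development is clocked in thermal time. All rates are driven by
degree-days above a base temperature, `tt = max(0, tmean - tbase)`.

Per day the model:

1. advances thermal time and processes phenology — phytomer initiation
   every plastochron (`plasto_init` °Cd), leaf `r` appears on an axis
   when axis thermal age reaches `r * phyllo_init`, and ligulates
   `ligulo_init` °Cd after appearance;
2. pre-dimensions newly appearing organs: potential blade length is
   `first_leaf_length + mgr_init * (rank - 1) * min(1, IC)` (the
   competition index caps the rank increment — a stressed plant makes
   smaller leaves, a surplus does not make bigger ones), blade area
   follows a fixed allometry (`area = shape * L * W`, `W = 0.1 L`), and
   blade dry mass is area over the rank's specific leaf area,
   `SLA(rank) = sla_first * (1 - slap)^(rank-1)`. The internode is
   pre-sized as `ll_to_il` times its blade length, with cylinder-volume
   times tissue-density dry mass, and grows over `3 * ligulo_init` °Cd
   from the ligulation of its leaf;
3. computes organ demand — each growing organ demands its potential mass
   times the fraction of its thermal growth window elapsed today;
4. computes supply — Beer–Lambert light interception
   `epsib * rad * ground_area * (1 - exp(-k * LAI))`, plus a seed-reserve
   flux during the first `heterotrophic_days` days (without it the model
   deadlocks: zero leaf area means zero interception means zero growth);
5. scales all organ growth by `min(1, IC_day)` where
   `IC_day = supply / demand` — growth slows when carbon supply is
   insufficient, and surplus supply is discarded (no reserve pool);
6. emits tillers: mainstem tiller sites sit on the plastochron clock —
   site `r` (for `r >= tiller_first_rank`) opens at thermal time
   `r * plasto_init + phyllo_init`, one "plastochron + phyllochron"
   cycle after its phytomer's initiation — and a tiller emerges iff the
   IC over a trailing window of about one phyllochron of days exceeds
   the genotypic threshold `ict` (a missed window stays empty). This is
   also what gives the plastochron an observable role: leaf appearance
   runs on the phyllochron alone. Tiller organs are scaled by
   `tiller_size_factor`; tillers do not themselves tiller.

All internal bookkeeping is in grams of dry mass; reported biomass
traits are fresh weight through a constant dry-matter content `dmc`.
The seed reserve is booked on the main stem so aboveground fresh weight
decomposes exactly into mainstem plus tillers.

The daily output traits are aboveground fresh weight (Biomaerofw, g),
plant leaf area (PLA, mm²), plant height (PHT, mm; ligulated mainstem
internode lengths plus the last ligulated blade as a sheath proxy, with
a non-shrinking ratchet), appeared and ligulated mainstem leaf counts
(App, Lig), tiller count (Tillernb), and at harvest the mainstem fresh
weight (Mainstemfw) and the area of the last ligulated mainstem leaf
(Arealfel).

### Genotypic parameters

| name | meaning | unit | interval |
|---|---|---|---|
| epsib | light conversion coefficient | g MJ⁻¹ | [3, 8] |
| plasto_init | plastochron | °Cd | [25, 45] |
| phyllo_init | phyllochron | °Cd | [25, 45] |
| ligulo_init | ligulochron | °Cd | [25, 45] |
| ict | IC threshold enabling tillering | – | [0.5, 2.5] |
| mgr_init | meristem growth rate | mm rank⁻¹ | [6, 14] |
| ll_to_il | internode/leaf length ratio | – | [0.1, 0.2] |
| slap | SLA decrease rate per rank | rank⁻¹ | [0, 0.1] |

The chrone parameters are held constant at their initial values (a full
Ecomeristem lets them drift with plant age; out of scope here).

### Functional constants

The narrative description of this model family leaves the
light-interception law, the leaf allometry, internode geometry, plant
height composition, and the tillering site map unspecified; they are
fixed as package constants with agronomically conventional values:
`tbase = 11` °C (standard sorghum base temperature), `k_light = 0.5`,
`ground_area = 0.08` m² (0.4 m × 0.2 m spacing), first leaf 100 mm,
blade width/length 0.1 and shape factor 0.72, `sla_first = 30000`
mm² g⁻¹, `dmc = 0.15`, internode diameter 8 mm and dry density
1.5·10⁻⁴ g mm⁻³, seed reserve 0.2 g released over 3 days, first tiller
site at mainstem rank 4 with size factor 0.8, maximum 25 phytomers per
axis, IC clamped to [0, 5]. With mid-interval parameters and 10 MJ m⁻²
day⁻¹ these give a 45-day plant of roughly 50–150 g fresh weight,
15–20 mainstem leaves and 0–15 tillers — the magnitude of a young
sorghum plant in a greenhouse.

Degenerate inputs: zero radiation keeps total biomass constant at the
seed-derived fresh weight; empty weather, NaN weather, or negative
radiation raise; out-of-bounds parameters are clamped with a warning
(or rejected under `strict=True`).

Whether tiller emission should test the IC over the window *preceding*
or *following* the appearance event is ambiguous in the model
narrative; the preceding window is used (the state of the plant is what
licenses the bud to grow out).

## 2. Calibration

Parameters are recovered per genotype by model inversion: minimize the
mean over traits of the replicate-mean NRMSE,
`NRMSE = sqrt(mean(((y - yhat)/y)^2))`, over matched time points of the
seven calibration traits (App, Lig, Tillernb, Biomaerofw, PHT,
Mainstemfw, Arealfel). Zero-valued observations (e.g. early tiller
counts) are dropped from the relative-error sums, which would otherwise
divide by zero. Harvest traits contribute a single point; the
aggregation is an unweighted mean (traits), of means (replicates).

The optimizer is Differential Evolution, strategy rand/1/bin: mutation
`v = a + F (b - c)` over distinct members, binomial crossover with one
forced coordinate, reflection of out-of-box candidates, greedy
selection. Defaults: `NP = 10·dim = 80`, `F = 0.8`, `CR = 0.5` (a low crossover rate suits this
partially separable objective — a high CR collapses the population into
local basins), 10 000
generations ("iterations" is read as generations), all configurable;
tests and the acceptance script run reduced budgets (NP 16–40, a few
hundred to 2 000 generations, early stop once the objective falls below
a tolerance).

Identifiability: the objective surface is rugged (weekly integer count
traits make it piecewise constant in the clock parameters) and carries
genuine compensations — a higher `epsib` with a higher `ict` (fewer
tillers) leaves trajectories nearly unchanged, so local minima within
~0.5 % trajectory error of the truth exist with `epsib` off by ~8 %.
A high crossover rate parks the population in such basins; with
CR = 0.5 the search reliably reaches the global basin on noise-free
self-generated data, recovering `mgr_init` sharply and `epsib` within
a few percent. Clock parameters remain the softest direction at weekly
observation cadence; `plasto_init` is observable only through tiller
timing. Recovery tests assert functional recovery (objective near
zero) plus `epsib`; exact equality of the full vector is not claimed.

## 3. Genomic-prediction engines

All engines share one contract: fit on an n × p {-1, 0, 1} marker
matrix and an n-vector (or n × m matrix) of targets, predict on new
genotypes with the same p; predictions are finite and on the original
target scale.

**LASSO** — `(1/2n)·RSS + λ‖β‖₁` with unpenalized intercept and
internally standardized markers, λ chosen by inner 5-fold CV
(minimum-MSE) over a 100-point log path from
`λ_max = max_j |x_jᵀ(y - ȳ)|/n` down four decades. Coordinate descent
is scikit-learn's (`Lasso`/`LassoCV`), which optimizes exactly this
objective; λ = 0 falls back to least squares. The test suite verifies
the soft-threshold closed form on orthonormal designs, the all-zero
solution at λ ≥ λ_max, and KKT residuals on CV fits.

**Bayes C** — `y = μ + Σ z_k a_k δ_k + e` with `P(δ_k = 1) = 1 - π`,
one *common* slab variance σ²ₐ for all SNPs, scaled-inverse-χ² priors
(ν = 4) on σ²ₐ and σ²ₑ with scales set from a 50/50 prior split of
var(y), flat prior on μ. Each (δ_k, a_k) is updated jointly from the
marginalized full conditional. π defaults to 0.99 and is an input (an
optional Beta–Bernoulli update gives the Cπ variant). The polygenic
term of the general model is omitted (no pedigree). Prediction is the
posterior-mean genomic value; the stored intercept is the
Rao-Blackwellized conditional mean `E[μ | rest]` per kept sample, so
the empty model (π = 1) returns the training mean exactly rather than
with Monte-Carlo noise. Chain defaults 12 000/2 000/10
(iterations/burn-in/thin); the per-SNP sweep is numba-compiled and the
chain is reproducible given the seed.

**CNN** — five 1-D convolutions (kernels 11, 11, 9, 13, 9; strides 1,
3, 5, 5, 5; 'same' padding, so feature lengths follow ceil(L/s)),
flatten, dense 32, sigmoid output of size m. Written directly in numpy
(hand-derived backward passes, Adam). Hidden activations are ReLU with
a switch to an alternating ReLU/softmax scheme; channel widths default
to (16, 32, 32, 64, 64) — these, like the learning rate (10⁻³), batch
size (16), epochs (200) and early stopping (10 % validation split,
patience 20), are not dictated by the model family and are fixed here
for reproducibility. The loss is the NRMSE of targets affinely scaled
to [0, 1] (the sigmoid's range) with an ε = 10⁻⁶ guard against zero
targets; growth-model parameters are scaled by their admissible
intervals (genotype-independent), the direct trait by training-fold
min/max.

## 4. Evaluation protocol

One random fold assignment (k = 5, sizes differing by at most one,
md5-checksummed) is shared by every engine and both scenarios. The
direct scenario regresses the integrative trait on markers; the CGM-GP
scenario regresses the 8 parameters on markers (jointly for the CNN,
per-parameter for the linear engines), clamps held-out predictions to
the admissible intervals, and simulates each held-out genotype with the
trial's weather. Metrics — NMAE and predictive ability (Pearson r) —
are computed on predictions pooled across folds (per-fold values are
also reported; pooling is a choice, the alternative of averaging
per-fold metrics is not used). Constant predictions make PA undefined
and are reported as an error flag. Parameter NMAEs skip exactly-zero
observed values (the `slap` interval starts at 0). Simulation failures
are recorded and excluded from metrics with a warning.

## 5. The synthetic-data generator

The generator emulates the structure of a greenhouse phenotyping study
of a sorghum diversity panel: a 45-day trial, 4 replicates, 30 °C days
and 23 °C nights (daily mean 26.5 °C plus 0.3 °C jitter), lognormal
radiation around 10 MJ m⁻² day⁻¹ (CV 0.15), and a MAF floor of 0.05
(the source filter phrase is ambiguous; it is read as a minimum-MAF
rule). The default scale is 300 genotypes × 3 000 markers so the full
pipeline runs in minutes; the motivating study's 136 × 31 713 scale is
a configuration choice.

*Genotypes*: two haplotypes per genotype; within a chromosome (10 by
default) each haplotype copies its previous-marker allele with
probability ρ = 0.9, otherwise redraws from the marker's allele
frequency — the cheapest mechanism with tunable, distance-decaying LD.
Markers violating the MAF floor are redrawn; as a last resort minor
alleles are planted by flipping.

*Parameters*: per parameter, a genetic score `g = Σ a_i x_i +
Σ e_ij x_i x_j` from additive QTL and epistatic marker pairs; the
default architecture draws 30 additive QTL with N(0, 1) effects and 5
epistatic *adjacent* pairs (LD-local interactions are the biologically
common case, and adjacency is what a 1-D convolution can see) with
N(0, 0.5) effects, and a target h² drawn from [0.5, 0.9]. Environmental
noise is decorrelated from g and rescaled so the sample
`var(g)/var(g+e)` hits the target h² exactly, then the score is min-max
mapped into the parameter's admissible interval (the simulator never
sees out-of-range values; the price is that the mapping is
population-dependent). A "strongly epistatic" architecture is the same
with no additive terms and 25 pairs.

*Trials*: the growth model is run once per genotype; every measurement
point of every replicate gets independent multiplicative lognormal
noise with CV 0.1 (unbiased: the factor has mean 1). Cadence follows
the emulated platform: daily for Biomaerofw/PLA/PHT, weekly for
App/Lig/Tillernb, harvest-only for Mainstemfw/Arealfel. The "observed"
integrative trait of a genotype is the noisy replicate mean of
final-day Biomaerofw — a stand-in for the spatial-model BLUP an actual
platform analysis would produce.

What the generator does **not** emulate: genotyping error and
missingness, pedigree/family structure, spatial greenhouse trends,
model misspecification (the trial is produced by the same simulator
that the CGM-GP scenario uses — so passing tests show the pipeline's
machinery is correct and that decomposing the trait helps *when the
growth model is right*, not that it would survive a wrong model), and
any water-deficit treatment arm (only the well-watered regime exists).

## 6. Heritability

VanRaden method-1 GRM (`G = ZZᵀ / 2Σp_j(1-p_j)`, dosages centered by
twice the allele frequency; monomorphic markers rejected by name), then
single-kernel REML for `y = μ + g + e`, `g ~ N(0, G σ²_g)`: one
eigendecomposition reduces the profile REML to a 1-D function of
h² ∈ [0, 1], maximized by a 101-point grid plus root-finding on the
analytic score (the derivative is far better conditioned than
comparing near-equal likelihoods on the flat top, and makes the
estimate exactly invariant to affine rescaling of the phenotype, which
is also standardized internally). Intercept-only fixed effects.

## 7. Problem sizes used by tests and the acceptance script

The package defaults define the full study conditions; the test suite
and `scripts/acceptance.py` exercise them at desk scale, chosen once as
the package's own reproducibility budget: the end-to-end comparisons
run 240 genotypes × 960 markers (10 chromosomes, all other generator
settings at their defaults) with reduced engine budgets — CNN channels
(8, 16, 16, 32, 32), 60 epochs, batch 16, learning rate 3·10⁻³;
Bayes C chains 1 500/500/5 — held in
`cgmgp.pipeline.DESK_ENGINE_SETTINGS`. Heritability-recovery
experiments use 300 × 1 000; Bayes C effect recovery 300 × 500;
calibration recovery a single genotype with reduced DE budgets.
Stochastic claims (the CGM-GP advantage, the CNN-vs-LASSO epistasis
comparison, h² recovery) are asserted as medians or majorities over 5–10
seeded replicates at these scales.

## 8. Known limitations

- The simulator is a deliberate simplification: no reproductive phase,
  senescence, water balance, leaf-level photosynthesis, higher-order
  tillering, or age-drifting chrones; no numeric correspondence with
  any C++ Ecomeristem build is claimed.
- Relative-error metrics (NRMSE/NMAE) are undefined at zero
  observations; the package drops such points, which slightly biases
  errors for traits with many zeros (early tiller counts, `slap` at its
  lower bound).
- DE calibration guarantees functional recovery only; parameter-level
  identifiability from the seven calibration traits is partial (see
  §2).
- The CNN is CPU-only numpy; it is adequate for desk-scale studies but
  not a performance claim.
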