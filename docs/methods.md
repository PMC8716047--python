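# Methods

## Population model

The simulator is an overlapping-generations, individual-based model in
continuous 2-D space. State per individual: position (m), sex, age (time
steps since birth; adults are age ≥ 1), a new-migrant flag, and a
two-slot genotype (males under the Y-shredder carry one X allele plus a Y
sentinel). A time step represents one breeding cycle (~2–3 months for
island rats) and runs three phases in order — reproduction, mortality,
migration — followed by an age increment. All randomness flows from a
single `numpy.random.Generator` per run, so equal seeds give bitwise-equal
trajectories.

**Reproduction.** Each adult female selects a uniform random adult male
within her home range (a disc of radius equal to the interaction distance
R; no mate → no litter; a male may serve any number of females) and bears
a Poisson(L) litter. Offspring are placed at a uniform angle and an
exponential distance (mean = average dispersal) from the mother.
Out-of-bounds placements redraw the entire displacement ("reprising"),
never reflect or clamp.

**Mortality.** Non-migrant adults survive with the flat rate s₀. Newborns
and individuals flagged as new migrants survive with
s₀ − c·E(x,y)·C(x,y), clamped to [0, 1], where C is the summed competition
from every other individual within R (Gaussian weight exp(−d²/2σ²),
σ = R/3, truncated to 0 beyond R), E ≥ 1 is the boundary compensation, and
c is the density tuning coefficient. Drive carriers multiply their
survival probability (both flat and density-dependent forms) by the drive
fitness parameter — the cost is dominant and acts on survival only. All
survival probabilities are computed from the same population snapshot and
applied simultaneously. The optional traditional-control add-on removes
round(rate × N) individuals uniformly at random, genotype-blind, during
this phase.

**Migration.** Each adult independently migrates with probability M,
displacing by an exponential draw with mean dispersal × adult multiplier
(reprising), and is flagged; the flag is consumed (density-dependent
mortality at the new location) at the next mortality phase and then
cleared. Juveniles never migrate.

**Capacity calibration.** c is solved once per run from the stationary
point of

    N(t+1) = N(t)(1−M)s₀ + N(t)(L/2 + M)s_d,
    s_d = s₀ − c · avg_competition,

giving s_d = (1−(1−M)s₀)/(L/2+M) and c = (s₀−s_d)/avg_competition.
`average_competition` exposes the closed form 2πσ²·D·(1+L/2) (D the
expected density per m², the (1+L/2) factor counting newborns); the
calibration itself integrates the kernel over the truncated interaction
disc, i.e. multiplies by 1 − e^{−9/2} ≈ 0.989, because the simulated
kernel is cut off at R. With that choice, plus the area-ratio edge
compensation below, the default configuration equilibrates ~6% above the
nominal capacity (≈4254 on the 2 km island vs K = 4000) — the excess is an
emergent clamp effect: local density fluctuations push many newborns into
zero-survival neighborhoods, and the survivors' surplus balances at a
higher N. Parameters for which no c ≥ 0 exists (required s_d > s₀) raise a
calibration error.

**Edge compensation.** Individuals whose interaction disc leaves the
arena have fewer competitors, which would otherwise cause edge clustering;
their summed competition is scaled up to compensate for the missing area.
The default factor is the plain area ratio πR²/area(disc ∩ arena)
(exactly 2 on an edge, 4 in a corner), precomputed on a normalized
(distance-to-edge/R) grid by midpoint quadrature with a 2-D suffix sum and
interpolated bilinearly. A kernel-mass variant (ratio of truncated-
Gaussian masses, which discounts the sparsely weighted rim and corrects
less aggressively) is available via `method="kernel_mass"`. The area form
is the default because it reproduces the emergent capacity and the
suppression thresholds of reference runs; the choice only affects the
~14% of individuals within R of a boundary.

**Performance.** Competition sums and mate search are numba cell-list
kernels (grid cells of side ≥ R, 3×3 neighborhoods). Both accumulate
neighbor contributions in ascending-index order, making results bitwise
identical to an exhaustive O(N²) scan — the test suite asserts exact
equality, not approximate. A 520-step default run (~4 000 adults, ~12 000
individuals at the post-reproduction peak) takes a few seconds.

## Drive genetics

Allele codes: wild type, drive, r1 (functional resistance), r2
(disrupted resistance), Y. Homing happens in the germline at gamete
formation, independently per gamete: in a drive/wild-type heterozygote a
transmitted wild-type allele first becomes a resistance allele with
probability ρ (r1 with the relative r1 fraction, else r2), otherwise
converts to drive with probability e, otherwise stays wild type. All other
genotypes transmit Mendelianly. The female-fertility target is
haplosufficient: a female is sterile iff both alleles are drive or r2
(sterile females still occupy space, compete, and can migrate). The
viability target removes drive/r2 homozygotes at generation — they are
never placed and never compete, and they do count against the drawn litter
size. The Y-shredder biases carrier males' offspring to a fraction
0.5+0.5e female; daughters inherit the paternal X (hence the drive) plus a
random maternal X, sons a random maternal X plus Y. Resistance is not
modeled for the Y-shredder. Two documented choices where the source
material is silent: the dominant fitness cost applies to carriers of
either sex (including female Y-shredder carriers, which have no shredding
phenotype), and it multiplies both the flat and the density-dependent
survival forms.

Release converts floor(p·N) uniformly chosen individuals to drive/wild-
type heterozygotes (Y-shredder: one X allele replaced) after 20
equilibration steps and flags them like new migrants, so they face
density-dependent mortality immediately. The measured capacity is the mean
population over the 10 steps strictly before release; elimination requires
N = 0 (single-sex remnants are left to decay under flat mortality); the
elimination step counts post-release steps, so the composite statistic
1 − t/500 uses the post-release budget as its denominator.

## Validation statistics

`age_summary` tabulates censuses taken after the mortality phase (newborn
survivors appear at age 0), giving the mean age over all individual-step
observations, the adult life expectancy (mean age at death among
individuals born after the census start that survived their first step),
and the fraction at or below a given age. Ripley's K uses a KD-tree pair
search with translation edge correction (switchable to none; the paper
leaves the correction unstated), L = √(K/π), and reports L(r) − r;
negative values mean the population is more dispersed than complete
spatial randomness, which the equilibrated model shows below ~100 m (the
competition radius is 75 m).

## Gaussian-process meta-model

An exact GP with a Matérn ν = 0.5 kernel — covariance
σ_f²·exp(−√(Σ_k (Δx_k/l_k)²)) with per-dimension (ARD) lengthscales —
plus learned homoscedastic noise; the non-smooth kernel suits the
near-discontinuous success/failure transitions of the outcome space.
Inputs are normalized to the unit hypercube via the per-drive parameter
bounds (11 dims, or 13 with the resistance parameters; fitness/efficiency
lower bounds 0.5 for homing drives without resistance, else 0.75); outputs
are standardized for training and de-standardized on prediction.
Hyperparameters are optimized by Adam (default rate 0.05) on the log
marginal likelihood; every `checkpoint_every` iterations the interim model
is scored on a held-out validation set and the best checkpoint is
returned. The validation metric defaults to RMSE and is switchable to F1,
since the reference procedure names only "the model that performed best".
Defaults (30 000 iterations, checkpoints every 1 000) match the reference
procedure; tests and examples run hundreds of iterations on hundreds of
points, which suffices for the fixture surfaces.

Predictions return the mean and the 95% CI width of the latent function.
Adaptive sampling selects candidates without replacement with probability
proportional to the CI width w (uncertainty rule) or to w·(1−|v|) for the
composite output — zero at certain success/failure v = ±1 — and
w·(1−2|v−0.5|) for the suppression-rate output, which mirrors that
behavior by vanishing at v ∈ {0, 1} and peaking at the most outcome-
uncertain prediction 0.5. All-zero weights fall back to uniform. The
training loop grows the set from `initial_n` to `final_n` in batches
(default split: 1/9 of the adaptive budget by the uncertainty rule, the
rest by the boundary rule; half of each batch chosen by the composite
model and half by the suppression-rate model) and logs a manifest of every
batch. Candidate pools default to 10⁵ points at desk scale (the reference
procedure used 10⁷).

Accuracy metrics follow the reference definitions: composite predictions
are mapped affinely from [−1, 1] to [0, 1] before RMSE against observed
suppression rates; a point is an actual positive at observed rate ≥ 0.5,
a predicted positive at prediction ≥ 0.5 (suppression model) or ≥ 0
(composite model); precision is undefined (None) with no predicted
positives.

## Sobol sensitivity analysis

Saltelli's scheme: a scrambled Sobol sequence in 2d dimensions split into
base matrices A and B plus cross matrices AB_i/BA_i, n(2d+2) rows total.
Estimators: Saltelli-2010 first order, Jansen total order, and the
standard second-order extension; variance is taken over the pooled A/B
evaluations, and confidence intervals come from bootstrap resampling of
sample rows (default 100 resamples — the reference procedure does not
state its resample count). Desk-scale default n = 2¹⁴ (the reference
analyses used 10⁶); the Ishigami benchmark recovers closed-form indices to
±0.005 at that size. Fixed-parameter analyses freeze dimensions and reduce
d. Power-of-two n avoids scipy's Sobol balance warning.

## Fixtures

`ThresholdSurrogate` is a deterministic stand-in for the simulator's
outcome surface: success iff every active coordinate exceeds its
threshold, with a steep sigmoid suppression output and a wider tanh
composite output, optional binomial noise emulating 20-replicate
averaging, and an analytic success volume. It emulates only the shape of
the outcome space — mostly binary, with abrupt transitions — not any
spatial dynamics, so surrogate tests passing on it demonstrate the
machinery, not simulator fidelity. `ishigami` is the standard Sobol
benchmark with closed-form indices.

## What the tests show, and known limitations

The no-drive model reproduces reference demography closely (emergent
capacity 4254 vs ≈4257 reported; mean age 4.59 vs 4.6; adult life
expectancy 5.90 vs 5.6; 92.5% vs ~90% of the population aged ≤ 12 steps;
negative Ripley deviation below 100 m), and the elimination-time scale of
all three drives matches reference values for the slower drives
(viability target and Y-shredder within a few percent). The suppression
response curves, however, sit about half to one percentage point of drive
efficiency above the reference ones: the female-fertility transition here
spans ~85–87% efficiency rather than 84–87%, so success *rates* sampled
exactly at a reference threshold (e.g. the Y-shredder at 99% efficiency)
can be substantially lower than reported even though the curve shape and
times match. Within-rule variants that were tested and rejected (event
order, edge-compensation form, calibration integral, kernel form) did not
close this residual; it most likely reflects unavailable implementation
details of the original simulation engine's interaction and mate-drawing
machinery. Near such sharp thresholds, a sub-percent model difference
moves replicate success rates by tens of points — results quoted at a
threshold should always be read together with the full efficiency
response curve.

Deliberate simplifications: homogeneous landscape, condition-blind
migration, no seasonality, no cap on male matings, no embryo/maternal
Cas9 activity, no multiplexed gRNAs, and only the eliminated/not-eliminated
dichotomy is scored (chasing vs equilibrium failure modes are not
classified). Desk-scale defaults throughout are downscaled (test-suite GP
budgets, sensitivity n, candidate pools); the full-scale settings are
plain arguments.
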