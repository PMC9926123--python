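# Methods

This note documents the models, scoring rules, numerical choices and
known limitations of the pipeline. The package analyzes a multidimensional
behavioral-phenotyping study: two rat genotypes (a control, `wildtype`,
and a brain-serotonin-depleted line, `knockout`) are profiled both in
classical operant/behavioral tests and in a semi-naturalistic group home
cage (a visible burrow system, VBS) instrumented with a 32-detector RFID
grid and scored with a dyadic ethogram. Per-animal scores are assembled
into a 16-variable profile and an unsupervised stage (random forest +
k-means on Gini importances, PCA) identifies which variables separate the
genotypes.

## Study layout and synthetic data

The synthetic generator (`vbsphenotyper.sim`) reproduces the study
design the analysis assumes: 8 wildtype and 5 knockout groups of 6
same-genotype animals, 4 days of VBS housing with 12-h dark/light
phases, the first 4 h of each phase scored for behavior; operant and
classical tests for every animal. A master seed expands into one child
RNG per (component, group) via `numpy.random.SeedSequence(...).spawn`
in a fixed order, so studies are byte-identical under the same config
and seed, and components are statistically independent.

**Movement.** Each animal walks the detector grid as a discrete-time
Markov chain at 1-s resolution with self-transitions. It is simulated
through its embedded jump chain: the dwell at a detector is geometric
with the animal's mean dwell time (equivalently, the 1-Hz self-loop
probability), and a jump goes to an adjacent detector with probability
proportional to the animal's preference weight for that zone. This is
statistically identical to stepping the 1-Hz chain and about two orders
of magnitude cheaper. Genotype enters through the zone-preference
weights (knockout: burrow/tunnel-biased, feeder/water-avoiding) and the
mean dwell (knockout 20 s vs wildtype 40 s, i.e. hyperactive), which
reproduce the roaming-entropy, activity, place-preference and open-area
contrasts downstream. Light phases multiply dwells by 2.5 (rest).
Per-animal idiosyncrasy: log-normal jitter on preference weights
(sd 0.2) and dwell tempo (sd 0.15).

**Ethogram events.** Within each scored 4-h window the number of events
per grouped behavior category is Poisson with the configured per-animal
rate times group size; initiators are drawn by actor propensity and
receivers uniformly among cage mates. For aggressive and sexual
behaviors one animal per group (the despot) carries a higher initiator
propensity (weight 6 in wildtype, 3 in knockout — a weaker despot makes
knockout hierarchies less stable). Default rates are chosen to be
realistic for group-housed rats and to reproduce the reported contrast
*directions* (knockout: more aggression, sniffing, sexual and defensive
behavior; less huddling, feeding and self-care) with home-cage effect
sizes around Cohen's d = 2; absolute per-phase magnitudes are not
reported in the literature the pipeline targets, so counts are
calibrated only for direction and separability, not absolute level.

**Operant records.** Gambling-task animals carry a latent
decision-maker type drawn from the mixture 0.74/0.09/0.17 (GDM/INT/PDM)
in both genotypes; the probability of an advantageous choice ramps
linearly from 0.5 to the type's asymptote (0.92/0.50/0.10, ±0.03
animal jitter) over the first 20 min. Penalty time-outs follow the task
contingencies (222/444 s with probability 1/2 and 1/4 on disadvantageous
choices; 6/12 s on advantageous). Discounting preferences come from a
hyperbolic value rule — V = A/(1 + kD) over delay, V = A/(1 + h·odds)
over odds = 1/P − 1 — passed through a logistic choice rule
(temperature 0.8); the defaults k = 0.2 /s and h = 1 put the
large-vs-small indifference point at a 20-s delay and at P = 0.2, the
anchors the task literature reports. Training/criterion sessions are
emitted as already passed (training logic is out of scope). All
cognitive parameters are identical across genotypes (null effects, d = 0),
mirroring the finding the discrimination stage is meant to recover: the
home cage separates the genotypes, the classical tests do not.

**Physiology and classical tests.** Pre/post body weight
(wildtype −5 ± 3 g; knockout −25 ± 5 g) and fecal corticosterone
(multipliers 1.1 ± 0.25 vs 3.0 ± 0.6 on a 2.0 ± 0.4 µg/g baseline)
carry the large physiology effects. Social recognition, odor and
dark-light-box records are generated with genotype-neutral parameters.

## Scoring rules

**Roaming entropy (RE).** Detection streams are dwell intervals; slicing
into 1-s detections weighs longer stays proportionally. For occupancy
frequencies p over k detectors, RE = −Σ p ln p / ln k ∈ [0, 1]
(0·ln 0 ≡ 0; natural log in numerator and denominator, i.e. the standard
normalized Shannon entropy — the base cancels). Daily RE uses the dark
phase of each of the first four days; *total* RE pools the detections of
those four dark phases (not the mean of daily REs; both are exposed).
The distance index sums Euclidean distances between consecutive distinct
detector coordinates (arbitrary units), per hour aligned to phase start
or in total. Place-preference maps average per-animal percent profiles
within genotype, so each genotype map sums to 100 and the difference map
to 0.

**Social networks.** Dyadic counts per grouped category form weighted
directed 6-node networks. Density, average path length (mean unweighted
shortest-path length over reachable ordered pairs; missing when none)
and Freeman out-degree centralization Σ(max − deg)/(n−1)² use binary tie
existence — density is a proportion of possible ties, so weights define
existence only. Per-node: in/out-degree, betweenness and closeness on
the directed unweighted graph (closeness of v: (r/(n−1))·(r/Σd) over
the r nodes v reaches — unreachable pairs excluded, scaled by the
reached fraction), Bonacich power centrality c = α(I − βA)⁻¹A·1 with
β = 0.9/λ_max of the binary adjacency (positive attenuation; the
parameter is not fixed by the dominance-network literature, so it is
configurable) and α scaled so Σc² = n, and hub centrality from the
mutually reinforcing hub/authority iteration on the *weighted*
adjacency (tolerance 1e−10, ≤10⁴ iterations, max-normalized; invariant
to weight rescaling; all-zero for edgeless networks). A weighted mode
for the path-based metrics exists behind the standard networkx
machinery but is off by default: whether the original toolkit treated
weights as distances is not stated, so the unweighted reading is the
default and documented.

**Glicko hierarchy.** Every dark-phase aggressive or sexual event is a
game: initiator wins, receiver loses, one rating period per
interaction. Glickman's update runs with r₀ = 2200, RD₀ = 300, c = 15
(the convention of the PlayerRatings toolkit used in the
animal-dominance literature; configurable). Inactive animals' RD grows
as √(RD² + c²t), capped at RD₀. The maximum rating contrast is
max − min of final ratings. The dominance wording "ratings higher than
1/3 of the maximum rating contrast" is ambiguous about its baseline; the
default reads it as final rating > r₀ + contrast/3 (strict), which
yields exactly one dominant per clearly despotic group; the alternative
baseline (group minimum + contrast/3) is available via
`baseline="minimum"`. Neither is asserted as the original convention.

**Change points.** Rating trajectories are segmented by the run-length
formulation of Bayesian change-point detection: constant hazard
h = 1/50, Gaussian observations with conjugate normal-gamma unknown
mean/variance (Student-t predictives). The reported change points are
the resets of the maximum a posteriori run-length *path* (max-product
recursion, backtracked from the last observation) — more stable than
the filtered run-length mode, whose transient jitter near a true change
produces spurious extra points. The scale prior is set from the MAD of
first differences and the new-regime mean restarts at the current
observation, making detection invariant to additive shifts; an exactly
constant trajectory short-circuits to zero change points. The restart
prior is weakly informative (κ₀ = 0.05, α₀ = 0.3 — near-diffuse mean,
heavy-tailed scale); these defaults were stress-tested on step
trajectories (a 200-point step of 200 units, noise sd 1, is recovered
as exactly one change point within ±3 of the true index in ≈99% of
seeds, and agrees with an offline least-squares single-break fit).
Hierarchy instability is the change-point count divided by the group's
total interactions. Absolute change-point counts depend on these
defaults and are not comparable across different CPD parameterizations.

**Blanchard dominance score.** Within a group of 6, animals are ranked
1–6 on open-area time (more → higher) and on weight loss (less → higher:
losing weight is the submissive outcome); ties get mean ranks; the score
is the mean of the two ranks, so a complete group always averages 3.5.
Wound counts, part of the original scale, are not included (too sporadic
to rank).

**Task scores.** Gambling: advantageous % per wall-clock 10-min bin;
the last-20-min percentage classifies GDM (> 70), PDM (< 30), INT
(otherwise) — strict inequalities, boundary values fall in the middle
class. Flexibility: % of last-20-min reversal choices on the side of
the formerly non-preferred options (> 60 flexible, < 40 inflexible).
Discounting AUC: per-level preference (mean of the two stable sessions)
normalized to training preference, x = delay/max-delay or
odds/max-odds, trapezoidal rule; when no measured level sits at x = 0
the curve is anchored there at the training level (y = 1). The anchor
and quadrature are package choices (the normalization sources do not
fix them); an unanchored variant is a one-line change on the returned
curve. FIEXT: the first FI of the session and the first FI after the
first EXT are excluded (12 of 14 analyzed); FI pokes binned at 10 s,
EXT pokes at 1 min (5 bins). Dark-light box: composite = first dark
visit duration (s) + number of risk assessments + total dark time (s),
units mixed as printed in the source scale; the risk-taking index is
the cohort maximum minus the composite (reference configurable).
Physiology: loss = before − after (positive = loss);
% variation = 100·(after − before)/before.

## Discrimination stage

The 16-variable table (Sexual, Weight %, Corticosterone %, Distance,
Entropy, Defensive, Maintenance, Aggressive, Pref.open area,
Affiliative, AUC.DDT, HUB.agg, Flexibility, RGT, Latency RGT,
Blanchard) must be complete; assembly fails naming the first missing
(animal, column). Random-forest discrimination: per seeded run, LOO
accuracy (one refit per held-out animal) and the Gini importances of a
full fit; defaults 500 trees, √p feature subsampling, per-run seed =
master seed + run index (hyperparameters are not fixed by the source
analysis; these are the toolkit conventions). K-means (k = 4, 10
restarts, seeded) groups variables by their importance profiles across
runs; clusters are relabeled by decreasing mean importance so tier 0 is
the most discriminating. PCA is centered and unit-variance scaled
(the variables mix units — counts, percent, seconds — so scaling is
necessary even though the source does not state it); per-variable
contributions are squared-loading shares (each dimension sums to 100%);
group centroids and 0.95 χ² confidence ellipses are exported.

`rank_sum_W` reports the Wilcoxon rank-sum statistic in the R
convention (W = Mann-Whitney U of the first sample, from pooled
mid-ranks) with scipy's two-sided p (exact for small tie-free samples,
tie-corrected normal approximation otherwise).

## What passing tests show — and what they do not

The generator produces Poisson counts, Markov walks and parametric
task curves with independent animals (aside from shared group totals
and the despot structure). Real colony data have richer dependence:
diurnal rhythms beyond a single dwell factor, behavioral contagion,
non-stationary rates over days, RFID dropouts. Passing the recovery
tests therefore shows the *pipeline* is correct and sensitive at the
configured effect sizes; it does not validate the behavioral model
against real colonies.

One structural effect is worth recording. With genotype assigned at the
housing-group level, leave-one-out random-forest accuracy under a true
null is systematically *below* 0.5 (≈0.40 here): the effective sample
is the number of groups, and the held-out animal's side of any chance
group-level split is underrepresented in training — the classic LOO
pessimism, amplified by clustering. On iid noise, or when labels are
permuted at the animal level (breaking the group-label alignment), LOO
accuracy is ≈0.5 and its binomial CI covers chance. The null tests
assert exactly that pair of facts: permutation null at 0.5 two-sided,
group-assigned null not *above* chance, and no PCA dimension-1
separation.

## Problem sizes

Default test and acceptance runs use the full study design (78 animals,
13 groups, 4 days). The structure-recovery suite uses 10 simulated
studies with 2 RF runs of 100 trees each and 3 null studies; the
acceptance script uses 10 RF runs of 100 trees and 5 replicate
gambling-task cohorts at the study's cohort sizes (47/30) for the
class-proportion estimates. Increasing runs/trees changes the Gini
boxplot resolution, not the conclusions.

## Known limitations

- The dominance-threshold baseline and the CPD parameters are
  documented choices, not reproductions of the original toolkits;
  quantities that depend on them (dominant counts, absolute change-point
  counts) are comparable within this package only.
- Closeness centrality uses the reached-fraction-scaled convention;
  toolkits differ on disconnected digraphs.
- The simulator emits already-stable discounting sessions and omits
  operant acquisition; training-phase analyses are out of scope.
- Event durations are generated but unused by the occurrence-based
  counts (the source analysis reports occurrences); duration-weighted
  counting would be a small extension.
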