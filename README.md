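# adaptgeom

Geometric modelling of athletic training adaptation from routine monitoring
data, for sport scientists and coaches tracking small squads (swimming in
particular) across a season.

## The problem and the model

A season of monitoring produces, per athlete and week, a pair of load/recovery
coordinates and — on the sparse weeks with a competition — a performance
outcome. Performance is scored as the **percentage of personal best time**,

    %PBT = (previous personal best time / achieved time)² × 100,

and thresholded at 100 into a binary label *b* = sign of improvement:
+1 **adaptation** (a new personal best), −1 **maladaptation**. Each
competition week then contributes a labelled point
(X(tᵢ), Y(tᵢ), b(Z(tᵢ))) in the unit square, where X and Y are weekly
metric averages normalised by their season maximum. Five metric
combinations are supported: (1) distance / session-RPE, (2) session-RPE /
recovery, (3) training strain / recovery, (4) training monotony / recovery,
(5) distance / acute:chronic workload ratio — computed from CR-10
session-RPE logs, 7-point wellness questionnaires and the training calendar.

The classifier is constructed geometrically rather than trained: within each
label class, points are clustered by average-linkage agglomeration under
three dissimilarities (Bray–Curtis, Chebyshev, normalised squared Euclidean)
with the cluster count chosen by the Calinski–Harabasz criterion, and the
sparsest of the three solutions is kept. Each cluster is convexified into
its *domain of influence*; every point of the unit square takes the label of
the nearest hull, the domains are disconnected by a thin neutral layer of
width ε along the frontier, and the separating boundary is the zero contour
of the signed nearest-hull distance field. The map is summarised by the
**Geometric Activity Performance Index**

    GAPI = area(Ω⁺) / area(Ω⁻),

the ratio of the adaptation region Ω⁺ to the maladaptation region Ω⁻, with
goodness of fit the percentage of competition weeks falling in the region
matching their label. Because a season yields only 4–8 labelled weeks,
results are stabilised by **jittering** (Gaussian noise, SD = 10% of each
raw series' SD, superimposed before normalisation) and a 50-replicate
ensemble combined by simple averaging. Association between per-athlete GAPI
and performance is assessed nonparametrically (Spearman rank and
Blomqvist β with exact small-sample p-values) under step-down Holm
correction, and Welch's t-test serves the group comparison.

A synthetic-cohort generator produces full seasons with a controllable
latent rule linking the load coordinates to improvement, including the
rule's closed-form true area ratio, so the whole pipeline is testable
end to end without any real athlete data.

## Worked example

```python
from adaptgeom import (CohortConfig, GroundTruthRule, JitterConfig,
                       run_ensemble, simulate_athlete)

rule = GroundTruthRule("halfplane", (-1.0, -1.0, 1.0))   # adapt iff x + y < 1
athlete = simulate_athlete(CohortConfig(seed=7, rule=rule), 3)
ens = run_ensemble(athlete, combo=1,
                   config=JitterConfig(noise_level=0.10, replicates=50, seed=7))
print(f"mean GAPI  = {ens.mean_gapi:.3f}  (sd {ens.gapi_sd:.3f})")
print(f"mean GOF   = {ens.mean_gof:.1f} %")
```

prints

```
mean GAPI  = 1.557  (sd 0.263)
mean GOF   = 100.0 %
```

Every jittered replicate classifies all of this athlete's competition weeks
correctly (goodness of fit 100%), and the adaptation region is on average
1.56× the size of the maladaptation region — a season spent mostly on the
favourable side of the latent rule. The ensemble SD (0.26) is the spread
induced by the 10% jitter, i.e. the fragility of the map under measurement
noise.

The same pipeline is scriptable from the shell:

```sh
adaptgeom simulate --out data/ --seed 7 --athletes 20 --rule halfplane:-1,-1,1
adaptgeom fit --data data/ --out fits/ --combo 1 --seed 7
adaptgeom correlate --reports fits/ --out grid.csv
```

`fit` writes one JSON report and one region-map SVG per included athlete
(athletes failing the inclusion prerequisites are listed with reasons in
`skipped.json`); `correlate` produces the tidy Spearman/Blomqvist ×
(quartile, best %PBT) grid with Holm-adjusted p-values.

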