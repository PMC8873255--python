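# navtrace

Digital navigation biomarkers from outdoor GPS traces.

Impaired spatial navigation is among the earliest consequences of
Alzheimer's-type neurodegeneration, but it is usually measured with
desk-based proxy tasks. `navtrace` implements an analysis of *real-world*
navigation: given two weeks of body-worn GPS logging per participant, it
extracts **return-loop segments** — sub-trajectories that start and end
within a 10 m slack radius, last 1–20 min, and cover ≥ 100 m — and
derives from them the feature families that separate patients from
controls:

- **mobility domain** (on a 100 m grid): segment entropy
  H = −Σ_c P(c) ln P(c) over pooled cell visits; per-segment similarity
  fractions (share of other segments with cell-set Jaccard > 0.5);
  distance from the estimated home (centroid of daily first/last fixes);
- **spatial shape**: segment complexity (count of points where the mean
  of first- and second-order turning-angle magnitudes exceeds 120°),
  total turning angle Σᵢ sin θ¹ᵢ, radius of gyration;
- **temporal**: durations and counts of stops (≥ 60 s within a 10 m
  radius);
- **mobility-graph topology**: grid cells dwelt ≥ 5 min as nodes,
  observed transitions as edges, transit cells removed with their
  neighbours re-cliqued; closeness, betweenness and degree centrality.

Groups are compared by pooling per-segment values and applying the
two-sample Kolmogorov–Smirnov test plus Cohen's d. Two supervised tasks
follow: patient-vs-control logistic regression trained by stochastic
gradient descent (10,000 steps, random initialisation), evaluated
leave-one-participant-out and repeated 50 times so that the spread of
the held-out class probabilities measures prediction uncertainty — with
sensitivity/specificity defined on predicted-class denominators — and
alone-vs-accompanied classification of individual patient segments with
an RBF-kernel SVM on repeated 80/20 splits.

Because cohort GPS data of this kind cannot be shared, the package
includes a seeded synthetic cohort generator (`navtrace.synth`) that
reproduces the study's structure — home-anchored round trips, persistent
destinations with Zipf-weighted revisits, route reuse, AR(1) GPS error,
3 s / 5 s sampling — with configurable group contrasts, down to a
zero-contrast twin for null calibration. See `docs/methods.md` for the
full model description and design rationale.

## Worked example

```python
from navtrace import CohortConfig, RunConfig, generate_cohort, analyze_cohort, loo_classify
from navtrace.pipeline import spatiotemporal_comparison

cohort = generate_cohort(CohortConfig(n_controls=6, n_patients=6, days=7, master_seed=0))
res = analyze_cohort(cohort.traces, cohort.annotations, RunConfig())

print(spatiotemporal_comparison(res).round(4).to_string(index=False))
loo = loo_classify(res.spatiotemporal,
                   ["segment_similarity", "entropy", "distance_from_home"],
                   runs=50, seed=0)
print(f"LOO median sensitivity {loo.median_sensitivity:.2f}, "
      f"specificity {loo.median_specificity:.2f}, "
      f"uncertainty {loo.uncertainty:.3f}")
```

prints

```
            feature  ks_statistic  p_value  cohens_d
 segment_similarity        0.8400   0.0000   -2.3203
            entropy        1.0000   0.0000    3.0616
 distance_from_home        0.2714   0.0861    0.4276
     stop_durations        0.0810   0.9735    0.0864
         complexity        0.1561   0.6584    0.2140
total_turning_angle        0.1635   0.6017    0.2756
 radius_of_gyration        0.5043   0.0000    0.5264
LOO median sensitivity 1.00, specificity 0.86, uncertainty 0.077
```

Reading this: on a small synthetic cohort the patients' segments are far
more self-similar (negative d: patients higher) and less spatially
diverse (entropy d ≈ +3: controls higher) than the controls', while stop
durations and the shape features are indistinguishable between groups —
the same pattern of strong mobility-domain contrasts and weak
alone-segment shape contrasts the method is designed around. The
classifier separates the groups with median sensitivity 1.00 and
specificity 0.86; the uncertainty value is the mean standard deviation
of each participant's 50 held-out control probabilities.

The same analysis is available from a shell:

```bash
navtrace simulate cohort/ --seed 0          # write a synthetic cohort
navtrace run-all cohort/ report/ --seed 0   # segments, features, graphs,
                                            # statistics, classification
navtrace bin-sweep cohort/ report/ --bins 5 --bins 10 --bins 20
```

`run-all` writes per-stage CSV tables (`segments.csv`,
`group_comparison_*.csv`, `loo_report.csv`, ...), a machine-readable
`summary.json`, and a snapshot of the configuration; a rerun with the
same seed is byte-identical.

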