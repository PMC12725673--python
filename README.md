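# vcclek

Reconstruction of artisanal-fishery catch and effort trends from **local
ecological knowledge (LEK)** surveys.

Many coastal artisanal fisheries have never had systematic monitoring, so
there is no time series to say how catches or fishing grounds have changed
since fishing began.  Structured interviews with the fishers themselves can
fill that gap: each fisher reports, per decade, whether their catches showed
a *major decline (MD), decline (D), stable (S), increase (I)* or *major
increase (MI)*, attaches their own percentage to that score, and draws their
fishing grounds on a map.  This package turns such interviews into
quantitative reconstructions.  It is written for quantitative fisheries
ecologists and survey teams working in data-poor settings.

## The model

**Virtual catch change (VCC).**  Catch is a dimensionless index anchored at
1 before the 1980s and updated multiplicatively once per decade for each
fisher *a*:

```
V_{k,a} = X_{k-1} + X_{k-1} · f_{k,a},        f_{k,a} = sign(Z_{k,a}) · Y_{k,a}/100
```

where `X_{k-1}` is the previous decade's virtual catch, `Z` the categorical
score (declines negative, increases positive, stable zero) and `Y` the
fisher's own percentage.  **Shifting-baseline correction:** a fisher who
started after the 1980s never saw the early abundance, so instead of
anchoring them at 1 their first `X` is the cohort mean virtual catch of the
decade preceding their entry.  Cohort trajectories are summarised as
per-decade mean ± sd, decade-over-decade relative changes
`100·(new − ref)/ref`, and a cubic least-squares trend over decade indices.

**Survey design.**  Required interviews per village follow Yamane's
finite-population formula `n = N / (1 + N·e²)` at precision `e = ±10 %`,
aggregated across conflicting population sources (mean with min/max of the
unrounded per-source sizes, rounded half-to-even).

**Spatial stage.**  Fisher-drawn polygons (WGS84, one per fisher × decade)
are rasterized on a 0.01° grid by cell-centre membership: an *effort
surface* (each polygon deposits 1; unit-normalized, cells with ≥ 60 % of
fishers are "core grounds") and an additive *VCC surface* (each polygon
deposits its VCC value; scaled sign-preservingly to [−4, 4]).  Polygon
centroids are measured to the port of origin with a WGS84 geodesic
(Vincenty), summarised as per-village and per-decade mean/median distances.

A synthetic-survey generator (`vcclek.synthetic_data`) reproduces the
statistical structure such surveys exhibit — staggered entry cohorts, score
polarity inverting from ~66 % positive (1980s) to ~89 % negative (2010s),
realistic gear shares, and decadally expanding ground-to-port distances —
with full ground truth recorded for recovery tests.

## Worked example

```python
from vcclek.synthetic_data import default_config, generate_survey
from vcclek.survey_model import filter_eligible
from vcclek.vcc_engine import build_trajectories, cohort_aggregate, relative_change

cfg = default_config()
cfg.n_villages, cfg.fishers_per_village = 5, 60
survey = generate_survey(cfg, seed=7)

retained = filter_eligible(survey.records).retained
print(f"retained {len(retained)} of {len(survey.records)} contacted fishers")

agg = cohort_aggregate(build_trajectories(retained, baseline_weighting=True))
for decade, (mean, sd, n) in agg.stats.items():
    print(f"{decade}: mean VCC {mean:.2f} (sd {sd:.2f}, n={n})")
print(f"change 2000s->2010s: "
      f"{relative_change(agg.stats['2010s'][0], agg.stats['2000s'][0]):+.1f}%")
```

prints

```
retained 240 of 300 contacted fishers
1980s: mean VCC 1.31 (sd 0.34, n=80)
1990s: mean VCC 1.48 (sd 0.61, n=129)
2000s: mean VCC 1.29 (sd 0.61, n=194)
2010s: mean VCC 0.85 (sd 0.65, n=240)
change 2000s->2010s: -34.2%
```

i.e. the classic increase–decrease parabola: perceived catches rise through
the 1990s and collapse by the 2010s; the 2010s cohort mean of 0.85 means
catches at 85 % of the pre-1980s baseline, a 34 % drop from the 2000s.

The same pipeline runs from the shell:

```
vcclek simulate --seed 7 --outdir data/
vcclek run-all --config config.json      # load → filter → VCC → spatial
```

writing trajectory/aggregate/relative-change tables (CSV), the cubic trend
fit (JSON), effort and VCC rasters (ESRI ASCII grid) and a manifest with a
SHA-256 digest of every output.

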