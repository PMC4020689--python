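# radshift

Quantitative comparison of ground-beetle (Carabidae) pitfall-trap
assemblages sampled at the same sites decades apart. Resurvey studies of
this kind ask whether species richness, abundance, and rank-abundance
structure have shifted — for example under climate warming in mountain
habitat sequences — and need a consistent statistical toolkit to answer
with: abundance standardization, richness estimation that accounts for
unequal sampling, species-abundance model comparison, and turnover indices.
`radshift` packages that toolkit for community ecologists, together with a
synthetic-data generator so every estimator can be validated against known
ground truth.

## What it computes

- **Annual activity density (aAD)** — pooled trap catches standardized to
  mean individuals per trap per 10 trapping days:
  `aAD = (count / n_traps) / (exposure_days / 10)`, making assemblages
  comparable across trap numbers and season lengths.
- **Rarefaction** — expected richness in a subsample of *m* individuals,
  E[S_m] = Σᵢ [1 − C(N−Nᵢ, m)/C(N, m)], with density rescaling for
  cross-period comparison.
- **Bootstrap richness** (Smith & van Belle) — Ŝ = S_obs + Σᵢ (1−pᵢ)ⁿ over
  incidence in n sampling units, with a percentile CI from resampling units.
- **SAD model fitting** — expected rank-abundance sequences for the broken
  stick, niche preemption (geometric), lognormal, Zipf, and Zipf–Mandelbrot
  models, fitted by Poisson maximum likelihood and compared by AIC.
- **Assemblage comparison** — Renkonen minimum percentage similarity
  PS = Σᵢ min(p_Ai, p_Bi); chord distance with minimum-variance (Ward)
  clustering; species-turnover accounting; and the **Index of
  Rank-abundance Change**:

  IRC(A, B) = Σᵢ |R_A(spᵢ) − R_B(spᵢ)| / |A ∪ B|

  the mean absolute rank shift over the species union of two samples, where
  a species absent from one sample takes rank S_present + 1 there.
- **Trait summaries** — percent activity density of high-dispersal
  (macropterous + dimorphic) and zoophytophagous species, and the species
  share of specialized predators.

## Worked example

Simulate a six-site paired resurvey (6 traps per site, three ~30-day
collections per season, assemblages drawn from a Zipf–Mandelbrot SAD with
trait-dependent turnover between periods) and run the full pipeline:

```sh
cat > demo.yaml <<EOF
out_dir: demo_out
scenario:
  n_sites: 6
  seed: 7
n_boot: 199
seed: 7
EOF
radshift run --config demo.yaml
```

This writes `report.json`, `comparison.csv`, `richness.csv`,
`sad_selection.csv`, `traits.csv` and `dendrogram.nwk` under `demo_out/`.
The per-site comparison begins:

```
site1: renkonen=0.677  irc=2.82  n_union=11  shared=8  only_before=2  only_now=1
site2: renkonen=0.336  irc=4.62  n_union=13  shared=7  only_before=5  only_now=1
```

Site 2 lost five species and kept only seven, so its similarity is low
(0.34) while its mean rank shift is high (4.6 positions per species) — the
two indices move in opposite directions, low similarity going with strong
rank reordering. The richness block reports, per period, observed species,
the bootstrap expectation with its 95% percentile interval, and coverage:

```
1980: s_obs=31  s_expected=31.0  ci=[31.0, 31.2]  coverage=100%
2009: s_obs=30  s_expected=30.1  ci=[29.0, 30.4]  coverage=100%
```

(coverage near 100% because the simulated sampling intensity detects nearly
every species present). `sad_selection.csv` lists every fitted model per
site-period with parameters, log-likelihood, AIC and the AIC-best flag.

The same stages are available individually (`radshift simulate`,
`richness`, `radfit`, `compare`, `traits`), and as library functions
(`radshift.rarefy`, `radshift.irc`, `radshift.select_sad`, ...).

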