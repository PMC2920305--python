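# livelihood-landscapes

Occupation networks from ranked household livelihood surveys.

Households in tropical coastal communities typically combine several income
activities — fishing, farming, informal trade, salaried work — and can rank
them by importance. This package turns such ranked portfolios into directed,
weighted **livelihood landscape** networks: occupations are nodes; a
household reporting occupation A above occupation B contributes a link
A → B; link weights are the fraction of households engaged in the origin
occupation that also engage in the destination occupation at a lower rank.
Because the node set is the fixed category list rather than whatever happens
to be reported, the same statistics are comparable across any level of
social aggregation, from a single village to a country.

It is aimed at researchers and practitioners in livelihoods, fisheries
governance and social-ecological systems who want systemic, quantitative
summaries of occupational diversification — and maps of it — from standard
ranked-occupation survey data.

## What it computes

For any selection of households:

- **Sectoral**: weighted in-/out-degree centrality per occupation
  (in-degree: taken on as a supplemental activity; out-degree: ranked above
  co-reported activities).
- **Systemic**: binary and weighted network density
  (links, or summed weights, over n(n−1)), and Freeman-style degree
  centralization

      C_d = Σ_v [d* − d(v)] / [(n−1)(n−2)],   d(v) = (in(v)+out(v))/2,

  equal to 1 on a perfect star and 0 on any degree-regular network
  (weighted variant: denominator × mean positive link weight), plus the
  mean number of occupations per household.
- **Gradient analysis**: per-site metric tables joined to a development
  index and log population density, with Spearman rank correlations.
- **Maps**: seeded spring-embedded drawings (node area = households
  involved, shaded pie = primary share, arrow width = link weight, links
  under the 5% weight threshold omitted) and GraphML/GML/DOT/edge-list
  exports.
- **Synthetic surveys**: a generator with controllable prevalence,
  specialization and sector coupling, so every stage is testable without
  field data.

Binary statistics follow the analysis protocol: prune links with weight
< 0.05, then binarize. Weighted statistics never prune.

## Worked example

```python
from livelihood_landscapes import (
    HouseholdRecord, build_landscape, normalize_weights, metrics_report,
)

households = [
    HouseholdRecord("h1", "shela", ("fishing", "farming", "informal")),
    HouseholdRecord("h2", "shela", ("fishing", "informal")),
    HouseholdRecord("h3", "shela", ("farming",)),
]
net = normalize_weights(build_landscape(households))
for (o, d), w in sorted(net.weights.items()):
    print(f"{o:>8} -> {d:<9} count={net.links[(o, d)]} weight={w:.2f}")
report = metrics_report(households)
for key, value in report.systemic().items():
    print(f"{key:>26} = {value:.4f}")
```

prints

```
 farming -> informal  count=1 weight=0.50
 fishing -> farming   count=1 weight=0.50
 fishing -> informal  count=2 weight=1.00
            density_binary = 0.0333
          density_weighted = 0.0222
     centralization_binary = 0.0972
   centralization_weighted = 0.1146
          mean_occupations = 2.0000
```

Household h1 links fishing → farming, fishing → informal and
farming → informal (every ordered rank pair, not just adjacent ranks).
Both households reporting fishing also report informal work at a lower
rank, so that weight is 1.00; one of the two fishing households also farms,
giving 0.50. Three links over the 90 ordered pairs of the fixed ten-category
node set give a binary density of 3/90 ≈ 0.033; the weight sum 2.0 gives
weighted density 2/90 ≈ 0.022. The low centralization values say no single
occupation acts as a hub shared by most multi-activity households.

The same pipeline is available from the shell:

```
liveland simulate --config design.yaml --seed 7 \
    --survey-out survey.csv --covariates-out sites.csv
liveland build --survey survey.csv --select site_id=g01 --out g01.graphml
liveland metrics --survey survey.csv --select site_id=g01 --out g01.json
liveland correlate --survey survey.csv --covariates sites.csv --out corr.json
liveland draw --network g01.graphml --seed 7 --out g01.svg
```

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.

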