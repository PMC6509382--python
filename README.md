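# sociospatial

Sociospatial analysis of GPS telemetry for gregarious, range-resident
animals: proximity-based social networks, kernel home-range overlap,
interannual site fidelity, a trajectory-shuffling permutation null, and
seasonal mixed-model comparisons — plus a movement simulator that plants
known social and spatial structure so the whole chain can be validated
end to end.

The package is aimed at movement ecologists who have collar data (one row
per fix: animal, herd, timestamp, projected x/y in metres) and want to ask
whether individuals *associate* beyond what their overlapping space use
already implies — the classic contrast between conspecific attraction and
resource-driven co-occurrence, typically with patchy winter versus
homogeneous summer resources.

## Methods at the core

**Rounds and chain-rule groups.** Fixes recorded within 5 min of each
other form a sampling round. Within a round, animals are grouped by the
chain rule: any chain of pairwise distances ≤ 50 m links animals into one
group, even if the chain's ends are farther apart.

**Simple ratio index.** Each dyad's association weight is

```
SRI = x / (x + y_AB + y_A + y_B)
```

where `x` counts rounds the pair was grouped, `y_AB` rounds both were
observed but separated, and `y_A`, `y_B` rounds only one was observed.
Graph strength — the sum of a node's SRI edge weights — is the
per-individual sociality index.

**Kernel home ranges and UDOI.** Each animal-season-year's utilization
distribution is a fixed bivariate-normal KDE with the reference bandwidth
`h_ref = σ·n^(−1/6)`; the home range is the 95 % isopleth. Pairwise
overlap uses the utilization distribution overlap index,
`UDOI = A₁₂ · ∫∫ UD₁·UD₂ dx dy` (0 = disjoint, 1 = identical uniform
ranges, > 1 possible for concentrated shared use). UDOI edges give a
*spatial* network, and within-animal UDOI across consecutive years of the
same season measures site fidelity.

**Permutation null.** Each animal's daily trajectories are shuffled
(dates permuted, within-day sequence kept), networks rebuilt, and
strengths recorded — 1,000 iterations by default. This keeps every
animal's space use fixed while destroying real-time coordination, so
observed-vs-null differences isolate genuine social association.

**Mixed models.** Four REML Gaussian LMMs on log-transformed responses —
site fidelity, spatial strength, social strength (observed vs null mean ×
season), and home-range area — each with season fixed and random
intercepts for year and animal nested in herd.

## Worked example

```python
import sociospatial as ss

cfg = ss.PipelineConfig(
    out_dir="demo_out", seed=7, n_iter=100,
    simulation=dict(n_herds=2, n_agents=8, n_years=2),
)
result = ss.run_pipeline(cfg)
print(result.fits["fidelity"].coefficients.round(3))
print(result.coefficient_null["season[T.winter]"])
```

The simulated study is winter-attracted (patchy landscape, conspecific
attraction, low interannual fidelity) and summer-independent. The run
above prints, for the fidelity model,

```
                  estimate     se      t      p
Intercept            0.191  3.122  0.061  0.951
season[T.winter]    -7.284  1.070 -6.807  0.000
```

i.e. winter site fidelity is far below summer, as planted. The social
strength model gives a winter effect of +2.10 with an
observed-random interaction of −0.54 (observed strengths exceed the null
only in winter), and the permutation CI check reports

```
observed 3.65, null 95 % CI (2.81, 3.13)  ->  nonrandom: True
```

so the winter season effect on observed social strength lies outside the
null coefficient distribution — winter association is not explained by
space use alone. Groups of two or more collared animals occur only in
winter networks in this run (64–91 per herd-year), mirroring the strong
seasonal contrast in gregariousness the simulator encodes.

A command-line interface mirrors the library
(`sociospatial simulate | preprocess | social-net | home-range | report |
all`), writing every stage's tables plus a manifest with parameters and
content hashes.

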