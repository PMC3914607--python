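# reefrange

Individual-based simulation of coral reef fish home-range movement and
passive acoustic telemetry, with minimum convex polygon (MCP) and
kernel-density (KD) home-range estimation.

## The problem

Passive acoustic arrays record a tagged fish only while it is within
detection range of a receiver, so home-range estimates from telemetry data
are shaped as much by array geometry, tracking duration and detection
physics as by the fish itself. `reefrange` is for movement ecologists and
marine-reserve planners who want to quantify those biases: it simulates
fish with known movement rules over a known array, computes home ranges
both from the true paths ("Sim-Actual") and from the detections the array
would have produced ("Sim-Detect"), and measures how and where the two
disagree.

## The model

A fish's routine movement within a home range is three linked behaviours,
evaluated once per 5-minute interval:

1. **Move decision** — with probability ψ the fish attempts a discernible
   move;
2. **Step length** — the distance is drawn from an exponential
   distribution with mean λ (m), clamped at 6 km per move (a 72 km/h speed
   limit) and suppressed below 200 m (the positioning resolution);
3. **Turning angle** — the direction θ is drawn from a von Mises
   distribution f(θ | θ̄, κ) = exp[κ cos(θ − θ̄)] / (2π I₀(κ)) centred on
   the bearing θ̄ from the fish's position toward its fixed home-range
   center. Larger κ means stronger site fidelity.

Positions live on a 200 m grid. The packaged parameter sets are
field-derived values for red grouper (*Epinephelus morio*: ψ = 0.80 %,
λ = 561 m, κ = 3.67), black grouper (*Mycteroperca bonaci*: 0.56 %, 456 m,
1.19) and mutton snapper (*Lutjanus analis*: 5.76 %, 608 m, 3.20).

Detection is deterministic in expectation: a receiver at distance *d*
registers (Δt / ping) · p(d) detections per interval, with a logistic
range curve p(d) and a 105 s mean ping interval. Multi-receiver detections
are batched per 5 minutes into position fixes by a two-pass
inverse-detection-probability weighted centroid. Home ranges are the 100 %
MCP (convex hull area) and the 95 % KD volume contour of a Gaussian kernel
density on a 20 m grid with a smoothed-cross-validation (SCV) bandwidth
matrix computed on binned fixes.

## Worked example

Simulate one year of red grouper on the default 32-receiver array
(one fish per receiver), estimate both home ranges both ways, and compare:

```python
import reefrange as rr

params = rr.get_species("red_grouper")
array = rr.staggered_array()          # 32 receivers, 4 x 8, 600 m spacing
res = rr.run_table2_experiment(params, array, seed=7)
print(res.summary.round(2).to_string(index=False))

bias = rr.peripheral_bias_map(res, array)
print(f"mean MCP bias: peripheral {bias['mean_bias_peripheral']:.0f}%, "
      f"core {bias['mean_bias_core']:.0f}%, t = {bias['t']:.2f}")
```

```
estimator               group  mean   sd  n   se
      MCP          Sim-Actual 18.85 3.42 32 0.60
      MCP          Sim-Detect  5.53 1.07 32 0.19
     KD95          Sim-Actual  2.52 0.59 32 0.10
     KD95          Sim-Detect  0.64 0.25 32 0.04
      MCP SimActual-SimDetect 13.32 3.30 32 0.58
     KD95 SimActual-SimDetect  1.88 0.60 32 0.11
mean MCP bias: peripheral -71%, core -69%, t = -0.78
```

Areas are km². The array-derived MCPs (5.5 km²) severely underestimate the
true path hulls (18.9 km²) because excursions beyond the array go
undetected, and the bias is (slightly) worse for fish whose home-range
centers sit on the array's convex hull — the negative t statistic is the
one-tailed core-vs-periphery contrast. The 95 % KD runs far below the MCP
here: the kernel density tracks where the fish *spends time* (dwell-
weighted fixes), while the hull is governed by the farthest excursions.

The filter analysis runs against the packaged per-fish tracking summary
(44 red grouper, 2 black grouper, 2 mutton snapper):

```sh
reefrange evaluate filters --species RG --min-days 60 \
    --min-detections 1000 --asymptote Yes --peripheral Low
```

```json
{
  "N": 12,
  "mcp_mean": 2.455833333333333,
  "mcp_se": 0.7629929686452033,
  "mcp_n_used": 12,
  "kd_mean": 0.7633333333333333,
  "kd_se": 0.36214707654557293,
  "kd_n_used": 12
}
```

Twelve of the 44 red grouper survive the most conservative filter
(tracked > 60 days, > 1000 detections, asymptotic area curve, low
peripheral effects), with a mean MCP home range of 2.46 km².

A CLI wraps the main pipelines (`reefrange simulate | detect | position |
fit | homerange | evaluate | fixtures`; see `--help`).

## Layout

| module | contents |
| --- | --- |
| `reefrange.params` | species movement-parameter sets |
| `reefrange.movement` | three-step movement kernel |
| `reefrange.world` | grid world, agents, track simulation |
| `reefrange.receivers` | array geometry, detection model, peripheral classes |
| `reefrange.positioning` | detection batching, weighted-centroid fixes |
| `reefrange.fitting` | ψ/λ/κ estimation, bootstrap sensitivity |
| `reefrange.homerange` | MCP, KD + SCV bandwidth, area curves, asymptotes |
| `reefrange.evaluation` | cohort experiments, bias maps, filter analysis |
| `reefrange.io` / `reefrange.cli` | tables, config, fixtures, CLI |

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
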