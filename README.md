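# dynexposure

Rapid assessment of **dynamic PM2.5 exposure for vehicle-based workers**
(taxi drivers are the motivating case) from three widely available inputs:

1. an **annual PM2.5 raster** (e.g. a satellite/LUR product on a 0.01°
   lon/lat grid) — high spatial, no temporal variability;
2. **hourly series from air-quality monitoring stations** — high temporal,
   no spatial variability;
3. **raw GPS trajectories** (taxi id, timestamp, position, heading,
   occupied/vacant flag).

Fixed monitors cannot follow a moving worker, and panel studies with
in-cabin sensors do not scale to a fleet.  `dynexposure` fuses the raster
and one *representative* station into a space-time concentration field,
map-matches each occupied trip to the road network, integrates exposure
along it, and summarizes the fleet by hour, day, weekday/weekend and
driver subgroup, including guideline comparisons and activity-hotspot
analysis.

## Model

**Fused field.**  Let $C_{i,j}$ be the annual raster value of cell
$(i,j)$ and $C^t_{\text{base}}$ the hourly value of the representative
station (annual value $C_{\text{base}}$ at its own cell).  The fused
concentration is additive:

$$C^t_{i,j} = C^t_{\text{base}} + \left(C_{i,j} - C_{\text{base}}\right)$$

The representative station is chosen among stations without obvious
outliers as the one minimizing the sample variance of the difference
series $D^t = C^t_{\text{station}} - C_{\text{station(annual)}}$.

**Trip exposure.**  For an occupied trip with matched path and times
$[t_\text{start}, t_\text{end}]$, the exposure integral is

$$\mathrm{EI} = \lambda \int_{t_\text{start}}^{t_\text{end}} C_e(t)\,dt
            = \lambda \sum_{\text{pieces}} C^t_{\text{grid}} \,\Delta t$$

where the trip is cut exactly at every grid-cell and clock-hour boundary,
$\Delta t$ is the time spent in each piece, and $\lambda \in (0,1]$ is the
in-cabin filtration coefficient (default 1, the open-window scenario).
The time-weighted average $\mathrm{TWA} = \mathrm{EI} / (\lambda \cdot
\text{duration})$ in μg/m³ is what summaries aggregate.

**Map matching** is a hidden-Markov-model Viterbi pass: emission
log-probability $-d^2/2\sigma^2$ from the geodesic distance $d$ between a
fix and its projection on a candidate edge, transition log-probability
$-|d_{\text{route}} - d_{\text{great circle}}|/\beta$ between consecutive
candidates.

**Hotspots** are quartic-kernel density surfaces (0.001° cells) over trip
origins/destinations of the top/bottom exposure driver groups.

Because fleet GPS data of this kind is proprietary, the package ships a
first-class **synthetic scenario generator** (`dynexposure.synthetic`)
that emulates the study structure — a smooth annual surface with urban
hotspots, stations sharing a diurnal cycle plus a multi-day pollution
episode peaking near 300 μg/m³, and taxis driving shortest paths with
noisy GPS — together with exact ground truth (continuous paths, traversed
edges, per-trip exposure) for recovery testing.

## Worked example

```bash
python examples/02_trip_exposure.py
```

prints (abridged):

```
simulated 86400 GPS fixes for 5 taxis over 2 days
extracted and matched 850 occupied trips

first trip (T000, 2014-05-13T00:02:40 -> 2014-05-13T00:27:30, 12.50 km):
  EI  = 22.78 ug.h/m3 over 14 cell-hour pieces
  TWA = 55.04 ug/m3
  ground truth TWA = 55.04 ug/m3 (rel. err 3.31e-06)

fleet mean exposure by hour of day (first 6 populated hours):
  00:00    52.6 ug/m3 [49.9, 55.4] (n=42)
  ...
weekday 24-h mean 50.31 ug/m3, weekend nan ug/m3
weekday mean is 2.0x the WHO 24-h guideline (101.3% above)
```

The trip's exposure integral (EI) accumulates concentration × time over
its 14 cell-hour pieces; dividing by the 0.41 h duration gives the
time-weighted mean of 55 μg/m³, which matches the generator's ground
truth to 3 × 10⁻⁶ relative.  The hourly rows are fleet means with 95%
normal-approximation confidence intervals; the final lines compare the
weekday 24-h mean against the WHO 25 μg/m³ guideline.

`examples/01_fused_field.py` shows station ranking and field evaluation,
`examples/03_hotspots.py` the extreme-group KDE analysis.

## Command line

The same stages run from a YAML config:

```bash
dynexposure run examples/config.yaml            # all stages
dynexposure run examples/config.yaml --stages field,exposure
dynexposure simulate examples/config.yaml       # one stage
```

Outputs (CSV/GeoJSON/ASCII grid plus a `manifest.json` with the seed and
row counts) land in the configured output directory; identical config and
seed reproduce byte-identical files.  Exit codes: 0 ok, 2 config error,
3 data error, 4 compute error.

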