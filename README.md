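# larvagram

Quantitative analysis of the two motor programs that drive *Drosophila*
larva navigation — tail-to-head **peristalsis** for forward crawling and
**asymmetric contraction of anterior segments** for head sweeping — together
with a ground-truthed synthetic fluorescence-video generator on which every
analysis stage is validated.

Who it is for: people building or validating behavioral machine-vision
pipelines for soft-bodied crawlers (larvae, worms), and anyone who needs a
fully controlled benchmark where the "animal" has known kinematics.

## The measurements

The larva body is modeled as eleven segments, three thoracic (T1–T3) and
eight abdominal (A1–A8). Segment boundaries intersect the body outline at
20 points, numbered +1…+10 along the left side and −1…−10 along the right
(head tip 0, tail tip ±11). From fluorescence video of a muscle-labeled
larva the pipeline extracts, per frame:

- the body outline (threshold → erosion/dilation → largest boundary →
  Gaussian smoothing with width 0.5% of boundary length);
- head and tail, as the two maxima of outline curvature computed with a
  sliding window spanning 20% of the boundary length, disambiguated by
  proximity to their previous-frame locations;
- the centerline (midpoints of corresponding left/right boundary points)
  and the operational body-bend angle θ — the signed angle between the
  tail→midpoint segment and the ¾-point→head segment, leftward positive.
  Head sweeps are flagged when |θ| ≥ 40°, and classed *small* / *large* by
  the 90° rule;
- per-segment contraction metrics: left/right boundary arc lengths
  L_left, L_right, quadrant fluorescence intensities, their fractional
  changes against an inter-wave reference image, and the asymmetry index
  a = ln(L_right / L_left) (positive for leftward bends).

Kymographs (body coordinate × time) of these metrics feed the event layer:
peristalsis waves (chained head-ward contraction peaks), per-wave forward
displacement (≈ 0.13 body lengths per wave), the region of asymmetric
contraction during a sweep (extent T3–A3, peak A1), wave-initiation site
(tail vs. within the bend), and reorientation maneuvers (sweeps grouped
until the body is straightened by subsequent waves). Navigation statistics
follow: turn frequency and first-head-sweep size per thermal phase
(warming/cooling at |dT/dt| ≷ 0.001 °C/s), forward speed excluding
maneuvers, and population thermotaxis speed.

The synthetic generator produces videos whose statistical structure matches
these observations: contraction pulses travelling A8→T1 with fluorophore
conservation (contraction brightens), raised-cosine bend profiles peaked on
A1, straightening waves that carry ~2 segments around the bend per cycle,
Poisson turn onsets with phase-dependent rates, and phase-dependent sweep
amplitude distributions.

## Worked example

```python
import numpy as np
from larvagram import SimulationConfig, TemperatureWaveform, simulate_dataset
from larvagram.behavior import BehaviorProgram
from larvagram.pipeline import run_video_pipeline

config = SimulationConfig()                      # 8 Hz, 2 mm body, 0.01 mm/px
program = BehaviorProgram(duration_s=60.0, turns=[])   # one 60 s forward run
dataset = simulate_dataset(config, TemperatureWaveform(), 60.0, seed=5,
                           program=program)
result = run_video_pipeline(dataset)             # track -> kymo -> events

disp = result.wave_displacements_bl()
print(f"{len(result.waves)} waves, "
      f"displacement {disp.mean():.3f} +/- {disp.std(ddof=1):.3f} BL/wave")
```

Output:

```
72 waves, displacement 0.130 +/- 0.010 BL/wave
```

i.e. the tracker found all 72 complete peristalsis cycles in the rendered
minute of crawling and measured a mean forward displacement of 0.130 body
lengths per wave — the generator's configured 0.13 — with the frame-grid
scatter one expects at 8 Hz.

The same machinery is available from the shell:

```bash
larvagram simulate --out sim/ --seed 3 --duration 30
larvagram track    --in sim/ --out trk/
larvagram kymo     --in sim/ --metric asymmetry --out asym.csv
larvagram all      --out run/ --seed 3          # full pipeline + manifest
```

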