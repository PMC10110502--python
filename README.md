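# pgcprot

Quantification of protrusion plasticity in migrating amoeboid cells from
time-lapse fluorescence microscopy, bundled with a synthetic-microscopy
generator that provides machine-readable ground truth for every analysis
stage.

The package implements:

- **`pgcprot.synthetic`** — deterministic generators for single-cell movies
  with a bright cortical ring (peaked angular intensity, configurable width),
  discrete bleb events, 3D nuclei point fields, two-channel ratio stacks,
  moving-stripe movies, biased-random-walk tracks in a drifting tissue, and
  scripted gel-encounter scenes. Every scene carries its ground truth.
- **`pgcprot.segmentation`** — threshold + fill-holes cell masks, cortex ring
  masks via repeated erosion (4 passes by default, difference with the
  original mask), centers of mass, and nuclei density (mean distance to the
  5 nearest neighbours).
- **`pgcprot.angular`** — cortical angular intensity profiles (120 bins of
  3°), circular Gaussian fitting (`c + A·exp(−Δ(θ,µ)²/2σ²)`), peak-height
  normalization with the peak rotated to 180°, per-cell peak normalization,
  and two-sample KS comparison of profile distributions.
- **`pgcprot.protrusions`** — bleb frequency (events/min) and relative bleb
  size (bleb area / cell area at maximum expansion), the >3 min
  forward-movement eligibility filter, the actin-rich protrusion time
  fraction, reference-group normalization, an automated bleb detector for
  synthetic benchmarking, gel-response scoring in a −1/+5 min window, and
  the pairwise Fisher + Bonferroni contingency test.
- **`pgcprot.kinetics`** — track speed (path length / duration), straightness
  (net displacement / path length), drift correction against nearby somatic
  tracks, kymograph construction, and retrograde-flow speed from row-pair
  cross-correlation with sub-pixel refinement.
- **`pgcprot.intensity`** — ratiometric (FRET-style) maps, whole-cell means,
  per-day normalization, front/back quarter ratios along the cell's longest
  axis, and projection-based stain quantification (10-slice average or
  whole-stack sum) with two-region background subtraction.
- **`pgcprot.stats`** — the normality-gated test choice
  (D'Agostino–Pearson → pooled t / Welch t / Mann–Whitney), KS, Fisher exact
  and Bonferroni primitives.
- **`pgcprot.pipeline`** — YAML-round-trippable run configuration with
  paper-default parameters, a stage runner, and a deterministic two-tissue
  demo that exercises every metric plus the group statistics.

## Command line

```bash
# synthetic scenes with ground truth
pgcprot simulate cell-movie --seed 1 --bleb-rate 2 --out out/movie
pgcprot simulate nuclei --mode uniform_random --n 200 --out out/nuclei.csv
pgcprot simulate stripes --speed 1.5 --out out/stripes.tif
pgcprot simulate tracks --n-tracks 20 --out out/tracks.csv
pgcprot simulate gel --behavior turn --turn-angle 90 --out out/gel.json

# analysis stages
pgcprot segment out/movie/cortical.tif --erosions 4 --out out/seg
pgcprot profile out/movie/cortical.tif --bin-width 3 --out out/profile
pgcprot density out/nuclei.csv --k 5 --out out/density.csv
pgcprot flow out/stripes.tif --line 0,8,127,8 --pixel-size 0.2 --interval 2
pgcprot tracks metrics out/tracks.csv --out out/track_metrics.csv
pgcprot gel score out/gel.json --turn-threshold 45
pgcprot blebs quantify out/movie/bleb_events.csv --minutes 2 --cell-area 800

# orchestration
pgcprot run --seed 3 --out out/run            # configured stages end to end
pgcprot demo --seed 42 --out out/demo         # two-tissue replica demo
```

All generators and the demo are pure functions of `(parameters, seed)`:
rerunning with the same seed reproduces outputs byte for byte.

## Conventions

- Pixel grid: 0-based, `(row, col) = (y, x)`, pixel centers at integers.
- Angles: degrees, counterclockwise from the image +x axis, in `[0, 360)`.
- Units: micrometers and seconds in data structures; speeds reported in
  µm/min.
- The erosion structuring element defaults to the 3×3 cross
  (4-connectivity); pass `SQUARE_ELEMENT` to match Fiji's 8-neighbourhood
  default.
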