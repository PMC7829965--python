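# ethokinetics

Video-trajectory kinematics for rodent behavioral tests: centroid tracking
from grayscale frame stacks, five bespoke kinematic statistics (traveled
distance, effective velocity, mean acceleration, stops, distance/stop),
arena-zone analysis for the open field, three-chamber sociability and
elevated-plus-maze geometries, minute-by-minute habituation profiles,
social/non-social ratio statistics, and the matching group-comparison
statistics (Mann-Whitney U, mixed two-way ANOVA, Tukey/Sidak post hoc).
A synthetic trajectory/video generator with full ground truth makes every
stage verifiable without animal data.

## Package layout

| module                       | purpose                                                        |
| ---------------------------- | -------------------------------------------------------------- |
| `ethokinetics.tracking`      | threshold + connected-component centroid extraction, gap interpolation, pixel-to-cm calibration |
| `ethokinetics.kinematics`    | movement segmentation, the five statistics, minute bins, straight-walk and turning detection |
| `ethokinetics.arenas`        | arena geometries, zone assignment, occupancy, per-zone kinematics, social ratios |
| `ethokinetics.stats`         | Mann-Whitney U (exact/asymptotic), mixed and between two-way ANOVA, Tukey and Sidak post hoc, cohort comparisons |
| `ethokinetics.synthetic_data`| correlated-random-walk bout simulator with phenotype presets, cohort builder, frame-stack renderer |
| `ethokinetics.pipeline`      | manifest-driven end-to-end runs with CSV/JSON reports          |

## Command line

```bash
# centroid track from a TIFF stack (or a directory of PNG frames)
ethokinetics track --stack video.tif --threshold 100 --min-area 20 \
    --fps 30 --calib calib.yaml --out track.csv

# five statistics + per-minute bins from a calibrated track
ethokinetics analyze --track track.csv --epsilon 0.3 --bin 60 --out summary.csv

# zone occupancy (plus social/non-social kinematics for 3C arenas)
ethokinetics zones --track track.csv --arena arena.yaml --out zones.csv

# group comparison over a long-format summary table
ethokinetics compare --summaries long.csv --design totals --out stats.csv

# synthetic cohorts with ground truth
ethokinetics simulate --preset vpa_like --arena OFT --n 8 --seed 0 --out-dir cohort/

# full pipeline over a cohort manifest
ethokinetics run --manifest cohort.csv --config run.yaml --out results/
```

Key analysis parameters are explicit everywhere: the immobility threshold
`epsilon` (cm per step, default 0.3) and the frame interval drive all five
statistics and are recorded in every output.

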