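# seedvigor

A toolkit for **non-destructive, full-time-series seed germination vigor
phenotyping** from time-lapse tray images.  It is aimed at seed scientists
and phenotyping engineers who image germination trays (e.g. 36 soybean
seeds on dark filter paper over 96 h) with an instance-segmentation model
and need to turn per-frame radicle masks into calibrated biology: root
lengths, germination timing, vigor indices, and treatment statistics.

No external dataset is required: a built-in synthetic tray generator with
exact ground truth (per-seed germination times and centerline arc lengths)
exercises — and validates — every stage of the chain.

## The measurement chain

1. **Radicle length from a mask** (`seedvigor.root_geometry`).  For an
   instance mask, trace the outer boundary of the largest connected
   component (8-connected Moore boundary following, holes filled) and sum
   Euclidean steps around the closed contour:

   $$S_p = \sum_{m=2}^{n} \lVert k_m - k_{m-1} \rVert, \qquad
     \text{perimeter} = S_p \, r, \qquad L = \tfrac{1}{2} S_p \, r$$

   where $k_1 \dots k_n$ are the traced boundary pixels and $r$ (mm/px) is
   the scale calibration from a reference object of known size.  Half the
   outer contour follows the natural curvature of the young root, avoiding
   the systematic underestimate of straight tip-to-base measurements.

2. **Tracking and vigor metrics** (`seedvigor.vigor_metrics`).  Radicle
   detections are assigned to seed grid slots (greedy nearest, capped at
   half the grid pitch), giving one length time series per seed.  A seed
   counts as germinated when $L \ge$ 2 mm (configurable).  Per dish:
   germination rate at 96 h, germination energy (rate at 72 h), germination
   index $GI = \sum_t G_t / D_t$ (newly germinated count per day over day
   number), and total/mean root length.

3. **Statistics** (`seedvigor.stats_eval`).  Shapiro–Wilk and Levene
   assumption checks (reported, never blocking), one-/two-way ANOVA with
   interaction, Tukey HSD at family level $\alpha$, compact letter
   displays, and the estimator-validation OLS regression with $R^2$ and
   residual diagnostics.

4. **Detector evaluation** (`seedvigor.stats_eval.evaluate_map`).
   COCO-style box and mask mAP:
   $\mathrm{mAP}_{0.5} = \frac{1}{n_c}\sum_c \int_0^1 P_c(R)\,dR$ with
   all-point interpolation, and $\mathrm{mAP}_{0.5:0.95}$ averaged over IoU
   thresholds 0.50:0.05:0.95.

5. **Architecture accounting** (`seedvigor.seg_arch`).  Exact multiply and
   weight accounting for ghost convolutions
   ($M C k^2$ vs $\frac{M}{s} C k^2 + \frac{M}{s}(s{-}1)d^2$), plus NumPy
   forward contracts for Squeeze-and-Excitation, windowed self-attention
   (W-MSA/SW-MSA), and patch merging — the verifiable surface of a
   lightweight segmentation backbone, without any training.

## Worked example

Generate a two-arm synthetic study (water control `CK` vs the optimal-dose
arm `ZnO600`, 3 dishes x 36 seeds each), measure it, and summarize:

```sh
seedvigor simulate --preset paper_calibrated --arms CK,ZnO600 \
    --seed 1 --no-images --out run/dataset
seedvigor measure  --dataset run/dataset --out run/measurements.csv
seedvigor metrics  --dataset run/dataset --measurements run/measurements.csv \
    --out run/metrics
seedvigor stats    --metrics-file run/metrics/vigor_summary.csv \
    --metric germination_rate --out run/stats
```

`run/metrics/vigor_summary.csv` holds one row per (arm, dish, metric).  In
this run the control arm germinates 69.4% of seeds at 96 h and the
optimal-dose arm 89.8%, a relative increase of **29.3%** against a
configured effect of +28%; mean radicle length of germinated seeds rises
by **38.5%** against a configured +42% — both recovered within the
binomial sampling noise of 108 seeds per arm.

Validate the length estimator against known centerline arc lengths, and
inspect the ghost-convolution accounting:

```text
$ seedvigor validate --n 100 --seed 1
n=100  slope=1.0546  intercept=1.376 mm  R^2=0.9977

$ seedvigor arch-report -c 64 -m 128
layer: C=64 M=128 k=3 | ghost s=2 d=3
                          multiplies/pos     weights
standard conv                     73,728      73,728
ghost intrinsic                   36,864
ghost cheap (depthwise)              576
ghost total                       37,440      37,440
reduction: 49.2% (bias and norm parameters excluded)
```

The slope near 1 and high $R^2$ say the half-contour estimate tracks the
true arc length almost perfectly; the ~1.4 mm intercept is the expected
additive excess from the two rounded tube ends ($\approx \pi w r / 2$).

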