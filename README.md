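# rbcqpi

Red blood cell morphometry from off-axis quantitative phase imaging (QPI).

Clinical impedance counters report little beyond MCV and MCHC, while manual
smear review is slow and needs staining. A common-path off-axis QPI
microscope instead records interferograms whose fringe bending encodes the
optical pathlength of every cell in the field of view; from a single frame
one can recover each RBC's thickness profile and hence a rich, label-free
morphological profile. `rbcqpi` implements the full analysis chain of such
an instrument, for hematology-oriented image analysts:

1. **Phase reconstruction** — Fourier/Hilbert demodulation of the
   first-order fringe lobe, 2D phase unwrapping, and subtraction of a
   cell-free background frame (dust, aberrations).
2. **Segmentation** — global phase threshold plus label-equivalence
   connected-component labeling (verified against a flood-fill oracle).
3. **Per-cell morphology** — with `h = λφ/(2πΔn)` and `Δn` set by the
   sample's MCHC via `n = n_w + βC`: projected area PA, equivalent
   diameter, volume `V = ∫h dA`, Monge surface area
   `SA = ∫√(1+h_x²+h_y²) dA + PA`, sphericity `Ψ = π^⅓(6V)^⅔/SA`,
   minimum cylindrical diameter (smallest positive root of
   `πD³ − 3·SA·D + 12V = 0`), perimeter, eccentricity, thickness
   statistics, circularity, integrated density, and height-distribution
   moments. Objects under 20 fL (platelets) are excluded.
4. **Population statistics** — MCV, RDW (= 100·sd/mean of volume),
   per-parameter histograms and quartiles, written as a kilobyte-scale
   text summary plus a per-cell CSV: arrays of numbers, not images.

A ground-truthed **phantom generator** (synthetic in every respect)
emulates the instrument: Evans–Fung biconcave cells, spherocyte-like
domes and sub-20 fL platelets rendered as off-axis interferograms with
aberrations, dirt and camera noise, with exact per-cell volume and
surface-area ground truth for recovery testing.

## Worked example

Simulate a 60-cell sample (mean 90 fL, RDW 15 %, 10 % platelets), analyze
it, and compare against ground truth:

```bash
rbcqpi simulate --out-dir demo/sim --n-cells 60 --mean-volume-fl 90 \
    --rdw-percent 15 --platelet-fraction 0.1 --seed 1
rbcqpi analyze demo/sim/sample_*.tif --background demo/sim/background.tif \
    --config demo/sim/optics.yaml --out-dir demo/out
rbcqpi recover --cells demo/out/cells.csv --truth demo/sim/truth.csv
```

prints

```
wrote 3 frame(s) to demo/sim
51 cells -> demo/out/cells.csv
MCV 90.4 fL, RDW 13.2%
matched 51/60 truth cells
median |volume error| 1.08%
```

The 60 cells contained 9 platelets; the 20 fL filter removed exactly
those, every remaining RBC was matched to its ground-truth twin by
centroid, and the median per-cell volume error is about 1 %. The summary
(`demo/out/summary.txt`) begins

```
n_cells: 51
mcv_fl: 90.444
rdw_percent: 13.169
msa_um2: 132.945
mean_sphericity: 0.7308
mean_mcd_um: 2.9060
```

i.e. the recovered MCV sits within half a femtoliter of the simulated
population mean, and the mean sphericity ≈ 0.73 and MCD ≈ 2.9 µm are in
the physiological range for normal biconcave cells.

The same stages are available as a library:

```python
import rbcqpi as rq

cfg = rq.OpticalConfig(mchc_g_dl=33.0)
specs = rq.sample_population(200, mean_volume_fl=90, rdw_percent=15, seed=7)
frames = rq.simulate_population_frames(specs, (512, 512), cfg,
                                       rq.InterferogramModel(), seed=7)
records = []
for scene, sample, background in frames:
    records += rq.analyze_frame(sample, background, cfg).records
stats = rq.summarize(records)
print(stats.mcv_fl, stats.rdw_percent)
```

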