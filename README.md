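# phagequant

Single-cell fluorescence quantification of mycobacteriophage adsorption and
infection.

Mycobacteria build new cell wall at their poles and division septa, and
phage particles preferentially attach there. `phagequant` provides the
image-analysis side of that observation as a tested, reusable Python
library: it quantifies **where** labelled phage particles sit on rod-shaped
cells relative to a fluorogenic cell-wall-synthesis probe, **how much**
phage each cell adsorbs, and **what happens next** in reporter time lapses
(expression and lysis versus resistant outgrowth) — plus the GC% landscape
of phage genomes, whose locally AT-rich islands are candidate binding
regions for host nucleoid-associated proteins such as Lsr2. Because raw
imaging data of this kind are rarely shareable, the package ships a seeded
synthetic microscopy generator with complete ground truth, so every stage
is validated by parameter recovery.

## What it computes

- **Perpendicular-profile colocalization** (`phagequant.coloc`): lines
  anchored at equal arclength spacing on each cell boundary, perpendicular
  to the surface. With cell-free background mean μ and standard deviation
  σ per channel, a line is *phage proximal* when its red-channel peak
  height exceeds μ + kσ strictly (k = 1 by default). Along proximal and
  non-proximal lines the background-subtracted maximum of the green
  (cell-wall probe) signal is compared via medians and quartiles.
- **Adsorption statistic** (`phagequant.adsorption`): per cell, the sum of
  background-subtracted red peak heights along the closed boundary divided
  by the circumference; two conditions compared with a two-tailed pooled
  Student's t-test (Welch optional).
- **Reporter time lapses** (`phagequant.timelapse`): IoU-overlap tracking,
  background-subtracted mCherry traces, persistent-threshold onset
  detection, and per-track fate calls
  (expressed_lysed / outgrowth / uninfected / censored).
- **Segmentation & geometry** (`phagequant.segmentation`): classical
  phase-contrast segmentation (or import of external label masks), sub-pixel
  boundary, midline, circumference, pole-to-pole length and width per cell.
- **Genome GC landscape** (`phagequant.genome`): overall and sliding-window
  GC fraction, merged low-GC region calls, BED/TSV output.
- **Synthetic scenes** (`phagequant.synthetic`): seeded capsule-shaped
  cells with polar/septal membrane label, PSF-convolved phage puncta with
  tunable polar bias, sigmoidal reporter time lapses with lysis/outgrowth
  fates, Poisson + Gaussian camera noise, and full ground-truth tables.

## Worked example

```python
from phagequant.coloc import median_difference, run_coloc
from phagequant.synthetic import SceneConfig, simulate_scene

cfg = SceneConfig(n_cells=25, seed=11, polar_bias=1.0, polar_green_ratio=3.0)
scene = simulate_scene(cfg)
table, summary = run_coloc(scene.channels["green"], scene.channels["red"],
                           scene.labels())
print(summary.n_lines, summary.n_proximal)
print(summary.proximal_stats["median"], summary.nonproximal_stats["median"])
print(median_difference(table))
```

prints

```
1424 678
11.797 9.881
+1.92
```

1424 perpendicular lines were sampled over 25 cells and 678 had a red peak
more than one background SD above the cell-free background. The
background-subtracted green maximum is higher along phage-proximal lines
(median 11.8 vs 9.9 intensity units): with fully polar dosing and 3x polar
label enrichment, the wall-synthesis probe is brighter where phages bind.
Under the built-in null (uniform dosing, uniform label) the same difference
falls inside a 95% resampling band around zero.

More narrative walk-throughs live in `examples/` (one script per
capability: scene simulation, colocalization, adsorption comparison,
time-lapse fates, GC landscape). A thin CLI wraps the batch entry points:

```bash
phagequant simulate --out scene_dir --seed 7
phagequant coloc --green g.tif --red r.tif --mask m.tif --out out_dir
phagequant gcmap --fasta genome.fasta --out gc_dir
```

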