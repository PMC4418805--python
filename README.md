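# fiberwrap

Quantitative image analysis of how endothelial cells wrap polymer
microfibers with their actin cytoskeleton.

Cells seeded on electrospun poly-ε-caprolactone scaffolds attach to single
scaffold microfibers (SMFs, diameters roughly 5–20 μm) and assemble
circumferential F-actin bands around them. Fully circumferential, low-pitch
bands — *actin grips* (AGs) — appear to clamp the cell onto the fiber;
partial, often oblique arcs — *concave actin bundles* (CABs) — look like
intermediates of grip assembly; classical stress fibers run longitudinally.
`fiberwrap` provides the measurement machinery to turn multichannel confocal
z-stacks of such specimens into numbers:

- **Fiber geometry** — segmentation of the fiber channel, center-line
  extraction, and local diameter estimation by scoring 1-μm-long template
  cylinders of pre-determined candidate diameters *D* against the fiber
  mask: `score(D) = inside_fraction(D) − guard_fraction(D)`, where the
  guard shell extends to 1.5 *D* and penalizes over-sized candidates.
- **Digital unwrapping** — the space around a fitted fiber axis is mapped to
  cylindrical coordinates (axial position *s*, azimuth *θ*), either
  projecting a radial band onto the (*s*, *θ*) plane (planar unwrapping) or
  sampling concentric shells at increasing radii (layered unwrapping). The
  azimuthal frame is parallel-transported along the axis, so curved fibers
  unwrap without twist artifacts.
- **Ring classification** — bands detected on the periodic (*s*, *θ*) grid
  are summarized by angular coverage (with wraparound, so an arc crossing
  θ = 0 is one segment) and obliquity in arc-length coordinates (*s*, *θ·r*),
  then classified AG / CAB / longitudinal.
- **Nuclear shape** — roundness = ℓ₁/ℓ₃, the ratio of the largest to the
  3rd-largest principal component (standard deviation) of the nucleus voxel
  cloud; 1 for a sphere. Regressed against the local fiber diameter at the
  attachment site.
- **Diameter distributions** — fiber diameters overall vs at cell-attachment
  sites, compared by normalized histograms, matched quantiles (Q-Q), and the
  two-sample Kolmogorov–Smirnov statistic.
- **Kinetics** — per-ROI mean-intensity tracks from GFP-actin time lapses
  (5-min frames) with Pearson correlation between tracks.
- **qPCR indices** — relative copy number RCN = 2^(−ΔCq) × 100 with
  ΔCq = Cq(target) − median Cq of four endogenous controls; per-gene percent
  change vs the pre-seeding baseline, averaged over a 10-gene cluster, and
  Welch *t*-tests between endothelial-relevant and -irrelevant clusters.

Because no public raw data exist for this kind of experiment, the package
ships a first-class synthetic scene generator (`fiberwrap.synthgen`) that
renders ground-truthed fibers, bands of set coverage/obliquity, stress
fibers, nuclei, membrane-stain gaps, PSF blur and Poisson+Gaussian noise —
every analysis stage is validated by parameter recovery against this truth.

## Worked example

```python
import numpy as np
from fiberwrap import synthgen as sg, fibergeom as fg, ringquant as rq
from fiberwrap import unwrap as uw

# a 6-μm fiber carrying a full ring, a 120° arc crossing θ=0, and a stress fiber
cfg = sg.SceneConfig(
    shape=(40, 40, 100), voxel_size=(0.4, 0.4, 0.4),
    fibers=[sg.Fiber(anchor=(8.0, 8.0, 2.0), direction=(0, 0, 1),
                     radius=3.0, length=36.0)],
    bands=[sg.Band(fiber=0, axial_center=18.0, axial_width=2.0, coverage_deg=360.0),
           sg.Band(fiber=0, axial_center=8.0, axial_width=2.0,
                   coverage_deg=120.0, offset_deg=300.0)],
    stress_fibers=[sg.StressFiber(fiber=0, azimuth_deg=90.0, axial_span=(24.0, 34.0))],
    seed=17,
).noise_free()
stack, truth = sg.render_scene(cfg)

labels = fg.segment_fibers(stack, threshold=0.5)
axis = fg.extract_axis(labels == 1, stack.voxel_size)
axis = fg.fit_local_diameter(labels == 1, axis, voxel_size=stack.voxel_size)
print(f"fiber diameter: median {np.nanmedian(2 * axis.local_radius):.1f} um "
      f"over {len(axis.points)} axis points")

unwrapped = uw.unwrap_planar(stack, "actin", axis, radial_band=(2.0, 4.0), n_theta=72)
for seg in sorted(rq.detect_bands(unwrapped, threshold=50.0),
                  key=lambda s: s.s_span[0]):
    print(f"{seg.band_class:12s} coverage {seg.angular_coverage:5.1f} deg  "
          f"obliquity {seg.obliquity:4.1f} deg  s = {seg.s_span[0]:.1f}-{seg.s_span[1]:.1f} um")
```

prints

```
fiber diameter: median 6.0 um over 74 axis points
CAB          coverage 115.0 deg  obliquity  0.0 deg  s = 7.4-8.9 um
AG           coverage 360.0 deg  obliquity  0.0 deg  s = 17.3-18.7 um
LONGITUDINAL coverage  25.0 deg  obliquity 90.0 deg  s = 24.2-34.0 um
```

The template fit recovers the true 6-μm diameter; the full ring comes back
as an AG covering all 360° of azimuth; the arc that wraps through θ = 0 is a
single CAB segment with its 120° coverage recovered to within one 5° bin;
and the axial stress fiber is classified longitudinal (obliquity 90°).

The same pipeline is scriptable end to end from a YAML config:

```sh
fiberwrap all --config run.yaml --out results/
fiberwrap qpcr --cq-table cq.csv --out results/
```

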