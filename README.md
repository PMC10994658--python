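# spiculometry

Quantitative 3D morphometry of sea urchin larval spicules — the calcite
skeletal rods built by skeletogenic cells — plus the fluorescence
quantification and group statistics used to compare control and perturbed
(e.g. ROCK-inhibited) cohorts.

Given a segmented µCT volume, the pipeline measures per spicule:

- **volume** `V = N_voxels · sz·sy·sx` and **surface area** (smoothed
  marching-cubes isosurface, or exposed voxel faces),
- **total length**: the spicule is thinned to a one-voxel medial skeleton,
  organized into a graph of endpoint/junction nodes and branch paths, spur
  artifacts are pruned, and branch lengths are summed,
- **mean thickness**: the Euclidean distance transform (EDT) sampled along
  the skeleton — each sample is the local radius `r(x) = d(x, surface)` —
  reported as diameter `2·mean r`,
- **tips and junctions** of the skeleton graph, which quantify ectopic
  branching (loss of tip dominance).

2D fluorescence images are quantified as stained-pixel densities inside
named regions of interest and their ratios (skeletogenic/ectoderm,
spicule tip/back), plus counts of calcein-stained vesicles as connected
blobs. Cohorts are compared with a one-sample z-test against 1, paired
t-test, tie-corrected Kruskal–Wallis H, fold changes, and
between-timepoint growth rates.

Because real µCT scans are large and not bundled here, the package ships a
first-class synthetic-phantom generator: capsule-shaped rods, triradiates
and branched spicules with analytic ground truth (length, radius, volume,
topology, junction positions), noisy 16-bit grayscale rendering, simulated
two-condition cohorts, and fluorescence fixtures with exact stained-pixel
truth. Every validation in the test suite runs against this analytic truth.

## Worked example

```python
from spiculometry import phantoms, morphometry

# a capsule rod: radius 4 µm, centerline length 100 µm, 1 µm voxels
prim = phantoms.RodPrimitive((0, 0, 0), (0, 0, 100.0), radius=4.0)
vol, truth = phantoms.make_rod_phantom(phantoms.PhantomSpec((prim,)))
record, details = morphometry.measure_spicule(vol.values, vol.spacing)
for k, v in record.items():
    print(f"{k:>18}: {v}")
```

prints

```
        volume_um3: 5157.0
  surface_area_um2: 2610.188232421875
   total_length_um: 98.0
 mean_thickness_um: 8.246211251235321
            n_tips: 2
       n_junctions: 0
```

Read against the analytic truth: the capsule volume is
πr²L + 4/3·πr³ = 5294.6 µm³ (voxelization undercounts by 2.6%), the
surface area 2πrL + 4πr² = 2714.3 µm² (−3.8%), the skeleton recovers 98 of
100 µm of centerline (thinning retracts one voxel into each rounded cap),
the mean thickness 8.25 µm is the diameter of a 4 µm-radius rod (+3%), and
the topology — two tips, no junction — is exact. A tip-split phantom
(`make_branched_phantom(..., branch_fraction=1.0)`) instead yields
3 tips / 1 junction with the junction localized at the split rod end.

The same flow works from the shell:

```bash
spiculometry phantom --preset triradiate --seed 7 --out run/
spiculometry measure --input run/phantom.tif --output run/records.csv
spiculometry compare --records run/records.csv --plan plan.yaml --output run/stats.csv
```

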