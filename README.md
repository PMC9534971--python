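# vesselwell

Quantification of *vessel-on-a-dish* coculture mosaics: stitched
fluorescence images of endothelial cells (ECs) grown on smooth-muscle-cell
(SMC) layers in circular wells swirled on an orbital shaker — the in vitro
setting used to model intimal hyperplasia, the SMC-driven vessel-wall
thickening that follows vascular injury.

In these cultures the endothelium is a patchwork of three textures:
confluent cobblestone **islands**, cord-like **networks** of elongated
cells, and bare **gaps** exposing the SMC layer. Where the endothelium is
defected, SMCs proliferate, stack into multilayered "corrugated"
structures, and incorporate plasma fibronectin into fibers; under
confluent islands they stay quiescent. The flow regime differs between
the well rim (pulsatile, tangential) and its middle (disturbed), so every
readout is split into a *periphery* and a *center* zone at half the
radius.

`vesselwell` provides, for users of such assays:

* **texture segmentation** of the EC channel into island / network / gap,
  built on an EC-thickness (distance-transform hysteresis) feature plus a
  local-coverage gate, with parameter calibration against ground truth;
* **region statistics**: coverage fractions per zone, SMC proliferation
  per region from DAPI/ERG1/Ki-67 nuclei, the island-normalized
  cell-tracker intensity that counts SMC layers, radial intensity
  profiles with the fibronectin/SMC ratio, EC flow-alignment order, and
  ANOVA + Tukey HSD group comparisons;
* **orbital-shaker shear estimation** via the Stokes-layer closed form
  `tau = r_orb * sqrt(rho * mu * omega^3)`;
* a **synthetic mosaic generator** that renders six-channel wells
  (EC, SMC, Fn, DAPI, Ki-67, ERG1) with complete ground truth — label
  maps, nucleus tables, corrugation and fiber masks — so the whole
  pipeline is testable against known parameters.

## Worked example

Simulate a low-density ("IH") coculture well under shear and run the full
pipeline (segmentation → nucleus detection → quantification):

```python
from vesselwell.pipeline import PipelineConfig, run_pipeline
from vesselwell.synthetic import model_config

sim = model_config("IH_low_density", "shear", canvas_px=768).to_dict()
sim.pop("seed")
report, labelmap, geom = run_pipeline(
    PipelineConfig(simulate=sim, output_dir="demo_out", seed=1)
)
```

The merged region table (`demo_out/region_table.csv`) reads:

```
     zone region_class  area_fraction  smc_prolif_pct  n_smc  smc_intensity_norm
   center       island          0.164           5.000     40               1.000
   center      network          0.288          26.667    105               1.930
   center          gap          0.548          28.903    647               1.993
periphery       island          0.303           8.397    262               1.000
periphery      network          0.238          26.872    227               2.018
periphery          gap          0.460          28.915   1539               2.054
```

Reading it: the segmented island fraction (0.30 at the periphery, 0.16 in
the center) recovers the configured scene (0.30 / 0.15); SMC proliferation
is ~5–8% under confluent islands but ~27–29% in networks and gaps — the
defect-driven proliferation pattern; and the cell-tracker layering index
reads ~2.0 in defected regions (multilayered, corrugated SMCs) against the
island single-layer reference of 1. The flow-alignment order parameter for
this scene is 0.51 at the periphery versus −0.04 in the center: peripheral
island ECs align with the tangential flow, central ones are isotropic.

The shear operating point, from the command line:

```
$ vesselwell shear --rpm 135
tau_peak_pa: 0.4459790790212551
periphery: {low_pa: 0.4, high_pa: 1.2, regime: pulsatile-laminar}
center:    {low_pa: 0.3, high_pa: 0.8, regime: disturbed}
periphery_consistent: true
beat_equivalent: {bpm: 135.0, band: exercise}
```

i.e. a 135 rpm orbit on a 9.5 mm-radius shaker produces a cycle-peak wall
shear stress of ~0.45 Pa — inside the 0.4–1.2 Pa window reported for the
peripheral zone of swirled 6-well plates, and a pulse rate equivalent to
an exercising heartbeat.

Other CLI verbs: `simulate`, `segment`, `quantify`, `profile`, `run`
(end-to-end from a YAML config), `report` (summary figures).

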