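# ctdosim

A self-contained toolkit for organ absorbed-dose estimation in fan-beam CT,
combining:

- an HVL-calibrated 120 kVp tungsten tube-spectrum model
  (`ctdosim.spectrum`),
- a CT gantry model — source trajectory, helical/axial projection schedules,
  fan-beam collimation, bowtie filter, patient table (`ctdosim.geometry`),
- voxel phantoms built from CT DICOM series through a piecewise HU→material
  calibration, plus the standard 32 cm PMMA CTDI phantom and a synthetic
  labeled abdomen (`ctdosim.phantom`),
- a Woodcock-tracking photon Monte Carlo with local energy deposition
  (collision kerma, 5 keV cutoff) producing per-voxel and per-region tallies
  with batch uncertainties (`ctdosim.transport`),
- tube-current-modulation (TCM) profiles mined from DICOM headers, averaged
  per rotation and converted to per-projection weights at constant total
  particle count (`ctdosim.tcm`),
- dosimetry metrics: CTDI_100 / CTDI_w, free-in-air normalization, organ-dose
  reports, dosimeter corrections, comparison statistics
  (`ctdosim.dosimetry`).

Everything runs offline: NIST-style element cross-section tables, the default
bowtie profile and the HU calibration ship as CSV files inside the package,
and a fixture generator (`ctdosim.fixtures`) writes standards-shaped DICOM CT
series (via the bundled minimal reader/writer `ctdosim.dicomlite`) so header
mining and phantom voxelization are testable with no external data.

## CLI

```bash
# synthetic CT series with TCM headers (280 x 0.625 mm slices by default)
ctdosim make-fixtures --outdir scratch/series --ma-profile gaussian-bump \
    --base-ma 90 --ma-amplitude 50 --seed 1

# TCM profile (rotation-averaged mA vs table position) + projection weights
ctdosim extract-tcm --dicom-dir scratch/series --out-prefix scratch/tcm

# end-to-end organ-dose simulation on the synthetic abdomen
ctdosim simulate --seed 1 --photons 20000 --out scratch/doses.json
ctdosim report --doses scratch/doses.json --out scratch/report.csv

# axial CTDI_100 run on the PMMA body phantom
ctdosim ctdi --seed 1 --photons 20000 --out scratch/ctdi.csv
```

`simulate` accepts a YAML config (see `ctdosim.cli.RunConfig` for all keys);
scanner-class defaults are pre-filled: SID 62.6 cm, SDD 110 cm, fan angle
47°, 40 projections per rotation at 9° steps, pitch 0.508, 80 mm beam width,
0.5 s rotation, first HVL 7.56 mm Al, start angle 0° (12 o'clock).

## Conventions

- World coordinates in mm; isocenter at (0, 0) in the gantry plane; z
  increases toward the head; voxel indices 0-based with world coordinates at
  voxel centers.
- Gantry angle 0° is 12 o'clock; rotation clockwise viewed from the feet
  (configurable).
- Tallies are keV; region doses are Gy per source photon; absolute doses are
  obtained via the measured/simulated free-in-air normalization factor and
  the protocol mAs.
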