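# sheetquant

Quantitative analysis of two-channel fluorescence micrographs of
plasma-**membrane sheets** — flat basal membranes left behind after
ultrasound "unroofing" of adherent cells.  The package was built for
studying how the amyloid precursor protein (APP) relates spatially to its
α-secretases (ADAM10/ADAM17) on the membrane, but every stage is generic:

* **Maxima detection** — intensity maxima ("pixel maxima") found by Gaussian
  smoothing (σ = 1 px), absolute thresholding and per-component peak
  finding; each maximum gets a mean intensity from a 5-px circular ROI and a
  subpixel position from the intensity center of mass, plus a cluster size
  from Gaussian line-scan fits (FWHM = 2√(2 ln 2) σ), and densities are
  reported per µm² of the analyzed ROI.
* **Cross-channel association** — for each query (secretase) maximum the
  shortest Euclidean distance to a target (APP) maximum; the chance level is
  estimated by flipping the target image vertically and horizontally
  (180° rotation) and re-detecting.  Maxima within 50 nm count as *closely
  associated*; fraction × density gives associated maxima per µm².
* **Coaggregation statistics** — per-ROI Pearson correlation coefficient
  (PCC) between channels, the rSDM clustering index (SD/mean of ROI pixel
  intensities), and background-corrected mean intensities, normalized as
  percent of a reference condition.
* **FRAP kinetics** — recovery traces normalized to the prebleach mean,
  QC'd by reference-ROI stability (>15% variation excluded), and fitted with
  the hyperbola *y(t) = offset + R·t/(t + t½)*.
* **Blot densitometry** — background-subtracted band intensities and the
  cleavage ratio sAPPα(Ly+Sn)/(APPm+APPi), expressed as percent of wild type.
* **Synthetic data** — a membrane-sheet simulator with known ground truth
  (clustered emitters, Gaussian PSF, Poisson noise, plantable cross-channel
  association, antibody cross-linking), plus FRAP-trace and blot-lane
  generators; it backs every accuracy claim in the test suite.

## Worked example

Simulate a sheet with a planted 30% association between channels, detect
maxima, and run the association analysis:

```bash
$ sheetquant simulate --seed 1 --assoc-fraction 0.3 --out demo/
wrote simulated sheet (seed=1) to demo

$ sheetquant maxima --in demo/channel_B.tif --pixel-size-nm 25 --out demo/maxima_B.csv
88 maxima, density 2.148/um^2 -> demo/maxima_B.csv

$ sheetquant assoc --query demo/channel_B.tif --target demo/channel_A.tif \
    --pixel-size-nm 25 --out demo/assoc.json
close fraction 0.295 (flipped 0.011) -> demo/assoc.json
```

Reading: 29.5% of the channel-B maxima lie within 50 nm of a channel-A
maximum, while the flipped-image null puts the chance level at 1.1%; the
excess close fraction 0.284 recovers the planted 30% association.  The
per-maximum CSV carries subpixel positions (nm), disc-mean intensities and
line-scan FWHMs, e.g. 72–79 nm for these simulated ~75 nm spots:

```
row_px,col_px,row_nm,col_nm,intensity_au,fwhm_nm,fwhm_r2,excluded_reason
8,133,209.35,3325.0,15.69,78.62,0.997,
11,102,277.0,2542.5,10.69,78.19,0.989,
```

The same operations are available as a library (`sheetquant.detect_maxima`,
`sheetquant.spatial.associate`, `sheetquant.coloc.pearson`, ...), and
figure-level recipes (`sheetquant run --recipe crosslink_coaggregation`)
compose them with deterministic, fully logged reports.

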