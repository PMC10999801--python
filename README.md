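# ielquant

Digital quantification of intraepithelial lymphocytes (IELs) and
subepithelial band thickness in colonic and ileal mucosa.

Microscopic colitis (MC) is diagnosed from subtle histology: lymphocytic
colitis (LC) requires CD3⁺ IELs in the surface epithelium exceeding
20 per 100 epithelial cells, collagenous colitis (CC) a subepithelial
collagen band exceeding 10 µm; the incomplete forms use 10–20 IELs (LCi)
and a 5–10 µm band (CCi). Both quantities depend strongly on the stain
(H&E vs CD3 immunohistochemistry vs connective-tissue stains) and on
whether counting is manual hotspot reading or whole-compartment digital
analysis. `ielquant` implements that digital analysis as a tested,
reusable pipeline for pathologists and image-analysis researchers:

- **synthetic histology generator** — calibrated brightfield biopsy images
  (surface epithelium, crypts, lamina propria, lumen; hematoxylin nuclei,
  DAB-positive CD3 cells at configurable per-compartment rates; a
  subepithelial band of configurable µm thickness that is visible on
  Van Gieson / Masson Trichrome / Weigert-Alcian-Sirius renders and not
  on H&E) with complete pixel- and cell-level ground truth;
- **stain separation** — Beer–Lambert OD conversion
  (OD = −log₁₀(I/I₀)) and least-squares unmixing against unit stain
  vectors (Ruifrok–Johnston hematoxylin/eosin/DAB);
- **tissue segmentation** — a four-class pixel classifier (background,
  surface epithelium, crypt epithelium, lamina propria) trained from
  sparse labelled ROIs at a reduced working scale, with mode-filter and
  minimum-region post-processing;
- **cell detection** — distance-transform watershed nucleus detection and
  CD3 positivity calling by mean DAB OD over the nucleus + 1 px halo
  against a calibrated threshold;
- **quantification** — IELs per 100 epithelial cells per compartment
  (100·pos/neg), lamina propria CD3⁺ density per mm², hotspot-window
  emulation of manual reading, integer-µm band thickness, and MC
  criteria classification;
- **statistics** — means with 95 % t-CIs and ranges, paired *t*-test,
  exact Wilcoxon–Pratt signed-rank test (full sign-assignment enumeration
  up to a cutoff, tie/zero-corrected normal approximation beyond),
  Bonferroni adjustment (0.05/6 reported as "<0.008"), ordinal frequency
  tables with not-assessed denominators, and pairwise comparison reports.

## Worked example

```bash
python examples/segment_and_count.py
```

```
training compartment classifier on 4 labelled synthetic images ...
segmentation pixel accuracy vs truth: 0.978
SURFACE  IELs/100: estimated  17.91 (24/134), truth  18.25 (25/137)
CRYPT    IELs/100: estimated   8.70 (6/69), truth   5.77 (3/52)
lamina propria CD3+/mm^2: estimated 317, truth 338 (configured 300)
```

The surface estimate means 24 CD3⁺ cells were counted against 134 CD3⁻
epithelial nuclei in the surface compartment, against a realized ground
truth of 25/137 — recovery within ~2 %. Crypt counts are the most
boundary-sensitive on a small fixture (a handful of lamina propria cells
adjacent to the crypt wall flip compartments under the centroid rule);
see `docs/methods.md` for the error model. Other examples: `simulate_biopsy.py` (fixture generation),
`stain_unmixing.py` (OD round trip), `band_thickness.py` (2 µm band
recovered on VG/MT/WAS, 0 µm on H&E), `cohort_statistics.py` (paired
tests, frequency tables), `full_pipeline.py` / the `ielquant` CLI
(end-to-end run with manifest and reports).

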