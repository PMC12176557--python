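# metresponse

Imaging-based assessment of treatment response in multi-site metastatic
ovarian cancer.

`metresponse` models a small longitudinal cohort of patients with
multi-site abdominal metastatic disease imaged by CT at three timepoints
(baseline `t0`, week 4 `t1`, week 12 `t2`) under a two-arm treatment
schedule (monotherapy for weeks 0–4, combination for weeks 4–12). It
provides:

- **Cohort data model** (`cohort`, `taxonomy`): tidy lesion and clinical
  tables over a fixed 15-code anatomical site taxonomy (8 peritoneal
  sites, 5 lymph-node stations, 2 other), with strict validation and
  volume-weighted per-site centres of mass.
- **Imaging layer** (`imaging`): NIfTI I/O, windowed-sinc intensity
  resampling and nearest-neighbour label resampling to a common study
  grid, and 26-connected component extraction that turns labelled masks
  back into lesion tables.
- **Synthetic cohort generator** (`synthetic`): licensed patient imaging
  is not redistributable, so the package ships a generative model of the
  study conditions — site occupancy, lesion counts and volumes,
  class-conditional volume-change factors per treatment arm, RECIST
  categories, PFS and enrollment times — plus a voxel renderer that
  rasterises lesion tables into CT + mask volumes with exact per-lesion
  voxel counts.
- **Response stratification** (`stratification`): RECIST 1.1 target
  selection and categorisation; four patient-level assessments — early
  response at week 4 (`er_4wk`), best overall response
  (`bor_responder`), long responder (`lr`, PFS > 39 weeks), long-term
  enrollee (`lte`, > 52 weeks) — and a volumetric responder definition
  (total volume change ≤ −30% from `t0` to `t1`), with confusion
  matrices between them.
- **Spatial dissemination** (`spatial`): per-patient fully connected
  anatomical networks over occupied sites (ordered-pair convention, so
  *k* sites give *k*(*k*−1) edges), cohort-level network combination,
  site co-occurrence matrices, intersite-distance metrics, and a
  presence grid.
- **Tumour burden** (`burden`): per-patient volumetric summaries,
  interval percentage changes and per-week rates, peritoneal volume
  fraction, waterfall and scatterpie tables.
- **First-order radiomics** (`radiomics`): energy, entropy (bits) and
  uniformity over fixed-bin-width (25 HU) discretised ROIs, aggregated
  per patient as median / range / sum across sites.
- **Statistics** (`stats`): Wilcoxon signed-rank tests across
  timepoints, Kruskal–Wallis tests between assessment groups, Pearson
  correlation, assembled into a comparison suite with
  Benjamini–Hochberg-adjusted p-values reported alongside raw ones.

## Worked example

```python
import metresponse as mr
from metresponse import stats as st

cfg = mr.CohortConfig(n_patients=20, seed=7)
lesions, clinical, truth = mr.generate_cohort(cfg)
print(lesions.head().to_string(index=False))
```

```
patient_id timepoint  site_code  lesion_index  volume_mm3        x_mm       y_mm       z_mm
    SYN000        t0         11             1  285.140356 -140.837418 -30.432389 200.523860
    SYN000        t1         11             1  137.650204 -140.837418 -30.432389 200.523860
    SYN000        t0         11             2  993.886698 -153.411408  -5.605014 190.280509
    SYN000        t1         11             2  479.794261 -153.411408  -5.605014 190.280509
    SYN000        t0         11             3  519.910879 -111.863189  -5.658996 192.427228
```

Volumetric burden and response labels:

```python
summ = mr.volumetric_summary(lesions)
print(summ[["patient_id", "volume_t0_mm3", "volume_t1_mm3",
            "change_pct_t0_t1", "peritoneal_pct_t0"]].head().round(1).to_string(index=False))
labels = mr.classify_cohort(clinical, summ)
print(labels.head().to_string(index=False))
```

```
patient_id  volume_t0_mm3  volume_t1_mm3  change_pct_t0_t1  peritoneal_pct_t0
    SYN000        33019.4        20052.8             -39.3               80.0
    SYN001        35335.6        34241.2              -3.1               55.4
    SYN002        11589.5        12646.4               9.1              100.0
    SYN003        34389.5        18626.4             -45.8               37.5
    SYN004         5992.1         3639.4             -39.3              100.0

patient_id  er_4wk  bor_responder    lr   lte  vol_responder
    SYN000   False           True  True  True           True
    SYN001   False          False False False          False
    SYN002   False          False  True False          False
    SYN003    True           True  True  True           True
    SYN004   False          False  True False           True
```

Dissemination metrics and anatomical-network edge counts (a patient with
*k* occupied sites has a fully connected network with *k*(*k*−1) ordered
edges, so 4 sites → 12 edges, 10 sites → 90, 1 site → 0):

```python
diss = mr.dissemination_table(lesions)
edges = mr.edge_count_table(lesions)
d0 = diss[diss.timepoint == "t0"]
e0 = edges[edges.timepoint == "t0"]
print("median n_sites =", d0["n_sites"].median(),
      "| median edges =", e0["n_edges"].median(),
      "| max edges =", e0["n_edges"].max())
```

```
median n_sites = 4.0 | median edges = 12.0 | max edges = 90
```

Cross-tabulating assessments, then running the full comparison suite:

```python
idx = labels.set_index("patient_id")
counts, pct = mr.confusion_matrix(idx["er_4wk"], idx["bor_responder"])
metrics = st.metrics_long_table(diss, edge_counts=edges, volumetrics=summ)
res = st.run_comparison_suite(
    metrics, labels[["patient_id", "er_4wk", "bor_responder", "lte", "lr"]]
)
sig = res[res.significant == True]
print(len(res), "rows;", len(sig), "significant at p <= 0.05")
print(sig[["metric", "interval", "test", "p_value"]].head(8).round(4).to_string(index=False))
```

```
120 rows; 20 significant at p <= 0.05
      metric interval            test  p_value
  edge_count   t0->t1 wilcoxon_paired   0.0074
  edge_count   t1->t2 wilcoxon_paired   0.0075
  edge_count   t0->t2 wilcoxon_paired   0.0006
max_distance   t1->t2 wilcoxon_paired   0.0391
max_distance   t0->t2 wilcoxon_paired   0.0076
   n_lesions   t0->t1 wilcoxon_paired   0.0075
   n_lesions   t1->t2 wilcoxon_paired   0.0032
   n_lesions   t0->t2 wilcoxon_paired   0.0006
```

Rendering volumes and extracting first-order features:

```python
rendered = mr.render_volumes(lesions[lesions.timepoint == "t0"], cfg)
feats = mr.cohort_features(rendered)          # per patient/timepoint/site
agg = mr.aggregate_patient(feats)             # median / range / sum per patient
```

## Command line

A `metresponse` CLI mirrors the library pipeline:

```bash
metresponse simulate --out cohort/ --n-patients 20 --seed 7 --render-volumes
metresponse stratify  --lesions cohort/lesions.csv --clinical cohort/clinical.csv --out stratify/
metresponse spatial   --lesions cohort/lesions.csv --out spatial/
metresponse burden    --lesions cohort/lesions.csv --out burden/
metresponse radiomics --volumes cohort/volumes/ --out radiomics/
metresponse compare   --lesions cohort/lesions.csv --clinical cohort/clinical.csv --out compare/
```

## Limitations

See `docs/methods.md` for the full model description, parameter tables,
numerical choices and limitations. In brief: the synthetic generator
reproduces cohort-level distributional structure, not patient-specific
anatomy; rendered CT volumes carry Gaussian texture rather than
realistic parenchyma; and all statistics are reported with and without
multiplicity adjustment but interpreted at the raw 0.05 level, matching
small-cohort exploratory practice.
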