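# cranioface

Craniofacial soft-tissue statistics and coarse-to-fine facial approximation
from dry-skull surface meshes.

The toolkit quantifies craniofacial relationships on cohorts of paired
skull/face triangle meshes — dense facial soft-tissue depths (FSTDs)
measured along fixed per-point directions, and nose/mouth hard↔soft shape
covariation via high-density geometric morphometrics — and applies the
learned relationships in a coarse-to-fine pipeline that generates and
evaluates an approximated face for a new dry skull.

## Components

| Subpackage | Contents |
| --- | --- |
| `cranioface.meshkit` | PLY/OBJ mesh I/O, landmark CSVs, vertex normals, Poisson-disk semilandmark sampling, surface reconstruction, Frankfort alignment, component boundary loops |
| `cranioface.registration` | 3D thin-plate-spline warps, non-rigid ICP with stiffness schedules, hybrid TPS+NICP registration, nearest-surface semilandmark projection, closed-form similarity alignment |
| `cranioface.morphometrics` | Generalized Procrustes analysis, Procrustes distances, shape PCA, two-block PLS with RV coefficient, permutation tests, PLS extreme shapes |
| `cranioface.craniofacial_model` | FSTD measurement by ray casting, per-point depth statistics, envelope generation, organ (nose/mouth) ridge regression from hard to soft PC scores, organ LOOCV |
| `cranioface.assembly` | Boundary-curve component placement, facial statistical shape model (build/fit), Laplacian mesh refinement, the end-to-end `approximate_face` pipeline |
| `cranioface.evaluation` | Resemblance metrics (Procrustes + dense surface distance), top-k recognition rate, full-pipeline leave-one-out driver |
| `cranioface.synthetic_data` | Deterministic paired skull/face cohort generator with known depth fields, shape variation and tunable hard↔soft covariation |

## Quick start (Python)

```python
from cranioface.synthetic_data import CohortSpec, generate_cohort
from cranioface.assembly import train_pipeline, approximate_face, PipelineSettings
from cranioface.evaluation import pipeline_loocv

cohort = generate_cohort(CohortSpec(n=12, seed=0, shape_mode_sd=0.02))
report = pipeline_loocv(cohort, PipelineSettings(organ_eta=0.01))
print(report.summary())   # dense error, recognition rates, baseline comparison
```

Training expects corresponded skull/face meshes (shared template topology)
with named skull landmarks including `Lp`, `Rp`, `Lo`, `G`, which define the
Frankfort reference frame. `approximate_face` then runs: Frankfort
alignment → hybrid TPS+NICP registration of the cohort-average skull →
semilandmark projection → depth-based envelope → nose/mouth prediction →
boundary placement → SSM fitting → Laplacian refinement.

## Command line

```bash
cranioface simulate --out cohort/ --n 8 --seed 1          # synthetic cohort
cranioface loocv --cohort cohort/ --out report.json       # end-to-end LOOCV
cranioface mesh info skull.ply
cranioface mesh sample skull.ply --n-target 5000 --seed 1 --out semis.csv
cranioface mesh align skull.ply --landmarks lm.csv --out aligned.ply
cranioface register --template avg.ply --target dry.ply \
    --template-landmarks a.csv --target-landmarks b.csv --out deformed.ply
cranioface fstd measure --skull-points pts.csv --directions dirs.csv \
    --face face.ply --out depths.csv
cranioface fstd stats d0.csv d1.csv --out stats.csv
cranioface fstd envelope --skull-points pts.csv --directions dirs.csv \
    --depths stats.csv --out envelope.ply
cranioface organ loocv --cohort cohort/ --organ nose --config dense --out organ.json
cranioface approximate --skull dry.ply --landmarks lm.csv --cohort cohort/ \
    --out face.ply --dump-stages
cranioface evaluate --approx face.ply --actual truth.ply \
    --eval-approx ea.csv --eval-actual et.csv
```

Every artifact-writing command drops a `run_config.json` (arguments, seeds,
version) next to its outputs.

## File formats

- Meshes: PLY (ASCII and binary little-endian) and OBJ (`v`/`f` records),
  coordinates in millimetres.
- Landmarks: UTF-8 CSV with header `name,x,y,z`; bilateral names carry
  ` (L)` / ` (R)` suffixes.
- Component labels: CSV `vertex_index,label` over the template mesh
  (`envelope`/`nasal`/`oral` on skulls, `envelope`/`nose`/`mouth` on faces).
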