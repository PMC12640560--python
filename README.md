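# dbscompare

Comparative evaluation of computational models that predict which neural
pathways deep brain stimulation (DBS) activates.

Clinicians program a DBS system by trial and error over contacts,
polarities and amplitudes.  Image-based biophysical models promise to guide
that search, but published pipelines differ in three load-bearing ways:

* **modeling method** — a binary *volume of tissue activated* (VTA:
  threshold the E-field magnitude at a fixed isolevel, default 0.2 V/mm)
  versus a *driving force* predictor (DF: the second spatial difference of
  the extracellular potential at nodes of Ranvier along realistic axon
  trajectories, converted to per-fiber current thresholds);
* **imaging space** — the patient's own (*native*) frame versus a
  population template (*normative*) frame reached by nonlinear warping,
  where the lead must be re-straightened and the field is recomputed around
  the idealized lead;
* **anatomical representation** — *pathway* streamlines (percent of fibers
  activated) versus *structure* masks (percent overlap of the VTA with the
  subthalamic nucleus or internal capsule).

Crossing these factors gives six admissible model variants (DF is
pathway-only).  `dbscompare` implements all six on top of one
finite-difference volume conductor, generates a fully synthetic cohort
whose evoked-potential readouts are tied to a designated ground-truth
variant, and reproduces the statistical comparison machinery: per-subject
R² (squared Pearson correlation between predicted activation and
evoked-potential amplitude), paired Wilcoxon signed-rank tests with the
exact small-sample distribution, and presence/absence F-scores for the
side-effect pathway with all-zero-subject exclusion.

The two pathway constructs are the cortico-subthalamic hyperdirect pathway
(HDP, thin 4 µm fibers, therapeutic readout EP1) and the
corticospinal/bulbar tract (CSBT, large 12 µm fibers, side-effect readout
EP0, heavily zero-inflated).

## Worked example

```python
from dbscompare.cohort import CohortSpec, generate_cohort
from dbscompare.evaluate import EvalOptions, run_cohort, compare_variants
from dbscompare.fields import SolverOptions

opts = EvalOptions(vta_solver=SolverOptions(spacing=1.0, padding=7.0))
subjects = generate_cohort(CohortSpec(n_subjects=11, seed=7), eval_options=opts)
activations = run_cohort(subjects, options=opts)   # 6 variants x 11 subjects
report = compare_variants(subjects, activations)
print(report.summary[report.summary.pathway == "HDP"][["variant", "median", "q1", "q3"]])
```

prints (seed 7):

```
                    variant    median        q1        q3
1         DF-Native-Pathway  0.967701  0.961994  0.974393
3      DF-Normative-Pathway  0.957900  0.951733  0.960425
5        VTA-Native-Pathway  0.801146  0.578545  0.819282
7      VTA-Native-Structure  0.148846  0.078003  0.214362
9     VTA-Normative-Pathway  0.744672  0.570310  0.843603
11  VTA-Normative-Structure  0.351038  0.292821  0.504115
```

Each row is the median and interquartile range of the per-subject R²
between that variant's predicted HDP activation and the EP1 amplitude over
the 11 synthetic subjects.  The designated truth variant
(`DF-Native-Pathway`) sits on top; its normative counterpart is degraded by
the warp; VTA-based variants trail because a fixed E-field isolevel
misrepresents activation away from the electrode.  `report.contrasts`
holds the paired Wilcoxon p-values (e.g. 0.000977 = 2/2¹¹ when all 11
subjects favor the same variant).

The same pipeline is scriptable from the shell:

```bash
dbscompare generate --outdir cohort/ --seed 7
dbscompare run      --cohort-dir cohort/ --outdir run/
dbscompare evaluate --cohort-dir cohort/ --rundir run/ --outdir report/ --plots
```

## Layout

| module | contents |
| --- | --- |
| `dbscompare.leads` | parametric lead catalog (MDT 3387/3389, BSC 2201/2202, ABT 6172), placements, setting enumeration |
| `dbscompare.fields` | finite-difference Laplace solver, tissue/scar conductivity models, floating contacts, equivalent-circuit temporal scaling |
| `dbscompare.predictors` | VTA construction and overlap/intersection metrics; driving-force thresholds |
| `dbscompare.anatomy` | structures, pathways, NIfTI/TCK/TRK/CSV I/O, deformation fields, lead re-straightening |
| `dbscompare.cohort` | synthetic cohort generator with zero-inflated evoked potentials |
| `dbscompare.evaluate` | six-variant runner, R²/Wilcoxon/F-score statistics, comparison reports |
| `dbscompare.cli` | `dbscompare generate / run / evaluate / fixtures` |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
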