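# pharmadual

Receptor-based pharmacophore virtual screening for the discovery of dual
ROCK1/ASK1 kinase inhibitors, packaged as a tested, fully offline Python
library with a thin CLI.

Rho-associated kinase 1 (ROCK1) and apoptosis signal-regulating kinase 1
(ASK1) are two targets whose simultaneous, ATP-competitive (type I)
inhibition is a proposed strategy against non-alcoholic steatohepatitis.
A dual-target pharmacophore for their kinase domains can be expressed as
five spherical features: three hydrogen-bond acceptors (catalytic-lysine
and hinge-region contacts, Lys105/709, Tyr155–Met156 / Gln756–Val757) and
two aromatic ring centers near the catalytic domain. This package builds
that query model, screens 3D conformer libraries against it, scores the
screen with the standard enrichment statistics, filters hits for
lead-likeness and pharmacokinetics, and clusters the survivors into
scaffold families.

## What it computes

* **Model geometry** — the packaged five-feature query (`build_model11`) is
  reconstructed from its inter-feature distance matrix by classical
  multidimensional scaling; recomputed distances agree with the published
  matrix to < 0.01 Å. Features F1 (acceptor), F4 and F5 (aromatic) are
  essential; F2 and F3 are partial, with a minimum of four matched features
  per hit. Excluded volumes can be added from any receptor PDB file.
* **Matching** — per conformer: type- and distance-pruned correspondence
  enumeration, Kabsch least-squares rigid alignment, per-feature sphere
  containment, excluded-volume clash check; per compound: a hit if any
  conformer matches. The mapping RMSD is reported as the quality score.
* **Validation** — compound-level confusion matrices and the eight
  retrieval statistics Se, Sp, Ya, E, Acc, DR = Se/Sp, F1, MCC:

      Se = TP/(TP+FN)    Sp = TN/(TN+FP)    Ya = TP/(TP+FP)
      E  = Ya/(A/N)      Acc = (TP+TN)/N    F1 = 2TP/(2TP+FP+FN)
      MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

  A packaged 13-model reference benchmark (39 actives vs 1198 decoys)
  reproduces the published statistics of all thirteen candidate models and
  selects model 11 (MCC 0.711, F1 0.708) as the best performer.
* **Filtration** — the post-screening cascade: duplicate removal, Oprea
  lead-likeness (MW < 450, logP ≤ 4.5, HBA ≤ 8, HBD ≤ 5), mutagenicity
  alerts, Veber TPSA < 140 Å², logS ≥ −5, PAINS, and a BOILED-Egg-based
  pharmacokinetic gate (high GI absorption, no BBB permeation, no P-gp
  transport), with a complete per-stage removal audit.
* **Clustering** — Tanimoto similarity of Morgan fingerprints,
  complete-linkage agglomeration stopped when the largest inter-cluster
  similarity falls below 60%, seeded random representatives.
* **Synthetic benchmarks** — because the original screening corpora are not
  redistributable, `pharmadual.synthetic_data` constructs molecules from
  rigid chemical fragments whose perceived features land exactly (or at a
  controlled jitter) on the query's feature centers, plus property-matched
  decoys that provably cannot match. Ground truth is known by construction,
  so the whole pipeline is testable offline.

## Worked example

```python
from pharmadual import (build_model11, make_benchmark, screen_library,
                        confusion, metrics)

model = build_model11()
bench = make_benchmark(model, n_actives=39, n_decoys=1198, seed=42)
hits = screen_library(bench.ensembles, model)
cm = confusion(set(hits["compound_id"]), bench.library)
rep = metrics(cm)
print(f"TP={cm.TP} FP={cm.FP} FN={cm.FN} TN={cm.TN}")
print(f"Se={rep.Se:.3f} Sp={rep.Sp:.3f} E={rep.E:.2f} MCC={rep.MCC:.3f}")
```

prints

```
TP=39 FP=0 FN=0 TN=1198
Se=1.000 Sp=1.000 E=31.72 MCC=1.000
```

— a jitter-free planted benchmark is recovered perfectly: all 39
constructed actives are retrieved, none of the 1198 decoys match, and the
enrichment equals its ceiling N/A = 1237/39. Raising `jitter_sigma`
degrades sensitivity monotonically, which is how the matcher's tolerance
radii are exercised.

The same steps are available from the shell:

```sh
pharmadual model build-model11 --out model11.json
pharmadual synth benchmark --seed 42 --out fixtures/
pharmadual screen --model model11.json --library fixtures/library.sdf --out hits.csv
pharmadual validate --confusions src/pharmadual/data/reference_models_confusion.csv
pharmadual filter --in hits.sdf --out survivors.csv --report report.json
pharmadual cluster --in survivors.sdf --threshold 0.60 --seed 17 --out clusters.csv
```

## Layout

| module | role |
| --- | --- |
| `pharmacophore_core` | model types, distance-geometry embedding, model JSON I/O, excluded volumes |
| `feature_perception` | SMARTS-driven acceptor/donor perception, aromatic centroids, SDF/SMILES I/O |
| `matching_engine` | correspondence search, Kabsch alignment, containment, screening |
| `screening_validation` | confusion matrices, the eight statistics, reference table |
| `hit_filtration` | descriptors and the lead-likeness/ADME cascade |
| `clustering` | fingerprints, similarity matrices, threshold-stopped agglomeration |
| `synthetic_data` | planted benchmarks, decoys, filter panels, fixtures |

See `docs/methods.md` for the underlying model, the numerical conventions
and the known limitations of the synthetic benchmarks.
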