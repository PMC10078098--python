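# consensus-vs

A consensus virtual-screening pipeline for small-molecule libraries, built
around four sequential ligand- and structure-based criteria:

1. **Similarity** — dual-fingerprint Tanimoto screening (166-bit structural
   keys + radius-2 circular fingerprints) against a reference-active set,
   with per-fingerprint consensus cutoffs at the median plus one sample
   standard deviation of the pooled pairwise distribution.
2. **Docking post-processing** — externally produced docking scores are
   normalized by heavy-atom count (ligand-efficiency style) and filtered at
   a reference-ligand-calibrated cutoff; distance contacts against key
   binding-site residues are checked in single poses or multi-frame PDB
   ensembles.
3. **Pharmacophore** — a consensus model is built from pre-aligned reference
   binding modes (features kept when present in ≥ 70% of references) and
   candidate poses pass when they match ≥ 5 model features.
4. **ADMET** — deterministic local rules: rule-of-five violation counts,
   ESOL-style solubility classes, a bundled substructure-alert subset, and
   optional externally supplied cytochrome-inhibition flags.

Compounds passing all four criteria are ranked by normalized docking score
and the top hits are selected greedily under Bemis-Murcko scaffold
diversity. An `ecif` module additionally computes typed protein–ligand
atom-pair interaction features within a distance cutoff and fits a pluggable
(ridge / gradient-boosting) pKi regressor.

A `fixtures` module generates every input the pipeline consumes — SMILES
libraries with controlled scaffold diversity, reference actives, score
tables, planted pharmacophore pose sets, and toy multi-frame protein–ligand
complexes — with recorded ground truth, so the whole funnel is testable
offline. Toy complexes use single-atom residues (geometrically exact,
biologically abstract) and candidate poses are feature-bearing fragment
assemblies tagged with compound ids.

## CLI

```bash
# generate a synthetic input set with ground truth, then run the funnel
consensus-vs fixtures --out fx --seed 7
consensus-vs run --config fx/config.yaml --out fx/run

# individual stages
consensus-vs similarity --library lib.smi --references refs.smi --out simdir
consensus-vs dock-post --scores scores.csv --library lib.smi --reference-score -10.01 --out dockdir
consensus-vs pharmacophore --reference-poses refs.sdf --poses cands.sdf --out phdir
consensus-vs admet --library lib.smi --out admet.csv
consensus-vs contacts --complex complex.pdb --key-set colchicine --out contacts.csv
consensus-vs ecif --protein protein.pdb --ligand ligand.sdf --out ecif.csv
```

`consensus-vs run` writes `consensus.csv`, per-stage tables, a thresholds
JSON, a Markdown report and a copy of the resolved config into `--out`.
All thresholds (consensus mode, prevalence, merge radius, minimum feature
matches, ADMET policy, top-k) are overridable in the YAML config.

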