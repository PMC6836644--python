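# mcscreen

Feature-clustered classifier ensembles for ligand-based virtual screening.

`mcscreen` implements a multiple-classifier-system workflow for prioritizing
compounds against a protein target:

1. **Data model** — tab-delimited compound tables keyed by a unique compound
   id, carrying binary substructure-fingerprint bits plus discrete/continuous
   physicochemical descriptors and an optional `Active`/`Inactive` class;
   rows are randomly partitioned into evenly sized (optionally stratified)
   groups, and fingerprint bits can be selected by closeness of their
   occurrence frequency to a target (50% by default).
2. **Feature clustering** — columns are ranked by a two-class Fisher score
   within each feature type and dealt round-robin into `k` clusters
   (default 3), so each cluster mixes strong and weak features of every type.
3. **Measure-guided model selection** — for each feature-cluster, a roster of
   classifier families (logistic, SVMs, random forest, gradient boosting,
   kNN, naive Bayes, decision tree by default) is grid-searched under
   stratified cross-validation with either MCC or PPV as the objective; the
   per-cluster winners plus a voting scheme (tie-to-Active majority, or
   weighted) form one ensemble.
4. **Meta-models** — the MCC-optimized and the PPV-optimized ensembles are
   combined with an AND rule (`minimize_fp`: Active only if both agree) or an
   OR rule (`minimize_fn`: Active if either says so).
5. **Ranking** — each predicted active is scored by the product of all its
   inner-classifier Active probabilities (its *global relevance*), which
   separates candidates whose probability sums and means tie; candidates are
   sorted descending.
6. **Diversity selection** — ranked actives are leader-clustered on their
   fingerprints with a Tanimoto-distance cap (default 0.35) and the
   top-relevance member of each cluster is kept; diversity statistics
   (mean ± SD pairwise distance, distance to the training set) are reported.

A synthetic-data generator emulates the real schema (optionally at full
2048-bit/84-descriptor width) with controllable class-conditional signal, so
the entire pipeline is testable offline. Small binding-assay utilities
(Cheng–Prusoff Ki, pKi, percent specific binding, displacement-hit
classification) are included for processing validation-assay tables.

## Test

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for the
declared invariants (metric bounds/symmetries, partition properties, Jaccard
triangle inequality, relevance monotonicity), exhaustive/brute-force oracle
checks (majority voting, MCC, Tanimoto, leader clustering) and an acceptance
suite (`tests/test_acceptance.py`) covering desk arithmetic, meta-model
theorems and parameter recovery on synthetic data.

## CLI

```bash
# full pipeline on synthetic data (all artifacts into ./run)
mcscreen run --seed 1 --out run

# or step by step
mcscreen generate --seed 1 --out data.tsv
mcscreen partition data.tsv --n-groups 4 --seed 1 --out groups.json
mcscreen cluster-features data.tsv -k 3 --out clusters.json
mcscreen train data.tsv --clusters clusters.json --objective mcc --seed 1 --out mcc.joblib
mcscreen train data.tsv --clusters clusters.json --objective ppv --seed 1 --out ppv.joblib
mcscreen evaluate data.tsv --model mcc.joblib --model ppv.joblib
mcscreen screen library.tsv --model-mcc mcc.joblib --model-ppv ppv.joblib \
    --rule minimize_fp --out predictions.tsv
mcscreen rank predictions.tsv --out ranking.tsv
mcscreen chem-cluster library.tsv --ranking ranking.tsv --threshold 0.35 --out clusters.tsv
mcscreen select clusters.tsv --top 21 --out selection.tsv

# assay utilities
mcscreen pharm ki --ic50 10 --ligand-conc 1.24 --kd 1.24
mcscreen pharm binding --raw 500 --total 900 --nonspecific 100
```

`mcscreen run` accepts a YAML config (`--config`) mirroring
`mcscreen.pipeline.PipelineConfig`; defaults are 4 row groups, 3 feature
clusters, majority voting, the `minimize_fp` meta-rule, a 0.35 chem-cluster
threshold and a 21-compound selection.

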