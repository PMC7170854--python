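# hetmda

Heterogeneous-network embedding pipeline for miRNA–disease association
prediction.

A five-node-type association network (miRNA, lncRNA, protein, disease, drug)
is embedded with a k-step transition-matrix SVD method (GraRep-style
"behavior" vectors). Node "attribute" vectors — 3-mer frequency encodings of
miRNA sequences and DAG-based disease semantic-similarity profiles — are
compressed with a stacked ReLU autoencoder, fused with the behavior vectors
into per-node representations, and concatenated into pair feature vectors.
Labelled pairs (known associations plus an equal number of uniformly sampled
negatives) are classified with a Random Forest under 5-fold cross-validation;
candidate miRNAs can then be ranked per disease with training pairs excluded.

Because the real source databases are not bundled, the package ships a
first-class synthetic-study generator (`hetmda.synthetic`) that plants a
block-structured miRNA–disease signal, biased sequences, and ancestor-sharing
disease DAGs, so the entire pipeline is testable offline and seeded.

## Layout

| module | contents |
|---|---|
| `hetmda.hetnet` | typed edge-list loading, de-duplication, node ordering, adjacency matrix |
| `hetmda.attributes` | 3-mer frequency vectors, disease DAG semantic value/similarity |
| `hetmda.grarep` | transition matrix, k-step powers, shifted log-probability matrix, truncated SVD embedding |
| `hetmda.autoencoder` | greedy layer-wise stacked ReLU autoencoder (numpy + Adam, seed-deterministic) |
| `hetmda.assoc_model` | feature fusion, negative sampling, k-fold CV, metrics (Acc/Prec/Sen/Spec/MCC/AUC/AUPR), candidate ranking |
| `hetmda.synthetic` | seeded synthetic studies with recoverable held-out truth |
| `hetmda.pipeline` | stage orchestration with content-hash skipping, YAML config, CLI |

## CLI

All stages are subcommands of `hetmda` (or `python -m hetmda.pipeline`):

```sh
# generate a synthetic study
hetmda simulate --out data/

# individual stages
hetmda build-net --config net.yaml --out net/
hetmda embed --net net/ --K 4 --dim-per-order 16 --seed 42 --out emb.tsv
hetmda featurize --net net/ --fasta data/mirna.fasta --dag data/disease_dag.tsv \
    --embeddings emb.tsv --out features/
hetmda cv --features features/ --positives data/positives.tsv \
    --classifier RandomForest --mode both --k 5 --seed 42 --report report.json
hetmda predict --features features/ --positives data/positives.tsv \
    --disease dis0001 --top 50 --out ranked.tsv

# or everything at once, with hash-gated stage skipping on re-runs
hetmda run-all --config run.yaml --seed 42 --out workdir/
```

A minimal `run.yaml` for an end-to-end synthetic run:

```yaml
seed: 1
simulate: {}          # default synthetic study; omit to use your own inputs
embed: {K: 4, d: 16}
sae: {hidden_sizes: [64], epochs: 100, lr: 0.001}
cv: {classifier: RandomForest, mode: both, k: 5}
```

The CV report (`report.json`) lists per-fold Acc, Prec, Sen, Spec, MCC, AUC
and AUPR plus their mean ± std.

### Input formats

- edge lists: one TSV per association class, `source_id<TAB>target_id`
  (nine classes: mirna-lncrna, mirna-protein, mirna-disease, lncrna-disease,
  lncrna-protein, drug-disease, drug-protein, protein-protein,
  protein-disease);
- miRNA sequences: FASTA (record ids must match network node ids; `T` is
  normalized to `U`);
- disease hierarchy: TSV of `child_id<TAB>parent_id` rows; each disease's DAG
  is its transitive ancestor closure;
- positives: TSV of `mirna_id<TAB>disease_id`.

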