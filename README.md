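# hypermet

Predicting metabolite–disease associations from heterogeneous biological
knowledge, using a **disease-as-hyperedge hypergraph**.

Metabolomics databases record which metabolites, proteins, and Gene
Ontology (GO) terms are linked to which diseases, but the catalog of
confirmed metabolite–disease associations is far from complete.
`hypermet` is a toolkit for researchers who want to prioritize candidate
associations computationally: it encodes each disease as one hyperedge
over *all* of its associated molecular entities, learns embeddings for
every entity from that structure, and scores disease–metabolite pairs
with a gradient-boosted tree classifier.

## The model

Let `V` be the union of metabolites, proteins, and GO terms, and let each
disease `e` be a hyperedge — the subset of `V` associated with it.  The
binary incidence matrix `H ∈ {0,1}^{|V|×|E|}` has `H(v,e) = 1` iff vertex
`v` belongs to hyperedge `e`.  The pipeline is:

1. **Per-type similarity features.** Metabolites: Tanimoto coefficient
   `Tc(A,B) = |A∩B| / |A∪B|` over hashed circular (Morgan) fingerprints.
   Proteins: pairwise sequence alignment (BLOSUM62, affine gaps, open 11 /
   extend 1), normalized by aligned-identity fraction or min–max of raw
   scores.  GO terms: ancestor-set Jaccard over the `is_a`/`part_of` DAG.
   Every matrix is symmetric, unit-diagonal, and in [0, 1].
2. **Autoencoder reduction.** Each type's similarity rows are compressed
   to a shared width *d* so all vertices live in one feature space.
3. **Spectral hypergraph smoothing.** Two message-passing layers
   `X ← ReLU(Θ X W)` with the degree-normalized operator

   ```
   Θ = D_v^{-1/2} H W_e D_e^{-1} Hᵀ D_v^{-1/2},   W_e = I
   ```

   trained self-supervised (hyperedge-membership reconstruction) with
   Adam, dropout, L2 weight decay, and early stopping on a held-out
   validation split.  Disease hyperedge embeddings are the mean of their
   member vertex embeddings.
4. **Pair classification.** A disease–metabolite pair is the
   concatenation `[z_disease ‖ z_metabolite]` (width 2*d*), classified by
   a leaf-wise gradient-boosted tree ensemble (LightGBM, leaf L2 = 0.1,
   otherwise defaults) at threshold 0.5.
5. **Filtered negative sampling & evaluation.** Negatives are drawn
   uniformly from the disease × metabolite grid, excluding known
   positives *and* any pair joined by a two-hop
   metabolite–protein–disease path (likely undiscovered positives).
   Evaluation is stratified k-fold cross-validation reporting ACC, SEN,
   SPE, PRE, MCC, AUC, and AUPRC with 95% CIs (`1.96·SD/√k`).

Because no public download is assumed, the package ships a seeded
synthetic-world generator with planted module structure: within-module
associations, fingerprints, sequences, and GO subtrees are correlated, so
the whole pipeline is testable end-to-end and the planted signal is
recoverable.

## Worked example

```python
import hypermet as hm

world = hm.generate_world(hm.SynthConfig(seed=1))       # 50 diseases, 300 metabolites
result = hm.run_experiment(world, hm.PipelineConfig(seed=1))
print(f"pairs: {int(result.pairs.labels.sum())} positive / "
      f"{int((1 - result.pairs.labels).sum())} negative")
for name in ("ACC", "SEN", "SPE", "PRE", "MCC", "AUC", "AUPRC"):
    print(f"{name:>6}: {result.report.mean[name]:.4f} "
          f"± {result.report.ci95[name]:.4f}")
```

prints

```
pairs: 430 positive / 430 negative
   ACC: 0.9279 ± 0.0196
   SEN: 0.9419 ± 0.0360
   SPE: 0.9140 ± 0.0171
   PRE: 0.9164 ± 0.0149
   MCC: 0.8569 ± 0.0398
   AUC: 0.9693 ± 0.0095
 AUPRC: 0.9578 ± 0.0174
```

i.e. on a 1:1-balanced pair set from the planted world, 5-fold
cross-validation recovers the module structure almost perfectly (AUC
0.97), with each `±` the 95% CI half-width over folds.  A label-permuted
control run collapses to AUC ≈ 0.5, confirming the signal comes from the
planted structure rather than the evaluation machinery.

The same study is scriptable from the shell:

```bash
hypermet simulate --seed 1 --out world/
hypermet embed    --world world/ --out emb/ --seed 1
hypermet sample   --world world/ --out pairs/ --ratio 1 --seed 1
hypermet train    --embeddings emb/ --pairs pairs/pairs.tsv --out model/ --seed 1
hypermet evaluate --embeddings emb/ --pairs pairs/pairs.tsv \
                  --model model/model.txt --out report/ --seed 1
hypermet sweep    --world world/ --embeddings emb/ --out sweep/ --seed 1
hypermet rank     --embeddings emb/ --model model/model.txt \
                  --disease D0007 --out ranked.tsv
```

All inputs and outputs are flat text (TSV / FASTA / OBO / JSON); every
output directory gets a `log.json` with the seed, config hash, and
library versions.

## Layout

- `src/hypermet/hypergraph.py` — incidence matrix, degrees, statistics
- `src/hypermet/similarity.py`, `godag.py` — the three similarity notions
- `src/hypermet/autoencoder.py`, `hgnn.py`, `optim.py` — feature
  reduction and hypergraph message-passing (NumPy, hand-derived gradients)
- `src/hypermet/association.py` — negative sampling, pair features,
  boosted classifier
- `src/hypermet/evaluation.py` — metrics, CV, CIs, ratio sweep
- `src/hypermet/synthetic.py` — planted-world generator and toy fixtures
- `src/hypermet/io.py`, `cli.py`, `pipeline.py` — formats, CLI, orchestration

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
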