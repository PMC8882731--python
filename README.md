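# methylvote

Prediction of DNA N6-methyladenine (6mA) sites in plant genomes by a
majority-voting ensemble over fixed-length sequence windows.

6mA is a common epigenetic mark — a methyl group on the N6 position of
adenine — involved in DNA replication, repair and defense against
foreign DNA. Experimental detection (SMRT sequencing, restriction-based
enrichment) is slow and expensive, so sequence-based classifiers are
used to call candidate sites genome-wide. `methylvote` is for
bioinformaticians who have 41-nt DNA windows centered on a candidate
adenine (the standard framing of plant 6mA benchmarks) and want a
reproducible train/predict/evaluate cycle, including a synthetic-data
generator so the whole pipeline can be exercised without any downloads.

## The method

Each window *D* = d₁…d₄₁ (alphabet {A,C,G,T,N}, central base A) is
encoded by one of six descriptors:

- **One-hot2** (the default): each of the 40 overlapping dinucleotides is
  mapped to a 25-bit indicator (codebook AA→0, AC→1, …, NN→24),
  concatenated into a 1000-dimensional 0/1 vector.
- **One-hot1**: per-nucleotide 5-bit indicators (205 dims for 41 nt).
- **AMNF / ADNF**: accumulated mono-/di-nucleotide frequencies — element
  *t* is the frequency of the current (di)nucleotide within the prefix
  ending at *t* (e.g. ACGTNA → (1, 0.5, 0.33, 0.25, 0.2, 0.33) under AMNF).
- **DPCP / TPCP**: per-k-mer counts times tabulated physicochemical
  property values, xPCPᵢⱼ = Nᵢ · xPCᵢⱼ, flattened token-major
  (25×15 and 125×11 with the bundled tables).

The encoded training set is fed to five base learners — random forest
(RF), linear discriminant analysis (LDA), a one-hidden-layer perceptron
(MLP), a linear SVM fit by stochastic gradient descent (SGD), and
gradient-boosted trees (XGB) — each optionally tuned by exhaustive grid
search under stratified cross-validation. A window is called positive
when **at least 3 of the 5** learners vote positive. Performance is
reported as

    ACC = (TP+TN)/N,   SN = TP/(TP+FN),   SP = TN/(TN+FP),
    MCC = (TP·TN − FN·FP) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

## Worked example

`examples/03_train_and_evaluate.py` simulates 1000 positive and 1000
negative 41-nt windows whose positives carry 21 position-specific
nucleotide enrichments at strength 0.5, trains the ensemble on 80% and
scores the held-out 20%:

```
per-learner held-out accuracy:
  RF   0.938
  LDA  0.897
  MLP  0.915
  SGD  0.915
  XGB  0.940

majority-vote ensemble: ACC=0.932  MCC=0.865  SN=0.935  SP=0.930
```

ACC is the fraction of held-out windows called correctly; MCC is the
correlation between true and predicted labels (0 = chance, 1 = perfect);
SN and SP are the recalls on the 6mA and non-6mA classes. The other
examples cover encoding (`01`), simulation and cleaning (`02`), and a
full encoder × classifier cross-validation sweep (`04`) in which the
position-aware encoders clearly outrank the density- and property-based
ones — the planted signal is positional, and One-hot encodings are the
ones that can see it.

File-based workflows (FASTA in, TSV/JSON out, with provenance records)
live in `methylvote.pipeline`: `simulate`, `train`, `predict`,
`evaluate`.

## Reference computations

`scripts/acceptance.py` recomputes the package's reference encoder
quantities from scratch — the accumulated-frequency vectors of the toy
sequence ACGTNA and the One-hot2 dimensionalities for 6-nt and 41-nt
windows — and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Scope notes

Benchmark datasets of real plant genomes (Rosaceae/rice/Arabidopsis
6mA collections) are third-party downloads and are not bundled; point
`pipeline.train`/`evaluate` at their FASTA files to reproduce full-scale
results. Upstream redundancy reduction (CD-HIT) and database extraction
are out of scope, as are soft/weighted voting, stacking, and
deep-learning baselines.
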