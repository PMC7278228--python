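# localspace

Exploring the *local chemical space* around known active molecules with a
character-level recurrent SMILES generator, and iteratively enriching that
space by virtual screening.

## The problem

Medicinal chemists often need molecules that are **novel but similar** to a
small set of known inhibitors — the neighborhood of a lead compound, not the
whole of drug-like space. `localspace` implements a complete pipeline for
this:

1. **Corpus preparation** — molecules are sanitized, stripped of
   stereochemistry, deduplicated, and augmented by *randomized SMILES*:
   each molecule's atom order is permuted at random so one structure yields
   many training sequences.
2. **Generative model** — a two-layer LSTM language model over a fixed
   37-token SMILES alphabet. Sequences are newline-terminated, concatenated
   without padding, and served as 128 parallel streams of 64 time steps
   with next-token targets; recurrent state is carried across chunks.
   Training minimizes sequence cross-entropy with Adam (lr 0.003) under
   global gradient-norm clipping at 5; dropout (keep 0.8) is applied to
   each LSTM layer's output. The model is pure NumPy and runs on one CPU.
3. **Transfer learning** — the generator is pretrained on a large generic
   corpus, then fine-tuned on a handful of target molecules so that
   sampling (200,000 tokens drawn autoregressively from the softmax,
   starting at "\n") concentrates near the targets.
4. **Chemical-space analytics** — radius-3 circular (Morgan) fingerprints,
   Tanimoto similarity (|A∩B|/|A∪B| over on-bits), exact
   nearest-training-neighbor reports, t-SNE projections of 1024-bit hashed
   fingerprints, and k-medoids clustering under Tanimoto distance on the
   feature-class fingerprint variant.
5. **Iterative screening loop** — fine-tune on seed molecules (30 epochs,
   sampling every 10), pool and deduplicate the samples, screen them with
   any pluggable `Screener`, retain the top 50% by score, cluster the
   retained set into 7 catalogs, and use the cluster medoids as the next
   round's seeds (20 epochs). Commercial pharmacophore/docking models are
   deliberately out of scope: the `Screener` interface (similarity-to-
   reference, descriptor-window, or an external command) stands in for any
   scoring model, and classifier quality is measured with
   specificity = TN/(TN+FP), sensitivity = TP/(TP+FN) and rank AUC.

Everything runs offline: a fragment-grammar fixture generator produces
valid, tokenizable drug-like SMILES so no database download is required.
Real corpora (ChEMBL inhibitor sets, DrugBank, vendor catalogs) can be fed
in as plain SMILES or CSV files.

## Worked example

```bash
localspace fixture corpus --n 100 --seed 7 --out corpus.smi
localspace prep standardize corpus.smi clean.smi
localspace gen train --config src/localspace/configs/tiny.yaml \
    --smiles clean.smi --epochs 15 --seed 0 --out ckpt.npz
localspace gen sample --ckpt ckpt.npz --tokens 2000 --seed 1 --out sampled.smi
```

which prints, for the sampling step:

```
2000 tokens -> 83 sequences, 10 valid unique (73 invalid, 0 duplicate)
```

i.e. the 2,000 sampled tokens split into 83 newline-delimited sequences, of
which 10 parsed to distinct valid molecules and 73 were chemically invalid
(validity rises sharply with more pretraining epochs and a larger corpus;
15 epochs on 100 molecules is deliberately quick). The same checkpoint can seed a screening campaign:

```bash
localspace screen campaign --ckpt ckpt.npz --seeds seeds.smi \
    --reference reference.smi --threshold 0.2 --rounds 2 \
    --config src/localspace/configs/tiny.yaml --seed 0 --out rundir/
```

`rundir/` then contains per-round retained molecules, cluster centers,
nearest-seed similarity reports and a `manifest.json` with every seed and
input hash. The library equivalents (`localspace.screening.run_campaign`
etc.) expose the same functionality with full programmatic control; the
full-scale protocol configuration ships as `configs/full.yaml`.

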