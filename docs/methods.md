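# Methods

## Model

The generator is an autoregressive character-level language model over
SMILES. The alphabet is fixed at 37 tokens: the aromatic/aliphatic organic
atoms (c, C, n, N, o, O, s, S, p, P, F, I), ring-closure digits 1–8, the
bond/branch/charge punctuation (-, +, [, ], (, ), =, #), the "\n" sequence
terminator, and eight multi-character symbols ([nH], [S+], [O-], [N+],
[N-], Br, Cl, Si). Tokenization is greedy longest-match, so "Br"/"Cl"/"Si"
and the bracket atoms are matched before their single-character prefixes;
a SMILES containing anything else (e.g. "%"-ring closures, boron,
stereo markers that survive standardization) is rejected as untokenizable
rather than the alphabet being extended, keeping the softmax head fixed.

Architecture: two stacked LSTM layers (forget-gate bias 1.0), inverted
dropout with keep probability 0.8 on each layer's upward output (the
recurrent path is never dropped), and a dense softmax head. One-hot input
times the first weight matrix is implemented as row selection. Hidden
width is 256 for directly trained models and 512 for the pretrained
transfer model; the benchmark configuration uses 64.

Training: corpora are shuffled once per run (seeded), newline-terminated,
and concatenated without padding into one token stream. The stream is cut
into `n_streams` (default 128) contiguous segments and served as
`n_streams × chunk_len` (default 64) blocks whose targets are the inputs
shifted by one token in the stream; `floor(L / (n_streams·chunk_len))`
blocks are served per epoch and the leftover tail is ignored. The single
stream position with no successor (when the tail is empty) receives the
"\n" terminator as target — a sequence boundary is the only neutral
choice. Recurrent state starts at zero each epoch and is carried across
consecutive blocks; gradients are truncated at block boundaries
(truncated BPTT, matching how a dynamic RNN trains on fixed-length
chunks). The loss is mean next-token cross-entropy with the probability
floored at 1e-12; optimization is Adam (lr 0.003, β₁ 0.9, β₂ 0.999,
ε 1e-8) after clipping the global gradient norm at 5. Weight matrices are
Glorot-uniform initialized (seeded); biases start at zero. The analytic
backward pass is verified against central finite differences in the test
suite.

Sampling: one continuous autoregressive run — "\n" and a zero state start
the chain; each next token is drawn from the softmax at temperature 1
(no top-k/nucleus truncation); exactly `token_budget` tokens (default
200,000) are drawn. The run is split at "\n"; a trailing unterminated
fragment is discarded and counted; fragments are parsed with RDKit,
canonicalized, and deduplicated, with invalid and duplicate counts kept
for reporting. "Convergence" in the fine-tuning schedules is
operationalized as the fixed epoch budgets (50 pretrain / 30 round 1 /
20 later rounds), not an early-stopping rule.

## Molecule standardization

All input molecules are sanitized by RDKit; the largest fragment of a
multi-fragment (salt) input is kept, since the alphabet has no "."
separator; **all** stereochemistry is removed — both tetrahedral centers
and double-bond geometry — because the alphabet has no stereo symbols and
partially stereo-annotated corpora would be untrainable. The canonical
achiral SMILES is the molecule's identity key throughout (deduplication,
similarity reports, screening). Randomized-SMILES augmentation writes a
configurable number of random-atom-order variants per molecule (default
10 per corpus build); variants may collide on small molecules. Corpus
loading drops unparsable entries with a logged count by default; a strict
flag aborts instead.

The drug-likeness prefilter retains molecules with zero Lipinski
violations (MW ≤ 500 Da, logP ≤ 5, H-bond donors ≤ 5, acceptors ≤ 10),
zero Veber violations (rotatable bonds ≤ 10, TPSA ≤ 140 Å²) and MW above
a floor (default 300 Da).

## Chemical-space analytics

Similarity uses radius-3 circular (Morgan) fingerprints. Nearest-neighbor
reports use the binary on-bit sets of the unhashed fingerprint and are
exact brute force (no approximate indexing). 2-D maps use t-SNE on the
1024-bit hashed vectors (scikit-learn; perplexity 30, auto-reduced to
(n−1)/3 for small n; seeded). Clustering into catalogs uses the
feature-class (pharmacophoric-invariant) variant of the radius-3
fingerprint under Tanimoto distance with partition-around-medoids:
k-medoids++-style seeded initialization, alternating assignment and
medoid updates, medoid = member minimizing summed distance with ties
broken by input order. The commercial descriptor this emulates has
unpublished bit semantics, so the contract is clustering behavior
(planted-partition recovery, medoid properties), not bit equality.

## Screening loop

One round: (1) write `n_variants` randomized SMILES per seed molecule and
mix them; (2) fine-tune the pretrained generator (30 epochs in round 1,
20 later, sampling every 10 epochs with the full token budget each time);
(3) pool the sample batches' valid unique molecules and deduplicate
before screening; (4) a molecule passes iff every screener passes it;
(5) score passers with the designated scorer and retain the top fraction
(default 50%, `ceil` on odd counts, stable descending sort so ties keep
input order); (6) cluster the retained set into k = 7 catalogs and take
the medoids as the next round's seeds. If fewer than 7 molecules are
retained, k is reduced to the retained count with a warning; a round with
zero passers ends the campaign with a diagnostic. Round 2 uses the same
retention cut as round 1.

Screeners are pluggable: similarity-to-reference (score = Tanimoto to a
reference molecule), descriptor windows, or an external command exchanging
smiles,id,score CSV. Classifier evaluation reports the confusion counts,
specificity TN/(TN+FP), sensitivity TP/(TP+FN), and the rank AUC (the
probability a random active outscores a random inactive, ties ½) —
computed via scikit-learn and cross-checked against all-pairs enumeration
in the tests.

## Synthetic benchmark

The fixture generator assembles molecules from a fragment grammar — seven
ring cores (benzene, pyridine, pyrazine, thiophene, pyrrole, cyclohexane,
piperidine), ten linkers and eighteen terminals, nested at most one ring
deep — restricted to the 37-token alphabet. Every grammar molecule is
valid and tokenizable by construction (asserted at generation). Planted
structure for tests: duplicates (rewritten in a different atom order),
untokenizable-but-valid boron molecules, and homologous series (oligoamide
vs thioether chains) whose interior repeat units contribute identical
radius-3 environments, giving within-group binary Tanimoto ≈ 1 and
between-group ≈ 0.05.

The generator emulates corpora of short drug-like molecules with realistic
token statistics. It does **not** emulate real bioactivity landscapes,
scaffold diversity at database scale, or measurement noise in activity
labels — so passing benchmarks demonstrate that the pipeline's mechanics
(training, transfer, screening, enrichment) behave as designed, not that
any particular screener will find actives in the wild.

Benchmark scale: the test suite and the reproduction script run the full
pipeline with a 64-unit model, 8 streams × 16 steps, a 200-molecule
synthetic corpus (4 randomized variants per molecule, 30 pretraining
epochs) and 2,000-token sampling budgets — the same pipeline code paths
as the full-scale configuration (`configs/full.yaml`), at sizes chosen
so the complete benchmark runs in minutes on one CPU. The mock screening
benchmark seeds the loop with 1 active-like + 6 inactive-like molecules
and scores with Tanimoto to a hidden close homolog of the active seed,
pass threshold 0.2: with a zero threshold the retention cut alone must
carry the enrichment signal, which at benchmark scale is dominated by
sampling noise in the small generated pools; 0.2 mirrors the fact that a
real screening model rejects most of chemical space outright. 30
pretraining epochs (scaled from the full protocol's 50) make sampled
validity stable across initialization seeds where 15 was not.

## Known limitations

- Pure-NumPy training is practical up to mid-sized corpora but slower
  than GPU frameworks at the full 512-unit, multi-million-token scale.
- The alphabet cannot express boron, selenium, %-ring closures, isotopes
  or charges beyond the eight bracket tokens; such molecules are dropped
  at load, which slightly biases what the model can learn from permissive
  corpora.
- k-medoids uses a dense n×n distance matrix — fine for retained sets of
  thousands, not for millions.
- Enrichment on the mock benchmark is directional evidence only; absolute
  enrichment depends entirely on the screener plugged in.
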