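# bescreen

Toolkit for **base-editor self-targeting screens**: simulate them with known
ground truth, quantify editing from reads or count tables, and train
attention-based models that predict editing outcomes per protospacer.

CRISPR base editors (ABE class: A•T→G•C; CBE class: C•G→T•A) edit within a
~5-nt window of the 20-nt protospacer, with efficiency that varies strongly
across target sequences — driven by position in the window and by the
trinucleotide context of the substrate base. Self-targeting screens measure
this at scale by pairing each sgRNA with its own target sequence on one
construct and sequencing the target. This package implements the full
downstream path for such screens, for people who design base-editing
experiments or study deaminase sequence preferences:

1. **Quantification** (`screen_proc`): exact-match read assignment on the
   designed 6+20+3+6 bp read geometry, per-position editing percentages
   (`100 × edited reads at position / total reads`), overall editing
   percentages, depth ≥ 100 and above-mean-efficiency locus filters,
   per-position activity profiles and trinucleotide-motif tables.
2. **Per-base model** (`perbase`): a Transformer-style classifier —
   nucleotide + position embeddings, multi-head self-attention encoder
   layers, and a position-attention output block — that scores each
   substrate base with the probability that it is edited
   (dichotomized against the library mean), evaluated by AUC/AUPR across
   stratified train/test/validation runs against a per-position Bernoulli
   majority-class baseline.
3. **Bystander model** (`bystander`): an encoder–decoder with masked
   self-attention and cross-attention that predicts the normalized
   probability of *every* canonical-transition outcome sequence (wild type
   included), capturing co-occurrence of target and bystander edits; an
   edited-only mode renormalizes over non-wild-type outcomes.
4. **Interpretation** (`interpret`): mean-aggregated attention maps per
   queried substrate position over sequences predicted to be edited there.
5. **Simulator** (`screen_sim`): screens with negative-binomial coverage,
   replicate noise on the logit scale, and packaged editor profiles
   (ABEmax-, CBE4max-, ABE8e- and Target-AID-like: window peaks at
   position 6 / 6 / 6 / 3, context preferences such as preceding-T
   enrichment) so every stage is testable by parameter recovery without any
   external data.

Positions are 1-based and counted from the PAM-distal end throughout. The
models run on a small numpy autodiff engine (`bescreen.nn`) — no GPU or
deep-learning framework required.

## Worked example

Simulate an ABEmax-like screen, quantify it, and profile the editing window:

```sh
$ bescreen simulate --editor ABEmax-like --n-targets 500 --depth-mean 1000 \
      --seed 11 --out-dir screen
simulated 500 targets x 2 replicates -> screen
$ bescreen quantify --counts screen/counts_rep1.tsv --counts screen/counts_rep2.tsv \
      --library screen/library.tsv --editor ABE --out efficiency.tsv
quantified 500 targets -> efficiency.tsv
$ bescreen profile --efficiency efficiency.tsv --out profile.tsv
argmax position: 6
```

`profile.tsv` holds the mean A→G editing percentage per protospacer
position over the filtered loci (depth ≥ 100, overall efficiency above the
library mean — here 223 of 500 loci):

```
position  mean_efficiency_pct
3         0.77
4         1.75
...
6         <maximum>
```

The argmax at position 6 recovers the simulated editor's activity-window
peak. The motif table shows its context preference — `TAC` (T preceding
the edited A, C following) is the most frequent motif among edited bases:

```sh
$ bescreen motifs --counts screen/counts_rep1.tsv --counts screen/counts_rep2.tsv \
      --library screen/library.tsv --editor ABE --out motifs.tsv
$ sort -t$'\t' -k2 -rn motifs.tsv | head -3
TAC   0.260
TAG   0.192
TAA   0.158
```

From here, `bescreen dataset` builds the dichotomized per-base dataset
(unedited targets added 1:4, ~80/10/10 stratified splits over 5 runs),
`bescreen train-perbase` / `train-bystander` fit the models,
`bescreen predict` scores new protospacers (FASTA in, TSV out),
`bescreen evaluate` reports AUC/AUPR and per-position accuracy against the
majority baseline, `bescreen attention` writes aggregated attention maps,
and `bescreen benchmark` correlates any two outcome-proportion tables in
the common schema. The same functionality is available as a library;
see `docs/methods.md` for the models, assumptions and design choices.

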