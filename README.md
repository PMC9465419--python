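# nesubtype

Rank-based gene-pair subtyping of lung neuroendocrine (NE) tumors.

Lung cancers split into NE tumors — small-cell lung cancer (SCLC),
large-cell neuroendocrine carcinoma (LCNEC) and carcinoid (CARCI) — and
non-NE tumors (adenocarcinoma, squamous cell carcinoma).  The subtypes need
different treatment, but morphology-based diagnosis is hard on small
biopsies and FFPE material, and quantitative expression signatures break
down under batch effects and RNA degradation.  `nesubtype` implements a
*qualitative* alternative: classification from **within-sample relative
expression orderings (REOs)** of gene pairs.

For a gene pair (G<sub>a</sub>, G<sub>b</sub>), only the ordering
E<sub>a</sub> &gt; E<sub>b</sub> vs E<sub>a</sub> ≤ E<sub>b</sub> inside one
sample is used.  This statistic is invariant to any strictly increasing
per-sample transformation, so it survives normalisation choices, platform
differences and partial degradation.  A *signature* is a set of pairs, each
voting for its positive class when E<sub>a</sub> &gt; E<sub>b</sub>; a
sample is called positive when a strict majority of the evaluable pairs vote
that way.  Pairs touching undetected genes simply drop out of the vote.  A
*panel* chains three binary signatures into a decision tree:

```
sample ── NE-signature ──(negative)── non-NE
              │(positive)
          CARCI-signature ──(positive)── CARCI
              │(negative)
          SCLC-signature ──(positive)── SCLC
              │(negative)
            LCNEC
```

The package ships the published 92-pair panel (22 NE + 30 CARCI + 40 SCLC
pairs, Entrez-keyed) as a built-in resource, plus the complete discovery
pipeline for training new signatures from labelled data:

1. **Candidate genes** — pooled-variance two-sample *t* test per gene,
   Benjamini–Hochberg FDR &lt; 5%, top 1,000 by |log₂ fold change|.
2. **Reversed pairs** — two-sided Fisher exact test on the 2×2 table of
   GT/LE pattern counts per group, BH FDR &lt; 5%, pairs oriented so GT is
   the positive-class pattern.
3. **Scoring** — apparent accuracy `S/N × 100` (concordance of the
   single-pair predictor with the reference labels) and, as tie-break,
   R̄<sub>ab</sub> = R̄<sub>ab</sub>(g₁) × R̄<sub>ab</sub>(g₂), the product
   over the two groups of the geometric mean of |rank(G<sub>a</sub>) −
   rank(G<sub>b</sub>)| within each sample.
4. **De-redundant selection** — greedy scan in score order keeping a pair
   only when neither gene is taken, so each gene sits in at most one pair.
5. **Label cleaning (optional)** — consensus clustering (resampled Ward
   clustering on Pearson-correlation distance over the most variable genes)
   flags samples whose cluster contradicts their pathological label before
   each training step.

A seeded synthetic-data generator plants reversed pairs with known truth so
every stage is testable offline.

## Worked example

`examples/01_classify_with_builtin_panel.py` builds three archetype samples
over the panel's 184 genes and classifies them:

```
biopsy_A: NE-signature 0/22 => non-NE
biopsy_B: NE-signature 22/22 -> CARCI-signature 30/30 => CARCI
biopsy_C: NE-signature 22/22 -> CARCI-signature 0/30 -> SCLC-signature 40/40 => SCLC
```

Each line is a sample's path through the decision tree: `22/22` means all 22
evaluable NE pairs voted NE, so the sample advances; `0/30` means no CARCI
pair voted CARCI, so it falls through to the SCLC vs LCNEC step.

`examples/02_discover_signature.py` trains a signature on simulated data
(30 + 30 samples, 15 planted reversed pairs among 300 genes):

```
DE genes (FDR < 5%):      31
candidate genes:          31
significant pairs mined:  260
signature size:           15 pairs
planted genes recovered:  30/30
training sensitivity:     100.00%
training specificity:     100.00%
```

All 30 planted genes are recovered and the training concordance is perfect,
as expected for a separable construction.  `03_consensus_label_cleaning.py`
and `04_dropout_robustness.py` demonstrate mislabel flagging (15/15 planted
swaps caught) and graceful degradation under missing data (97.5% accuracy at
50% random dropout).

The same operations are available from the shell:

```sh
nesubtype classify --expr expr.tsv --panel builtin --out results/
nesubtype train    --expr expr.tsv --labels labels.tsv --out model/
nesubtype simulate --config sim.yaml --seed 1 --out data/
nesubtype evaluate --pred results/predictions.tsv --labels labels.tsv \
                   --positive-label SCLC
```

## Layout

- `src/nesubtype/model.py` — domain types (matrix, pair, signature, panel)
- `src/nesubtype/io.py` — TSV/JSON readers and writers, built-in panel
- `src/nesubtype/classify.py` — pair votes, majority calls, panel routing
- `src/nesubtype/discovery.py` — DE screen, pair mining, scoring, selection
- `src/nesubtype/consensus.py` — consensus clustering, discordance filter
- `src/nesubtype/synthetic.py` — planted-truth data generator
- `src/nesubtype/cli.py` — `nesubtype` command-line tool
- `docs/methods.md` — modelling assumptions, parameters and limitations
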