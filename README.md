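# sascreen

Analysis suite for pooled SaCas9/sgRNA activity screens in bacteria.

SaCas9 cleaves DNA targets flanked by a 5'-NNGRRN-3' PAM. Pooled screens
measure per-guide activity genome-wide: in a two-plasmid *enrichment* screen
active guides clear a toxic plasmid and rise in frequency, while in a
chromosomal *depletion* screen active guides kill their host and fall.
`sascreen` turns such screens into quantitative activity scores, learns a
sequence-to-activity model, and dissects what drives cleavage — including an
epigenetic effect: adenine methylation of GATC motifs lying across PAM
positions 4-6 and the [+1] flank suppresses SaCas9 activity roughly ten-fold.

The pipeline covers:

- **Target scanning & curation** — NNGRRN PAM scanning on both strands,
  spacer/flank extraction, count- and off-target-based filters.
- **Counting** — barcode demultiplexing of merged amplicon reads and exact
  spacer counting into `sgRNA × replicate` tables.
- **Compositional scoring** — Dirichlet Monte-Carlo CLR transformation of
  count tables into effect sizes. With Dirichlet(counts + ½) posterior draws
  x, CLR(x)_i = log2 x_i − mean_j log2 x_j, and the activity score is the
  median between-condition CLR difference (diff.btw), sign-flipped for
  depletion screens.
- **Modelling** — a dual-branch CNN / bidirectional-GRU / dense regressor
  over one-hot DNA windows (spacer + PAM + downstream flanks), with
  deterministic 80/20 splitting, five-fold cross-validation, and a nested
  input-window scan that measures what flanking context adds. The network
  runs on a small self-contained autodiff core (`sascreen.nn`).
- **Feature & methylation association** — positional single/dinucleotide
  mean-activity tables, PAM[4,5,6,+1] tetranucleotide groups, bedMethyl
  parsing, the 75% both-strand methylation rule, and PAM-relative GATC
  annotation categories.
- **Kinetics** — nonlinear least-squares fits of s(t) = s0·e^(−k_obs·t) to
  in vitro cleavage time courses and DAM(+)/DAM(−) fold-change reports.
- **Synthetic data** — a generator that plants known sequence and
  methylation effects so every stage is testable end-to-end without
  external data.

## Worked example

Simulate a depletion screen with planted effects, score it, and check that
the methylated-GATC PAM penalty is recovered:

```python
import numpy as np
from scipy import stats
import sascreen as sa

screen = sa.simulate_screen(
    n_sites=2000, genome_bp=120_000, seed=7,
    effects=sa.EffectModel(pam6_T_bonus=1.0, plus1_pyrimidine_bonus=0.5,
                           gatc_pam_penalty=-3.32, noise_sd=0.3, seed=8),
    design=sa.ScreenDesign(mode="depletion", read_depth=1_000_000),
)
scored = sa.score_table(screen.counts, "depletion", n_instances=128, seed=3)

truth = [screen.truth[i] for i in scored.index]
print("score vs planted truth Spearman:",
      round(stats.spearmanr(scored.activity, truth).statistic, 3))

ann = sa.annotate_sites(screen.sites, screen.methylome)
per_gen = dict(zip(scored.index, scored.activity / screen.design.generations))
penalty = sa.methylation.matched_register_contrast(screen.sites, ann, per_gen)
print("recovered GATC-PAM methylation penalty:", round(penalty, 2),
      "log2 units  (~%.0f-fold)" % 2 ** -penalty)
```

Output:

```
score vs planted truth Spearman: 0.999
recovered GATC-PAM methylation penalty: -3.46 log2 units  (~11-fold)
```

The score tracks the planted ground truth almost perfectly at this depth,
and the contrast between methylated-GATC-PAM sites and sequence-matched
unmethylated controls recovers the planted −3.32 log2 (ten-fold) penalty
within sampling error.

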