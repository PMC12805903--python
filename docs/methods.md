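# Methods

`sascreen` re-implements, as a tested pipeline, the analysis chain that turns
pooled SaCas9/sgRNA screens in bacteria into on-target activity scores, a
sequence-to-activity deep model, and sequence/epigenetic determinants of
cleavage — down to in vitro kinetics comparisons. This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Target-site model

SaCas9 requires a 5'-NNGRRN-3' PAM (IUPAC: position 3 = G, positions 4-5 =
A/G) immediately 3' of a 21- or 22-nt protospacer. `targets.scan_pam_sites`
reports every PAM match on both strands whose full window (upstream flank +
spacer + PAM + downstream flank) fits inside the contig; overlapping matches
are all kept. Coordinates are 0-based half-open on the forward strand;
minus-strand sites store reverse-complemented sequences so a site always
reads upstream → spacer → PAM(1..6) → flanks [+1], [+2], ... in its own
orientation. On uniform random DNA the expected NNGRRN density is 1/16 per
strand per position, 1/8 over both strands; this is used as a property check.

Curation mirrors screen practice: sgRNAs with any control replicate count at
or below 20 are removed (the boundary is inclusive), sgRNAs whose spacer
occurs exactly in a user-supplied off-target genome are removed, and for
depletion screens sgRNAs with a second PAM-adjacent locus within 3 spacer
mismatches in the host genome are removed. Mismatch counting is spacer-only
with the PAM required to match, because off-target cleavage needs a PAM.

## Compositional activity scoring

Screen counts are compositional, so effect sizes are computed on
centred-log-ratio (CLR) coordinates via a Dirichlet Monte-Carlo procedure:
each replicate column yields `n_instances` (default 128) posterior
probability vectors drawn from Dirichlet(counts + 0.5); each draw is
log2-transformed and centred (every CLR vector sums to zero). Per sgRNA:

- `diff_btw` = median over instances of (mean CLR in experimental − mean CLR
  in control) — the absolute effect size in log2 units;
- `diff_win` = the larger of the two conditions' median absolute CLR
  difference between randomly paired replicates (within-condition
  dispersion). The statistic is named without a formula in the screening
  literature; the max-over-conditions convention of the established
  Dirichlet-CLR method is used;
- `rab_all` = median CLR over all replicates and instances.

The activity score is `diff_btw` for enrichment screens and `-diff_btw` for
depletion screens, so higher is always more active. The Jeffreys-style 0.5
prior handles zeros with no additional pseudocount; the prior and instance
count are configurable and all draws are seeded. Because the median over
instances integrates out the posterior jitter, 128 instances already agree
with a 10^4-instance reference within ~0.05 on small tables.

## Sequence-to-activity model

Inputs are one-hot encoded DNA (4×N binary matrices, rows A,C,G,T). The
regressor is a dual-branch network: a shared 1-D convolution block (128
filters, window 3, 'same' padding → LeakyReLU(0.01) → max-pool 2, 'same' →
dropout 0.3) feeding (i) three further convolution blocks flattened into
dense blocks of 128 and 64 units (LeakyReLU, dropout 0.3) converging to size
1, and (ii) a bidirectional GRU of 128 units with recurrent dropout 0.2 into
the same dense-block stack converging to size 1; the two scalar outputs are
concatenated into a final size-1 linear head. Training minimises mean
squared error with Adam.

The network runs on a self-contained reverse-mode autodiff core
(`sascreen.nn`) over float32 numpy arrays; gradients of every op (conv,
pooling, GRU recursion, dropout scaling) are verified against central
differences in the test suite. The GRU uses the classic formulation (reset
gate applied inside the candidate), Glorot-uniform input weights and
orthogonal recurrent weights; recurrent dropout uses one mask per sequence.

The input window is the 21-nt spacer plus configurable upstream (PAM-distal)
and downstream context, where downstream counts the 6-nt PAM first and then
flanks; the default is spacer + PAM + 2 flanks (N = 29), the window at which
the planted downstream effects are fully visible. Batch size, learning rate
and epochs are tunables (defaults 64 / 1e-3 / 50); the heavier synthetic
experiments below use batch 256 with learning rate 2e-3 and 8-24 epochs,
which reach the same plateau in far less wall time.

Data discipline: `split_train_test` is a deterministic 80/20 split (fixed
state 1, delegating to scikit-learn, so 20 253 examples give exactly 16 202
train / 4 051 test); five-fold cross-validation operates on the training
split only; `assert_quarantine` audits by id that no test example is ever
seen in training. The input-length scan re-runs cross-validation per nested
window and reports mean ± SD Spearman, optionally stratified by the final
PAM nucleotide.

## Sequence-feature and methylation association

Positional preference tables average activity per (position, nucleotide) or
per adjacent dinucleotide over a fixed window of 4 nt upstream + 21-nt
spacer + 6-nt PAM + 8 nt downstream (39 positions; empty cells stay NaN so
count-weighted cell means reconstruct the global mean exactly).
Tetranucleotide grouping keys activity by PAM positions 4, 5, 6 and flank
[+1] — the register at which GATC can sit inside the PAM.

Methylation analysis consumes bedMethyl tables (percent-modified converted
to proportions, 0-based positions). A motif strand is called methylated at
fraction ≥ 0.75 (inclusive — the cutoff is quoted without strictness);
"methylated" for the GATC palindrome requires both strands, and a missing
call counts as unmethylated with the missing count reported — conservative
for penalty detection. Sites are classified into mutually exclusive,
exhaustive categories: methylated GATC spanning PAM[4-6]+[+1]; a single
substitution away from GATC at that register; methylated adenines only
inside the spacer; no methylation near the site; other. Cytosine
methylation at PAM positions 1-2 is annotated separately and summarised
only (its in vivo effect is bimodal and its in vitro test was null, so no
category is built on it).

Two contrasts are reported for the methylated-GATC category: against the
all-sites mean (the screen-level observable — this contrast mixes the
methylation penalty with the base-composition bonuses the GATC register
implies, since such sites always have PAM6 = T and [+1] = C), and against
sequence-matched controls (PAM6 = T, [+1] = C, non-GATC register), which
isolates the methylation penalty itself. In the synthetic screens the
matched contrast recovers the planted penalty; the all-sites contrast is
smaller by the bonus composition difference, exactly as the screen-level
means differ in real data.

## Kinetics

Supercoiled-substrate disappearance is fitted as s(t) = s0·exp(−k_obs·t) by
nonlinear least squares on the linear scale (log transforms would be biased
by near-zero late timepoints). s0 is floated within [0, 1.5] because gel
densitometry has unknown normalisation. Replicates are fitted independently
and aggregated as mean ± SD (a pooled fit is available). A fit with less
than 0.1% total decay over the experiment is flagged degenerate rather than
rejected. Fold changes k_a/k_b propagate uncertainty to first order; the
paired DAM(+)/DAM(−) report counts methylation-sensitive sgRNAs
(k_DAM+ < k_DAM−).

## Synthetic data: what it emulates and what it does not

The generator plants recoverable ground truth: a uniform-composition random
genome; an additive log2 activity model (baseline 0, +1.0 for T at PAM 6,
+0.5 for a pyrimidine at [+1], +0.25 for T at [+2], and −log2(10) ≈ −3.32
when a methylated GATC spans PAM[4-6]+[+1]) plus Gaussian noise (default sd
0.3 log2 units); a Dam-like methylome (every GATC called on both strands at
a given fraction, 0.98 for dam+ and 0.0 for dam−); and screen counts in
which a guide's expected abundance changes by 2^(±generations×activity)
(log-linear growth, default 3 effective doublings — the screens' true
effective doublings and depths are not published, so these are free
parameters chosen once). Control replicates are independent multinomial
draws at uniform proportions.

Consequences worth knowing: measured scores are approximately
generations × activity, so planted per-generation effects are recovered
after dividing scores by the known generations; and the generator has no
sequencing-error, PCR-bias or overdispersion model, so passing tests
demonstrate pipeline correctness under sampling noise, not robustness to
library-preparation artifacts. Real screens will sit below the synthetic
recovery correlations.

## Problem sizes and numerical choices

The heavier synthetic experiments use sizes chosen to exercise the pipeline
at realistic scale while keeping a full run on a single CPU short: the
end-to-end recovery screen uses 16 000 sgRNAs sampled from a 236-kb genome
at 10^6 reads per replicate with 3 replicates per condition; the
input-window scan uses a 2 000-sgRNA subset with five-fold cross-validation;
kinetics grids use triplicate series with timepoints spanning ~4 half-lives
(rate estimation degrades sharply when the grid under-samples the decay).
Dirichlet-CLR uses 128 instances everywhere. All random draws flow from
explicit integer seeds; training is deterministic for a fixed seed on a
fixed BLAS.

## Known limitations

- No hypothesis-testing output (q-values/expected effects); the pipeline
  consumes effect sizes only.
- Exact-match barcode demultiplexing by default; no error correction.
- The deep model's deterministic-training guarantee is per-platform
  (single-threaded numpy); cross-platform bit-equality is not promised.
- Cytosine-methylation handling is annotation + summary only.
- Paired-end read merging and modified-base calling are upstream of this
  package: it consumes merged reads and bedMethyl calls.
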