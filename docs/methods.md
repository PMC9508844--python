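# Methods

This document records the models, conventions and numerical choices behind
`chromcut`. Coordinates are **0-based, half-open** throughout; every interval
`[start, end)` includes `start` and excludes `end`.

## 1. Guide design

A candidate is a 20-nt protospacer. A *target site* on the `+` strand is a
genomic 20-mer followed immediately by an NGG PAM; on the `−` strand it is a
position where the reverse complement of the protospacer appears with CCN
immediately 5′ of it on the reference. SpCas9 cuts bluntly 3 bp from the PAM,
between protospacer bases 17 and 18, so the cut coordinate is
`protospacer_start + 17` on `+` and `protospacer_start + 3` on `−`.

`find_matches(genome, protospacer, max_mismatches=3, require_pam=True)`
performs an exhaustive Hamming scan of both strands (no gaps/bulges —
mismatch-only off-target models are the standard first-order approximation
for SpCas9 specificity). The scan is vectorized with a numpy
`sliding_window_view` over a byte-encoded genome; the test suite proves
equivalence to an independent pure-Python oracle on both PAM policies.

`design_single_cutters` retains a candidate only if it has **exactly one**
perfect, PAM-adjacent target and **zero** additional sites within 3
mismatches. Duplicated input protospacers are deduplicated first.
`assemble_library` adds non-targeting controls by rejection-sampling random
20-mers with *no* genomic match within 3 mismatches even ignoring the PAM
(`require_pam=False`), which is deliberately stricter than the targeting
criterion. Every expression sequence is the protospacer with a 5′ G
prepended (21 nt), the U6/T7 convention, applied uniformly so targeting and
control guides are transcribed identically.

Defaults: `max_mismatches=3`, `n_controls=100`.

## 2. Window annotation

`annotate_guides` centers a window (default **4 kb**) on each cut site:
`[cut − w/2, cut + w/2)`. Windows are clipped at chromosome ends, but all
fractions are computed over the **nominal** window length, with clipped or
uncovered base pairs counted as `unannotated`. This keeps fractions summing
to exactly 1 and makes thresholds comparable between interior and edge
windows (an edge window cannot spuriously reach a 99% state fraction).

Per window:

- **state_fraction** — bp fraction per label of a non-overlapping labeled
  segmentation (ChromHMM-style states "1"–"10" in the synthetic tracks),
  plus `unannotated`; also the label at the exact cut position
  (`breaksite_state`).
- **lad_fraction / ilad_fraction** — bp fractions of `LAD` and `iLAD`
  labels; any other label in the lamina track is an error.
- **dnase_max** — maximum interval value overlapping the window.
- **h3k9me3_wmean** — coverage-weighted mean: Σ(value × overlap bp) divided
  by the nominal window length, so uncovered bp dilute the mean toward 0.
- **gene context** — evaluated at the cut position itself (not the window):
  `genic`, `intronic`, `exonic` and `expressed` (any overlapping gene with
  expression ≥ `expression_threshold`, default 1.0).

Tracks may declare a chromosome namespace; annotating a guide on a
chromosome outside a track's namespace raises an error naming the track,
while a merely uncovered region silently yields `unannotated`.

## 3. Pool rules and selection

Six built-in pools, each a conjunction of clauses over one annotation record.
Bounds are strict (`>`/`<`) unless marked inclusive:

| pool   | state clause                  | other clauses |
|--------|-------------------------------|---------------|
| pool2  | state 2 ≥ 0.65 (inclusive) and breaksite in state 2 | dnase_max > 0.2, iLAD > 0.90, intronic in an expressed gene |
| pool4  | state 4 > 0.50                | iLAD > 0.99 |
| pool7  | state 7 > 0.99                | dnase_max < 0.06, iLAD > 0.90, intronic in an expressed gene |
| pool8a | state 8 > 0.99                | iLAD > 0.99, non-genic |
| pool8b | state 8 > 0.99                | LAD > 0.99, non-genic |
| pool9  | breaksite in state 9          | h3k9me3_wmean > 5.5, LAD > 0.99, non-genic |

`evaluate_rule` returns a pass flag plus the list of failed clause names, so
every exclusion is auditable in the per-pool ledger. Custom rule sets load
from TOML.

Selection picks `k = 10` guides per pool with at most 2 per chromosome: a
seeded uniform shuffle followed by a greedy cap-respecting scan. The cap is
a partition-matroid constraint, for which greedy is exactly optimal, so
infeasibility is decided precisely; `InsufficientCandidates` reports the
true maximum feasible size Σ min(per-chromosome count, cap). The test suite
confirms the feasibility decisions against brute-force subset enumeration.
Pools are filled in declaration order with each guide claimed at most once
(`exclusive=True`); per-pool randomness derives sub-seeds as
`seed*1000 + pool_index` so adding a pool does not reshuffle earlier ones.

## 4. Screen count analysis

Inputs are an integer count matrix (guides × samples, controls identified by
an id prefix, default `CTRL`) and sample metadata (timepoint, replicate).

- **RPM** (`total_count_normalize`) — library-size scaling to reads per
  million, for inspection only.
- **Size factors** (`control_size_factors`) — median-of-ratios computed on
  the non-targeting controls only: ratios of each control's count to its
  geometric mean across samples; controls with any zero count are excluded.
  Using controls only makes the normalization robust to the global depletion
  of targeting guides, which would bias a whole-library estimator upward.
- **Fold changes** (`log2_fold_change`) — per replicate,
  `log2((target/sf_t + c) / (reference/sf_r + c))` with a symmetric
  pseudocount `c = 0.5`, averaged over replicates. Pairing day-16 (or day-8)
  to day-4 within the same replicate cancels replicate-level infection
  bottlenecks. Each sample may appear in at most one pair.
- **Region dose** (`region_dose_comparison`) — two-sided Wilcoxon rank-sum
  between guides cutting inside vs outside a region (e.g. a higher-copy
  segment, where each cell receives proportionally more breaks), with group
  medians and their difference.
- **chromosome_summary** — per-chromosome n, median and MAD of mean lfc.

No count GLM is fitted; the estimator is deliberately the transparent
fold-change statistic.

## 5. Synthetic fixture generator

The generator emulates the *inputs* of the workflow at desk scale, not human
biology: by default 6 chromosomes × 120 kb of i.i.d. uniform sequence,
exponential-length state segments (mean 4 kb) tiling each chromosome
completely, alternating LAD/iLAD segments (mean 25 kb), DNaseI peaks placed
preferentially in state-2 segments, H3K9me3 plateaus covering state-9
segments, and a few 6 kb genes with 3 exons each, half of them expressed.

`plant_pool_sites` engineers ground-truth candidates: for each pool it
overwrites the chromatin tracks in an exact 4 kb window to satisfy that
pool's clauses (including planting an expressed gene whose intron covers the
cut for pools 2 and 7, and removing conflicting background genes around the
window), then writes a protospacer + TGG PAM at the cut site. A verification
loop re-randomizes any planted protospacer that is not a genome-wide
single-cutter. The returned truth table maps every planted guide to its
pool, coordinates and sequence.

### Screen simulator

Per guide, the cell population is a mixture: a fraction `efficiency` of
cells is edited and depletes exponentially as `2^(−depletion·day)`
(depletion in halvings/day); the rest is unedited and neutral. One library
composition is drawn from a symmetric Dirichlet (concentration 1.0) and
shared by all replicates — replicates are independent infections of the
*same* physical library — with a small per-replicate lognormal bottleneck
jitter (log2 sd 0.1). Counts per sample are negative binomial around
`depth × relative_abundance` (default depth 10⁶) with overdispersion
`α = 0.01` (variance `μ + αμ²`; Poisson when 0).

Numerical/design choices worth noting:

- **Overdispersion 0.01.** At α = 0.05 the count noise alone makes the
  control-guide mean lfc fluctuate beyond ±0.05 in a large fraction of
  seeds, i.e. the centering property the analysis is designed to deliver is
  not achievable at the chosen library size. α = 0.01 corresponds to a
  well-executed screen with high coverage per guide.
- **Shared library + jitter.** Drawing an independent Dirichlet per
  replicate would shuffle guide abundances across replicates and inflate
  size-factor noise; sharing one draw matches how replicate infections are
  actually performed.
- **Study regime.** The recovery analyses use depletion ~ U(0, 0.2)/day and
  efficiency ~ U(0.3, 1.0). In this regime the day-4→16 lfc is close to
  monotone in depletion × efficiency (Spearman ≲ −0.84 across seeds). At
  much higher depletion the mixture saturates — the unedited fraction
  dominates the late counts — and lfc is no longer monotone in the product,
  which is a property of the biology being modeled, not an estimator
  defect. For the same reason the region-dose demonstration uses uniform
  intrinsic toxicity (depletion 0.05/day, efficiency 0.9) with a 2× dose on
  the duplicated chromosome, so copy number is the only variable.

## 6. Limitations

- Off-target search is mismatch-only (no DNA/RNA bulges) and PAM-exact
  (NGG; no NAG tolerance).
- Chromatin annotation assumes non-overlapping segmentation tracks; signal
  tracks must be non-negative and non-overlapping per chromosome.
- The screen model has no cell-cycle structure, no cutting-time dynamics
  (editing is instantaneous at day 0) and no guide-sequence efficacy model.
- Problem sizes (120 kb chromosomes, 10-state segmentation, 6 kb genes) are
  the package's own desk-scale choices; all thresholds and window sizes are
  parameters.
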