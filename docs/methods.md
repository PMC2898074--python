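# Methods

## The question and the estimand

A sense transcript and its natural antisense transcript (NAT) can base-pair
over their overlapping region.  If that duplex forms in the cytoplasm it can
occlude miRNA binding sites, so selection should tend to keep miRNA sites
out of overlap regions.  The quantity the package estimates is the contrast
in predicted miRNA binding-site density between the pairing (overlap) and
non-pairing regions of a set of sense-antisense transcript pairs, with a
two-sided Wilcoxon rank-sum test on per-pair densities and a Monte Carlo
randomization null.

## Pipeline stages and their assumptions

**Overlap mapping.**  The pairing region is the single best local alignment
between the sense transcript and the reverse complement of the antisense
transcript (Gotoh affine-gap, match +2, mismatch −3, gap open −5, extend
−2, minimum score 30; all exposed as flags).  One overlap per pair is
assumed — no chaining of multiple high-scoring segments.  The aligned span
on each transcript becomes its pairing segment; everything else is
non-pairing; gaps inside the alignment are tolerated and the overlap length
is measured on the sense transcript's span.  Among equal-scoring optima the
aligner's first (deterministic, leftmost-biased) traceback is used.  Pairs
with overlap < 25 nt (inclusive boundary: 25 passes) are dropped before
scanning.  The alignment runs on transcript sequences; genome coordinates
are never consulted.

**Site scanning.**  A two-phase miRanda-style scheme.  Phase 1 aligns the
reversed miRNA to the target scoring complementarity — A:U and G:C +5, G:U
wobble +1 in both orientations, mismatch −3, affine gaps −8/−2 — with every
per-position score multiplied by 4.0 when the miRNA base sits at seed
positions 2–8 from the 5′ end; candidates need score ≥ 90.  Phase 2 keeps a
candidate only if its nearest-neighbor duplex free energy is ≤ −17
kcal/mol.  Per miRNA, candidates are selected greedily best-first and may
not overlap on the target; sites of different miRNAs may overlap and all
count.  By default both transcripts of a pair are scanned (`strands=both`)
and their lengths are summed per region class; `strands=sense` is provided
because the original protocol is ambiguous about which strand(s) were
scanned.  The numeric scoring constants are this package's choices
approximating the published miRanda scheme; the regional *contrast* is
insensitive to them because both region classes are scanned under one
setting.

**Duplex energies.**  Turner 2004 RNA:RNA ΔG°37 nearest-neighbor stacks
(Watson-Crick and G:U wobble), duplex initiation +4.10 kcal/mol, terminal
AU/GU penalty +0.50 per helix end.  The published table is asymmetric by up
to 0.1 kcal/mol from rounding; each stack is symmetrized with its 180°
rotation.  Aligned mismatches and gaps are treated as interior-loop content
charged a flat +3.5 kcal/mol per loop opening — a coarse destabilization
term, not a full loop model; the scanner only needs a stability *filter*,
and no attempt is made to reproduce Microinspector/RNA22/miRacle numerics.
An alignment with zero paired positions is defined to have energy 0 (with a
warning).

**Densities and the Wilcoxon comparison.**  The observation unit is the
per-pair, per-class density n/L (one value per pair per region class);
per-segment units are deliberately not the default because the overlap of a
pair is one biological feature.  Quartiles use linear interpolation between
order statistics (numpy's default, the common "type 7" rule).  The
aggregate mean per 100 nt is the totals ratio 100·Σn/ΣL, not the mean of
per-pair densities — the only definition under which an aggregate
per-100-nt figure equals its pooled totals.  The rank-sum statistic W is
the rank sum of the pairing sample with midranks for ties.  The null is
enumerated exactly (subset-sum dynamic program) when min(n, m) ≤ 10 and the
pooled sample is tie-free; otherwise a normal approximation with
tie-corrected variance and a 0.5 continuity correction is used.  An
all-identical pooled sample returns p = 1 by convention.

**Randomization test.**  Default mode reassigns the pooled per-region
(count, length) records uniformly at random to two simulated classes of the
real sizes ("label permutation") and recomputes the Wilcoxon comparison;
x counts randomizations whose metric (Wilcoxon p by default; W selectable)
is *strictly* smaller than the observed one — ties count toward
not-smaller, which is conservative — and P = x/n_reps exactly.  A
`nucleotide_shuffle` mode instead shuffles every region sequence (mono- or
dinucleotide-preserving Euler-path shuffle) and re-runs the scanner before
splitting; it matches a literal reading of "shuffled sequences" but costs a
full re-scan per repetition.  Both modes are deterministic under the seed.
The corroboration cut-off is 0.05.

## The synthetic generator

Each pair is a duplex core of configurable length carried by the sense
transcript and, as an exact reverse complement, by the antisense
transcript, with independent i.i.d. flanks (configurable GC) on both
transcripts.  Sites are planted as exact reverse complements of a random
miRNA panel (a mismatch-rate knob exists for harder tests) at Poisson rates
per nucleotide — separately for pairing and non-pairing regions.  Defaults
mirror the study-scale scenario: 391 pairs, overlap 400–1400 nt, four
flanks of 500–1500 nt each, rates 0.0521 (pairing) vs 0.0708 (non-pairing)
per nt.

Because both strands are scanned by default, the pairing length of a pair
is 2× the core length and planted pairing events are split between the two
strands, so planted rates equal measured densities under the pipeline's own
convention.

Two deliberate departures from naive simulation:

* **Boundary insulation.**  An 8-nt block borders the core on every
  transcript, drawn from alphabets that cannot match under the
  reverse-complement comparison ({A,C} on the sense side against {G,T} on
  the reverse-complemented antisense side).  Without it, a chance match in
  the flank next to the core extends the local alignment past the planted
  boundary in a substantial fraction of pairs; with it, the overlap mapper
  recovers every planted core coordinate exactly.  Insulators count toward
  non-pairing length and never host planted sites.

* **Counts before placement.**  Per-region site counts are drawn first from
  the Poisson process; they are the ground truth the enrichment statistics
  consume.  Physical insertion then places each site without overlapping
  earlier insertions (rejection sampling, 100 attempts).  At study-scale
  rates this saturates — 0.0708 sites/nt exceeds the 1/22 ≈ 0.0455/nt
  packing bound of non-overlapping 22-mers, just as real predicted sites
  from hundreds of miRNAs overlap each other — in which case the site is
  written over earlier insertions and any clobbered insertion is flagged
  `intact=False`.  Sequence-level recovery guarantees therefore hold at low
  planting rates (where everything stays intact), while count-level
  statistics are exact at any rate.

What the generator does *not* emulate: splicing and exon structure, UTR
composition, conservation, k-mer background beyond GC content, expression
levels, and miRNA families with shared seeds.  Passing recovery and
depletion tests on synthetic data therefore demonstrates correctness of the
machinery and calibration of the statistics, not biological conclusions
about any real transcriptome.

A count-level sampler (`sample_density_records`) draws only the
(site count, region length) records at the configured rates.  Statistical
calibration at hundreds-to-thousands of repetitions uses it because the
test statistics consume nothing else; sequence assembly would add cost and
no information.

## Numerical and reproducibility choices

* Internal alphabet is DNA (U→T on read); internal coordinates 0-based
  half-open; all written tables 1-based inclusive; site tables sorted
  deterministically so equal site sets give byte-identical files.
* IUPAC ambiguity codes other than N collapse to N; N never pairs anywhere
  (overlap aligner, scanner, energy model).
* Every stochastic component takes a numpy `Generator` or integer seed and
  is fully deterministic under it; pipeline logs record counts, filter
  losses and seeds at each stage so the pair accounting is auditable.
* The scanner's vectorized forward pass resolves the horizontal-gap state
  with a running-maximum scan, which requires gap-open ≥ gap-extend
  (validated); tracebacks re-run a window around each optimum and fall back
  to the full interval if a long-gapped optimum escapes the window.
* Degenerate inputs: empty overlap → whole transcripts are non-pairing;
  segments < 7 nt are skipped with a log entry; a pair contributing only
  one region class stays in the comparison with that class.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data:
the study-scale depletion scenario at its full 391 pairs (counts-level),
sequence-level recovery on 20-pair sets at low planting rates, end-to-end
rate recovery on 200 pairs, scanner/alignment oracle equivalence on ≥ 200
random instances of ≤ 60-nt targets, Wilcoxon exact-vs-enumeration checks
for all n = m ≤ 7, type-I-error calibration over 1000 null repeats and
randomization-uniformity calibration over 100 trials of 200 repetitions.

## Known limitations

* The scanner approximates miRanda; scores and energies are not
  interchangeable with any published tool's output.
* The energy model ignores dangling ends, coaxial stacking and
  loop-sequence dependence.
* One overlap per pair: pairs with several distinct duplex-forming blocks
  are represented by their best block only (`--chain-hsps` is reserved but
  not implemented).
* Real medians/IQRs of site densities depend on the actual transcript and
  miRNA inputs (curated conserved sense-antisense catalogs and miRBase panels) and are not
  reproduced from synthetic data; the package reproduces the arithmetic,
  the filters, the statistics and the study-scale contrast.
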