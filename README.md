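# asmirmask

**Are miRNA binding sites depleted where sense and antisense transcripts can
pair?**  Natural antisense transcripts (NATs) overlap their sense partners
and can form RNA duplexes with them; a duplex over a miRNA binding site can
occlude ("mask") it — the mechanism proposed for the
BACE1 / BACE1-antisense / miR-485-5p triad.  `asmirmask` implements the
genome-scale computational side of that model for anyone studying
sense-antisense pairs and miRNA regulation: it maps the pairing (overlap)
and non-pairing regions of transcript pairs, predicts miRNA binding sites,
and tests whether predicted sites are depleted in the pairing regions.

## Method

For each sense-antisense pair the **overlap** is the best local alignment
(BLASTN-like scores: match +2, mismatch −3, gap −5/−2) between the sense
transcript and the reverse complement of the antisense transcript; pairs
with an overlap < 25 nt are excluded.  **Sites** are predicted with a
miRanda-style two-phase scanner: a Smith–Waterman/Gotoh alignment of the
reversed miRNA against the target scoring complementarity (A:U, G:C match
+5; G:U wobble +1; mismatch −3; affine gaps −8/−2) with positions pairing
the miRNA **seed** (positions 2–8 from the 5′ end) scaled ×4, followed by a
thermodynamic filter: nearest-neighbor RNA:RNA duplex free energy (Turner
2004 ΔG°37 stacks, initiation +4.10, terminal AU/GU +0.50 kcal/mol) must be
≤ −17 kcal/mol, and the alignment score ≥ 90.

Counts are normalized to scanned length: for pair *i* and region class
*c* ∈ {pairing, non-pairing}, the density is *d<sub>ic</sub>* =
*n<sub>ic</sub>* / *L<sub>ic</sub>* (sites per nt).  The two density lists
are compared with a two-sided Wilcoxon rank-sum test (exact enumeration for
small tie-free samples, tie-corrected normal approximation otherwise), and
with a Monte Carlo randomization null: the pooled per-region (count,
length) records are reassigned to two simulated classes of the real sizes,
the Wilcoxon comparison is recomputed each time, and

&nbsp;&nbsp;&nbsp;&nbsp;*P*<sub>rand</sub> = *x* / *n*<sub>reps</sub>,

where *x* counts randomizations with a smaller Wilcoxon *p* than the real
data (a sequence-shuffling mode that re-scans dinucleotide- or
mononucleotide-shuffled regions is also available).  A synthetic-data
module generates pair sets with exact reverse-complement overlap cores and
miRNA-complementary sites planted as a Poisson process at separate rates in
pairing vs non-pairing regions, so the whole pipeline is testable with no
external data.

## Worked example

Simulate 60 pairs with sites planted at 0.005/nt in overlaps and 0.012/nt
in flanks, then run the full analysis:

```sh
asmirmask simulate --n-pairs 60 --overlap-min 200 --overlap-max 500 \
    --flank-min 300 --flank-max 700 --rate-pairing 0.005 \
    --rate-nonpairing 0.012 --panel-size 6 --seed 7 --out-dir demo
asmirmask run-all --fasta demo/transcripts.fasta --pairs demo/pairs.tsv \
    --mirnas demo/mirnas.fasta --reps 1000 --seed 7 --out-dir demo/results
```

which prints

```
miRNA site-density enrichment: pairing vs non-pairing regions
==============================================================
                                 pairing        nonpairing
pairs (records)                       60                60
median (sites/nt)                0.00505           0.01206
Q1                               0.00302           0.01083
Q3                               0.00643           0.01305
min                              0.00000           0.00811
max                              0.01059           0.01632
mean per 100 nt                     0.51              1.20
total sites                          207              1477
total length (nt)                  40878            123459
--------------------------------------------------------------
Wilcoxon rank-sum W = 1883.0 (normal), two-sided p = 4.87e-20
direction: nonpairing>pairing
randomization: x=0/1000 -> p=0.0
```

The medians and aggregate means recover the planted rates (0.5 vs 1.2
sites per 100 nt); the Wilcoxon p-value and the randomization p = 0/1000
call the depletion of sites in pairing regions, which is the signature the
masking model predicts.  `demo/results/` holds the partition, site and
density tables plus `summary.json`.

The same analysis is available as library calls:

```python
from asmirmask import MirnaSiteEnrichment

model = MirnaSiteEnrichment.from_sites(sites, partitions)   # or from_dataframe
results = model.fit()
print(results.summary())
rand = results.randomization_test(n_reps=1000, seed=7)
```

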