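# Methods

## The mapping model

The pipeline localises a foreign DNA cassette integrated into a host
genome, under the standard random-transgenesis model: at each integration
site a host interval `[left_bp, right_bp)` (possibly empty) is replaced by
one or more tandem copies of the vector sequence. Evidence comes from two
read classes. *Discordant pairs* — one mate matching the vector, the other
the host — tether the junction to within roughly a fragment length.
*Split reads* — single reads crossing a host/vector boundary — resolve a
breakpoint to the base, provided their host flank places uniquely.

Assumptions: reads are substitution-noisy but ungapped copies of the
sample genome (no indels, no chimeric library artefacts); the vector is
absent from the reference; integration sites are far enough apart
(> merge distance) to cluster separately; FR mate orientation.

### Coordinates

Internally everything is 0-based half-open; `left_bp` is the first deleted
base, `right_bp` the first base retained on the right, and
`deletion_length = right_bp − left_bp` always. Reports print 1-based
*outer* coordinates — the last retained base on the left and the last
deleted base on the right — which are numerically identical to the
internal bounds, so the printed pair's difference is the deletion length
(a 204 bp deletion prints as, e.g., 36382105 / 36382309). A
clean insertion prints the same coordinate twice. `to_report` /
`from_report` round-trip without drift; calls carry a free-text
genome-build label and no build conversion is ever attempted.

## Parameters

| parameter | default | why |
|---|---|---|
| screen k | 15 bp | seed short enough to find "any part" of the vector |
| min_match_len | 25 bp | shortest reported vector match; at 1 Mb scale random 25 bp matches at 0.9 identity are negligible |
| min_identity | 0.9 | tolerates ~1 substitution per 10 bp |
| anchor k | 31 bp | unique seeds on megabase genomes; fits 2-bit codes in int64 |
| junction flank k | 20 bp | flanks are 20–80 bp; a 20-mer is still effectively unique at this genome scale |
| max_mismatch | 3 | matches the substitution-only error model at ≤ ~1%/base |
| merge_distance | 1000 bp | ≈ frag_mean + 3·frag_sd + read length: mates of one junction cannot fall further apart |
| min_support | 3 reads | suppresses stray chimeric pairs; real loci at ~10× coverage collect ≥ 10 |
| read_len / frag_mean / frag_sd | 100 / 300 / 30 bp | the sequencing design being emulated (100 bp pairs from ~300 bp fragments); the fragment SD is a free parameter, set to 10% of the mean |
| Ct baseline / control / sd | 26 / 12 / 0.2 cycles | typical moderately expressed target and abundant rRNA control; 0.2 cycles is ordinary replicate scatter |
| non-detect cutoff | Ct ≥ 40 or "ND" | standard qPCR cycle cutoff |

## Screening and triage

A read "contains vector" iff some substring of length ≥ `min_match_len`
matches the vector concatenation (either strand) at ≥ `min_identity`.
Candidate reads are found by exact k-mer seeding (vectorised over read
batches); seeded diagonals are then scanned exhaustively for the longest
qualifying window, so within a seeded diagonal the reported hit is optimal.
Ties break by identity, then smallest vector offset, then '+' strand —
determinism over biology, since the alternatives are equivalent. Matches
spanning component boundaries are attributed to the component under the
match midpoint. Reads with non-ACGTN characters are skipped with a
warning; N never matches anything.

Pairs partition exhaustively into VECTOR_BOTH (discarded — internal to the
cassette), VECTOR_HOST (kept; the host mate plus any unmatched flank
≥ flank-k of the hit mate are forwarded), and HOST_HOST. A consequence of
discarding VECTOR_BOTH worth knowing: a junction-spanning read whose
partner lies inside the vector is discarded with its pair, so only one of
the two spanning orientations yields split-read evidence. At the default
simulation scale (50,000 pairs on ~1 Mb) the expected split-read yield is
~3 per junction side; a few percent of random seeds produce none on one
side, in which case the call degrades gracefully to the mate-evidence
outer bound (tens of bp, flagged by `n_exact`).

## Anchoring and ambiguity

Placement is seed-and-vote: exact k-mers of both read orientations against
a sorted-array index of the reference; every candidate diagonal is scored
by full ungapped mismatch count, and all co-optimal placements within
`max_mismatch` are kept. One co-optimal placement → unique; several →
ambiguous with the full candidate list; none → unmapped. Ambiguous
anchors contribute to locus ranking but never to coordinates — the
treatment a ~180-member gene family forces, where a read matching the
family consensus fits many copies equally well.

Locus grouping: unique anchors are single-linkage clustered per contig
within `merge_distance`; each ambiguous anchor then adds ambiguous support
to *every* group covering one of its candidates (one ambiguous read may
support several family copies — deliberate, since it genuinely cannot
adjudicate between them), and ambiguous anchors near no unique group form
zero-unique groups of their own. Groups rank by unique support, then total
support; processing order is canonicalised so grouping is input-order
invariant. Groups with no unique junction evidence yield *no* breakpoint
call — they stay visible in the ranked table as unresolved candidate loci.

Per side, the called breakpoint is the modal exact coordinate when split
reads exist (ties toward the inner side of the deleted interval),
otherwise the tightest mate bound (max of left-side ends / min of
right-side starts). If inexact bounds cross, the exact side wins; with no
exact side the call collapses to a zero-length locus at the inner bound.

## Synthetic data: what it emulates, and what not

The generator reproduces the features the pipeline actually exercises: a
random host contig; one multi-exon gene model (default 27 exons over
380 kb, with intron 1 given 30% of the intronic length so a breakpoint can
sit 15 kb inside it); an optional repeat family (n copies of one master,
each copy independently substituted at the divergence rate — at 2% the
copies sit ~98% identical to the master, ~96% to each other); vector
integration with host deletion; uniform-coverage FR read pairs with
Normal(300, 30) fragment lengths (rejection-resampled to ≥ read length)
and i.i.d. substitution errors; truth tags in read names.

It does **not** emulate: indels or structurally chimeric reads, quality
score variation (constant Q40), GC or positional coverage bias, diploidy,
or target-site duplications. Passing tests therefore demonstrate the
logic of screening/anchoring/calling under substitution noise and
repeat-induced ambiguity — not robustness to gapped alignment or library
artefacts, which a production SV caller would need.

One property of the independent-divergence family model matters for
interpretation: a read drawn from a *specific* diverged copy carries that
copy's private substitutions and so usually maps uniquely back to it. A
genuinely unresolvable family locus — the situation reported for a large
Ig-family hit — therefore corresponds to evidence whose host side comes
from an allele *not present verbatim in the reference* (family members are
highly polymorphic between strains). The ambiguity scenario in the
acceptance suite builds exactly that: decoy junction pairs whose host side
is the family master sequence; such reads are ambiguous across the ~24
copies expected to be locally identical to the master, with probability
near 1. Planting the vector inside one reference copy instead would be
resolvable by construction and would test nothing.

Generators are deterministic given their seed, and independent generators
must be given *different* seeds: two `default_rng(seed)` streams with the
same seed are identical, so seeding the vector and the reference alike
would make the vector a verbatim copy of the genome head. The CLI derives
the vector seed from the run seed with a fixed offset for this reason.

## Expression quantification

Detection is majority-of-replicates (robust to one failed well; the source
protocol states triplicates but no rule). Means are taken over detected
replicates only; an animal whose control replicates all fail raises
(control failure is a plate problem, not a biology result). ΔΔCt is
referenced to the calibrator group's arithmetic mean ΔCt per assay, so the
calibrator's own geometric-mean fold is exactly 1. Group fold is the
geometric mean of per-animal folds over detected animals (equivalently
2^(−mean ΔΔCt)) — the natural mean on the log2 scale the assay lives on;
non-detects are reported as counts alongside, never imputed as folds.
Amplification efficiency is fixed at 2.0 (the plain comparative-Ct
method); no standard-curve correction.

## Morphometry statistics

Welch is the default test because the summaries being compared routinely
have unequal SDs and n; the pooled variant is exposed for sensitivity.
p-values are two-sided from the t distribution (scipy); the t statistic
and Welch–Satterthwaite df are closed-form. Degenerate inputs (n < 2, or
both SDs zero) raise rather than return a fake p. The permutation oracle
in the test suite permutes group labels on the absolute mean difference
with the add-one estimator, giving an implementation-independent check of
the t-test path at small n.

## Problem sizes

The simulated study runs at 1 Mb of host genome, 50,000 read pairs
(~10× coverage), a 180-copy × 500 bp decoy family, 600 decoy junction
pairs, and a 9+9-animal qPCR design (5 detected per group — the
calibrator side trimmed to 5 so both groups match the stated detected-n —
with 4 zero-expression homozygotes). The whole test suite runs in about
half a minute; the acceptance script in under one.

## Known limitations

- Ungapped scoring only: an indel near a junction would shift or lose
  evidence; out of scope by design.
- Tandem multi-copy insertions at one site are planted correctly but the
  caller reports the locus, not copy number.
- Ambiguity handling reports candidate sets; it does not attempt
  probabilistic assignment across family copies.
- The screen's "iff" guarantee is relative to its seeding: a qualifying
  window whose every k-mer is broken by mismatches (possible only near the
  identity floor) can be missed; at the default settings and ≤1% error
  this is negligible (measured recall ≥ 0.99).
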