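# Methods

This note records the models behind each stage of `marinitax`, the
parameters that matter, the numerical conventions that make runs
bit-reproducible, and what the synthetic benchmarks do and do not show.

## Alignment engine

Protein comparison uses optimal local alignment (Smith–Waterman) under
BLOSUM62 with affine gap costs in the BLAST convention: a gap of length
*L* costs `gap_open + L·gap_extend` (defaults 11/1, so the first gap
residue costs 12). Raw scores are converted with fixed Karlin–Altschul
constants for the gapped BLOSUM62/11/1 system — λ = 0.267, K = 0.041 —
into bit scores `(λS − ln K)/ln 2` and expectations `E = K·m·n·e^(−λS)`,
where *m* is the query length and *n* the total residue count of the
searched proteome. Estimating λ and K per scoring system is deliberately
out of scope; the fixed constants give desk-scale fidelity to BLAST
statistics without its heuristics. Residues outside the BLOSUM62
alphabet score as `X`.

Determinism is a contract, not an accident: the alignment endpoint is the
first maximal cell in row-major order, traceback ties resolve
diagonal > up > left (up consumes a query residue), and within a gap the
gap closes as early as possible. Global nucleotide alignment
(Needleman–Wunsch, linear gaps, defaults +1/−1/−2) uses the same tie
order. Identity is counted BLAST-style as identities over all alignment
columns, gap columns included, because the POCP filter set was defined on
BLAST output. The DP kernels are numba-compiled; the test suite checks
their scores against Bio.Align.PairwiseAligner and against an
independently written full-matrix DP with explicit pointer recording.

Best-hit search keeps, per query, the subject with the highest raw score
at `E < 10⁻⁵`; score ties go to the lexicographically smaller subject id.
The search computes score-only DP for all pairs and runs a traceback only
for hits whose statistics are actually needed, which changes nothing
relative to aligning every pair.

## AAI and POCP

AAI is the unweighted mean identity over reciprocal best hits that pass
identity ≥ 30%, coverage ≥ 70% of the **shorter** protein, and
e-value < 10⁻⁵. These filter values follow common AAI practice and are
exposed as configuration; the mean is unweighted (not length-weighted).
A pair with no qualifying RBH yields an explicitly *undefined* AAI, never
a zero. POCP applies its published filters literally and strictly
(e-value < 10⁻⁵, identity > 40%, alignable region > 50% of the query
length) and counts, per direction, queries with **any** qualifying hit:
candidates are examined in decreasing score order and the scan stops at
the first success, which is equivalent to checking all hits.

Both metrics are symmetric by construction. The RBH set is
direction-free; per-pair identities and alignable regions are measured on
the alignment computed in a canonical orientation (genomes ordered by
id), so `f(A,B)` and `f(B,A)` are bit-identical, with `(C1,T1)` and
`(C2,T2)` swapping roles. The identity `pocp·(T1+T2) = 100·(C1+C2)` holds
to 1e-9 and is asserted in tests.

Genus decisions use means: a genus pair is *congeneric* when its
inter-genus mean AAI ≥ 65% **and** mean POCP ≥ 50% (both inclusive),
*distinct* when both fall below, *ambiguous* otherwise. Ambiguous pairs
never create merge edges — both metrics must converge — but remain in the
evidence tables. Merge proposals are connected components of the
congeneric-pair graph: single linkage, i.e. congeneric-ness is treated as
transitive, the simplest rule consistent with merging several genera into
one. Means are taken over all genome pairs by default (a
type-strains-only restriction is a matter of subsetting the label map).
The component's proposed name comes from a user-supplied nomenclatural
priority list, falling back to the lexicographically smallest genus;
automatic priority inference from publication dates is out of scope.

## PUL, PUL-like and CGC detection

Marker genes are degradative CAZymes (GH, PL, CE, CBM, AA — glycosyl
transferases excluded), sulfatases, TBDTs (susC-like transporters) and
susD-like genes. Markers on one contig chain into a cluster by single
linkage whenever their gene ordinals differ by ≤ `max_gap_genes`
(default 10, inclusive: a gap of 10 means up to 9 intervening genes).
The often-quoted seven-gene scan window is an implementation detail of
scanning and cannot change membership; the within-ten-genes linkage is
the operative rule. Strand is ignored. Clusters need ≥ 2 markers and, by
default, ≥ 1 degradative CAZyme. Classification follows the PUL
literature's susC/susD-tandem convention, since the three class names are
conventional rather than formally defined: a TBDT and a susD gene at
adjacent ordinals plus a degradative CAZyme make a PUL; a transporter
gene without such a tandem makes the cluster PUL-like; the rest are CGCs.
All three criteria are configurable. Genome summaries count every
CAZyme-labeled gene (GT included) genome-wide, not only cluster members.

## 16S distances, neighbor joining, bootstrap

Pairwise 16S identity excludes gap columns from the denominator
(EzTaxon-like); a BLAST-style include-gaps variant is a flag, because
published similarity percentages are platform-dependent. Distances from a
multiple alignment (the alignment itself is an input; only pairs are
aligned in-package) use pairwise-complete columns — both sequences an
unambiguous A/C/G/T — with p-distance, JC69
(`d = −(3/4)·ln(1 − 4p/3)`) or K2P
(`d = −(1/2)·ln((1−2P−Q)√(1−2Q))`). K2P is the default, the common
choice for rRNA NJ trees. Pairs whose log argument is non-positive are
flagged *saturated*; tree building refuses saturated matrices rather than
guessing.

Neighbor joining is the standard Saitou–Nei agglomeration with the Q
criterion. Ties on Q resolve to the smallest (i, j) index pair; negative
intermediate branch lengths are clamped to zero with the deficit moved to
the sister edge (a display convention that leaves path lengths of
additive matrices untouched). On exactly additive matrices the algorithm
provably returns the generating topology with exact edge lengths, which
the tests exploit as an oracle (random trees → path-length matrices →
rebuild → compare, to 1e-9).

Bootstrap supports resample alignment columns with replacement
`n_bootstrap` times (default 1,000, seeded) and score each internal edge
of the full-data tree by the percentage of replicate trees containing the
same bipartition (normalized against a reference taxon so rootings do not
matter), rounded to the nearest integer. Supports below
`min_show_support` (default 50) are retained but flagged hidden, the
usual >50%-shown display rule. Replicates whose resampled distances
saturate are skipped and removed from the denominator.

## Module completeness

Definition strings are parsed with precedence minus > plus > comma >
space (parentheses override): space-separated blocks are sequential
steps (AND), commas are alternatives (OR), plus joins complex subunits
(all required), and minus-prefixed components are optional. Completeness
is block-level — `100 · satisfied / total` over the top-level AND blocks
— matching step-fraction semantics; optional components are excluded from
both numerator and denominator, and a definition with no non-optional
step is rejected at parse time. The score is monotone in the KO set.

## Synthetic data: what it emulates, what it does not

Ortholog pairs are generated by substitution-only point mutation, so
each pair's realized identity is exact by construction (`100·(L−k)/L`)
and serves as the oracle for AAI recovery; background proteins are i.i.d.
uniform over the 20 residues (collision probability negligible at the
default 100–400 residue lengths). An indel-free generator keeps the
oracle clean but means the benchmarks do not probe gap handling under
realistic indel processes, nor paralogy, domain shuffling, or
composition bias — passing them shows the metric machinery is correct,
not that real genomes behave this simply. The small residual bias of
measured AAI above realized identity (strongest near 50% identity,
≈1–1.5 points at default lengths) is real: local alignment trims
negative-scoring ends, which raises identity slightly; shortening
proteins amplifies it.

Planted gene tables separate clusters (and background singleton markers)
by more than the chaining gap, so exact recovery is the correct expected
outcome; tables with adversarial spacings are exercised separately in
unit tests. Alignments evolve site-independently under JC69 or K2P
(κ default 2) from a uniform root — no rate heterogeneity, no indels, no
base-composition drift.

## Problem sizes and runtime choices

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path while keeping the full suite in minutes: oracle equivalence on
20 proteome pairs of ≤ 26 proteins; parameter recovery on 25+25-protein
pairs with 12 orthologs at default lengths, 20 seeds × 6 identity levels;
the POCP construction at 100+100 proteins; 200 planted-cluster tables;
100 random additive matrices of 4–8 taxa; bootstrap with 200 replicates
on 10-taxon alignments of 500 columns. All seeds are fixed or derived
from a single command-line seed.

## Known limitations

* E-value constants are fixed for BLOSUM62/11/1; changing the matrix or
  gap costs without adjusting λ and K distorts e-values (scores and
  identities are unaffected).
* AAI/POCP values are aligner-sensitive in the second decimal; published
  values computed with other search tools are reproducible only
  approximately.
* Multiple sequence alignment, gene calling, CAZyme/KO annotation and
  ANI are inputs or out of scope, not computed here.
* The susC/susD-tandem PUL definition is a convention; per-genome PUL
  counts from pipelines with different conventions will differ.
* Single-linkage genus merging assumes congeneric-ness is transitive;
  a chain of borderline pairs can pull distant genera into one
  component. The evidence tables expose every pairwise mean so such
  chains are visible.
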