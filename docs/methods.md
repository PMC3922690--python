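# Methods

## Signal quantification

Loci come from BED6+ files (0-based half-open); row order of every
matrix follows the file.  Three-column records get generated names
`locus_<i>`; duplicate names are suffixed; records with `start >= end`
are dropped with a warning naming the line.  A mapped read contributes
to every locus its aligned reference span (including deletions and
splices) overlaps by at least one base, strand-blind; a read spanning k
loci counts in all k.  Unmapped, secondary, supplementary and QC-fail
records are always excluded.  Duplicate-flagged reads are *kept* by
default (`--filter-dup` reverses this) and no MAPQ floor is applied
(`--min-mapq`): ChIP-seq inputs of the era this method targets usually
retained duplicates, and both choices are exposed rather than imposed.
No fragment-size extension or paired-end reconstruction is performed —
each mapped record counts once.

In windowed mode a locus of length L is tiled left-to-right into
⌈L/w⌉ non-overlapping windows (default w = 100 bp; the last window may
be short).  A read overlapping two windows counts in both, so window
sums can exceed whole-locus counts.  One ambiguity was resolved here:
where a "step" parameter could mean either window width or a sliding
stride, the implementation has a single parameter, the non-overlapping
window width.

## Column scaling

Each column x of V is scaled with x̂ = 2/(1 + e^(−2x/u)) − 1, u being
the 95th percentile of x under the linear-interpolation percentile
estimator (the estimator is a documented choice; any reasonable
percentile definition changes u marginally).  The map is exactly 0 at
0, strictly below 1, monotone, and scale-invariant (u rescales with the
data), which equalizes marks of very different dynamic range.
Degenerate columns: an all-zero column is passed through as zeros with
a warning; if ≥ 95 % of entries are zero (u = 0) the smallest positive
value is used as u.

## Differential gain/loss

Per mark, window counts of the two conditions are pooled into a
(windows × 2) matrix and depth-corrected with median-of-ratios size
factors (rows containing a zero are excluded from the median; if no
all-positive row exists the user is told to coarsen windows).  Size
factors are computed per mark because each ChIP library has its own
depth.  Replicates within a condition are merged by summing window
counts.  The per-window difference B/f_B − A/f_A is integrated into
gain = Σ max(diff, 0) and loss = Σ max(−diff, 0); both are stored as
non-negative magnitudes so the NMF non-negativity constraint applies
directly.  A broadened peak — lower at the summit, higher at the
flanks — yields gain > 0 *and* loss > 0 at one locus, which whole-locus
subtraction would cancel.  Numerical guard: window differences below
10⁻⁹ of the locus's depth-corrected coverage scale are snapped to zero;
exactly-cancelling conditions otherwise leave float dust that the
scale-invariant sigmoid would amplify into spurious signal.  The 2m
gain/loss columns are sigmoid-scaled like any other signal.

## Factorization

Objective: ‖V − WH‖²_F + λ Σ H, W ≥ 0, H ≥ 0, with the l1 penalty on H
only so codes stay combinations of few marks.  Because the penalty
touches only H, the objective alone is scale-degenerate (inflate W,
deflate H); the columns of W are therefore constrained to the unit
l2 ball during optimization and H rows carry the magnitude.  The
optimizer is HALS — cyclic exact minimization over W columns and H
rows.  Each block objective is an isotropic quadratic, so the
constrained block minimum is the projection of the unconstrained one
and the penalized objective is monotonically non-increasing (the
recorded trace asserts this).  HALS can re-activate entries that are
zero at initialization, which matters because plain NNDSVD starts
roughly half the entries at exactly zero.  After convergence W is
re-solved by exact row-wise NNLS against the final H: this only lowers
the unpenalized error, gives weights that are optimal given the codes,
and makes the one-class discriminatory pipeline bit-identical to the
absolute pipeline.

Defaults (documented choices where the method itself fixes none):
λ = 0.1 on sigmoid-scaled data, tol = 10⁻⁴ relative change of the
penalized objective, max_iter = 500.  The reported
`reconstruction_error` is always the unpenalized Frobenius norm.
All-zero rows of V are retained (their weights converge to zero) to
keep row indexing aligned with the region set.

NNDSVD: truncated SVD of V; the leading singular triplet enters with
absolute values; each later triplet is split into positive and negative
parts, the part pair with the larger norm product is kept — ties go to
the positive part, deterministically — and rescaled by its singular
value.  `nndsvdar` replaces exact zeros with seeded uniform draws from
(0, mean(V)/100]; `random` fills W and H with uniform [0, 1) draws.
NNDSVD orders codes roughly by explained variance, keeping numbering
comparable across datasets.

The rank scan records mean Hoyer sparsity of H rows and W rows and the
reconstruction error per candidate c; no automatic rank selection is
attempted, the curves are for locating a knee.  Hoyer sparsity
(√n − ‖v‖₁/‖v‖₂)/(√n − 1) is undefined for length-1 vectors, so W-row
sparsity is reported as n/a at rank 1.

## Discriminatory details

Each class is sigmoid-scaled with its own column percentiles (a
class-specific u) and factorized separately; the combined NNLS step
reuses each class's own scaled submatrix.  Rationale: the per-class
stage is exactly the absolute pipeline run per class, and rescaling
globally afterwards would make the stacked H incommensurable with the
matrices it was trained on.  Codes carry provenance labels
`<class>:code_<j>`.  The default gives every class the same c,
overridable per class.

## Enrichment

The random-set statistic for a gene set of size m over N scored genes
uses the exact finite-population moments of the set mean under sampling
without replacement: E[X̄] = μ, Var[X̄] = (σ²/m)·(N − m)/(N − 1) with σ²
the population variance of all scores, and a one-sided upper-tail
normal p-value (a two-sided flag exists).  The population-variance form
was adopted and is validated in the tests against subset enumeration
(exact moments) and permutation sampling (p-values).  The normal
approximation carries an O(1/m) error; the oracle fixtures therefore
use smooth, near-symmetric score vectors and moderate set sizes, and
the exact-moment check is the binding one at very small m.  Loci are
mapped to genes via the BED name field; multiple loci per gene are
averaged; raw weights are used without rank transformation.  P-values
are BH-corrected jointly over every (code, set) pair — the stricter
family — with per-collection slicing left to the caller.  Degenerate
all-equal scores return (z = 0, p = 0.5), the continuous limit of the
statistic.

## Synthetic benchmarks

The planted generator draws codes with disjoint dominant mark sets of
at most three marks (dominant entries equal within a code), gives each
locus one primary code weight uniform on 0.6–1.4 and, with probability
0.3, a secondary code at a quarter weight, adds Gaussian noise, clips
at zero and sigmoid-scales.  The standard benchmark size is n = 200
loci, m = 8 marks, c = 3 codes, noise sd 0.05 — large enough for stable
recovery statistics, small enough that the full suite runs in seconds.
The two-class fixture gives the classes disjoint halves of the mark
space (or, as a control, an identical basis).  The alignment generator
writes coordinate-sorted, indexed BAMs of 36 bp perfect single-end
reads on a synthetic 100 kb contig `chrS`, with deterministic
placements and a machine-readable truth table per dataset.  None of
this emulates fragment-length distributions, GC or mappability biases,
input-control structure or replicate noise of real ChIP-seq, so passing
tests demonstrate algorithmic correctness on the stated generative
model, not performance on real libraries.

## Known limitations

* Differential mode supports exactly two conditions.
* No peak calling, input subtraction, GC or quantile normalization.
* The l1 weight, tolerance and iteration cap are package defaults, not
  method-prescribed constants; rank c must be chosen by the user.
* Identifier mapping between gene annotation systems is out of scope;
  gene-set members must use the same namespace as the BED names (or the
  supplied locus→gene map).
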