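# Methods

## The statistical problem

A bipartite network is held as a non-negative biadjacency matrix
B (n × m). Nestedness — the tendency of each node's interaction set to be a
subset of busier nodes' sets — is treated as a context-free property of the
matrix: row and column order carry no information, so any order-sensitive
score is computed on a canonical maximally nested arrangement. Because every
nestedness score is strongly confounded by matrix size and fill, an absolute
score is never interpreted; instead it is compared against ensembles of
random matrices that conserve chosen properties of the input.

The pipeline is: read → drop empty rows/columns → sort → score the observed
matrix with the selected measures → for each selected null model, draw an
ensemble, push every draw through the identical strip/sort/score path, and
summarize (mean, SD, z, normalised temperature, p-value).

## Sorting

`degree_sort` orders rows and columns by descending degree (count of nonzero
entries). Tie-breaking is deterministic:

* binary data — descending lexicographic comparison of the 0/1 line vector,
  then ascending original index. Columns are ordered first (vectors read in
  the input row order), then rows against the new column order.
* weighted data — between equal-degree lines, the one with greater values on
  the majority of mutually occupied positions ranks first; then descending
  total sum; then ascending original index. The pairwise "majority" rule is
  applied through a comparator and is not guaranteed transitive on
  adversarial inputs; with generic (tie-free) weights it never fires beyond
  pairs and the order is well defined.

The context-free contract — identical scores for any row/column permutation
of the input — holds exactly whenever equal-degree lines are either
identical or distinguishable by these rules; the test suite exercises it
with 100 random permutations per fixture. Binary matrices containing
equal-degree lines with different patterns can, in principle, resolve ties
differently for different input orders; this residual sensitivity affects
only the discrepancy and temperature scores and is a known limitation.

`ntc_sort` (used only by the temperature) starts from the degree sort of the
presence pattern and hill-climbs over adjacent row-pair and column-pair
swaps, accepting a swap only when the temperature strictly decreases, until
a full sweep changes nothing. A deterministic local search was chosen over
stochastic optimizers (e.g. genetic algorithms used historically for
temperature) so that repeated runs are bit-identical; the result is a local
optimum no warmer than the degree-sorted arrangement, not a certified global
optimum (globally optimal ordering search is combinatorial and out of
scope).

## Temperature geometry

The matrix maps to the unit square (cell midpoints, origin top-left). An
isocline of perfect order separates the presence side (top-left) from the
absence side with presence-side area equal to the fill proportion
p = F/(n·m). Every unexpected cell — a presence on the absence side or an
absence on the presence side — contributes u = (d/D)², where d is the
distance from the cell midpoint to the isocline along the cell's
negative-slope diagonal direction and D = √2 is the full main-diagonal
length. The temperature is

    T = 100 · Σu / (U_max · n · m),  U_max = 0.04145,

the classic normalisation constant placing maximally disordered matrices
near 100.

Two geometric choices were genuinely open and are fixed as follows:

* **Isocline family.** The straight line x + y = c, with c solving the area
  constraint in closed form (c = √(2p) for p ≤ ½, else 2 − √(2(1−p))). A
  curved family would also satisfy the contract; the straight line is the
  simplest monotone-decreasing boundary, gives T = 0 on perfectly nested
  staircases and full matrices, and makes d available in closed form
  (d = |x + y − c|/√2).
* **D constant.** Taking D as the square's main-diagonal length (√2) rather
  than the chord through each cell keeps per-cell unexpectedness bounded by
  ¼ everywhere; a cell-dependent chord would weight near-corner cells
  enormously and push disordered matrices far beyond the nominal 0–100
  scale. With D = √2, a fully anti-nested arrangement (all mass in the
  wrong corner) scores ≈100, while unsorted checkerboards and random
  matrices sit near 50.

An independent oracle in the test suite re-derives the same quantity with
numeric area integration and root-finding instead of the closed forms.

## Measures — conventions that needed fixing

* **NODF**: ordered pairs only, strict decreasing fill (equal fills
  contribute 0); a pair whose sparser line is empty contributes 0.
* **MD**: 0-based offsets from the top-left, unnormalised — the normalised
  temperature T = M/⟨M⟩ provides scale-freeness downstream, so no per-matrix
  normalisation is applied.
* **JDM**: score = (Σ observed pairwise overlaps)/(Σ expected), expectation
  k_a·k_b/s per same-side pair with s the opposite side's size, both sides
  pooled before the ratio. Complete matrices score exactly 1.
* **BR**: computed row-wise against the leftmost-r_i packing with columns in
  their sorted order.
* **Binary-only measures on weighted data**: the matrix is sorted once with
  the weight-aware rules, then NODF/MD/NTC/JDM/BR read the presence pattern
  of that arrangement, so all measures in one run see the same
  configuration.
* **Direction detection** is empirical: each measure scores a reference
  weighted nested staircase (10×10, entry 12−i−j on i+j ≤ 11) and a
  reference weighted checkerboard (10×11, entry 4 on even i+j), both with
  55 nonzero entries summing to 220; "more nested" is whichever direction
  separates them. This keeps newly added measures orientable with no other
  code changes.

## Null models

Cell probabilities for the degree-based models use
p_ij = (k_i/m + d_j/n)/2 (row degree k_i, column degree d_j): DD draws each
cell independently with p_ij; CC instead fixes the fill exactly and samples
F cells without replacement with inclusion weight proportional to p_ij; EE
uses the constant p = F/(n·m). SS places F cells uniformly. The published
description of CC ("some structure preserved, rest shuffled", conserving
shape and fill) does not pin down a mechanism; fill-constrained
degree-weighted sampling is this package's reading, and results under CC
should not be assumed numerically interchangeable with other
implementations.

FF conserves both degree sequences exactly via curveball trades: repeatedly
pick two rows and randomly reallocate the columns held by exactly one of
them. One draw applies 5·max(n, m) trades; successive draws continue the
same chain, whose stationary distribution is uniform over matrices with the
observed margins (verified by chi-square on an exhaustively enumerable
case). Draws from one chain are exchangeable but serially dependent; for
ensemble summaries (means, quantiles) this is immaterial.

Weighted models keep the zero pattern fixed. CRT redraws each row's weights
over its occupied cells and rescales to the row total — integer rows get 1
unit per occupied cell plus a uniform multinomial remainder (keeping integer
matrices integer and every occupied cell positive), other rows get symmetric
Dirichlet(1) shares times the total (positive almost surely). CCT mirrors
this on columns; RCTA averages one independent CRT and CCT draw, conserving
the grand total exactly and row/column totals in expectation. DD/EE/CC can
produce empty lines; draws are returned untouched so the conservation
contracts stay literal, and the ensemble stage strips empty lines before
scoring (a draw collapsing to nothing is redrawn; 1,000 consecutive
collapses abort).

## Ensembles and statistics

One ensemble of draws serves all selected measures, so scores of different
measures are comparable member by member. The adaptive scheme grows two
groups from 500 in steps of 500 per group, comparing the groups' scores of
the *first* selected measure with a two-sided Mann–Whitney U-test (normal
approximation with tie and continuity corrections at these sizes) after
each step; p > 0.10 merges them. The per-first-measure policy and the
500-step increment are this package's choices — the growth schedule was not
prescribed — fixed for determinism. The cap of 100,000 applies to the
combined size. The floor of 1,000 guarantees p-values down to 0.001 are
resolvable.

p counts ensemble members *strictly* more nested than the observed score
(ties count as not more nested — conservative); a zero count reports the
resolution bound p = 1/N with an explicit flag, rendered "<1/N" in reports.
SD uses the N−1 denominator. A constant ensemble (σ = 0) yields z = missing
with a warning; a zero-mean ensemble yields T = missing.

Randomness: one user seed; null model k draws from an independent substream
seeded by (seed, k), so adding measures or later models never perturbs
earlier draws, and every run is bit-reproducible.

## Problem sizes in the test suite

The statistical suites run at desk scale: conservation contracts over 1,000
seeded draws per null model across 5 fixture matrices (≤ 8×8); curveball
uniformity with 30,000 chained draws on a 3×3 all-degrees-2 matrix (6
reachable states); p-value calibration with 200 replicates of N = 1,000
uniform-shuffle ensembles on a 10×10, fill-30 matrix; NODF against a
brute-force oracle exhaustively over all nonzero binary matrices up to 4×4;
sort-invariance over 100 random permutations per fixture. The calibration
experiment draws both the "observed" matrix and its ensemble from the same
null, making the p-value's rank uniform by exchangeability; the check
asserts P(p ≤ 0.05) within 0.05 ± 0.03.

## What the synthetic fixtures do and do not show

Fixture generators produce perfectly nested staircases (binary and
weighted), checkerboards, and uniform random binary matrices. These span the
extremes measures must pin down (NODF 100 / temperature 0 / WNODF 100 on
perfect order; direction separation on the checkerboard) and give
calibration-friendly null inputs. They do not emulate the heavy-tailed
degree distributions, modularity, or sampling noise of real interaction
data, so passing tests demonstrate correctness of the computations and
calibration of the statistics under the stated nulls — not that any
particular empirical network is, or is not, nested.

## Known limitations

* NTC's arrangement is a deterministic local optimum; matrices with rugged
  temperature landscapes may admit colder arrangements.
* The CC mechanism and the CRT/CCT redistribution laws are this package's
  operationalizations of loosely specified models (see above); conclusions
  that hinge on those specific nulls should say so.
* Sort tie-breaking can retain residual input-order sensitivity for binary
  matrices containing equal-degree, non-identical lines (affects BR/NTC
  only).
* The adaptive U-test monitors the first selected measure only; a measure
  whose null distribution mixes more slowly than the first's may be
  marginally undersampled at the merge point.
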