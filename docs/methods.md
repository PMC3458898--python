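# Methods

## Problem and representation

`hexilp` learns human-readable first-order rules that discriminate
hexose-binding protein sites from non-binding ones.  A binding site is the
set of protein heavy atoms within a 10 Å sphere of a *binding center* — the
centroid of the bound hexose's pyranose ring (C1–C5, O5) for positives, and
the ligand or cavity-serial centroid for negatives.  The 10 Å radius follows
from the geometry of the problem: pyranose ring atoms lie up to 2.9 Å from
the ring centroid and atomic interactions can matter out to about 7 Å, so the
sphere covers the docked sugar plus its first interaction shell.  The sphere
boundary is inclusive (distance ≤ radius); atoms exactly at 10 Å are kept.

Each site becomes a set of ground Prolog facts (`center_coords/2`,
`has_aminoacid/3`, `has_atom/4`), from which distance predicates are derived
at query time.  Two hypothesis languages are supported:

* **atom-only** — `center_coords/2, has_atom/4, dist/4`: the site is a bag
  of points; one inter-atom distance costs three literals (two `has_atom`
  plus one `dist`).
* **amino acid** — `has_aminoacid/3, atom_to_center_dist/4,
  atom_to_atom_dist/6, diff_aminoacid/2`: residues own their atoms and must
  be introduced by `has_aminoacid` before any distance literal may touch
  them ("no dangling atoms").  `diff_aminoacid` asserts residue-identifier
  inequality only, so two residues of the same name can be distinguished.

Distance literals store a constant rounded to 0.1 Å and match an observed
distance `a` iff `|a − d| ≤ t`, with tolerance `t = 0.5 Å` by default — a
sensible error margin for hexose-site geometry.

## Recall bound and background ordering

Bottom clauses enumerate at most *recall* solutions per non-determinate
predicate (default 7).  Because only the first *recall* solutions are taken,
the order of residues and atoms in the background knowledge is semantically
load-bearing.  Three ordering schemes are implemented:

* `primary_sequence` — source-file order;
* `randomized` — a seeded uniform permutation of residues and of atoms
  within residues.  The per-site generator seed is
  `global_seed XOR crc32(site_id)` (masked to 31 bits), so a site's
  permutation is independent of dataset order;
* `domain_dependent` — atoms ascending by distance to the binding center;
  residues ordered by their *closest* atom.  The residue key is our choice
  (the atom ordering principle does not itself induce a residue order); it is
  implemented as a stable sort with ties broken by source order, which also
  makes the scheme idempotent.

## Saturation

The bottom clause of an example is the conjunction of all features admissible
under the recall caps, in site order.  In the amino-acid language the first
`recall` residues are introduced; each introduced residue contributes an
`atom_to_center_dist` literal for its first `recall` atoms, and each such
atom contributes `atom_to_atom_dist` literals to the `recall` most recently
enumerated atoms of already-introduced residues (intra-residue pairs
included; each unordered pair appears once).  `diff_aminoacid` is generated
only for pairs of introduced residues that share a name — that is the only
situation in which it adds discriminative power, and it keeps bottoms small.
In the atom-only language `center_coords` introduces the center point, the
first `recall` atoms are introduced by `has_atom`, and each new point gets
`dist` literals to the `recall` most recent earlier points (center included).
Bottom clauses expose the center only through distances; the body size is
bounded by a closed form in `recall` and the per-predicate arities, which the
test suite asserts on random sites.

## Coverage

A clause covers a site iff a variable binding satisfies every body literal
(θ-subsumption over the ground facts, distances memoized per site).  Two
complete strategies are provided: left-to-right depth-first backtracking
(SLD-style) and a fail-first *smallest-domain* strategy that at each step
evaluates every literal whose inputs are bound and resolves the one with the
fewest candidate extensions.  Both short-circuit on the first solution and
always agree on the covered/uncovered answer; the package asserts answer
equivalence (together with a brute-force enumerator over all variable
assignments, guarded to ≤ 60 atoms) rather than relative speed.  Full
enumeration of bindings, with realized distances per literal, is kept to the
`instantiate` explanation path.

## Learning

Search is specific-to-general.  From a sampled seed positive's bottom
clause, *asymmetric relative minimal generalization* (ARMG) drops the
minimal set of body literals needed to also cover another positive: the body
is scanned left to right and a literal is kept iff its input variables
survive in the kept prefix and the prefix extended with it still admits a
binding on the new example.  The result provably covers both examples, and
dropping a `has_aminoacid` automatically drops its dependent distance
literals.  The partial-solution frontier carried through the scan is capped
at 256 bindings; a surviving binding always witnesses coverage, so the cap
can only make a reduction slightly more general, never unsound.

Candidates are scored by **compression** `P − N − L` (positives covered −
negatives covered − clause length including the head) and must cover at most
`noise_cap` negatives (default 5).  The beam search (width 3, five sampled
reduction examples per iteration, both config-exposed) stops when no
extension strictly improves compression.  These two search-breadth
parameters are this package's own; the underlying system defers them to its
implementation.

The final **theory** is built globally after all candidates exist: clauses
are added greedily by union-coverage theory score
`|pos covered| − |neg covered| − Σ lengths` while the score strictly
improves, with ties broken toward higher P, shorter clauses, then clause
text.  Union coverage avoids double-counting positives shared by overlapping
rules.  Covered positives are *not* removed during candidate generation —
the point of global construction.  Prediction is any-of: a site is positive
iff some theory clause covers it.

## Evaluation

The benchmark protocol is fixed-assignment 10-fold cross-validation (8
positives + 8 negatives per fold on the 160-site manifest): train on nine
folds, test on the held-out one.  Summaries report the arithmetic mean and
the *sample* (n−1) standard deviation — verified to reproduce the published
Mean/Std Dev rows to one decimal.  Method comparisons use a two-tailed
paired Student t-test on per-fold accuracies (df = n−1, via
`scipy.stats.ttest_rel`); identical columns return `t = 0, p = 1` by
convention.  The published fold-accuracy columns are packaged as fixtures,
and all seven published p-values (0.026, 0.021, 0.043, 0.004, 0.029, 0.025,
0.005) are reproduced at printed precision.  The original fold assignment is
not public, so replication runs accept any user-supplied fold file;
homology-constrained folding over CATH superfamilies is not implemented (it
is infeasible for this dataset because sites span multiple superfamilies).

## Synthetic data

The generator emulates the statistical structure of the task without
structure downloads: *carrier* sites embed a planted relational pattern
(e.g. two distinct asn residues plus an asp whose CG atom is 5.4 Å from the
center) with realized distances inside the matching tolerance minus a jitter
margin (default 0.2 Å), while non-carriers are rejection-sampled until the
pattern's clause verifiably fails to cover them.  Decoy residues (3–6 per
site, 3–5 atoms each) draw from the 20 standard amino acids with canonical
heavy-atom names, placed uniformly in the 10 Å ball.  Defaults are 20
positives and 20 negatives with pattern frequencies (1.0, 0.0) — a
noise-free planted-pattern regime sized so the whole learn cycle runs in
about a second.

What passing on synthetic data does and does not show: the generator
guarantees relational/geometric ground truth (exact carrier labels, exact
planted distances) but not protein realism — no covalent geometry, no
packing, no homology structure, no class imbalance.  Recovery of planted
rules demonstrates the correctness of saturation, reduction, scoring and
theory construction; it does not certify the published cross-validated
accuracies on the real 160-site benchmark, which require the original PDB
structures and folds.  The evaluation harness runs that experiment unchanged
when a user supplies extracted sites and a fold file.

## Numerical choices and degenerate inputs

* Coordinates are stored at full precision and serialized at one decimal;
  distance constants are rounded to 0.1 Å before storage.
* Altloc conformers: highest occupancy wins; non-standard residues, waters
  and hetero atoms inside the sphere are dropped (the mode language covers
  only the 20 codes).
* Negative-example cavity centers given as atom serials are resolved as the
  centroid of those serials' coordinates.
* An empty site saturates to the head-only clause `bind(A):- true`, which
  covers every site; an empty theory predicts negative everywhere.
* RNG streams all derive from a single user seed; derived seeds are masked
  below 2^31.

## Known limitations

* Only the five site predicates of the fact dialect are parsed — this is not
  a general Prolog reader.
* The top-down comparator system is not reimplemented; its published fold
  accuracies enter only as t-test inputs.
* Synthetic geometry is not physically realistic (documented above).
* Greedy global construction is not guaranteed optimal over candidate
  subsets; the test suite checks optimality only on small instances where
  exhaustive enumeration is feasible.
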