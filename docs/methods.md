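# Methods

## Scope and model

`grinmap` treats the three major NMDA-receptor subunits (GluN1, GluN2A,
GluN2B) as a family whose amino-terminal (ATD), ligand-binding (LBD) and
transmembrane (TMD) domains are structurally conserved, and whose
C-terminal domain is unsolved.  The object of interest is the *equivalence
map*: for each unordered subunit pair, a partial bijection between
canonical residue positions, assembled per domain from rigid-body
superposition and, where coordinates are missing, from sequence alignment.
On top of the map sit two consumers: annotation transfer (extrapolating
pathogenicity and functional class between homologous missense variants)
and concordance evaluation (measuring how often annotations agree at
equivalent positions).

Canonical numbering is 1-based over the full-length protein with signal
peptide, the convention of clinical HGVS `p.` names.  Other numberings
(deposited constructs, ortholog structures) are rewritten through a
`NumberingMap` derived from a global sequence alignment against the
canonical sequence; mismatched residues remain mapped — they are alignment
columns — so a near-identical ortholog chain can stand in for the human
protein, with the mismatches visible downstream.

## Superposition

`kabsch` computes the least-squares proper rigid transform via SVD of the
cross-covariance of centered coordinates; when the SVD solution is a
reflection the smallest singular direction is sign-flipped.  Degenerate
(collinear) geometry and fewer than three pairs are errors.

`iterative_superpose` mirrors align-style refinement: fit on a seed residue
pairing, reject pairs whose post-fit CA distance exceeds `reject_cutoff`
(default 2.0 Å), refit, up to `cycles` (default 5) rounds, stopping early
when nothing is rejected.  Two deliberate choices:

* **Annealed rejection.**  At most the worst 30 % of retained pairs are
  dropped per cycle.  A partially wrong seed register then refines toward
  the self-consistent majority instead of rejecting everything at once and
  collapsing.  Retention never falls below three pairs.
* **Convergence guard (pipeline level).**  If the retained-pair RMSD is
  still above the rejection cutoff after the final cycle, the fit never
  found a consistent register; the pipeline discards the structural
  alignment for that domain pair rather than emit pairs from a wrong
  superposition, leaving the region to the sequence fallback.

Both the retained-pair RMSD and the all-seed-pair RMSD under the final
transform are reported, since superposition tools differ in which they
print; domain-level comparisons should be read with a tolerance of a few
tenths of an Å for exactly that reason.

## Alignments

The structure-based alignment pairs residues that are mutual nearest
neighbours within `pairing_cutoff` (default 4.0 Å) after superposition,
then keeps the maximum-cardinality non-crossing subset (longest increasing
subsequence on the partner positions; candidate scan ordered by distance).
Mutual nearest neighbours make the pairing one-to-one before pruning, so
the LIS step only removes order violations.

Sequence alignment is Needleman–Wunsch through Biopython's
`PairwiseAligner` with BLOSUM62, gap open 10 and gap extend 0.5 (a gap of
length L costs `10 + (L−1)·0.5`); the first optimal traceback is used,
which is deterministic.  Sequence-derived pairs enter the equivalence map
only inside runs of at least five consecutive aligned columns
(`min_fallback_run`), a guard against spurious single-residue matches in
low-identity stretches; structural entries always take precedence at a
contested position.

Identity statistics support two denominators: aligned columns (pairs plus
gap columns; the default, and the convention used for the per-domain
summary) and aligned pairs only.  Both are exposed because published
identity tables are ambiguous about the convention; values are exact
internally and rounded to two decimals only for display.

## Equivalence map and three-way consistency

Each subunit pair's entries form a partial bijection (enforced at
insertion; conflicting claims raise).  The three pairwise maps are built
independently, so composed lookups (GluN1→GluN2A→GluN2B vs direct
GluN1→GluN2B) can disagree; `check_three_way_consistency` reports such
triangles and nothing is auto-repaired.  In practice inconsistencies arise
only in fallback-covered low-identity tails (CTD), where global sequence
alignments of three diverged sequences need not compose.

## Transfer semantics

A homolog is a database variant with the same reference and substituted
residue at the equivalent position of another subunit — variants differing
in either residue are explicitly non-informative.  Pathogenicity and
functional class transfer independently; uncertain-significance and
unannotated values neither transfer nor veto.  Disagreeing confident
supporters yield `conflict` with no call (no majority vote: the tool is
clinical-adjacent, and silence beats a coin flip).  Predictions are emitted
as a separate table with an `inferred-by-homology` provenance column and
never merged into observations.  Transfer is idempotent at the call level:
accepting all predictions and rerunning produces no new calls.

## Concordance evaluation

Variants are grouped within equivalence classes of positions by category:
homologous (same ref, same alt), same-final (same alt, ≥ 2 distinct refs),
same-initial (same ref, ≥ 2 distinct alts; extra members from the same
subunit at the same position are kept, covering the
one-position-two-substitutions comparisons).  The categories are disjoint
by construction.  For pathogenicity, uncertain members are discarded first
and a group left with fewer than two members leaves the denominator; a trio
counts as one group and must agree in full.  Functional concordance treats
`complex` as its own class.

## Synthetic data generator

Everything is testable offline through `fixtures`:

* **Toy chain pairs** (`make_structure_pair`): an ideal helix (100° twist,
  1.5 Å rise, 2.3 Å radius) or zigzag trace; chain B is a seeded random
  rigid transform of chain A plus optional Gaussian coordinate noise and
  per-residue displacements, with the ground-truth correspondence and
  transform returned for recovery tests.
* **The demo trio** (`write_demo_workspace`): three synthetic canonical
  sequences with the real numbering relationship planted — GluN2A is the
  master (1464 aa), GluN2B inserts one residue after the signal peptide
  (offset +1, 1484 aa), GluN1 deletes one (offset −1, 938 aa) — so the
  printed homologous positions (GluN2B 459↔GluN2A 458 … 824↔823, GluN1
  685↔GluN2B 687) hold by construction and must be *recovered* by the
  pipeline, not assumed.  Domain architecture uses LBD = 317 and TMD = 140
  positions per subunit.  Coordinates follow a shared master helix **with a
  deterministic smooth meander** (amplitudes 2–3 Å, periods 7–18 residues):
  a pure helix has a screw symmetry under which a register-shifted
  superposition is itself a rigid motion, and the meander removes that
  degeneracy.  Per-chain Gaussian noise (default σ = 0.25 Å per coordinate,
  i.e. ≈ 0.61 Å expected pairwise RMSD) models independent experimental
  error.  Signal peptide and CTD carry no coordinates, exercising the
  fallback path; the deposited GluN2B chain uses construct numbering
  (canonical − 2), exercising renumbering.
* **Divergence model.**  Substitutions are applied per domain with shared
  per-site variability: one uniform draw per site decides which subunits
  diverge there, so sites mutable in GluN2B are also mutable in GluN1 (rate
  heterogeneity among sites, as in real families).  This keeps cross-pair
  identity near the per-subunit level instead of the product of rates.
  Default rates give GluN2A–GluN2B identities of ≈ 55 / 85 / 93 % for
  ATD / LBD / TMD and ≈ 26–38 % for the GluN1 pairs.  The real GluN1 ATD is
  more diverged (≈ 12–15 % identity); a sequence-seeded toy at that level
  has no recoverable register, because the toy geometry lacks the deep fold
  conservation that rescues real low-identity superpositions — a stated
  limit of what passing tests show about real data.
* **Planted variant tables.**  Homologous pairs are planted at
  identical-residue mapped positions with an annotation-agreement
  probability `p`; exactly `round(p·n)` groups agree (which ones is
  randomized and seeded), so the realized rate equals the planted rate and
  the generation ledger reconciles with the concordance reports.
* **Concordance benchmark** (`make_concordance_benchmark`): a synthetic
  stand-in with a fixed census of comparison groups (33 homologous groups /
  78 filtered variants, 13 same-final with one discordant pair, 72
  same-initial with 59 coincident and 23/30 functional agreements).  The
  variants are fabricated; only the group/annotation structure is
  meaningful.  It pins the grouping and counting rules, not any property of
  real variant data.

All generators draw from explicit per-spec seeds (`numpy` `SeedSequence`
streams); identical seeds give byte-identical workspaces.

## Numerical choices and degenerate inputs

Rotation orthonormality and det = +1 are enforced to 1e-6.  Kabsch raises
on rank-deficient (collinear) input, detected via the second singular
value.  Tie-breaks: alternate locations keep the highest occupancy, first
in file on ties; MSE reads as MET; other non-standard residues are dropped
with a warning.  Structure round-trips through fixed-width PDB are exact to
1e-3 Å.  Problem sizes in tests and the acceptance script (50-residue toy
chains, a ~2 900-residue trio workspace, 200 planted groups, enumeration
oracles at sequence length ≤ 8 and ≤ 6-point rotation search) keep the full
run in the tens of seconds while leaving each statistic well-determined.

## Known limitations

* Only GluN1/GluN2A/GluN2B; GluN2C/2D and GluN3A/B lack the structural
  models this approach needs.
* Missense only; truncating and splice variants are rejected at parse time.
* Rigid-body superposition only — no flexible alignment, no TM-score.
* The fallback sequence alignment is unreliable below ≈ 20 % identity;
  such regions may be left unmapped or flagged as three-way inconsistent.
* Real-structure workflows (public coordinate files for the receptor
  heterodimers and curated OPM-derived domain ranges) run through the same
  `Workspace` interface, but the shipped domain config is an approximate
  reconstruction and should be replaced with curated ranges for production
  analyses.
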