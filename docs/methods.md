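# Methods

## Fragmentation model

A cleavage rule is a SMARTS pattern in which atom maps `:1` and `:2`
label two bonded atoms; every substructure match designates the mapped
bond as cleavable. Matches are collapsed to bond identity: a bond
matched in both orientations, or by several rules, is one cleavable
bond. Ring bonds are never cleavable — deleting a single ring bond
does not disconnect the molecule, so it cannot contribute a fragment —
and are dropped at match time. All parsing, matching, canonicalization
and component extraction is delegated to RDKit; fragment identity is
RDKit canonical SMILES, and open valences left by a cut are saturated
with hydrogens (no attachment-point dummy atoms), so fragments behave
as ordinary molecules downstream.

Cutting b acyclic bonds of a molecule always yields exactly b + 1
connected components, and heavy atoms are conserved. A fragment only
counts if it has at least `min_size` heavy atoms (inclusive: `-n 4`
keeps 4-atom fragments). Because a cut is only useful when every piece
survives this floor, bonds interact:

* a bond is **solo-feasible** when cutting it alone leaves both pieces
  at or above `min_size`;
* two solo-feasible bonds are **compatible** when their joint cut also
  leaves every piece at or above `min_size`.

Solo-feasible bonds and the compatibility relation form an undirected
graph; its maximal cliques — enumerated with Bron–Kerbosch with
pivoting, in deterministic order — are the candidate sets of
simultaneously cleavable bonds. Extensive mode cuts every maximal
clique, one at a time, and pools the canonical fragments; default mode
grows one clique greedily in match order and cuts it, so its output is
always a subset of the extensive output. Solo-infeasible bonds are
excluded from the graph outright: a singleton clique on such a bond
could only produce fragments that the size filter immediately removes.

### Pairwise vs. joint feasibility

Compatibility is checked pairwise, so a clique of three or more bonds
can still strand a middle piece below `min_size` when cut jointly (a
central scaffold whose every arm is compatible with every other).
Such undersized pieces are filtered from the output. This is the one
point where clique-based cutting differs from exhaustive enumeration of
maximal feasible cut-sets: the test-suite oracle enumerates every
subset of candidate bonds, keeps the inclusion-maximal subsets whose
cuts leave all pieces at or above the floor, and pools their
fragments. Whenever every maximal clique is jointly feasible the two
routes provably coincide; on the pathological case the oracle
additionally reports the coarser fragments that still contain the
undersized core, and the fixture library plants exactly one such
molecule (a triacetate star) to keep the difference visible.

### Non-monotonicity in `min_size`

For a fixed cut-set, raising `min_size` only removes fragments. Whole
result sets, however, are *not* nested across `min_size`: raising the
floor can delete a compatibility edge, and the smaller cliques that
remain produce coarser fragments never generated at the lower floor
(diethyl ether: `{CC, O}` at floor 1 but `{CC, CCO}` at floor 2). This
is intrinsic to cutting maximal cliques only, and the suite pins the
counterexample in a regression test rather than pretending the
property holds.

## Fingerprints and clustering

Fragments are compared through hashed linear-path fingerprints: every
simple path of 1–7 heavy atoms contributes one bit. A path is encoded
as its sequence of (element, aromatic flag, formal charge) atom
descriptors interleaved with bond orders; the lexicographically smaller
of the two traversal directions is used, making the encoding
independent of atom numbering; the code is hashed with SHA-256 and
folded modulo the width (default 1024 bits), so fingerprints are
identical across runs and platforms. Single-atom paths of plain
aliphatic, uncharged C, N or O are excluded so that near-universal
atoms do not dominate similarity. This construction follows the
linear-segment design of Open Babel's default FP2 but is not
bit-compatible with it; every behavioural contract in the suite is
stated through Tanimoto values of these fingerprints, and
`cluster_fragments` accepts a `fingerprint_fn` so another toolkit's
linear fingerprint can be substituted.

Tanimoto similarity is |AND| / |OR| of the bit vectors, defined as 0
when both are empty so that clustering of tiny fragments stays
well-defined. At threshold `c` (inclusive ≥, so `-c 0.8` means "at
least 0.8 similar") fragments are joined by an edge and clusters are
the connected components (single linkage); raising the threshold can
only refine the partition. Each cluster's representative is the member
with the highest mean similarity to the other members, ties broken to
the lexicographically smallest SMILES.

## Enrichment statistics

The frequency of a fragment is the number of molecules containing it;
multiple occurrences inside one molecule count once. Enrichment of a
foreground table against a background table uses the hypergeometric
upper tail P(X ≥ k), computed with exact integer binomials and one
rational division — exact to double precision for any library size met
in practice — rather than floating-point survival functions. Two
sampling universes are available:

* **occurrences** (default): the population is the molecule–fragment
  incidence pairs; N and n are the total background and foreground
  occurrence counts, K and k the per-unit counts. This treats "drawing
  fragments" as the sampling process.
* **molecules**: the population is the molecules; N and n are library
  sizes, K and k count molecules containing the unit. This is the
  direct analogue of GO term enrichment.

Only units with at least one foreground occurrence are tested — testing
absent units would add p = 1 hypotheses and inflate the correction —
and the Benjamini–Hochberg step-up runs over exactly the tested units
(fragment-level and cluster-level analyses are corrected separately).
Cluster occurrence means "contains at least one member fragment", again
counted once per molecule. The background must contain every
foreground fragment; the analysis aborts otherwise, since p-values
against a background missing the foreground are meaningless.

## Synthetic study design

The planted-enrichment generator emulates the typical use case — a
library in which a subset with a property of interest shares a moiety —
without external databases. Molecules are esters `L-C(=O)O-R` drawn
from small scaffold pools (L: ethyl…phenyl…cyclohexyl; R: C3–C8
alkyl/arylalkyl chosen so every piece survives the toy analysis floor
of 3 heavy atoms). Ten foreground molecules carry a chlorophenyl L at
rate 1.0; forty background-only molecules carry it at rate 0.25; the
background file is the full 50-molecule library, so foreground
fragments are contained in the background by construction. A single
integer seed determines the files byte-for-byte. These toy molecules
are deliberately simple: they exercise rule matching, clique logic,
deduplication and the statistics, but they say nothing about the
behaviour of real drug-like libraries (ring-rich scaffolds, many
interacting cleavable bonds, rare fragments), and passing tests should
be read accordingly. Reported study sizes (50 molecules, 50 power
replicates, 200 null draws) were chosen as the smallest designs whose
outcomes are stable across seeds.

## Numerical and design choices

* Exact rational arithmetic for the hypergeometric tail; BH implemented
  directly from the step-up definition and cross-checked against an
  independent reference implementation in tests.
* Deterministic orderings everywhere: cleavable bonds by bond index,
  cliques by sorted node tuples, clusters by size then representative,
  results by p-value then unit name — reruns are byte-identical.
* Default molecule ids are `mol<k>` by 1-based file line; duplicate
  explicit ids abort (frequency counts depend on molecule identity).
  Unparseable SMILES lines are skipped with a warning; `--strict`
  promotes them to errors.
* The `.frag` interchange format (TSV: id, parent SMILES, sorted
  comma-separated canonical fragments, `-` for none) is this package's
  own dialect.
* Shipped RECAP/BRICS/CCQ rule files are approximate re-encodings of
  the published bond classes as mapped SMARTS; correctness tests rely
  only on the three-rule toy set.

## Known limitations

* Ring-opening fragmentation is out of scope; rules matching ring bonds
  are ignored.
* Stereochemistry contributes to fragment identity only as far as
  canonical SMILES preserves it; no stereo-aware equality beyond that.
* Extensive output is not monotone in `min_size` (see above).
* Cliques of ≥ 3 bonds may hide coarser fragments that only maximal
  feasible cut-sets produce; the pooled output can therefore miss some
  legitimate fragments on star-like scaffolds.
* Fingerprints are linear paths only — branched or ring-closure
  features beyond path traversal are not encoded.
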