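"""Rule-based fragmentation with clique-driven extensive enumeration.

Cleavable bonds are the acyclic bonds matched by SMARTS cleavage rules.
Not every pair of matched bonds can be cut together: a joint cut may
leave a piece smaller than the user's minimum heavy-atom size.  Pairwise
co-cleavability therefore defines an undirected *compatibility graph*
over the cleavable bonds, and the maximal cliques of that graph (found
with Bron-Kerbosch) are the candidate sets of bonds to cut
simultaneously.  Extensive mode cuts every maximal clique, one at a
time, and pools the resulting fragments; default mode performs a single
deterministic greedy fragmentation.

A clique of three or more pairwise-compatible bonds can still yield an
undersized middle fragment when cut jointly (pairwise checks cannot see
it); such fragments are filtered from the output, which is the only
point where this route can differ from exhaustive enumeration of
feasible cut-sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from rdkit import Chem

from .chem_io import (
    CleavageRule,
    FragmentRow,
    FragmentTable,
    MoleculeRecord,
    canonical_smiles,
    heavy_atom_count,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleavableBond:
    """One cleavable (acyclic) bond of a parent molecule.

    ``atom_pair`` stores the parent-atom indices matched to the rule's
    atom maps 1 and 2, in that order.
    """

    bond_index: int
    atom_pair: tuple[int, int]
    rule_name: str


@dataclass
class CompatibilityGraph:
    """Solo-feasible cleavable bonds plus pairwise co-cleavability edges.

    ``nodes`` is ordered (match order); ``edges`` holds unordered pairs of
    positions into ``nodes``.
    """

    nodes: list[CleavableBond]
    edges: set[frozenset[int]]

    def neighbors(self, i: int) -> set[int]:
        return {
            j for j in range(len(self.nodes))
            if j != i and frozenset((i, j)) in self.edges
        }


@dataclass
class FragmentationResult:
    molecule_id: str
    fragments: set[str]


def match_cleavable_bonds(
    mol: MoleculeRecord | Chem.Mol, rules: list[CleavageRule]
) -> list[CleavableBond]:
    """Find every distinct (bond, rule) cleavage site in a molecule.

    A bond matched by the same rule in both atom orders counts once (the
    first orientation encountered is kept).  Ring bonds never qualify:
    cutting a single ring bond does not split the molecule.  Results are
    ordered by bond index, then by rule order.
    """
    rdmol = mol.mol if isinstance(mol, MoleculeRecord) else mol
    found: dict[tuple[int, str], CleavableBond] = {}
    for rule_pos, rule in enumerate(rules):
        i1, i2 = rule.map_indices
        for match in rdmol.GetSubstructMatches(rule.pattern, uniquify=False):
            a1, a2 = match[i1], match[i2]
            bond = rdmol.GetBondBetweenAtoms(a1, a2)
            if bond is None:  # pragma: no cover - guaranteed by rule compile
                continue
            if bond.IsInRing():
                logger.debug(
                    "rule %s matches ring bond %d; not cleavable",
                    rule.name, bond.GetIdx(),
                )
                continue
            key = (bond.GetIdx(), rule.name)
            if key not in found:
                found[key] = CleavableBond(
                    bond_index=bond.GetIdx(),
                    atom_pair=(a1, a2),
                    rule_name=rule.name,
                )
    rule_order = {r.name: k for k, r in enumerate(rules)}
    return sorted(
        found.values(), key=lambda b: (b.bond_index, rule_order[b.rule_name])
    )


def cut_bonds(
    mol: MoleculeRecord | Chem.Mol, bonds: list[CleavableBond] | set[CleavableBond]
) -> list[Chem.Mol]:
    """Delete a set of acyclic bonds and return the connected components.

    Open valences at the cut sites are saturated with hydrogen, so each
    fragment is an ordinary molecule.  Cutting b acyclic bonds always
    yields exactly b + 1 fragments; asking to cut a ring bond is an error
    because it breaks that contract.
    """
    rdmol = mol.mol if isinstance(mol, MoleculeRecord) else mol
    indices = {b.bond_index for b in bonds}
    if len(indices) != len(list(bonds)):
        raise ValueError("duplicate bonds in cut set")
    rw = Chem.RWMol(rdmol)
    for b in bonds:
        bond = rdmol.GetBondWithIdx(b.bond_index)
        if bond.IsInRing():
            raise ValueError(
                f"bond {b.bond_index} is in a ring and cannot be cut"
            )
        begin, end = bond.GetBeginAtom(), bond.GetEndAtom()
        # Atoms that forbid implicit hydrogens (e.g. written as [nH]) must
        # be capped explicitly; the rest are capped by the valence model.
        for atom_idx in (begin.GetIdx(), end.GetIdx()):
            atom = rw.GetAtomWithIdx(atom_idx)
            if atom.GetNoImplicit():
                atom.SetNumExplicitHs(atom.GetNumExplicitHs() + 1)
        rw.RemoveBond(begin.GetIdx(), end.GetIdx())
    cut = rw.GetMol()
    Chem.SanitizeMol(cut)
    frags = list(Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True))
    if len(frags) != len(indices) + 1:
        raise AssertionError(
            f"cut of {len(indices)} acyclic bonds gave {len(frags)} fragments"
        )
    return frags


def _cut_sizes(mol, bonds) -> list[int]:
    return [heavy_atom_count(f) for f in cut_bonds(mol, bonds)]


def build_compatibility_graph(
    mol: MoleculeRecord | Chem.Mol,
    candidate_bonds: list[CleavableBond],
    min_size: int,
) -> CompatibilityGraph:
    """Build the bond-compatibility graph for one molecule.

    Nodes are the solo-feasible candidate bonds (cutting the bond alone
    leaves both pieces at or above ``min_size`` heavy atoms); an edge
    joins two nodes whose joint cut also leaves every piece at or above
    ``min_size``.  Candidates matched by several rules collapse to one
    node per bond (cuttability is a property of the bond, not the match).
    """
    by_bond: dict[int, CleavableBond] = {}
    for cb in candidate_bonds:
        by_bond.setdefault(cb.bond_index, cb)
    unique = [by_bond[k] for k in sorted(by_bond)]

    nodes = [
        cb for cb in unique
        if min(_cut_sizes(mol, [cb])) >= min_size
    ]
    edges: set[frozenset[int]] = set()
    for i, j in itertools.combinations(range(len(nodes)), 2):
        if min(_cut_sizes(mol, [nodes[i], nodes[j]])) >= min_size:
            edges.add(frozenset((i, j)))
    return CompatibilityGraph(nodes=nodes, edges=edges)


def maximal_cliques(graph: CompatibilityGraph) -> list[frozenset[int]]:
    """All maximal cliques of the compatibility graph (Bron-Kerbosch).

    Uses the pivoting variant; output is deterministic: each clique is a
    frozenset of node positions, and the list is sorted by the cliques'
    sorted index tuples.  The empty graph yields the empty list.
    """
    n = len(graph.nodes)
    if n == 0:
        return []
    adj = {i: graph.neighbors(i) for i in range(n)}
    cliques: list[frozenset[int]] = []

    def expand(r: set[int], p: set[int], x: set[int]) -> None:
        if not p and not x:
            cliques.append(frozenset(r))
            return
        pivot = max(p | x, key=lambda v: len(adj[v] & p))
        for v in sorted(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(range(n)), set())
    return sorted(cliques, key=lambda c: tuple(sorted(c)))


def _fragments_of_cut(mol, bonds, min_size: int) -> set[str]:
    return {
        canonical_smiles(f)
        for f in cut_bonds(mol, bonds)
        if heavy_atom_count(f) >= min_size
    }


def fragment_extensive(
    mol: MoleculeRecord,
    rules: list[CleavageRule],
    min_size: int,
) -> FragmentationResult:
    """All fragments of at least ``min_size`` heavy atoms (extensive mode).

    Every maximal clique of the compatibility graph is cut in turn and
    the canonical fragments are pooled; fragments that fall below
    ``min_size`` (possible in cliques of three or more bonds) are
    filtered out.  A molecule with no solo-feasible bond yields an empty
    set -- the intact parent is not a fragment.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    candidates = match_cleavable_bonds(mol, rules)
    graph = build_compatibility_graph(mol, candidates, min_size)
    fragments: set[str] = set()
    for clique in maximal_cliques(graph):
        bonds = [graph.nodes[i] for i in clique]
        fragments |= _fragments_of_cut(mol, bonds, min_size)
    return FragmentationResult(molecule_id=mol.id, fragments=fragments)


def fragment_single(
    mol: MoleculeRecord,
    rules: list[CleavageRule],
    min_size: int,
) -> FragmentationResult:
    """One deterministic fragmentation (default, non-extensive mode).

    Grows a single clique greedily: walk the solo-feasible bonds in match
    order and keep each bond that is pairwise compatible with everything
    already selected.  The greedy set is a maximal clique, so this output
    is always a subset of the extensive-mode output.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    candidates = match_cleavable_bonds(mol, rules)
    graph = build_compatibility_graph(mol, candidates, min_size)
    selected: list[int] = []
    for i in range(len(graph.nodes)):
        if all(frozenset((i, j)) in graph.edges for j in selected):
            selected.append(i)
    if not selected:
        return FragmentationResult(molecule_id=mol.id, fragments=set())
    bonds = [graph.nodes[i] for i in selected]
    return FragmentationResult(
        molecule_id=mol.id,
        fragments=_fragments_of_cut(mol, bonds, min_size),
    )


def fragment_library(
    molecules: list[MoleculeRecord],
    rules: list[CleavageRule],
    min_size: int,
    extensive: bool = False,
) -> FragmentTable:
    """Fragment a whole molecule library into a FragmentTable.

    One row per input molecule, in input order; molecules producing no
    fragment keep an empty row so downstream frequency counts see the
    full library size.
    """
    if not molecules:
        raise ValueError("empty molecule list")
    run = fragment_extensive if extensive else fragment_single
    rows: list[FragmentRow] = []
    total = 0
    for mol in molecules:
        result = run(mol, rules, min_size)
        total += len(result.fragments)
        logger.debug("%s: %d fragment(s)", mol.id, len(result.fragments))
        rows.append(
            FragmentRow(
                molecule_id=mol.id,
                parent_smiles=mol.smiles,
                fragments=frozenset(result.fragments),
            )
        )
    table = FragmentTable(rows=rows)
    logger.info(
        "fragmented %d molecule(s): %d fragment entries, %d distinct",
        len(molecules), total, len(table.fragment_universe()),
    )
    return table
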