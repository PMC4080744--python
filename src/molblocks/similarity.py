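"""Linear-path fingerprints, Tanimoto similarity and threshold clustering.

Fragments are encoded as fixed-width bit vectors whose set bits hash the
linear heavy-atom paths of one to seven atoms in the fragment graph
(element, aromaticity, formal charge per atom; bond order per bond).
Single-atom paths of plain aliphatic, uncharged C, N and O are excluded,
so ubiquitous atoms do not dominate the similarity.  Fragments whose
Tanimoto coefficient reaches a user threshold are joined by an edge, the
connected components of that graph are the clusters, and each cluster is
summarised by the member with the highest average similarity to the
others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import networkx as nx
from rdkit import Chem

DEFAULT_FP_BITS = 1024
MAX_PATH_ATOMS = 7

_PLAIN_SINGLE_ATOMS = {"C", "N", "O"}


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-width bit vector with its popcount cached."""

    bits: int
    width: int

    @property
    def popcount(self) -> int:
        return self.bits.bit_count()


@dataclass
class FragmentCluster:
    cluster_id: int
    members: frozenset[str]
    representative: str


def _atom_code(atom: Chem.Atom) -> tuple:
    return (atom.GetSymbol(), atom.GetIsAromatic(), atom.GetFormalCharge())


def _enumerate_paths(mol: Chem.Mol) -> set[tuple]:
    """Canonical codes of all simple heavy-atom paths of 1..7 atoms.

    Each path is encoded as alternating atom and bond descriptors; the
    lexicographically smaller of the two traversal directions is kept, so
    the code set is independent of atom numbering.
    """
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    adjacency: dict[int, list[int]] = {i: [] for i in heavy}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in adjacency and j in adjacency:
            adjacency[i].append(j)
            adjacency[j].append(i)

    def code_of(path: list[int]) -> tuple:
        parts: list = [_atom_code(mol.GetAtomWithIdx(path[0]))]
        for a, b in zip(path, path[1:]):
            parts.append(str(mol.GetBondBetweenAtoms(a, b).GetBondType()))
            parts.append(_atom_code(mol.GetAtomWithIdx(b)))
        return tuple(parts)

    codes: set[tuple] = set()
    for idx in heavy:
        atom = mol.GetAtomWithIdx(idx)
        symbol, aromatic, charge = _atom_code(atom)
        # FP2-style exclusion of featureless single atoms
        if not (
            symbol in _PLAIN_SINGLE_ATOMS and not aromatic and charge == 0
        ):
            codes.add(code_of([idx]))

    def walk(path: list[int]) -> None:
        if len(path) > 1:
            forward = code_of(path)
            backward = code_of(path[::-1])
            codes.add(min(forward, backward))
        if len(path) == MAX_PATH_ATOMS:
            return
        for nxt in adjacency[path[-1]]:
            if nxt not in path:
                walk(path + [nxt])

    for idx in heavy:
        walk([idx])
    return codes


def _hash_code(code: tuple, width: int) -> int:
    digest = hashlib.sha256(repr(code).encode()).digest()
    return int.from_bytes(digest[:8], "big") % width


def linear_path_fingerprint(
    mol: Chem.Mol | str, width: int = DEFAULT_FP_BITS
) -> Fingerprint:
    """Hash the linear heavy-atom paths of a molecule into a bit vector.

    Accepts an RDKit Mol or a SMILES string.  The hash (SHA-256 of the
    path code, folded modulo ``width``) is fixed, so fingerprints are
    stable across runs and platforms.
    """
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol = parsed
    if width < 1:
        raise ValueError("fingerprint width must be positive")
    bits = 0
    for code in _enumerate_paths(mol):
        bits |= 1 << _hash_code(code, width)
    return Fingerprint(bits=bits, width=width)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; two all-zero fingerprints score 0."""
    if a.width != b.width:
        raise ValueError(f"fingerprint width mismatch: {a.width} != {b.width}")
    union = (a.bits | b.bits).bit_count()
    if union == 0:
        return 0.0
    return (a.bits & b.bits).bit_count() / union


FingerprintFn = Callable[[str], Fingerprint]


def pairwise_similarities(
    fragments: Sequence[str],
    width: int = DEFAULT_FP_BITS,
    fingerprint_fn: FingerprintFn | None = None,
) -> dict[frozenset[str], float]:
    """Tanimoto similarity for every unordered fragment pair."""
    fp_of = fingerprint_fn or (lambda s: linear_path_fingerprint(s, width))
    fps = {f: fp_of(f) for f in fragments}
    sims: dict[frozenset[str], float] = {}
    names = list(fragments)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            sims[frozenset((names[i], names[j]))] = tanimoto(
                fps[names[i]], fps[names[j]]
            )
    return sims


def select_representative(
    members: Sequence[str],
    similarities: Mapping[frozenset[str], float],
) -> str:
    """The member with the highest mean similarity to the other members.

    Singleton clusters return their only member; ties break to the
    lexicographically smallest fragment string.
    """
    members = sorted(members)
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    best, best_mean = None, -1.0
    for m in members:
        mean = sum(
            similarities[frozenset((m, o))] for o in members if o != m
        ) / (len(members) - 1)
        if mean > best_mean + 1e-12:
            best, best_mean = m, mean
    return best


def cluster_fragments(
    fragments: Sequence[str],
    threshold: float,
    width: int = DEFAULT_FP_BITS,
    fingerprint_fn: FingerprintFn | None = None,
) -> list[FragmentCluster]:
    """Single-linkage clustering of fragments at a Tanimoto cutoff.

    Fragments with similarity >= ``threshold`` (inclusive) are joined;
    clusters are the connected components.  Cluster ids are assigned from
    1 by descending cluster size, ties by representative string.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if len(set(fragments)) != len(fragments):
        raise ValueError("fragments must be unique")
    sims = pairwise_similarities(fragments, width, fingerprint_fn)
    graph = nx.Graph()
    graph.add_nodes_from(fragments)
    for pair, s in sims.items():
        if s >= threshold:
            graph.add_edge(*pair)
    clusters = []
    for component in nx.connected_components(graph):
        members = frozenset(component)
        rep = select_representative(sorted(members), sims)
        clusters.append((members, rep))
    clusters.sort(key=lambda c: (-len(c[0]), c[1]))
    return [
        FragmentCluster(cluster_id=k + 1, members=members, representative=rep)
        for k, (members, rep) in enumerate(clusters)
    ]
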