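"""Deterministic toy inputs and independent oracles for the whole suite.

Everything here is synthetic and seed-driven: a hand-verified toy rule
set (ester, amide, ether), a small golden molecule library whose
extensive fragmentations were enumerated by hand, a generator for
planted-enrichment libraries (ester-linked scaffold pairs in which one
acid moiety is over-represented in the foreground), and a brute-force
fragmentation oracle used only in tests.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from pathlib import Path

from .chem_io import CleavageRule, MoleculeRecord, _compile_rule
from .fragmenter import CleavableBond, cut_bonds, match_cleavable_bonds
from .chem_io import canonical_smiles, heavy_atom_count

MAX_ORACLE_BONDS = 12

TOY_RULE_SPECS = [
    # name, SMARTS; maps :1/:2 mark the bond to cut
    ("ester", "C(=O)[O:1][C:2]"),          # ester O - alkyl C
    ("amide", "[C:1](=O)[N:2]"),           # amide carbonyl C - N
    ("ether", "[C;!$(C=O):1][O:2][C;!$(C=O)]"),  # ether C - O (both sides)
]


def toy_rules() -> list[CleavageRule]:
    """Three hand-verified cleavage rules: ester, amide, ether."""
    return [
        _compile_rule(name, smarts, where=f"toy_rules[{name}]")
        for name, smarts in TOY_RULE_SPECS
    ]


@dataclass(frozen=True)
class GoldenMolecule:
    """A fixture molecule with its hand-enumerated expected output.

    ``extensive_min2`` is the expected extensive-mode fragment set at a
    minimum size of 2 heavy atoms under :func:`toy_rules`, derived by
    enumerating cut-sets by hand; ``n_cleavable`` the number of distinct
    cleavable bonds.  ``pathological`` flags the one molecule whose
    pairwise-compatible bond triple is jointly undersized, where the
    clique route and exhaustive cut-set enumeration legitimately differ.
    """

    id: str
    smiles: str
    n_cleavable: int
    extensive_min2: frozenset[str]
    pathological: bool = False


GOLDEN_MOLECULES: list[GoldenMolecule] = [
    GoldenMolecule("butane", "CCCC", 0, frozenset()),
    GoldenMolecule("benzene", "c1ccccc1", 0, frozenset()),
    GoldenMolecule("ethyl_acetate", "CC(=O)OCC", 1,
                   frozenset({"CC(=O)O", "CC"})),
    GoldenMolecule("n_methylacetamide", "CC(=O)NC", 1,
                   frozenset({"CC=O", "CN"})),
    GoldenMolecule("benzyl_acetate", "CC(=O)OCc1ccccc1", 1,
                   frozenset({"CC(=O)O", "Cc1ccccc1"})),
    GoldenMolecule("diethyl_succinate", "CCOC(=O)CCC(=O)OCC", 2,
                   frozenset({"CC", "O=C(O)CCC(=O)O"})),
    GoldenMolecule("diethyl_ether", "CCOCC", 2,
                   frozenset({"CC", "CCO"})),
    GoldenMolecule("ester_amide_mixed", "CCOC(=O)CCC(=O)NC", 2,
                   frozenset({"CC", "CN", "O=CCCC(=O)O"})),
    GoldenMolecule("diethoxy_ethane", "CCOCCOCC", 4,
                   frozenset({"CC", "CCO", "OCCO"})),
    # Central CH carries three acetate arms; all three ester bonds are
    # pairwise compatible at min_size 2 but the joint cut strands the
    # 1-atom core, which is post-filtered.
    GoldenMolecule("triacetate_star", "CC(=O)OC(OC(C)=O)OC(C)=O", 3,
                   frozenset({"CC(=O)O"}), pathological=True),
]


def golden_records() -> list[MoleculeRecord]:
    from rdkit import Chem

    return [
        MoleculeRecord(id=g.id, smiles=g.smiles,
                       mol=Chem.MolFromSmiles(g.smiles))
        for g in GOLDEN_MOLECULES
    ]


# --- planted-enrichment library ------------------------------------------

# Ester-linked scaffold pairs: molecule = LEFT + "C(=O)O" + RIGHT.  The
# ester rule cuts the O-alkyl bond, releasing the acid LEFT-C(=O)OH and
# the hydrocarbon RIGHT-H.  Every scaffold piece has at least 3 heavy
# atoms after the cut, so at the toy analysis size (min_size 3) each
# library molecule contributes both of its fragments.
LEFT_PARTS = ["CC", "CCC", "CCCC", "c1ccccc1", "C1CCCCC1"]
RIGHT_PARTS = ["CCC", "CCCC", "CC(C)C", "CCc1ccccc1", "CCCCC"]
TOY_MIN_SIZE = 3
PLANTED_LEFT = "Clc1ccccc1"
# canonical form of PLANTED_LEFT + "C(=O)O" after the ester cut
PLANTED_FRAGMENT = "O=C(O)c1ccccc1Cl"


@dataclass
class ToyLibrarySpec:
    """Conditions for one synthetic planted-enrichment experiment.

    The background library holds ``n_background`` molecules carrying the
    planted acid moiety at rate ``planted_rate_bg`` plus all
    ``n_foreground`` foreground molecules, which carry it at rate
    ``planted_rate_fg``; the seed fully determines both files.
    """

    n_background: int = 40
    n_foreground: int = 10
    planted_rate_fg: float = 1.0
    planted_rate_bg: float = 0.25
    seed: int = 0
    left_parts: list[str] = field(default_factory=lambda: list(LEFT_PARTS))
    right_parts: list[str] = field(default_factory=lambda: list(RIGHT_PARTS))

    def __post_init__(self) -> None:
        for rate in (self.planted_rate_fg, self.planted_rate_bg):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate out of [0, 1]: {rate}")


def _draw_molecule(rng: random.Random, spec: ToyLibrarySpec,
                   planted_rate: float) -> tuple[str, bool]:
    planted = rng.random() < planted_rate
    left = PLANTED_LEFT if planted else rng.choice(spec.left_parts)
    right = rng.choice(spec.right_parts)
    return f"{left}C(=O)O{right}", planted


def generate_enriched_library(
    spec: ToyLibrarySpec,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict]:
    """Generate (foreground, background) molecule lists plus truth record.

    Each list holds ``(SMILES, id)`` pairs.  The background contains the
    foreground molecules (so foreground fragments are always present in
    the background) plus ``n_background`` background-only molecules.
    """
    rng = random.Random(spec.seed)
    foreground: list[tuple[str, str]] = []
    fg_carriers: list[str] = []
    for i in range(1, spec.n_foreground + 1):
        smiles, planted = _draw_molecule(rng, spec, spec.planted_rate_fg)
        mol_id = f"fg{i}"
        foreground.append((smiles, mol_id))
        if planted:
            fg_carriers.append(mol_id)
    bg_only: list[tuple[str, str]] = []
    bg_carriers: list[str] = []
    for i in range(1, spec.n_background + 1):
        smiles, planted = _draw_molecule(rng, spec, spec.planted_rate_bg)
        mol_id = f"bg{i}"
        bg_only.append((smiles, mol_id))
        if planted:
            bg_carriers.append(mol_id)
    background = foreground + bg_only
    truth = {
        "planted_fragment": PLANTED_FRAGMENT,
        "planted_left_part": PLANTED_LEFT,
        "foreground_carriers": fg_carriers,
        "background_carriers": fg_carriers + bg_carriers,
        "seed": spec.seed,
        "n_foreground": spec.n_foreground,
        "n_background_total": len(background),
        "degenerate_design": spec.planted_rate_fg <= spec.planted_rate_bg,
    }
    return foreground, background, truth


def make_enriched_library(
    spec: ToyLibrarySpec, outdir: str | Path
) -> tuple[Path, Path, dict]:
    """Write foreground/background SMILES files for a planted experiment.

    Identical specs (same seed) produce byte-identical files.  Returns
    the two paths and the truth record; a design with
    ``planted_rate_fg <= planted_rate_bg`` carries a warning flag in the
    truth record instead of failing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    foreground, background, truth = generate_enriched_library(spec)
    fg_path = outdir / "foreground.smi"
    bg_path = outdir / "background.smi"
    for path, mols in ((fg_path, foreground), (bg_path, background)):
        with open(path, "w") as fh:
            for smiles, mol_id in mols:
                fh.write(f"{smiles} {mol_id}\n")
    return fg_path, bg_path, truth


# --- brute-force fragmentation oracle ------------------------------------


def brute_force_fragmenter(
    mol: MoleculeRecord,
    rules: list[CleavageRule],
    min_size: int,
) -> set[str]:
    """Exhaustive reference for extensive fragmentation (tests only).

    Enumerates every non-empty subset of the candidate cleavable bonds,
    keeps the subsets whose cut leaves every piece at or above
    ``min_size`` heavy atoms, restricts to the inclusion-maximal such
    cut-sets (the sets of bonds that really can be cleaved
    simultaneously), and pools their canonical fragments.  The intact
    parent (the empty cut) is not a fragment.  Guarded at
    ``MAX_ORACLE_BONDS`` candidate bonds.
    """
    candidates = match_cleavable_bonds(mol, rules)
    by_bond: dict[int, CleavableBond] = {}
    for cb in candidates:
        by_bond.setdefault(cb.bond_index, cb)
    unique = [by_bond[k] for k in sorted(by_bond)]
    if len(unique) > MAX_ORACLE_BONDS:
        raise ValueError(
            f"{len(unique)} candidate bonds exceed the oracle guard "
            f"({MAX_ORACLE_BONDS})"
        )
    feasible: list[frozenset[int]] = []
    fragments_of: dict[frozenset[int], set[str]] = {}
    for r in range(1, len(unique) + 1):
        for combo in itertools.combinations(range(len(unique)), r):
            bonds = [unique[i] for i in combo]
            frags = cut_bonds(mol, bonds)
            if all(heavy_atom_count(f) >= min_size for f in frags):
                key = frozenset(combo)
                feasible.append(key)
                fragments_of[key] = {canonical_smiles(f) for f in frags}
    out: set[str] = set()
    for s in feasible:
        if not any(s < t for t in feasible):
            out |= fragments_of[s]
    return out
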