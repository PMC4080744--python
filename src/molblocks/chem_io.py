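"""Reading and writing the external representations used throughout the suite.

Molecules arrive as SMILES files (one molecule per line, optional
whitespace-separated identifier), cleavage rules as SMARTS files (one
pattern per line, optional ``name<TAB>`` prefix), and fragment tables move
between the fragmentation and analysis stages as ``.frag`` files.  All
molecular-graph handling is delegated to RDKit; fragment identity is
defined by RDKit canonical SMILES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit logs its own parse errors to stderr; we report them ourselves.
RDLogger.DisableLog("rdApp.error")

FRAG_EMPTY_SENTINEL = "-"


class InputError(ValueError):
    """A fatal problem with user-supplied input (file, SMILES, SMARTS)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """An identified molecule with its parsed molecular graph."""

    id: str
    smiles: str
    mol: Chem.Mol

    def __repr__(self) -> str:  # Mol has no useful repr
        return f"MoleculeRecord(id={self.id!r}, smiles={self.smiles!r})"


@dataclass(frozen=True)
class CleavageRule:
    """A SMARTS pattern whose atom maps 1 and 2 mark one cleavable bond."""

    name: str
    smarts: str
    pattern: Chem.Mol = field(compare=False, hash=False)

    @property
    def map_indices(self) -> tuple[int, int]:
        """Pattern-atom indices carrying atom maps 1 and 2, in that order."""
        by_map = {
            a.GetAtomMapNum(): a.GetIdx()
            for a in self.pattern.GetAtoms()
            if a.GetAtomMapNum()
        }
        return by_map[1], by_map[2]


@dataclass(frozen=True)
class FragmentRow:
    molecule_id: str
    parent_smiles: str
    fragments: frozenset[str]


@dataclass
class FragmentTable:
    """Per-molecule sets of canonical fragment SMILES (``.frag`` contents)."""

    rows: list[FragmentRow]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, FragmentTable) and self.rows == other.rows

    def fragment_universe(self) -> set[str]:
        """All distinct fragments appearing anywhere in the table."""
        out: set[str] = set()
        for row in self.rows:
            out |= row.fragments
        return out


def _iter_data_lines(path: Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks and '#'."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_smiles_file(path: str | Path, strict: bool = False) -> list[MoleculeRecord]:
    """Parse a SMILES file into molecule records.

    Each non-comment line is ``SMILES[<whitespace>ID]``; lines without an
    identifier get ``mol<line-number>`` (1-based).  Unparseable SMILES are
    skipped with a warning unless ``strict``.  Duplicate identifiers and a
    file with zero valid molecules are fatal.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read SMILES file: {path}")
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    n_skipped = 0
    for lineno, line in _iter_data_lines(path):
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            msg = f"{path}:{lineno}: unparseable SMILES {smiles!r}"
            if strict:
                raise InputError(msg)
            logger.warning("%s -- skipped", msg)
            n_skipped += 1
            continue
        if mol_id in seen:
            raise InputError(f"{path}:{lineno}: duplicate molecule id {mol_id!r}")
        seen.add(mol_id)
        records.append(MoleculeRecord(id=mol_id, smiles=smiles, mol=mol))
    if not records:
        raise InputError(f"{path}: no valid molecules")
    if n_skipped:
        logger.warning("%s: skipped %d unparseable line(s)", path, n_skipped)
    return records


def _compile_rule(name: str, smarts: str, where: str) -> CleavageRule:
    pattern = Chem.MolFromSmarts(smarts)
    if pattern is None:
        raise InputError(f"{where}: SMARTS does not compile: {smarts!r}")
    maps = sorted(
        a.GetAtomMapNum() for a in pattern.GetAtoms() if a.GetAtomMapNum() != 0
    )
    if maps != [1, 2]:
        raise InputError(
            f"{where}: rule must carry exactly atom maps :1 and :2 "
            f"(found {maps or 'none'}): {smarts!r}"
        )
    by_map = {
        a.GetAtomMapNum(): a.GetIdx() for a in pattern.GetAtoms() if a.GetAtomMapNum()
    }
    if pattern.GetBondBetweenAtoms(by_map[1], by_map[2]) is None:
        raise InputError(
            f"{where}: mapped atoms :1 and :2 are not bonded in the pattern: "
            f"{smarts!r}"
        )
    return CleavageRule(name=name, smarts=smarts, pattern=pattern)


def read_rules_file(path: str | Path) -> list[CleavageRule]:
    """Parse a cleavage-rule file: one ``[name<TAB>]SMARTS`` per line.

    Every SMARTS must compile and carry atom maps :1 and :2 on two bonded
    atoms; violations are fatal with the offending line number.  Unnamed
    rules are called ``rule<k>`` by position.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read rules file: {path}")
    rules: list[CleavageRule] = []
    for lineno, line in _iter_data_lines(path):
        if "\t" in line:
            name, smarts = line.split("\t", 1)
            name, smarts = name.strip(), smarts.strip()
        else:
            name, smarts = f"rule{len(rules) + 1}", line
        rules.append(_compile_rule(name, smarts, where=f"{path}:{lineno}"))
    if not rules:
        raise InputError(f"{path}: no rules")
    return rules


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical SMILES of a molecular graph.

    Isomorphic graphs map to the same string; open valences left by bond
    cutting are saturated with (implicit) hydrogens by RDKit's valence
    model before writing, so fragments compare as ordinary molecules.
    """
    return Chem.MolToSmiles(mol)


def is_canonical(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    return mol is not None and Chem.MolToSmiles(mol) == smiles


def heavy_atom_count(mol: Chem.Mol) -> int:
    """Number of non-hydrogen atoms."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def write_frag_file(table: FragmentTable, path: str | Path) -> None:
    """Write a fragment table as TSV: id, parent SMILES, fragment list.

    Fragments are comma-separated, sorted lexicographically; an empty set
    is written as ``-``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for row in table.rows:
            frags = (
                ",".join(sorted(row.fragments))
                if row.fragments
                else FRAG_EMPTY_SENTINEL
            )
            fh.write(f"{row.molecule_id}\t{row.parent_smiles}\t{frags}\n")


def read_frag_file(path: str | Path) -> FragmentTable:
    """Read a ``.frag`` file back into a FragmentTable (inverse of write).

    Malformed lines (wrong field count, non-canonical fragment SMILES) are
    fatal with the offending line number.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read fragment file: {path}")
    rows: list[FragmentRow] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise InputError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            mol_id, parent, frag_field = fields
            if frag_field == FRAG_EMPTY_SENTINEL:
                fragments: frozenset[str] = frozenset()
            else:
                frags = frag_field.split(",")
                for f in frags:
                    if not is_canonical(f):
                        raise InputError(
                            f"{path}:{lineno}: fragment {f!r} is not a "
                            "canonical SMILES"
                        )
                fragments = frozenset(frags)
            rows.append(
                FragmentRow(molecule_id=mol_id, parent_smiles=parent,
                            fragments=fragments)
            )
    return FragmentTable(rows=rows)


def write_analysis_table(
    rows: Sequence[dict],
    path: str | Path,
) -> None:
    """Write the analysis output TSV.

    Columns: fragment (or cluster representative), cluster id, foreground
    count, background count, p-value, FDR.  Missing values (clustering or
    enrichment disabled) are ``-``.
    """
    header = ["fragment", "cluster", "fg_count", "bg_count", "p_value", "fdr"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fields = []
            for key in header:
                value = row.get(key)
                if value is None:
                    fields.append("-")
                elif isinstance(value, float):
                    fields.append(format(value, ".6g"))
                else:
                    fields.append(str(value))
            fh.write("\t".join(fields) + "\n")
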