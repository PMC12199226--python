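"""Atom-signature fragment descriptors and descriptor-table ingestion.

A signature descriptor is an atom-centred canonical substructure string —
the root element followed by its neighbour subtrees in parentheses, sorted
lexicographically at every level.  At height 1 the central carbon of
tert-butanol reads C(CCCO); at height 2 each neighbour expands with its own
neighbours (excluding the edge back to the root), e.g. C(C(CFF)C(FFF)FF)
for the fluorine-rich carbon of a -CF2-CF3 moiety.  Per-molecule signature
counts form the fragment-descriptor matrix used by the adsorption models.
Bond order is not encoded in the strings.

External descriptor tables (e.g. the commercial Dragon set, which this
package never computes) are ingested as CSV and may be merged column-wise
with computed signatures.  ``count_tertiary_amines`` provides a structural
proxy for the nRNR2 count used only in synthetic studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # RDKit parse errors are re-raised as ValueError

__all__ = [
    "MolecularGraph",
    "parse_molecule",
    "parse_adjacency",
    "atom_signature",
    "count_signatures",
    "count_tertiary_amines",
    "signature_matrix",
    "load_descriptor_table",
    "merge_descriptor_tables",
    "read_smiles_file",
]


@dataclass
class MolecularGraph:
    """Heavy-atom graph: element/aromatic per atom, order-labelled bonds."""

    atoms: list[tuple[str, bool]]
    bonds: list[tuple[int, int, object]]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond endpoints ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for i, j, _ in self.bonds:
            if i == idx:
                out.append(j)
            elif j == idx:
                out.append(i)
        return out

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def parse_molecule(text: str) -> MolecularGraph:
    """Parse SMILES (via RDKit) or the minimal adjacency format into a graph."""
    if text.lstrip().startswith("atoms:"):
        return parse_adjacency(text)
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {text!r}")
    atoms = [(a.GetSymbol(), a.GetIsAromatic()) for a in mol.GetAtoms()]
    bonds = []
    for b in mol.GetBonds():
        order: object
        if b.GetIsAromatic():
            order = "aromatic"
        else:
            order = int(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(atoms=atoms, bonds=bonds)


def parse_adjacency(text: str) -> MolecularGraph:
    """Parse the package's adjacency format:

        atoms: C C C C O
        bonds: 0-1 1-2 1-3 1-4

    An optional order suffix (``0-1:2`` double, ``:ar`` aromatic) defaults
    to a single bond; an atom symbol may carry a trailing ``*`` to mark it
    aromatic.
    """
    atoms: list[tuple[str, bool]] = []
    bonds: list[tuple[int, int, object]] = []
    for raw in text.strip().splitlines():
        line = raw.strip()
        if line.startswith("atoms:"):
            for token in line[len("atoms:") :].split():
                aromatic = token.endswith("*")
                atoms.append((token.rstrip("*"), aromatic))
        elif line.startswith("bonds:"):
            for token in line[len("bonds:") :].split():
                if ":" in token:
                    pair, order_txt = token.split(":", 1)
                    order: object = "aromatic" if order_txt == "ar" else int(order_txt)
                else:
                    pair, order = token, 1
                i_txt, j_txt = pair.split("-")
                bonds.append((int(i_txt), int(j_txt), order))
        elif line:
            raise ValueError(f"unrecognised adjacency line: {line!r}")
    if not atoms:
        raise ValueError("adjacency input has no atoms")
    return MolecularGraph(atoms=atoms, bonds=bonds)


def _label(graph: MolecularGraph, idx: int, aromatic_lowercase: bool) -> str:
    symbol, aromatic = graph.atoms[idx]
    return symbol.lower() if (aromatic and aromatic_lowercase) else symbol


def atom_signature(
    graph: MolecularGraph,
    atom: int,
    height: int = 1,
    aromatic_lowercase: bool = False,
) -> str:
    """Canonical atom-centred signature string at height 1 or 2.

    Height 1 lists the sorted neighbour element labels; height 2 expands
    each neighbour with its own neighbours excluding the root, neighbours
    without further neighbours printing as a bare element.  The root always
    carries parentheses, so an isolated atom reads "C()".
    """
    if height not in (1, 2):
        raise ValueError("height must be 1 or 2")
    root = _label(graph, atom, aromatic_lowercase)
    subtrees = []
    for nb in graph.neighbors(atom):
        if height == 1:
            subtrees.append(_label(graph, nb, aromatic_lowercase))
        else:
            grandchildren = sorted(
                _label(graph, g, aromatic_lowercase)
                for g in graph.neighbors(nb)
                if g != atom
            )
            label = _label(graph, nb, aromatic_lowercase)
            subtrees.append(label + "(" + "".join(grandchildren) + ")" if grandchildren else label)
    return root + "(" + "".join(sorted(subtrees)) + ")"


def count_signatures(
    graph: MolecularGraph, height: int = 1, aromatic_lowercase: bool = False
) -> dict[str, int]:
    """Signature string -> number of atoms bearing it (partitions the atoms)."""
    counts: dict[str, int] = {}
    for idx in range(graph.n_atoms):
        sig = atom_signature(graph, idx, height, aromatic_lowercase)
        counts[sig] = counts.get(sig, 0) + 1
    return counts


def count_tertiary_amines(graph: MolecularGraph) -> int:
    """Aliphatic tertiary amines: non-aromatic N single-bonded to exactly
    three carbons, excluding amide nitrogens (N adjacent to a carbonyl C).

    Structural proxy for the nRNR2 constitutional descriptor; used only in
    synthetic studies (name it "nRNR2_proxy" in descriptor tables).
    """
    # carbonyl carbons: C double-bonded to O
    carbonyl = set()
    for i, j, order in graph.bonds:
        if order == 2:
            si, sj = graph.atoms[i][0], graph.atoms[j][0]
            if si == "C" and sj == "O":
                carbonyl.add(i)
            elif si == "O" and sj == "C":
                carbonyl.add(j)
    count = 0
    for idx, (symbol, aromatic) in enumerate(graph.atoms):
        if symbol != "N" or aromatic:
            continue
        single_c = []
        ok = True
        for i, j, order in graph.bonds:
            if idx not in (i, j):
                continue
            other = j if i == idx else i
            if order != 1:
                ok = False
                break
            if graph.atoms[other][0] != "C":
                ok = False
                break
            single_c.append(other)
        if ok and len(single_c) == 3 and not any(c in carbonyl for c in single_c):
            count += 1
    return count


def signature_matrix(
    molecules: dict[str, MolecularGraph],
    heights: Sequence[int] = (1, 2),
    aromatic_lowercase: bool = False,
) -> pd.DataFrame:
    """Polymer × signature count matrix over the union of observed signatures."""
    rows = {}
    for mol_id, graph in molecules.items():
        counts: dict[str, int] = {}
        for h in heights:
            counts.update(count_signatures(graph, h, aromatic_lowercase))
        rows[mol_id] = counts
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df = df[sorted(df.columns)]
    df.index.name = "polymer_id"
    return df


def load_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Load a descriptor CSV (polymer_id column + numeric columns).

    Raises on non-numeric cells (naming row and column); warns about
    constant columns, which carry no information for regression.
    """
    import warnings

    df = pd.read_csv(path)
    if "polymer_id" not in df.columns:
        raise ValueError(f"{path}: missing polymer_id column")
    df = df.set_index("polymer_id")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any() and not df[col].isna().any():
            bad = df.index[numeric.isna()][0]
            raise ValueError(f"{path}: non-numeric cell at row {bad!r}, column {col!r}")
        if df[col].isna().any():
            bad = df.index[df[col].isna()][0]
            raise ValueError(f"{path}: missing cell at row {bad!r}, column {col!r}")
        df[col] = numeric
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"{path}: constant descriptor column(s): {constant}")
    return df


def merge_descriptor_tables(*tables: pd.DataFrame) -> pd.DataFrame:
    """Column-wise merge on polymer_id; duplicate column names are rejected."""
    if not tables:
        raise ValueError("no tables to merge")
    merged = tables[0]
    for tbl in tables[1:]:
        overlap = set(merged.columns) & set(tbl.columns)
        if overlap:
            raise ValueError(f"descriptor name collision: {sorted(overlap)}")
        merged = merged.join(tbl, how="inner")
    return merged


def read_smiles_file(path: str | Path) -> dict[str, MolecularGraph]:
    """Read an id TAB smiles file (one molecule per line) into graphs."""
    out: dict[str, MolecularGraph] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>smiles'")
        mol_id, smiles = parts
        out[mol_id] = parse_molecule(smiles)
    return out
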