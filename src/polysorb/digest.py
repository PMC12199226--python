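"""In-silico tryptic digestion and peptide/fragment mass computation.

Proteins are modelled as one or more chains (1-letter residue strings) with
optional inter- or intra-chain disulfide bonds.  Digestion follows the Keil
rule for trypsin: cleavage C-terminal to K or R, suppressed when the next
residue is proline.  Peptides still tethered to the rest of the molecule
through a disulfide-bonded cysteine are not released as free species — for
mature insulin this leaves GFFYTPK as the single free tryptic peptide of
length >= 2, which is why insulin serves as the digestion-efficiency probe.

Masses are monoisotopic throughout; the residue table is taken from
pyteomics and frozen into a :class:`MassTable` so every m/z equation in the
package draws on one set of constants.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from pyteomics import mass as _pt_mass

__all__ = [
    "MassTable",
    "ProteinEntry",
    "Peptide",
    "FragmentIon",
    "tryptic_digest",
    "free_peptides",
    "monoisotopic_mass",
    "precursor_mz",
    "fragment_ions",
    "read_fasta_chains",
    "read_disulfide_table",
]

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic residue masses plus the water/proton constants (Da)."""

    residues: dict[str, float]
    water_mass: float = 18.0105646863
    proton_mass: float = 1.00727646688

    def __post_init__(self) -> None:
        if set(self.residues) != set(CANONICAL_RESIDUES):
            raise ValueError("mass table must cover exactly the 20 canonical residues")

    @classmethod
    def default(cls) -> "MassTable":
        residues = {aa: _pt_mass.std_aa_mass[aa] for aa in CANONICAL_RESIDUES}
        return cls(residues=residues)


DEFAULT_MASS_TABLE = MassTable.default()


def _validate_sequence(sequence: str) -> None:
    for ch in sequence:
        if ch not in CANONICAL_RESIDUES:
            raise ValueError(f"unknown residue code {ch!r} in sequence")


@dataclass(frozen=True)
class ProteinEntry:
    """A protein: one or more chains and (chain, 1-based position) disulfide pairs."""

    id: str
    name: str
    chains: tuple[str, ...]
    disulfides: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = ()

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for chain in self.chains:
            _validate_sequence(chain)
        for pair in self.disulfides:
            for chain_idx, pos in pair:
                if not (0 <= chain_idx < len(self.chains)):
                    raise ValueError(f"disulfide chain index {chain_idx} out of range")
                chain = self.chains[chain_idx]
                if not (1 <= pos <= len(chain)):
                    raise ValueError(f"disulfide position {pos} out of range")
                if chain[pos - 1] != "C":
                    raise ValueError(
                        f"disulfide endpoint chain {chain_idx} pos {pos} is not a cysteine"
                    )
                if (chain_idx, pos) in seen:
                    raise ValueError(
                        f"residue chain {chain_idx} pos {pos} participates in two disulfides"
                    )
                seen.add((chain_idx, pos))

    @property
    def bonded_cysteines(self) -> frozenset[tuple[int, int]]:
        return frozenset(pt for pair in self.disulfides for pt in pair)


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide located within a parent chain (1-based inclusive)."""

    sequence: str
    protein_id: str
    chain_index: int
    start: int
    end: int
    missed_cleavages: int
    monoisotopic_mass: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" or "y"
    index: int
    charge: int
    mz: float


def monoisotopic_mass(sequence: str, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """Sum of residue monoisotopic masses plus one water (the peptide termini)."""
    _validate_sequence(sequence)
    return sum(table.residues[aa] for aa in sequence) + table.water_mass


def precursor_mz(mass: float, charge: int, table: MassTable = DEFAULT_MASS_TABLE) -> float:
    """(M + z·H+) / z for a positive-mode precursor."""
    if charge <= 0:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * table.proton_mass) / charge


def cleavage_sites(chain: str) -> list[int]:
    """0-based indices i such that trypsin cuts between chain[i] and chain[i+1].

    Keil rule: after K or R unless the next residue is P; the chain terminus
    is never listed (it is always a peptide boundary).
    """
    _validate_sequence(chain)
    return [
        i
        for i in range(len(chain) - 1)
        if chain[i] in "KR" and chain[i + 1] != "P"
    ]


def tryptic_digest(
    protein: ProteinEntry,
    max_missed: int = 0,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[Peptide]:
    """All fully tryptic peptides of every chain with 0..max_missed missed cleavages."""
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    peptides: list[Peptide] = []
    for chain_index, chain in enumerate(protein.chains):
        if not chain:
            continue
        boundaries = [0] + [s + 1 for s in cleavage_sites(chain)] + [len(chain)]
        n_segments = len(boundaries) - 1
        for i in range(n_segments):
            for missed in range(max_missed + 1):
                j = i + missed + 1
                if j > n_segments:
                    break
                start, end = boundaries[i], boundaries[j]
                seq = chain[start:end]
                peptides.append(
                    Peptide(
                        sequence=seq,
                        protein_id=protein.id,
                        chain_index=chain_index,
                        start=start + 1,
                        end=end,
                        missed_cleavages=missed,
                        monoisotopic_mass=monoisotopic_mass(seq, table),
                    )
                )
    return peptides


def free_peptides(
    protein: ProteinEntry,
    peptides: Iterable[Peptide],
    min_length: int = 2,
) -> list[Peptide]:
    """Peptides released as free species: long enough and with no bonded cysteine.

    A peptide spanning a disulfide-bonded cysteine stays covalently tethered
    to its partner chain after digestion and is therefore never observed as a
    linear species.
    """
    bonded = protein.bonded_cysteines
    out = []
    for pep in peptides:
        if pep.protein_id != protein.id:
            raise ValueError(f"peptide {pep.sequence} does not derive from {protein.id}")
        if len(pep) < min_length:
            continue
        if any(
            (pep.chain_index, pos) in bonded for pos in range(pep.start, pep.end + 1)
        ):
            continue
        out.append(pep)
    return out


def fragment_ions(
    peptide: Peptide | str,
    max_charge: int = 1,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[FragmentIon]:
    """b- and y-series fragment m/z values for charges 1..max_charge.

    b_i is the sum of the first i residues plus the charging protons; y_i is
    the sum of the last i residues plus water plus the charging protons.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    _validate_sequence(seq)
    if len(seq) < 2:
        raise ValueError("fragment ions require a peptide of length >= 2")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    n = len(seq)
    prefix = [0.0]
    for aa in seq:
        prefix.append(prefix[-1] + table.residues[aa])
    ions: list[FragmentIon] = []
    for z in range(1, max_charge + 1):
        for i in range(1, n):
            b_mass = prefix[i]
            y_mass = prefix[n] - prefix[n - i] + table.water_mass
            ions.append(FragmentIon("b", i, z, (b_mass + z * table.proton_mass) / z))
            ions.append(FragmentIon("y", i, z, (y_mass + z * table.proton_mass) / z))
    return ions


# ---------------------------------------------------------------------------
# File interfaces: FASTA chains + disulfide sidecar CSV

def read_fasta_chains(path: str | Path) -> dict[str, list[str]]:
    """Read chains from FASTA, one record per chain, ids "<protein>|chain<k>".

    Records without the "|chain<k>" suffix are treated as single-chain
    proteins.  Returns protein id -> chains ordered by chain number.
    """
    chains: dict[str, list[tuple[int, str]]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        ident = record.id
        if "|chain" in ident:
            protein_id, chain_part = ident.rsplit("|chain", 1)
            k = int(chain_part)
        else:
            protein_id, k = ident, 0
        chains.setdefault(protein_id, []).append((k, str(record.seq).upper()))
    return {
        pid: [seq for _, seq in sorted(entries)] for pid, entries in chains.items()
    }


def read_disulfide_table(
    path: str | Path,
) -> dict[str, list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Read the disulfide sidecar CSV: protein_id, chain_a, pos_a, chain_b, pos_b."""
    out: dict[str, list[tuple[tuple[int, int], tuple[int, int]]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["protein_id"], []).append(
                (
                    (int(row["chain_a"]), int(row["pos_a"])),
                    (int(row["chain_b"]), int(row["pos_b"])),
                )
            )
    return out


def load_proteins(
    fasta_path: str | Path, disulfide_path: str | Path | None = None
) -> list[ProteinEntry]:
    """Assemble ProteinEntry objects from a chain FASTA and optional sidecar."""
    chain_map = read_fasta_chains(fasta_path)
    ss_map = read_disulfide_table(disulfide_path) if disulfide_path else {}
    return [
        ProteinEntry(
            id=pid,
            name=pid,
            chains=tuple(chains),
            disulfides=tuple(ss_map.get(pid, ())),
        )
        for pid, chains in chain_map.items()
    ]
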