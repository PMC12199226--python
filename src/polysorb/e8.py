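"""Bundled protein fixtures: the four proteins of Essential 8 medium.

Essential 8 (E8) is a defined stem-cell culture medium whose only proteins
are insulin, transferrin, FGF2 and TGFβ1; these are the adsorption targets
the pipeline quantifies.  Insulin carries the exact mature human chains and
disulfide topology (A6–A11, A7–B7, A20–B19) — required for the worked
example in which GFFYTPK is the single free tryptic peptide.  FGF2 and
TGFβ1 carry the standard mature reference sequences.  The transferrin entry
is a SYNTHETIC surrogate sequence (the 679-residue serotransferrin sequence
is not bundled): a fixed peptide-like sequence with realistic tryptic-site
density that stands in wherever a fourth-protein peptide source is needed.
Nothing downstream depends on transferrin's true sequence, only on a valid
residue string.

Disulfides are annotated for insulin only; the other entries are treated as
unbonded peptide sources, so their complete tryptic digests are all "free".
"""

from __future__ import annotations

import csv
from pathlib import Path

from .digest import ProteinEntry

__all__ = ["INSULIN", "TRANSFERRIN", "FGF2", "TGFB1", "E8_PROTEINS", "write_fixture_fasta"]

INSULIN = ProteinEntry(
    id="insulin",
    name="insulin (mature human, A+B chains)",
    chains=(
        "GIVEQCCTSICSLYQLENYCN",
        "FVNQHLCGSHLVEALYLVCGERGFFYTPKT",
    ),
    disulfides=(
        ((0, 6), (0, 11)),
        ((0, 7), (1, 7)),
        ((0, 20), (1, 19)),
    ),
)

# Synthetic surrogate — see module docstring.
_TRANSFERRIN_SURROGATE = (
    "MVTEAQLSDGKVDSGLYLAQNRAVGETFVNDLSKTLPEYAVSRGDEWFLTNHPKASNVQLDGYTR"
    "ELFTDVSGNKYPSAVEQLGRNTVDFLESGKAQYLPDNVTRGFESALDNQKVTLSGYEPNR"
    "DWQAVFESGKNLPTYDVSAREGFVQLDNTKSAYPLEVGNRTDFNQLASGKVLEYPDSATR"
    "GNQAVFELDKTPSYLVEGNRADFQNLTSGKEVLYPSDGTRQNGAFVELDKSPTYLVNEGR"
    "FADQNLTSEKYEVLPSDGNR"
)

TRANSFERRIN = ProteinEntry(
    id="transferrin",
    name="transferrin (synthetic surrogate sequence)",
    chains=(_TRANSFERRIN_SURROGATE,),
)

FGF2 = ProteinEntry(
    id="FGF2",
    name="fibroblast growth factor 2 (155 aa)",
    chains=(
        "MAAGSITTLPALPEDGGSGAFPPGHFKDPKRLYCKNGGFFLRIHPDGRVDGVREKSDPHIKLQLQAEE"
        "RGVVSIKGVCANRYLAMKEDGRLLASKCVTDECFFFERLESNNYNTYRSRKYTSWYVALKRTGQYKLG"
        "SKTGPGQKAILFLPMSAKS",
    ),
)

TGFB1 = ProteinEntry(
    id="TGFb1",
    name="transforming growth factor beta 1 (mature, 112 aa)",
    chains=(
        "ALDTNYCFSSTEKNCCVRQLYIDFRKDLGWKWIHEPKGYHANFCLGPCPYIWSLDTQYSKVLALYNQH"
        "NPGASAAPCCVPQALEPLPIVYYVGRKPKVEQLSNMIVRSCKCS",
    ),
)

E8_PROTEINS: tuple[ProteinEntry, ...] = (INSULIN, TRANSFERRIN, FGF2, TGFB1)


def write_fixture_fasta(fasta_path: str | Path, disulfide_path: str | Path) -> None:
    """Write the bundled proteins as a chain FASTA plus disulfide sidecar CSV."""
    with open(fasta_path, "w") as fh:
        for protein in E8_PROTEINS:
            for k, chain in enumerate(protein.chains):
                fh.write(f">{protein.id}|chain{k} {protein.name}\n")
                for i in range(0, len(chain), 60):
                    fh.write(chain[i : i + 60] + "\n")
    with open(disulfide_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["protein_id", "chain_a", "pos_a", "chain_b", "pos_b"])
        for protein in E8_PROTEINS:
            for (ca, pa), (cb, pb) in protein.disulfides:
                writer.writerow([protein.id, ca, pa, cb, pb])
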