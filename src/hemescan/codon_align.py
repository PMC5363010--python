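"""Reference-anchored star alignment and codon-aware back-translation.

The multiple protein alignment is assembled by merging each
candidate's pairwise reference alignment: reference positions act as
anchor columns shared by all rows, and residues a candidate inserts
relative to the reference get private columns (insertions from
different rows are deliberately *not* aligned to each other — the
conservative choice for downstream per-site statistics).  An
externally computed protein MSA in FASTA can be supplied instead;
``backtranslate`` accepts any protein MSA unchanged and replaces every
residue cell by its source codon and every gap by ``---``, so that
degapping a nucleotide row reproduces the input CDS exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import PositionMap, map_to_reference
from .discovery import _translate_codon
from .reference_model import ReferenceModel

__all__ = ["StarAlignment", "CodonAlignment", "star_align", "backtranslate"]


@dataclass(frozen=True)
class StarAlignment:
    """A protein MSA plus the reference position behind each column.

    ``column_ref[j]`` is the 1-based reference position anchoring
    column j, or None for a private insertion column.
    """

    rows: dict[str, str]
    column_ref: tuple[int | None, ...]

    @property
    def n_columns(self) -> int:
        return len(self.column_ref)


@dataclass(frozen=True)
class CodonAlignment:
    """Paired protein and nucleotide MSAs (3 nt columns per aa column)."""

    protein_rows: dict[str, str]
    nt_rows: dict[str, str]


def star_align(
    proteins: dict[str, str],
    ref: ReferenceModel,
    maps: dict[str, PositionMap] | None = None,
) -> StarAlignment:
    """Merge pairwise reference alignments into one protein MSA.

    ``maps`` may carry precomputed position maps; missing ones are
    computed here.  Rows keep the input (dict) order; all-gap columns
    never appear because every emitted column holds at least one
    residue.
    """
    if maps is None:
        maps = {}
    resolved: dict[str, PositionMap] = {}
    for cid, protein in proteins.items():
        pm = maps.get(cid) or map_to_reference(protein, ref, cid)
        if not pm.pairs:
            raise ValueError(f"candidate {cid} has an empty position map")
        resolved[cid] = pm

    n_ref = len(ref.myo_template)
    ids = list(proteins)
    # per row: anchored residue per reference position, and insertion runs
    anchored: dict[str, dict[int, str]] = {}
    inserts: dict[str, dict[int, list[str]]] = {}  # slot p -> residues after anchor p
    for cid in ids:
        protein = proteins[cid]
        pm = resolved[cid]
        cand_to_ref = pm.cand_to_ref
        anchored[cid] = {}
        inserts[cid] = {}
        prev_ref = 0
        for i, aa in enumerate(protein, start=1):
            r = cand_to_ref.get(i)
            if r is not None:
                anchored[cid][r] = aa
                prev_ref = r
            else:
                inserts[cid].setdefault(prev_ref, []).append(aa)

    columns: list[tuple[int | None, dict[str, str]]] = []

    def emit_insertions(slot: int) -> None:
        for cid in ids:
            for aa in inserts[cid].get(slot, ()):
                columns.append((None, {cid: aa}))

    emit_insertions(0)
    for p in range(1, n_ref + 1):
        cells = {cid: anchored[cid][p] for cid in ids if p in anchored[cid]}
        if cells:
            columns.append((p, cells))
        emit_insertions(p)

    rows = {
        cid: "".join(cells.get(cid, "-") for _, cells in columns)
        for cid in ids
    }
    return StarAlignment(rows=rows, column_ref=tuple(c for c, _ in columns))


def backtranslate(protein_msa: dict[str, str], cds: dict[str, str]) -> CodonAlignment:
    """Replace each aligned residue by its source codon.

    Raises ValueError when a CDS length disagrees with the ungapped
    protein length or a codon does not translate to its residue (which
    signals upstream corruption, not a recoverable condition).
    """
    nt_rows: dict[str, str] = {}
    for cid, row in protein_msa.items():
        source = cds[cid]
        ungapped = row.replace("-", "")
        if len(source) != 3 * len(ungapped):
            raise ValueError(
                f"{cid}: CDS length {len(source)} != 3 x {len(ungapped)} residues"
            )
        out = []
        k = 0
        for aa in row:
            if aa == "-":
                out.append("---")
                continue
            codon = source[3 * k : 3 * k + 3]
            if _translate_codon(codon) != aa:
                raise ValueError(f"{cid}: codon {codon} does not encode {aa}")
            out.append(codon)
            k += 1
        nt_rows[cid] = "".join(out)
    return CodonAlignment(protein_rows=dict(protein_msa), nt_rows=nt_rows)


def write_msa(rows: dict[str, str], path) -> None:
    """Write an alignment as FASTA (one row per record)."""
    with open(path, "w") as fh:
        for cid, row in rows.items():
            fh.write(f">{cid}\n{row}\n")


def read_msa(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
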