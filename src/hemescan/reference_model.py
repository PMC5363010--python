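"""Reference coordinate system for hemerythrin (Hr) annotation.

All positional reasoning in this package is anchored to a single 1-based
residue numbering, conventionally taken from the *Themiste zostericola*
myohemerythrin sequence.  In that numbering the seven iron-coordinating
signature residues sit at His26, His56, His75, His79, His108, Glu60 and
Asp113, and the four helices of the up-and-down bundle occupy the closed
intervals A=[19,38], B=[43,65], C=[72,88] and D=[98,118].  Circulating
hemerythrins (cHr) differ from non-circulating/myo-type hemerythrins
(ncHr) by a five-residue block inserted between the C and D helices,
immediately before the D helix; the inter-helix window [89,97] contains
that block in the ncHr form.

The reference ships with a *synthetic* pair of template sequences (one
per subtype, identical outside the insertion window) built once from a
fixed seed, so the whole pipeline is exercisable without any external
sequence.  A real reference can be substituted via ``from_dict`` /
``from_yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import yaml
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "AMINO_ACIDS",
    "ReferenceModel",
    "SignatureCheck",
    "default_reference",
    "signature_at",
    "synonymous_codons",
    "translate_cds",
]

#: The 20 standard amino acids, fixed order used by every stochastic routine.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

# seed for the synthetic template pair; fixed so the default reference is a
# constant of the package, not a run-time random object
_TEMPLATE_SEED = 715


def synonymous_codons() -> dict[str, list[str]]:
    """Map each amino acid to its codons under the standard genetic code."""
    table: dict[str, list[str]] = {}
    for codon, aa in _STANDARD_TABLE.forward_table.items():
        table.setdefault(aa, []).append(codon)
    for codons in table.values():
        codons.sort()
    return table


_SYNONYMOUS = synonymous_codons()


def translate_cds(cds: str) -> str:
    """Translate a CDS (no stop) under the standard genetic code; N -> X."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return str(Seq(cds).translate())


class SignatureCheck(NamedTuple):
    """Verdict for one signature position."""

    expected: str
    observed: str | None
    match: bool


@dataclass(frozen=True)
class ReferenceModel:
    """The Hr coordinate system plus paired subtype templates.

    Positions are 1-based; helix intervals and the insertion window are
    closed.  ``myo_template`` carries the five-residue insertion block,
    ``chr_template`` lacks it; they are identical everywhere else.
    """

    signature: tuple[tuple[int, str], ...]
    helices: dict[str, tuple[int, int]]
    insertion_window: tuple[int, int]
    insertion_length: int
    myo_template: str
    chr_template: str
    myo_cds: str
    chr_cds: str
    #: 1-based myo positions occupied by the insertion block.
    insertion_block: tuple[int, int] = field(default=(93, 97))

    # -- derived views ---------------------------------------------------

    @property
    def signature_positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.signature)

    def chr_index(self, ref_pos: int) -> int | None:
        """Map a reference (myo) position to a 1-based chr_template index.

        Positions inside the insertion block have no counterpart and map
        to ``None``.
        """
        lo, hi = self.insertion_block
        if ref_pos < lo:
            return ref_pos
        if ref_pos <= hi:
            return None
        return ref_pos - self.insertion_length

    def region_of(self, ref_pos: int) -> str:
        """Assign a reference position to A/B/C/D or 'inter-helix'."""
        for name, (lo, hi) in self.helices.items():
            if lo <= ref_pos <= hi:
                return name
        return "inter-helix"

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Raise ValueError on any violated structural invariant."""
        residues = sorted(r for _, r in self.signature)
        if len(self.signature) != 7 or residues != ["D", "E", "H", "H", "H", "H", "H"]:
            raise ValueError("signature must contain exactly 5 His, 1 Glu, 1 Asp")
        n = len(self.myo_template)
        prev_end = 0
        for name in "ABCD":
            lo, hi = self.helices[name]
            if not (prev_end < lo <= hi <= n):
                raise ValueError(f"helix {name} interval [{lo},{hi}] out of order/range")
            prev_end = hi
        for pos, _ in self.signature:
            if not 1 <= pos <= n:
                raise ValueError(f"signature position {pos} outside template")
        if len(self.myo_template) - len(self.chr_template) != self.insertion_length:
            raise ValueError("template length difference != insertion_length")
        if self.insertion_length != 5:
            raise ValueError("insertion_length must be 5")
        c_end = self.helices["C"][1]
        d_start = self.helices["D"][0]
        wlo, whi = self.insertion_window
        if not (c_end < wlo <= whi < d_start):
            raise ValueError("insertion window must lie strictly between C and D")
        blo, bhi = self.insertion_block
        if not (wlo <= blo <= bhi <= whi) or bhi - blo + 1 != self.insertion_length:
            raise ValueError("insertion block inconsistent with window/length")
        expected_chr = self.myo_template[: blo - 1] + self.myo_template[bhi:]
        if expected_chr != self.chr_template:
            raise ValueError("templates differ outside the insertion block")
        for cds, prot, label in (
            (self.myo_cds, self.myo_template, "myo"),
            (self.chr_cds, self.chr_template, "chr"),
        ):
            if translate_cds(cds) != prot:
                raise ValueError(f"{label} CDS does not translate to its template")
            if not prot.startswith("M"):
                raise ValueError(f"{label} template does not start with Met")

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "signature": [[p, r] for p, r in self.signature],
            "helices": {k: list(v) for k, v in self.helices.items()},
            "insertion_window": list(self.insertion_window),
            "insertion_length": self.insertion_length,
            "insertion_block": list(self.insertion_block),
            "myo_template": self.myo_template,
            "chr_template": self.chr_template,
            "myo_cds": self.myo_cds,
            "chr_cds": self.chr_cds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceModel":
        model = cls(
            signature=tuple((int(p), str(r)) for p, r in d["signature"]),
            helices={k: (int(v[0]), int(v[1])) for k, v in d["helices"].items()},
            insertion_window=tuple(d["insertion_window"]),
            insertion_length=int(d["insertion_length"]),
            insertion_block=tuple(d.get("insertion_block", (93, 97))),
            myo_template=d["myo_template"],
            chr_template=d["chr_template"],
            myo_cds=d["myo_cds"],
            chr_cds=d["chr_cds"],
        )
        model.validate()
        return model

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ReferenceModel":
        return cls.from_dict(yaml.safe_load(text))


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with codons drawn uniformly among synonyms."""
    out = []
    for aa in protein:
        codons = _SYNONYMOUS[aa]
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def _build_templates() -> tuple[str, str, str, str]:
    """Synthesize the paired subtype templates from the fixed seed.

    The myo template is a random 125-residue protein with Met at position
    1 and the signature residues overwritten; the chr template is the
    same protein with the five-residue block at positions 93-97 deleted.
    """
    rng = np.random.default_rng(_TEMPLATE_SEED)
    n = 125  # D helix ends at 118; keep the 7 post-helix residues as well
    aa = [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=n)]
    aa[0] = "M"
    for pos, res in ((26, "H"), (56, "H"), (60, "E"), (75, "H"), (79, "H"), (108, "H"), (113, "D")):
        aa[pos - 1] = res
    myo = "".join(aa)
    chr_ = myo[:92] + myo[97:]
    myo_cds = _back_translate(myo, rng)
    chr_cds = myo_cds[: 92 * 3] + myo_cds[97 * 3:]
    return myo, chr_, myo_cds, chr_cds


_DEFAULT: ReferenceModel | None = None


def default_reference() -> ReferenceModel:
    """Return the package's built-in reference model (cached singleton)."""
    global _DEFAULT
    if _DEFAULT is None:
        myo, chr_, myo_cds, chr_cds = _build_templates()
        _DEFAULT = ReferenceModel(
            signature=((26, "H"), (56, "H"), (60, "E"), (75, "H"), (79, "H"), (108, "H"), (113, "D")),
            helices={"A": (19, 38), "B": (43, 65), "C": (72, 88), "D": (98, 118)},
            insertion_window=(89, 97),
            insertion_length=5,
            myo_template=myo,
            chr_template=chr_,
            myo_cds=myo_cds,
            chr_cds=chr_cds,
        )
        _DEFAULT.validate()
    return _DEFAULT


def signature_at(ref: ReferenceModel, protein: str) -> dict[int, SignatureCheck]:
    """Check the seven signature residues on a reference-numbered protein.

    ``protein`` must be indexed in reference numbering: residue i of the
    string corresponds to reference position i+1; gap characters ('-')
    are allowed.  A gapped or absent position never matches.
    """
    report: dict[int, SignatureCheck] = {}
    for pos, expected in ref.signature:
        if pos <= len(protein) and protein[pos - 1] not in "-.":
            observed: str | None = protein[pos - 1]
            match = observed == expected
        else:
            observed = None
            match = False
        report[pos] = SignatureCheck(expected, observed, match)
    return report
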