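"""Candidate annotation: reference mapping, signature verification,
subtype classification and trimming.

A candidate protein is globally aligned (affine gaps, free ends)
against the insertion-bearing reference template, which yields a
monotone residue-to-reference ``PositionMap``.  Through that map the
seven iron-binding signature residues are verified, helices are
located, and the subtype is read off the inter-helix window: the
number of candidate residues lying strictly between the end of the C
helix and the start of the D helix, minus the circulating-form
baseline, is the observed insertion length — 5 means non-circulating
(myo-type, ncHr), 0 means circulating (cHr), anything else is reported
as ambiguous rather than forced into the dichotomy.

Trimming retains the region from the initiator Met through seven
residues past the end of the D helix (in reference numbering), with
the CDS cut to the exact corresponding codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import global_aligner
from .reference_model import ReferenceModel, SignatureCheck, signature_at

__all__ = ["PositionMap", "HrCall", "map_to_reference", "check_signatures", "classify_subtype", "trim_candidate"]


@dataclass(frozen=True)
class PositionMap:
    """Residue-level map between a candidate and reference numbering.

    ``pairs`` holds (candidate index, reference position), both 1-based,
    strictly increasing in both coordinates.
    """

    candidate_id: str
    pairs: tuple[tuple[int, int], ...]
    coverage: float

    def __post_init__(self):
        prev = (0, 0)
        for pair in self.pairs:
            if not (pair[0] > prev[0] and pair[1] > prev[1]):
                raise ValueError("PositionMap pairs must be strictly increasing")
            prev = pair

    @property
    def cand_to_ref(self) -> dict[int, int]:
        return {c: r for c, r in self.pairs}

    @property
    def ref_to_cand(self) -> dict[int, int]:
        return {r: c for c, r in self.pairs}


def map_to_reference(candidate: str, ref: ReferenceModel, candidate_id: str = "candidate") -> PositionMap:
    """Globally align a candidate onto the reference template.

    Gap columns are excluded from the map; coverage is the fraction of
    reference positions receiving a candidate residue.
    """
    if not candidate:
        raise ValueError("empty candidate protein")
    aligner = global_aligner()
    best = aligner.align(candidate, ref.myo_template)[0]
    pairs: list[tuple[int, int]] = []
    for (c_lo, c_hi), (r_lo, r_hi) in zip(best.aligned[0], best.aligned[1]):
        for off in range(c_hi - c_lo):
            pairs.append((c_lo + off + 1, r_lo + off + 1))
    coverage = len(pairs) / len(ref.myo_template)
    return PositionMap(candidate_id, tuple(pairs), coverage)


def _ref_numbered(pm: PositionMap, candidate: str, ref: ReferenceModel) -> str:
    """Project the candidate into reference numbering (gaps elsewhere)."""
    cells = ["-"] * len(ref.myo_template)
    for c, r in pm.pairs:
        cells[r - 1] = candidate[c - 1]
    return "".join(cells)


def check_signatures(
    pm: PositionMap,
    candidate: str,
    ref: ReferenceModel,
    min_matches: int = 7,
) -> tuple[dict[int, SignatureCheck], int, bool]:
    """Verify the iron-binding signature through a position map.

    Returns (per-position report, number of matches, accepted), where
    acceptance requires at least ``min_matches`` of the 7 residues
    (default: all of them).
    """
    report = signature_at(ref, _ref_numbered(pm, candidate, ref))
    n_match = sum(chk.match for chk in report.values())
    return report, n_match, n_match >= min_matches


@dataclass(frozen=True)
class HrCall:
    """Per-candidate verdict."""

    candidate_id: str
    signature_matches: int
    signature_report: dict[int, SignatureCheck]
    helix_spans: dict[str, tuple[int, int] | None]
    insertion_observed: int
    subtype: str  # cHr | ncHr | ambiguous
    starts_with_met: bool
    coverage: float
    notes: tuple[str, ...] = field(default=())


#: sentinel for an inter-helix window that could not be delimited
UNDETERMINED_INSERTION = -9


def classify_subtype(pm: PositionMap, candidate: str, ref: ReferenceModel) -> HrCall:
    """Classify a signature-verified candidate as cHr / ncHr / ambiguous.

    The observed insertion length is the count of candidate residues
    falling strictly between the C-helix end and D-helix start, minus
    the count the circulating template places there.  Measuring against
    the cHr-length window (rather than counting alignment gap columns)
    makes the statistic symmetric across subtypes and robust to where
    the aligner happens to place the gap.
    """
    report, n_match, _ = check_signatures(pm, candidate, ref)
    c_end = ref.helices["C"][1]
    d_start = ref.helices["D"][0]
    ref_to_cand = pm.ref_to_cand
    notes: list[str] = []

    # Anchor the window at the conserved signature residues flanking it
    # (His79 / His108 in the default reference): the count then depends
    # only on two exactly conserved positions, not on where the aligner
    # places gaps among mutable boundary residues.  Fall back to the
    # helix boundary positions for partial candidates.
    sig_left = [p for p in ref.signature_positions if p <= c_end]
    sig_right = [p for p in ref.signature_positions if p >= d_start]
    anchor_left = max(sig_left) if sig_left else None
    anchor_right = min(sig_right) if sig_right else None
    anchors_usable = (
        anchor_left in ref_to_cand
        and anchor_right in ref_to_cand
        and ref.chr_index(anchor_left) is not None
        and ref.chr_index(anchor_right) is not None
    )
    if anchors_usable:
        observed = ref_to_cand[anchor_right] - ref_to_cand[anchor_left] - 1
        chr_count = ref.chr_index(anchor_right) - ref.chr_index(anchor_left) - 1
        insertion = observed - chr_count
    else:
        left_idx = [c for c, r in pm.pairs if r <= c_end]
        right_idx = [c for c, r in pm.pairs if r >= d_start]
        if not left_idx or not right_idx:
            insertion = UNDETERMINED_INSERTION
            notes.append("inter-helix window not delimited by the alignment")
        else:
            chr_window_count = (d_start - 1 - c_end) - ref.insertion_length
            insertion = (min(right_idx) - max(left_idx) - 1) - chr_window_count

    if insertion == UNDETERMINED_INSERTION:
        subtype = "ambiguous"
    else:
        subtype = {ref.insertion_length: "ncHr", 0: "cHr"}.get(insertion, "ambiguous")
        if subtype == "ambiguous":
            notes.append(f"non-canonical insertion length {insertion}")

    ref_to_cand = pm.ref_to_cand
    spans: dict[str, tuple[int, int] | None] = {}
    for helix, (lo, hi) in ref.helices.items():
        mapped = [ref_to_cand[p] for p in range(lo, hi + 1) if p in ref_to_cand]
        spans[helix] = (min(mapped), max(mapped)) if mapped else None

    return HrCall(
        candidate_id=pm.candidate_id,
        signature_matches=n_match,
        signature_report=report,
        helix_spans=spans,
        insertion_observed=insertion,
        subtype=subtype,
        starts_with_met=candidate.startswith("M"),
        coverage=pm.coverage,
        notes=tuple(notes),
    )


def trim_candidate(
    pm: PositionMap,
    protein: str,
    cds: str,
    ref: ReferenceModel,
) -> tuple[str, str, tuple[int, int]]:
    """Trim a candidate to [initiator Met .. D-helix end + 7].

    The start is the first mapped Met near the reference N-terminus
    (reference position <= 5), falling back to the first mapped residue
    for 5'-incomplete candidates; the end is the last residue mapping
    at or before reference position D.end + 7.  The CDS is cut to the
    same codons.  Returns (protein, cds, (start, end)) with 1-based
    inclusive candidate coordinates of the retained region.
    """
    if len(cds) != 3 * len(protein):
        raise ValueError("CDS length must be 3x protein length")
    d_lo, d_hi = ref.helices["D"]
    if not any(d_lo <= r <= d_hi for _, r in pm.pairs):
        raise ValueError("D helix entirely unmapped; cannot trim")

    first_mapped = pm.pairs[0][0]
    met_starts = [c for c, r in pm.pairs if r <= 5 and protein[c - 1] == "M"]
    start = min(met_starts) if met_starts else first_mapped

    tail_limit = d_hi + 7
    end = max(c for c, r in pm.pairs if r <= tail_limit)
    if end < start:
        raise ValueError("degenerate trim window")
    return protein[start - 1 : end], cds[3 * (start - 1) : 3 * end], (start, end)
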