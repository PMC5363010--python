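"""Candidate discovery: six-frame ORF extraction and similarity screening.

The screen replaces a BLAST database search with an explicit
Smith-Waterman comparison of every ORF against a small panel of known
hemerythrin proteins.  Scores are normalized by the self-score of the
panel sequence, giving a [0, 1] similarity that is 1.0 for an exact
copy of a panel protein; candidates are retained when the best
normalized score reaches a threshold (default 0.35) and the aligned
region spans more than 300 nt of coding sequence.  Length filtering
(default 100 aa minimum) happens at ORF extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Seq import Seq

from ._align import local_aligner, self_score

__all__ = ["OrfRecord", "SimilarityHit", "six_frame_orfs", "local_align", "screen", "best_hits_per_contig"]

_STOPS = set(CodonTable.unambiguous_dna_by_id[1].stop_codons)
_FWD = CodonTable.unambiguous_dna_by_id[1].forward_table
_VALID = set("ACGTN")


def _translate_codon(codon: str) -> str:
    """One codon to one residue; stops -> '*', anything with N -> 'X'."""
    if codon in _STOPS:
        return "*"
    return _FWD.get(codon, "X")


@dataclass(frozen=True)
class OrfRecord:
    """A translated open reading frame with contig provenance.

    Coordinates are 0-based half-open on the forward strand of the
    input contig regardless of the ORF's strand.  ``cds`` is the coding
    sequence in reading orientation (reverse-complemented for '-'),
    excluding any stop codon, so ``translate(cds) == protein``.
    """

    contig_id: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    protein: str
    cds: str
    starts_with_met: bool

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}|{self.strand}{self.frame}|{self.nt_start}-{self.nt_end}"


def six_frame_orfs(contig: str, min_aa: int = 100, contig_id: str = "contig") -> list[OrfRecord]:
    """Extract all maximal ORFs from the six reading frames of a contig.

    Reading frames are segmented at stop codons.  Every stop-to-stop
    (or edge-bounded) fragment of at least ``min_aa`` residues is
    reported; when a fragment does not itself begin with Met but
    contains one, the Met-initiated sub-ORF is reported as well.  The
    non-Met fragments are kept, flagged, to accommodate 5'-incomplete
    transcripts.
    """
    contig = contig.upper()
    bad = set(contig) - _VALID
    if bad:
        raise ValueError(f"non-IUPAC characters in contig: {sorted(bad)}")
    n = len(contig)
    out: list[OrfRecord] = []
    for strand in "+-":
        seq = contig if strand == "+" else str(Seq(contig).reverse_complement())
        for frame in range(3):
            codons = [seq[i : i + 3] for i in range(frame, n - 2, 3)]
            aa = [_translate_codon(c) for c in codons]
            # segment boundaries at stop codons
            seg_start = 0
            for j, residue in enumerate(aa + ["*"]):
                if residue != "*":
                    continue
                if j > seg_start:
                    out.extend(
                        _emit_segment(contig_id, strand, frame, seg_start, j, aa, codons, min_aa, n)
                    )
                seg_start = j + 1
    return out


def _emit_segment(contig_id, strand, frame, seg_start, seg_end, aa, codons, min_aa, contig_len):
    """Yield the fragment (and its Met sub-ORF) for one stop-free segment."""
    records = []
    candidates = [(seg_start, aa[seg_start] == "M")]
    if aa[seg_start] != "M" and "M" in aa[seg_start:seg_end]:
        met = seg_start + aa[seg_start:seg_end].index("M")
        candidates.append((met, True))
    for start, is_met in candidates:
        protein = "".join(aa[start:seg_end])
        if len(protein) < min_aa:
            continue
        cds = "".join(codons[start:seg_end])
        lo = frame + 3 * start
        hi = frame + 3 * seg_end
        if strand == "+":
            nt_start, nt_end = lo, hi
        else:
            nt_start, nt_end = contig_len - hi, contig_len - lo
        records.append(
            OrfRecord(contig_id, strand, frame, nt_start, nt_end, protein, cds, is_met)
        )
    return records


@dataclass(frozen=True)
class SimilarityHit:
    """Best panel match for one ORF."""

    orf: OrfRecord
    query_id: str
    raw_score: float
    norm_score: float
    orf_span: tuple[int, int]  # residue span on the ORF protein, 0-based half-open
    query_span: tuple[int, int]


def local_align(a: str, b: str):
    """Optimal Smith-Waterman local alignment of two proteins.

    Returns ``(score, a_spans, b_spans)`` where the spans are the lists
    of 0-based half-open aligned blocks on each sequence.
    """
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    aligner = local_aligner()
    if aligner.score(a, b) <= 0:  # no positive-scoring local alignment
        return 0.0, [], []
    best = aligner.align(a, b)[0]
    a_spans = [(int(lo), int(hi)) for lo, hi in best.aligned[0]]
    b_spans = [(int(lo), int(hi)) for lo, hi in best.aligned[1]]
    return float(best.score), a_spans, b_spans


def screen(
    orfs: list[OrfRecord],
    panel: dict[str, str],
    threshold: float = 0.35,
    min_span_nt: int = 300,
) -> list[SimilarityHit]:
    """Retain each ORF's best panel hit if it passes score and span filters.

    ``norm_score`` is the local alignment score divided by the panel
    sequence's self-score.  A hit is kept when ``norm_score >=
    threshold`` and the aligned ORF region covers more than
    ``min_span_nt`` nucleotides of coding sequence.
    """
    if not panel:
        raise ValueError("empty query panel")
    selfs = {qid: self_score(q) for qid, q in panel.items()}
    hits: list[SimilarityHit] = []
    for orf in orfs:
        best: SimilarityHit | None = None
        for qid, qseq in sorted(panel.items()):
            score, orf_spans, q_spans = local_align(orf.protein, qseq)
            norm = score / selfs[qid] if selfs[qid] > 0 else 0.0
            if best is None or norm > best.norm_score:
                span = (orf_spans[0][0], orf_spans[-1][1]) if orf_spans else (0, 0)
                qspan = (q_spans[0][0], q_spans[-1][1]) if q_spans else (0, 0)
                best = SimilarityHit(orf, qid, score, norm, span, qspan)
        if best is None or best.norm_score < threshold:
            continue
        aligned_nt = 3 * (best.orf_span[1] - best.orf_span[0])
        if aligned_nt > min_span_nt:
            hits.append(best)
    return hits


def best_hits_per_contig(hits: list[SimilarityHit]) -> list[SimilarityHit]:
    """Deduplicate overlapping-frame hits: one best hit per contig.

    Ties on normalized score are broken by longer protein, then lower
    start coordinate, so the result is deterministic.
    """
    by_contig: dict[str, SimilarityHit] = {}
    for hit in hits:
        key = hit.orf.contig_id
        cur = by_contig.get(key)
        if cur is None:
            by_contig[key] = hit
            continue
        a = (hit.norm_score, len(hit.orf.protein), -hit.orf.nt_start)
        b = (cur.norm_score, len(cur.orf.protein), -cur.orf.nt_start)
        if a > b:
            by_contig[key] = hit
    return [by_contig[k] for k in sorted(by_contig)]
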