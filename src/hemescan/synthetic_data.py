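"""Synthetic inputs: transcriptomes with planted Hr genes, and two-clade
alignments with planted site-rate shifts.

Transcriptome emulation
-----------------------
``make_transcriptome`` plants back-translated, mutated copies of the two
subtype templates among decoy contigs.  Divergence is hierarchical: a
subtype *founder* is first mutated away from its template (a fraction
``founder_share`` of the requested divergence), then each gene mutates
independently away from its founder.  This mimics a gene family in
which paralog lineages are older than the sampled species, so members
of a subtype resemble each other more than they resemble the other
subtype — the regime in which the subtypes form two clades.  Signature
positions are never mutated.  Decoys are first-order Markov resamples
of the planted coding pool (preserving dinucleotide composition, hence
hard negatives for a similarity screen) plus uniform-random sequence.

Rate-shift simulation
---------------------
``simulate_two_clades`` evolves a protein alignment down a two-clade
tree by per-site Poisson substitution with Gamma-distributed site rates
shared between clades (rate heterogeneity across sites is what makes
the two clades' per-site change counts correlated).  A chosen fraction
of sites is "shifted": their rate is multiplied by ``rate_ratio`` in
clade 2 only.  Ground truth (shifted columns, site rates, true trees)
is returned alongside the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference_model import AMINO_ACIDS, ReferenceModel, default_reference, synonymous_codons

__all__ = [
    "SyntheticTruth",
    "TwoCladeSim",
    "mutate_protein",
    "back_translate",
    "make_transcriptome",
    "simulate_two_clades",
    "write_fasta",
    "read_fasta",
]

_SYN = synonymous_codons()
_STOP_CODONS = ("TAA", "TAG", "TGA")
_NT = "ACGT"


# ---------------------------------------------------------------------------
# protein / nucleotide mutation primitives
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def mutate_protein(template: str, divergence: float, preserve: set[int], seed) -> str:
    """Substitute residues of ``template`` at an expected rate ``divergence``.

    Each position outside ``preserve`` (1-based indices) is replaced,
    independently with probability ``divergence``, by a residue drawn
    uniformly from the 19 alternatives.  No indels are introduced.
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    rng = _as_rng(seed)
    out = list(template)
    for i in range(len(out)):
        if (i + 1) in preserve:
            continue
        if rng.random() < divergence:
            alternatives = AMINO_ACIDS.replace(out[i], "")
            out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def back_translate(protein: str, seed) -> str:
    """Back-translate with uniformly random synonymous codons."""
    rng = _as_rng(seed)
    return "".join(_SYN[aa][rng.integers(len(_SYN[aa]))] for aa in protein)


def _derive_cds(
    parent_protein: str,
    parent_cds: str,
    child_protein: str,
    syn_rate: float,
    rng: np.random.Generator,
) -> str:
    """CDS for a mutated child, inheriting the parent's codons.

    Codons at substituted residues are redrawn among the new residue's
    synonyms; unchanged codons are silently substituted with
    probability ``syn_rate``.  Inheritance keeps synonymous sites
    phylogenetically informative, as in real transcripts.
    """
    codons = []
    for i, aa in enumerate(child_protein):
        codon = parent_cds[3 * i : 3 * i + 3]
        if aa != parent_protein[i] or rng.random() < syn_rate:
            codon = _SYN[aa][rng.integers(len(_SYN[aa]))]
        codons.append(codon)
    return "".join(codons)


def _markov_decoy(pool: str, length: int, rng: np.random.Generator) -> str:
    """Sample a sequence from the first-order Markov chain of ``pool``.

    Preserves the pool's dinucleotide composition in expectation, which
    makes these decoys much harder than uniform-random sequence.
    """
    counts = np.ones((4, 4))  # +1 smoothing keeps the chain irreducible
    idx = {c: i for i, c in enumerate(_NT)}
    for a, b in zip(pool, pool[1:]):
        counts[idx[a], idx[b]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    state = rng.integers(4)
    out = []
    for _ in range(length):
        out.append(_NT[state])
        state = rng.choice(4, p=probs[state])
    return "".join(out)


# ---------------------------------------------------------------------------
# transcriptome generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated contig.

    ``start``/``end`` are 0-based half-open CDS coordinates on the
    contig's forward strand (stop codon excluded); decoys carry -1/-1
    and strand '.'.  ``divergence`` is the realized fraction of
    residues differing from the subtype template.
    """

    contig_id: str
    label: str  # cHr | ncHr | decoy
    start: int
    end: int
    strand: str
    divergence: float

    @staticmethod
    def frame(records: list["SyntheticTruth"]) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in records])


def make_transcriptome(
    n_chr: int,
    n_nchr: int,
    n_decoy: int,
    divergence: float = 0.25,
    utr_len_range: tuple[int, int] = (30, 300),
    seed: int = 0,
    founder_share: float = 0.5,
    ref: ReferenceModel | None = None,
) -> tuple[dict[str, str], list[SyntheticTruth]]:
    """Generate contigs with planted Hr genes among decoys.

    Returns an ordered ``{contig_id: sequence}`` mapping and the truth
    records (one per contig).  Deterministic for a fixed seed.
    """
    if min(n_chr, n_nchr, n_decoy) < 0:
        raise ValueError("contig counts must be non-negative")
    ref = ref or default_reference()
    rng = np.random.default_rng(seed)

    myo_preserve = set(ref.signature_positions)
    chr_preserve = {ref.chr_index(p) for p in ref.signature_positions} - {None}

    founder_div = divergence * founder_share
    gene_div = divergence * (1.0 - founder_share)
    founders = {}
    for label, template, template_cds, preserve in (
        ("cHr", ref.chr_template, ref.chr_cds, chr_preserve),
        ("ncHr", ref.myo_template, ref.myo_cds, myo_preserve),
    ):
        protein = mutate_protein(template, founder_div, preserve, rng)
        cds = _derive_cds(template, template_cds, protein, founder_div, rng)
        founders[label] = (protein, cds, template, preserve)

    genes: list[tuple[str, str, str, float]] = []  # (label, protein, cds, divergence)
    for label, count in (("cHr", n_chr), ("ncHr", n_nchr)):
        founder, founder_cds, template, preserve = founders[label]
        for _ in range(count):
            protein = mutate_protein(founder, gene_div, preserve, rng)
            cds = _derive_cds(founder, founder_cds, protein, gene_div, rng)
            realized = sum(a != b for a, b in zip(protein, template)) / len(template)
            genes.append((label, protein, cds, realized))

    lo, hi = utr_len_range
    entries: list[tuple[str, str, int, int, str, float]] = []  # seq,label,start,end,strand,div
    cds_pool: list[str] = []
    for label, protein, cds, realized in genes:
        cds_pool.append(cds)
        utr5 = "".join(_NT[i] for i in rng.integers(0, 4, size=rng.integers(lo, hi + 1)))
        utr3 = "".join(_NT[i] for i in rng.integers(0, 4, size=rng.integers(lo, hi + 1)))
        stop = _STOP_CODONS[rng.integers(3)]
        full = utr5 + cds + stop + utr3
        start, end = len(utr5), len(utr5) + len(cds)
        if rng.random() < 0.5:
            strand, contig = "+", full
        else:
            strand = "-"
            contig = str(Seq(full).reverse_complement())
            start, end = len(full) - end, len(full) - start
        entries.append((contig, label, start, end, strand, realized))

    pool = "".join(cds_pool) if cds_pool else ref.myo_cds
    gene_lengths = [len(e[0]) for e in entries] or [500]
    for k in range(n_decoy):
        length = int(rng.integers(min(gene_lengths), max(gene_lengths) + 1))
        if k % 2 == 0:
            seq = _markov_decoy(pool, length, rng)
        else:
            seq = "".join(_NT[i] for i in rng.integers(0, 4, size=length))
        entries.append((seq, "decoy", -1, -1, ".", float("nan")))

    order = rng.permutation(len(entries))
    contigs: dict[str, str] = {}
    truth: list[SyntheticTruth] = []
    for rank, j in enumerate(order):
        seq, label, start, end, strand, div = entries[j]
        cid = f"contig_{rank:05d}"
        contigs[cid] = seq
        truth.append(SyntheticTruth(cid, label, start, end, strand, div))
    return contigs, truth


# ---------------------------------------------------------------------------
# two-clade rate-shift simulator
# ---------------------------------------------------------------------------

def _discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability categories of a mean-1 gamma."""
    from scipy.special import gammainc
    from scipy.stats import gamma as gamma_dist

    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1.0 / shape)
    x = edges * shape
    means = (gammainc(shape + 1, x[1:]) - gammainc(shape + 1, x[:-1])) * k
    return means / means.mean()


class _Node:
    __slots__ = ("label", "children", "length")

    def __init__(self, label=None, children=(), length=0.0):
        self.label = label
        self.children = list(children)
        self.length = length

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.6f}"
        inner = ",".join(c._nwk() for c in self.children)
        return f"({inner}):{self.length:.6f}"

    def total_length(self) -> float:
        return sum(c.length + c.total_length() for c in self.children)


def _random_clade(
    labels: list[str],
    total_length: float,
    rng: np.random.Generator,
    terminal_fraction: float = 0.8,
) -> _Node:
    """Random bifurcating tree over ``labels``.

    Branch lengths are Exp(1) draws rescaled so that terminal branches
    carry ``terminal_fraction`` of the clade's total length — a
    radiation-like shape (short internal, long terminal branches) in
    which most substitutions arise independently on tip lineages, as
    in a gene family sampled across long-diverged species.
    """
    nodes = [_Node(label=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.exponential(1.0))
        b.length = float(rng.exponential(1.0))
        nodes.append(_Node(children=(a, b)))
    root = nodes[0]
    terminals = [n for n in _iter_branches(root) if not n.children]
    internals = [n for n in _iter_branches(root) if n.children]
    for group, share in ((terminals, terminal_fraction), (internals, 1 - terminal_fraction)):
        total = sum(n.length for n in group)
        if total > 0:
            for n in group:
                n.length *= share * total_length / total
    return root


def _iter_branches(node: _Node):
    for c in node.children:
        yield c
        yield from _iter_branches(c)


@dataclass
class TwoCladeSim:
    """A simulated two-clade protein alignment with planted rate shifts."""

    alignment: dict[str, str]
    newick: str
    clade1: list[str]
    clade2: list[str]
    clade1_newick: str
    clade2_newick: str
    shifted_sites: list[int]  # 0-based column indices
    site_rates: np.ndarray
    params: dict = field(default_factory=dict)


def simulate_two_clades(
    n1: int,
    n2: int,
    L: int = 132,
    shifted_fraction: float = 0.1,
    rate_ratio: float = 5.0,
    base_rate: float = 6.0,
    seed: int = 0,
    gamma_shape: float = 0.5,
    n_rate_categories: int = 4,
    clade_tree_length: float = 1.0,
    stem_length: float = 0.25,
) -> TwoCladeSim:
    """Evolve two clades with a rate multiplier on a subset of sites.

    Background sites evolve at ``base_rate * g_k`` where ``g_k`` is a
    discrete-gamma site rate (``n_rate_categories`` equal-probability
    categories of a mean-1 Gamma(gamma_shape) distribution) shared by
    both clades — the shared rate heterogeneity that makes the clades'
    per-site change counts correlated.  Shifted sites abandon the shared rate: they evolve at
    exactly ``base_rate`` in clade 1 and ``base_rate * rate_ratio`` in
    clade 2, modelling a change of functional constraint after the
    duplication.  Expected substitutions per site within a clade are
    ``rate * clade_tree_length``.
    """
    if n1 < 3 or n2 < 3:
        raise ValueError("each clade needs at least 3 tips")
    if not 0 <= shifted_fraction <= 1:
        raise ValueError("shifted_fraction must be in [0, 1]")
    if rate_ratio < 1:
        raise ValueError("rate_ratio must be >= 1")
    rng = np.random.default_rng(seed)

    n_shift = int(round(shifted_fraction * L))
    shifted = sorted(rng.choice(L, size=n_shift, replace=False).tolist())
    shift_mask = np.zeros(L, dtype=bool)
    shift_mask[shifted] = True
    cats = _discrete_gamma_rates(gamma_shape, n_rate_categories)
    g = cats[rng.integers(0, n_rate_categories, size=L)]

    clade_roots = {
        1: _random_clade([f"c1_{i:02d}" for i in range(n1)], clade_tree_length, rng),
        2: _random_clade([f"c2_{i:02d}" for i in range(n2)], clade_tree_length, rng),
    }
    clade_roots[1].length = stem_length
    clade_roots[2].length = stem_length

    root_seq = rng.integers(0, len(AMINO_ACIDS), size=L)
    alignment: dict[str, str] = {}

    def rates_for(clade: int) -> np.ndarray:
        r = base_rate * g
        r[shift_mask] = base_rate * (rate_ratio if clade == 2 else 1.0)
        return r

    def evolve(seq: np.ndarray, branch_len: float, rates: np.ndarray) -> np.ndarray:
        seq = seq.copy()
        n_events = rng.poisson(rates * branch_len)
        for k in np.nonzero(n_events)[0]:
            for _ in range(n_events[k]):
                new = rng.integers(len(AMINO_ACIDS) - 1)
                if new >= seq[k]:
                    new += 1
                seq[k] = new
        return seq

    def walk(node: _Node, seq: np.ndarray, rates: np.ndarray) -> None:
        if not node.children:
            alignment[node.label] = "".join(AMINO_ACIDS[i] for i in seq)
            return
        for child in node.children:
            walk(child, evolve(seq, child.length, rates), rates)

    for clade in (1, 2):
        root = clade_roots[clade]
        rates = rates_for(clade)
        seq_at_clade_root = evolve(root_seq, root.length, rates)
        walk(root, seq_at_clade_root, rates)

    full = _Node(children=(clade_roots[1], clade_roots[2]))
    sim = TwoCladeSim(
        alignment=alignment,
        newick=full.newick(),
        clade1=sorted(l for l in alignment if l.startswith("c1_")),
        clade2=sorted(l for l in alignment if l.startswith("c2_")),
        clade1_newick=clade_roots[1].newick(),
        clade2_newick=clade_roots[2].newick(),
        shifted_sites=shifted,
        site_rates=g,
        params={
            "n1": n1, "n2": n2, "L": L, "shifted_fraction": shifted_fraction,
            "rate_ratio": rate_ratio, "base_rate": base_rate, "seed": seed,
            "gamma_shape": gamma_shape, "clade_tree_length": clade_tree_length,
        },
    )
    return sim


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_truth(truth: list[SyntheticTruth], path: str | Path) -> None:
    SyntheticTruth.frame(truth).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
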