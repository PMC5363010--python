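"""End-to-end pipeline: simulate/load contigs, scan, classify, align,
build the gene tree, test subtype monophyly, and score rate shifts.

Every stage writes its artifact into the run directory and the run
finishes with a machine-readable ``report.json`` echoing the full
configuration, the filter-cascade counts (which must be monotone
non-increasing: ORFs >= screen hits >= signature-passing >=
classified), the monophyly verdicts and the divergence summary.  A run
is deterministic for a fixed seed: repeating it produces byte-identical
artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import classify_subtype, map_to_reference, trim_candidate
from .codon_align import backtranslate, star_align, write_msa
from .discovery import best_hits_per_contig, screen, six_frame_orfs
from .divergence import rate_shift_profile
from .phylo import bootstrap_support, is_monophyletic, nj_tree, p_distance, root_with_outgroup
from .reference_model import ReferenceModel, default_reference
from .synthetic_data import back_translate, make_transcriptome, mutate_protein, write_fasta, write_truth

log = logging.getLogger("hemescan")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run (all thresholds in one place)."""

    outdir: str = "hemescan_run"
    seed: int = 7
    # synthetic input (used when no contig FASTA is supplied)
    contigs: str | None = None
    n_chr: int = 10
    n_nchr: int = 10
    n_decoy: int = 200
    divergence: float = 0.25
    utr_len_range: tuple[int, int] = (30, 300)
    # discovery
    min_aa: int = 100
    threshold: float = 0.35
    min_span_nt: int = 300
    # annotation
    min_signature: int = 7
    min_coverage_non_met: float = 0.8
    # phylogenetics / divergence
    bootstrap: int = 100
    cutoff: float = 0.7
    outgroup_divergence: float = 0.4

    def validate(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must be in [0, 1]")
        if not 0 <= self.cutoff <= 1:
            raise ValueError("cutoff must be in [0, 1]")
        if not 0 <= self.min_signature <= 7:
            raise ValueError("min_signature must be in [0, 7]")
        if self.min_aa < 1:
            raise ValueError("min_aa must be positive")


@dataclass
class RunReport:
    """Per-stage counts plus the analysis summaries."""

    config: dict
    version: str
    counts: dict = field(default_factory=dict)
    subtypes: dict = field(default_factory=dict)
    monophyly: dict = field(default_factory=dict)
    divergence: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def check_cascade(self) -> None:
        c = self.counts
        cascade = [c["orfs"], c["screen_hits"], c["signature_pass"], c["classified"]]
        if any(a < b for a, b in zip(cascade, cascade[1:])):
            raise AssertionError(f"filter cascade not monotone: {cascade}")


def _outgroup_pair(ref: ReferenceModel, seed: int, divergence: float) -> dict[str, tuple[str, str]]:
    """Two deeply diverged sequences used to root the gene tree."""
    rng = np.random.default_rng(seed + 101)
    preserve = set(ref.signature_positions)
    founder = mutate_protein(ref.myo_template, divergence, preserve, rng)
    out = {}
    for i in (1, 2):
        protein = mutate_protein(founder, 0.05, preserve, rng)
        out[f"outgroup_{i}"] = (protein, back_translate(protein, rng))
    return out


def run_all(config: RunConfig, ref: ReferenceModel | None = None) -> RunReport:
    """Execute the full pipeline and write all artifacts to ``outdir``."""
    config.validate()
    ref = ref or default_reference()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config), version=__version__)

    # --- stage 0: input contigs -------------------------------------------
    if config.contigs:
        from .synthetic_data import read_fasta

        contigs = read_fasta(config.contigs)
        log.info("loaded %d contigs from %s", len(contigs), config.contigs)
    else:
        contigs, truth = make_transcriptome(
            config.n_chr, config.n_nchr, config.n_decoy,
            divergence=config.divergence, utr_len_range=tuple(config.utr_len_range),
            seed=config.seed, ref=ref,
        )
        write_fasta(contigs, outdir / "contigs.fasta")
        write_truth(truth, outdir / "truth.tsv")
        log.info("simulated %d contigs (seed=%d)", len(contigs), config.seed)
    report.counts["contigs"] = len(contigs)

    # --- stage 1: ORFs + similarity screen --------------------------------
    orfs = [o for cid, seq in contigs.items() for o in six_frame_orfs(seq, config.min_aa, cid)]
    panel = {"ncHr_template": ref.myo_template, "cHr_template": ref.chr_template}
    hits = best_hits_per_contig(
        screen(orfs, panel, threshold=config.threshold, min_span_nt=config.min_span_nt)
    )
    report.counts["orfs"] = len(orfs)
    report.counts["screen_hits"] = len(hits)
    log.info("%d ORFs -> %d screened candidates", len(orfs), len(hits))
    pd.DataFrame(
        [
            {
                "contig_id": h.orf.contig_id, "strand": h.orf.strand, "frame": h.orf.frame,
                "nt_start": h.orf.nt_start, "nt_end": h.orf.nt_end, "query_id": h.query_id,
                "raw_score": h.raw_score, "norm_score": round(h.norm_score, 6),
                "starts_with_met": h.orf.starts_with_met,
            }
            for h in hits
        ]
    ).to_csv(outdir / "hits.tsv", sep="\t", index=False)

    # --- stage 2: signature gate, classification, trimming ----------------
    calls = []
    trimmed_prot: dict[str, str] = {}
    trimmed_cds: dict[str, str] = {}
    for h in hits:
        cid = h.orf.contig_id
        pm = map_to_reference(h.orf.protein, ref, cid)
        call = classify_subtype(pm, h.orf.protein, ref)
        sig_ok = call.signature_matches >= config.min_signature
        met_ok = h.orf.starts_with_met or pm.coverage >= config.min_coverage_non_met
        accepted = sig_ok and met_ok
        calls.append((call, accepted))
        if accepted and call.subtype in ("cHr", "ncHr"):
            prot_t, cds_t, _ = trim_candidate(pm, h.orf.protein, h.orf.cds, ref)
            trimmed_prot[cid] = prot_t
            trimmed_cds[cid] = cds_t

    n_sig = sum(1 for c, acc in calls if acc)
    by_subtype = {"cHr": 0, "ncHr": 0, "ambiguous": 0}
    for call, accepted in calls:
        if accepted:
            by_subtype[call.subtype] += 1
    report.counts["signature_pass"] = n_sig
    report.counts["classified"] = by_subtype["cHr"] + by_subtype["ncHr"]
    report.subtypes = by_subtype
    log.info("signature-passing: %d; subtypes: %s", n_sig, by_subtype)
    pd.DataFrame(
        [
            {
                "candidate_id": c.candidate_id, "signature_matches": c.signature_matches,
                "insertion_observed": c.insertion_observed, "subtype": c.subtype,
                "starts_with_met": c.starts_with_met, "coverage": round(c.coverage, 4),
                "accepted": acc, "notes": ";".join(c.notes),
            }
            for c, acc in calls
        ]
    ).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    report.check_cascade()

    chr_tips = sorted(cid for cid in trimmed_prot if _subtype_of(calls, cid) == "cHr")
    nchr_tips = sorted(cid for cid in trimmed_prot if _subtype_of(calls, cid) == "ncHr")

    if len(trimmed_prot) < 2:
        report.notes.append("fewer than 2 classified candidates; tree and divergence stages skipped")
        report.save(outdir / "report.json")
        return report

    write_fasta(trimmed_prot, outdir / "trimmed_proteins.faa")
    write_fasta(trimmed_cds, outdir / "trimmed_cds.fna")

    # --- stage 3: alignment ------------------------------------------------
    outgroups = _outgroup_pair(ref, config.seed, config.outgroup_divergence)
    proteins = dict(trimmed_prot)
    cds = dict(trimmed_cds)
    for oid, (p, c) in outgroups.items():
        proteins[oid] = p
        cds[oid] = c
    msa = star_align(proteins, ref)
    codon = backtranslate(msa.rows, cds)
    write_msa(msa.rows, outdir / "protein_msa.faa")
    write_msa(codon.nt_rows, outdir / "codon_msa.fna")

    # --- stage 4: tree + monophyly -----------------------------------------
    tree = bootstrap_support(codon.nt_rows, replicates=config.bootstrap, seed=config.seed)
    rooted = root_with_outgroup(tree, list(outgroups))
    rooted.write(path=str(outdir / "gene_tree.nwk"), schema="newick")
    for name, tips in (("cHr", chr_tips), ("ncHr", nchr_tips)):
        report.monophyly[name] = is_monophyletic(rooted, tips) if tips else None
    log.info("monophyly: %s", report.monophyly)

    # --- stage 5: site-specific rate shifts --------------------------------
    if len(chr_tips) >= 3 and len(nchr_tips) >= 3:
        tree1 = rooted.extract_tree_with_taxa_labels(chr_tips)
        tree2 = rooted.extract_tree_with_taxa_labels(nchr_tips)
        prof = rate_shift_profile(
            msa.rows, chr_tips, nchr_tips, tree1, tree2,
            cutoff=config.cutoff, column_ref=msa.column_ref, ref=ref,
        )
        pd.DataFrame(
            {
                "column": range(msa.n_columns),
                "ref_position": [p if p is not None else -1 for p in msa.column_ref],
                "c1": prof.c1, "c2": prof.c2, "q": np.round(prof.q, 6),
                "flagged": [k in set(prof.flagged) for k in range(msa.n_columns)],
                "region": [
                    ref.region_of(p) if p is not None else "unmapped" for p in msa.column_ref
                ],
            }
        ).to_csv(outdir / "site_rates.tsv", sep="\t", index=False)
        report.divergence = {
            "theta_d": round(prof.theta_d, 6),
            "cutoff": config.cutoff,
            "n_flagged": len(prof.flagged),
            "lambda1": prof.lambda1,
            "lambda2": prof.lambda2,
            "region_counts": prof.region_counts,
        }
        log.info("theta_D=%.3f, %d flagged sites", prof.theta_d, len(prof.flagged))
    else:
        report.notes.append("a subtype has fewer than 3 members; divergence stage skipped")

    report.save(outdir / "report.json")
    return report


def _subtype_of(calls, cid: str) -> str | None:
    for call, accepted in calls:
        if call.candidate_id == cid and accepted:
            return call.subtype
    return None
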