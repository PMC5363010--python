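import numpy as np
import pytest
from Bio.Seq import Seq

from hemescan.reference_model import signature_at, translate_cds
from hemescan.synthetic_data import (
    make_transcriptome,
    mutate_protein,
    simulate_two_clades,
    back_translate,
)


class TestMutateProtein:
    def test_zero_divergence_is_identity(self, ref):
        assert mutate_protein(ref.myo_template, 0.0, set(), 1) == ref.myo_template

    def test_preserved_positions_untouched(self, ref):
        sig = set(ref.signature_positions)
        mutated = mutate_protein(ref.myo_template, 0.25, sig, 1)
        assert len(mutated) == len(ref.myo_template)
        assert all(chk.match for chk in signature_at(ref, mutated).values())

    def test_mean_divergence_matches_request(self, ref):
        """Observed substitution fraction is binomial around the request."""
        diffs = []
        for seed in range(200):
            mutated = mutate_protein(ref.myo_template, 0.25, set(), seed)
            diffs.append(sum(a != b for a, b in zip(mutated, ref.myo_template)))
        mean = np.mean(diffs) / len(ref.myo_template)
        assert abs(mean - 0.25) < 0.01  # 3+ sigma of the binomial mean

    def test_rejects_divergence_of_one(self, ref):
        with pytest.raises(ValueError):
            mutate_protein(ref.myo_template, 1.0, set(), 0)


class TestMakeTranscriptome:
    def test_decoys_only(self):
        contigs, truth = make_transcriptome(0, 0, 5, seed=1)
        assert len(contigs) == 5
        assert all(t.label == "decoy" for t in truth)

    def test_identity_case_recovers_templates(self, ref):
        contigs, truth = make_transcriptome(1, 1, 0, divergence=0.0, utr_len_range=(0, 0), seed=3)
        proteins = set()
        for t in truth:
            cds = contigs[t.contig_id][t.start : t.end]
            if t.strand == "-":
                cds = str(Seq(contigs[t.contig_id]).reverse_complement())[
                    len(contigs[t.contig_id]) - t.end : len(contigs[t.contig_id]) - t.start
                ]
            proteins.add(translate_cds(cds))
        assert proteins == {ref.myo_template, ref.chr_template}

    def test_planted_genes_keep_signature(self, ref):
        """Every planted CDS re-translates and passes the 7/7 signature check."""
        contigs, truth = make_transcriptome(10, 10, 0, divergence=0.25, seed=7)
        lo, hi = ref.insertion_block
        for t in truth:
            contig = contigs[t.contig_id]
            if t.strand == "-":
                contig = str(Seq(contig).reverse_complement())
                start, end = len(contigs[t.contig_id]) - t.end, len(contigs[t.contig_id]) - t.start
            else:
                start, end = t.start, t.end
            protein = translate_cds(contig[start:end])
            if t.label == "cHr":  # project into reference numbering first
                protein = protein[: lo - 1] + "-" * 5 + protein[lo - 1 :]
            assert all(chk.match for chk in signature_at(ref, protein).values()), t

    def test_labels_partition_and_truth_complete(self):
        contigs, truth = make_transcriptome(3, 4, 10, seed=2)
        assert len(truth) == len(contigs) == 17
        assert sorted(t.contig_id for t in truth) == sorted(contigs)
        counts = {"cHr": 0, "ncHr": 0, "decoy": 0}
        for t in truth:
            counts[t.label] += 1
        assert counts == {"cHr": 3, "ncHr": 4, "decoy": 10}

    def test_deterministic_under_seed(self):
        from hemescan.synthetic_data import SyntheticTruth

        a = make_transcriptome(2, 2, 10, seed=42)
        b = make_transcriptome(2, 2, 10, seed=42)
        assert a[0] == b[0]
        # frame comparison treats the decoys' NaN divergence as equal
        assert SyntheticTruth.frame(a[1]).equals(SyntheticTruth.frame(b[1]))


class TestBackTranslate:
    def test_round_trip(self, ref, rng):
        for _ in range(20):
            protein = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 40))
            assert translate_cds(back_translate(protein, rng)) == protein


class TestSimulateTwoClades:
    def test_shifted_site_count(self):
        sim = simulate_two_clades(20, 20, 132, 0.1, 5.0, seed=1)
        assert len(sim.shifted_sites) == round(0.1 * 132) == 13
        assert all(0 <= k < 132 for k in sim.shifted_sites)

    def test_no_shift_when_fraction_zero(self):
        sim = simulate_two_clades(5, 5, 50, 0.0, 5.0, seed=1)
        assert sim.shifted_sites == []

    def test_clades_partition_tips(self):
        sim = simulate_two_clades(4, 6, 30, 0.1, 2.0, seed=5)
        assert len(sim.clade1) == 4 and len(sim.clade2) == 6
        assert set(sim.clade1) | set(sim.clade2) == set(sim.alignment)
        assert not set(sim.clade1) & set(sim.clade2)
        assert all(len(s) == 30 for s in sim.alignment.values())

    def test_deterministic_under_seed(self):
        a = simulate_two_clades(4, 4, 40, 0.1, 3.0, seed=9)
        b = simulate_two_clades(4, 4, 40, 0.1, 3.0, seed=9)
        assert a.alignment == b.alignment and a.newick == b.newick

    def test_rejects_degenerate_clades(self):
        with pytest.raises(ValueError):
            simulate_two_clades(2, 5, 30, 0.1, 2.0, seed=0)

    def test_clades_exchangeable_without_rate_shift(self):
        """At rate_ratio=1 neither clade accumulates systematically more
        changes (sign test over replicate totals)."""
        from hemescan.divergence import fitch_site_changes

        wins = 0
        for seed in range(30):
            sim = simulate_two_clades(8, 8, 60, 0.5, 1.0, seed=seed)
            c1 = fitch_site_changes({k: sim.alignment[k] for k in sim.clade1}, sim.clade1_newick)
            c2 = fitch_site_changes({k: sim.alignment[k] for k in sim.clade2}, sim.clade2_newick)
            wins += c1.sum() > c2.sum()
        assert 5 <= wins <= 25  # binomial(30, 1/2) central range
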