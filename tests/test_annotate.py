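import numpy as np
import pytest

from hemescan.annotate import (
    check_signatures,
    classify_subtype,
    map_to_reference,
    trim_candidate,
)
from hemescan.reference_model import translate_cds
from hemescan.synthetic_data import back_translate, mutate_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestMapToReference:
    def test_identity_mapping(self, ref):
        pm = map_to_reference(ref.myo_template, ref)
        assert pm.pairs == tuple((i, i) for i in range(1, len(ref.myo_template) + 1))
        assert pm.coverage == 1.0

    def test_leading_deletion_shifts_map(self, ref):
        pm = map_to_reference(ref.myo_template[5:], ref)
        assert pm.pairs == tuple((i, i + 5) for i in range(1, len(ref.myo_template) - 4))
        assert pm.coverage < 1.0

    def test_rejects_empty(self, ref):
        with pytest.raises(ValueError):
            map_to_reference("", ref)

    def test_mapped_signatures_survive_divergence(self, ref):
        """At 20% divergence, signature positions stay mapped correctly."""
        sig = set(ref.signature_positions)
        good = 0
        for seed in range(50):
            cand = mutate_protein(ref.myo_template, 0.2, sig, seed)
            pm = map_to_reference(cand, ref)
            _, n, _ = check_signatures(pm, cand, ref)
            good += n
        assert good >= 0.95 * 50 * 7


class TestCheckSignatures:
    def test_template_full_match(self, ref):
        pm = map_to_reference(ref.chr_template, ref)
        report, n, ok = check_signatures(pm, ref.chr_template, ref)
        assert n == 7 and ok

    def test_planted_mismatch_counted(self, ref):
        cand = ref.myo_template[:59] + "Q" + ref.myo_template[60:]
        pm = map_to_reference(cand, ref)
        report, n, ok = check_signatures(pm, cand, ref)
        assert n == 6 and not ok
        assert report[60].observed == "Q"

    def test_configurable_minimum(self, ref):
        cand = ref.myo_template[:59] + "Q" + ref.myo_template[60:]
        pm = map_to_reference(cand, ref)
        assert check_signatures(pm, cand, ref, min_matches=6)[2]


class TestClassifySubtype:
    def test_templates(self, ref):
        for protein, subtype, ins in (
            (ref.myo_template, "ncHr", 5),
            (ref.chr_template, "cHr", 0),
        ):
            call = classify_subtype(map_to_reference(protein, ref), protein, ref)
            assert (call.subtype, call.insertion_observed) == (subtype, ins)
            assert call.signature_matches == 7

    def test_partial_insertion_is_ambiguous(self, ref):
        lo = ref.insertion_block[0]
        cand = ref.chr_template[: lo - 1] + "AGA" + ref.chr_template[lo - 1 :]
        call = classify_subtype(map_to_reference(cand, ref), cand, ref)
        assert call.subtype == "ambiguous"
        assert call.insertion_observed == 3

    def test_helix_spans_on_template(self, ref):
        call = classify_subtype(map_to_reference(ref.myo_template, ref), ref.myo_template, ref)
        assert call.helix_spans == {k: v for k, v in ref.helices.items()}

    def test_robust_under_divergence(self, ref):
        """Subtype calls stay exact for indel-free mutants up to 30%."""
        sig = set(ref.signature_positions)
        chr_sig = {ref.chr_index(p) for p in sig} - {None}
        for seed in range(50):
            myo_mut = mutate_protein(ref.myo_template, 0.3, sig, seed)
            chr_mut = mutate_protein(ref.chr_template, 0.3, chr_sig, seed)
            call_m = classify_subtype(map_to_reference(myo_mut, ref), myo_mut, ref)
            call_c = classify_subtype(map_to_reference(chr_mut, ref), chr_mut, ref)
            assert call_m.subtype == "ncHr", seed
            assert call_c.subtype == "cHr", seed


class TestTrimCandidate:
    def test_n_terminal_extension_removed(self, ref, rng):
        ext = "".join(AA[i] for i in rng.integers(0, 20, 10))
        cand = ext + ref.myo_template
        cds = back_translate(cand, rng)
        pm = map_to_reference(cand, ref)
        prot_t, cds_t, (start, end) = trim_candidate(pm, cand, cds, ref)
        assert prot_t == ref.myo_template
        assert start == 11
        assert translate_cds(cds_t) == prot_t

    def test_c_terminal_tail_cut_after_d_helix(self, ref, rng):
        tail = "".join(AA[i] for i in rng.integers(0, 20, 20))
        cand = ref.myo_template + tail
        cds = back_translate(cand, rng)
        pm = map_to_reference(cand, ref)
        prot_t, cds_t, (start, end) = trim_candidate(pm, cand, cds, ref)
        # retained through the residue mapped to reference D.end + 7
        d_end_cand = pm.ref_to_cand[ref.helices["D"][1]]
        assert end == d_end_cand + 7
        assert prot_t == ref.myo_template
        assert translate_cds(cds_t) == prot_t

    def test_unmapped_d_helix_raises(self, ref, rng):
        cand = ref.myo_template[:60]
        cds = back_translate(cand, rng)
        pm = map_to_reference(cand, ref)
        with pytest.raises(ValueError):
            trim_candidate(pm, cand, cds, ref)

    def test_trim_then_remap_is_stable(self, ref, rng):
        """Re-mapping a trimmed candidate reproduces the restriction of
        the original position map."""
        sig = set(ref.signature_positions)
        for seed in range(10):
            ext = "".join(AA[i] for i in rng.integers(0, 20, 8))
            cand = ext + mutate_protein(ref.myo_template, 0.15, sig, seed)
            cds = back_translate(cand, rng)
            pm = map_to_reference(cand, ref)
            prot_t, cds_t, (start, end) = trim_candidate(pm, cand, cds, ref)
            pm2 = map_to_reference(prot_t, ref)
            original = {(c - start + 1, r) for c, r in pm.pairs if start <= c <= end}
            assert original == set(pm2.pairs)
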