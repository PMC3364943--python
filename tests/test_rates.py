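"""NG86+JC estimator against independent oracles, plus alignment plumbing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from oracles import OracleSaturated, ng86_dn_ds
from structage import rates as rt
from structage.rates import (
    CodonAlignment,
    RateError,
    SaturatedAlignmentError,
    estimate_dn_ds,
)
from structage.synthetic import _mutate_codon_indices


def random_related_pair(rng, n_codons=50, p_sub=0.3):
    """A pair of coding sequences related by random single-nt substitutions."""
    ia = rt.SENSE_CODON_IDX[rng.integers(0, len(rt.SENSE_CODON_IDX), size=n_codons)]
    ib = _mutate_codon_indices(ia, p_sub, 0.75, rng)
    return rt.decode_codons(ia), rt.decode_codons(ib)


class TestEstimateDnDs:
    def test_identical_sequences_give_zero_rates(self):
        seq = "ATGGCTAAATTTGGG"
        est = estimate_dn_ds(CodonAlignment(seq, seq))
        assert est.dn == 0.0 and est.ds == 0.0
        assert est.omega is None  # dS = 0 leaves the ratio undefined

    def test_single_synonymous_change(self):
        """One GCT->GCC among 11 alanines: dN = 0, dS ~= 0.097."""
        a, b = "GCT" * 11, "GCC" + "GCT" * 10
        est = estimate_dn_ds(CodonAlignment(a, b))
        assert est.dn == 0.0
        assert est.ds == pytest.approx(0.0969, abs=5e-4)

    def test_single_nonsynonymous_change(self):
        """One GCT->GTT among 11 alanines: dS = 0, dN ~= 0.047, omega undefined."""
        a, b = "GCT" * 11, "GTT" + "GCT" * 10
        est = estimate_dn_ds(CodonAlignment(a, b))
        assert est.ds == 0.0
        assert est.dn == pytest.approx(0.0469, abs=5e-4)
        assert est.omega is None

    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = random_related_pair(rng)
            est = estimate_dn_ds(CodonAlignment(a, b))
            assert est.n_sites + est.s_sites == pytest.approx(3 * est.n_codons, abs=1e-9)

    def test_symmetric_in_the_two_sequences(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = random_related_pair(rng)
            e1 = estimate_dn_ds(CodonAlignment(a, b))
            e2 = estimate_dn_ds(CodonAlignment(b, a))
            assert e1.dn == pytest.approx(e2.dn, abs=1e-12)
            assert e1.ds == pytest.approx(e2.ds, abs=1e-12)

    def test_agrees_with_bruteforce_oracle(self):
        """Exact agreement with the independent NG86+JC oracle."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b = random_related_pair(rng, n_codons=30)
            try:
                expected = ng86_dn_ds(a, b)
            except OracleSaturated:
                with pytest.raises(SaturatedAlignmentError):
                    estimate_dn_ds(CodonAlignment(a, b))
                continue
            est = estimate_dn_ds(CodonAlignment(a, b))
            assert est.dn == pytest.approx(expected["dn"], abs=1e-12)
            assert est.ds == pytest.approx(expected["ds"], abs=1e-12)
            assert est.n_sites == pytest.approx(expected["n"], abs=1e-12)
            assert est.n_diffs == pytest.approx(expected["nd"], abs=1e-12)

    def test_agrees_with_biopython_ng86(self):
        """Cross-check against Bio.codonalign's independent NG86."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b = random_related_pair(rng, n_codons=30)
            est = estimate_dn_ds(CodonAlignment(a, b))
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert est.dn == pytest.approx(dn, abs=1e-6)
            assert est.ds == pytest.approx(ds, abs=1e-6)

    def test_saturation_raises(self):
        # fully divergent at every third position -> pS = 1
        a, b = "GCT" * 20, "GCC" * 20
        with pytest.raises(SaturatedAlignmentError):
            estimate_dn_ds(CodonAlignment(a, b))

    def test_internal_stop_rejected(self):
        with pytest.raises(RateError):
            estimate_dn_ds(CodonAlignment("ATGTAAGCT", "ATGAAAGCT"))

    def test_purely_synonymous_process_gives_zero_dn(self):
        """Substitutions restricted to synonymous changes never produce dN."""
        rng = np.random.default_rng(5)
        ia = rt.SENSE_CODON_IDX[rng.integers(0, len(rt.SENSE_CODON_IDX), size=500)]
        ib = _mutate_codon_indices(ia, 0.2, nonsyn_fraction=0.0, rng=rng)
        # codons without synonymous neighbours fall back to nonsyn; exclude them
        keep = np.array([rt.S_SITES[i] > 0 for i in ia])
        est = rt.estimate_from_indices(ia[keep], ib[keep])
        assert est.dn == 0.0


class TestBacktranslate:
    def test_direct_expansion(self):
        aln = rt.backtranslate_alignment(("MA", "MA"), "ATGGCT", "ATGGCA")
        assert (aln.seq_a, aln.seq_b) == ("ATGGCT", "ATGGCA")

    def test_gap_expansion(self):
        aln = rt.backtranslate_alignment(("M-A", "MKA"), "ATGGCT", "ATGAAAGCA")
        assert aln.seq_a == "ATG---GCT"
        assert aln.seq_b == "ATGAAAGCA"
        ungapped = aln.drop_gap_columns()
        assert ungapped.seq_a == "ATGGCT"

    def test_translation_mismatch_reports_position(self):
        with pytest.raises(RateError, match="residue 2"):
            rt.backtranslate_alignment(("MA", "MA"), "ATGTTT", "ATGGCA")


class TestConcatenation:
    def test_additivity_over_structures(self, toy_structure):
        from structage.pipeline import _features_from_synthetic
        from structage.synthetic import SimulationConfig, generate_ortholog_pair

        feats = _features_from_synthetic(toy_structure)
        cfg = SimulationConfig(chain_length=120, seed=5)
        aln = generate_ortholog_pair(toy_structure, feats, cfg)
        groups = rt.concatenate_by_category(
            {"s1": feats, "s2": feats}, {"s1": aln, "s2": aln}, "ss_category"
        )
        n_helix = sum(f.ss_category == "helix" for f in feats)
        if n_helix:
            assert groups["helix"].n_codons == 2 * n_helix

    def test_low_identity_pair_contributes_nothing(self, toy_structure):
        from structage.pipeline import _features_from_synthetic
        from structage.synthetic import SimulationConfig, generate_ortholog_pair

        feats = _features_from_synthetic(toy_structure)
        # extreme rate -> protein identity far below 50%
        cfg = SimulationConfig(chain_length=120, base_rate=1.0, nonsyn_fraction=1.0, seed=5)
        aln = generate_ortholog_pair(toy_structure, feats, cfg)
        groups = rt.concatenate_by_category({"s": feats}, {"s": aln}, "exposure")
        assert groups == {}

    def test_rsa_bin_grouping_bounded_by_20(self, toy_structure):
        from structage.pipeline import _features_from_synthetic
        from structage.synthetic import SimulationConfig, generate_ortholog_pair

        feats = _features_from_synthetic(toy_structure)
        cfg = SimulationConfig(chain_length=120, seed=5)
        aln = generate_ortholog_pair(toy_structure, feats, cfg)
        groups = rt.concatenate_by_category({"s": feats}, {"s": aln}, "rsa_bin")
        assert len(groups) <= 20
        assert all(1 <= b <= 20 for b in groups)


class TestRateFilters:
    @pytest.mark.parametrize(
        "length,dn,ds,expected,reason",
        [
            (59, 0.1, 0.1, False, "length"),
            (100, 0.6, 0.1, False, "dN"),
            (100, 0.1, 2.5, False, "dS"),
            (100, 0.1, 1.0, True, ""),
            (60, 0.5, 2.0, True, ""),  # thresholds are exclusive
        ],
    )
    def test_filter_rules(self, length, dn, ds, expected, reason):
        est = rt.RateEstimate(dn, ds, 100, 50, 1, 1, length)
        retained, why = rt.apply_rate_filters(est, length)
        assert retained is expected and why == reason
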