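"""Generator contracts: determinism, geometry, planted statistical structure."""

import numpy as np
import pytest
from scipy import stats as sps

from structage import features as ft
from structage import homology as hm
from structage import rates as rt
from structage import synthetic as syn
from structage.homology import AgeClass
from structage.pipeline import _features_from_synthetic
from structage.synthetic import InvalidConfigError, SimulationConfig


class TestToyStructure:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(chain_length=100, seed=7)
        s1 = syn.generate_toy_structure(cfg)
        s2 = syn.generate_toy_structure(cfg)
        assert np.array_equal(s1.ca_coords(), s2.ca_coords())
        assert s1.sequence == s2.sequence
        assert np.array_equal(s1.asa, s2.asa)

    def test_consecutive_ca_distance_bounds(self):
        for seed in range(5):
            s = syn.generate_toy_structure(SimulationConfig(chain_length=150, seed=seed))
            d = np.linalg.norm(np.diff(s.ca_coords(), axis=0), axis=1)
            assert d.min() >= 3.6 and d.max() <= 4.0

    def test_chain_is_compact(self):
        """Radius of gyration grows sublinearly with chain length."""

        def rg(length, seed):
            c = syn.generate_toy_structure(
                SimulationConfig(chain_length=length, seed=seed)
            ).ca_coords()
            c = c - c.mean(axis=0)
            return np.sqrt((c**2).sum(axis=1).mean())

        rg100 = np.mean([rg(100, s) for s in range(3)])
        rg400 = np.mean([rg(400, s) for s in range(3)])
        assert rg400 / rg100 < 2.5  # linear growth would give 4

    def test_backbone_complete_and_valid(self):
        s = syn.generate_toy_structure(SimulationConfig(chain_length=60, seed=1))
        assert all(r.has_complete_backbone() for r in s.residues)
        ok, reason = ft.validate_structure(s)
        assert ok, reason

    def test_core_fraction_recovered_via_rsa(self):
        """Fraction of residues with computed RSA < 0.25 tracks core_fraction."""
        fracs = []
        for seed in range(50):
            s = syn.generate_toy_structure(
                SimulationConfig(chain_length=200, core_fraction=0.4, seed=seed)
            )
            rsa = np.array(
                [ft.compute_rsa(r.amino_acid, s.asa[i]) for i, r in enumerate(s.residues)]
            )
            fracs.append(np.mean(rsa < 0.25))
        assert abs(np.mean(fracs) - 0.4) < 0.1

    def test_core_is_buried(self):
        """Planted core residues have lower mean RSA than surface residues."""
        s = syn.generate_toy_structure(SimulationConfig(chain_length=150, seed=11))
        assert s.rsa_planted[s.core_mask].mean() < s.rsa_planted[~s.core_mask].mean()

    def test_short_chain_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(chain_length=9)


class TestOrthologPair:
    def test_zero_rate_gives_identical_sequences(self, toy_structure):
        feats = _features_from_synthetic(toy_structure)
        cfg = SimulationConfig(chain_length=120, base_rate=0.0, rsa_slope=0.0, seed=5)
        pair = syn.generate_ortholog_pair(toy_structure, feats, cfg)
        assert pair.seq_a == pair.seq_b

    def test_seq_a_backtranslates_to_structure(self, toy_structure):
        feats = _features_from_synthetic(toy_structure)
        cfg = SimulationConfig(chain_length=120, seed=5)
        pair = syn.generate_ortholog_pair(toy_structure, feats, cfg)
        prot = rt.translate_codon_indices(rt.encode_codons(pair.seq_a))
        assert prot == toy_structure.sequence

    def test_feature_mismatch_raises(self, toy_structure):
        feats = _features_from_synthetic(toy_structure)[:-1]
        with pytest.raises(InvalidConfigError):
            syn.generate_ortholog_pair(
                toy_structure, feats, SimulationConfig(chain_length=120, seed=5)
            )

    def test_planted_linear_rsa_rate_relation_recovered(self):
        """Pooling 500 replicate pairs per RSA bin recovers the linear trend."""
        cfg = SimulationConfig(chain_length=200, base_rate=0.02, rsa_slope=0.2, seed=21)
        structure = syn.generate_toy_structure(cfg)
        feats = _features_from_synthetic(structure)
        per_bin_a: dict[int, list] = {}
        per_bin_b: dict[int, list] = {}
        for rep in range(500):
            pair = syn.generate_ortholog_pair(structure, feats, cfg, seed=1000 + rep)
            ia, ib = rt.encode_codons(pair.seq_a), rt.encode_codons(pair.seq_b)
            for f in feats:
                per_bin_a.setdefault(f.rsa_bin, []).append(ia[f.position - 1])
                per_bin_b.setdefault(f.rsa_bin, []).append(ib[f.position - 1])
        mids, dns = [], []
        for b in sorted(per_bin_a):
            if len(per_bin_a[b]) < 1000:
                continue
            est = rt.estimate_from_indices(
                np.array(per_bin_a[b]), np.array(per_bin_b[b])
            )
            mids.append((b - 0.5) / 20)
            dns.append(est.dn)
        r = sps.pearsonr(mids, dns).statistic
        assert r >= 0.9


class TestHomologProfile:
    @pytest.mark.parametrize("age", list(AgeClass))
    def test_round_trip_recovers_age(self, age):
        hits, _ = syn.generate_homolog_profile(age, seed=17)
        assigned, excluded = hm.assign_age(hits)
        assert assigned == age
        assert excluded == (age == AgeClass.mammalia)
        assert all(h.e_value <= 1e-4 for h in hits)

    def test_eukarya_profile_reaches_listed_eukaryotes(self):
        hits, _ = syn.generate_homolog_profile(AgeClass.eukarya, seed=3)
        eukaryotes = {
            sp for sp, g in hm.DEFAULT_SPECIES_GROUPS.items() if g == AgeClass.eukarya
        }
        assert any(h.subject_species in eukaryotes for h in hits)

    def test_mammalia_profile_stays_in_mammals(self):
        hits, _ = syn.generate_homolog_profile(AgeClass.mammalia, seed=3)
        assert {h.subject_species for h in hits} <= {"Mus musculus", "Rattus norvegicus"}

    def test_unknown_age_class_raises(self):
        with pytest.raises(InvalidConfigError):
            syn.generate_homolog_profile("archaea", seed=0)


class TestDecoys:
    def test_shuffle_preserves_composition(self, toy_structure):
        decoys = syn.generate_decoy_set(toy_structure, 5, "shuffle_sequence", seed=1)
        for d in decoys:
            assert sorted(d.sequence) == sorted(toy_structure.sequence)
            assert np.array_equal(d.ca_coords(), toy_structure.ca_coords())

    def test_deterministic(self, toy_structure):
        d1 = syn.generate_decoy_set(toy_structure, 10, "shuffle_sequence", seed=4)
        d2 = syn.generate_decoy_set(toy_structure, 10, "shuffle_sequence", seed=4)
        assert [d.sequence for d in d1] == [d.sequence for d in d2]

    def test_zero_displacement_is_identity(self, toy_structure):
        (d,) = syn.generate_decoy_set(
            toy_structure, 1, "perturb_coordinates", seed=2, displacement_bound=0.0
        )
        assert np.array_equal(d.ca_coords(), toy_structure.ca_coords())
        assert d.sequence == toy_structure.sequence

    def test_nonpositive_count_rejected(self, toy_structure):
        with pytest.raises(InvalidConfigError):
            syn.generate_decoy_set(toy_structure, 0, "shuffle_sequence", seed=0)


class TestFileEmission:
    def test_pdb_dssp_round_trip(self, tmp_path, toy_structure):
        syn.write_pdb(toy_structure, tmp_path / "s.pdb")
        syn.write_dssp(toy_structure, tmp_path / "s.dssp")
        parsed = ft.parse_structure(tmp_path / "s.pdb")
        assert parsed.sequence == toy_structure.sequence
        assert np.allclose(parsed.ca_coords(), toy_structure.ca_coords(), atol=1e-3)
        dssp = ft.parse_dssp(tmp_path / "s.dssp")
        feats = ft.build_feature_table(parsed, dssp)
        assert len(feats) == len(toy_structure)

    def test_blast_tab_round_trip(self, tmp_path):
        hits, species_map = syn.generate_homolog_profile(AgeClass.metazoa, seed=8)
        syn.write_blast_tab(hits, tmp_path / "hits.tsv")
        back = hm.read_blast_tab(tmp_path / "hits.tsv", species_map)
        assert len(back) == len(hits)
        assert {h.subject_species for h in back} == {h.subject_species for h in hits}
        assigned, _ = hm.assign_age(back)
        assert assigned == AgeClass.metazoa

    def test_fasta_written(self, tmp_path, toy_structure):
        from Bio import SeqIO

        syn.write_fasta({"prot": toy_structure.sequence}, tmp_path / "p.fasta")
        rec = next(SeqIO.parse(str(tmp_path / "p.fasta"), "fasta"))
        assert str(rec.seq) == toy_structure.sequence
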