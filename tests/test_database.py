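import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psmlod.chem import DEFAULT_MODIFICATIONS, IonConfig, ModificationSpec, generate_ion_series
from psmlod.database import (
    PeptideIndex,
    build_index,
    digest,
    enumerate_modified_forms,
    load_index,
    make_decoy_database,
    query_by_mass,
    save_index,
)
from psmlod.simulate import SimulationConfig, generate_database

OXIDATION = ModificationSpec("oxidation", 15.994915, frozenset("M"), "variable", 2)
OXIDATION_MAX1 = ModificationSpec("oxidation", 15.994915, frozenset("M"), "variable", 1)


def brute_force_digest(seq, max_missed):
    """Oracle: enumerate all substrings that are unions of adjacent tryptic
    segments."""
    sites = [
        i + 1
        for i, ch in enumerate(seq)
        if ch in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P")
    ]
    bounds = sorted(set([0] + sites + [len(seq)]))
    out = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + max_missed + 2, len(bounds))):
            out.append(seq[bounds[a]:bounds[b]])
    return out


class TestDigest:
    def test_no_missed(self):
        assert set(digest("MKAKRPGK", 0)) == {"MK", "AK", "RPGK"}

    def test_two_missed(self):
        assert set(digest("MKAKRPGK", 2)) == {
            "MK", "AK", "RPGK", "MKAK", "AKRPGK", "MKAKRPGK",
        }
        assert len(digest("MKAKRPGK", 2)) == 6

    def test_no_sites(self):
        for mm in (0, 1, 5):
            assert digest("AAA", mm) == ["AAA"]

    def test_empty_sequence(self):
        assert digest("", 2) == []

    def test_negative_missed_rejected(self):
        with pytest.raises(ValueError):
            digest("AKAK", -1)

    @settings(max_examples=100, deadline=None)
    @given(
        st.text(alphabet="ACDGKPRS", min_size=1, max_size=30),
        st.integers(min_value=0, max_value=3),
    )
    def test_matches_brute_force(self, seq, max_missed):
        assert sorted(digest(seq, max_missed)) == sorted(brute_force_digest(seq, max_missed))


class TestModifiedForms:
    def test_single_target(self):
        forms = enumerate_modified_forms("AMK", [OXIDATION])
        assert len(forms) == 2
        masses = sorted(p.neutral_mass for p in forms)
        assert masses[1] - masses[0] == pytest.approx(15.994915, abs=1e-9)

    def test_two_targets_max_one(self):
        forms = enumerate_modified_forms("MM", [OXIDATION_MAX1])
        assert len(forms) == 3  # none, M1, M2

    def test_no_targets(self):
        assert len(enumerate_modified_forms("AAA", list(DEFAULT_MODIFICATIONS))) == 1

    def test_fixed_applied_everywhere(self):
        carb = ModificationSpec("carbamidomethyl", 57.02146, frozenset("C"), "fixed")
        forms = enumerate_modified_forms("ACCA", [carb])
        assert len(forms) == 1
        assert len(forms[0].applied_mods) == 2

    def test_cap_truncates(self):
        spec = ModificationSpec("x", 1.0, frozenset("A"), "variable", 10)
        forms = enumerate_modified_forms("A" * 12, [spec], cap=64)
        assert len(forms) == 64

    def test_unmodified_form_included(self):
        forms = enumerate_modified_forms("AMK", [OXIDATION])
        assert any(not p.applied_mods for p in forms)


class TestQueryByMass:
    def test_empty_index(self):
        assert query_by_mass(PeptideIndex([]), 500.0, 1.0) == []

    def test_interval(self):
        peps = [
            enumerate_modified_forms(s, ())[0]
            for s in ("GGG", "GGGG", "GGGGGG")
        ]
        index = PeptideIndex(peps)
        masses = [p.neutral_mass for p in index.records]
        hits = query_by_mass(index, masses[0] + 30.0, 60.0)
        expected = [p for p in index.records if abs(p.neutral_mass - (masses[0] + 30.0)) <= 60.0]
        assert hits == expected

    def test_out_of_range(self):
        index = PeptideIndex([enumerate_modified_forms("GGG", ())[0]])
        assert query_by_mass(index, 5000.0, 0.1) == []

    def test_negative_tolerance_rejected(self):
        index = PeptideIndex([])
        with pytest.raises(ValueError):
            query_by_mass(index, 100.0, -1.0)

    def test_agrees_with_linear_scan(self, small_proteome):
        _cfg, _fasta, index = small_proteome
        rng = np.random.default_rng(0)
        masses = index.masses
        for _ in range(1000):
            q = float(rng.uniform(masses.min() - 50, masses.max() + 50))
            tol = float(rng.uniform(0, 20))
            fast = query_by_mass(index, q, tol)
            slow = [p for p in index.records if abs(p.neutral_mass - q) <= tol]
            assert fast == slow


class TestDecoy:
    def test_reversed_protein_digest(self):
        fasta = ">p1\nMKAR\n"
        decoy = make_decoy_database(fasta, (), max_missed=0, min_length=1, max_length=60)
        assert sorted(p.sequence for p in decoy.records) == ["AK", "M", "R"]
        assert all(p.is_decoy for p in decoy.records)
        assert all(p.protein_id == "rev_p1" for p in decoy.records)

    def test_palindromic_protein(self):
        fasta = ">p1\nGAKAG\n"
        target = build_index(fasta, (), max_missed=0, min_length=1)
        decoy = make_decoy_database(fasta, (), max_missed=0, min_length=1)
        assert sorted(p.sequence for p in target.records) == sorted(
            p.sequence for p in decoy.records
        )

    def test_size_within_ten_percent_of_target(self):
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_proteins=15, protein_length_range=(60, 120))
            fasta, target = generate_database(cfg, max_missed=1)
            decoy = make_decoy_database(fasta, (), max_missed=1)
            assert abs(len(decoy) - len(target)) <= 0.1 * len(target)


class TestSerialization:
    def test_round_trip_bitwise(self, tmp_path, small_proteome):
        _cfg, fasta, _index = small_proteome
        index = build_index(fasta, DEFAULT_MODIFICATIONS, max_missed=1,
                            min_length=5, max_length=30)
        path = tmp_path / "peptides.index"
        save_index(index, path)
        loaded = load_index(path)
        assert len(loaded) == len(index)
        for a, b in zip(index.records, loaded.records):
            assert a == b  # dataclass equality: bitwise-equal floats
        assert loaded.metadata == index.metadata

    def test_rejects_wrong_format(self, tmp_path):
        path = tmp_path / "bogus"
        path.write_text('{"format": "something-else"}\n')
        with pytest.raises(ValueError):
            load_index(path)


class TestPrecomputedAttributes:
    def test_y_series_matches_ion_generator(self, small_proteome):
        _cfg, _fasta, index = small_proteome
        config = IonConfig(ion_types=("y",), include_y2=False)
        for pep in index.records[:50]:
            ions = generate_ion_series(pep.sequence, pep.applied_mods, config)
            expected = [i.mz for i in sorted(ions, key=lambda i: i.index)]
            assert len(pep.y_series) == len(pep.sequence) - 1
            np.testing.assert_allclose(pep.y_series, expected, atol=1e-6)

    def test_mass_invariant(self, small_proteome):
        from psmlod.chem import peptide_mass

        _cfg, _fasta, index = small_proteome
        for pep in index.records[:50]:
            assert pep.neutral_mass == pytest.approx(
                peptide_mass(pep.sequence, pep.applied_mods), abs=1e-6
            )

    def test_records_sorted_by_mass(self, small_proteome):
        _cfg, _fasta, index = small_proteome
        assert np.all(np.diff(index.masses) >= 0)
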