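import math

import numpy as np
import pytest

from psmlod.chem import PROTON, WATER, AminoAcidTable, IonConfig, TheoreticalIon
from psmlod.lod import (
    FragmentMatch,
    MatchProbabilityModel,
    fragment_lod_metric1,
    fragment_lod_metric2,
    fragment_lod_metric3,
    fragment_lod_metric4,
    mass_bin,
    match_fragments,
    peptide_lod,
    random_match_probability,
    z_score,
)
from psmlod.spectra import Spectrum

from .conftest import make_peptide


def fake_match(expected_mz=500.0, error=0.25, intensity=10.0):
    ion = TheoreticalIon("y", 3, 1, 0, 0, expected_mz, "XYZ")
    return FragmentMatch(ion, expected_mz + error, intensity, error)


class TestMassBin:
    def test_upper_inclusive(self):
        assert mass_bin(200.0, 200.0) == 200.0
        assert mass_bin(200.0001, 200.0) == 400.0
        assert mass_bin(150.0, 200.0) == 200.0

    def test_first_bin_catches_everything_below(self):
        assert mass_bin(3.0, 200.0) == 200.0


class TestMatchFragments:
    def test_empty_spectrum(self):
        pep = make_peptide("PEPTIDEK")
        s = Spectrum.from_peaks(900.0, 1, [5000.0], [1.0])
        assert match_fragments(s, pep, 0.5) == []

    def test_tie_broken_by_lower_theoretical_mz(self):
        # custom residue table making two ions land at exactly 100 and 104 Th
        table = AminoAcidTable(
            residue_mass={"G": 100.0 - PROTON, "A": 104.0 - WATER - PROTON},
            hydrophobicity_rank={"G": 0.0, "A": 1.0},
            pka={"n_term": 8.6, "c_term": 3.6},
        )
        pep = make_peptide("GA", table=table)
        ions = {
            i.ion_type: i.mz
            for i in __import__("psmlod.chem", fromlist=["generate_ion_series"])
            .generate_ion_series("GA", (), IonConfig(ion_types=("y", "b")), 1, table)
        }
        assert ions["b"] == pytest.approx(100.0, abs=1e-12)
        assert ions["y"] == pytest.approx(104.0, abs=1e-12)
        s = Spectrum.from_peaks(300.0, 1, [102.0], [5.0])
        matches = match_fragments(s, pep, 2.5, IonConfig(ion_types=("y", "b")), 1, table)
        assert len(matches) == 1
        assert matches[0].ion.ion_type == "b"  # lower theoretical m/z wins

    def test_one_to_one_assignment(self):
        pep = make_peptide("PEPTIDEK")
        y0 = pep.y_series[0]
        s = Spectrum.from_peaks(900.0, 1, [y0 - 0.1, y0 + 0.05], [1.0, 2.0])
        matches = match_fragments(s, pep, 0.5, IonConfig(ion_types=("y",)))
        by_label = [m for m in matches if m.ion.label == "y1"]
        assert len(by_label) == 1
        assert by_label[0].mass_error == pytest.approx(0.05, abs=1e-9)

    def test_noiseless_spectrum_all_matched_error_zero(self, noiseless_sims):
        config = IonConfig(ion_types=("y", "b"), include_y2=False)
        for sim in noiseless_sims[:5]:
            matches = match_fragments(sim.spectrum, sim.peptide, 0.5, config, 1)
            n = len(sim.peptide.sequence)
            assert len(matches) == 2 * (n - 1)
            assert all(m.mass_error == 0.0 for m in matches)

    def test_deterministic(self, noiseless_sims):
        sim = noiseless_sims[0]
        a = match_fragments(sim.spectrum, sim.peptide, 0.5)
        b = match_fragments(sim.spectrum, sim.peptide, 0.5)
        assert [(m.ion, m.observed_mz, m.mass_error) for m in a] == [
            (m.ion, m.observed_mz, m.mass_error) for m in b
        ]


class TestMetric1:
    def test_worked_example(self):
        lod = fragment_lod_metric1(fake_match(error=0.25), density=0.1)
        assert lod == pytest.approx(math.log(0.5 / 0.05), abs=1e-12)
        assert round(lod, 1) == 2.3

    def test_equal_odds_zero(self):
        # p_random = 2 * 2.5 * 0.1 = 0.5
        assert fragment_lod_metric1(fake_match(error=2.5), density=0.1) == pytest.approx(0.0)

    def test_closed_form(self):
        lod = fragment_lod_metric1(fake_match(error=0.5), density=0.2)
        assert lod == pytest.approx(math.log(2.5), abs=1e-12)

    def test_floors_prevent_infinity(self):
        lod = fragment_lod_metric1(fake_match(error=0.0), density=1e-9)
        assert math.isfinite(lod)
        assert random_match_probability(0.0, 1e-9) == 1e-4

    def test_monte_carlo_oracle(self):
        """Uniformly placed peaks hit a +/-err window at the rate the
        closed form predicts."""
        rng = np.random.default_rng(42)
        n, lo, hi = 10_000, 150.0, 1150.0
        err, target = 0.25, 650.0
        peaks = rng.uniform(lo, hi, size=n)
        hits = int((np.abs(peaks - target) <= err).sum())
        density = n / (hi - lo)
        expected = 2 * err * density  # expected count in the window
        q = 2 * err / (hi - lo)
        se = math.sqrt(n * q * (1 - q))
        assert abs(hits - expected) <= 3 * se


class TestMetric2:
    def _model(self, value):
        return MatchProbabilityModel(
            correct_table={"1": {mass_bin(m, 200.0): value for m in np.arange(100, 2000, 200)}}
        )

    def test_illustrative_value(self):
        model = self._model(0.4)
        lod = fragment_lod_metric2(fake_match(expected_mz=300.0, error=0.25), model, 0.1)
        assert lod == pytest.approx(math.log(0.4 / 0.05), abs=1e-12)

    def test_reduces_to_metric1_with_half_table(self):
        model = self._model(0.5)
        rng = np.random.default_rng(3)
        for _ in range(200):
            m = fake_match(expected_mz=float(rng.uniform(100, 1900)),
                           error=float(rng.uniform(-0.5, 0.5)))
            d = float(rng.uniform(0.01, 0.5))
            assert fragment_lod_metric2(m, model, d) == pytest.approx(
                fragment_lod_metric1(m, d), abs=1e-12
            )

    def test_high_mass_value(self):
        model = self._model(0.8)
        lod = fragment_lod_metric2(fake_match(expected_mz=1500.0, error=0.25), model, 0.1)
        assert lod == pytest.approx(math.log(16.0), abs=1e-12)

    def test_missing_bin_falls_back_to_nearest(self):
        model = MatchProbabilityModel(correct_table={"1": {400.0: 0.4}})
        lod = fragment_lod_metric2(fake_match(expected_mz=1500.0, error=0.25), model, 0.1)
        assert lod == pytest.approx(math.log(0.4 / 0.05), abs=1e-12)

    def test_3plus_uses_average(self):
        model = MatchProbabilityModel(
            correct_table={"1": {200.0: 0.2, 400.0: 0.4}, "2": {200.0: 0.6}}
        )
        assert model.p_correct(300.0, 3) == pytest.approx((0.2 + 0.4 + 0.6) / 3)


class TestMetric3:
    def _model(self):
        return MatchProbabilityModel(
            correct_table={"1": {200.0: 0.4, 400.0: 0.8}},
            random_table={"1": {200.0: 0.3, 400.0: 0.1}},
        )

    def test_arithmetic_example(self):
        model = self._model()
        lod_low = fragment_lod_metric3(fake_match(expected_mz=150.0), model)
        lod_high = fragment_lod_metric3(fake_match(expected_mz=350.0), model)
        assert lod_low == pytest.approx(math.log((1 / 3) / 0.75), abs=1e-9)
        assert lod_high == pytest.approx(math.log((2 / 3) / 0.25), abs=1e-9)

    def test_identical_distributions_zero(self):
        model = MatchProbabilityModel(
            correct_table={"1": {200.0: 0.5, 400.0: 0.7}},
            random_table={"1": {200.0: 0.5, 400.0: 0.7}},
        )
        for mz in (100.0, 300.0):
            assert fragment_lod_metric3(fake_match(expected_mz=mz), model) == pytest.approx(0.0)

    def test_scale_invariance(self):
        a = self._model()
        b = MatchProbabilityModel(
            correct_table={"1": {k: 7 * v for k, v in a.correct_table["1"].items()}},
            random_table={"1": {k: 0.2 * v for k, v in a.random_table["1"].items()}},
        )
        for mz in (150.0, 350.0):
            assert fragment_lod_metric3(fake_match(expected_mz=mz), b) == pytest.approx(
                fragment_lod_metric3(fake_match(expected_mz=mz), a), abs=1e-12
            )


class TestMetric4:
    def _model(self, mu=0.02, sigma=0.05):
        return MatchProbabilityModel(
            correct_table={"1": {200.0: 0.4, 600.0: 0.8}},
            random_table={"1": {200.0: 0.3, 600.0: 0.1}},
            error_pdfs={mass_bin(500.0, 100.0): (mu, sigma)},
        )

    def test_at_mean_equals_metric3(self):
        model = self._model(mu=0.02)
        m = fake_match(expected_mz=500.0, error=0.02)
        assert fragment_lod_metric4(m, model) == pytest.approx(
            fragment_lod_metric3(m, model), abs=1e-12
        )

    def test_one_sigma_penalty(self):
        model = self._model(mu=0.02, sigma=0.05)
        m = fake_match(expected_mz=500.0, error=0.07)
        assert fragment_lod_metric4(m, model) == pytest.approx(
            fragment_lod_metric3(m, model) - 0.5, abs=1e-9
        )

    def test_two_sigma_penalty(self):
        model = self._model(mu=0.02, sigma=0.05)
        m = fake_match(expected_mz=500.0, error=0.12)
        assert fragment_lod_metric4(m, model) == pytest.approx(
            fragment_lod_metric3(m, model) - 2.0, abs=1e-9
        )

    def test_sigma_floored(self):
        model = self._model(mu=0.0, sigma=1e-6)
        m = fake_match(expected_mz=500.0, error=0.01)
        # with the 0.01 floor the penalty is (0.01/0.01)^2 / 2 = 0.5
        assert fragment_lod_metric4(m, model) == pytest.approx(
            fragment_lod_metric3(m, model) - 0.5, abs=1e-9
        )


class TestPeptideLod:
    def test_empty(self):
        assert peptide_lod([]) == 0.0

    def test_sum(self):
        matches = [fake_match() for _ in range(3)]
        for m, v in zip(matches, (2.3, 0.9, -0.5)):
            m.fragment_lod = v
        assert peptide_lod(matches) == pytest.approx(2.7, abs=1e-12)

    def test_single(self):
        m = fake_match()
        m.fragment_lod = 1.234
        assert peptide_lod([m]) == 1.234


class TestZScore:
    def test_at_decoy_mean(self):
        decoys = list(np.random.default_rng(0).normal(5.0, 2.0, size=30))
        assert z_score(float(np.mean(decoys)), decoys) == pytest.approx(0.0, abs=1e-9)

    def test_sample_sd(self):
        assert z_score(3.0, [0.0, 2.0], min_decoys=2) == pytest.approx(
            2.0 / math.sqrt(2.0), abs=1e-6
        )

    def test_missing_below_min_decoys(self):
        assert z_score(3.0, [0.0, 1.0, 2.0, 3.0, 4.0], min_decoys=20) is None

    def test_sd_floor(self):
        z = z_score(1.0, [0.5] * 25)
        assert z is not None and math.isfinite(z)
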