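"""Digestion, label-free quantities, IBAQ, and reporter-ion correction."""

import numpy as np
import pandas as pd
import pytest

from quantcore.protein_inference import ProteinGroup
from quantcore.quantify import (
    IsotopeCorrectionMatrix,
    compute_ibaq,
    correct_reporter_intensities,
    digest_count,
    load_isotope_matrix,
    normalize_reporters,
    protein_intensity,
    spectral_counts,
    tryptic_peptides,
)

from conftest import regex_digest_count


class TestDigestion:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("AAAAAA", 1),  # whole chain in range, no cleavage site
            ("AAAKAAAR", 0),  # both peptides length 4 < 6
            ("AAAKPAAAAR", 1),  # KP suppresses cleavage
        ],
    )
    def test_known_cases(self, seq, expected):
        assert digest_count(seq) == expected

    def test_empty_sequence_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert digest_count("") == 0

    def test_invalid_residues_rejected(self):
        with pytest.raises(ValueError):
            tryptic_peptides("AAA1AAA")

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWYX"))
        for _ in range(200):
            n = int(rng.integers(1, 400))
            seq = "".join(rng.choice(alphabet, size=n))
            assert digest_count(seq) == regex_digest_count(seq)


def _groups_two_proteins():
    return [
        ProteinGroup(
            accessions=("P1",), score=0.1,
            peptides=frozenset({"AAAAAAK", "CCCCCCK", "SHAREDK"}),
            unique_peptide_count=2,
        ),
        ProteinGroup(
            accessions=("P2",), score=0.1,
            peptides=frozenset({"DDDDDDK", "SHAREDK"}),
            unique_peptide_count=1,
        ),
    ]


class TestSpectralCounts:
    def test_counts_unique_peptide_psms(self):
        from quantcore.id_scoring import PsmRecord

        psms = [
            PsmRecord("r1", f"s{i}", pep, 2, pep=0.01, accessions=("P1",))
            for i, pep in enumerate(["AAAAAAK", "AAAAAAK", "CCCCCCK"])
        ]
        counts = spectral_counts(psms, _groups_two_proteins())
        assert counts[(("P1",), "r1")] == 3

    def test_shared_peptide_contributes_nowhere(self):
        from quantcore.id_scoring import PsmRecord

        psms = [PsmRecord("r1", "s1", "SHAREDK", 2, pep=0.01, accessions=("P1", "P2"))]
        assert spectral_counts(psms, _groups_two_proteins()) == {}

    def test_empty_psms(self):
        assert spectral_counts([], _groups_two_proteins()) == {}


class TestProteinIntensity:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["peptide", "charge", "run", "channel", "intensity"]
        )

    def test_unique_peptides_summed(self):
        table = self._table(
            [("AAAAAAK", 2, "r1", "LF", 100.0), ("CCCCCCK", 2, "r1", "LF", 200.0)]
        )
        out = protein_intensity(table, _groups_two_proteins())
        assert out.loc[out["accession"] == "P1", "intensity"].iloc[0] == 300.0

    def test_all_missing_stays_missing(self):
        table = self._table([("AAAAAAK", 2, "r1", "LF", np.nan)])
        out = protein_intensity(table, _groups_two_proteins())
        assert np.isnan(out["intensity"].iloc[0])

    def test_fractions_of_one_sample_summed(self):
        table = self._table(
            [("AAAAAAK", 2, "r1_f1", "LF", 100.0), ("AAAAAAK", 2, "r1_f2", "LF", 50.0)]
        )
        out = protein_intensity(
            table, _groups_two_proteins(), run_to_sample={"r1_f1": "s1", "r1_f2": "s1"}
        )
        assert len(out) == 1
        assert out["intensity"].iloc[0] == 150.0

    def test_negative_intensity_rejected(self):
        table = self._table([("AAAAAAK", 2, "r1", "LF", -5.0)])
        with pytest.raises(ValueError, match="negative"):
            protein_intensity(table, _groups_two_proteins())


class TestIbaq:
    def test_definition_and_missing_convention(self):
        quant = pd.DataFrame(
            {
                "group": ["P1"],
                "accession": ["P1"],
                "sample": ["s1"],
                "intensity": [1000.0],
            }
        )
        fasta = {"P1": "AAAAAAK" * 10}  # 10 observable peptides
        out = compute_ibaq(quant, fasta)
        assert out["ibaq"].iloc[0] == pytest.approx(100.0)

    def test_zero_digest_count_gives_missing(self):
        quant = pd.DataFrame(
            {"group": ["P1"], "accession": ["P1"], "sample": ["s1"], "intensity": [10.0]}
        )
        out = compute_ibaq(quant, {"P1": "AAAK"})  # only a too-short peptide
        assert np.isnan(out["ibaq"].iloc[0])

    def test_ribaq_normalizes_per_sample(self):
        quant = pd.DataFrame(
            {
                "group": ["P1", "P2"],
                "accession": ["P1", "P2"],
                "sample": ["s1", "s1"],
                "intensity": [100.0 * 8, 300.0 * 8],
            }
        )
        fasta = {"P1": "AAAAAAK" * 8, "P2": "CCCCCCK" * 8}
        out = compute_ibaq(quant, fasta, ribaq=True)
        assert out["ribaq"].tolist() == pytest.approx([0.25, 0.75])

    def test_missing_accession_listed(self):
        quant = pd.DataFrame(
            {"group": ["PX"], "accession": ["PX"], "sample": ["s1"], "intensity": [1.0]}
        )
        with pytest.raises(LookupError, match="PX"):
            compute_ibaq(quant, {"P1": "AAAAAAK"})


class TestReporterCorrection:
    def test_identity_matrix_is_fixed_point(self):
        obs = np.array([5.0, 7.0, 9.0])
        out = correct_reporter_intensities(obs, np.eye(3))
        np.testing.assert_allclose(out, obs)

    def test_two_channel_solve(self):
        m = np.array([[0.9, 0.1], [0.1, 0.9]])
        out = correct_reporter_intensities([90.0, 10.0], m)
        np.testing.assert_allclose(out, [100.0, 0.0], atol=1e-10)
        # forward consistency: M @ [100, 0] reproduces the observation
        np.testing.assert_allclose(m @ [100.0, 0.0], [90.0, 10.0])

    def test_negative_solution_clipped(self):
        m = np.array([[0.9, 0.1], [0.1, 0.9]])
        out = correct_reporter_intensities([0.0, 10.0], m)
        np.testing.assert_allclose(out, [0.0, 11.25])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="plex size"):
            correct_reporter_intensities([1.0, 2.0, 3.0], np.eye(2))

    def test_ill_conditioned_rejected(self):
        m = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-12]])
        with pytest.raises(np.linalg.LinAlgError):
            correct_reporter_intensities([1.0, 1.0], m)

    def test_matrix_invariants_validated(self):
        with pytest.raises(ValueError, match="diagonal"):
            IsotopeCorrectionMatrix(("a", "b"), np.array([[0.1, 0.9], [0.9, 0.1]]))
        with pytest.raises(ValueError, match="negative"):
            IsotopeCorrectionMatrix(("a", "b"), np.array([[0.9, -0.1], [0.1, 0.9]]))

    def test_load_matrix_from_tsv(self):
        text = "\tTMT126\tTMT127\nTMT126\t0.95\t0.05\nTMT127\t0.05\t0.95\n"
        m = load_isotope_matrix(text)
        assert m.channels == ("TMT126", "TMT127")
        np.testing.assert_allclose(m.values.sum(axis=0), [1.0, 1.0])

    def test_forward_consistency_random_matrices(self, rng):
        """Recover non-negative truth x from M @ x for random diagonally
        dominant impurity matrices (clipping inactive)."""
        for _ in range(50):
            k = int(rng.integers(2, 12))
            off = rng.random((k, k)) * (0.1 / k)
            m = off + np.diag(0.8 + rng.random(k) * 0.15)
            m /= np.maximum(m.sum(axis=0), 1.0)
            x = rng.random(k) * 1000
            rec = correct_reporter_intensities(m @ x, m)
            np.testing.assert_allclose(rec, x, rtol=1e-8)


class TestReporterNormalization:
    def test_factors_scale_to_lowest_median(self):
        mat = pd.DataFrame({"c1": [50.0, 100.0, 150.0], "c2": [100.0, 200.0, 300.0]})
        normed, factors = normalize_reporters(mat)
        assert factors.tolist() == pytest.approx([1.0, 0.5])
        med = normed.median()
        assert med["c1"] == pytest.approx(med["c2"], rel=1e-9)

    def test_single_channel_unchanged(self):
        mat = pd.DataFrame({"c1": [1.0, 2.0]})
        normed, factors = normalize_reporters(mat)
        assert factors.tolist() == [1.0]
        pd.testing.assert_frame_equal(normed, mat)

    def test_identical_channels_all_unit_factors(self):
        mat = pd.DataFrame({"c1": [1.0, 2.0], "c2": [1.0, 2.0]})
        _, factors = normalize_reporters(mat)
        assert factors.tolist() == [1.0, 1.0]

    def test_all_missing_channel_warns_factor_one(self):
        mat = pd.DataFrame({"c1": [1.0, 2.0], "c2": [np.nan, np.nan]})
        with pytest.warns(UserWarning, match="c2"):
            _, factors = normalize_reporters(mat)
        assert factors["c2"] == 1.0
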