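"""Sequence parsing, in silico digestion and precursor mass arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipscout import cps1
from lipscout.constants import PROTON_MASS, WATER_MONO
from lipscout.digest import (
    ENZYMES,
    TRYPSIN,
    TRYPSIN_LYSC,
    TrypticStatus,
    annotate_tryptic_status,
    digest,
    peptide_from_span,
)
from lipscout.mass import mz_to_mass, precursor_mz, sequence_mass
from lipscout.proteins import FastaParseError, ProteinRecord, read_fasta, write_fasta

from .conftest import random_protein
from .oracles import brute_force_digest, tryptic_status_oracle

aa_text = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60)


class TestFasta:
    def test_two_entry_roundtrip(self, tmp_path):
        records = [
            ProteinRecord("P1", "MKTAYIAK", "first"),
            ProteinRecord("P2", "GG" * 50),
        ]
        path = tmp_path / "two.fasta"
        write_fasta(records, path, width=30)
        back = read_fasta(path)
        assert [r.id for r in back] == ["P1", "P2"]
        assert [r.length for r in back] == [8, 100]
        assert [r.sequence for r in back] == [r.sequence for r in records]

    def test_non_canonical_residue_rejected_with_line(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">P1 ok\nMKTA\n>P2 bad\nMKBA\n")
        with pytest.raises(FastaParseError, match="line 4"):
            read_fasta(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "nope.fasta")

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            ProteinRecord("X", "MKZ")
        with pytest.raises(ValueError):
            ProteinRecord("X", "")


class TestDigest:
    @pytest.mark.parametrize(
        "sequence,expected",
        [
            ("AKAK", [(1, 2, "AK"), (3, 4, "AK")]),
            # K2 precedes P, so trypsin does not cut there
            ("AKPAK", [(1, 5, "AKPAK")]),
            ("R", [(1, 1, "R")]),
        ],
    )
    def test_zero_missed_examples(self, sequence, expected):
        protein = ProteinRecord("T", sequence)
        peps = digest(protein, TRYPSIN, max_missed=0)
        assert [(p.start, p.end, p.sequence) for p in peps] == expected

    def test_lysc_cuts_before_proline(self):
        protein = ProteinRecord("T", "AKPAK")
        peps = digest(protein, TRYPSIN_LYSC, max_missed=0)
        assert [(p.start, p.end) for p in peps] == [(1, 2), (3, 5)]

    def test_missed_cleavage_counts(self):
        protein = ProteinRecord("T", "AKCKDK")
        peps = digest(protein, TRYPSIN, max_missed=2)
        by_span = {(p.start, p.end): p.missed_cleavages for p in peps}
        assert by_span == {
            (1, 2): 0, (3, 4): 0, (5, 6): 0,
            (1, 4): 1, (3, 6): 1, (1, 6): 2,
        }

    def test_zero_missed_tiling(self, rng):
        for _ in range(20):
            protein = random_protein(rng, int(rng.integers(50, 250)))
            peps = digest(protein, TRYPSIN, max_missed=0)
            covered = []
            for p in peps:
                covered.extend(range(p.start, p.end + 1))
            assert covered == list(range(1, protein.length + 1))

    @pytest.mark.parametrize("enzyme_name", ["trypsin", "trypsin/lysc"])
    @pytest.mark.parametrize("max_missed", [0, 2])
    def test_matches_brute_force_enumeration(self, rng, enzyme_name, max_missed):
        enzyme = ENZYMES[enzyme_name]
        lysc = enzyme_name == "trypsin/lysc"
        for _ in range(50):
            protein = random_protein(rng, 200)
            got = {(p.start, p.end)
                   for p in digest(protein, enzyme, max_missed=max_missed)}
            expected = brute_force_digest(protein.sequence, max_missed, lysc)
            assert got == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ProteinRecord("T", "")


class TestTrypticStatus:
    def test_examples(self):
        protein = ProteinRecord("T", "AKAK")
        fully = peptide_from_span(protein, 1, 2)
        assert fully.tryptic_status is TrypticStatus.FULLY_TRYPTIC
        semi = peptide_from_span(protein, 2, 4)  # preceded by A
        assert semi.sequence == "KAK"
        assert semi.tryptic_status is TrypticStatus.SEMI_TRYPTIC
        non = peptide_from_span(ProteinRecord("T", "AAKAA"), 2, 4)
        assert non.tryptic_status is TrypticStatus.NON_TRYPTIC

    def test_out_of_range_errors(self):
        protein = ProteinRecord("T", "AKAK")
        with pytest.raises(IndexError):
            peptide_from_span(protein, 1, 9)

    def test_exhaustive_against_predicate_oracle(self, rng):
        for _ in range(50):
            protein = random_protein(rng, 30)
            for start in range(1, 31):
                for end in range(start, 31):
                    pep = peptide_from_span(protein, start, end)
                    assert pep.tryptic_status.value == tryptic_status_oracle(
                        protein.sequence, start, end)


class TestMass:
    def test_gg_singly_protonated(self):
        pep = peptide_from_span(ProteinRecord("T", "GG"), 1, 2)
        prec = precursor_mz(pep, charge=1)
        assert prec.mz == pytest.approx(133.0608, abs=5e-4)

    def test_charge_state_mass_identity(self, rng):
        # reconstructing the neutral mass from m/z is charge-independent
        for _ in range(20):
            protein = random_protein(rng, int(rng.integers(5, 30)))
            pep = peptide_from_span(protein, 1, protein.length)
            for z in (1, 2, 3):
                m1 = mz_to_mass(precursor_mz(pep, z).mz, z)
                m2 = mz_to_mass(precursor_mz(pep, z + 1).mz, z + 1)
                assert abs(m1 - m2) < 1e-9

    @given(seq=aa_text, extra=st.sampled_from(list("ACDEFGHIKLMNPQRSTVWY")))
    @settings(max_examples=100, derandomize=True)
    def test_mass_strictly_increases_with_length(self, seq, extra):
        assert sequence_mass(seq + extra) > sequence_mass(seq)

    @given(seq=aa_text)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_agrees_with_pyteomics(self, seq):
        """Cross-check the pinned mass table against an independent library."""
        from pyteomics import mass as pmass

        ours = sequence_mass(seq, fixed_mods={})
        theirs = pmass.calculate_mass(sequence=seq)
        assert ours == pytest.approx(theirs, abs=2e-4)

    def test_carbamidomethyl_applied_per_cysteine(self):
        bare = sequence_mass("ACCA", fixed_mods={})
        fixed = sequence_mass("ACCA")
        assert fixed - bare == pytest.approx(2 * 57.02146, abs=1e-9)

    def test_invalid_charge(self):
        pep = peptide_from_span(ProteinRecord("T", "GG"), 1, 2)
        with pytest.raises(ValueError):
            precursor_mz(pep, charge=0)


class TestReferenceProtein:
    """The reconstructed CPS1 record reproduces the published coordinates."""

    def test_length(self, cps1_record):
        assert cps1_record.length == 1462

    def test_protected_peptides_fully_tryptic_zero_missed(self, cps1_record):
        for start, end in cps1.PROTECTED_SPANS:
            pep = peptide_from_span(cps1_record, start, end)
            assert pep.tryptic_status is TrypticStatus.FULLY_TRYPTIC
            assert pep.missed_cleavages == 0

    def test_first_protected_peptide_q1(self, cps1_record):
        pep = peptide_from_span(cps1_record, 275, 286)
        assert precursor_mz(pep, charge=2).mz == pytest.approx(663.36, abs=0.02)
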