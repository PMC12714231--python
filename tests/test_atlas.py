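"""Peptide placement, monoisotopic masses, cleavage sites, coverage atlas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from eecquant.atlas import (
    AMINO_ACIDS,
    MODIFICATION_MASS,
    PeptideHit,
    Precursor,
    build_atlas,
    find_dibasic_sites,
    locate_peptide,
    peptide_mass,
    ppm_match,
)


class TestLocatePeptide:
    def test_simple_substring(self):
        pre = Precursor("p", "MGSSFLSPSQR")
        assert locate_peptide("GSSFL", pre) == [{"start": 2, "end": 6, "variant": None}]

    def test_single_variant_substitution(self):
        pre = Precursor("p", "MGSR", variants=[(3, "S", "T")])
        hits = locate_peptide("GTR", pre)
        assert hits == [{"start": 2, "end": 4, "variant": (3, "S", "T")}]

    def test_overlapping_occurrences_reported(self):
        pre = Precursor("p", "AAA")
        hits = locate_peptide("AA", pre)
        assert [(h["start"], h["end"]) for h in hits] == [(1, 2), (2, 3)]

    def test_matches_exhaustive_substring_oracle(self, rng):
        letters = np.array(list(AMINO_ACIDS))
        for _ in range(20):
            seq = "".join(rng.choice(letters, size=30))
            pre = Precursor("p", seq)
            k = int(rng.integers(2, 6))
            start = int(rng.integers(0, 30 - k))
            pep = seq[start : start + k]
            oracle = [
                (i + 1, i + k)
                for i in range(len(seq) - k + 1)
                if seq[i : i + k] == pep
            ]
            assert [(h["start"], h["end"]) for h in locate_peptide(pep, pre)] == oracle

    def test_extraction_returns_peptide_or_variant_image(self, ghrelin_like_precursor):
        pre = ghrelin_like_precursor
        for pep in ["GSSLL", "SSFLSPSQ", "EDKVESF"]:  # GSSLL needs variant F25L
            for hit in locate_peptide(pep, pre):
                s, e = hit["start"], hit["end"]
                observed = pre.sequence[s - 1 : e]
                if hit["variant"] is None:
                    assert observed == pep
                else:
                    pos, ref, alt = hit["variant"]
                    mutated = observed[: pos - s] + alt + observed[pos - s + 1 :]
                    assert mutated == pep

    def test_no_occurrence_empty(self):
        assert locate_peptide("WWW", Precursor("p", "MGSSFLSPSQR")) == []

    def test_variant_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            Precursor("p", "MGSR", variants=[(3, "A", "T")])


class TestPeptideMass:
    def test_glycine_equals_elemental_composition(self):
        # C2H5NO2, summed from atomic monoisotopic masses
        expected = 2 * 12.0 + 5 * 1.0078250319 + 14.0030740052 + 2 * 15.9949146221
        assert peptide_mass("G") == pytest.approx(expected, abs=1e-9)

    def test_exactly_one_water_regardless_of_length(self):
        g1 = peptide_mass("G")
        g2 = peptide_mass("GG")
        water = 2 * 1.0078250319 + 15.9949146221
        assert g2 == pytest.approx(2 * (g1 - water) + water, abs=1e-9)

    def test_concatenation_additivity(self, rng):
        letters = np.array(list(AMINO_ACIDS))
        water = peptide_mass("G") - (peptide_mass("GG") - peptide_mass("G"))
        for _ in range(10):
            p = "".join(rng.choice(letters, size=int(rng.integers(1, 10))))
            q = "".join(rng.choice(letters, size=int(rng.integers(1, 10))))
            assert peptide_mass(p + q) == pytest.approx(
                peptide_mass(p) + peptide_mass(q) - water, abs=1e-9
            )

    def test_amidation_matches_nh2_for_oh_substitution(self):
        delta = peptide_mass("AGLK", [(4, "amidation", None)]) - peptide_mass("AGLK")
        # replacing the C-terminal OH by NH2: -O +NH
        expected = (14.0030740052 + 1.0078250319) - 15.9949146221
        assert delta == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("name", sorted(MODIFICATION_MASS))
    def test_supported_mods_against_pyteomics_oracle(self, name):
        """Each modification delta agrees with elemental-composition sums."""
        comps = {
            "carbamidomethyl": {"C": 2, "H": 3, "N": 1, "O": 1},
            "oxidation": {"O": 1},
            "amidation": {"N": 1, "H": 1, "O": -1},
            "acetyl": {"C": 2, "H": 2, "O": 1},
            "pyroglutamate-from-Q": {"N": -1, "H": -3},
            "pyroglutamate-from-E": {"H": -2, "O": -1},
            "octanoyl": {"C": 8, "H": 14, "O": 1},
            "decanoyl": {"C": 10, "H": 18, "O": 1},
        }
        expected = sum(
            n * pyteomics_mass.calculate_mass(formula=el)
            for el, n in comps[name].items()
        )
        assert MODIFICATION_MASS[name] == pytest.approx(expected, abs=1e-5)

    def test_random_modified_peptides_against_pyteomics(self, rng):
        """200 random peptides with random mods match the elemental oracle."""
        letters = np.array(list(AMINO_ACIDS))
        mod_names = sorted(MODIFICATION_MASS)
        for _ in range(200):
            seq = "".join(rng.choice(letters, size=int(rng.integers(1, 31))))
            mods = []
            for _ in range(int(rng.integers(0, 3))):
                pos = int(rng.integers(1, len(seq) + 1))
                mods.append((pos, mod_names[int(rng.integers(len(mod_names)))], None))
            expected = pyteomics_mass.calculate_mass(sequence=seq) + sum(
                MODIFICATION_MASS[m[1]] for m in mods
            )
            assert peptide_mass(seq, mods) == pytest.approx(expected, abs=1e-5)

    def test_unknown_residue_and_mod_errors(self):
        with pytest.raises(ValueError, match="unknown residue"):
            peptide_mass("GXZ")
        with pytest.raises(ValueError, match="unknown modification"):
            peptide_mass("GG", [(1, "phospho-madeup", None)])

    def test_numeric_delta_accepted(self):
        assert peptide_mass("GG", [(1, 79.96633, None)]) == pytest.approx(
            peptide_mass("GG") + 79.96633
        )


class TestPpmMatch:
    def test_exact_match(self):
        assert ppm_match(1000.0, 1000.0)

    def test_eleven_ppm_fails_at_ten(self):
        assert not ppm_match(1000.011, 1000.0, tolerance_ppm=10)
        assert ppm_match(1000.009, 1000.0, tolerance_ppm=10)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.floats(100.0, 5000.0),
        st.floats(-4e-5, 4e-5),
        st.floats(1.0, 50.0),
    )
    def test_symmetric_and_monotone_in_tolerance(self, m, rel, tol):
        other = m * (1.0 + rel)
        # symmetry: the two orders agree away from the knife edge, where
        # the 1e-12-relative difference in denominators can flip the call
        observed_ppm = abs(other - m) / m * 1e6
        if abs(observed_ppm - tol) > tol * 1e-6:
            assert ppm_match(m, other, tol) == ppm_match(other, m, tol)
        if ppm_match(m, other, tol):
            assert ppm_match(m, other, tol * 2)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            ppm_match(0.0, 100.0)


class TestDibasicSites:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AKRG", [(2, 3)]),
            ("KKK", [(1, 2), (2, 3)]),
            ("ARKA", [(2, 3)]),
            ("AKAKA", []),
        ],
    )
    def test_motifs(self, seq, expected):
        assert find_dibasic_sites(seq) == expected

    def test_matches_pair_scan_oracle(self, rng):
        letters = np.array(list(AMINO_ACIDS))
        for _ in range(50):
            seq = "".join(rng.choice(letters, size=40))
            oracle = [
                (i + 1, i + 2)
                for i in range(39)
                if seq[i] in "KR" and seq[i + 1] in "KR"
            ]
            assert find_dibasic_sites(seq) == oracle


class TestBuildAtlas:
    def test_abutting_peptides_share_a_junction(self):
        pre = Precursor("p", "ACDEFGHIKLMN")
        hits = [
            PeptideHit("ACDEF", precursor_id="p", alignment=(1, 5)),
            PeptideHit("GHIKL", precursor_id="p", alignment=(6, 10)),
        ]
        atlas = build_atlas(pre, hits)
        assert atlas.junctions == [5]
        assert np.array_equal(atlas.coverage[:10], np.ones(10, dtype=int))
        assert atlas.coverage[10:].sum() == 0

    def test_no_hits_empty_atlas(self, ghrelin_like_precursor):
        atlas = build_atlas(ghrelin_like_precursor, [])
        assert not atlas.coverage.any()
        assert atlas.junctions == []
        assert atlas.dibasic_sites == find_dibasic_sites(ghrelin_like_precursor)

    def test_region_overlap_labels(self, ghrelin_like_precursor):
        hits = [
            PeptideHit("MLSSK", precursor_id="g", alignment=(1, 5)),
            PeptideHit("GSSFLSPSQKPQG", precursor_id="g", alignment=(22, 34)),
        ]
        atlas = build_atlas(ghrelin_like_precursor, hits)
        assert atlas.region_overlaps[0] == ["signal"]
        assert atlas.region_overlaps[1] == ["functional"]

    def test_out_of_bounds_hit_rejected(self):
        pre = Precursor("p", "ACDEFGHIKL")
        bad = PeptideHit("KLMNP", precursor_id="p", alignment=(9, 13))
        with pytest.raises(ValueError, match="outside precursor"):
            build_atlas(pre, [bad])

    def test_simulated_coverage_matches_interval_stabbing_oracle(
        self, ghrelin_like_precursor
    ):
        from eecquant.synthetic import simulate_peptides

        pre = ghrelin_like_precursor
        hits = simulate_peptides(pre, 50, seed=31)
        atlas = build_atlas(pre, hits)
        spans = [h.alignment for h in hits]
        for i in range(1, len(pre) + 1):
            depth = sum(s <= i <= e for s, e in spans)
            assert atlas.coverage[i - 1] == depth
        assert atlas.coverage.sum() == sum(e - s + 1 for s, e in spans)
        # junction oracle
        expected = sorted(
            {e for _s, e in spans if any(s2 == e + 1 for s2, _e2 in spans)}
        )
        assert atlas.junctions == expected
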