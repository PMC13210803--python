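import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popband import (SeqAlignment, ValidationError, collapse_haplotypes,
                     diagnostic_sites, extract_gapfree_core, p_distance,
                     species_summary)

BASES = "ACGT"


def _aln(rows, species=None, names=None):
    n = len(rows)
    species = species or tuple("s" for _ in rows)
    names = names or tuple(f"q{i}" for i in range(n))
    return SeqAlignment(tuple(names), tuple(species), tuple(rows))


def random_alignment(rng, n, L, gap_prob=0.1):
    arr = rng.choice(list(BASES), size=(n, L))
    gaps = rng.random((n, L)) < gap_prob
    arr[gaps] = "-"
    return _aln(["".join(r) for r in arr])


class TestGapFreeCore:
    def test_matches_brute_force_column_scan(self):
        rng = np.random.default_rng(3)
        a = random_alignment(rng, 20, 50)
        core = extract_gapfree_core(a)
        arr = a.as_array()
        expected = [j for j in range(50) if "-" not in arr[:, j]]
        assert core.column_count == len(expected)
        assert core.rows[0] == "".join(arr[0, expected])

    def test_gapless_alignment_unchanged_and_idempotent(self):
        a = _aln(["ACGT", "ACGA"])
        core = extract_gapfree_core(a)
        assert core.rows == a.rows
        assert extract_gapfree_core(core).rows == core.rows

    def test_records_removed_columns_in_provenance(self):
        a = _aln(["A-GT", "ACG-"])
        core = extract_gapfree_core(a)
        assert core.column_count == 2
        assert any("1,3" in p for p in core.provenance)

    def test_all_gap_columns_error(self):
        with pytest.raises(ValidationError, match="core is empty"):
            extract_gapfree_core(_aln(["-A", "A-"]))


class TestPDistance:
    def test_direct_site_count(self):
        assert p_distance("ACGT", "ACGA") == pytest.approx(0.25)
        assert p_distance("ACGT", "ACGT") == 0.0

    def test_core_pair_differing_at_32_of_697_sites(self):
        rng = np.random.default_rng(0)
        s1 = "".join(rng.choice(list(BASES), size=697))
        sites = rng.choice(697, size=32, replace=False)
        s2 = list(s1)
        for i in sites:
            s2[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s2[i]]
        assert p_distance(s1, "".join(s2)) == pytest.approx(32 / 697)
        assert round(p_distance(s1, "".join(s2)), 4) == 0.0459

    def test_n_sites_use_pairwise_deletion(self):
        # N removes the site from numerator and denominator
        assert p_distance("ANGT", "ACGA") == pytest.approx(1 / 3)
        with pytest.raises(ValidationError, match="comparable"):
            p_distance("NN", "AC")

    def test_length_mismatch_and_gaps_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            p_distance("ACG", "AC")
        with pytest.raises(ValidationError, match="gap-free"):
            p_distance("A-G", "ACG")

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10**6))
    def test_symmetric_and_zero_on_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 40))
        s1 = "".join(rng.choice(list(BASES + "N"), size=L))
        s2 = "".join(rng.choice(list(BASES + "N"), size=L))
        try:
            d12 = p_distance(s1, s2)
        except ValidationError:
            return  # no comparable sites
        if set(s1) != {"N"}:
            assert p_distance(s1, s1) == 0.0
        assert d12 == p_distance(s2, s1)
        assert 0.0 <= d12 <= 1.0


class TestHaplotypesAndDiagnostics:
    def test_haplotype_count_equals_distinct_strings(self):
        rng = np.random.default_rng(5)
        pool = ["".join(rng.choice(list(BASES), size=12)) for _ in range(4)]
        rows = [pool[i] for i in rng.integers(0, 4, size=20)]
        a = _aln(rows, species=("x",) * 20)
        assert collapse_haplotypes(a, "x") == len(set(rows))
        assert collapse_haplotypes(_aln(["AAAA"] * 14, species=("x",) * 14), "x") == 1
        with pytest.raises(KeyError):
            collapse_haplotypes(a, "unknown")

    def test_fixed_vs_polymorphic_columns_classified_exhaustively(self):
        #        0123456789AB   cols 0 and 5 fixed-different; col 9 polymorphic in A
        a_rows = ["ACGTACGTACGT",
                  "ACGTACGTAGGT",
                  "ACGTACGTACGT"]
        b_rows = ["TCGTAGGTACGT",
                  "TCGTAGGTACGT",
                  "TCGTAGGTACGT"]
        a = _aln(a_rows + b_rows, species=("A",) * 3 + ("B",) * 3)
        assert diagnostic_sites(a, "A", "B") == [0, 5]
        # oracle: exhaustive per-column classification
        arr = a.as_array()
        expected = []
        for j in range(arr.shape[1]):
            ca, cb = set(arr[:3, j]), set(arr[3:, j])
            if len(ca) == 1 == len(cb) and ca != cb and "N" not in ca | cb:
                expected.append(j)
        assert diagnostic_sites(a, "A", "B") == expected

    def test_identical_groups_have_no_diagnostic_sites(self):
        a = _aln(["ACGT"] * 4, species=("A", "A", "B", "B"))
        assert diagnostic_sites(a, "A", "B") == []

    def test_n_disqualifies_column(self):
        a = _aln(["ANGT", "ACGT", "TCGT", "TCGT"], species=("A", "A", "B", "B"))
        assert diagnostic_sites(a, "A", "B") == [0]


class TestSpeciesSummary:
    def test_two_haplotype_study_shaped_set(self):
        rng = np.random.default_rng(1)
        h1 = "".join(rng.choice(list(BASES), size=697))
        sites = rng.choice(697, size=32, replace=False)
        h2 = list(h1)
        for i in sites:
            h2[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[h2[i]]
        a = _aln([h1] * 14 + ["".join(h2)] * 2, species=("lit",) * 14 + ("rac",) * 2)
        s = species_summary(a, "lit", "rac")
        assert s.core_length == 697
        assert s.n_per_species == {"lit": 14, "rac": 2}
        assert s.haplotypes_per_species == {"lit": 1, "rac": 1}
        assert s.within_range["lit"] == (0.0, 0.0)
        assert s.between_range[0] == pytest.approx(32 / 697)
        assert s.between_range[0] == s.between_range[1]
        assert len(s.diagnostic_sites) == 32
        assert s.barcode_gap_present

    def test_single_sequence_species_is_degenerate_not_fatal(self):
        a = _aln(["ACGT", "ACGA", "TGCA"], species=("x", "x", "y"))
        s = species_summary(a, "x", "y")
        assert s.within_range["y"] == (0.0, 0.0)
        assert "y" in s.degenerate_within

    def test_same_species_twice_is_an_error(self):
        a = _aln(["ACGT", "ACGA"], species=("x", "x"))
        with pytest.raises(ValidationError):
            species_summary(a, "x", "x")

    def test_diagnostic_sites_contribute_exactly_one_over_core_length(self):
        """With zero within-species variation every diagnostic site adds
        exactly 1/core_length to the between-species p-distance."""
        from popband import SyntheticBarcodeConfig, simulate_barcode_alignment
        from popband.barcode import extract_gapfree_core
        for n_diag in (0, 5, 32):
            cfg = SyntheticBarcodeConfig(core_length=100, n_diagnostic=n_diag,
                                         n_gap_columns=4, seed=n_diag + 1)
            core = extract_gapfree_core(simulate_barcode_alignment(cfg))
            s = species_summary(core, "littorea", "racemosa")
            assert len(s.diagnostic_sites) == n_diag
            assert s.between_range[0] == pytest.approx(n_diag / 100)
            assert s.barcode_gap_present == (n_diag > 0)
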