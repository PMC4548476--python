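"""Data model: parsing, validation, operators, canonical keys."""

import numpy as np
import pytest

import iscoal as ic
from iscoal.data import _enumerate_fast
from iscoal.errors import DataFormatError, DataValidationError, StuckConfigurationError

XML_OK = """<k69data name="t"><haplotype count="2">10</haplotype>
<haplotype count="1">01</haplotype></k69data>"""


class TestParsing:
    def test_table1_fixture_round_numbers(self, table1):
        assert table1.num_haplotypes == 4
        assert table1.num_sites == 4
        assert table1.nu.tolist() == [2, 1, 1, 1]
        assert table1.n == 5

    def test_xml_parse(self):
        d = ic.parse_dataset(XML_OK, format="xml")
        assert d.X.tolist() == [[1, 0], [0, 1]]
        assert d.nu.tolist() == [2, 1]

    def test_tsv_parse_with_comments(self):
        d = ic.parse_dataset("# comment\n10\t2\n01\t1\n", format="tsv")
        assert d.n == 3

    def test_mrca_file(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("\t1\n")
        d = ic.read_dataset(p)
        assert d.num_sites == 0 and d.n == 1
        assert d.initial_config().is_mrca

    @pytest.mark.parametrize(
        "text,fmt",
        [
            ('<k69data><haplotype count="1">10</haplotype>'
             '<haplotype count="1">10</haplotype></k69data>', "xml"),  # dup rows
            ('<k69data><haplotype count="0">10</haplotype></k69data>', "xml"),
            ('<k69data><haplotype count="1">102</haplotype></k69data>', "xml"),
            ('<k69data><haplotype count="1">10</haplotype>'
             '<haplotype count="1">101</haplotype></k69data>', "xml"),  # lengths
            ("10\t2\t9\n", "tsv"),
            ("<nope/>", "xml"),
            ("not xml at all <", "xml"),
        ],
    )
    def test_bad_files_rejected(self, text, fmt):
        with pytest.raises((DataFormatError, DataValidationError)):
            ic.parse_dataset(text, format=fmt)

    def test_round_trip_xml_tsv(self, table1, tmp_path):
        for fmt in ("xml", "tsv"):
            p = tmp_path / f"t.{fmt}"
            ic.write_dataset(table1, p, format=fmt)
            d = ic.read_dataset(p, format=fmt)
            assert np.array_equal(d.X, table1.X)
            assert np.array_equal(d.nu, table1.nu)


class TestValidation:
    def test_table1_ok(self, table1):
        assert ic.validate(table1).ok

    def test_non_binary_entry(self):
        d = ic.table1()
        d.X[0, 0] = 2
        rep = ic.validate(d)
        assert not rep.ok
        assert any("non-binary" in r for r, _ in rep.violations)

    def test_multiplicity_below_one(self):
        d = ic.K69Dataset(X=np.array([[1], [0]], dtype=np.uint8), nu=[0, 1])
        rep = ic.validate(d)
        assert any("multiplicity" in r for r, _ in rep.violations)

    def test_all_one_column_rejected_at_load_but_ok_mid_path(self):
        d = ic.K69Dataset(X=np.array([[1, 1], [1, 0]], dtype=np.uint8), nu=[1, 1])
        assert not ic.validate(d).ok
        assert ic.validate(d, allow_fixed_columns=True).ok


class TestConsensusRecode:
    def test_majority_column_flipped(self, table1):
        # column 1 carried by 4 of 5 sequences -> flipped
        out = ic.consensus_root_recode(table1)
        assert out.X[:, 0].tolist() == [0, 0, 0, 1]
        # input untouched
        assert table1.X[:, 0].tolist() == [1, 1, 1, 0]

    def test_minority_column_unchanged(self, table1):
        out = ic.consensus_root_recode(table1)
        # columns 3,4 carried once each: unchanged
        assert out.X[:, 2].tolist() == table1.X[:, 2].tolist()

    def test_identity_on_minor_allele_coding(self):
        d = ic.K69Dataset(X=np.array([[1], [0]], dtype=np.uint8), nu=[1, 2])
        out = ic.consensus_root_recode(d)
        assert np.array_equal(out.X, d.X)


class TestEvents:
    def test_table1_initial_events(self, table1):
        evs = ic.enumerate_events(table1.initial_config())
        assert len(evs) == 2
        coal, mut = evs
        assert coal.kind is ic.EventKind.COALESCENCE and coal.row == 0
        assert mut.kind is ic.EventKind.MUT_TYPE_I
        assert mut.row == 1 and mut.column == 2  # smallest eligible site (site 3)

    def test_coalescence_only_for_duplicated_row(self):
        c = ic.AncestralConfig(X=np.zeros((1, 0), dtype=np.uint8), nu=[2])
        evs = ic.enumerate_events(c)
        assert [e.kind for e in evs] == [ic.EventKind.COALESCENCE]

    def test_type_two_merge(self, one_mutation_pair):
        evs = ic.enumerate_events(one_mutation_pair.initial_config())
        assert len(evs) == 1
        e = evs[0]
        assert e.kind is ic.EventKind.MUT_TYPE_II
        assert e.row == 0 and e.column == 0 and e.merge_row == 1

    def test_stuck_configuration_raises(self):
        # three singleton rows with no private mutation cannot reduce
        c = ic.AncestralConfig(X=np.array([[1, 1], [1, 0], [0, 1]], dtype=np.uint8),
                               nu=[1, 1, 1])
        with pytest.raises(StuckConfigurationError):
            ic.enumerate_events(c)

    def test_apply_coalescence(self, table1):
        c = table1.initial_config()
        out = ic.apply_event(c, ic.enumerate_events(c)[0])
        assert np.array_equal(out.X, c.X)
        assert out.nu.tolist() == [1, 1, 1, 1]

    def test_apply_type_one_deletes_column(self, table1):
        c = table1.initial_config()
        mut = ic.enumerate_events(c)[1]
        out = ic.apply_event(c, mut)
        assert out.num_sites == 3
        assert out.X[1].tolist() == [1, 1, 1]
        assert out.site_labels == ("1", "2", "4")
        assert len({tuple(r) for r in out.X.tolist()}) == out.num_haplotypes

    def test_apply_type_two_merges(self, one_mutation_pair):
        c = one_mutation_pair.initial_config()
        out = ic.apply_event(c, ic.enumerate_events(c)[0])
        assert out.num_sites == 0
        assert out.nu.tolist() == [2]

    def test_inapplicable_event_rejected(self, table1):
        c = table1.initial_config()
        bad = ic.EvolutionEvent(kind=ic.EventKind.COALESCENCE, row=3)
        with pytest.raises(DataValidationError):
            ic.apply_event(c, bad)

    def test_path_length_invariant(self, table1):
        # every event sequence from the sample reaches the MRCA in
        # (#mutation columns) + (n - 1) steps: 4 + 4 = 8 on this data
        rng = np.random.default_rng(0)
        for _ in range(25):
            c = table1.initial_config()
            steps = 0
            while not c.is_mrca:
                evs = ic.enumerate_events(c)
                c = ic.apply_event(c, evs[rng.integers(len(evs))])
                steps += 1
            assert steps == 8


class TestTargetCoefficient:
    def test_coalescence_coefficient(self, table1):
        c = table1.initial_config()
        coal = ic.enumerate_events(c)[0]
        assert ic.target_coefficient(c, coal, 3.0) == 2.0  # nu=2 -> 2*1

    def test_mutation_coefficients(self, table1, one_mutation_pair):
        c = table1.initial_config()
        mut = ic.enumerate_events(c)[1]
        assert ic.target_coefficient(c, mut, 0.0) == 0.0
        assert ic.target_coefficient(c, mut, 2.5) == 2.5
        c2 = one_mutation_pair.initial_config()
        e2 = ic.enumerate_events(c2)[0]
        assert ic.target_coefficient(c2, e2, 2.0) == 4.0  # theta*(nu_b+1)

    def test_negative_theta_rejected(self, table1):
        c = table1.initial_config()
        with pytest.raises(ValueError):
            ic.target_coefficient(c, ic.enumerate_events(c)[0], -1.0)

    def test_coefficient_sum_bounded(self, table1):
        # sum of coefficients never exceeds the recursion denominator
        rng = np.random.default_rng(1)
        for theta in (0.5, 2.0, 7.0):
            c = table1.initial_config()
            while not c.is_mrca:
                evs = ic.enumerate_events(c)
                total = sum(ic.target_coefficient(c, e, theta) for e in evs)
                assert total <= c.n * (c.n - 1 + theta) + 1e-12
                c = ic.apply_event(c, evs[rng.integers(len(evs))])


class TestCanonicalKey:
    def test_invariant_under_permutations(self, table1):
        rng = np.random.default_rng(42)
        c = table1.initial_config()
        base = ic.canonical_key(c)
        for _ in range(100):
            rp = rng.permutation(c.num_haplotypes)
            cp = rng.permutation(c.num_sites)
            perm = ic.AncestralConfig(X=c.X[np.ix_(rp, cp)], nu=c.nu[rp])
            assert ic.canonical_key(perm) == base

    def test_distinct_multiplicities_distinct_keys(self):
        a = ic.AncestralConfig(X=np.array([[1], [0]], dtype=np.uint8), nu=[1, 2])
        b = ic.AncestralConfig(X=np.array([[1], [0]], dtype=np.uint8), nu=[2, 1])
        c = ic.AncestralConfig(X=np.array([[1], [0]], dtype=np.uint8), nu=[1, 1])
        assert ic.canonical_key(a) != ic.canonical_key(c)
        # swapping rows AND nu together is the same object
        assert ic.canonical_key(a) == ic.canonical_key(
            ic.AncestralConfig(X=np.array([[0], [1]], dtype=np.uint8), nu=[2, 1])
        )
        assert ic.canonical_key(b) != ic.canonical_key(a)

    def test_simulated_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            d = ic.simulate_dataset(8, 3.0, rng)
            c = d.initial_config()
            base = ic.canonical_key(c)
            rp = rng.permutation(c.num_haplotypes)
            cp = rng.permutation(c.num_sites)
            perm = ic.AncestralConfig(X=c.X[np.ix_(rp, cp)], nu=c.nu[rp])
            assert ic.canonical_key(perm) == base
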