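import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from motifnull import (
    AlphabetError,
    DimensionError,
    EmptyInputError,
    Motif,
    igc,
    motif_entropy,
    motif_gc,
    motif_ic,
    positional_ic,
    read_motif,
    read_motifs,
    write_motifs,
)
from motifnull.motif_core import gini

motif_strategy = st.integers(2, 6).flatmap(
    lambda L: st.lists(
        st.text(alphabet="ACGT", min_size=L, max_size=L), min_size=1, max_size=8
    )
).map(lambda seqs: Motif(tuple(seqs)))


class TestMotifType:
    def test_dimensions_and_uppercasing(self):
        m = Motif(("acgt", "ACGT"))
        assert (m.N, m.L) == (2, 4)
        assert m.sequences == ("ACGT", "ACGT")

    @pytest.mark.parametrize(
        "seqs,err",
        [
            (("ACGT", "ACG"), DimensionError),
            (("ACNT",), AlphabetError),
            (("AC-T",), AlphabetError),
            ((), EmptyInputError),
        ],
    )
    def test_invalid_motifs_rejected(self, seqs, err):
        with pytest.raises(err):
            Motif(tuple(seqs))

    def test_array_round_trip(self, random_motif_factory):
        m = random_motif_factory(7, 5)
        assert Motif.from_array(m.to_array()) == m


class TestInformationStatistics:
    @pytest.mark.parametrize(
        "columns,expected_entropy",
        [
            (["A", "A", "A", "A"], 0.0),
            (["A", "C", "G", "T"], 2.0),
            (["A", "A", "C", "G"], 1.5),
        ],
    )
    def test_single_column_entropy(self, columns, expected_entropy):
        assert motif_entropy(Motif(tuple(columns))) == pytest.approx(expected_entropy)

    @pytest.mark.parametrize(
        "seqs,expected_ic",
        [
            (("AAA", "CCC", "GGG", "TTT"), 0.0),
            (("AAA", "AAA", "AAA", "AAA"), 6.0),
            (("A", "A", "C", "G"), 0.5),
        ],
    )
    def test_motif_ic(self, seqs, expected_ic):
        assert motif_ic(Motif(seqs)) == pytest.approx(expected_ic)

    def test_positional_profile(self):
        # first column fully conserved, second uniform over the 4 sites
        m = Motif(("AA", "AC", "AG", "AT"))
        prof = positional_ic(m)
        assert prof.column_ic == pytest.approx([2.0, 0.0])
        assert prof.total_ic == pytest.approx(motif_ic(m))
        assert prof.total_entropy == pytest.approx(motif_entropy(m))

    def test_ic_entropy_complementarity_random(self, random_motif_factory):
        for _ in range(1000):
            m = random_motif_factory(5, 4)
            assert motif_ic(m) + motif_entropy(m) == pytest.approx(
                2 * m.L, abs=1e-9
            )

    @pytest.mark.parametrize(
        "seqs,expected_gc",
        [(("AA", "AA"), 0.0), (("GG", "GG"), 1.0), (("AC", "GT"), 0.5)],
    )
    def test_motif_gc(self, seqs, expected_gc):
        assert motif_gc(Motif(seqs)) == pytest.approx(expected_gc)

    @given(motif_strategy)
    def test_row_permutation_invariance(self, m):
        reversed_m = Motif(tuple(reversed(m.sequences)))
        assert motif_ic(reversed_m) == pytest.approx(motif_ic(m))
        assert igc(reversed_m) == pytest.approx(igc(m))
        assert motif_gc(reversed_m) == pytest.approx(motif_gc(m))


class TestIGC:
    def test_equal_columns_give_zero(self):
        m = Motif(("AAAA", "AAAA"))  # every column IC = 2
        assert igc(m) == pytest.approx(0.0)

    def test_two_column_extreme(self):
        # column ICs (0, 2): Gini = (L-1)/L = 1/2 at L=2
        m = Motif(("AA", "CA", "GA", "TA"))
        assert igc(m) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "column_ics,expected",
        [((1.0, 1.0, 1.0, 1.0), 0.0), ((0.0, 0.0, 0.0, 4.0), 0.75)],
    )
    def test_gini_formula_values(self, column_ics, expected):
        assert gini(np.array(column_ics)) == pytest.approx(expected)

    def test_gini_against_lorenz_oracle(self, rng):
        # independent cumulative-share (Lorenz curve) implementation
        def lorenz_gini(values):
            c = np.sort(values)
            shares = np.concatenate([[0.0], np.cumsum(c) / c.sum()])
            x = np.linspace(0, 1, len(shares))
            area = np.trapezoid(shares, x)
            return 1.0 - 2.0 * area

        for _ in range(50):
            vals = rng.random(rng.integers(2, 10))
            assert gini(vals) == pytest.approx(lorenz_gini(vals), abs=1e-12)

    def test_zero_ic_motif_warns_and_returns_zero(self):
        m = Motif(("A", "C", "G", "T"))
        with pytest.warns(RuntimeWarning):
            assert igc(m) == 0.0

    def test_igc_bounds_exhaustive_n2_l2(self):
        # all 256 motifs with N=2, L=2: IGC in [0, (L-1)/L] when total IC > 0
        for code in range(256):
            digits = [(code >> (2 * k)) & 3 for k in range(4)]
            arr = np.array(digits).reshape(2, 2)
            m = Motif.from_array(arr)
            if positional_ic(m).total_ic > 0:
                assert 0.0 <= igc(m) <= 0.5 + 1e-12

    def test_column_permutation_and_relabeling_invariance(self):
        m = Motif(("ACG", "ACG", "ACT", "AGT"))
        swapped = Motif(tuple(s[::-1] for s in m.sequences))
        relabeled = Motif(tuple(s.translate(str.maketrans("ACGT", "TGCA")) for s in m.sequences))
        assert igc(swapped) == pytest.approx(igc(m))
        assert igc(relabeled) == pytest.approx(igc(m))


class TestIO:
    def test_fasta_parse(self):
        text = ">a\nACGTA\n>b\nACGTA\n>c\nACGTT\n"
        m = read_motif(io.StringIO(text), format="fasta")
        assert (m.N, m.L) == (3, 5)

    def test_lines_parse_with_comments_and_case(self):
        text = "# comment\nacgt\nACGT\n"
        m = read_motif(io.StringIO(text), format="lines")
        assert m.sequences == ("ACGT", "ACGT")

    def test_lines_unequal_lengths_error(self):
        with pytest.raises(DimensionError):
            read_motif(io.StringIO("ACGT\nACG\n"), format="lines")

    @pytest.mark.parametrize("fmt", ["fasta", "lines"])
    @pytest.mark.parametrize("n_motifs", [1, 2])
    def test_round_trip(self, fmt, n_motifs, random_motif_factory):
        motifs = [random_motif_factory(3, 6) for _ in range(n_motifs)]
        buf = io.StringIO()
        write_motifs(motifs, buf, format=fmt)
        buf.seek(0)
        assert read_motifs(buf, format=fmt) == motifs

    def test_fasta_headers_encode_indices(self, random_motif_factory):
        buf = io.StringIO()
        write_motifs([random_motif_factory(2, 4)], buf, format="fasta")
        assert ">motif0_site0" in buf.getvalue()
        assert ">motif0_site1" in buf.getvalue()

    def test_empty_inputs(self):
        with pytest.raises(EmptyInputError):
            read_motif(io.StringIO(""), format="fasta")
        with pytest.raises(EmptyInputError):
            read_motif(io.StringIO("\n#\n"), format="lines")
        with pytest.raises(EmptyInputError):
            write_motifs([], io.StringIO(), format="fasta")
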