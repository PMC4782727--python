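"""Character-matrix I/O, polymorphism recoding, step matrices, counts."""

import numpy as np
import pytest

from tipchron.matrix import (CalibrationTable, Cell, CharacterMatrix,
                             NexusParseError, POLY, STATE,
                             build_step_matrix, classify_characters,
                             read_calibrations, read_nexus_matrix,
                             recode_polymorphisms, write_calibrations,
                             write_nexus_matrix, read_config)
from conftest import make_matrix, random_raw_matrix


class TestNexusIO:
    def test_toy_parse(self, toy_nexus):
        m = read_nexus_matrix(toy_nexus)
        assert m.taxa == ["TaxonA", "TaxonB", "TaxonC"]
        assert m.n_char == 2
        assert m.cells[0][1] == Cell(POLY, (0, 1))
        assert m.cells[1][1].kind == "missing"
        assert m.ordered_flags == [True, False]

    def test_missing_is_full_ambiguity(self, toy_nexus):
        m = recode_polymorphisms(read_nexus_matrix(toy_nexus))
        assert m.recoded[1][1] is None

    def test_duplicate_taxon_rejected(self, tmp_path):
        text = ("#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=1;\n"
                "MATRIX\nA 0\nA 1\n;\nEND;\n")
        p = tmp_path / "dup.nex"
        p.write_text(text)
        with pytest.raises(ValueError, match="duplicate"):
            read_nexus_matrix(p)

    def test_malformed_polymorphism_names_line(self, tmp_path):
        text = ("#NEXUS\nBEGIN DATA;\nMATRIX\nA 0(1\nB 11\n;\nEND;\n")
        p = tmp_path / "bad.nex"
        p.write_text(text)
        with pytest.raises(NexusParseError, match="line"):
            read_nexus_matrix(p)

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "nohdr.nex"
        p.write_text("BEGIN DATA; MATRIX A 0 ; END;")
        with pytest.raises(NexusParseError):
            read_nexus_matrix(p)

    @pytest.mark.parametrize("seed", range(6))
    def test_round_trip(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        m = random_raw_matrix(rng)
        path = tmp_path / f"rt{seed}.nex"
        write_nexus_matrix(m, path)
        assert read_nexus_matrix(path) == m

    def test_sidecar_ordering(self, tmp_path):
        text = ("#NEXUS\nBEGIN DATA;\nMATRIX\nA 010\nB 111\n;\nEND;\n")
        nex = tmp_path / "m.nex"
        nex.write_text(text)
        side = tmp_path / "m.cfg"
        side.write_text("ordered = 1 3\n")
        m = read_nexus_matrix(nex, sidecar=side)
        assert m.ordered_flags == [True, False, True]


class TestRecoding:
    def test_adjacent_polymorphism_becomes_state(self):
        m = make_matrix("ABCD", [[0, (0, 1), 1, 2]], [True])
        meta = m.char_meta[0]
        assert meta.positions == [("fixed", 0), ("poly", (0, 1)),
                                  ("fixed", 1), ("fixed", 2)]
        assert meta.n_states == 4
        assert m.recoded[1][0] == 1  # the inserted intermediate

    def test_no_polymorphism_identity(self):
        m = make_matrix("ABC", [[0, 1, 2]], [True])
        assert m.char_meta[0].positions == [("fixed", 0), ("fixed", 1),
                                            ("fixed", 2)]
        assert [m.recoded[i][0] for i in range(3)] == [0, 1, 2]

    def test_unordered_polymorphism_stays_ambiguity(self):
        m = make_matrix("ABC", [[1, (1, 2), 2]], [False])
        meta = m.char_meta[0]
        # state count unchanged and cell is exactly the spanned set
        assert meta.n_states == 2
        assert m.recoded[1][0] == frozenset({0, 1})
        observed = {c for c in (m.recoded[i][0] for i in range(3))
                    if not isinstance(c, frozenset)}
        assert observed == {0, 1}

    def test_nonadjacent_polymorphism_is_ambiguity_over_span(self):
        m = make_matrix("ABC", [[0, (0, 2), 2]], [True])
        assert m.recoded[1][0] == frozenset({0, 1, 2})

    def test_fixed_k_forces_state_space(self):
        m = make_matrix("AB", [[0, 0]], [False])
        assert m.char_meta[0].n_states == 1
        m2 = make_matrix("AB", [[0, 0]], [False])
        recode_polymorphisms(m2, fixed_k=3)
        assert m2.char_meta[0].n_states == 3


class TestStepMatrix:
    def test_equal_scheme_counts_intermediate(self):
        m = make_matrix("ABC", [[0, (0, 1), 1]], [True])
        sm = build_step_matrix(m.char_meta[0], "equal")
        assert sm.cost[0, 2] == 2.0      # fixed 0 -> fixed 1 via intermediate
        assert sm.cost[0, 1] == 1.0      # fixed 0 -> (01)

    def test_half_step_scheme(self):
        m = make_matrix("ABC", [[0, (0, 1), 1]], [True])
        sm = build_step_matrix(m.char_meta[0], "half_step")
        assert sm.cost[0, 2] == 1.0
        assert sm.cost[0, 1] == 0.5

    def test_plain_ordered_distance(self):
        m = make_matrix("ABC", [[0, 1, 2]], [True])
        for scheme in ("equal", "half_step"):
            sm = build_step_matrix(m.char_meta[0], scheme)
            assert np.array_equal(sm.cost,
                                  np.abs(np.subtract.outer(range(3), range(3))))

    @pytest.mark.parametrize("seed", range(8))
    def test_extreme_state_costs_identity(self, seed):
        """equal cost between morphocline ends = (n_fixed-1) + n_poly;
        half-step cost = n_fixed-1."""
        rng = np.random.default_rng(seed)
        n_fixed = int(rng.integers(2, 6))
        column = [[s, s] for s in range(n_fixed)]
        polys = [(s, s + 1) for s in range(n_fixed - 1) if rng.random() < 0.5]
        col = [s for pair in column for s in pair] + list(polys)
        taxa = [f"T{i}" for i in range(len(col))]
        m = make_matrix(taxa, [col], [True])
        meta = m.char_meta[0]
        eq = build_step_matrix(meta, "equal").cost
        hf = build_step_matrix(meta, "half_step").cost
        assert eq[0, -1] == (n_fixed - 1) + len(polys)
        assert hf[0, -1] == n_fixed - 1

    def test_triangle_inequality_and_symmetry(self):
        rng = np.random.default_rng(3)
        m = random_raw_matrix(rng)
        recode_polymorphisms(m)
        for meta in m.char_meta:
            for scheme in ("equal", "half_step"):
                c = build_step_matrix(meta, scheme).cost
                k = c.shape[0]
                assert np.allclose(c, c.T)
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            assert c[i, j] <= c[i, l] + c[l, j] + 1e-12


class TestClassification:
    def test_textbook_cases(self):
        m = make_matrix("ABCD", [[0, 0, 0, 1],   # variable, uninformative
                                 [0, 0, 0, 0],   # constant
                                 [0, 0, 1, 1]],  # informative
                        [False, False, False])
        s = m.classification
        assert s["classes"] == ["variable", "constant", "informative"]

    def test_counts_sum(self):
        rng = np.random.default_rng(11)
        m = random_raw_matrix(rng, n_taxa=8, n_char=30)
        s = classify_characters(recode_polymorphisms(m))
        assert (s["n_constant"] + s["n_variable"] + s["n_informative"]
                == s["n_total"] == 30)

    def test_recoded_polymorphic_state_counts_as_state(self):
        # two taxa share the intermediate: that state occurs twice
        m = make_matrix("ABCD", [[(0, 1), (0, 1), 0, 0]], [True])
        assert m.char_meta[0].informative


class TestCalibrations:
    def test_window_row(self, tmp_path):
        p = tmp_path / "cal.tsv"
        p.write_text("tip\tkind\tmin_age\tmax_age\tfixed_age\tlocality\n"
                     "Prepomonomys_bogenfelsi\tuniform\t20\t47\t\tSilica_North\n")
        t = read_calibrations(p)
        assert t.bounds("Prepomonomys_bogenfelsi") == (20.0, 47.0)
        assert t.locality("Prepomonomys_bogenfelsi") == "Silica_North"

    def test_degenerate_window_becomes_fixed(self, tmp_path):
        p = tmp_path / "cal.tsv"
        p.write_text("tip\tkind\tmin_age\tmax_age\tfixed_age\tlocality\n"
                     "A\tuniform\t5\t5\t\tX\n")
        t = read_calibrations(p)
        assert t["A"]["kind"] == "fixed"
        assert t.bounds("A") == (5.0, 5.0)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        entries = {}
        for i in range(10):
            if rng.random() < 0.5:
                lo = float(rng.uniform(0, 30))
                entries[f"T{i}"] = {"kind": "uniform", "min_age": lo,
                                    "max_age": lo + float(rng.uniform(0.1, 20)),
                                    "locality": f"L{i % 3}"}
            else:
                entries[f"T{i}"] = {"kind": "fixed",
                                    "fixed_age": float(rng.uniform(0, 30)),
                                    "locality": None}
        table = CalibrationTable(entries)
        p = tmp_path / "rt.tsv"
        write_calibrations(table, p)
        assert read_calibrations(p) == table

    def test_unknown_tips_flagged(self):
        t = CalibrationTable({"X": {"kind": "fixed", "fixed_age": 1.0}})
        with pytest.raises(ValueError, match="X"):
            t.validate_tips(["A", "B"])

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            CalibrationTable({"A": {"kind": "uniform", "min_age": 5.0,
                                    "max_age": 2.0}})


def test_config_reader(tmp_path):
    p = tmp_path / "run.cfg"
    p.write_text("# comment\nordered = 1-3 7\nmode = tipdating\n")
    cfg = read_config(p)
    assert cfg == {"ordered": "1-3 7", "mode": "tipdating"}


# ---------------------------------------------------------------------------
# property-based checks
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@st.composite
def raw_matrices(draw):
    n_taxa = draw(st.integers(3, 7))
    n_char = draw(st.integers(1, 8))
    taxa = [f"T{i}" for i in range(n_taxa)]
    cells, flags = [[] for _ in taxa], []
    for _ in range(n_char):
        k = draw(st.integers(2, 4))
        flags.append(draw(st.booleans()))
        for i in range(n_taxa):
            kind = draw(st.sampled_from(["state", "state", "state", "poly",
                                         "missing"]))
            if kind == "missing":
                cells[i].append(Cell("missing"))
            elif kind == "poly":
                s = draw(st.integers(0, k - 2))
                cells[i].append(Cell(POLY, (s, s + 1)))
            else:
                cells[i].append(Cell(STATE, (draw(st.integers(0, k - 1)),)))
    return CharacterMatrix(taxa, cells, flags)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(raw_matrices())
def test_nexus_round_trip_property(tmp_path_factory, matrix):
    path = tmp_path_factory.mktemp("rt") / "m.nex"
    write_nexus_matrix(matrix, path)
    assert read_nexus_matrix(path) == matrix


@settings(max_examples=30, deadline=None, derandomize=True)
@given(raw_matrices())
def test_step_matrices_are_metrics(matrix):
    recode_polymorphisms(matrix)
    for meta in matrix.char_meta:
        for scheme in ("equal", "half_step"):
            c = build_step_matrix(meta, scheme).cost
            assert np.allclose(c, c.T)
            assert np.all(np.diagonal(c) == 0)
            k = c.shape[0]
            # triangle inequality via min-plus closure
            closure = c.copy()
            for l in range(k):
                closure = np.minimum(closure,
                                     closure[:, [l]] + closure[[l], :])
            assert np.allclose(closure, c)
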