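import warnings

import numpy as np
import pytest

from tipchron.matrix import (Cell, CharacterMatrix, STATE, POLY,
                             recode_polymorphisms)
from tipchron.trees import Tree

warnings.filterwarnings("ignore", category=FutureWarning)

TOY_NEXUS = """#NEXUS

BEGIN DATA;
  DIMENSIONS NTAX=3 NCHAR=2;
  FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;
  MATRIX
    TaxonA  0(01)
    TaxonB  1?
    TaxonC  21
  ;
END;

BEGIN ASSUMPTIONS;
  TYPESET * default = ord: 1, unord: 2;
END;
"""


@pytest.fixture
def toy_nexus(tmp_path):
    path = tmp_path / "toy.nex"
    path.write_text(TOY_NEXUS)
    return path


def make_matrix(taxa, columns, ordered_flags):
    """Build a CharacterMatrix from per-character state lists.

    A column entry may be an int (single state), a tuple (polymorphism),
    or None (missing).
    """
    cells = [[] for _ in taxa]
    for col in columns:
        for i, entry in enumerate(col):
            if entry is None:
                cells[i].append(Cell("missing"))
            elif isinstance(entry, tuple):
                cells[i].append(Cell(POLY, tuple(sorted(entry))))
            else:
                cells[i].append(Cell(STATE, (entry,)))
    return recode_polymorphisms(CharacterMatrix(list(taxa), cells,
                                                list(ordered_flags)))


@pytest.fixture
def four_taxon_ordered():
    """Spec-style ordered 3-state character: A=0, B=1, C=2, D=2."""
    return make_matrix("ABCD", [[0, 1, 2, 2]], [True])


@pytest.fixture
def quartet_tree():
    return Tree.from_newick("((A,B),(C,D));")


def random_raw_matrix(rng, n_taxa=6, n_char=12):
    """Random small matrix with polymorphisms and missing cells."""
    taxa = [f"T{i}" for i in range(n_taxa)]
    cells = [[] for _ in taxa]
    flags = []
    for _ in range(n_char):
        k = int(rng.integers(2, 5))
        ordered = bool(rng.random() < 0.5)
        flags.append(ordered)
        for i in range(n_taxa):
            u = rng.random()
            if u < 0.08:
                cells[i].append(Cell("missing"))
            elif u < 0.16 and k >= 2:
                s = int(rng.integers(0, k - 1))
                cells[i].append(Cell(POLY, (s, s + 1)))
            else:
                cells[i].append(Cell(STATE, (int(rng.integers(k)),)))
    return CharacterMatrix(taxa, cells, flags)
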