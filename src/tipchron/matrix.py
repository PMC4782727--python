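"""Morphological character matrices and their file formats.

Discrete morphological data arrive as NEXUS matrices whose cells may be
single states, polymorphisms like ``(01)``, missing ``?`` or gap ``-``,
with per-character ordered/unordered flags.  Following common practice
for ordered morphoclines, a polymorphism observed between two adjacent
"fixed" states is recoded as its own intermediate state, which doubles
the resolution of the morphocline wherever polymorphisms occur; on
unordered characters a polymorphism stays an ambiguity set.

The NEXUS character-matrix reader here is intentionally self-contained:
the polymorphism-vs-ambiguity distinction and per-character ordering
metadata are load-bearing for everything downstream, and the dialect we
accept is exactly the dialect we emit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Cell",
    "CharacterMeta",
    "CharacterMatrix",
    "StepMatrix",
    "CalibrationTable",
    "read_nexus_matrix",
    "write_nexus_matrix",
    "recode_polymorphisms",
    "build_step_matrix",
    "classify_characters",
    "read_calibrations",
    "write_calibrations",
    "read_traits",
    "write_traits",
    "read_locality_map",
    "write_locality_map",
]

SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"

MISSING = "missing"
GAP = "gap"
STATE = "state"
POLY = "poly"


@dataclass(frozen=True)
class Cell:
    """One observed scoring: a state, a polymorphism, or missing/gap."""

    kind: str
    states: tuple[int, ...] = ()

    def __post_init__(self):
        if self.kind == STATE and len(self.states) != 1:
            raise ValueError("state cell needs exactly one state")
        if self.kind == POLY and len(self.states) < 2:
            raise ValueError("polymorphism needs >= 2 states")


@dataclass
class CharacterMeta:
    """Per-character metadata after recoding.

    ``positions`` lists the recoded state space in morphocline order:
    ``('fixed', s)`` for an original state ``s`` or ``('poly', (a, b))``
    for an inserted intermediate between adjacent fixed states a < b.
    Unordered characters only carry ``('fixed', s)`` entries.
    """

    ordered: bool
    positions: list[tuple] = field(default_factory=list)
    informative: bool | None = None

    @property
    def n_states(self) -> int:
        return len(self.positions)

    @property
    def n_fixed_states(self) -> int:
        return sum(1 for p in self.positions if p[0] == "fixed")

    @property
    def polymorphic_states(self) -> list[tuple]:
        return [p[1] for p in self.positions if p[0] == "poly"]

    def is_poly_position(self, i: int) -> bool:
        return self.positions[i][0] == "poly"


class CharacterMatrix:
    """Taxa x characters with raw and (optionally) recoded cells.

    ``cells[i][j]`` is a :class:`Cell`; after :func:`recode_polymorphisms`
    the parallel ``recoded[i][j]`` holds ``int`` (single recoded state),
    ``frozenset`` (ambiguity over recoded states) or ``None`` (missing/gap,
    i.e. full ambiguity).
    """

    def __init__(self, taxa: list[str], cells: list[list[Cell]],
                 ordered_flags: list[bool] | None = None):
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        ncols = {len(row) for row in cells}
        if len(ncols) > 1:
            raise ValueError("rows have unequal numbers of characters")
        self.taxa = list(taxa)
        self.cells = cells
        self.n_char = len(cells[0]) if cells else 0
        if ordered_flags is None:
            ordered_flags = [False] * self.n_char
        if len(ordered_flags) != self.n_char:
            raise ValueError("ordered_flags length mismatch")
        self.ordered_flags = list(ordered_flags)
        self.char_meta: list[CharacterMeta] | None = None
        self.recoded: list[list] | None = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def is_recoded(self) -> bool:
        return self.recoded is not None

    def column(self, j: int) -> list[Cell]:
        return [row[j] for row in self.cells]

    def recoded_column(self, j: int) -> list:
        if not self.is_recoded:
            raise ValueError("matrix not recoded yet")
        return [row[j] for row in self.recoded]

    def __eq__(self, other) -> bool:
        return (isinstance(other, CharacterMatrix)
                and self.taxa == other.taxa
                and self.cells == other.cells
                and self.ordered_flags == other.ordered_flags)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CharacterMatrix({self.n_taxa} taxa x {self.n_char} characters)"


# ---------------------------------------------------------------------------
# NEXUS I/O
# ---------------------------------------------------------------------------

class NexusParseError(ValueError):
    pass


def _strip_comments(text: str) -> str:
    out, depth = [], 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth = max(0, depth - 1)
        elif depth == 0:
            out.append(ch)
    return "".join(out)


def _parse_cell_token(chars: str, lineno: int, missing: str, gap: str):
    sym2state = {c: i for i, c in enumerate(SYMBOLS)}
    cells = []
    i = 0
    while i < len(chars):
        ch = chars[i]
        if ch in "({":
            close = ")" if ch == "(" else "}"
            j = chars.find(close, i)
            if j < 0:
                raise NexusParseError(f"line {lineno}: unclosed '{ch}'")
            group = chars[i + 1:j].replace(",", "").replace(" ", "")
            try:
                states = tuple(sorted(sym2state[c] for c in group))
            except KeyError as exc:
                raise NexusParseError(f"line {lineno}: bad symbol {exc}") from None
            cells.append(Cell(POLY, states))
            i = j + 1
        elif ch == missing:
            cells.append(Cell(MISSING))
            i += 1
        elif ch == gap:
            cells.append(Cell(GAP))
            i += 1
        elif ch in sym2state:
            cells.append(Cell(STATE, (sym2state[ch],)))
            i += 1
        elif ch.isspace():
            i += 1
        else:
            raise NexusParseError(f"line {lineno}: unexpected character {ch!r}")
    return cells


def _parse_ranges(spec: str) -> list[int]:
    """Parse NEXUS 1-based character lists like ``1-5 7 9-10`` to 0-based."""
    out: list[int] = []
    for tok in spec.replace(",", " ").split():
        if "-" in tok:
            lo, hi = tok.split("-")
            out.extend(range(int(lo) - 1, int(hi)))
        else:
            out.append(int(tok) - 1)
    return out


def read_nexus_matrix(path, ordered: list[int] | None = None,
                      sidecar=None) -> CharacterMatrix:
    """Read a NEXUS CHARACTERS/DATA block into a :class:`CharacterMatrix`.

    Ordering flags come from, in precedence order: the ``ordered`` argument
    (0-based character indices), a sidecar flat key=value file with an
    ``ordered = 1-5 7`` entry (1-based, NEXUS style), or an ASSUMPTIONS
    block ``TYPESET`` line in the file itself.
    """
    text = open(path).read()
    if not text.lstrip().lower().startswith("#nexus"):
        raise NexusParseError("line 1: missing #NEXUS header")
    clean = _strip_comments(text)

    m = re.search(r"begin\s+(?:data|characters)\s*;(.*?)end\s*;", clean,
                  re.IGNORECASE | re.DOTALL)
    if not m:
        raise NexusParseError("no DATA/CHARACTERS block found")
    block = m.group(1)

    dims = re.search(r"dimensions([^;]*);", block, re.IGNORECASE)
    ntax = nchar = None
    if dims:
        mt = re.search(r"ntax\s*=\s*(\d+)", dims.group(1), re.IGNORECASE)
        mc = re.search(r"nchar\s*=\s*(\d+)", dims.group(1), re.IGNORECASE)
        ntax = int(mt.group(1)) if mt else None
        nchar = int(mc.group(1)) if mc else None

    missing, gap = "?", "-"
    fmt = re.search(r"format([^;]*);", block, re.IGNORECASE)
    if fmt:
        mm = re.search(r"missing\s*=\s*(\S)", fmt.group(1), re.IGNORECASE)
        mg = re.search(r"gap\s*=\s*(\S)", fmt.group(1), re.IGNORECASE)
        if mm:
            missing = mm.group(1)
        if mg:
            gap = mg.group(1)

    mmat = re.search(r"matrix(.*?);", block, re.IGNORECASE | re.DOTALL)
    if not mmat:
        raise NexusParseError("no MATRIX statement in character block")
    taxa: list[str] = []
    rows: list[list[Cell]] = []
    base_line = text[:text.lower().find("matrix")].count("\n") + 1
    for off, line in enumerate(mmat.group(1).splitlines()):
        line = line.strip()
        if not line:
            continue
        lm = re.match(r"('(?:[^']|'')*'|\S+)\s+(.*)", line)
        if not lm:
            raise NexusParseError(f"line {base_line + off}: cannot parse row {line!r}")
        label = lm.group(1)
        if label.startswith("'"):
            label = label[1:-1].replace("''", "'")
        taxa.append(label)
        rows.append(_parse_cell_token(lm.group(2), base_line + off, missing, gap))

    if ntax is not None and len(taxa) != ntax:
        raise NexusParseError(f"NTAX={ntax} but matrix has {len(taxa)} rows")
    n_char = len(rows[0])
    for label, row in zip(taxa, rows):
        if len(row) != n_char:
            raise NexusParseError(f"row {label!r} has {len(row)} cells, expected {n_char}")
    if nchar is not None and n_char != nchar:
        raise NexusParseError(f"NCHAR={nchar} but rows have {n_char} cells")

    ordered_idx: list[int] | None = None
    if ordered is not None:
        ordered_idx = list(ordered)
    elif sidecar is not None:
        cfg = read_config(sidecar)
        if "ordered" in cfg:
            ordered_idx = _parse_ranges(cfg["ordered"])
    else:
        ma = re.search(r"begin\s+assumptions\s*;(.*?)end\s*;", clean,
                       re.IGNORECASE | re.DOTALL)
        if ma:
            ordered_idx = []
            for mts in re.finditer(r"typeset[^;]*?=\s*([^;]*);", ma.group(0),
                                   re.IGNORECASE):
                for part in mts.group(1).split(","):
                    if ":" in part:
                        kind, spec = part.split(":", 1)
                        if kind.strip().lower() in ("ord", "ordered"):
                            ordered_idx.extend(_parse_ranges(spec))
    flags = [False] * n_char
    for j in ordered_idx or []:
        flags[j] = True
    return CharacterMatrix(taxa, rows, flags)


def write_nexus_matrix(matrix: CharacterMatrix, path) -> None:
    """Write a matrix (raw cells) plus an ASSUMPTIONS ordering block."""
    def cell_str(cell: Cell) -> str:
        if cell.kind == MISSING:
            return "?"
        if cell.kind == GAP:
            return "-"
        if cell.kind == STATE:
            return SYMBOLS[cell.states[0]]
        return "(" + "".join(SYMBOLS[s] for s in cell.states) + ")"

    width = max(len(t) for t in matrix.taxa) + 2
    lines = ["#NEXUS", "", "BEGIN DATA;",
             f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};",
             "  FORMAT DATATYPE=STANDARD SYMBOLS=\"0123456789\" MISSING=? GAP=-;",
             "  MATRIX"]
    for taxon, row in zip(matrix.taxa, matrix.cells):
        label = taxon if not re.search(r"\s", taxon) else f"'{taxon}'"
        lines.append(f"    {label:<{width}}" + "".join(cell_str(c) for c in row))
    lines.append("  ;")
    lines.append("END;")
    ordered = [str(j + 1) for j, f in enumerate(matrix.ordered_flags) if f]
    unordered = [str(j + 1) for j, f in enumerate(matrix.ordered_flags) if not f]
    lines.append("")
    lines.append("BEGIN ASSUMPTIONS;")
    parts = []
    if ordered:
        parts.append("ord: " + " ".join(ordered))
    if unordered:
        parts.append("unord: " + " ".join(unordered))
    lines.append("  TYPESET * default = " + ", ".join(parts) + ";")
    lines.append("END;")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# recoding
# ---------------------------------------------------------------------------

def recode_polymorphisms(matrix: CharacterMatrix,
                         fixed_k: int | None = None) -> CharacterMatrix:
    """Recode each character onto its final state space.

    Ordered characters get a morphocline covering every integer state from
    the smallest to the largest observed, with each observed adjacent-state
    polymorphism inserted as its own intermediate position.  A polymorphism
    spanning non-adjacent states becomes an ambiguity set over the spanned
    recoded positions.  Unordered characters map observed states onto
    0..k-1 and keep polymorphisms as ambiguity sets.  Missing and gap cells
    become ``None`` (full ambiguity).  Returns the same matrix object with
    ``recoded`` and ``char_meta`` populated.

    By default the state space of each character is spanned by its observed
    states; ``fixed_k`` instead forces every character onto the fixed range
    0..fixed_k-1 (useful when the maximum state count is known a priori and
    for likelihood computations over enumerated patterns).
    """
    metas: list[CharacterMeta] = []
    recoded: list[list] = [[] for _ in matrix.taxa]
    for j in range(matrix.n_char):
        column = matrix.column(j)
        ordered = matrix.ordered_flags[j]
        observed: set[int] = set()
        polys: set[tuple[int, ...]] = set()
        for cell in column:
            if cell.kind == STATE:
                observed.add(cell.states[0])
            elif cell.kind == POLY:
                observed.update(cell.states)
                polys.add(cell.states)
        if not observed:
            observed = {0}
        if fixed_k is not None:
            if max(observed) >= fixed_k:
                raise ValueError(f"character {j}: observed state "
                                 f"{max(observed)} outside fixed_k={fixed_k}")
            observed = set(range(fixed_k))
        meta = CharacterMeta(ordered=ordered)
        if ordered:
            lo, hi = min(observed), max(observed)
            adjacent = {p for p in polys if len(p) == 2 and p[1] == p[0] + 1}
            for s in range(lo, hi + 1):
                meta.positions.append(("fixed", s))
                if (s, s + 1) in adjacent:
                    meta.positions.append(("poly", (s, s + 1)))
            index = {pos: i for i, pos in enumerate(meta.positions)}
            for i, cell in enumerate(column):
                if cell.kind in (MISSING, GAP):
                    recoded[i].append(None)
                elif cell.kind == STATE:
                    recoded[i].append(index[("fixed", cell.states[0])])
                elif cell.states in adjacent:
                    recoded[i].append(index[("poly", cell.states)])
                else:
                    a, b = min(cell.states), max(cell.states)
                    span = range(index[("fixed", a)], index[("fixed", b)] + 1)
                    recoded[i].append(frozenset(span))
        else:
            states = sorted(observed)
            index = {s: i for i, s in enumerate(states)}
            meta.positions = [("fixed", s) for s in states]
            for i, cell in enumerate(column):
                if cell.kind in (MISSING, GAP):
                    recoded[i].append(None)
                elif cell.kind == STATE:
                    recoded[i].append(index[cell.states[0]])
                else:
                    recoded[i].append(frozenset(index[s] for s in cell.states))
        metas.append(meta)
    matrix.char_meta = metas
    matrix.recoded = recoded
    classify_characters(matrix)
    return matrix


# ---------------------------------------------------------------------------
# step matrices
# ---------------------------------------------------------------------------

@dataclass
class StepMatrix:
    """Symmetric step costs between recoded states of one character."""

    cost: np.ndarray
    scheme: str

    def __post_init__(self):
        c = np.asarray(self.cost, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("cost must be square")
        if not np.allclose(c, c.T):
            raise ValueError("cost must be symmetric")
        if np.any(np.diagonal(c) != 0):
            raise ValueError("diagonal must be zero")
        self.cost = c


def build_step_matrix(meta: CharacterMeta, scheme: str = "equal") -> StepMatrix:
    """Step costs over a character's recoded state space.

    equal: every adjacent move on the morphocline costs 1 (so fixed to
    next-fixed costs 2 when a polymorphic intermediate intervenes);
    half_step: moves into/out of a polymorphic intermediate cost 0.5, so a
    fixed-to-next-fixed transition totals 1.  Unordered characters cost 1
    between any two distinct states under either scheme.
    """
    if scheme not in ("equal", "half_step"):
        raise ValueError(f"unknown scheme {scheme!r}")
    k = meta.n_states
    if not meta.ordered:
        cost = 1.0 - np.eye(k)
        return StepMatrix(cost, scheme)
    adj = np.zeros(max(k - 1, 0))
    for i in range(k - 1):
        if scheme == "half_step" and (meta.is_poly_position(i)
                                      or meta.is_poly_position(i + 1)):
            adj[i] = 0.5
        else:
            adj[i] = 1.0
    cum = np.concatenate([[0.0], np.cumsum(adj)])
    cost = np.abs(cum[:, None] - cum[None, :])
    return StepMatrix(cost, scheme)


# ---------------------------------------------------------------------------
# character classification
# ---------------------------------------------------------------------------

def classify_characters(matrix: CharacterMatrix) -> dict:
    """Classify each recoded character as constant / variable / informative.

    A character is parsimony-informative iff at least two recoded states
    each occur in at least two taxa; cells that are not a single determinate
    state (missing, gap, ambiguity sets) are ignored for the tally.
    """
    if not matrix.is_recoded:
        raise ValueError("recode the matrix first")
    classes: list[str] = []
    for j, meta in enumerate(matrix.char_meta):
        counts: dict[int, int] = {}
        for cell in matrix.recoded_column(j):
            if isinstance(cell, (int, np.integer)):
                counts[cell] = counts.get(cell, 0) + 1
        distinct = len(counts)
        if distinct <= 1:
            cls = "constant"
        elif sum(1 for c in counts.values() if c >= 2) >= 2:
            cls = "informative"
        else:
            cls = "variable"
        meta.informative = cls == "informative"
        classes.append(cls)
    summary = {
        "classes": classes,
        "n_constant": classes.count("constant"),
        "n_variable": classes.count("variable"),
        "n_informative": classes.count("informative"),
        "n_total": len(classes),
    }
    matrix.classification = summary
    return summary


# ---------------------------------------------------------------------------
# calibrations, traits, locality maps, configs
# ---------------------------------------------------------------------------

class CalibrationTable:
    """Per-tip age constraints: a uniform window or a fixed age, in Ma."""

    def __init__(self, entries: dict[str, dict]):
        for tip, entry in entries.items():
            kind = entry.get("kind")
            if kind == "uniform":
                if not (0 <= entry["min_age"] <= entry["max_age"]):
                    raise ValueError(f"{tip}: bad window "
                                     f"[{entry['min_age']}, {entry['max_age']}]")
            elif kind == "fixed":
                if entry["fixed_age"] < 0:
                    raise ValueError(f"{tip}: negative fixed age")
            else:
                raise ValueError(f"{tip}: unknown kind {kind!r}")
        self.entries = dict(entries)

    def __getitem__(self, tip: str) -> dict:
        return self.entries[tip]

    def __contains__(self, tip: str) -> bool:
        return tip in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def tips(self) -> list[str]:
        return list(self.entries)

    def bounds(self, tip: str) -> tuple[float, float]:
        e = self.entries[tip]
        if e["kind"] == "fixed":
            return e["fixed_age"], e["fixed_age"]
        return e["min_age"], e["max_age"]

    def locality(self, tip: str) -> str | None:
        return self.entries[tip].get("locality")

    def validate_tips(self, taxa: list[str]) -> None:
        unknown = sorted(set(self.entries) - set(taxa))
        if unknown:
            raise ValueError(f"calibrations name unknown tips: {unknown}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, CalibrationTable):
            return NotImplemented
        if set(self.entries) != set(other.entries):
            return False
        for tip, e in self.entries.items():
            o = other.entries[tip]
            if e["kind"] != o["kind"] or e.get("locality") != o.get("locality"):
                return False
            for k in ("min_age", "max_age", "fixed_age"):
                a, b = e.get(k), o.get(k)
                if (a is None) != (b is None):
                    return False
                if a is not None and abs(a - b) > 1e-9:
                    return False
        return True


def read_calibrations(path) -> CalibrationTable:
    df = pd.read_csv(path, sep="\t", dtype={"tip": str, "kind": str,
                                            "locality": str})
    entries = {}
    for _, row in df.iterrows():
        entry: dict = {"kind": row["kind"],
                       "locality": row.get("locality") if pd.notna(row.get("locality")) else None}
        if row["kind"] == "uniform":
            entry["min_age"] = float(row["min_age"])
            entry["max_age"] = float(row["max_age"])
            if entry["min_age"] == entry["max_age"]:
                entry = {"kind": "fixed", "fixed_age": entry["min_age"],
                         "locality": entry["locality"]}
        else:
            entry["fixed_age"] = float(row["fixed_age"])
        entries[row["tip"]] = entry
    return CalibrationTable(entries)


def write_calibrations(table: CalibrationTable, path) -> None:
    rows = []
    for tip, e in table.entries.items():
        rows.append({"tip": tip, "kind": e["kind"],
                     "min_age": e.get("min_age", ""),
                     "max_age": e.get("max_age", ""),
                     "fixed_age": e.get("fixed_age", ""),
                     "locality": e.get("locality") or ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9f")


def read_traits(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    taxon_col, value_col = df.columns[0], df.columns[1]
    return dict(zip(df[taxon_col].astype(str), df[value_col].astype(float)))


def write_traits(traits: dict[str, float], path,
                 value_name: str = "ln_m1_area") -> None:
    pd.DataFrame({"taxon": list(traits), value_name: list(traits.values())}
                 ).to_csv(path, sep="\t", index=False, float_format="%.9f")


def read_locality_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df[df.columns[0]].astype(str), df[df.columns[1]].astype(str)))


def write_locality_map(mapping: dict[str, str], path) -> None:
    pd.DataFrame({"tip": list(mapping), "locality": list(mapping.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` run-configuration file; '#' starts a comment."""
    out: dict[str, str] = {}
    for line in open(path):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {line!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out
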