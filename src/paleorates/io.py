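"""Domain types and file formats.

The stratigraphic scaffold (:class:`TimeBin`, :class:`TaxonRange`), the
discrete character matrix, and readers/writers for the standard formats the
pipeline touches: NEXUS (matrix and trees), Newick, and CSV tables for time
bins and taxon ranges.  Everything downstream consumes the validated objects
built here; no other module re-parses text.

Conventions
-----------
* Ages are Ma before present (larger = older); durations are Myr.
* A bin is the half-open interval ``[older, younger)`` on the age axis: an
  event exactly at a bin's older bound belongs to that bin, one at the
  younger bound belongs to the next (younger) bin.
* Missing ``?`` and inapplicable ``-`` matrix cells are both treated as full
  ambiguity — every meaningful state of that character is possible.  The
  source analyses this pipeline serves do not distinguish the two, and full
  ambiguity is the conservative reading for unambiguous-change counting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence, Union

import dendropy
import pandas as pd

from .trees import Node, Tree


class ValidationError(ValueError):
    """Input fails a domain invariant."""


# ---------------------------------------------------------------------------
# Time bins
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TimeBin:
    """A named stratigraphic interval with bounds in Ma (older > younger)."""

    name: str
    older: float
    younger: float

    def __post_init__(self):
        if not (self.older > self.younger >= 0):
            raise ValidationError(
                f"bin {self.name!r}: need older > younger >= 0, got "
                f"({self.older}, {self.younger})"
            )

    @property
    def length(self) -> float:
        return self.older - self.younger

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.older + self.younger)

    def contains(self, age: float) -> bool:
        """Half-open containment: ``younger < age <= older``."""
        return self.younger < age <= self.older


class BinTable:
    """An ordered (old -> young), non-overlapping collection of time bins."""

    def __init__(self, bins: Iterable[TimeBin]):
        bins = sorted(bins, key=lambda b: -b.older)
        if not bins:
            raise ValidationError("empty bin table")
        for a, b in zip(bins, bins[1:]):
            if b.older > a.younger + 1e-9:
                raise ValidationError(
                    f"bins {a.name!r} and {b.name!r} overlap "
                    f"({a.older}-{a.younger} vs {b.older}-{b.younger})"
                )
        names = [b.name for b in bins]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate bin names")
        self.bins: list[TimeBin] = bins
        self._by_name = {b.name: b for b in bins}

    def __iter__(self):
        return iter(self.bins)

    def __len__(self):
        return len(self.bins)

    def __getitem__(self, name: str) -> TimeBin:
        try:
            return self._by_name[name]
        except KeyError:
            raise ValidationError(f"unknown bin name {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def index(self, name: str) -> int:
        return self.bins.index(self[name])

    @property
    def oldest(self) -> float:
        return self.bins[0].older

    @property
    def youngest(self) -> float:
        return self.bins[-1].younger

    @property
    def mean_length(self) -> float:
        return sum(b.length for b in self.bins) / len(self.bins)

    def bin_containing(self, age: float) -> TimeBin:
        for b in self.bins:
            if b.contains(age):
                return b
        raise ValidationError(f"age {age} Ma falls in no bin")


def default_bins() -> BinTable:
    """Cretaceous ICS stages plus Cenozoic NALMAs, packaged as a default.

    These standard published bounds stand in for the stage/NALMA scaffold a
    user would normally supply; override with :func:`read_bins`.
    """
    with resources.files(__package__).joinpath("data/bins_default.csv").open() as fh:
        return _bins_from_frame(pd.read_csv(fh))


# ---------------------------------------------------------------------------
# Taxon ranges
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TaxonRange:
    """First/last appearance bins of one taxon (FAD not younger than LAD)."""

    taxon: str
    fad_bin: str
    lad_bin: str


class RangeTable:
    """Per-taxon stratigraphic ranges, validated against a bin table."""

    def __init__(self, ranges: Iterable[TaxonRange], bins: BinTable):
        self.bins = bins
        self.ranges: dict[str, TaxonRange] = {}
        errors = []
        for r in ranges:
            if r.taxon in self.ranges:
                errors.append(f"duplicate range row for taxon {r.taxon!r}")
                continue
            for bname in (r.fad_bin, r.lad_bin):
                if bname not in bins:
                    errors.append(f"taxon {r.taxon!r}: unknown bin {bname!r}")
            if r.fad_bin in bins and r.lad_bin in bins:
                if bins.index(r.fad_bin) > bins.index(r.lad_bin):
                    errors.append(
                        f"taxon {r.taxon!r}: FAD bin {r.fad_bin!r} is younger "
                        f"than LAD bin {r.lad_bin!r}"
                    )
            self.ranges[r.taxon] = r
        if errors:
            raise ValidationError("; ".join(errors))

    def __getitem__(self, taxon: str) -> TaxonRange:
        try:
            return self.ranges[taxon]
        except KeyError:
            raise ValidationError(f"no range row for taxon {taxon!r}") from None

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.ranges

    def __iter__(self):
        return iter(self.ranges.values())

    def __len__(self):
        return len(self.ranges)

    @property
    def taxa(self) -> list[str]:
        return list(self.ranges)

    def duration_bins(self, taxon: str) -> int:
        """Range length in bins (FAD bin through LAD bin, inclusive)."""
        r = self[taxon]
        return self.bins.index(r.lad_bin) - self.bins.index(r.fad_bin) + 1

    def check_covers(self, taxa: Iterable[str]) -> None:
        missing = [t for t in taxa if t not in self.ranges]
        if missing:
            raise ValidationError(f"taxa missing from range table: {sorted(missing)}")


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------
StateSet = Optional[frozenset]  # None == missing/inapplicable == full ambiguity


class CharacterMatrix:
    """Taxa x discrete characters, with per-character ordering and weights.

    ``states[i][j]`` is a frozenset of small non-negative ints (usually a
    singleton; polymorphic observations allowed) or ``None`` for missing or
    inapplicable, both read as full ambiguity.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        states: Sequence[Sequence[StateSet]],
        ordered: Optional[Sequence[bool]] = None,
        weights: Optional[Sequence[float]] = None,
    ):
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon labels in matrix")
        self.states = [list(row) for row in states]
        if len(self.states) != len(self.taxa):
            raise ValidationError(
                f"matrix has {len(self.states)} rows for {len(self.taxa)} taxa"
            )
        ncols = {len(row) for row in self.states}
        if len(ncols) > 1:
            raise ValidationError("matrix is not rectangular")
        self.nchar = ncols.pop() if ncols else 0
        self.ordered = list(ordered) if ordered is not None else [False] * self.nchar
        self.weights = [float(w) for w in weights] if weights is not None else [1.0] * self.nchar
        if len(self.ordered) != self.nchar or len(self.weights) != self.nchar:
            raise ValidationError("ordering/weight vectors do not match character count")
        if any(w <= 0 for w in self.weights):
            raise ValidationError("character weights must be positive")
        self._row = {t: i for i, t in enumerate(self.taxa)}

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    def observed_states(self, j: int) -> list[int]:
        obs = set()
        for row in self.states:
            if row[j] is not None:
                obs |= row[j]
        return sorted(obs)

    def state_space(self, j: int) -> list[int]:
        """Meaningful states: observed set (unordered) or the consecutive
        integer range spanning the observations (ordered)."""
        obs = self.observed_states(j)
        if not obs:
            return []
        if self.ordered[j]:
            return list(range(obs[0], obs[-1] + 1))
        return obs

    def tip_state_set(self, taxon: str, j: int) -> frozenset:
        """Tip state set with missing/inapplicable expanded to full ambiguity."""
        s = self.states[self._row[taxon]][j]
        if s is None:
            return frozenset(self.state_space(j))
        return s

    def check_taxa_match(self, labels: Iterable[str]) -> None:
        labels = set(labels)
        mine = set(self.taxa)
        problems = []
        if labels - mine:
            problems.append(f"in tree but not matrix: {sorted(labels - mine)}")
        if mine - labels:
            problems.append(f"in matrix but not tree: {sorted(mine - labels)}")
        if problems:
            raise ValidationError("; ".join(problems))


# ---------------------------------------------------------------------------
# NEXUS matrix reading/writing
# ---------------------------------------------------------------------------
def read_nexus_matrix(path: str) -> CharacterMatrix:
    """Read a NEXUS CHARACTERS/DATA block into a :class:`CharacterMatrix`.

    Ordering flags come from an ASSUMPTIONS ``TYPESET`` (``ord``/``unord``)
    and weights from a ``WTSET``; both default to unordered, weight 1.
    """
    try:
        ds = dendropy.DataSet.get(path=path, schema="nexus")
    except Exception as exc:  # dendropy raises rich, line-numbered errors
        raise ValidationError(f"malformed NEXUS in {path}: {exc}") from exc
    mats = list(ds.char_matrices)
    if not mats:
        raise ValidationError(f"{path}: no CHARACTERS/DATA block found")
    mat = mats[0]
    taxa = [t.label for t in mat.taxon_namespace]
    states: list[list[StateSet]] = []
    for t in mat.taxon_namespace:
        seq = mat[t]
        row: list[StateSet] = []
        for cell in seq:
            sym = cell.symbol
            if cell.is_gap_state or sym in ("?", "-"):
                row.append(None)  # missing / inapplicable -> full ambiguity
            elif cell.is_fundamental_state:
                row.append(frozenset([int(sym)]))
            else:  # polymorphic / uncertain
                members = frozenset(
                    int(m.symbol) for m in (cell.member_states or [])
                    if m.symbol not in ("?", "-")
                )
                row.append(members if members else None)
        states.append(row)
    nchar = len(states[0]) if states else 0

    # dendropy tolerates dimension mismatches; enforce the declaration
    with open(path) as fh:
        text = fh.read()
    m = re.search(r"dimensions[^;]*ntax\s*=\s*(\d+)", text, re.IGNORECASE)
    if m and int(m.group(1)) != len(taxa):
        raise ValidationError(
            f"{path}: DIMENSIONS declares NTAX={m.group(1)} but the matrix "
            f"holds {len(taxa)} taxa"
        )
    m = re.search(r"dimensions[^;]*nchar\s*=\s*(\d+)", text, re.IGNORECASE)
    if m and int(m.group(1)) != nchar:
        raise ValidationError(
            f"{path}: DIMENSIONS declares NCHAR={m.group(1)} but rows hold "
            f"{nchar} characters"
        )

    ordered, weights = _parse_assumptions(path, nchar)
    return CharacterMatrix(taxa, states, ordered, weights)


def _parse_index_list(index_text: str, nchar: int) -> list[int]:
    """Parse a NEXUS character-index list like ``1 3-5`` (1-based) to 0-based."""
    out: list[int] = []
    for tok in index_text.replace(",", " ").split():
        if tok.lower() == "all" or tok == ".":
            out.extend(range(nchar))
        elif "-" in tok:
            a, b = tok.split("-")
            b = nchar if b == "." else int(b)
            out.extend(range(int(a) - 1, b))
        else:
            out.append(int(tok) - 1)
    bad = [i + 1 for i in out if not 0 <= i < nchar]
    if bad:
        raise ValidationError(f"character indices out of range: {bad}")
    return out


def _parse_assumptions(path: str, nchar: int) -> tuple[list[bool], list[float]]:
    """Scan raw NEXUS text for TYPESET (ord/unord) and WTSET commands.

    dendropy does not expose these; the syntax is simple enough to scan for
    directly.  Unmentioned characters default to unordered, weight 1.
    """
    with open(path) as fh:
        text = fh.read()
    text = re.sub(r"\[[^\]]*\]", " ", text)  # strip comments
    ordered = [False] * nchar
    weights = [1.0] * nchar
    for m in re.finditer(r"typeset\b[^=]*=\s*([^;]+);", text, re.IGNORECASE):
        for part in m.group(1).split(","):
            if ":" not in part:
                continue
            kind, idx = part.split(":", 1)
            kind = kind.strip().lower()
            flag = kind in ("ord", "ordered")
            for i in _parse_index_list(idx, nchar):
                ordered[i] = flag
    for m in re.finditer(r"wtset\b[^=]*=\s*([^;]+);", text, re.IGNORECASE):
        for part in m.group(1).split(","):
            if ":" not in part:
                continue
            w, idx = part.split(":", 1)
            for i in _parse_index_list(idx, nchar):
                weights[i] = float(w)
    return ordered, weights


def write_nexus_matrix(matrix: CharacterMatrix, path: str) -> None:
    """Write a matrix (with TYPESET/WTSET assumptions) that round-trips."""
    symbols = sorted({s for j in range(matrix.nchar) for s in matrix.observed_states(j)})
    sym_str = " ".join(str(s) for s in symbols) if symbols else "0 1"
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.ntax} NCHAR={matrix.nchar};",
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{sym_str}" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    width = max((len(t) for t in matrix.taxa), default=1) + 2
    for i, taxon in enumerate(matrix.taxa):
        cells = []
        for s in matrix.states[i]:
            if s is None:
                cells.append("?")
            elif len(s) == 1:
                cells.append(str(next(iter(s))))
            else:
                cells.append("(" + "".join(str(x) for x in sorted(s)) + ")")
        lines.append(f"    {_nexus_label(taxon):<{width}}" + "".join(cells))
    lines += ["    ;", "END;", "", "BEGIN ASSUMPTIONS;"]
    ords = [str(j + 1) for j in range(matrix.nchar) if matrix.ordered[j]]
    unords = [str(j + 1) for j in range(matrix.nchar) if not matrix.ordered[j]]
    parts = []
    if ords:
        parts.append("ord: " + " ".join(ords))
    if unords:
        parts.append("unord: " + " ".join(unords))
    if parts:
        lines.append("    TYPESET * default = " + ", ".join(parts) + ";")
    wparts = {}
    for j, w in enumerate(matrix.weights):
        wparts.setdefault(w, []).append(str(j + 1))
    if set(wparts) != {1.0}:
        lines.append(
            "    WTSET * default = "
            + ", ".join(f"{_fmt_weight(w)}: {' '.join(ix)}" for w, ix in wparts.items())
            + ";"
        )
    lines += ["END;", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _fmt_weight(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(w)


def _nexus_label(label: str) -> str:
    if re.search(r"[\s()\[\]{}/\\,;:=*'\"`<>]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------
def read_trees(path: str) -> list[Tree]:
    """Read rooted trees from a Newick file or a NEXUS TREES block.

    Polytomies are preserved.  Trees explicitly flagged unrooted (``[&U]``)
    are rejected with instructions to root them first; tip labels must be
    unique within each tree.
    """
    with open(path) as fh:
        head = fh.read(1024)
    schema = "nexus" if head.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tl = dendropy.TreeList.get(path=path, schema=schema,
                                   rooting="default-rooted",
                                   preserve_underscores=True)
    except Exception as exc:
        raise ValidationError(f"could not parse trees in {path}: {exc}") from exc
    if not tl:
        raise ValidationError(f"{path}: no trees found")
    out = []
    for i, dtree in enumerate(tl):
        if dtree.is_rooted is False:
            raise ValidationError(
                f"{path}: tree {i + 1} is unrooted; root it (e.g. on the "
                f"outgroup) before time-scaling"
            )
        out.append(_from_dendropy(dtree, where=f"{path} tree {i + 1}"))
    return out


def _from_dendropy(dtree: "dendropy.Tree", where: str = "") -> Tree:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        return Node(label)

    root_new = convert(dtree.seed_node)
    stack = [(dtree.seed_node, root_new)]
    while stack:
        old, new = stack.pop()
        for c in old.child_nodes():
            cc = convert(c)
            new.add_child(cc)
            stack.append((c, cc))
    tree = Tree(root_new)
    labels = tree.leaf_labels
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"{where}: duplicate tip labels {dupes}")
    return tree


def write_trees(trees: Iterable[Tree], path: str, lengths: bool = True) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.newick(lengths=lengths) + "\n")


def read_dated_trees(path: str, youngest_age: float = 0.0) -> list[Tree]:
    """Read trees whose branch lengths are durations in Myr and convert to
    absolute node ages, anchoring the youngest tip at ``youngest_age`` Ma."""
    with open(path) as fh:
        head = fh.read(1024)
    schema = "nexus" if head.lstrip().upper().startswith("#NEXUS") else "newick"
    tl = dendropy.TreeList.get(path=path, schema=schema,
                               rooting="default-rooted",
                               preserve_underscores=True)
    out = []
    for i, dtree in enumerate(tl):
        depths: dict = {}
        for dnode in dtree.preorder_node_iter():
            if dnode.parent_node is None:
                depths[dnode] = 0.0
            else:
                el = dnode.edge.length
                if el is None:
                    raise ValidationError(
                        f"{path} tree {i + 1}: missing branch length; cannot "
                        "recover node ages"
                    )
                depths[dnode] = depths[dnode.parent_node] + el
        max_depth = max(depths.values())

        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon is not None else (dnode.label or None)
            node = Node(label, youngest_age + (max_depth - depths[dnode]))
            stack = [(dnode, node)]
            while stack:
                od, on = stack.pop()
                for c in od.child_nodes():
                    lab = c.taxon.label if c.taxon is not None else (c.label or None)
                    cc = Node(lab, youngest_age + (max_depth - depths[c]))
                    on.add_child(cc)
                    stack.append((c, cc))
            return node

        tree = Tree(convert(dtree.seed_node))
        labels = tree.leaf_labels
        if len(set(labels)) != len(labels):
            raise ValidationError(f"{path} tree {i + 1}: duplicate tip labels")
        tree.validate_ages()
        out.append(tree)
    return out


def parse_newick(text: str) -> Tree:
    """Parse a single Newick string (convenience for tests/examples)."""
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              rooting="default-rooted",
                              preserve_underscores=True)
    return _from_dendropy(dtree, where="<string>")


# ---------------------------------------------------------------------------
# Bin / range CSVs
# ---------------------------------------------------------------------------
def _bins_from_frame(df: pd.DataFrame) -> BinTable:
    need = {"name", "older", "younger"}
    if not need <= set(df.columns):
        raise ValidationError(f"bin table needs columns {sorted(need)}, got {list(df.columns)}")
    return BinTable(
        TimeBin(str(r["name"]), float(r["older"]), float(r["younger"]))
        for _, r in df.iterrows()
    )


def read_bins(path: str) -> BinTable:
    return _bins_from_frame(pd.read_csv(path))


def write_bins(bins: BinTable, path: str) -> None:
    pd.DataFrame(
        [(b.name, b.older, b.younger) for b in bins],
        columns=["name", "older", "younger"],
    ).to_csv(path, index=False)


def read_ranges(path: str, bins: BinTable) -> RangeTable:
    df = pd.read_csv(path)
    need = {"taxon", "fad_bin", "lad_bin"}
    if not need <= set(df.columns):
        raise ValidationError(f"range table needs columns {sorted(need)}, got {list(df.columns)}")
    return RangeTable(
        (TaxonRange(str(r["taxon"]), str(r["fad_bin"]), str(r["lad_bin"]))
         for _, r in df.iterrows()),
        bins,
    )


def write_ranges(ranges: RangeTable, path: str) -> None:
    pd.DataFrame(
        [(r.taxon, r.fad_bin, r.lad_bin) for r in ranges],
        columns=["taxon", "fad_bin", "lad_bin"],
    ).to_csv(path, index=False)
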