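"""Reading and writing matrices, trees, manifests and result tables.

The NEXUS support is a pragmatic subset covering the dialects of
published morphological matrices: DATA/CHARACTERS, TAXA and
ASSUMPTIONS/SETS blocks, single-line or interleaved MATRIX rows, digit
state symbols 0-9, ``?`` and ``-`` both read as missing, and
polymorphism written ``(01)`` or ``{01}``.  Character ordering is
recovered from TYPESET ``ord``/``unord`` entries; partitions come from
two named charsets that must disjointly cover all characters.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .characters import (
    HARD,
    MISSING,
    ORDERED,
    SOFT,
    UNORDERED,
    CharacterColumn,
    CharacterMatrix,
)
from .errors import ParseError, ValidationError
from .trees import PhyloTree

_NA = "NA"


# ---------------------------------------------------------------------------
# NEXUS reading
# ---------------------------------------------------------------------------

def _strip_comments(text: str) -> str:
    """Remove [...] comments, preserving newlines for line numbering."""
    out = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            if depth > 0:
                depth -= 1
            else:
                out.append(ch)
        elif depth == 0 or ch == "\n":
            out.append(ch)
    return "".join(out)


def _blocks(text: str):
    """Yield (name, body, start_line) for each BEGIN ... END; block."""
    pattern = re.compile(
        r"begin\s+(\w+)\s*;(.*?)end\s*;", re.IGNORECASE | re.DOTALL
    )
    for m in pattern.finditer(text):
        start_line = text[: m.start()].count("\n") + 1
        yield m.group(1).lower(), m.group(2), start_line


def _parse_ranges(spec: str, n_char: int, line: int) -> list:
    """NEXUS 1-based character lists: ``1-5 7 9-.`` -> 0-based indices."""
    out = []
    for tok in spec.replace(",", " ").split():
        m = re.fullmatch(r"(\d+)(?:-(\d+|\.))?", tok)
        if not m:
            raise ParseError(f"bad character list token {tok!r}", line)
        a = int(m.group(1))
        b = m.group(2)
        if b is None:
            b = a
        elif b == ".":
            b = n_char
        else:
            b = int(b)
        if not (1 <= a <= b <= n_char):
            raise ParseError(
                f"character range {tok!r} outside 1..{n_char}", line
            )
        out.extend(range(a - 1, b))
    return out


def _parse_cells(s: str, missing: str, gap: str, line: int) -> list:
    cells = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch.isspace():
            i += 1
            continue
        if ch in (missing, gap):
            cells.append(MISSING)
            i += 1
        elif ch.isdigit():
            cells.append(frozenset((int(ch),)))
            i += 1
        elif ch in "({":
            close = ")" if ch == "(" else "}"
            j = s.find(close, i)
            if j < 0:
                raise ParseError(f"unclosed polymorphism {s[i:]!r}", line)
            states = frozenset(
                int(c) for c in s[i + 1 : j] if c.isdigit()
            )
            if len(states) < 2:
                raise ParseError(
                    f"polymorphic set {s[i:j+1]!r} needs >= 2 states", line
                )
            cells.append(states)
            i = j + 1
        else:
            raise ParseError(f"unexpected state symbol {ch!r}", line)
    return cells


def read_nexus_matrix(
    path,
    partition_spec: dict | None = None,
    partition_labels: Sequence[str] | None = None,
    dataset_id: str = "",
    clade: str = "",
) -> CharacterMatrix:
    """Read a morphological character matrix with its partition.

    ``partition_spec`` maps the labels ``hard`` and ``soft`` to charset
    names (default: charsets literally named ``hard`` and ``soft``).
    Alternatively per-character ``partition_labels`` may be supplied
    directly, in which case charsets are ignored.  Ordering flags are
    read from TYPESET ``ord``/``unord`` entries when present, else all
    characters are unordered.
    """
    raw = Path(path).read_text()
    text = _strip_comments(raw)
    blocks = {name: (body, ln) for name, body, ln in _blocks(text)}
    data_key = "data" if "data" in blocks else "characters"
    if data_key not in blocks:
        raise ParseError("no DATA or CHARACTERS block found", 1)
    body, block_line = blocks[data_key]

    mdim = re.search(
        r"dimensions[^;]*ntax\s*=\s*(\d+)[^;]*nchar\s*=\s*(\d+)\s*;",
        body,
        re.IGNORECASE | re.DOTALL,
    )
    if not mdim:
        raise ParseError("DIMENSIONS with NTAX and NCHAR required", block_line)
    n_tax, n_char = int(mdim.group(1)), int(mdim.group(2))

    missing_sym, gap_sym = "?", "-"
    mfmt = re.search(r"format([^;]*);", body, re.IGNORECASE | re.DOTALL)
    if mfmt:
        fm = mfmt.group(1)
        m = re.search(r"missing\s*=\s*(\S)", fm, re.IGNORECASE)
        if m:
            missing_sym = m.group(1)
        m = re.search(r"gap\s*=\s*(\S)", fm, re.IGNORECASE)
        if m:
            gap_sym = m.group(1)

    mmat = re.search(r"matrix(.*?);", body, re.IGNORECASE | re.DOTALL)
    if not mmat:
        raise ParseError("no MATRIX command in data block", block_line)
    matrix_line0 = block_line + body[: mmat.start()].count("\n")

    taxa_order: list = []
    rows: dict = {}
    for off, line_text in enumerate(mmat.group(1).split("\n")):
        ln = matrix_line0 + off
        stripped = line_text.strip()
        if not stripped:
            continue
        m = re.match(r"('(?:[^']|'')+'|\S+)\s+(.*)", stripped)
        if not m:
            raise ParseError(f"cannot split row {stripped!r}", ln)
        label = m.group(1)
        if label.startswith("'"):
            label = label[1:-1].replace("''", "'")
        cells = _parse_cells(m.group(2), missing_sym, gap_sym, ln)
        if label not in rows:
            taxa_order.append(label)
            rows[label] = []
        rows[label].extend(cells)

    if len(taxa_order) != n_tax:
        raise ValidationError(
            f"matrix has {len(taxa_order)} taxa, DIMENSIONS says {n_tax}"
        )
    for label in taxa_order:
        if len(rows[label]) != n_char:
            raise ValidationError(
                f"taxon {label!r} has {len(rows[label])} characters, "
                f"DIMENSIONS says {n_char}"
            )

    # charsets and typesets may live in ASSUMPTIONS or SETS
    charsets: dict = {}
    ordering = [UNORDERED] * n_char
    for bname in ("assumptions", "sets"):
        if bname not in blocks:
            continue
        abody, aline = blocks[bname]
        for m in re.finditer(
            r"charset\s+(\S+)\s*=\s*([^;]+);", abody, re.IGNORECASE
        ):
            ln = aline + abody[: m.start()].count("\n")
            charsets[m.group(1).lower()] = _parse_ranges(
                m.group(2), n_char, ln
            )
        for m in re.finditer(
            r"typeset\s+\*?\s*\S+\s*=\s*([^;]+);", abody, re.IGNORECASE
        ):
            ln = aline + abody[: m.start()].count("\n")
            for part in m.group(1).split(","):
                pm = re.match(r"\s*(ord|unord)\s*:\s*(.*)", part,
                              re.IGNORECASE)
                if not pm:
                    continue
                flag = ORDERED if pm.group(1).lower() == "ord" else UNORDERED
                for j in _parse_ranges(pm.group(2), n_char, ln):
                    ordering[j] = flag

    if partition_labels is not None:
        partition = list(partition_labels)
        if len(partition) != n_char:
            raise ValidationError("partition_labels must cover every column")
    else:
        spec = partition_spec or {HARD: HARD, SOFT: SOFT}
        partition = [None] * n_char
        for label in (HARD, SOFT):
            name = spec.get(label, label).lower()
            if name not in charsets:
                raise ValidationError(
                    f"charset {name!r} (for the {label} partition) not found"
                )
            for j in charsets[name]:
                if partition[j] is not None:
                    raise ValidationError(
                        f"character {j + 1} assigned to both partitions"
                    )
                partition[j] = label
        uncovered = [j + 1 for j, p in enumerate(partition) if p is None]
        if uncovered:
            raise ValidationError(
                f"charsets do not cover characters {uncovered[:10]}"
            )

    columns = tuple(
        CharacterColumn(tuple(rows[t][j] for t in taxa_order))
        for j in range(n_char)
    )
    return CharacterMatrix(
        tuple(taxa_order), columns, tuple(ordering), tuple(partition),
        dataset_id=dataset_id, clade=clade,
    )


# ---------------------------------------------------------------------------
# NEXUS writing
# ---------------------------------------------------------------------------

def _format_cell(c) -> str:
    if c is MISSING:
        return "?"
    if len(c) == 1:
        return str(next(iter(c)))
    return "(" + "".join(str(s) for s in sorted(c)) + ")"


def _quote(label: str) -> str:
    if re.fullmatch(r"[\w.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _ranges_1based(indices) -> str:
    """Compact 1-based NEXUS list: [0,1,2,5] -> '1-3 6'."""
    out = []
    run = []
    for j in sorted(indices):
        if run and j == run[-1] + 1:
            run.append(j)
        else:
            if run:
                out.append(run)
            run = [j]
    if run:
        out.append(run)
    return " ".join(
        f"{r[0] + 1}" if len(r) == 1 else f"{r[0] + 1}-{r[-1] + 1}"
        for r in out
    )


def write_nexus_matrix(matrix: CharacterMatrix, path) -> None:
    """Write a matrix with its partition charsets and TYPESET."""
    lines = ["#NEXUS", "", "BEGIN DATA;"]
    lines.append(
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};"
    )
    lines.append("FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS=\"0123456789\";")
    lines.append("MATRIX")
    width = max(len(_quote(t)) for t in matrix.taxa) + 2
    for i, t in enumerate(matrix.taxa):
        row = "".join(
            _format_cell(col.cells[i]) for col in matrix.columns
        )
        lines.append(f"{_quote(t):<{width}}{row}")
    lines.append(";")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN ASSUMPTIONS;")
    hard = matrix.hard_indices
    soft = matrix.soft_indices
    if hard:
        lines.append(f"CHARSET hard = {_ranges_1based(hard)};")
    if soft:
        lines.append(f"CHARSET soft = {_ranges_1based(soft)};")
    ordered = [j for j, o in enumerate(matrix.ordering) if o == ORDERED]
    unordered = [j for j, o in enumerate(matrix.ordering) if o == UNORDERED]
    if ordered:
        parts = [f"ord: {_ranges_1based(ordered)}"]
        if unordered:
            parts.append(f"unord: {_ranges_1based(unordered)}")
        lines.append(f"TYPESET * default = {', '.join(parts)};")
    lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick_tree(path) -> PhyloTree:
    """Read one Newick tree; polytomies preserved, lengths kept but
    ignored by parsimony scoring."""
    return PhyloTree.from_file(path)


def write_newick_tree(tree: PhyloTree, path, lengths: bool = False) -> None:
    Path(path).write_text(tree.to_newick(lengths=lengths) + "\n")


def write_tree_set(trees: Iterable[PhyloTree], path) -> None:
    """Multi-tree Newick export (one topology per line)."""
    Path(path).write_text(
        "".join(t.to_newick() + "\n" for t in trees)
    )


# ---------------------------------------------------------------------------
# collection manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    dataset_id: str
    matrix_path: Path
    tree_path: Path | None
    clade: str


def read_manifest(path) -> tuple:
    """Tab-separated manifest: id, matrix path, tree path or '-', clade.

    Relative paths resolve against the manifest's directory.
    """
    base = Path(path).parent
    entries = []
    seen = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(
                f"manifest line needs 4 tab-separated fields, got {len(parts)}",
                lineno,
            )
        did, mpath, tpath, clade = (p.strip() for p in parts)
        if did in seen:
            raise ValidationError(f"duplicate dataset id {did!r}")
        seen.add(did)
        entries.append(
            ManifestEntry(
                did,
                (base / mpath).resolve(),
                None if tpath == "-" else (base / tpath).resolve(),
                clade,
            )
        )
    return tuple(entries)


def write_manifest(entries: Iterable[ManifestEntry], path) -> None:
    base = Path(path).parent
    lines = []
    for e in entries:
        tp = "-" if e.tree_path is None else _relpath(e.tree_path, base)
        lines.append(
            f"{e.dataset_id}\t{_relpath(e.matrix_path, base)}\t{tp}\t{e.clade}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _relpath(p: Path, base: Path) -> str:
    try:
        return str(Path(p).relative_to(base))
    except ValueError:
        return str(p)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

RESULT_FIELDS = (
    "dataset_id", "clade", "ild_p", "ird_p", "mww_p", "RI_hard", "RI_soft"
)


def _fmt(v) -> str:
    if v is None:
        return _NA
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_results(rows: Sequence[dict], out_dir, run_record: dict | None = None):
    """Write the per-dataset table and a machine-readable run record.

    ``rows`` are dicts with the :data:`RESULT_FIELDS` keys; ``None``
    values are emitted as ``NA``.  Returns the table path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join(RESULT_FIELDS)]
    for row in rows:
        lines.append("\t".join(_fmt(row.get(k)) for k in RESULT_FIELDS))
    table = out / "results.tsv"
    table.write_text("\n".join(lines) + "\n")
    if run_record is not None:
        (out / "run_record.json").write_text(
            json.dumps(run_record, indent=1, sort_keys=True, default=str)
            + "\n"
        )
    return table
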