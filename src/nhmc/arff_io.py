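"""Readers and writers for the ARFF dialect with a hierarchical class attribute.

The dialect is the CLUS-community interchange format for HMC datasets:

.. code-block:: text

    @RELATION example
    @ATTRIBUTE id string
    @ATTRIBUTE x1 numeric
    @ATTRIBUTE d1 {a,b,c}
    @ATTRIBUTE class hierarchical A,B,B/B1
    @DATA
    g1,0.41,a,B/B1@A
    g2,?,b,B

Exactly one ``hierarchical`` attribute declares the class hierarchy as
comma-separated slash paths (tree hierarchies; DAGs are declared in a
separate parent/child TSV and passed in explicitly).  Data rows list an
example's (possibly most-specific) classes ``@``-separated; labels are
ancestor-closed on load.  ``?`` marks a missing attribute value.  A
``string`` attribute named ``id``/``key``/``name`` provides example
identifiers; otherwise the row index is used.  ``%`` starts a comment.

Plain hand-rolled parsing is used deliberately: generic ARFF readers do not
understand the ``hierarchical`` attribute type.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data import HMCDataset
from .hierarchy import ClassHierarchy

__all__ = [
    "read_arff_hmc",
    "write_arff_hmc",
    "read_hierarchy_tsv",
    "write_hierarchy_tsv",
    "read_split_file",
    "write_scores_tsv",
    "read_scores_tsv",
]

_ID_NAMES = {"id", "key", "name"}


def _strip_comment(line: str) -> str:
    return line.split("%", 1)[0].rstrip("\n")


def read_arff_hmc(
    path, w0: float = 0.75, hierarchy: Optional[ClassHierarchy] = None
) -> tuple[HMCDataset, ClassHierarchy]:
    """Read an HMC dataset (and its hierarchy) from the ARFF dialect.

    ``hierarchy`` overrides the inline declaration (needed for DAG
    hierarchies, which slash paths cannot express); its class identifiers
    must cover every label used in the data section.
    """
    lines = Path(path).read_text().splitlines()
    attrs: list[tuple[str, str, Optional[list[str]]]] = []  # (name, kind, cats)
    class_paths: Optional[list[str]] = None
    class_col: Optional[int] = None
    id_col: Optional[int] = None
    data_start = None
    for lineno, raw in enumerate(lines):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@data"):
            data_start = lineno + 1
            break
        if low.startswith("@attribute"):
            rest = line[len("@attribute"):].strip()
            name, _, decl = rest.partition(" ")
            decl = decl.strip()
            if not name or not decl:
                raise ValueError(f"malformed attribute on line {lineno + 1}: {raw!r}")
            if any(name == a[0] for a in attrs):
                raise ValueError(f"duplicate attribute name {name!r} (line {lineno + 1})")
            dlow = decl.lower()
            if dlow.startswith("hierarchical"):
                if class_paths is not None:
                    raise ValueError("more than one hierarchical class attribute")
                class_paths = [p.strip() for p in decl[len("hierarchical"):].split(",") if p.strip()]
                class_col = len(attrs)
                attrs.append((name, "class", None))
            elif dlow in ("numeric", "real", "integer"):
                attrs.append((name, "continuous", None))
            elif decl.startswith("{") and decl.endswith("}"):
                cats = [c.strip() for c in decl[1:-1].split(",") if c.strip()]
                attrs.append((name, "discrete", cats))
            elif dlow == "string":
                if name.lower() in _ID_NAMES and id_col is None:
                    id_col = len(attrs)
                    attrs.append((name, "id", None))
                else:
                    attrs.append((name, "discrete", None))
            else:
                raise ValueError(f"unsupported attribute type on line {lineno + 1}: {decl!r}")
    if data_start is None:
        raise ValueError("no @DATA section found")
    if class_col is None:
        raise ValueError("no hierarchical class attribute declared")
    if hierarchy is None:
        if not class_paths:
            raise ValueError("empty hierarchical class declaration")
        hierarchy = ClassHierarchy.from_paths(class_paths, w0=w0)
    # accept both full paths and bare class identifiers in data rows
    ref_map = {c: c for c in hierarchy.classes}
    if class_paths:
        for p in class_paths:
            leaf = p.split("/")[-1]
            if leaf in hierarchy.index:
                ref_map.setdefault(p, leaf)

    ids: list[str] = []
    label_rows: list[np.ndarray] = []
    columns: dict[str, list] = {
        name: [] for name, kind, _ in attrs if kind in ("continuous", "discrete")
    }
    n_rows = 0
    for lineno in range(data_start, len(lines)):
        line = _strip_comment(lines[lineno]).strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != len(attrs):
            raise ValueError(
                f"row {lineno + 1}: expected {len(attrs)} fields, got {len(parts)}"
            )
        n_rows += 1
        for (name, kind, _cats), value in zip(attrs, parts):
            if kind == "id":
                ids.append(value)
            elif kind == "continuous":
                columns[name].append(np.nan if value == "?" else float(value))
            elif kind == "discrete":
                columns[name].append(None if value == "?" else value)
            else:  # class
                if value in ("?", ""):
                    refs: list[str] = []
                else:
                    refs = [r.strip() for r in value.split("@") if r.strip()]
                names = []
                for r in refs:
                    c = ref_map.get(r, ref_map.get(r.split("/")[-1]))
                    if c is None:
                        raise ValueError(
                            f"row {lineno + 1}: undeclared class {r!r}"
                        )
                    names.append(c)
                label_rows.append(hierarchy.close(names))
    if not ids:
        ids = [str(i) for i in range(n_rows)]
    X = pd.DataFrame(
        {
            name: (
                pd.array(columns[name], dtype=float)
                if kind == "continuous"
                else pd.array(columns[name], dtype=object)
            )
            for name, kind, _ in attrs
            if kind in ("continuous", "discrete")
        }
    )
    Y = np.vstack(label_rows) if label_rows else np.zeros((0, hierarchy.n_classes), np.uint8)
    ds = HMCDataset(X=X, Y=Y, ids=ids, hierarchy=hierarchy, name=Path(path).stem)
    return ds, hierarchy


def _hierarchy_paths(h: ClassHierarchy) -> list[str]:
    """Slash paths in declaration order (trees only)."""
    paths: dict[str, str] = {}
    out = []
    for c in h.classes:
        ps = h.parents[c]
        if len(ps) > 1:
            raise ValueError(
                "the ARFF dialect cannot express DAG hierarchies; "
                "write a parent/child TSV instead"
            )
        paths[c] = c if not ps else f"{paths[ps[0]]}/{c}"
        out.append(paths[c])
    return out


def write_arff_hmc(dataset: HMCDataset, path, relation: Optional[str] = None) -> None:
    """Write an HMC dataset in the ARFF dialect (labels as most-specific sets)."""
    h = dataset.hierarchy
    paths = _hierarchy_paths(h)
    lines = [f"@RELATION {relation or dataset.name}"]
    lines.append("@ATTRIBUTE id string")
    col_kinds: list[tuple[str, str]] = []
    for name in dataset.X.columns:
        s = dataset.X[name]
        if pd.api.types.is_numeric_dtype(s):
            lines.append(f"@ATTRIBUTE {name} numeric")
            col_kinds.append((name, "continuous"))
        else:
            cats = sorted({str(v) for v in s if not pd.isna(v)})
            lines.append(f"@ATTRIBUTE {name} {{{','.join(cats)}}}")
            col_kinds.append((name, "discrete"))
    lines.append(f"@ATTRIBUTE class hierarchical {','.join(paths)}")
    lines.append("@DATA")
    for i, ex_id in enumerate(dataset.ids):
        fields = [ex_id]
        for name, kind in col_kinds:
            v = dataset.X[name].iloc[i]
            if pd.isna(v):
                fields.append("?")
            elif kind == "continuous":
                fields.append(repr(float(v)))
            else:
                fields.append(str(v))
        specific = sorted(h.most_specific(dataset.Y[i]))
        fields.append("@".join(specific) if specific else "?")
        lines.append(",".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_hierarchy_tsv(path, w0: float = 0.75) -> ClassHierarchy:
    """Read a two-column parent<TAB>child file (``root`` = virtual root)."""
    pairs = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'parent<TAB>child', got {raw!r}")
        pairs.append((parts[0], parts[1]))
    return ClassHierarchy.from_parent_child(pairs, w0=w0)


def write_hierarchy_tsv(h: ClassHierarchy, path) -> None:
    lines = []
    for c in h.classes:
        ps = h.parents[c] or ("root",)
        for p in ps:
            lines.append(f"{p}\t{c}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_split_file(path) -> list[str]:
    """One example id per line."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_scores_tsv(path, ids, scores: np.ndarray, classes) -> None:
    """Per-example membership scores: id column + one column per class."""
    scores = np.asarray(scores, dtype=float)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(classes) + "\n")
        for ex_id, row in zip(ids, scores):
            fh.write(str(ex_id) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_scores_tsv(path) -> tuple[list[str], np.ndarray, list[str]]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if header[0] != "id":
        raise ValueError("score TSV must start with an 'id' column")
    classes = header[1:]
    ids, rows = [], []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return ids, np.array(rows, dtype=float), classes
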