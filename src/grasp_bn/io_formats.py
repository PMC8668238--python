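"""Reading and writing networks and datasets.

Supports the BIF (Bayesian Interchange Format) dialect used by the public
Bayesian Network Repository: ``network``, ``variable`` and ``probability``
blocks, with conditional tables given either as ``table`` lines or as
per-parent-configuration rows ``( label, ... ) p1, p2, ...;``.  Learned
structures are written as tab-separated edge lists or DOT digraphs; datasets
are delimited text tables with a header row of variable names and one
category label per cell.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .data_model import BayesianNetwork, CategoricalDataset, DAG, Variable

__all__ = [
    "BIFParseError",
    "read_bif",
    "write_bif",
    "read_dataset",
    "write_dataset",
    "read_edge_list",
    "write_structure",
]


class BIFParseError(ValueError):
    """Malformed BIF input; the message names the offending block."""


_TOKEN_RE = re.compile(r"//[^\n]*|[{}()\[\];,|=]|[^\s{}()\[\];,|=]+")


def _tokenize(text: str) -> list[str]:
    return [t for t in _TOKEN_RE.findall(text) if not t.startswith("//")]


@dataclass
class _TokenStream:
    tokens: list[str]
    pos: int = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        if self.pos >= len(self.tokens):
            raise BIFParseError("unexpected end of input")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, tok: str, where: str) -> None:
        got = self.next()
        if got != tok:
            raise BIFParseError(f"{where}: expected {tok!r}, got {got!r}")

    def skip_block(self) -> None:
        """Skip a brace-balanced block starting at the next '{'."""
        self.expect("{", "block")
        depth = 1
        while depth:
            tok = self.next()
            if tok == "{":
                depth += 1
            elif tok == "}":
                depth -= 1


def _collect_floats(ts: _TokenStream, stop: str, where: str) -> list[float]:
    out: list[float] = []
    while True:
        tok = ts.peek()
        if tok is None:
            raise BIFParseError(f"{where}: unterminated number list")
        if tok == stop:
            ts.next()
            return out
        if tok == ",":
            ts.next()
            continue
        try:
            out.append(float(ts.next()))
        except ValueError as exc:
            raise BIFParseError(f"{where}: expected a probability, got {tok!r}") from exc


def read_bif(source: TextIO | str) -> BayesianNetwork:
    """Parse a BIF document into a :class:`BayesianNetwork`.

    Node order follows declaration order.  CPT rows must sum to 1 within
    1e-3 and are renormalized exactly after load.  In ``table`` form with
    parents, the child state varies fastest and the *last* declared parent's
    configuration varies fastest among parents.
    """
    text = source if isinstance(source, str) else source.read()
    ts = _TokenStream(_tokenize(text))

    variables: list[Variable] = []
    index: dict[str, int] = {}
    # parents in *declared* order per child, plus raw rows
    parent_decl: dict[int, list[int]] = {}
    table_rows: dict[int, np.ndarray] = {}

    while ts.peek() is not None:
        kw = ts.next()
        if kw == "network":
            while ts.peek() != "{":
                ts.next()
            ts.skip_block()
        elif kw == "variable":
            name = ts.next()
            ts.expect("{", f"variable {name}")
            arity = None
            labels: list[str] = []
            while ts.peek() != "}":
                tok = ts.next()
                if tok == "type":
                    kind = ts.next()
                    if kind != "discrete":
                        raise BIFParseError(f"variable {name}: only discrete supported")
                    ts.expect("[", f"variable {name}")
                    arity = int(ts.next())
                    ts.expect("]", f"variable {name}")
                    ts.expect("{", f"variable {name}")
                    while ts.peek() != "}":
                        t = ts.next()
                        if t != ",":
                            labels.append(t)
                    ts.next()  # }
                    if ts.peek() == ";":
                        ts.next()
                elif tok == "property":
                    while ts.next() != ";":
                        pass
            ts.next()  # }
            if arity is None or len(labels) != arity:
                raise BIFParseError(f"variable {name}: bad type declaration")
            if name in index:
                raise BIFParseError(f"variable {name}: declared twice")
            index[name] = len(variables)
            variables.append(Variable(name, arity, tuple(labels)))
        elif kw == "probability":
            ts.expect("(", "probability block")
            names: list[str] = []
            bar = False
            parents_decl: list[str] = []
            while ts.peek() != ")":
                tok = ts.next()
                if tok == "|":
                    bar = True
                elif tok != ",":
                    (parents_decl if bar else names).append(tok)
            ts.next()  # )
            if len(names) != 1:
                raise BIFParseError(f"probability block {names}: exactly one child required")
            child_name = names[0]
            for nm in [child_name, *parents_decl]:
                if nm not in index:
                    raise BIFParseError(
                        f"probability block for {child_name}: undeclared variable {nm!r}"
                    )
            child = index[child_name]
            decl = [index[nm] for nm in parents_decl]
            parent_decl[child] = decl
            r = variables[child].arity
            decl_arities = [variables[u].arity for u in decl]
            q = int(np.prod(decl_arities)) if decl else 1
            cpt = np.full((q, r), np.nan)

            ts.expect("{", f"probability block for {child_name}")
            while ts.peek() != "}":
                tok = ts.next()
                if tok == ";":
                    continue
                if tok == "table":
                    vals = _collect_floats(ts, ";", f"table for {child_name}")
                    if len(vals) != q * r:
                        raise BIFParseError(
                            f"table for {child_name}: {len(vals)} values, expected {q * r}"
                        )
                    # child fastest, last declared parent next fastest
                    cpt[:, :] = np.asarray(vals).reshape(q, r)
                elif tok == "(":
                    labels = []
                    while ts.peek() != ")":
                        t = ts.next()
                        if t != ",":
                            labels.append(t)
                    ts.next()  # )
                    if len(labels) != len(decl):
                        raise BIFParseError(
                            f"probability row for {child_name}: {len(labels)} labels "
                            f"for {len(decl)} parents"
                        )
                    row = 0
                    for lab, u, ra in zip(labels, decl, decl_arities):
                        try:
                            li = variables[u].labels.index(lab)
                        except ValueError as exc:
                            raise BIFParseError(
                                f"probability row for {child_name}: label {lab!r} "
                                f"not a category of {variables[u].name}"
                            ) from exc
                        row = row * ra + li
                    vals = _collect_floats(ts, ";", f"probability row for {child_name}")
                    if len(vals) != r:
                        raise BIFParseError(
                            f"probability row for {child_name}: {len(vals)} values, "
                            f"expected {r}"
                        )
                    cpt[row, :] = vals
                else:
                    raise BIFParseError(
                        f"probability block for {child_name}: unexpected token {tok!r}"
                    )
            ts.next()  # }
            if np.isnan(cpt).any():
                raise BIFParseError(
                    f"probability block for {child_name}: missing parent configurations"
                )
            sums = cpt.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-3:
                raise BIFParseError(
                    f"probability block for {child_name}: row sums off by "
                    f"{np.abs(sums - 1.0).max():.2g}"
                )
            table_rows[child] = cpt / sums[:, None]
        else:
            raise BIFParseError(f"unexpected top-level token {kw!r}")

    p = len(variables)
    dag = DAG(p)
    for child, decl in parent_decl.items():
        for u in decl:
            dag.add_edge(u, child)

    cpts: list[np.ndarray] = []
    for i in range(p):
        if i not in table_rows:
            raise BIFParseError(f"no probability block for variable {variables[i].name}")
        decl = parent_decl[i]
        raw = table_rows[i]
        cpts.append(_reorder_cpt(raw, decl, [variables[u].arity for u in decl]))
    return BayesianNetwork(dag=dag, variables=variables, cpts=cpts)


def _reorder_cpt(raw: np.ndarray, decl: list[int], decl_arities: list[int]) -> np.ndarray:
    """Convert rows from declared-parent-order (last fastest) to the internal
    sorted-parent-order (first fastest) configuration coding."""
    if not decl:
        return raw.copy()
    m = len(decl)
    r = raw.shape[1]
    # raw row index: mixed radix over declared order, LAST declared fastest,
    # so a C-order reshape puts declared parent t on axis t (axis 0 slowest)
    shaped = raw.reshape(*decl_arities, r)
    # internal code: FIRST sorted parent fastest -> axes must run from the
    # last sorted parent (slowest) down to the first (fastest), then states
    axes = [decl.index(u) for u in sorted(decl, reverse=True)] + [m]
    return np.ascontiguousarray(np.transpose(shaped, axes)).reshape(-1, r)


def write_bif(bn: BayesianNetwork, name: str = "network") -> str:
    """Serialize a network to BIF text (per-configuration rows for parents)."""
    out = io.StringIO()
    out.write(f"network {name} {{\n}}\n")
    for v in bn.variables:
        labels = ", ".join(v.labels)
        out.write(
            f"variable {v.name} {{\n  type discrete [ {v.arity} ] {{ {labels} }};\n}}\n"
        )
    for i, v in enumerate(bn.variables):
        parents = sorted(bn.dag.parents[i])
        cpt = bn.cpts[i]
        if not parents:
            vals = ", ".join(f"{x:.12g}" for x in cpt[0])
            out.write(f"probability ( {v.name} ) {{\n  table {vals};\n}}\n")
            continue
        pnames = ", ".join(bn.variables[u].name for u in parents)
        out.write(f"probability ( {v.name} | {pnames} ) {{\n")
        arities = [bn.variables[u].arity for u in parents]
        for code in range(cpt.shape[0]):
            # internal code: first sorted parent varies fastest
            rem, states = code, []
            for ra in arities:
                states.append(rem % ra)
                rem //= ra
            labs = ", ".join(
                bn.variables[u].labels[s] for u, s in zip(parents, states)
            )
            vals = ", ".join(f"{x:.12g}" for x in cpt[code])
            out.write(f"  ( {labs} ) {vals};\n")
        out.write("}\n")
    return out.getvalue()


def read_dataset(
    source: TextIO | str,
    delimiter: str = "\t",
    reference: BayesianNetwork | None = None,
) -> CategoricalDataset:
    """Load a delimited text table of category labels into a dataset.

    Per-column label order is first-appearance unless ``reference`` supplies
    a network whose variables (matched by name) fix the label order and
    arity.  Empty cells and ragged rows raise with the offending row number.
    """
    buf = io.StringIO(source) if isinstance(source, str) else source
    df = pd.read_csv(buf, sep=delimiter, dtype=str, keep_default_na=False, header=0)
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError("dataset must have at least one column and one row")
    ref_vars = {v.name: v for v in reference.variables} if reference else {}
    variables: list[Variable] = []
    values = np.zeros(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        cells = df[col].tolist()
        for r, c in enumerate(cells):
            if c == "":
                raise ValueError(f"missing value at data row {r + 1}, column {col!r}")
        if col in ref_vars:
            var = ref_vars[col]
            lut = {lab: s for s, lab in enumerate(var.labels)}
            try:
                values[:, j] = [lut[c] for c in cells]
            except KeyError as exc:
                raise ValueError(
                    f"column {col!r}: label {exc.args[0]!r} not in reference network"
                ) from exc
        else:
            lut = {}
            for r, c in enumerate(cells):
                if c not in lut:
                    lut[c] = len(lut)
                values[r, j] = lut[c]
            var = Variable(col, len(lut), tuple(lut))
        variables.append(var)
    return CategoricalDataset(variables, values)


def write_dataset(data: CategoricalDataset, delimiter: str = "\t") -> str:
    """Dataset back to delimited text, labels resolved per variable."""
    out = io.StringIO()
    out.write(delimiter.join(data.names) + "\n")
    for row in data.values:
        out.write(
            delimiter.join(data.variables[j].labels[row[j]] for j in range(data.p))
            + "\n"
        )
    return out.getvalue()


def write_structure(
    dag: DAG, variables: Sequence[Variable] | Sequence[str], fmt: str = "edge-list"
) -> str:
    """Serialize a DAG as a sorted TSV edge list or a DOT digraph."""
    names = [v.name if isinstance(v, Variable) else str(v) for v in variables]
    if len(names) != dag.p:
        raise ValueError("one name required per node")
    pairs = sorted((names[u], names[v]) for u, v in dag.edges)
    if fmt == "edge-list":
        return "".join(f"{a}\t{b}\n" for a, b in pairs)
    if fmt == "dot":
        lines = ["digraph G {"]
        lines += [f'  "{n}";' for n in names]
        lines += [f'  "{a}" -> "{b}";' for a, b in pairs]
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def read_edge_list(
    source: TextIO | str, names: Sequence[str]
) -> DAG:
    """Parse a parent<TAB>child edge list back into a DAG over ``names``."""
    text = source if isinstance(source, str) else source.read()
    lut = {n: i for i, n in enumerate(names)}
    dag = DAG(len(names))
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"edge list line {ln}: expected two tab-separated names")
        a, b = parts
        if a not in lut or b not in lut:
            raise ValueError(f"edge list line {ln}: unknown variable name")
        dag.add_edge(lut[a], lut[b])
    return dag
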