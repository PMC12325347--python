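"""KEGG-style metabolic module completeness from per-genome KO sets.

A module definition is a boolean expression over KO identifiers:

* space   — AND of sequential reaction steps (lowest precedence),
* comma   — OR between alternative genes/blocks,
* plus    — protein complex (all subunits required),
* minus   — optional component, excluded from scoring (highest precedence),
* parentheses override precedence.

Completeness is block-level: the percentage of satisfied top-level AND
blocks, the step-fraction semantics KEGG Mapper reports. Optional
(minus-prefixed) components count toward neither numerator nor
denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import pandas as pd


class DefinitionParseError(ValueError):
    """Malformed module definition; message carries the token offset."""


@dataclass(frozen=True)
class Step:
    ko: str


@dataclass(frozen=True)
class And:
    blocks: tuple["Node", ...]


@dataclass(frozen=True)
class Or:
    alternatives: tuple["Node", ...]


@dataclass(frozen=True)
class Complex:
    subunits: tuple["Node", ...]
    optional: tuple[bool, ...]  # parallel to subunits


@dataclass(frozen=True)
class Optional_:
    inner: "Node"


Node = Union[Step, And, Or, Complex, Optional_]


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    expression: Node

    @property
    def normalized(self) -> str:
        return _unparse(self.expression)


_TOKEN_RE = re.compile(r"(\s+|,|\+|-|\(|\)|[A-Za-z0-9_.]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise DefinitionParseError(f"unexpected character at offset {pos}")
        tok = m.group(0)
        if not tok.isspace():
            tokens.append((tok, m.start()))
        else:
            tokens.append((" ", m.start()))
        pos = m.end()
    if pos != len(text):
        raise DefinitionParseError(f"unexpected character at offset {pos}")
    # keep a space only where it acts as the AND operator
    out: list[tuple[str, int]] = []
    for k, (tok, off) in enumerate(tokens):
        if tok == " ":
            prev = out[-1][0] if out else None
            nxt = next((t for t, _ in tokens[k + 1 :] if t != " "), None)
            if prev in (")",) or (prev is not None and _is_ko(prev)):
                if nxt is not None and (nxt == "(" or nxt == "-" or _is_ko(nxt)):
                    out.append((" ", off))
        else:
            out.append((tok, off))
    return out


def _is_ko(tok: str) -> bool:
    return bool(re.fullmatch(r"[A-Za-z0-9_.]+", tok))


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.k = 0

    def peek(self) -> str | None:
        return self.tokens[self.k][0] if self.k < len(self.tokens) else None

    def take(self) -> tuple[str, int]:
        if self.k >= len(self.tokens):
            raise DefinitionParseError(f"unexpected end of definition at offset {len(self.text)}")
        tok = self.tokens[self.k]
        self.k += 1
        return tok

    def fail(self, msg: str) -> None:
        off = self.tokens[self.k][1] if self.k < len(self.tokens) else len(self.text)
        raise DefinitionParseError(f"{msg} at offset {off}")

    # seq := alt (SPACE alt)*
    def parse_seq(self) -> Node:
        blocks = [self.parse_alt()]
        while self.peek() == " ":
            self.take()
            blocks.append(self.parse_alt())
        return blocks[0] if len(blocks) == 1 else And(tuple(blocks))

    # alt := cpx (',' cpx)*
    def parse_alt(self) -> Node:
        alts = [self.parse_cpx()]
        while self.peek() == ",":
            self.take()
            alts.append(self.parse_cpx())
        return alts[0] if len(alts) == 1 else Or(tuple(alts))

    # cpx := unit (('+'|'-') unit)* ; a leading '-' marks the unit optional
    def parse_cpx(self) -> Node:
        units: list[Node] = []
        flags: list[bool] = []
        optional = False
        if self.peek() == "-":
            self.take()
            optional = True
        units.append(self.parse_atom())
        flags.append(optional)
        while self.peek() in ("+", "-"):
            op, _ = self.take()
            units.append(self.parse_atom())
            flags.append(op == "-")
        if len(units) == 1:
            return Optional_(units[0]) if flags[0] else units[0]
        return Complex(tuple(units), tuple(flags))

    def parse_atom(self) -> Node:
        tok, off = self.take()
        if tok == "(":
            inner = self.parse_seq()
            closing = self.take()
            if closing[0] != ")":
                raise DefinitionParseError(f"expected ')' at offset {closing[1]}")
            return inner
        if _is_ko(tok):
            return Step(tok)
        raise DefinitionParseError(f"unexpected token {tok!r} at offset {off}")


def parse_definition(text: str, module_id: str = "") -> ModuleDefinition:
    """Parse a KEGG-style definition string.

    Raises :class:`DefinitionParseError` (with character offset) on
    unbalanced parentheses, dangling operators, or a definition without any
    non-optional step.
    """
    if not text or not text.strip():
        raise DefinitionParseError("empty module definition")
    parser = _Parser(text.strip())
    node = parser.parse_seq()
    if parser.k != len(parser.tokens):
        parser.fail("trailing input")
    if _count_required_steps(node) == 0:
        raise DefinitionParseError("definition has no non-optional step")
    return ModuleDefinition(module_id=module_id, expression=node)


def _count_required_steps(node: Node) -> int:
    if isinstance(node, Step):
        return 1
    if isinstance(node, Optional_):
        return 0
    if isinstance(node, And):
        return sum(_count_required_steps(b) for b in node.blocks)
    if isinstance(node, Or):
        return max(_count_required_steps(a) for a in node.alternatives)
    if isinstance(node, Complex):
        return sum(
            _count_required_steps(u) for u, opt in zip(node.subunits, node.optional) if not opt
        )
    raise TypeError(node)


def _evaluate(node: Node, kos: frozenset[str]) -> bool:
    if isinstance(node, Step):
        return node.ko in kos
    if isinstance(node, Optional_):
        return True
    if isinstance(node, And):
        return all(
            _evaluate(b, kos) for b in node.blocks if not isinstance(b, Optional_)
        )
    if isinstance(node, Or):
        return any(_evaluate(a, kos) for a in node.alternatives)
    if isinstance(node, Complex):
        return all(
            _evaluate(u, kos) for u, opt in zip(node.subunits, node.optional) if not opt
        )
    raise TypeError(node)


def completeness_percent(m: ModuleDefinition, ko_set: Iterable[str]) -> float:
    """Block-level completeness: 100 · satisfied / total top-level AND blocks.

    Optional blocks are excluded from both counts; a top-level expression
    without AND structure is a single block.
    """
    kos = frozenset(ko_set)
    top = m.expression
    blocks = list(top.blocks) if isinstance(top, And) else [top]
    scored = [b for b in blocks if not isinstance(b, Optional_)]
    if not scored:
        return 0.0
    satisfied = sum(1 for b in scored if _evaluate(b, kos))
    return 100.0 * satisfied / len(scored)


def _unparse(node: Node, parent: str = "seq") -> str:
    if isinstance(node, Step):
        return node.ko
    if isinstance(node, Optional_):
        return "-" + _unparse(node.inner, "cpx")
    if isinstance(node, And):
        s = " ".join(_unparse(b, "seq") for b in node.blocks)
        return f"({s})" if parent != "seq" else s
    if isinstance(node, Or):
        s = ",".join(_unparse(a, "alt") for a in node.alternatives)
        return f"({s})" if parent == "cpx" else s
    if isinstance(node, Complex):
        parts = []
        for k, (u, opt) in enumerate(zip(node.subunits, node.optional)):
            txt = _unparse(u, "cpx")
            if k == 0:
                parts.append(("-" if opt else "") + txt)
            else:
                parts.append(("-" if opt else "+") + txt)
        return "".join(parts)
    raise TypeError(node)


# ---------------------------------------------------------------------------
# tabular IO


def read_definitions(path: str | Path) -> list[ModuleDefinition]:
    """Two-column TSV (module_id, definition string) → parsed modules."""
    df = pd.read_csv(path, sep="\t", header=None, names=["module_id", "definition"])
    return [parse_definition(row.definition, module_id=row.module_id) for row in df.itertuples()]


def read_ko_sets(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (genome_id, KO id), one KO per row."""
    df = pd.read_csv(path, sep="\t", header=None, names=["genome_id", "ko"])
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.genome_id), set()).add(str(row.ko))
    return out


def completeness_table(
    modules: list[ModuleDefinition], ko_sets: dict[str, Iterable[str]]
) -> pd.DataFrame:
    """Long-form (genome, module, completeness_pct) table for heatmapping."""
    rows = [
        {
            "genome_id": gid,
            "module_id": m.module_id,
            "completeness_pct": completeness_percent(m, kos),
        }
        for gid, kos in ko_sets.items()
        for m in modules
    ]
    return pd.DataFrame(rows)
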