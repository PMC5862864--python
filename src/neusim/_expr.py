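"""Expression layer of the equation dialect.

Hand-written tokenizer and recursive-descent parser producing a small AST,
plus the serializers and tree transforms the rest of the package is built on:

* ``ser``       -- canonical dialect text ('^' for powers, minimal parens)
* ``to_python`` -- numpy-ready Python source ('**', fully parenthesized)
* ``rename`` / ``substitute`` / ``replace_linkers`` -- used by namespacing
  and linker resolution
* ``iter_nodes`` / ``free_names`` / ``linker_names`` -- analysis helpers

The dialect is deliberately small: arithmetic with '^' exponentiation,
comparisons, elementwise logic ('&', '|', '!' or '~'), calls to whitelisted
builtins or user-declared functions, and '@'-prefixed linker placeholders.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterator

from .errors import DSLSyntaxError, UnknownIdentifierError

# ---------------------------------------------------------------------------
# AST nodes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Num:
    raw: str  # literal text, preserved for round-tripping ('.7', '1e3', ...)

    @property
    def value(self) -> float:
        return float(self.raw)


@dataclass(frozen=True)
class Name:
    id: str


@dataclass(frozen=True)
class LinkerRef:
    name: str  # includes the leading '@'


@dataclass(frozen=True)
class Call:
    fn: str
    args: tuple


@dataclass(frozen=True)
class Un:
    op: str  # '-', '+', '!'
    operand: object


@dataclass(frozen=True)
class Bin:
    op: str
    left: object
    right: object


Node = object

# ---------------------------------------------------------------------------
# Builtins
# ---------------------------------------------------------------------------

#: name -> (min arity, max arity)
BUILTIN_FUNCTIONS = {
    "exp": (1, 1),
    "log": (1, 1),
    "log10": (1, 1),
    "sqrt": (1, 1),
    "sin": (1, 1),
    "cos": (1, 1),
    "tan": (1, 1),
    "tanh": (1, 1),
    "floor": (1, 1),
    "ceil": (1, 1),
    "abs": (1, 1),
    "sign": (1, 1),
    "min": (2, 2),
    "max": (2, 2),
    "mod": (2, 2),
    "heaviside": (1, 1),
    "step": (1, 1),
    "sum": (1, 1),
    "mean": (1, 1),
    "rowsum": (1, 1),
    "rand": (1, 2),
    "randn": (1, 2),
}

#: names that are always in scope inside expressions
BUILTIN_NAMES = {"t", "dt", "pi"}

#: straightforward numpy translations
_NUMPY_FN = {
    "exp": "np.exp",
    "log": "np.log",
    "log10": "np.log10",
    "sqrt": "np.sqrt",
    "sin": "np.sin",
    "cos": "np.cos",
    "tan": "np.tan",
    "tanh": "np.tanh",
    "floor": "np.floor",
    "ceil": "np.ceil",
    "abs": "np.abs",
    "sign": "np.sign",
    "min": "np.minimum",
    "max": "np.maximum",
    "mod": "np.mod",
    "heaviside": "_step",
    "step": "_step",
    "sum": "np.sum",
    "mean": "np.mean",
    "rowsum": "_rowsum",
    "rand": "_rand",
    "randn": "_randn",
}

# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<NUMBER>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
  | (?P<LINKER>@[A-Za-z_][A-Za-z0-9_]*)
  | (?P<NAME>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<OP><=|>=|==|!=|\+=|-=|\*=|[-+*/^(),<>=&|!~\[\]])
  | (?P<WS>\s+)
  | (?P<BAD>.)
    """,
    re.VERBOSE,
)


def tokenize(text: str):
    """Yield (kind, value, position) tuples; raises on illegal characters."""
    out = []
    for m in _TOKEN_RE.finditer(text):
        kind = m.lastgroup
        if kind == "WS":
            continue
        if kind == "BAD":
            raise DSLSyntaxError(
                f"illegal character {m.group()!r} in expression", col=m.start(), text=text
            )
        out.append((kind, m.group(), m.start()))
    return out


# ---------------------------------------------------------------------------
# Parser (precedence climbing via nested productions)
# ---------------------------------------------------------------------------


class _Parser:
    def __init__(self, tokens, text):
        self.toks = tokens
        self.pos = 0
        self.text = text

    def peek(self):
        return self.toks[self.pos] if self.pos < len(self.toks) else (None, None, None)

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect(self, value):
        kind, val, at = self.next()
        if val != value:
            raise DSLSyntaxError(
                f"expected {value!r}, found {val!r}", col=at, text=self.text
            )

    def fail(self, msg):
        _, val, at = self.peek()
        raise DSLSyntaxError(f"{msg} (near {val!r})", col=at, text=self.text)

    # expression := orexpr
    def parse(self):
        node = self.orexpr()
        if self.pos != len(self.toks):
            self.fail("unexpected trailing input")
        return node

    def orexpr(self):
        node = self.andexpr()
        while self.peek()[1] == "|":
            self.next()
            node = Bin("|", node, self.andexpr())
        return node

    def andexpr(self):
        node = self.notexpr()
        while self.peek()[1] == "&":
            self.next()
            node = Bin("&", node, self.notexpr())
        return node

    def notexpr(self):
        if self.peek()[1] in ("!", "~"):
            self.next()
            return Un("!", self.notexpr())
        return self.comparison()

    def comparison(self):
        node = self.arith()
        if self.peek()[1] in ("<", "<=", ">", ">=", "==", "!="):
            op = self.next()[1]
            node = Bin(op, node, self.arith())
        return node

    def arith(self):
        node = self.term()
        while self.peek()[1] in ("+", "-"):
            op = self.next()[1]
            node = Bin(op, node, self.term())
        return node

    def term(self):
        node = self.unary()
        while self.peek()[1] in ("*", "/"):
            op = self.next()[1]
            node = Bin(op, node, self.unary())
        return node

    def unary(self):
        if self.peek()[1] in ("-", "+"):
            op = self.next()[1]
            return Un(op, self.unary())
        return self.power()

    def power(self):
        node = self.atom()
        if self.peek()[1] == "^":
            self.next()
            node = Bin("^", node, self.unary())  # right-assoc, allows 2^-3
        return node

    def atom(self):
        kind, val, at = self.next()
        if kind == "NUMBER":
            return Num(val)
        if kind == "LINKER":
            return LinkerRef(val)
        if kind == "NAME":
            if self.peek()[1] == "(":
                self.next()
                args = []
                if self.peek()[1] != ")":
                    args.append(self.orexpr())
                    while self.peek()[1] == ",":
                        self.next()
                        args.append(self.orexpr())
                self.expect(")")
                return Call(val, tuple(args))
            return Name(val)
        if val == "(":
            node = self.orexpr()
            self.expect(")")
            return node
        raise DSLSyntaxError(f"unexpected token {val!r}", col=at, text=self.text)


def parse_expr(text: str) -> Node:
    """Parse one expression of the dialect into an AST."""
    tokens = tokenize(text)
    if not tokens:
        raise DSLSyntaxError("empty expression", text=text)
    return _Parser(tokens, text).parse()


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_PREC = {
    "|": 1,
    "&": 2,
    "<": 3, "<=": 3, ">": 3, ">=": 3, "==": 3, "!=": 3,
    "+": 4, "-": 4,
    "*": 5, "/": 5,
    "u": 6,  # unary
    "^": 7,
}


def ser(node: Node) -> str:
    """Canonical dialect text with minimal parentheses."""
    return _ser(node, 0)


def _ser(node, parent_prec, right_of=None):
    if isinstance(node, Num):
        return node.raw
    if isinstance(node, Name):
        return node.id
    if isinstance(node, LinkerRef):
        return node.name
    if isinstance(node, Call):
        return f"{node.fn}({','.join(_ser(a, 0) for a in node.args)})"
    if isinstance(node, Un):
        op = node.op if node.op != "!" else "!"
        inner = _ser(node.operand, _PREC["u"])
        text = f"{op}{inner}"
        return f"({text})" if parent_prec > _PREC["u"] else text
    if isinstance(node, Bin):
        prec = _PREC[node.op]
        left = _ser(node.left, prec)
        # right child of a left-assoc op of equal precedence needs parens
        # ('^' is right-assoc, so the mirrored rule applies on the left)
        if node.op == "^":
            left = _ser(node.left, prec + 1)
            right = _ser(node.right, prec)
        else:
            right = _ser(node.right, prec + 1)
        text = f"{left}{node.op}{right}"
        return f"({text})" if prec < parent_prec else text
    raise TypeError(f"not an AST node: {node!r}")


def to_python(node: Node, name_map: Callable[[str], str] | None = None,
              fn_map: Callable[[str], str] | None = None) -> str:
    """Render as numpy-ready Python source (fully parenthesized, '**')."""
    nm = name_map or (lambda s: s)
    fm = fn_map or (lambda s: s)
    return _to_py(node, nm, fm)


def _to_py(node, nm, fm):
    if isinstance(node, Num):
        return node.raw if "." in node.raw or "e" in node.raw.lower() else node.raw + ".0"
    if isinstance(node, Name):
        if node.id == "pi":
            return "np.pi"
        return nm(node.id)
    if isinstance(node, LinkerRef):
        raise ValueError(f"unresolved linker {node.name!r} in expression")
    if isinstance(node, Call):
        fn = _NUMPY_FN.get(node.fn) if node.fn in BUILTIN_FUNCTIONS else fm(node.fn)
        args = ", ".join(_to_py(a, nm, fm) for a in node.args)
        return f"{fn}({args})"
    if isinstance(node, Un):
        op = {"-": "-", "+": "+", "!": "~"}[node.op]
        return f"({op}{_to_py(node.operand, nm, fm)})"
    if isinstance(node, Bin):
        op = "**" if node.op == "^" else node.op
        return f"({_to_py(node.left, nm, fm)} {op} {_to_py(node.right, nm, fm)})"
    raise TypeError(f"not an AST node: {node!r}")


# ---------------------------------------------------------------------------
# Analysis and transforms
# ---------------------------------------------------------------------------


def iter_nodes(node: Node) -> Iterator[Node]:
    yield node
    if isinstance(node, Call):
        for a in node.args:
            yield from iter_nodes(a)
    elif isinstance(node, Un):
        yield from iter_nodes(node.operand)
    elif isinstance(node, Bin):
        yield from iter_nodes(node.left)
        yield from iter_nodes(node.right)


def free_names(node: Node) -> set[str]:
    """All identifiers referenced (names and non-builtin call targets)."""
    out = set()
    for n in iter_nodes(node):
        if isinstance(n, Name) and n.id not in BUILTIN_NAMES:
            out.add(n.id)
        elif isinstance(n, Call) and n.fn not in BUILTIN_FUNCTIONS:
            out.add(n.fn)
    return out


def called_names(node: Node) -> set[str]:
    return {n.fn for n in iter_nodes(node)
            if isinstance(n, Call) and n.fn not in BUILTIN_FUNCTIONS}


def linker_names(node: Node) -> set[str]:
    return {n.name for n in iter_nodes(node) if isinstance(n, LinkerRef)}


def rename(node: Node, mapping: dict[str, str]) -> Node:
    """Rename identifiers (both Name ids and non-builtin call targets)."""
    if isinstance(node, (Num, LinkerRef)):
        return node
    if isinstance(node, Name):
        return Name(mapping.get(node.id, node.id))
    if isinstance(node, Call):
        fn = node.fn if node.fn in BUILTIN_FUNCTIONS else mapping.get(node.fn, node.fn)
        return Call(fn, tuple(rename(a, mapping) for a in node.args))
    if isinstance(node, Un):
        return Un(node.op, rename(node.operand, mapping))
    if isinstance(node, Bin):
        return Bin(node.op, rename(node.left, mapping), rename(node.right, mapping))
    raise TypeError(f"not an AST node: {node!r}")


def substitute(node: Node, mapping: dict[str, Node]) -> Node:
    """Replace Name references by whole subtrees."""
    if isinstance(node, (Num, LinkerRef)):
        return node
    if isinstance(node, Name):
        return mapping.get(node.id, node)
    if isinstance(node, Call):
        return Call(node.fn, tuple(substitute(a, mapping) for a in node.args))
    if isinstance(node, Un):
        return Un(node.op, substitute(node.operand, mapping))
    if isinstance(node, Bin):
        return Bin(node.op, substitute(node.left, mapping),
                   substitute(node.right, mapping))
    raise TypeError(f"not an AST node: {node!r}")


def replace_linkers(node: Node, mapping: dict[str, Node]) -> Node:
    """Replace linker placeholders by resolved subtrees."""
    if isinstance(node, (Num, Name)):
        return node
    if isinstance(node, LinkerRef):
        if node.name in mapping:
            return mapping[node.name]
        return node
    if isinstance(node, Call):
        return Call(node.fn, tuple(replace_linkers(a, mapping) for a in node.args))
    if isinstance(node, Un):
        return Un(node.op, replace_linkers(node.operand, mapping))
    if isinstance(node, Bin):
        return Bin(node.op, replace_linkers(node.left, mapping),
                   replace_linkers(node.right, mapping))
    raise TypeError(f"not an AST node: {node!r}")


def check_scope(node: Node, scope: set[str], known_functions: dict[str, int] | None = None,
                *, text: str = "") -> None:
    """Raise UnknownIdentifierError/DSLSyntaxError on out-of-scope symbols.

    ``known_functions`` maps user-declared function names to their arity.
    """
    known_functions = known_functions or {}
    for n in iter_nodes(node):
        if isinstance(n, Name):
            if n.id in BUILTIN_NAMES:
                continue
            if n.id not in scope and n.id not in known_functions:
                raise UnknownIdentifierError(
                    f"unknown identifier {n.id!r}", text=text or ser(node)
                )
        elif isinstance(n, Call):
            if n.fn in BUILTIN_FUNCTIONS:
                lo, hi = BUILTIN_FUNCTIONS[n.fn]
                if not (lo <= len(n.args) <= hi):
                    raise DSLSyntaxError(
                        f"{n.fn}() takes {lo}"
                        + (f"-{hi}" if hi != lo else "")
                        + f" arguments, got {len(n.args)}",
                        text=text or ser(node),
                    )
            elif n.fn in known_functions:
                if len(n.args) != known_functions[n.fn]:
                    raise DSLSyntaxError(
                        f"{n.fn}() takes {known_functions[n.fn]} arguments, "
                        f"got {len(n.args)}",
                        text=text or ser(node),
                    )
            elif n.fn in scope:
                raise DSLSyntaxError(
                    f"{n.fn!r} is not callable", text=text or ser(node)
                )
            else:
                raise UnknownIdentifierError(
                    f"unknown function {n.fn!r}", text=text or ser(node)
                )


def is_numeric_literal(node: Node) -> bool:
    """True for a plain number, possibly under unary sign(s)."""
    while isinstance(node, Un) and node.op in ("-", "+"):
        node = node.operand
    return isinstance(node, Num)


def literal_value(node: Node) -> float:
    sign = 1.0
    while isinstance(node, Un) and node.op in ("-", "+"):
        if node.op == "-":
            sign = -sign
        node = node.operand
    if not isinstance(node, Num):
        raise ValueError("not a numeric literal")
    return sign * node.value
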