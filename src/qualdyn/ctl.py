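"""Computation Tree Logic over state graphs: parsing and fixpoint labeling.

The formula dialect matches the style used to encode wet-lab observations for
logical-parameter identification:

* atoms ``NAME = n`` (entity spellings normalized, e.g. ``GLUT1`` for
  ``GLUT-1``), ``TRUE``/``FALSE`` (``⊤``/``⊥`` also accepted)
* connectives ``!`` (¬), ``&`` (∧), ``|`` (∨), ``->`` or ``⇒`` (⇒,
  right-associative; ``&`` binds tighter than ``|``, which binds tighter
  than implication)
* temporal operators ``EX EF EG AX AF AG`` and until forms ``E[p U q]``,
  ``A[p U q]``

Satisfaction sets are computed by the standard fixpoint labeling algorithm
(EX by preimage, EF/EU as least fixpoints, EG as a greatest fixpoint, the
universal quantifiers by duality).  CTL semantics requires a total transition
relation, so fixed points (deadlocks) are given an implicit self-loop: a
deadlock satisfies ``AG φ`` whenever it satisfies ``φ``, which is exactly how
``EF(AG(...))`` describes settling into a stable state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from .dynamics import StateGraph
from .network import RegulatoryNetwork, normalize_name

__all__ = [
    "CtlFormula",
    "Atom",
    "BoolConst",
    "Not",
    "And",
    "Or",
    "Implies",
    "Temporal",
    "Until",
    "CtlSyntaxError",
    "SatResult",
    "parse_ctl",
    "parse_formula_file",
    "sat_set",
    "holds",
]

State = Tuple[int, ...]


class CtlFormula:
    """Base class of the abstract syntax tree."""

    def atoms(self) -> List["Atom"]:
        out: List[Atom] = []
        stack: List[CtlFormula] = [self]
        while stack:
            node = stack.pop()
            if isinstance(node, Atom):
                out.append(node)
            stack.extend(node.children())
        return out

    def children(self) -> Tuple["CtlFormula", ...]:
        return ()


@dataclass(frozen=True)
class Atom(CtlFormula):
    entity: str
    level: int

    def __str__(self) -> str:
        return f"{self.entity} = {self.level}"


@dataclass(frozen=True)
class BoolConst(CtlFormula):
    value: bool

    def __str__(self) -> str:
        return "TRUE" if self.value else "FALSE"


@dataclass(frozen=True)
class Not(CtlFormula):
    operand: CtlFormula

    def children(self):
        return (self.operand,)

    def __str__(self) -> str:
        return f"!({self.operand})"


@dataclass(frozen=True)
class And(CtlFormula):
    left: CtlFormula
    right: CtlFormula

    def children(self):
        return (self.left, self.right)

    def __str__(self) -> str:
        return f"({self.left} & {self.right})"


@dataclass(frozen=True)
class Or(CtlFormula):
    left: CtlFormula
    right: CtlFormula

    def children(self):
        return (self.left, self.right)

    def __str__(self) -> str:
        return f"({self.left} | {self.right})"


@dataclass(frozen=True)
class Implies(CtlFormula):
    left: CtlFormula
    right: CtlFormula

    def children(self):
        return (self.left, self.right)

    def __str__(self) -> str:
        return f"({self.left} -> {self.right})"


@dataclass(frozen=True)
class Temporal(CtlFormula):
    op: str  # EX EF EG AX AF AG
    operand: CtlFormula

    def children(self):
        return (self.operand,)

    def __str__(self) -> str:
        return f"{self.op}({self.operand})"


@dataclass(frozen=True)
class Until(CtlFormula):
    quantifier: str  # "E" or "A"
    left: CtlFormula
    right: CtlFormula

    def children(self):
        return (self.left, self.right)

    def __str__(self) -> str:
        return f"{self.quantifier}[{self.left} U {self.right}]"


class CtlSyntaxError(ValueError):
    """Raised on malformed formula text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<arrow>->|⇒|=>)
      | (?P<and>&{1,2}|∧)
      | (?P<or>\|{1,2}|∨)
      | (?P<not>!|¬)
      | (?P<lpar>\()
      | (?P<rpar>\))
      | (?P<lbrack>\[)
      | (?P<rbrack>\])
      | (?P<eq>=)
      | (?P<int>\d+)
      | (?P<top>⊤)
      | (?P<bot>⊥)
      | (?P<name>[A-Za-zβ_][A-Za-z0-9β_\-]*)
    )""",
    re.VERBOSE,
)

_TEMPORAL = {"EX", "EF", "EG", "AX", "AF", "AG"}


def _tokenize(text: str) -> List[Tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise CtlSyntaxError(f"unexpected character {text[pos]!r}", pos)
        for kind, value in m.groupdict().items():
            if value is not None:
                tokens.append((kind, value, m.start()))
                break
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
    """Recursive-descent parser for the CTL dialect."""

    def __init__(self, text: str, net: Optional[RegulatoryNetwork]):
        self.text = text
        self.net = net
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> Tuple[str, str, int]:
        return self.tokens[self.pos]

    def advance(self) -> Tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, kind: str) -> Tuple[str, str, int]:
        tok = self.advance()
        if tok[0] != kind:
            raise CtlSyntaxError(f"expected {kind}, found {tok[1]!r}", tok[2])
        return tok

    def parse(self) -> CtlFormula:
        node = self.parse_implies()
        tok = self.peek()
        if tok[0] != "eof":
            raise CtlSyntaxError(f"unexpected trailing input {tok[1]!r}", tok[2])
        return node

    def parse_implies(self) -> CtlFormula:
        left = self.parse_or()
        if self.peek()[0] == "arrow":
            self.advance()
            right = self.parse_implies()  # right-associative
            return Implies(left, right)
        return left

    def parse_or(self) -> CtlFormula:
        node = self.parse_and()
        while self.peek()[0] == "or":
            self.advance()
            node = Or(node, self.parse_and())
        return node

    def parse_and(self) -> CtlFormula:
        node = self.parse_unary()
        while self.peek()[0] == "and":
            self.advance()
            node = And(node, self.parse_unary())
        return node

    def parse_unary(self) -> CtlFormula:
        kind, value, pos = self.peek()
        if kind == "not":
            self.advance()
            return Not(self.parse_unary())
        if kind == "top":
            self.advance()
            return BoolConst(True)
        if kind == "bot":
            self.advance()
            return BoolConst(False)
        if kind == "lpar":
            self.advance()
            node = self.parse_implies()
            self.expect("rpar")
            return node
        if kind == "name":
            upper = value.upper()
            if upper in _TEMPORAL:
                self.advance()
                self.expect("lpar")
                node = self.parse_implies()
                self.expect("rpar")
                return Temporal(upper, node)
            if upper in ("E", "A") and self.tokens[self.pos + 1][0] == "lbrack":
                self.advance()
                self.advance()  # "["
                left = self.parse_implies()
                utok = self.advance()
                if utok[1].upper() != "U":
                    raise CtlSyntaxError("expected 'U' in until form", utok[2])
                right = self.parse_implies()
                self.expect("rbrack")
                return Until(upper, left, right)
            if upper == "TRUE":
                self.advance()
                return BoolConst(True)
            if upper == "FALSE":
                self.advance()
                return BoolConst(False)
            return self.parse_atom()
        raise CtlSyntaxError(f"unexpected token {value!r}", pos)

    def parse_atom(self) -> Atom:
        kind, value, pos = self.advance()
        if kind != "name":
            raise CtlSyntaxError(f"expected entity name, found {value!r}", pos)
        name = value
        if self.net is not None:
            name = normalize_name(name, self.net.entity_names)
            if name not in self.net:
                raise CtlSyntaxError(f"unknown entity {value!r}", pos)
        self.expect("eq")
        _, lvl, lpos = self.expect("int")
        level = int(lvl)
        if self.net is not None:
            max_level = self.net.entities[self.net.index(name)].max_level
            if not 0 <= level <= max_level:
                raise CtlSyntaxError(
                    f"level {level} of {name!r} outside [0, {max_level}]", lpos
                )
        return Atom(name, level)


def parse_ctl(text: str, net: Optional[RegulatoryNetwork] = None) -> CtlFormula:
    """Parse a formula string; with ``net`` given, atoms are validated and
    entity spellings normalized against it."""
    return _Parser(text, net).parse()


def parse_formula_file(path, net: Optional[RegulatoryNetwork] = None) -> List[CtlFormula]:
    """Read a plain-text formula file: one formula per line, ``#`` comments."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(parse_ctl(line, net))
    return out


# ---------------------------------------------------------------------------
# Fixpoint semantics


def _totalized_maps(graph: StateGraph):
    """Successor/predecessor maps with self-loops added on deadlocks."""
    succ: Dict[State, List[State]] = {}
    pred: Dict[State, List[State]] = {s: [] for s in graph.states}
    for s in graph.states:
        nexts = list(graph.graph.successors(s))
        if not nexts:
            nexts = [s]
        succ[s] = nexts
        for t in nexts:
            pred[t].append(s)
    return succ, pred


def sat_set(graph: StateGraph, formula: CtlFormula) -> Set[State]:
    """States of ``graph`` satisfying ``formula`` (standard CTL semantics)."""
    net = graph.network
    for atom in formula.atoms():
        if atom.entity not in net:
            raise ValueError(f"formula atom references unknown entity {atom.entity!r}")
        max_level = net.entities[net.index(atom.entity)].max_level
        if not 0 <= atom.level <= max_level:
            raise ValueError(
                f"formula atom {atom} outside level range of {atom.entity!r}"
            )
    succ, pred = _totalized_maps(graph)
    all_states = set(graph.states)

    def ex(phi: Set[State]) -> Set[State]:
        return {s for t in phi for s in pred[t]}

    def eval_(f: CtlFormula) -> Set[State]:
        if isinstance(f, BoolConst):
            return set(all_states) if f.value else set()
        if isinstance(f, Atom):
            i = net.index(f.entity)
            return {s for s in all_states if s[i] == f.level}
        if isinstance(f, Not):
            return all_states - eval_(f.operand)
        if isinstance(f, And):
            return eval_(f.left) & eval_(f.right)
        if isinstance(f, Or):
            return eval_(f.left) | eval_(f.right)
        if isinstance(f, Implies):
            return (all_states - eval_(f.left)) | eval_(f.right)
        if isinstance(f, Temporal):
            if f.op == "EX":
                return ex(eval_(f.operand))
            if f.op == "AX":
                return all_states - ex(all_states - eval_(f.operand))
            if f.op == "EF":
                # least fixpoint of  φ ∨ EX Z
                phi = eval_(f.operand)
                z = set(phi)
                frontier = set(phi)
                while frontier:
                    newly = {s for t in frontier for s in pred[t]} - z
                    z |= newly
                    frontier = newly
                return z
            if f.op == "AG":
                inner = Temporal("EF", Not(f.operand))
                return all_states - eval_(inner)
            if f.op == "EG":
                # greatest fixpoint of  φ ∧ EX Z
                phi = eval_(f.operand)
                z = set(phi)
                changed = True
                while changed:
                    changed = False
                    drop = {s for s in z if not any(t in z for t in succ[s])}
                    if drop:
                        z -= drop
                        changed = True
                return z
            if f.op == "AF":
                inner = Temporal("EG", Not(f.operand))
                return all_states - eval_(inner)
            raise ValueError(f"unknown temporal operator {f.op!r}")
        if isinstance(f, Until):
            p, q = eval_(f.left), eval_(f.right)
            if f.quantifier == "E":
                # least fixpoint of  q ∨ (p ∧ EX Z)
                z = set(q)
                frontier = set(q)
                while frontier:
                    newly = {s for t in frontier for s in pred[t] if s in p} - z
                    z |= newly
                    frontier = newly
                return z
            # A[p U q]  =  ¬( E[¬q U ¬p∧¬q]  ∨  EG ¬q )
            not_q = all_states - q
            not_p_and_not_q = not_q - p
            z = set(not_p_and_not_q)
            frontier = set(z)
            while frontier:
                newly = {s for t in frontier for s in pred[t] if s in not_q} - z
                z |= newly
                frontier = newly
            eg_not_q = eval_(Temporal("EG", Not(f.right)))
            return all_states - (z | eg_not_q)
        raise TypeError(f"unknown formula node {type(f).__name__}")

    return eval_(formula)


@dataclass
class SatResult:
    """A formula with its satisfying states."""

    formula: CtlFormula
    satisfying_states: Set[State]
    holds_globally: bool


def holds(
    graph: StateGraph,
    formula: CtlFormula,
    mode: str = "all_states",
    at: Optional[Iterable[State]] = None,
) -> bool:
    """Check a formula against a graph.

    ``mode="all_states"`` (the convention for parameter identification: the
    formulas are implications, vacuously true off their antecedent) requires
    every state to satisfy the formula; ``"some_state"`` requires a nonempty
    satisfaction set; ``"at"`` requires the given states to satisfy it.
    """
    sat = sat_set(graph, formula)
    if mode == "all_states":
        return len(sat) == len(graph.states)
    if mode == "some_state":
        return bool(sat)
    if mode == "at":
        if at is None:
            raise ValueError("mode='at' requires the `at` state set")
        return all(tuple(s) in sat for s in at)
    raise ValueError(f"unknown mode {mode!r}")
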