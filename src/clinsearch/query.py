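"""Query language: AST node types and the parser.

Grammar (highest binding first)::

    atom   := '(' expr ')'
            | NEG '(' expr ')' | HYP '(' expr ')' | FAM '(' expr ')'
            | SEG '(' label ',' expr ')'
            | '"..."' ['~' N]          phrase, optionally with slope
            | attr ':' value           structured-attribute filter
            | word                     term; '*' makes it a wildcard
    unary  := NOT unary | atom
    conj   := unary (AND unary)*
    expr   := conj (OR conj)*

Keywords are case-sensitive uppercase (AND, OR, NOT, NEG, HYP, FAM, SEG),
keeping lowercase French words available as search terms. Attribute
filters accept ``age:40``, ``age:40-60``, ``sex:M``, ``date:2019..2020``,
``type:"consultation"``, ``unit:...``, ``icd10:I50`` and ``ccam:...``
(code filters match by prefix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .corpus import Tag

__all__ = [
    "QueryNode", "Term", "Wildcard", "Phrase", "Proximity", "And", "Or",
    "Not", "TagScope", "SegmentScope", "AttrFilter", "QueryParseError",
    "parse_query",
]

ATTRIBUTES = {"age", "sex", "date", "doc_date", "type", "doc_type", "unit",
              "icd10", "ccam"}

_SCOPE_TAGS = {"NEG": Tag.NEGATION, "HYP": Tag.HYPOTHESIS, "FAM": Tag.FAMILY}


class QueryParseError(ValueError):
    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


class QueryNode:
    pass


@dataclass(frozen=True)
class Term(QueryNode):
    word: str


@dataclass(frozen=True)
class Wildcard(QueryNode):
    pattern: str  # '*' is the only metacharacter


@dataclass(frozen=True)
class Phrase(QueryNode):
    words: tuple[str, ...]


@dataclass(frozen=True)
class Proximity(QueryNode):
    words: tuple[str, ...]
    slope: int
    ordered: bool = False


@dataclass(frozen=True)
class And(QueryNode):
    children: tuple[QueryNode, ...]


@dataclass(frozen=True)
class Or(QueryNode):
    children: tuple[QueryNode, ...]


@dataclass(frozen=True)
class Not(QueryNode):
    child: QueryNode


@dataclass(frozen=True)
class TagScope(QueryNode):
    tag: Tag
    child: QueryNode


@dataclass(frozen=True)
class SegmentScope(QueryNode):
    label: str
    child: QueryNode


@dataclass(frozen=True)
class AttrFilter(QueryNode):
    attribute: str
    value: str


# ---------------------------------------------------------------------------
# Lexer


@dataclass
class _Tok:
    kind: str  # LPAREN RPAREN COMMA WORD PHRASE SCOPE ATTR
    value: str
    pos: int
    slope: Optional[int] = None


def _lex(q: str) -> list[_Tok]:
    toks: list[_Tok] = []
    i, n = 0, len(q)
    while i < n:
        ch = q[i]
        if ch.isspace():
            i += 1
        elif ch in "(),":
            kind = {"(": "LPAREN", ")": "RPAREN", ",": "COMMA"}[ch]
            toks.append(_Tok(kind, ch, i))
            i += 1
        elif ch == '"':
            end = q.find('"', i + 1)
            if end == -1:
                raise QueryParseError("unbalanced quote", i)
            tok = _Tok("PHRASE", q[i + 1 : end], i)
            i = end + 1
            if i < n and q[i] == "~":
                j = i + 1
                while j < n and q[j].isdigit():
                    j += 1
                if j == i + 1:
                    raise QueryParseError("slope '~' must be followed by a number", i)
                tok.slope = int(q[i + 1 : j])
                i = j
            toks.append(tok)
        elif ch == "~":
            raise QueryParseError("slope applies only to a quoted phrase", i)
        else:
            j = i
            while j < n and not q[j].isspace() and q[j] not in '(),"':
                j += 1
            word = q[i:j]
            if word.rstrip(":") in (*_SCOPE_TAGS, "SEG") and j < n and q[j] == "(":
                toks.append(_Tok("SCOPE", word.rstrip(":"), i))
            elif ":" in word and word.split(":", 1)[0].lower() in ATTRIBUTES:
                attr, value = word.split(":", 1)
                if not value and j < n and q[j] == '"':  # type:"two words"
                    end = q.find('"', j + 1)
                    if end == -1:
                        raise QueryParseError("unbalanced quote", j)
                    value = q[j + 1 : end]
                    j = end + 1
                toks.append(_Tok("ATTR", f"{attr.lower()}:{value}", i))
            else:
                toks.append(_Tok("WORD", word, i))
            i = j
    return toks


# ---------------------------------------------------------------------------
# Recursive-descent parser


class _Parser:
    def __init__(self, toks: list[_Tok], source: str,
                 segment_labels: Optional[set[str]]) -> None:
        self.toks = toks
        self.source = source
        self.i = 0
        self.segment_labels = segment_labels

    def peek(self) -> Optional[_Tok]:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> _Tok:
        tok = self.peek()
        if tok is None:
            raise QueryParseError("unexpected end of query", len(self.source))
        self.i += 1
        return tok

    def expect(self, kind: str) -> _Tok:
        tok = self.next()
        if tok.kind != kind:
            raise QueryParseError(f"expected {kind}, got {tok.value!r}", tok.pos)
        return tok

    def parse(self) -> QueryNode:
        node = self.expr()
        tok = self.peek()
        if tok is not None:
            raise QueryParseError(f"unexpected trailing {tok.value!r}", tok.pos)
        return node

    def expr(self) -> QueryNode:
        children = [self.conj()]
        while (tok := self.peek()) and tok.kind == "WORD" and tok.value == "OR":
            self.next()
            children.append(self.conj())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def conj(self) -> QueryNode:
        # infix NOT is set difference: "C NOT NEG(C)" == C AND (NOT NEG(C))
        children = [self.unary()]
        while (tok := self.peek()) and tok.kind == "WORD" and tok.value in (
            "AND", "NOT",
        ):
            op = self.next().value
            operand = self.unary()
            children.append(Not(operand) if op == "NOT" else operand)
        return children[0] if len(children) == 1 else And(tuple(children))

    def unary(self) -> QueryNode:
        tok = self.peek()
        if tok and tok.kind == "WORD" and tok.value == "NOT":
            self.next()
            return Not(self.unary())
        return self.atom()

    def atom(self) -> QueryNode:
        tok = self.next()
        if tok.kind == "LPAREN":
            node = self.expr()
            self.expect("RPAREN")
            return node
        if tok.kind == "SCOPE":
            self.expect("LPAREN")
            if tok.value == "SEG":
                label_tok = self.expect("WORD")
                label = label_tok.value
                if self.segment_labels is not None and label not in self.segment_labels:
                    raise QueryParseError(
                        f"unknown segment label {label!r}", label_tok.pos
                    )
                self.expect("COMMA")
                child = self.expr()
                self.expect("RPAREN")
                return SegmentScope(label, child)
            child = self.expr()
            self.expect("RPAREN")
            return TagScope(_SCOPE_TAGS[tok.value], child)
        if tok.kind == "PHRASE":
            words = tuple(tok.value.split())
            if not words:
                raise QueryParseError("empty phrase", tok.pos)
            if tok.slope is not None:
                return Proximity(words, tok.slope)
            return Phrase(words) if len(words) > 1 else Term(words[0])
        if tok.kind == "ATTR":
            attr, value = tok.value.split(":", 1)
            if not value:
                raise QueryParseError(f"empty value for attribute {attr!r}", tok.pos)
            return AttrFilter(attr, value)
        if tok.kind == "WORD":
            if tok.value in {"AND", "OR", "NOT"}:
                raise QueryParseError(f"misplaced operator {tok.value}", tok.pos)
            if "*" in tok.value:
                return Wildcard(tok.value)
            return Term(tok.value)
        raise QueryParseError(f"unexpected {tok.value!r}", tok.pos)


def parse_query(
    q: str, segment_labels: Optional[Sequence[str]] = None
) -> QueryNode:
    """Parse a query string into a :class:`QueryNode` tree.

    When ``segment_labels`` is given (default: the shipped 19-label
    catalogue), an unknown label inside ``SEG(...)`` is a parse error.
    """
    if segment_labels is None:
        from .segmenter import default_segment_rules

        segment_labels = [r.label for r in default_segment_rules()]
    toks = _lex(q)
    if not toks:
        raise QueryParseError("empty query", 0)
    return _Parser(toks, q, set(segment_labels)).parse()
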