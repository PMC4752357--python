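"""The class-expression grammar shared by OBO sidecar sections and DL queries.

Grammar (Protégé Manchester-like, as used in the competency queries)::

    expr    := primary ("and" primary)*
    primary := "(" expr ")" | name ["some" primary]
    name    := quoted label/synonym/CURIE | bare single word

``some`` binds tighter than ``and``; both straight and typographic quotes
are accepted; property names match with spaces or underscores
(``attached to`` == ``attached_to``). Names in class position are resolved
through :meth:`Ontology.resolve_label`, names in property position through
:meth:`Ontology.resolve_property`.
"""

from __future__ import annotations

import re

from .errors import QuerySyntaxError
from .model import (
    ClassExpression,
    Conjunction,
    Existential,
    Named,
    Ontology,
    conjunction_of,
)

__all__ = ["parse_expression", "render_expression"]

_TOKEN = re.compile(
    r"""\s*(?:
        (?P<lparen>\() |
        (?P<rparen>\)) |
        (?P<quoted>'[^']*'|‘[^’]*’|"[^"]*") |
        (?P<word>[^\s()'‘’"]+)
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == m.start():
            raise QuerySyntaxError(f"unexpected character {text[pos]!r}", pos)
        if m.lastgroup == "quoted":
            tokens.append(("name", m.group()[1:-1], m.start()))
        elif m.lastgroup == "word":
            word = m.group().strip()
            low = word.casefold()
            if low in ("and", "some"):
                tokens.append((low, word, m.start()))
            else:
                tokens.append(("name", word, m.start()))
        elif m.lastgroup == "lparen":
            tokens.append(("(", "(", m.start()))
        elif m.lastgroup == "rparen":
            tokens.append((")", ")", m.start()))
        pos = m.end()
        if not text[pos:].strip():
            break
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], ontology: Ontology):
        self.tokens = tokens
        self.i = 0
        self.ontology = ontology

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of expression")
        self.i += 1
        return tok

    def expect(self, kind: str) -> tuple[str, str, int]:
        tok = self.next()
        if tok[0] != kind:
            raise QuerySyntaxError(f"expected {kind!r}, found {tok[1]!r}", tok[2])
        return tok

    def parse_expr(self) -> ClassExpression:
        parts = [self.parse_primary()]
        while True:
            tok = self.peek()
            if tok is not None and tok[0] == "and":
                self.next()
                parts.append(self.parse_primary())
            else:
                break
        return conjunction_of(parts) if len(parts) > 1 else parts[0]

    def parse_primary(self) -> ClassExpression:
        tok = self.next()
        if tok[0] == "(":
            inner = self.parse_expr()
            self.expect(")")
            return inner
        if tok[0] != "name":
            raise QuerySyntaxError(f"expected a name, found {tok[1]!r}", tok[2])
        nxt = self.peek()
        if nxt is not None and nxt[0] == "some":
            self.next()
            filler = self.parse_primary()
            prop = self.ontology.resolve_property(tok[1])
            return Existential(prop, filler)
        return Named(self.ontology.resolve_label(tok[1]))


def parse_expression(text: str, ontology: Ontology) -> ClassExpression:
    """Parse a class-expression string against an ontology's vocabulary."""
    tokens = _tokenize(text)
    if not tokens:
        raise QuerySyntaxError("empty expression")
    parser = _Parser(tokens, ontology)
    expr = parser.parse_expr()
    trailing = parser.peek()
    if trailing is not None:
        raise QuerySyntaxError(f"trailing input {trailing[1]!r}", trailing[2])
    return expr


def render_expression(expr: ClassExpression, ontology: Ontology) -> str:
    """Render an expression back to the grammar, using quoted labels.

    ``parse_expression(render_expression(e)) == e`` for any expression over
    a valid ontology.
    """
    if isinstance(expr, Named):
        return f"'{ontology.label_of(expr.cls)}'"
    if isinstance(expr, Existential):
        filler = render_expression(expr.filler, ontology)
        if isinstance(expr.filler, Conjunction):
            filler = f"({filler})"
        prop = ontology.properties[expr.prop].label
        return f"'{prop}' some {filler}"
    parts = []
    for c in expr.conjuncts:
        rendered = render_expression(c, ontology)
        if isinstance(c, Existential):
            rendered = f"({rendered})"
        parts.append(rendered)
    return " and ".join(parts)
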