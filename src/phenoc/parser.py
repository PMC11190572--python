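"""Parser for the semantic-phenotype description language.

A description is a sequence of statements, each a chain of *nodes*
(ontology terms, node lists, or numeric literals) joined by *edges*
(operator glyphs or dotted object properties), closed by ``;``:

    uberon-male_organism > aism-metafemur > bspo-dorsal_margin > aism-cuticular_carina;

Edge glyphs: ``>`` has_part, ``<`` part_of, ``>>`` has_characteristic,
``<<`` characteristic_of, ``|>|`` / ``|<|`` increased/decreased in
magnitude, ``!>`` negated has_part (absence).  Any registered property can
be written in dotted form ``.prefix-local``.  Nodes may carry an identity
tag (``iao-measurement_datum:md-c4c164``), an OTU binding
(``uberon-male_organism::grebennikovius_armiger``) and bracketed options
(``[exclude = True]``).

Statements are grouped into per-species blocks::

    otu grebennikovius_armiger {
      label = "Grebennikovius armiger"
      taxon_id = "http://zoobank.org/..."
      ...metadata...
      <statements>
    }

Whitespace and newlines are insignificant outside quoted strings, so a
measurement statement may be broken across lines freely.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterator, Optional

import yaml

from .terms import ALIAS_TABLE, DEFAULT_PREFIX_BASES


class PhenoscriptError(ValueError):
    def __init__(self, message: str, line: int = 0, col: int = 0) -> None:
        super().__init__(f"line {line}:{col}: {message}" if line else message)
        self.line = line
        self.col = col


class LexError(PhenoscriptError):
    pass


class SyntaxErrorPS(PhenoscriptError):
    pass


class UnresolvedPrefixError(PhenoscriptError):
    pass


# ---------------------------------------------------------------------------
# Lexer
# ---------------------------------------------------------------------------

GLYPHS = ("|>|", "|<|", "!>", ">>", "<<", ">", "<")

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+|\#[^\n]*)
  | (?P<number>\d+(?:\.\d+)?)
  | (?P<glyph>\|\>\||\|\<\||!>|>>|<<|>|<)
  | (?P<dotprop>\.[A-Za-z_][A-Za-z0-9_\-]*)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_\-]*)
  | (?P<string>"[^"\n]*")
  | (?P<dcolon>::)
  | (?P<punct>[:(),;\[\]={}])
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class Token:
    kind: str  # number|glyph|dotprop|ident|string|dcolon|punct|eof
    value: str
    line: int
    col: int


def lex(text: str) -> list[Token]:
    """Tokenize description source; raises :class:`LexError` with position."""
    tokens: list[Token] = []
    pos, line, line_start = 0, 1, 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            col = pos - line_start + 1
            raise LexError(f"illegal character {text[pos]!r}", line, col)
        kind = m.lastgroup or ""
        value = m.group()
        if kind != "ws":
            tokens.append(Token(kind, value, line, m.start() - line_start + 1))
        nl = value.count("\n")
        if nl:
            line += nl
            line_start = m.start() + value.rfind("\n") + 1
        pos = m.end()
    tokens.append(Token("eof", "", line, len(text) - line_start + 1))
    return tokens


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass
class NodeExpr:
    """A node in a statement chain.

    ``kind`` is ``"term"`` (ontology class reference, possibly tagged or
    OTU-bound), ``"literal"`` (terminal number) or ``"list"`` (parenthesised
    term nodes over which the incoming edge distributes).
    """

    kind: str
    term: Optional[str] = None          # curie, kind == "term"
    tag: Optional[str] = None
    otu_binding: Optional[str] = None
    exclude: bool = False
    options: dict[str, str] = field(default_factory=dict)
    value: Optional[Decimal] = None     # kind == "literal"; Decimal keeps
                                        # the written precision ("1.0" != "1")
    items: list["NodeExpr"] = field(default_factory=list)  # kind == "list"
    # raw single-colon suffix; resolved to tag or otu_binding by the document
    colon_suffix: Optional[str] = None


@dataclass
class EdgeExpr:
    """An edge: operator glyph or dotted property curie, optionally negated."""

    property: str    # glyph (">", "|<|", ...) or curie for dotted properties
    negated: bool = False
    dotted: bool = False


@dataclass
class StatementAST:
    elements: list  # alternating NodeExpr / EdgeExpr, node-terminated
    source_span: tuple[int, int] = (0, 0)  # (start line, end line)

    @property
    def nodes(self) -> list[NodeExpr]:
        return [e for e in self.elements if isinstance(e, NodeExpr)]

    @property
    def edges(self) -> list[EdgeExpr]:
        return [e for e in self.elements if isinstance(e, EdgeExpr)]


@dataclass
class OTUDecl:
    otu_id: str
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.metadata.get("label", self.otu_id.replace("_", " "))


@dataclass
class ProjectConfig:
    title: str = ""
    authors: list[str] = field(default_factory=list)
    prefixes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PREFIX_BASES))
    organism_class: str = "uberon-male_organism"

    @classmethod
    def from_yaml(cls, text: str) -> "ProjectConfig":
        data = yaml.safe_load(text) or {}
        prefixes = dict(DEFAULT_PREFIX_BASES)
        prefixes.update(data.get("prefixes") or {})
        return cls(
            title=data.get("title", ""),
            authors=list(data.get("authors") or []),
            prefixes=prefixes,
            organism_class=data.get("organism_class", "uberon-male_organism"),
        )


@dataclass
class Document:
    config: ProjectConfig
    otus: list[OTUDecl]
    statements: dict[str, list[StatementAST]]  # otu_id -> ordered statements

    @property
    def otu_ids(self) -> list[str]:
        return [o.otu_id for o in self.otus]


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, tokens: list[Token]) -> None:
        self.tokens = tokens
        self.i = 0

    @property
    def cur(self) -> Token:
        return self.tokens[self.i]

    def advance(self) -> Token:
        tok = self.cur
        if tok.kind != "eof":
            self.i += 1
        return tok

    def expect(self, kind: str, value: Optional[str] = None) -> Token:
        tok = self.cur
        if tok.kind != kind or (value is not None and tok.value != value):
            want = value or kind
            raise SyntaxErrorPS(f"expected {want!r}, found {tok.value!r}",
                                tok.line, tok.col)
        return self.advance()

    # -- nodes -----------------------------------------------------------

    def _term_node(self) -> NodeExpr:
        tok = self.expect("ident")
        if "-" not in tok.value:
            raise SyntaxErrorPS(
                f"term {tok.value!r} lacks an ontology prefix", tok.line, tok.col
            )
        node = NodeExpr(kind="term", term=tok.value)
        if self.cur.kind == "dcolon":
            self.advance()
            node.otu_binding = self.expect("ident").value
        elif self.cur.kind == "punct" and self.cur.value == ":":
            self.advance()
            node.colon_suffix = self.expect("ident").value
        while self.cur.kind == "punct" and self.cur.value == "[":
            self.advance()
            key = self.expect("ident").value
            self.expect("punct", "=")
            val_tok = self.advance()
            if val_tok.kind not in ("ident", "number", "string"):
                raise SyntaxErrorPS("malformed option value", val_tok.line, val_tok.col)
            self.expect("punct", "]")
            node.options[key] = val_tok.value.strip('"')
        if "exclude" in node.options:
            node.exclude = node.options["exclude"].lower() == "true"
        unknown = set(node.options) - {"exclude"}
        if unknown:
            import warnings
            warnings.warn(f"unknown node options ignored: {sorted(unknown)}",
                          stacklevel=4)
        return node

    def _node(self) -> NodeExpr:
        tok = self.cur
        if tok.kind == "number":
            self.advance()
            return NodeExpr(kind="literal", value=Decimal(tok.value))
        if tok.kind == "punct" and tok.value == "(":
            self.advance()
            items = [self._term_node()]
            while self.cur.kind == "punct" and self.cur.value == ",":
                self.advance()
                items.append(self._term_node())
            self.expect("punct", ")")
            return NodeExpr(kind="list", items=items)
        if tok.kind == "ident":
            return self._term_node()
        raise SyntaxErrorPS(f"expected a node, found {tok.value!r}",
                            tok.line, tok.col)

    # -- statements ------------------------------------------------------

    def statement(self) -> StatementAST:
        start = self.cur.line
        if self.cur.kind in ("glyph", "dotprop"):
            raise SyntaxErrorPS("statement may not begin with an edge",
                                self.cur.line, self.cur.col)
        elements: list = [self._node()]
        while True:
            tok = self.cur
            if tok.kind == "punct" and tok.value == ";":
                end = tok.line
                self.advance()
                return StatementAST(elements=elements, source_span=(start, end))
            if tok.kind == "glyph":
                self.advance()
                if tok.value == "!>":
                    edge = EdgeExpr(property=">", negated=True)
                else:
                    edge = EdgeExpr(property=tok.value)
            elif tok.kind == "dotprop":
                self.advance()
                edge = EdgeExpr(property=tok.value[1:], dotted=True)
            elif tok.kind == "eof":
                raise SyntaxErrorPS("unterminated statement (missing ';')",
                                    tok.line, tok.col)
            else:
                raise SyntaxErrorPS(f"expected an edge or ';', found {tok.value!r}",
                                    tok.line, tok.col)
            if self.cur.kind == "punct" and self.cur.value == ";":
                raise SyntaxErrorPS("statement may not end with an edge",
                                    self.cur.line, self.cur.col)
            elements.append(edge)
            elements.append(self._node())

    # -- document --------------------------------------------------------

    def document(self, config: ProjectConfig) -> Document:
        otus: list[OTUDecl] = []
        statements: dict[str, list[StatementAST]] = {}
        while self.cur.kind != "eof":
            self.expect("ident", "otu")
            otu_id = self.expect("ident").value
            decl = OTUDecl(otu_id=otu_id)
            otus.append(decl)
            statements[otu_id] = []
            self.expect("punct", "{")
            while not (self.cur.kind == "punct" and self.cur.value == "}"):
                if self.cur.kind == "eof":
                    raise SyntaxErrorPS(f"unclosed otu block {otu_id!r}",
                                        self.cur.line, self.cur.col)
                if (self.cur.kind == "ident" and "-" not in self.cur.value
                        and self.tokens[self.i + 1].kind == "punct"
                        and self.tokens[self.i + 1].value == "="):
                    key = self.advance().value
                    self.advance()  # '='
                    val = self.advance()
                    if val.kind not in ("string", "ident", "number"):
                        raise SyntaxErrorPS("malformed metadata value",
                                            val.line, val.col)
                    decl.metadata[key] = val.value.strip('"')
                else:
                    statements[otu_id].append(self.statement())
            self.advance()  # '}'
        return Document(config=config, otus=otus, statements=statements)


def parse_statement(text: str) -> StatementAST:
    """Parse a single ``;``-terminated statement.

    Outside a document, a single-colon suffix is an identity tag.
    """
    p = _Parser(lex(text))
    stmt = p.statement()
    if p.cur.kind != "eof":
        raise SyntaxErrorPS("trailing content after statement",
                            p.cur.line, p.cur.col)
    _resolve_colons(stmt, set())
    return stmt


def _iter_term_nodes(stmt: StatementAST) -> Iterator[NodeExpr]:
    for el in stmt.elements:
        if isinstance(el, NodeExpr):
            if el.kind == "list":
                yield from el.items
            elif el.kind == "term":
                yield el


def _resolve_colons(stmt: StatementAST, otu_ids: set[str]) -> None:
    # a single-colon suffix is an OTU binding when it names a declared OTU
    # (both spellings occur in the wild), otherwise an identity tag
    for node in _iter_term_nodes(stmt):
        if node.colon_suffix is not None:
            if node.colon_suffix in otu_ids:
                node.otu_binding = node.colon_suffix
            else:
                node.tag = node.colon_suffix
            node.colon_suffix = None


def _check_prefixes(doc: Document) -> None:
    declared = set(doc.config.prefixes)
    for otu_id, stmts in doc.statements.items():
        for stmt in stmts:
            for node in _iter_term_nodes(stmt):
                prefix = (node.term or "").split("-", 1)[0]
                if prefix not in declared:
                    line = stmt.source_span[0]
                    raise UnresolvedPrefixError(
                        f"prefix {prefix!r} not declared in config "
                        f"(term {node.term}, otu {otu_id})", line, 0
                    )
            for edge in stmt.edges:
                if edge.dotted:
                    prefix = edge.property.split("-", 1)[0]
                    if prefix not in declared:
                        raise UnresolvedPrefixError(
                            f"prefix {prefix!r} not declared in config "
                            f"(property .{edge.property})", stmt.source_span[0], 0
                        )


def parse_document(text: str, config: str | ProjectConfig) -> Document:
    """Parse a full description (OTU blocks with statements) plus config."""
    cfg = config if isinstance(config, ProjectConfig) else ProjectConfig.from_yaml(config)
    doc = _Parser(lex(text)).document(cfg)
    otu_ids = set(doc.otu_ids)
    for stmts in doc.statements.values():
        for stmt in stmts:
            _resolve_colons(stmt, otu_ids)
    _check_prefixes(doc)
    return doc


# ---------------------------------------------------------------------------
# Unparse (canonical form)
# ---------------------------------------------------------------------------

def _unparse_term(node: NodeExpr) -> str:
    s = node.term or ""
    if node.otu_binding:
        s += f"::{node.otu_binding}"
    elif node.tag:
        s += f":{node.tag}"
    elif node.colon_suffix:
        s += f":{node.colon_suffix}"
    for key in sorted(node.options):
        val = node.options[key]
        s += f"[{key} = {val}]"
    return s


def _unparse_node(node: NodeExpr) -> str:
    if node.kind == "literal":
        return str(node.value)
    if node.kind == "list":
        return "(" + ", ".join(_unparse_term(i) for i in node.items) + ")"
    return _unparse_term(node)


def unparse_statement(stmt: StatementAST) -> str:
    """Canonical single-line source for a statement (re-parses identically)."""
    parts: list[str] = []
    for el in stmt.elements:
        if isinstance(el, NodeExpr):
            parts.append(_unparse_node(el))
        else:
            if el.negated:
                parts.append("!>")
            elif el.dotted:
                parts.append("." + el.property)
            else:
                parts.append(el.property)
    return " ".join(parts) + ";"


def unparse_document(doc: Document) -> str:
    blocks: list[str] = []
    for otu in doc.otus:
        lines = [f"otu {otu.otu_id} {{"]
        for key, val in otu.metadata.items():
            lines.append(f'  {key} = "{val}"')
        for stmt in doc.statements.get(otu.otu_id, []):
            lines.append("  " + unparse_statement(stmt))
        lines.append("}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
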