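"""Aligned-layer query language: AST, parser, renderer, SDM expansion.

Grammar (whitespace separates top-level nodes; any node may carry a
trailing ``^w`` weight):

    term        := [layer ':'] value            (bare value -> layer "text")
    list        := '#l(' member ('|' member)* ')'
    phrase      := '#p(' window '|' ordered '|' comp ('|' comp)+ ')'
    relation    := '#r(' layer '|' pattern '|' pattern ')'
    comp        := term | list
    member      := term
    pattern     := '*' | term

Rendering then re-parsing is the identity on valid ASTs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple, Union

from .layer_model import TEXT_LAYER


class QueryParseError(ValueError):
    """Parse failure; carries the character position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


def _format_weight(w: float) -> str:
    return f"{w:g}"


@dataclass(frozen=True)
class Term:
    layer: str
    value: str
    weight: float = 1.0


@dataclass(frozen=True)
class ListNode:
    """Disjunctive group; members are scored individually when standalone
    and act as a single any-member matcher inside a phrase."""

    members: Tuple[Term, ...]
    weight: float = 1.0


@dataclass(frozen=True)
class Phrase:
    window: int
    ordered: bool
    components: Tuple[Union[Term, ListNode], ...]
    weight: float = 1.0


WILDCARD = "*"


@dataclass(frozen=True)
class Relation:
    layer: str
    label_pattern: str
    source: Union[Term, str]  # Term or WILDCARD
    target: Union[Term, str]
    weight: float = 1.0


QueryNode = Union[Term, ListNode, Phrase, Relation]


@dataclass(frozen=True)
class Query:
    nodes: Tuple[QueryNode, ...]


def _validate_node(node: QueryNode, pos: int) -> None:
    if node.weight <= 0:
        raise QueryParseError("weight must be positive", pos)
    if isinstance(node, Phrase):
        if node.window < 1:
            raise QueryParseError("phrase window must be >= 1", pos)
        if len(node.components) < 2:
            raise QueryParseError("phrase needs at least 2 components", pos)
    if isinstance(node, ListNode) and not node.members:
        raise QueryParseError("list needs at least 1 member", pos)


_TERM_DELIMS = set(" \t\n|()^")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> QueryParseError:
        return QueryParseError(msg, self.pos)

    def eof(self) -> bool:
        return self.pos >= len(self.text)

    def peek(self) -> str:
        return self.text[self.pos] if not self.eof() else ""

    def skip_ws(self) -> None:
        while not self.eof() and self.text[self.pos].isspace():
            self.pos += 1

    def expect(self, ch: str) -> None:
        if self.eof() or self.text[self.pos] != ch:
            raise self.error(f"expected {ch!r}")
        self.pos += 1

    def read_until_delim(self) -> str:
        start = self.pos
        while not self.eof() and self.text[self.pos] not in _TERM_DELIMS:
            self.pos += 1
        if self.pos == start:
            raise self.error("expected a value")
        return self.text[start : self.pos]

    # -- grammar productions ------------------------------------------------

    def parse_term(self) -> Term:
        raw = self.read_until_delim()
        if ":" in raw:
            layer, value = raw.split(":", 1)
            if not layer or not value:
                raise self.error(f"malformed term {raw!r}")
            return Term(layer, value)
        return Term(TEXT_LAYER, raw)

    def parse_list(self) -> ListNode:
        opening = self.pos
        self.pos += 2  # "#l"
        self.expect("(")
        members = []
        while True:
            self.skip_ws()
            members.append(self.parse_term())
            self.skip_ws()
            if self.peek() == "|":
                self.pos += 1
                continue
            break
        self.expect(")")
        node = ListNode(tuple(members))
        _validate_node(node, opening)
        return node

    def parse_phrase(self) -> Phrase:
        opening = self.pos
        self.pos += 2  # "#p"
        self.expect("(")
        self.skip_ws()
        window_s = self.read_until_delim()
        try:
            window = int(window_s)
        except ValueError:
            raise QueryParseError(f"bad window {window_s!r}", opening)
        self.skip_ws()
        self.expect("|")
        self.skip_ws()
        ordered_s = self.read_until_delim().lower()
        if ordered_s not in ("true", "false"):
            raise QueryParseError(f"ordering must be true/false, got {ordered_s!r}", opening)
        components: List[Union[Term, ListNode]] = []
        while True:
            self.skip_ws()
            if self.peek() == "|":
                self.pos += 1
                self.skip_ws()
                if self.text.startswith("#l", self.pos):
                    components.append(self.parse_list())
                else:
                    components.append(self.parse_term())
                continue
            break
        self.skip_ws()
        self.expect(")")
        node = Phrase(window, ordered_s == "true", tuple(components))
        _validate_node(node, opening)
        return node

    def parse_relation(self) -> Relation:
        opening = self.pos
        self.pos += 2  # "#r"
        self.expect("(")
        self.skip_ws()
        layer = self.read_until_delim()
        patterns: List[Union[Term, str]] = []
        for _ in range(2):
            self.skip_ws()
            self.expect("|")
            self.skip_ws()
            if self.peek() == "*":
                self.pos += 1
                patterns.append(WILDCARD)
            else:
                patterns.append(self.parse_term())
        self.skip_ws()
        self.expect(")")
        # layer token may itself carry a label pattern "layer" (all labels)
        node = Relation(layer, WILDCARD, patterns[0], patterns[1])
        _validate_node(node, opening)
        return node

    def parse_node(self) -> QueryNode:
        opening = self.pos
        if self.text.startswith("#p(", self.pos):
            node: QueryNode = self.parse_phrase()
        elif self.text.startswith("#l(", self.pos):
            node = self.parse_list()
        elif self.text.startswith("#r(", self.pos):
            node = self.parse_relation()
        else:
            node = self.parse_term()
        if self.peek() == "^":
            self.pos += 1
            weight_s = self.read_until_delim()
            try:
                weight = float(weight_s)
            except ValueError:
                raise self.error(f"bad weight {weight_s!r}")
            node = replace(node, weight=weight)
        _validate_node(node, opening)
        return node

    def parse_query(self) -> Query:
        nodes = []
        self.skip_ws()
        while not self.eof():
            nodes.append(self.parse_node())
            self.skip_ws()
        if not nodes:
            raise self.error("empty query")
        return Query(tuple(nodes))


def parse_query(text: str) -> Query:
    """Parse a query string into an AST; raises QueryParseError with position."""
    parser = _Parser(text)
    query = parser.parse_query()
    # relation label patterns are written "#r(layer/label|...)" is not part of
    # the dialect; a label pattern may be attached via "layer" only when the
    # name contains a '/' separator.
    fixed = []
    for node in query.nodes:
        if isinstance(node, Relation) and "/" in node.layer:
            layer, label = node.layer.split("/", 1)
            node = replace(node, layer=layer, label_pattern=label)
        fixed.append(node)
    return Query(tuple(fixed))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_term_bare(t: Term) -> str:
    return t.value if t.layer == TEXT_LAYER else f"{t.layer}:{t.value}"


def _render_node_bare(node: QueryNode) -> str:
    if isinstance(node, Term):
        return _render_term_bare(node)
    if isinstance(node, ListNode):
        return "#l(" + "|".join(_render_term_bare(m) for m in node.members) + ")"
    if isinstance(node, Phrase):
        comps = "|".join(_render_node_bare(c) for c in node.components)
        return f"#p({node.window}|{'true' if node.ordered else 'false'}|{comps})"
    if isinstance(node, Relation):
        layer = node.layer if node.label_pattern == WILDCARD else f"{node.layer}/{node.label_pattern}"
        src = WILDCARD if node.source == WILDCARD else _render_term_bare(node.source)
        tgt = WILDCARD if node.target == WILDCARD else _render_term_bare(node.target)
        return f"#r({layer}|{src}|{tgt})"
    raise TypeError(f"not a query node: {node!r}")


def render_node(node: QueryNode) -> str:
    s = _render_node_bare(node)
    if node.weight != 1.0:
        s += f"^{_format_weight(node.weight)}"
    return s


def render_query(q: Query) -> str:
    """Canonical string form; ``parse_query(render_query(q))`` equals ``q``."""
    return " ".join(render_node(n) for n in q.nodes)


# ---------------------------------------------------------------------------
# Sequential-dependence (MRF) expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SDMConfig:
    """Interpolation weights and window schedule for SDM expansion."""

    term_weight: float = 0.85
    ordered_weight: float = 0.1
    unordered_weight: float = 0.05
    window_per_component: int = 4
    max_components: int = 5


def sdm_expand(
    atoms: Sequence[Union[Term, ListNode]], config: SDMConfig | None = None
) -> Query:
    """Sequential-dependence expansion of an ordered atom sequence.

    Emits every atom reweighted, then for each contiguous subsequence of
    length ``k`` (2 <= k <= max_components, shortest first, left to right)
    an ordered and an unordered phrase with window ``k * window_per_component``.
    """
    config = config or SDMConfig()
    if not atoms:
        raise ValueError("sdm_expand requires at least one atom")
    for atom in atoms:
        if not isinstance(atom, (Term, ListNode)):
            raise TypeError(f"SDM atoms must be terms or lists, got {type(atom).__name__}")

    nodes: List[QueryNode] = [replace(a, weight=config.term_weight) for a in atoms]
    bare = [replace(a, weight=1.0) for a in atoms]
    n = len(atoms)
    for k in range(2, min(n, config.max_components) + 1):
        window = k * config.window_per_component
        for i in range(n - k + 1):
            comps = tuple(bare[i : i + k])
            nodes.append(Phrase(window, True, comps, config.ordered_weight))
            nodes.append(Phrase(window, False, comps, config.unordered_weight))
    return Query(tuple(nodes))


def sdm_size(n: int, max_components: int = 5) -> int:
    """Closed-form node count of sdm_expand on n atoms."""
    return n + 2 * sum(n - k + 1 for k in range(2, min(n, max_components) + 1))


def query_atoms(q: Query) -> List[Union[Term, ListNode]]:
    """Extract the Term/List atoms of a flat query (for SDM expansion)."""
    atoms = []
    for node in q.nodes:
        if isinstance(node, (Term, ListNode)):
            atoms.append(node)
        else:
            raise ValueError(
                "SDM expansion expects a flat query of terms and lists; "
                f"found {type(node).__name__}"
            )
    return atoms
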