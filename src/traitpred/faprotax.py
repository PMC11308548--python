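"""Parser for the FAPROTAX flat-text taxon→function database.

FAPROTAX is a literature-curated database that associates prokaryotic taxa
with phenotypic and metabolic functions.  Each functional group is declared
by a non-indented header line ``name<TAB>annotation`` and is followed, until
the next header, by its member lines: taxonomic paths whose levels are
separated and delimited by asterisks (e.g. ``*Archaea*Methanosarcina*``).
Groups may also reference each other through set-operation directives
(``add_group:NAME``, ``subtract_group:NAME``, ``intersect_group:NAME``),
which gives the database a hierarchical structure.  This module parses that
dialect, resolves the directive graph and emits a binary taxon×function
membership matrix.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

_DIRECTIVE_RE = re.compile(
    r"^(add|subtract|intersect)_group\s*:\s*(\S.*?)\s*$"
)

#: operation keywords accepted in directive lines
OPERATIONS = ("add", "subtract", "intersect")


class FaprotaxParseError(ValueError):
    """Raised on malformed database content (duplicate groups, bad refs)."""


class FaprotaxResolutionError(ValueError):
    """Raised when the directive graph cannot be resolved (cycles)."""


def canonical_taxon(raw: str) -> str:
    """Canonical identity of a member taxon path.

    Strips surrounding whitespace and the delimiting asterisks; internal
    asterisks are kept as level separators.  Case is preserved (matching
    against a taxonomy handles case downstream).
    """
    return raw.strip().strip("*").strip()


def leaf_name(taxon_path: str) -> str:
    """Deepest (rightmost) named level of a canonical taxon path."""
    return taxon_path.rsplit("*", 1)[-1].strip()


@dataclass
class FunctionalGroup:
    """One functional group: literal members plus set-operation directives."""

    name: str
    annotation: str = ""
    members: list[str] = field(default_factory=list)
    directives: list[tuple[str, str]] = field(default_factory=list)

    def add_member(self, raw: str) -> None:
        taxon = canonical_taxon(raw)
        if taxon and taxon not in self.members:  # stored without repetition
            self.members.append(taxon)


@dataclass
class FunctionalGroupSet:
    """All groups of one database file, keyed by group name."""

    groups: dict[str, FunctionalGroup] = field(default_factory=dict)
    source_version: str = ""

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups.values())

    def __getitem__(self, name: str) -> FunctionalGroup:
        return self.groups[name]

    def to_text(self) -> str:
        """Serialize back to the flat-file dialect (round-trip safe)."""
        lines: list[str] = []
        for g in self.groups.values():
            lines.append(f"{g.name}\t{g.annotation}")
            for m in g.members:
                lines.append(f"*{m}*")
            for op, target in g.directives:
                lines.append(f"{op}_group:{target}")
            lines.append("")
        return "\n".join(lines)


def _looks_like_header(line: str) -> bool:
    # header lines are non-indented and carry a TAB between name and
    # annotation; member paths never start a line with a TAB-bearing name
    return "\t" in line and not line.startswith(("*", " ", "\t"))


def parse_faprotax(text: str, source_version: str = "") -> FunctionalGroupSet:
    """Parse FAPROTAX flat-file content into a :class:`FunctionalGroupSet`.

    Comment lines (leading ``#``) and blank lines are permitted anywhere.
    Unknown line types are skipped with a logged warning.  Duplicate group
    names and directives naming undefined groups raise
    :class:`FaprotaxParseError`; the undefined-reference check runs after
    the full file scan so every forward reference is legal.
    """
    fgs = FunctionalGroupSet(source_version=source_version)
    current: FunctionalGroup | None = None
    pending_refs: list[tuple[str, str, int]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = _DIRECTIVE_RE.match(stripped)
        if m:
            if current is None:
                raise FaprotaxParseError(
                    f"line {lineno}: directive before any group header"
                )
            op, target = m.group(1), m.group(2)
            current.directives.append((op, target))
            pending_refs.append((current.name, target, lineno))
            continue
        if _looks_like_header(line):
            name, _, annotation = line.partition("\t")
            name = name.strip()
            if not name:
                raise FaprotaxParseError(f"line {lineno}: empty group name")
            if name in fgs.groups:
                raise FaprotaxParseError(
                    f"line {lineno}: duplicate group name {name!r}"
                )
            current = FunctionalGroup(name=name, annotation=annotation.strip())
            fgs.groups[name] = current
            continue
        if stripped.startswith("*") or "*" in stripped:
            if current is None:
                raise FaprotaxParseError(
                    f"line {lineno}: member taxon before any group header"
                )
            current.add_member(stripped)
            continue
        logger.warning("faprotax: skipping unrecognized line %d: %r",
                       lineno, stripped[:80])

    for group, target, lineno in pending_refs:
        if target not in fgs.groups:
            raise FaprotaxParseError(
                f"line {lineno}: group {group!r} references undefined "
                f"group {target!r}"
            )
    _check_acyclic(fgs)
    return fgs


def _directive_graph(fgs: FunctionalGroupSet) -> dict[str, list[str]]:
    return {name: [t for _, t in g.directives] for name, g in fgs.groups.items()}


def _check_acyclic(fgs: FunctionalGroupSet) -> None:
    order = _topological_order(fgs)
    if order is None:
        cycle = _find_cycle(_directive_graph(fgs))
        raise FaprotaxParseError(
            f"directive graph contains a cycle: {' -> '.join(cycle)}"
        )


def _topological_order(fgs: FunctionalGroupSet) -> list[str] | None:
    """Order in which groups can be resolved (dependencies first)."""
    graph = _directive_graph(fgs)
    state: dict[str, int] = {}  # 0 visiting, 1 done
    order: list[str] = []

    def visit(node: str) -> bool:
        if state.get(node) == 1:
            return True
        if state.get(node) == 0:
            return False  # back edge
        state[node] = 0
        for dep in graph.get(node, ()):
            if not visit(dep):
                return False
        state[node] = 1
        order.append(node)
        return True

    for name in graph:
        if not visit(name):
            return None
    return order


def _find_cycle(graph: dict[str, list[str]]) -> list[str]:
    path: list[str] = []
    on_path: set[str] = set()
    done: set[str] = set()

    def visit(node: str) -> list[str] | None:
        if node in done:
            return None
        if node in on_path:
            return path[path.index(node):] + [node]
        path.append(node)
        on_path.add(node)
        for dep in graph.get(node, ()):
            found = visit(dep)
            if found:
                return found
        path.pop()
        on_path.discard(node)
        done.add(node)
        return None

    for n in graph:
        found = visit(n)
        if found:
            return found
    return []


def resolve_groups(fgs: FunctionalGroupSet) -> dict[str, set[str]]:
    """Resolve every group to its final taxon membership.

    Directives are applied in file order on top of the literal members:
    ``add`` is set union, ``subtract`` set difference, ``intersect`` set
    intersection.  Referenced groups are fully resolved first (topological
    order), so a directive always sees its target's final membership.
    """
    order = _topological_order(fgs)
    if order is None:
        cycle = _find_cycle(_directive_graph(fgs))
        raise FaprotaxResolutionError(
            f"cannot resolve groups, directive cycle: {' -> '.join(cycle)}"
        )
    resolved: dict[str, set[str]] = {}
    for name in order:
        group = fgs.groups[name]
        membership = set(group.members)
        for op, target in group.directives:
            other = resolved[target]
            if op == "add":
                membership |= other
            elif op == "subtract":
                membership -= other
            elif op == "intersect":
                membership &= other
            else:  # pragma: no cover - parser restricts operations
                raise FaprotaxResolutionError(f"unknown operation {op!r}")
        resolved[name] = membership
    # return in original file order for stable downstream behaviour
    return {name: resolved[name] for name in fgs.groups}


def build_taxon_function_matrix(
    resolved: dict[str, set[str]],
) -> pd.DataFrame:
    """Binary taxon×function membership matrix.

    Rows are the lexicographically sorted union of all resolved
    memberships (taxa subtracted out of every group do not appear: each
    row has at least one positive cell); columns are sorted group names.
    """
    if not resolved:
        raise ValueError("no resolved groups")
    taxa = sorted(set().union(*resolved.values()))
    functions = sorted(resolved)
    matrix = pd.DataFrame(0, index=taxa, columns=functions, dtype="int8")
    for fn in functions:
        members = resolved[fn]
        if members:
            matrix.loc[sorted(members), fn] = 1
    matrix.index.name = "taxon"
    return matrix


def group_report(fgs: FunctionalGroupSet,
                 resolved: dict[str, set[str]] | None = None) -> str:
    """JSON report of group sizes and the directive graph."""
    if resolved is None:
        resolved = resolve_groups(fgs)
    payload = {
        "source_version": fgs.source_version,
        "n_groups": len(fgs),
        "groups": {
            name: {
                "literal_members": len(g.members),
                "resolved_members": len(resolved[name]),
                "directives": [f"{op}_group:{t}" for op, t in g.directives],
            }
            for name, g in fgs.groups.items()
        },
    }
    return json.dumps(payload, indent=2)
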