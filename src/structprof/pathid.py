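"""Path-tree stable identifiers.

Entities are addressed by hierarchical identifiers of the form
``PDB/assembly/chain/NAME`NUM[/...]`` — e.g. ``2P33/0/A/J07`507`` is the
ligand J07 507 in chain A of the asymmetric unit (assembly 0) of entry
2P33.  The identifiers are deliberately deducible from PDB conventions and
support two query operations modelled on PostgreSQL's ltree type:

* :func:`path_match` — wildcard matching, where a bare ``*`` level matches
  *zero or more* levels and a token containing ``*`` matches within a
  single level (so ``*/STI*`` matches any id whose last level starts with
  ``STI``);
* :func:`is_descendant` — prefix containment (``1OPJ`` is an ancestor of
  every identifier inside entry 1OPJ).
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass


class PathError(ValueError):
    """Raised for malformed path identifiers or patterns."""


MAX_LEVELS = 6


@dataclass(frozen=True)
class PathID:
    components: tuple[str, ...]

    def __init__(self, *components: str):
        if len(components) == 1 and "/" in components[0]:
            components = tuple(components[0].split("/"))
        if not 1 <= len(components) <= MAX_LEVELS:
            raise PathError(f"path must have 1-{MAX_LEVELS} levels, "
                            f"got {len(components)}")
        for c in components:
            if not c:
                raise PathError("empty path level")
            if "/" in c:
                raise PathError(f"'/' inside path level: {c!r}")
        object.__setattr__(self, "components", tuple(components))

    def __str__(self) -> str:
        return path_format(self)

    @property
    def pdb_id(self) -> str:
        return self.components[0]

    @property
    def residue_token(self) -> str | None:
        return self.components[3] if len(self.components) >= 4 else None


def residue_token(name: str, number: int, insertion_code: str = "") -> str:
    """Format the residue level, e.g. ``J07`507`` (icode appended)."""
    return f"{name}`{number}{insertion_code}"


def split_residue_token(token: str) -> tuple[str, int, str]:
    """Inverse of :func:`residue_token`."""
    if "`" not in token:
        raise PathError(f"residue token without '`': {token!r}")
    name, num = token.split("`", 1)
    icode = ""
    while num and not num[-1].isdigit():
        icode = num[-1] + icode
        num = num[:-1]
    if not name or not num:
        raise PathError(f"malformed residue token: {token!r}")
    try:
        return name, int(num), icode
    except ValueError as exc:  # pragma: no cover - guarded above
        raise PathError(f"malformed residue token: {token!r}") from exc


def path_format(pid: PathID) -> str:
    return "/".join(pid.components)


def path_parse(s: str) -> PathID:
    if not s:
        raise PathError("empty path string")
    return PathID(*s.split("/"))


def _match_levels(levels: tuple[str, ...], pattern: tuple[str, ...]) -> bool:
    # Dynamic recursion; '*' as a whole level spans zero or more levels.
    if not pattern:
        return not levels
    head, rest = pattern[0], pattern[1:]
    if head == "*":
        return any(_match_levels(levels[i:], rest)
                   for i in range(len(levels) + 1))
    if not levels:
        return False
    if not fnmatch.fnmatchcase(levels[0], head):
        return False
    return _match_levels(levels[1:], rest)


def path_match(pid: PathID | str, pattern: str) -> bool:
    """True iff the identifier matches the wildcard pattern."""
    if isinstance(pid, str):
        pid = path_parse(pid)
    if not pattern:
        raise PathError("empty pattern")
    pat_levels = tuple(pattern.split("/"))
    for p in pat_levels:
        if not p:
            raise PathError(f"empty level in pattern {pattern!r}")
    return _match_levels(pid.components, pat_levels)


def is_descendant(pid: PathID | str, ancestor: PathID | str) -> bool:
    """True iff ``ancestor`` is a (non-strict) prefix of ``pid``."""
    if isinstance(pid, str):
        pid = path_parse(pid)
    if isinstance(ancestor, str):
        ancestor = path_parse(ancestor)
    anc = ancestor.components
    return pid.components[: len(anc)] == anc
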