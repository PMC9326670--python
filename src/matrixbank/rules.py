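"""The six construction rules as set/transform operations on one family.

Each rule relates the first two cells of a row to the third within its
scope family: addition (union), subtraction (difference), disjunctive
union (symmetric difference), intersection, rotation (one orbit step per
cell along the row), and completeness (the row must exhibit a fixed
required set, the third cell supplying whatever is missing).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .elements import CCW, CW, family_members, family_of, rotate_set
from .errors import ConfigurationError, RuleViolationError


class RuleKind(str, Enum):
    ADD = "ADD"
    SUB = "SUB"
    DIS = "DIS"
    INT = "INT"
    ROT = "ROT"
    COM = "COM"


RULE_KINDS: tuple[RuleKind, ...] = tuple(RuleKind)


@dataclass(frozen=True)
class RuleInstance:
    rule_kind: RuleKind
    scope_family: int
    direction: str | None = None  # CW/CCW, ROT only
    required_set: frozenset[int] | None = None  # COM only

    def __post_init__(self):
        kind = RuleKind(self.rule_kind)
        object.__setattr__(self, "rule_kind", kind)
        if kind is RuleKind.ROT:
            if self.direction not in (CW, CCW):
                raise ConfigurationError(
                    f"ROT rule requires direction CW or CCW, got {self.direction!r}"
                )
        elif self.direction is not None:
            raise ConfigurationError(f"direction is only valid for ROT, not {kind.value}")
        if kind is RuleKind.COM:
            req = self.required_set
            if not req:
                raise ConfigurationError("COM rule requires a nonempty required_set")
            req = frozenset(req)
            if not req <= family_members(self.scope_family):
                raise ConfigurationError(
                    f"required_set {sorted(req)} not within family {self.scope_family}"
                )
            object.__setattr__(self, "required_set", req)
        elif self.required_set is not None:
            raise ConfigurationError(f"required_set is only valid for COM, not {kind.value}")
        family_members(self.scope_family)  # range check

    @property
    def scope(self) -> frozenset[int]:
        return family_members(self.scope_family)


def scoped(cell: frozenset[int], family_id: int) -> frozenset[int]:
    """Restrict a cell to the elements of one family."""
    return frozenset(e for e in cell if family_of(e) == family_id)


def apply_rule(
    rule: RuleInstance, first_cell: frozenset[int], second_cell: frozenset[int]
) -> frozenset[int]:
    """Return the rule's contribution to the third cell of a row.

    Inputs are restricted to the rule's scope family before the set
    operation is applied, so callers may pass whole cells.
    """
    first = scoped(frozenset(first_cell), rule.scope_family)
    second = scoped(frozenset(second_cell), rule.scope_family)
    kind = rule.rule_kind
    if kind is RuleKind.ADD:
        return first | second
    if kind is RuleKind.SUB:
        return first - second
    if kind is RuleKind.DIS:
        return first ^ second
    if kind is RuleKind.INT:
        return first & second
    if kind is RuleKind.ROT:
        if not rotate_set(first, rule.direction) <= second:
            raise RuleViolationError(
                "ROT rule broken: second cell does not contain the rotated "
                f"image of the first ({sorted(first)} -> {sorted(second)})"
            )
        return rotate_set(second, rule.direction)
    if kind is RuleKind.COM:
        union = first | second
        if not union <= rule.required_set:
            raise RuleViolationError(
                f"COM rule broken: {sorted(union)} not within required set "
                f"{sorted(rule.required_set)}"
            )
        return rule.required_set - union
    raise AssertionError(f"unhandled rule kind {kind}")  # pragma: no cover
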