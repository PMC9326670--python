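"""Stem solver: exhaustive rule-hypothesis enumeration and uniqueness check.

Given the eight visible cells of an item, the solver enumerates, for every
shape family present, every rule hypothesis (all six kinds with all
admissible parameters) consistent with the two complete rows and with the
visible part of row three.  Each surviving hypothesis predicts that
family's contribution to the hidden ninth cell.  The stem is uniquely
solvable when all consistent hypothesis combinations agree on the ninth
cell; the agreed cell is the solution.

Uniqueness is defined over predictions, not over rule labels: two distinct
hypotheses that predict the same ninth cell do not make a stem ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

from .elements import CCW, CW, family_members, family_of, rotate_set
from .errors import DataError
from .rules import RuleKind, scoped

Cell = frozenset[int]

_MAX_COMPETING = 32  # cap on enumerated competing solutions


@dataclass(frozen=True)
class ValidationReport:
    rules_hold: bool
    solvable: bool
    unique: bool
    competing_solutions: tuple[Cell, ...] = field(default_factory=tuple)
    solution: Cell | None = None

    def __post_init__(self):
        if self.unique and not self.solvable:
            raise ValueError("unique implies solvable")
        if self.unique and self.competing_solutions:
            raise ValueError("a unique report cannot carry competing solutions")


def _family_predictions(stem: list[Cell], fam: int) -> set[Cell]:
    """Predictions for one family's ninth-cell contribution.

    Returns the set of distinct predictions over all rule hypotheses
    consistent with rows one and two and the visible cells of row three;
    empty when no hypothesis survives.
    """
    rows = [
        (scoped(stem[0], fam), scoped(stem[1], fam), scoped(stem[2], fam)),
        (scoped(stem[3], fam), scoped(stem[4], fam), scoped(stem[5], fam)),
    ]
    f3 = scoped(stem[6], fam)
    s3 = scoped(stem[7], fam)
    preds: set[Cell] = set()

    set_ops = {
        RuleKind.ADD: lambda a, b: a | b,
        RuleKind.SUB: lambda a, b: a - b,
        RuleKind.DIS: lambda a, b: a ^ b,
        RuleKind.INT: lambda a, b: a & b,
    }
    for kind, op in set_ops.items():
        if all(op(first, second) == third for first, second, third in rows):
            preds.add(op(f3, s3))

    for direction in (CW, CCW):
        ok = all(
            rotate_set(first, direction) <= second
            and rotate_set(second, direction) == third
            for first, second, third in rows
        )
        if ok and rotate_set(f3, direction) <= s3:
            preds.add(rotate_set(s3, direction))

    members = sorted(family_members(fam))
    for size in range(1, len(members) + 1):
        for req in combinations(members, size):
            required = frozenset(req)
            ok = all(
                (first | second) <= required
                and required - (first | second) == third
                for first, second, third in rows
            )
            if ok and (f3 | s3) <= required:
                preds.add(required - (f3 | s3))

    return preds


def solve_stem(stem: list[Cell] | tuple[Cell, ...]) -> ValidationReport:
    """Solve the eight visible cells of an item.

    Returns a report with ``solvable``/``unique`` flags, the solution when
    unique, and the list of competing ninth-cell candidates otherwise.
    Unsolvable stems yield ``solvable=False`` rather than an exception.
    """
    if len(stem) != 8:
        raise DataError(f"a stem has 8 cells, got {len(stem)}")
    cells = [frozenset(c) for c in stem]
    for i, cell in enumerate(cells):
        for e in cell:
            family_of(e)  # raises on out-of-range ids

    families = sorted({family_of(e) for cell in cells for e in cell})
    per_family: list[set[Cell]] = []
    for fam in families:
        preds = _family_predictions(cells, fam)
        if not preds:
            return ValidationReport(
                rules_hold=True, solvable=False, unique=False
            )
        per_family.append(preds)

    candidates: set[Cell] = set()
    for combo in product(*per_family) if per_family else [()]:
        candidates.add(frozenset().union(*combo) if combo else frozenset())
        if len(candidates) > _MAX_COMPETING:
            break

    if len(candidates) == 1:
        return ValidationReport(
            rules_hold=True,
            solvable=True,
            unique=True,
            solution=next(iter(candidates)),
        )
    return ValidationReport(
        rules_hold=True,
        solvable=True,
        unique=False,
        competing_solutions=tuple(sorted(candidates, key=sorted)),
    )
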