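"""Item composition, validation, and response scoring."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import family_members, family_of, rotate_set
from .errors import ConfigurationError, GenerationError
from .rules import RuleInstance, RuleKind, apply_rule, scoped
from .solver import Cell, ValidationReport, solve_stem

MAX_RULES = 5
DEFAULT_MAX_ATTEMPTS = 50


@dataclass(frozen=True)
class MatrixItem:
    """A 3x3 figural matrix item.

    ``cells`` are row-major; the ninth cell is the hidden solution and is
    withheld from the stem shown to respondents.
    """

    item_id: str
    cells: tuple[Cell, ...]
    rules: tuple[RuleInstance, ...]
    rule_count: int
    is_anchor: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.cells) != 9:
            raise ConfigurationError(f"an item has 9 cells, got {len(self.cells)}")
        object.__setattr__(self, "cells", tuple(frozenset(c) for c in self.cells))
        object.__setattr__(self, "rules", tuple(self.rules))
        if self.rule_count != len(self.rules):
            raise ConfigurationError(
                f"rule_count {self.rule_count} != number of rules {len(self.rules)}"
            )
        _check_rule_set(self.rules)

    @property
    def stem(self) -> tuple[Cell, ...]:
        return self.cells[:8]

    @property
    def solution(self) -> Cell:
        return self.cells[8]


def _check_rule_set(rules: tuple[RuleInstance, ...]) -> None:
    if not 1 <= len(rules) <= MAX_RULES:
        raise ConfigurationError(
            f"an item carries 1-{MAX_RULES} rules, got {len(rules)}"
        )
    fams = [r.scope_family for r in rules]
    if len(set(fams)) != len(fams):
        raise ConfigurationError(
            f"rule scope families must be pairwise disjoint, got {fams}"
        )


def _draw_subset(rng: np.random.Generator, pool: frozenset[int], size: int) -> frozenset[int]:
    return frozenset(rng.choice(sorted(pool), size=size, replace=False).tolist())


def _draw_row(rule: RuleInstance, rng: np.random.Generator) -> tuple[Cell, Cell, Cell]:
    """Draw one row's scoped (first, second, third) cells satisfying the rule."""
    fam = family_members(rule.scope_family)
    kind = rule.rule_kind
    if kind is RuleKind.ROT:
        first = _draw_subset(rng, fam, int(rng.integers(1, 4)))
        second = rotate_set(first, rule.direction)
        return first, second, rotate_set(second, rule.direction)
    if kind is RuleKind.COM:
        req = rule.required_set
        if len(req) < 2:
            raise ConfigurationError(
                "COM generation needs a required_set of at least 2 elements"
            )
        # nonempty missing part and nonempty shown part; first/second
        # jointly cover the shown part and are each nonempty
        missing = _draw_subset(rng, req, int(rng.integers(1, len(req))))
        shown = sorted(req - missing)
        first, second = set(), set()
        for e in shown:
            slot = rng.integers(0, 3)
            if slot == 0:
                first.add(e)
            elif slot == 1:
                second.add(e)
            else:
                first.add(e)
                second.add(e)
        if not first:
            first.add(shown[int(rng.integers(len(shown)))])
        if not second:
            second.add(shown[int(rng.integers(len(shown)))])
        return frozenset(first), frozenset(second), frozenset(missing)
    first = _draw_subset(rng, fam, int(rng.integers(1, 4)))
    second = _draw_subset(rng, fam, int(rng.integers(1, 4)))
    return first, second, apply_rule(rule, first, second)


def compose_item(
    rules: list[RuleInstance] | tuple[RuleInstance, ...],
    seed: int,
    item_id: str | None = None,
    is_anchor: bool = False,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> MatrixItem:
    """Compose a matrix item realising ``rules`` with a unique solution.

    Deterministic for a given ``(rules, seed)``.  Cell contents are redrawn
    (up to ``max_attempts``) until the solver certifies a unique solution
    and no cell is empty.
    """
    rules = tuple(rules)
    _check_rule_set(rules)
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        cells = [set() for _ in range(9)]
        for rule in rules:
            for row in range(3):
                first, second, third = _draw_row(rule, rng)
                cells[3 * row] |= first
                cells[3 * row + 1] |= second
                cells[3 * row + 2] |= third
        if any(not c for c in cells):
            continue
        frozen = tuple(frozenset(c) for c in cells)
        report = solve_stem(frozen[:8])
        if report.unique and report.solution == frozen[8]:
            return MatrixItem(
                item_id=item_id or f"item-{seed}",
                cells=frozen,
                rules=rules,
                rule_count=len(rules),
                is_anchor=is_anchor,
                seed=seed,
            )
    raise GenerationError(
        "could not realise a uniquely solvable item in "
        f"{max_attempts} attempts for rules "
        f"{[(r.rule_kind.value, r.scope_family) for r in rules]} (seed {seed})"
    )


def validate_item(item: MatrixItem) -> ValidationReport:
    """Full validation: declared rules hold on every row, scope coverage,
    and the stem solves uniquely to the stored ninth cell."""
    scope_union = frozenset().union(*(r.scope for r in item.rules))
    in_scope = all(cell <= scope_union for cell in item.cells)
    rules_hold = in_scope
    if rules_hold:
        for rule in item.rules:
            for row in range(3):
                first, second, third = (
                    item.cells[3 * row],
                    item.cells[3 * row + 1],
                    item.cells[3 * row + 2],
                )
                try:
                    contribution = apply_rule(rule, first, second)
                except Exception:
                    rules_hold = False
                    break
                if contribution != scoped(third, rule.scope_family):
                    rules_hold = False
                    break
            if not rules_hold:
                break
    report = solve_stem(item.stem)
    unique = report.unique and report.solution == item.solution
    return ValidationReport(
        rules_hold=rules_hold,
        solvable=report.solvable,
        unique=unique,
        competing_solutions=report.competing_solutions,
        solution=report.solution,
    )


def score_response(item: MatrixItem, selected) -> int:
    """Dichotomous exact-match scoring: 1 iff the selection equals the
    solution set, else 0."""
    selected = frozenset(selected)
    for e in selected:
        family_of(e)  # range check
    return int(selected == item.solution)
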