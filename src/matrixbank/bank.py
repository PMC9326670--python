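"""Bank assembly: generate the full item pool, split it into test sets,
and attach the common anchor block and practice items.

The default configuration produces 220 unique items (20/50/80/50/20 items
with 1-5 rules), splits them into 10 test sets of 22 (2/5/8/5/2 per rule
count), and adds the same 6 anchor items (rule counts 1, 2, 3, 3, 4, 5) to
every form, for 28 scored tasks per form.  Rule-kind usage follows the
per-rule-count marginal targets of the default usage table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import CCW, CW, N_FAMILIES, family_members
from .errors import ConfigurationError, GenerationError
from .items import MatrixItem, compose_item, validate_item
from .rules import RULE_KINDS, RuleInstance, RuleKind

DEFAULT_ITEMS_PER_RULE_COUNT = {1: 20, 2: 50, 3: 80, 4: 50, 5: 20}
DEFAULT_SET_COMPOSITION = {1: 2, 2: 5, 3: 8, 4: 5, 5: 2}
DEFAULT_ANCHOR_COMPOSITION = {1: 1, 2: 1, 3: 2, 4: 1, 5: 1}

# marginal rule-kind usage targets per rule count for the default pool
DEFAULT_RULE_USAGE = {
    1: {"ADD": 4, "SUB": 4, "DIS": 3, "INT": 3, "ROT": 3, "COM": 3},
    2: {"ADD": 20, "SUB": 16, "DIS": 16, "INT": 16, "ROT": 16, "COM": 16},
    3: {"ADD": 44, "SUB": 44, "DIS": 37, "INT": 41, "ROT": 37, "COM": 37},
    4: {"ADD": 35, "SUB": 36, "DIS": 32, "INT": 35, "ROT": 31, "COM": 31},
    5: {"ADD": 17, "SUB": 17, "DIS": 17, "INT": 17, "ROT": 16, "COM": 16},
}

ANCHOR_POSITIONS = (5, 9, 13, 17, 21, 25)  # 1-based ordinals in the scored order


@dataclass
class BankConfig:
    items_per_rule_count: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_ITEMS_PER_RULE_COUNT)
    )
    n_test_sets: int = 10
    set_composition: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_SET_COMPOSITION)
    )
    anchor_composition: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_ANCHOR_COMPOSITION)
    )
    n_practice: int = 2
    master_seed: int = 0
    rule_usage_targets: dict[int, dict[str, int]] | None = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RULE_USAGE.items()}
    )

    def validate(self) -> None:
        for counts, label in (
            (self.items_per_rule_count, "items_per_rule_count"),
            (self.set_composition, "set_composition"),
            (self.anchor_composition, "anchor_composition"),
        ):
            for k in counts:
                if not 1 <= k <= N_FAMILIES:
                    raise ConfigurationError(
                        f"{label}: rule count {k} outside 1-{N_FAMILIES} "
                        f"(only {N_FAMILIES} disjoint families exist)"
                    )
                if counts[k] < 0:
                    raise ConfigurationError(f"{label}[{k}] is negative")
        for k, n in self.items_per_rule_count.items():
            expected = self.n_test_sets * self.set_composition.get(k, 0)
            if n != expected:
                raise ConfigurationError(
                    f"items_per_rule_count[{k}]={n} != n_test_sets x "
                    f"set_composition[{k}] = {expected}"
                )
        for k in self.set_composition:
            if k not in self.items_per_rule_count and self.set_composition[k]:
                raise ConfigurationError(f"set_composition names unknown rule count {k}")
        if self.rule_usage_targets is not None:
            for k, targets in self.rule_usage_targets.items():
                n = self.items_per_rule_count.get(k, 0)
                unknown = set(targets) - {r.value for r in RULE_KINDS}
                if unknown:
                    raise ConfigurationError(f"unknown rule kinds in usage targets: {unknown}")
                if sum(targets.values()) != k * n:
                    raise ConfigurationError(
                        f"usage targets for rule count {k} sum to "
                        f"{sum(targets.values())}, expected {k * n}"
                    )
                if any(v > n for v in targets.values()):
                    raise ConfigurationError(
                        f"usage target exceeds item count for rule count {k}"
                    )

    @property
    def n_items(self) -> int:
        return sum(self.items_per_rule_count.values())

    @property
    def n_anchors(self) -> int:
        return sum(self.anchor_composition.values())

    def anchor_rule_counts(self) -> list[int]:
        out: list[int] = []
        for k in sorted(self.anchor_composition):
            out.extend([k] * self.anchor_composition[k])
        return out


@dataclass(frozen=True)
class Form:
    form_id: str
    test_set_item_ids: tuple[str, ...]
    anchor_item_ids: tuple[str, ...]
    practice_item_ids: tuple[str, ...]
    presentation_order: tuple[str, ...]

    def __post_init__(self):
        if set(self.test_set_item_ids) & set(self.anchor_item_ids):
            raise ConfigurationError("test-set items must be disjoint from anchors")
        if len(set(self.test_set_item_ids)) != len(self.test_set_item_ids):
            raise ConfigurationError("duplicate item in test set")

    @property
    def scored_item_ids(self) -> tuple[str, ...]:
        return self.presentation_order


@dataclass
class ItemBank:
    config: BankConfig
    items: list[MatrixItem]
    anchors: list[MatrixItem] = field(default_factory=list)
    practice: list[MatrixItem] = field(default_factory=list)
    forms: list[Form] = field(default_factory=list)

    def item_map(self) -> dict[str, MatrixItem]:
        out = {}
        for it in self.items + self.anchors + self.practice:
            if it.item_id in out:
                raise ConfigurationError(f"duplicate item id {it.item_id}")
            out[it.item_id] = it
        return out


def _assign_rule_kinds(
    rule_count: int,
    n_items: int,
    targets: dict[str, int] | None,
    rng: np.random.Generator,
) -> list[tuple[RuleKind, ...]]:
    """Assign ``rule_count`` distinct kinds to each of ``n_items`` items.

    With marginal usage targets, a largest-remaining-first greedy honours
    the targets exactly (feasible whenever each target is at most
    ``n_items`` and they sum to ``rule_count * n_items``).
    """
    kinds = [r.value for r in RULE_KINDS]
    if targets is None:
        return [
            tuple(RuleKind(k) for k in rng.permutation(kinds)[:rule_count])
            for _ in range(n_items)
        ]
    remaining = {k: int(targets.get(k, 0)) for k in kinds}
    out = []
    for _ in range(n_items):
        order = rng.permutation(kinds)
        chosen = sorted(order, key=lambda k: -remaining[k])[:rule_count]
        if any(remaining[k] <= 0 for k in chosen):
            raise ConfigurationError(
                f"infeasible usage targets for rule count {rule_count}"
            )
        for k in chosen:
            remaining[k] -= 1
        out.append(tuple(RuleKind(k) for k in chosen))
    return out


def _draw_rules(
    kinds: tuple[RuleKind, ...], rng: np.random.Generator
) -> tuple[RuleInstance, ...]:
    fams = rng.permutation(N_FAMILIES)[: len(kinds)]
    rules = []
    for kind, fam in zip(kinds, fams):
        fam = int(fam)
        kwargs = {}
        if kind is RuleKind.ROT:
            kwargs["direction"] = CW if rng.integers(2) else CCW
        elif kind is RuleKind.COM:
            members = sorted(family_members(fam))
            size = int(rng.integers(2, len(members) + 1))
            kwargs["required_set"] = frozenset(
                rng.choice(members, size=size, replace=False).tolist()
            )
        rules.append(RuleInstance(kind, fam, **kwargs))
    return tuple(rules)


def _generate_item(
    item_id: str,
    kinds: tuple[RuleKind, ...],
    rng: np.random.Generator,
    is_anchor: bool = False,
    outer_attempts: int = 20,
) -> MatrixItem:
    last_err: Exception | None = None
    for _ in range(outer_attempts):
        rules = _draw_rules(kinds, rng)
        seed = int(rng.integers(1 << 31))
        try:
            return compose_item(rules, seed, item_id=item_id, is_anchor=is_anchor)
        except GenerationError as err:  # re-draw families/parameters
            last_err = err
    raise GenerationError(
        f"exhausted parameter redraws for item {item_id} with kinds "
        f"{[k.value for k in kinds]}"
    ) from last_err


def build_bank(config: BankConfig | None = None) -> ItemBank:
    """Generate the full validated bank and its forms.

    Deterministic per ``config.master_seed``.  Every generated item passes
    :func:`matrixbank.items.validate_item` by construction (the composer
    certifies uniqueness before returning).
    """
    config = config or BankConfig()
    config.validate()
    ss = np.random.SeedSequence(config.master_seed)
    rng_items, rng_anchor, rng_practice, rng_split = [
        np.random.default_rng(child) for child in ss.spawn(4)
    ]

    items: list[MatrixItem] = []
    idx = 1
    for rule_count in sorted(config.items_per_rule_count):
        n = config.items_per_rule_count[rule_count]
        targets = (
            config.rule_usage_targets.get(rule_count)
            if config.rule_usage_targets is not None
            else None
        )
        for kinds in _assign_rule_kinds(rule_count, n, targets, rng_items):
            items.append(_generate_item(f"M{idx:03d}", kinds, rng_items))
            idx += 1

    anchors: list[MatrixItem] = []
    for j, rule_count in enumerate(config.anchor_rule_counts(), start=1):
        kinds = _assign_rule_kinds(rule_count, 1, None, rng_anchor)[0]
        anchors.append(
            _generate_item(f"A{j:02d}", kinds, rng_anchor, is_anchor=True)
        )

    practice: list[MatrixItem] = []
    practice_kinds = [(RuleKind.ADD,), (RuleKind.ROT,)]
    for j in range(config.n_practice):
        kinds = practice_kinds[j % len(practice_kinds)]
        practice.append(_generate_item(f"P{j + 1:02d}", kinds, rng_practice))

    bank = ItemBank(config=config, items=items, anchors=anchors, practice=practice)
    bank.forms = split_and_anchor(items, config, anchors, practice, rng_split)
    return bank


def split_and_anchor(
    bank_items: list[MatrixItem],
    config: BankConfig,
    anchors: list[MatrixItem],
    practice: list[MatrixItem] | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[Form]:
    """Split unique items into test sets and attach the common anchors.

    Assignment is seeded-random within rule-count strata and independent of
    the incoming item order (items are sorted by id before shuffling).
    Anchors are interleaved at fixed ordinal positions in the scored
    presentation order.
    """
    config.validate()
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    practice = practice or []

    expected_anchors = len(config.anchor_rule_counts())
    if len(anchors) != expected_anchors:
        raise ConfigurationError(
            f"expected {expected_anchors} anchors, got {len(anchors)}"
        )
    anchor_ids = tuple(it.item_id for it in anchors)
    practice_ids = tuple(it.item_id for it in practice)

    strata: dict[int, list[str]] = {k: [] for k in config.set_composition}
    for it in sorted(bank_items, key=lambda x: x.item_id):
        if it.rule_count not in strata:
            raise ConfigurationError(
                f"item {it.item_id} has rule count {it.rule_count} absent "
                "from set_composition"
            )
        strata[it.rule_count].append(it.item_id)
    for k, ids in strata.items():
        need = config.n_test_sets * config.set_composition[k]
        if len(ids) != need:
            raise ConfigurationError(
                f"stratum for rule count {k} holds {len(ids)} items, needs {need}"
            )
        rng.shuffle(ids)

    forms: list[Form] = []
    for g in range(config.n_test_sets):
        unique_ids: list[str] = []
        for k in sorted(strata):
            c = config.set_composition[k]
            unique_ids.extend(strata[k][g * c : (g + 1) * c])
        order = list(unique_ids)
        for pos, aid in zip(ANCHOR_POSITIONS, anchor_ids):
            order.insert(min(pos - 1, len(order)), aid)
        forms.append(
            Form(
                form_id=f"F{g + 1:02d}",
                test_set_item_ids=tuple(unique_ids),
                anchor_item_ids=anchor_ids,
                practice_item_ids=practice_ids,
                presentation_order=tuple(order),
            )
        )
    return forms
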