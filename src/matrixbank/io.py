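"""Readers and writers for the artifact formats.

Bank descriptor: JSON (schema validated on read, items re-validated).
Responses: wide CSV — person_id, form_id, then one 0/1/empty column per
item.  Parameters: CSV with item_id, a, b, standard errors and fit
columns.  All files are UTF-8; missing responses are empty cells.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bank import BankConfig, Form, ItemBank
from .elements import CCW, CW, N_ELEMENTS
from .errors import ConfigurationError, DataError, ParseError
from .irt import FitStatistics, ItemParams2PL
from .items import MatrixItem, validate_item
from .rules import RuleInstance, RuleKind
from .simulate import ResponseMatrix

PARAMS_COLUMNS = [
    "item_id",
    "a",
    "b",
    "se_a",
    "se_b",
    "infit_msq",
    "outfit_msq",
    "infit_z",
    "outfit_z",
    "flagged",
]


# ---------------------------------------------------------------- bank JSON

def _item_to_json(item: MatrixItem) -> dict:
    rules = []
    for r in item.rules:
        entry: dict = {"kind": r.rule_kind.value, "family": r.scope_family}
        if r.direction is not None:
            entry["direction"] = r.direction
        if r.required_set is not None:
            entry["required_set"] = sorted(r.required_set)
        rules.append(entry)
    return {
        "item_id": item.item_id,
        "cells": [sorted(c) for c in item.cells],
        "rules": rules,
        "rule_count": item.rule_count,
        "is_anchor": item.is_anchor,
        "seed": item.seed,
    }


def _expect(condition: bool, pointer: str, message: str) -> None:
    if not condition:
        raise ParseError(message, location=pointer)


def _item_from_json(obj, pointer: str) -> MatrixItem:
    _expect(isinstance(obj, dict), pointer, "item must be an object")
    for key in ("item_id", "cells", "rules", "rule_count", "is_anchor", "seed"):
        _expect(key in obj, pointer, f"missing key {key!r}")
    cells = obj["cells"]
    _expect(
        isinstance(cells, list) and len(cells) == 9,
        f"{pointer}/cells",
        "cells must be an array of 9 arrays",
    )
    parsed_cells = []
    for i, cell in enumerate(cells):
        _expect(
            isinstance(cell, list)
            and all(isinstance(e, int) and 0 <= e < N_ELEMENTS for e in cell),
            f"{pointer}/cells/{i}",
            f"cell must be a list of integer element ids in 0-{N_ELEMENTS - 1}",
        )
        parsed_cells.append(frozenset(cell))
    rules = []
    for i, robj in enumerate(obj["rules"]):
        rptr = f"{pointer}/rules/{i}"
        _expect(isinstance(robj, dict), rptr, "rule must be an object")
        _expect("kind" in robj and "family" in robj, rptr, "rule needs kind and family")
        kind = robj["kind"]
        _expect(
            kind in {r.value for r in RuleKind}, f"{rptr}/kind", f"unknown rule kind {kind!r}"
        )
        direction = robj.get("direction")
        _expect(
            direction in (None, CW, CCW), f"{rptr}/direction", "direction must be CW or CCW"
        )
        required = robj.get("required_set")
        try:
            rules.append(
                RuleInstance(
                    RuleKind(kind),
                    int(robj["family"]),
                    direction=direction,
                    required_set=frozenset(required) if required is not None else None,
                )
            )
        except (ConfigurationError, ValueError) as err:
            raise ParseError(str(err), location=rptr) from err
    try:
        return MatrixItem(
            item_id=str(obj["item_id"]),
            cells=tuple(parsed_cells),
            rules=tuple(rules),
            rule_count=int(obj["rule_count"]),
            is_anchor=bool(obj["is_anchor"]),
            seed=int(obj["seed"]),
        )
    except ConfigurationError as err:
        raise ParseError(str(err), location=pointer) from err


def _form_to_json(form: Form) -> dict:
    return {
        "form_id": form.form_id,
        "test_set_item_ids": list(form.test_set_item_ids),
        "anchor_item_ids": list(form.anchor_item_ids),
        "practice_item_ids": list(form.practice_item_ids),
        "presentation_order": list(form.presentation_order),
    }


def _form_from_json(obj, pointer: str) -> Form:
    _expect(isinstance(obj, dict), pointer, "form must be an object")
    for key in (
        "form_id",
        "test_set_item_ids",
        "anchor_item_ids",
        "practice_item_ids",
        "presentation_order",
    ):
        _expect(key in obj, pointer, f"missing key {key!r}")
    try:
        return Form(
            form_id=str(obj["form_id"]),
            test_set_item_ids=tuple(obj["test_set_item_ids"]),
            anchor_item_ids=tuple(obj["anchor_item_ids"]),
            practice_item_ids=tuple(obj["practice_item_ids"]),
            presentation_order=tuple(obj["presentation_order"]),
        )
    except ConfigurationError as err:
        raise ParseError(str(err), location=pointer) from err


def write_bank(path, bank: ItemBank) -> None:
    """Serialise a bank to JSON; refuses items that fail validation."""
    for group, label in (
        (bank.items, "items"),
        (bank.anchors, "anchors"),
        (bank.practice, "practice"),
    ):
        for i, item in enumerate(group):
            report = validate_item(item)
            if not (report.rules_hold and report.unique):
                raise DataError(
                    f"refusing to write invalid item at /{label}/{i} "
                    f"({item.item_id}): rules_hold={report.rules_hold}, "
                    f"unique={report.unique}"
                )
    cfg = bank.config
    payload = {
        "format": "matrixbank-bank",
        "version": 1,
        "config": {
            "items_per_rule_count": {str(k): v for k, v in cfg.items_per_rule_count.items()},
            "n_test_sets": cfg.n_test_sets,
            "set_composition": {str(k): v for k, v in cfg.set_composition.items()},
            "anchor_composition": {str(k): v for k, v in cfg.anchor_composition.items()},
            "n_practice": cfg.n_practice,
            "master_seed": cfg.master_seed,
            "rule_usage_targets": (
                {str(k): dict(v) for k, v in cfg.rule_usage_targets.items()}
                if cfg.rule_usage_targets is not None
                else None
            ),
        },
        "items": [_item_to_json(it) for it in bank.items],
        "anchors": [_item_to_json(it) for it in bank.anchors],
        "practice": [_item_to_json(it) for it in bank.practice],
        "forms": [_form_to_json(f) for f in bank.forms],
    }
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_bank(path) -> ItemBank:
    """Load and validate a bank descriptor; raises :class:`ParseError` with
    a JSON-pointer location on any schema violation."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as err:
        raise ParseError(f"not valid JSON: {err}", location="/") from err
    _expect(isinstance(payload, dict), "/", "top level must be an object")
    _expect(
        payload.get("format") == "matrixbank-bank",
        "/format",
        "not a matrixbank bank descriptor",
    )
    for key in ("config", "items", "anchors", "practice", "forms"):
        _expect(key in payload, "/", f"missing key {key!r}")
    cobj = payload["config"]
    try:
        config = BankConfig(
            items_per_rule_count={int(k): int(v) for k, v in cobj["items_per_rule_count"].items()},
            n_test_sets=int(cobj["n_test_sets"]),
            set_composition={int(k): int(v) for k, v in cobj["set_composition"].items()},
            anchor_composition={int(k): int(v) for k, v in cobj["anchor_composition"].items()},
            n_practice=int(cobj["n_practice"]),
            master_seed=int(cobj["master_seed"]),
            rule_usage_targets=(
                {int(k): {kk: int(vv) for kk, vv in v.items()} for k, v in cobj["rule_usage_targets"].items()}
                if cobj.get("rule_usage_targets") is not None
                else None
            ),
        )
        config.validate()
    except (KeyError, TypeError, ValueError, ConfigurationError) as err:
        raise ParseError(f"bad config: {err}", location="/config") from err

    items = [_item_from_json(o, f"/items/{i}") for i, o in enumerate(payload["items"])]
    anchors = [_item_from_json(o, f"/anchors/{i}") for i, o in enumerate(payload["anchors"])]
    practice = [_item_from_json(o, f"/practice/{i}") for i, o in enumerate(payload["practice"])]
    forms = [_form_from_json(o, f"/forms/{i}") for i, o in enumerate(payload["forms"])]

    for group, label in ((items, "items"), (anchors, "anchors"), (practice, "practice")):
        for i, item in enumerate(group):
            report = validate_item(item)
            if not (report.rules_hold and report.unique):
                raise ParseError(
                    f"item {item.item_id} fails validation "
                    f"(rules_hold={report.rules_hold}, unique={report.unique})",
                    location=f"/{label}/{i}",
                )
    bank = ItemBank(config=config, items=items, anchors=anchors, practice=practice, forms=forms)
    bank.item_map()  # duplicate-id check
    known = set(bank.item_map())
    for i, form in enumerate(forms):
        for iid in form.presentation_order:
            _expect(iid in known, f"/forms/{i}", f"unknown item id {iid!r}")
    return bank


# ------------------------------------------------------------ responses CSV

def write_responses(path, matrix: ResponseMatrix) -> None:
    frame = matrix.data
    cols = {"person_id": frame.index, "form_id": matrix.form_assignment}
    for col in frame.columns:
        values = frame[col]
        cols[col] = np.where(values.notna(), values.fillna(0).astype(int).astype(str), "")
    pd.DataFrame(cols, index=frame.index).to_csv(path, index=False)


def read_responses(path) -> ResponseMatrix:
    """Read a response CSV; bad cell values raise :class:`ParseError`
    naming the row and column.  Persons with no observed responses are
    excluded and reported on the returned matrix."""
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as err:
        raise ParseError(f"cannot read CSV: {err}") from err
    for col in ("person_id", "form_id"):
        if col not in raw.columns:
            raise ParseError(f"missing required column {col!r}", location="header")
    item_cols = [c for c in raw.columns if c not in ("person_id", "form_id")]
    if not item_cols:
        raise ParseError("no item columns", location="header")
    if raw["person_id"].duplicated().any():
        dup = raw.loc[raw["person_id"].duplicated(), "person_id"].iloc[0]
        raise ParseError(f"duplicate person_id {dup!r}", location="person_id")

    data = np.full((len(raw), len(item_cols)), np.nan)
    for j, col in enumerate(item_cols):
        values = raw[col].str.strip()
        bad = ~values.isin(["", "0", "1"])
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"invalid response value {values.iloc[row]!r} "
                "(expected 0, 1 or empty)",
                location=f"row {row + 2}, column {col!r}",
            )
        observed = values != ""
        data[observed.to_numpy(), j] = values[observed].astype(float)

    frame = pd.DataFrame(data, index=raw["person_id"].tolist(), columns=item_cols)
    assignment = pd.Series(
        raw["form_id"].tolist(), index=raw["person_id"].tolist(), name="form_id"
    )
    empty = frame.isna().all(axis=1)
    excluded = list(frame.index[empty])
    frame = frame[~empty]
    assignment = assignment[~empty]
    return ResponseMatrix(frame, assignment, excluded_persons=excluded)


# ------------------------------------------------------------- params CSV

def write_params(
    path,
    params: list[ItemParams2PL],
    fit_stats: list[FitStatistics] | None = None,
    form_id: str | None = None,
) -> None:
    stats_by_id = {s.item_id: s for s in fit_stats or []}
    rows = []
    for p in params:
        s = stats_by_id.get(p.item_id)
        row = {
            "item_id": p.item_id,
            "a": p.a,
            "b": p.b,
            "se_a": p.se_a,
            "se_b": p.se_b,
            "infit_msq": s.infit_msq if s else None,
            "outfit_msq": s.outfit_msq if s else None,
            "infit_z": s.infit_z if s else None,
            "outfit_z": s.outfit_z if s else None,
            "flagged": s.flagged if s else None,
        }
        if form_id is not None:
            row["form_id"] = form_id
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_params(path) -> list[ItemParams2PL]:
    frame = pd.read_csv(path)
    for col in ("item_id", "a", "b"):
        if col not in frame.columns:
            raise ParseError(f"missing required column {col!r}", location="header")
    out = []
    for i, row in frame.iterrows():
        try:
            out.append(
                ItemParams2PL(
                    item_id=str(row["item_id"]),
                    a=float(row["a"]),
                    b=float(row["b"]),
                    se_a=float(row["se_a"]) if "se_a" in frame.columns and pd.notna(row.get("se_a")) else None,
                    se_b=float(row["se_b"]) if "se_b" in frame.columns and pd.notna(row.get("se_b")) else None,
                )
            )
        except (ValueError, ConfigurationError) as err:
            raise ParseError(f"bad parameter row: {err}", location=f"row {i + 2}") from err
    return out


def read_anchor_list(path) -> list[str]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    out = [ln.strip() for ln in lines if ln.strip()]
    if not out:
        raise ParseError("anchor list is empty")
    return out
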