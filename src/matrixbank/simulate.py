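"""Synthetic respondents: dichotomous responses under the two-parameter
logistic model for any multi-form design, with misfit injection for
exercising the diagnostic pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bank import Form
from .errors import ConfigurationError, UsageError

MISFIT_MODES = ("random_responder", "reversed")


@dataclass(frozen=True)
class PersonAbility:
    person_id: str
    theta: float

    def __post_init__(self):
        if not np.isfinite(self.theta):
            raise ConfigurationError(f"non-finite ability for {self.person_id}")


@dataclass
class ResponseMatrix:
    """Persons x items dichotomous data with missing-by-design cells.

    ``data`` holds floats in {0.0, 1.0, NaN} indexed by person id with one
    column per item id; ``form_assignment`` maps each person to a form.
    """

    data: pd.DataFrame
    form_assignment: pd.Series
    excluded_persons: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.data.index.equals(self.form_assignment.index):
            raise ConfigurationError("data and form assignment index mismatch")

    @property
    def person_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.data.columns)

    def observed_mask(self) -> pd.DataFrame:
        return self.data.notna()

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            self.data.copy(), self.form_assignment.copy(), list(self.excluded_persons)
        )


def sample_abilities(
    n: int, mean: float = 0.0, sd: float = 1.0, seed: int | None = None
) -> list[PersonAbility]:
    """Seeded draws from Normal(mean, sd) on the logit ability scale."""
    if n < 1:
        raise UsageError(f"need at least one person, got n={n}")
    if sd <= 0:
        raise UsageError(f"ability sd must be positive, got {sd}")
    rng = np.random.default_rng(seed)
    thetas = rng.normal(mean, sd, size=n)
    width = len(str(n))
    return [
        PersonAbility(person_id=f"P{i + 1:0{width}d}", theta=float(t))
        for i, t in enumerate(thetas)
    ]


def assign_forms_round_robin(
    abilities: list[PersonAbility], forms: list[Form]
) -> dict[str, str]:
    """Deal persons to forms round-robin, in person order."""
    if not forms:
        raise ConfigurationError("no forms to assign")
    return {
        p.person_id: forms[i % len(forms)].form_id for i, p in enumerate(abilities)
    }


def simulate_responses(
    forms: list[Form],
    item_params: dict[str, tuple[float, float]],
    abilities: list[PersonAbility],
    seed: int | None = None,
    form_of: dict[str, str] | None = None,
) -> ResponseMatrix:
    """Simulate one Bernoulli response per administered item.

    ``item_params`` maps item id to ``(a, b)``.  Success probability is the
    2PL response function; cells for items not on a person's form stay
    missing.  Deterministic per seed.
    """
    from .irt import two_pl_probability  # local import to avoid a cycle

    form_by_id = {f.form_id: f for f in forms}
    if form_of is None:
        form_of = assign_forms_round_robin(abilities, forms)
    for pid, fid in form_of.items():
        if fid not in form_by_id:
            raise ConfigurationError(f"person {pid} assigned to unknown form {fid}")

    item_ids: list[str] = []
    for f in forms:
        for iid in f.scored_item_ids:
            if iid not in item_params:
                raise ConfigurationError(
                    f"no parameters for administered item {iid} (form {f.form_id})"
                )
            if iid not in item_ids:
                item_ids.append(iid)

    rng = np.random.default_rng(seed)
    person_ids = [p.person_id for p in abilities]
    data = np.full((len(abilities), len(item_ids)), np.nan)
    col = {iid: j for j, iid in enumerate(item_ids)}
    for i, person in enumerate(abilities):
        form = form_by_id[form_of[person.person_id]]
        for iid in form.scored_item_ids:
            a, b = item_params[iid]
            p = two_pl_probability(a, b, person.theta)
            data[i, col[iid]] = float(rng.random() < p)

    frame = pd.DataFrame(data, index=person_ids, columns=item_ids)
    assignment = pd.Series({pid: form_of[pid] for pid in person_ids}, name="form_id")
    return ResponseMatrix(frame, assignment.loc[person_ids])


def inject_misfit(
    matrix: ResponseMatrix, item_id: str, mode: str, seed: int | None = None
) -> ResponseMatrix:
    """Return a copy with one item's observed responses corrupted.

    ``random_responder`` replaces the column with fair coin flips;
    ``reversed`` flips every observed response.  All other cells are
    untouched.
    """
    if item_id not in matrix.data.columns:
        raise ConfigurationError(f"item {item_id} not in the response matrix")
    if mode not in MISFIT_MODES:
        raise UsageError(f"unknown misfit mode {mode!r}; expected one of {MISFIT_MODES}")
    out = matrix.copy()
    col = out.data[item_id]
    observed = col.notna()
    if mode == "random_responder":
        rng = np.random.default_rng(seed)
        flips = rng.integers(0, 2, size=int(observed.sum())).astype(float)
        out.data.loc[observed, item_id] = flips
    else:
        out.data.loc[observed, item_id] = 1.0 - col[observed]
    return out
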