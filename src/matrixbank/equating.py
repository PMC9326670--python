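"""Anchor-based linear equating of separately calibrated forms.

Each non-reference form is linked directly to the reference form through
the common anchor block: mean-sigma uses the anchor threshold moments
(A = sd_ref / sd_form, B = mean_ref - A * mean_form), mean-mean uses the
anchor discrimination ratio for the slope.  Parameters move onto the
reference scale as b* = A b + B and a* = a / A.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, NumericalError
from .irt import ItemParams2PL

METHODS = ("mean_sigma", "mean_mean")


@dataclass(frozen=True)
class EquatingCoefficients:
    form_id: str
    A: float
    B: float
    method: str

    def __post_init__(self):
        if self.A <= 0:
            raise ConfigurationError(f"equating slope must be positive, got {self.A}")
        if self.method not in METHODS:
            raise ConfigurationError(
                f"unknown equating method {self.method!r}; expected one of {METHODS}"
            )


def _anchor_params(
    params: list[ItemParams2PL], anchor_ids, form_id: str
) -> list[ItemParams2PL]:
    by_id = {p.item_id: p for p in params}
    missing = [aid for aid in anchor_ids if aid not in by_id]
    if missing:
        raise ConfigurationError(
            f"form {form_id} calibration is missing anchors {missing}"
        )
    return [by_id[aid] for aid in anchor_ids]


def link_forms(
    per_form_params: dict[str, list[ItemParams2PL]],
    anchor_ids,
    method: str = "mean_sigma",
    reference_form: str | None = None,
) -> list[EquatingCoefficients]:
    """Estimate per-form linking coefficients onto the reference scale.

    The reference form gets the identity transformation.  Anchor order is
    irrelevant (only moments enter the formulas).
    """
    if method not in METHODS:
        raise ConfigurationError(
            f"unknown equating method {method!r}; expected one of {METHODS}"
        )
    anchor_ids = list(anchor_ids)
    if len(anchor_ids) < 2 and method == "mean_sigma":
        raise ConfigurationError("mean_sigma linking needs at least 2 anchors")
    if not anchor_ids:
        raise ConfigurationError("no anchor ids supplied")
    form_ids = list(per_form_params)
    if reference_form is None:
        reference_form = form_ids[0]
    if reference_form not in per_form_params:
        raise ConfigurationError(f"reference form {reference_form} not supplied")

    ref_anchors = _anchor_params(
        per_form_params[reference_form], anchor_ids, reference_form
    )
    ref_b = np.array([p.b for p in ref_anchors])
    ref_a = np.array([p.a for p in ref_anchors])

    out = []
    for form_id in form_ids:
        if form_id == reference_form:
            out.append(EquatingCoefficients(form_id, 1.0, 0.0, method))
            continue
        anchors = _anchor_params(per_form_params[form_id], anchor_ids, form_id)
        g_b = np.array([p.b for p in anchors])
        g_a = np.array([p.a for p in anchors])
        if method == "mean_sigma":
            sd_g = g_b.std(ddof=1)
            if sd_g <= 1e-12:
                raise NumericalError(
                    f"zero anchor-threshold variance on form {form_id}; "
                    "mean_sigma is degenerate, consider method='mean_mean'"
                )
            A = float(ref_b.std(ddof=1) / sd_g)
        else:  # mean_mean: slope from the discrimination ratio
            A = float(g_a.mean() / ref_a.mean())
        if A <= 0:
            raise NumericalError(f"non-positive equating slope for form {form_id}")
        B = float(ref_b.mean() - A * g_b.mean())
        out.append(EquatingCoefficients(form_id, A, B, method))
    return out


def transform_params(
    params: list[ItemParams2PL], coeffs: EquatingCoefficients
) -> list[ItemParams2PL]:
    """Apply b* = A b + B, a* = a / A to every item (anchors included)."""
    return [
        replace(p, a=p.a / coeffs.A, b=coeffs.A * p.b + coeffs.B)
        for p in params
    ]


def inverse_coefficients(coeffs: EquatingCoefficients) -> EquatingCoefficients:
    return EquatingCoefficients(
        coeffs.form_id, 1.0 / coeffs.A, -coeffs.B / coeffs.A, coeffs.method
    )


def equating_check(
    equated_params: dict[str, list[ItemParams2PL]],
    anchor_ids=(),
):
    """One-way ANOVAs of equated unique-item parameters across forms.

    Returns ``(anova_a, anova_b)``.  Anchor items are excluded (they are
    shared, not form-specific).
    """
    from .report import oneway_anova  # local import to avoid a cycle

    anchor_ids = set(anchor_ids)
    if len(equated_params) < 2:
        raise ConfigurationError("equating check needs at least 2 forms")
    groups_a, groups_b = [], []
    for form_id, params in equated_params.items():
        unique = [p for p in params if p.item_id not in anchor_ids]
        if len(unique) < 2:
            raise ConfigurationError(
                f"form {form_id} has fewer than 2 unique items"
            )
        groups_a.append([p.a for p in unique])
        groups_b.append([p.b for p in unique])
    return oneway_anova(groups_a), oneway_anova(groups_b)
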