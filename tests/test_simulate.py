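import numpy as np
import pytest
from scipy import integrate, stats

from matrixbank.bank import Form
from matrixbank.errors import ConfigurationError, UsageError
from matrixbank.simulate import (
    assign_forms_round_robin,
    inject_misfit,
    sample_abilities,
    simulate_responses,
)

from conftest import make_matrix


def _single_item_form(item_id="i1"):
    return Form(
        form_id="F1",
        test_set_item_ids=(item_id,),
        anchor_item_ids=(),
        practice_item_ids=(),
        presentation_order=(item_id,),
    )


def test_sample_abilities_moments():
    abilities = sample_abilities(10000, 0.0, 1.0, seed=1)
    thetas = np.array([p.theta for p in abilities])
    assert abs(thetas.mean()) < 0.05
    assert abs(thetas.std(ddof=1) - 1.0) < 0.05


def test_sample_abilities_deterministic():
    a = sample_abilities(50, seed=9)
    b = sample_abilities(50, seed=9)
    assert a == b


def test_sample_abilities_bad_args():
    with pytest.raises(UsageError):
        sample_abilities(0, seed=1)
    with pytest.raises(UsageError):
        sample_abilities(10, sd=0.0, seed=1)


def test_probability_half_at_threshold():
    form = _single_item_form()
    abilities = [
        type(a)(a.person_id, -0.4) for a in sample_abilities(10000, seed=2)
    ]
    matrix = simulate_responses([form], {"i1": (1.7, -0.4)}, abilities, seed=3)
    assert abs(matrix.data["i1"].mean() - 0.5) < 0.02


def test_marginal_proportion_matches_quadrature_oracle():
    """Observed proportion correct matches the normal integral of the 2PL
    curve (independent adaptive-quadrature oracle)."""
    a, b = 2.09, -0.17
    oracle, _ = integrate.quad(
        lambda t: stats.norm.pdf(t) / (1.0 + np.exp(-a * (t - b))), -10, 10
    )
    form = _single_item_form()
    abilities = sample_abilities(50000, seed=4)
    matrix = simulate_responses([form], {"i1": (a, b)}, abilities, seed=5)
    assert abs(matrix.data["i1"].mean() - oracle) < 0.01


def test_simulation_deterministic(toy_bank):
    params = {
        it.item_id: (1.5, 0.0) for it in toy_bank.items + toy_bank.anchors
    }
    abilities = sample_abilities(40, seed=6)
    m1 = simulate_responses(toy_bank.forms, params, abilities, seed=7)
    m2 = simulate_responses(toy_bank.forms, params, abilities, seed=7)
    assert m1.data.equals(m2.data)


def test_missingness_matches_form_design(toy_bank):
    params = {
        it.item_id: (1.5, 0.0) for it in toy_bank.items + toy_bank.anchors
    }
    abilities = sample_abilities(40, seed=8)
    matrix = simulate_responses(toy_bank.forms, params, abilities, seed=9)
    form_items = {f.form_id: set(f.scored_item_ids) for f in toy_bank.forms}
    for pid in matrix.person_ids:
        administered = form_items[matrix.form_assignment[pid]]
        observed = set(matrix.data.columns[matrix.data.loc[pid].notna()])
        assert observed == administered
    # round-robin split: each form gets half the persons
    counts = matrix.form_assignment.value_counts()
    assert set(counts) == {20}


def test_missing_parameters_rejected(toy_bank):
    abilities = sample_abilities(4, seed=10)
    with pytest.raises(ConfigurationError):
        simulate_responses(toy_bank.forms, {}, abilities, seed=1)


def test_column_means_decrease_in_b():
    rng = np.random.default_rng(11)
    abilities = sample_abilities(20000, seed=12)
    bs = [-1.5, -0.5, 0.5, 1.5]
    means = []
    for j, b in enumerate(bs):
        form = _single_item_form("i1")
        m = simulate_responses([form], {"i1": (2.0, b)}, abilities, seed=100 + j)
        means.append(m.data["i1"].mean())
    assert all(x > y for x, y in zip(means, means[1:]))


def test_steeper_slope_spreads_conditional_rates():
    # at theta far above b, a larger slope gives a higher success rate
    abilities = [
        type(a)(a.person_id, 1.0) for a in sample_abilities(20000, seed=13)
    ]
    form = _single_item_form("i1")
    low = simulate_responses([form], {"i1": (0.8, 0.0)}, abilities, seed=14)
    high = simulate_responses([form], {"i1": (2.5, 0.0)}, abilities, seed=15)
    assert high.data["i1"].mean() > low.data["i1"].mean()


def test_inject_random_responder():
    X = np.ones((10000, 3))
    matrix = make_matrix(X)
    out = inject_misfit(matrix, "i1", "random_responder", seed=16)
    assert abs(out.data["i1"].mean() - 0.5) < 0.02
    assert out.data["i0"].equals(matrix.data["i0"])
    assert out.data["i2"].equals(matrix.data["i2"])
    # original untouched
    assert matrix.data["i1"].mean() == 1.0


def test_inject_reversed_flips_observed_only():
    X = np.array([[1.0, 0.0], [np.nan, 1.0], [0.0, np.nan]])
    matrix = make_matrix(X)
    out = inject_misfit(matrix, "i0", "reversed", seed=17)
    assert out.data.loc["p0", "i0"] == 0.0
    assert np.isnan(out.data.loc["p1", "i0"])
    assert out.data.loc["p2", "i0"] == 1.0
    assert out.data["i1"].equals(matrix.data["i1"])


def test_inject_bad_args():
    matrix = make_matrix(np.ones((3, 2)))
    with pytest.raises(ConfigurationError):
        inject_misfit(matrix, "zzz", "reversed")
    with pytest.raises(UsageError):
        inject_misfit(matrix, "i0", "shuffled")


def test_round_robin_assignment(toy_bank):
    abilities = sample_abilities(5, seed=18)
    assignment = assign_forms_round_robin(abilities, toy_bank.forms)
    forms = [assignment[p.person_id] for p in abilities]
    assert forms == ["F01", "F02", "F01", "F02", "F01"]
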