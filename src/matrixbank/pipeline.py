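"""Seeded end-to-end demo: generate -> split/anchor -> simulate -> fit ->
misfit exclusion -> equate -> report, with a reproducibility manifest.

All randomness flows from one master seed through named sub-streams so
stages can be re-run independently.  The manifest records input/output
file digests; re-running with the same seed reproduces byte-identical
bank JSON and parameter CSVs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bank import BankConfig, build_bank
from .equating import equating_check, link_forms, transform_params
from .errors import MatrixBankError, NumericalError
from .irt import ItemParams2PL, fit_2pl, misfit_screen
from .items import MatrixItem
from .report import (
    correlate_with_trim,
    ctt_stats,
    item_rule_table,
    rule_regression,
)
from .simulate import sample_abilities, simulate_responses
from . import io as mbio

# default generating model for synthetic "true" parameters: discrimination
# is lognormal (moment-matched mean 2.09, sd 0.84); threshold is a linear
# function of the rule indicators plus noise
DEFAULT_DIFFICULTY_INTERCEPT = -1.56
DEFAULT_DIFFICULTY_WEIGHTS = {
    "ADD": 0.41,
    "SUB": 0.51,
    "DIS": 0.77,
    "INT": 0.68,
    "ROT": 0.34,
    "COM": 0.12,
}
DEFAULT_DIFFICULTY_NOISE_SD = 0.45
DEFAULT_DISCRIMINATION_MEAN = 2.09
DEFAULT_DISCRIMINATION_SD = 0.84


def draw_true_params(
    items: list[MatrixItem],
    seed: int | None = None,
    intercept: float = DEFAULT_DIFFICULTY_INTERCEPT,
    weights: dict[str, float] | None = None,
    noise_sd: float = DEFAULT_DIFFICULTY_NOISE_SD,
    a_mean: float = DEFAULT_DISCRIMINATION_MEAN,
    a_sd: float = DEFAULT_DISCRIMINATION_SD,
) -> dict[str, tuple[float, float]]:
    """Draw generating (a, b) per item from the rule-based model."""
    weights = weights or DEFAULT_DIFFICULTY_WEIGHTS
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p((a_sd / a_mean) ** 2)
    mu = np.log(a_mean) - sigma2 / 2.0
    out = {}
    for item in items:
        a = float(rng.lognormal(mu, np.sqrt(sigma2)))
        b = intercept + sum(
            weights.get(r.rule_kind.value, 0.0) for r in item.rules
        )
        if noise_sd > 0:
            b += float(rng.normal(0.0, noise_sd))
        out[item.item_id] = (max(a, 0.2), float(b))
    return out


@dataclass
class RunManifest:
    tool_version: str
    master_seed: int
    config_digest: str
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, inputs: dict[str, str], outputs: dict[str, str]):
        self.stages.append({"stage": name, "inputs": inputs, "outputs": outputs})

    def to_json(self) -> str:
        return json.dumps(
            {
                "tool_version": self.tool_version,
                "master_seed": self.master_seed,
                "config_digest": self.config_digest,
                "stages": self.stages,
            },
            indent=1,
            sort_keys=True,
        )

    @property
    def output_digests(self) -> dict[str, str]:
        out = {}
        for stage in self.stages:
            out.update(stage["outputs"])
        return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_demo(
    seed: int,
    out_dir,
    n_persons: int = 2560,
    config: BankConfig | None = None,
) -> RunManifest:
    """Run the full design end-to-end and write all artifacts to one
    directory.  Fully deterministic per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seed_bank, seed_params, seed_abil, seed_resp = [
        int(c.generate_state(1)[0]) for c in ss.spawn(4)
    ]

    config = config or BankConfig(master_seed=seed_bank)
    config_digest = hashlib.sha256(
        json.dumps(
            {
                "items_per_rule_count": config.items_per_rule_count,
                "n_test_sets": config.n_test_sets,
                "set_composition": config.set_composition,
                "master_seed": config.master_seed,
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()
    manifest = RunManifest(
        tool_version=__version__, master_seed=seed, config_digest=config_digest
    )

    stage = "generate"
    try:
        bank = build_bank(config)
        bank_path = out / "bank.json"
        mbio.write_bank(bank_path, bank)
        manifest.add_stage(stage, {}, {"bank.json": _digest(bank_path)})

        stage = "simulate"
        all_items = bank.items + bank.anchors
        true_params = draw_true_params(all_items, seed=seed_params)
        abilities = sample_abilities(n_persons, 0.0, 1.0, seed=seed_abil)
        matrix = simulate_responses(bank.forms, true_params, abilities, seed=seed_resp)
        resp_path = out / "responses.csv"
        mbio.write_responses(resp_path, matrix)
        true_path = out / "true_params.csv"
        mbio.write_params(
            true_path,
            [ItemParams2PL(i, a, b) for i, (a, b) in sorted(true_params.items())],
        )
        manifest.add_stage(
            stage,
            {"bank.json": _digest(bank_path)},
            {"responses.csv": _digest(resp_path), "true_params.csv": _digest(true_path)},
        )

        stage = "fit"
        per_form_params: dict[str, list[ItemParams2PL]] = {}
        per_form_stats = {}
        dropped: dict[str, list[str]] = {}
        fit_outputs = {}
        for form in bank.forms:
            persons = matrix.form_assignment[matrix.form_assignment == form.form_id].index
            sub = matrix.data.loc[persons, list(form.scored_item_ids)]
            form_matrix = type(matrix)(
                sub, matrix.form_assignment.loc[persons]
            )
            stats, _ = misfit_screen(form_matrix)
            flagged = {
                s.item_id
                for s in stats
                if s.flagged and s.item_id not in form.anchor_item_ids
            }
            dropped[form.form_id] = sorted(flagged)
            keep = [i for i in form.scored_item_ids if i not in flagged]
            fit = fit_2pl(
                type(matrix)(sub[keep], matrix.form_assignment.loc[persons]),
                drop_degenerate=True,
            )
            per_form_params[form.form_id] = fit.params
            per_form_stats[form.form_id] = stats
            ppath = out / f"params_{form.form_id}.csv"
            mbio.write_params(ppath, fit.params, stats, form_id=form.form_id)
            fit_outputs[ppath.name] = _digest(ppath)
        manifest.add_stage(stage, {"responses.csv": _digest(resp_path)}, fit_outputs)

        stage = "equate"
        anchor_ids = [a.item_id for a in bank.anchors]
        # an anchor can drop out of a small-sample calibration (all-correct
        # on one form); link on the anchors estimable everywhere
        usable = [
            aid
            for aid in anchor_ids
            if all(
                any(p.item_id == aid for p in params)
                for params in per_form_params.values()
            )
        ]
        if len(usable) < 2:
            raise NumericalError(
                "fewer than 2 anchors were estimable on every form"
            )
        coeffs = link_forms(per_form_params, usable, method="mean_sigma")
        equated: dict[str, list[ItemParams2PL]] = {}
        for c in coeffs:
            equated[c.form_id] = transform_params(per_form_params[c.form_id], c)
        eq_rows = []
        for form_id, params in equated.items():
            for p in params:
                eq_rows.append(
                    {"form_id": form_id, "item_id": p.item_id, "a": p.a, "b": p.b}
                )
        eq_path = out / "equated.csv"
        pd.DataFrame(eq_rows).to_csv(eq_path, index=False)
        coeff_path = out / "equating_coefficients.csv"
        pd.DataFrame(
            [{"form_id": c.form_id, "A": c.A, "B": c.B, "method": c.method} for c in coeffs]
        ).to_csv(coeff_path, index=False)
        manifest.add_stage(
            stage,
            fit_outputs,
            {eq_path.name: _digest(eq_path), coeff_path.name: _digest(coeff_path)},
        )

        stage = "report"
        report_dir = out / "report"
        anova_a, anova_b = equating_check(equated, anchor_ids)
        # one scale value per item; anchors keep their reference-form estimate
        by_item: dict[str, ItemParams2PL] = {}
        for form_id, params in equated.items():
            for p in params:
                by_item.setdefault(p.item_id, p)
        ctt = ctt_stats(matrix)
        unique_items = [it for it in bank.items if it.item_id in by_item]
        table = item_rule_table(unique_items, by_item)
        regression = rule_regression(table)
        p_by_item = (
            ctt.item_stats[ctt.item_stats.item_id.isin(table.index)]
            .groupby("item_id")["p"]
            .mean()
        )
        common = [i for i in table.index if i in p_by_item.index]
        trim = correlate_with_trim(
            p_by_item.loc[common].to_numpy(), table.loc[common, "b"].to_numpy()
        )
        outputs = write_report_bundle(
            report_dir, ctt, anova_a, anova_b, trim, regression, dropped
        )
        manifest.add_stage(
            stage,
            {eq_path.name: _digest(eq_path)},
            {k: _digest(v) for k, v in outputs.items()},
        )
    except MatrixBankError as err:
        manifest.add_stage(f"FAILED:{stage}", {}, {})
        (out / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
        raise MatrixBankError(f"demo failed at stage {stage!r}: {err}") from err

    (out / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest


def write_report_bundle(
    report_dir, ctt, anova_a, anova_b, trim, regression, dropped=None
) -> dict[str, Path]:
    """Write the CSV tables and box-plot figures; returns name -> path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    p = report_dir / "ctt_items.csv"
    ctt.item_stats.to_csv(p, index=False)
    outputs[p.name] = p
    p = report_dir / "ctt_alpha.csv"
    ctt.alpha.rename_axis("form_id").reset_index().to_csv(p, index=False)
    outputs[p.name] = p

    p = report_dir / "equating_anova.csv"
    pd.DataFrame(
        [
            {"parameter": "a", "F": anova_a.F, "df1": anova_a.df_between,
             "df2": anova_a.df_within, "p": anova_a.p, "omega_sq": anova_a.omega_sq},
            {"parameter": "b", "F": anova_b.F, "df1": anova_b.df_between,
             "df2": anova_b.df_within, "p": anova_b.p, "omega_sq": anova_b.omega_sq},
        ]
    ).to_csv(p, index=False)
    outputs[p.name] = p

    p = report_dir / "difficulty_correlation.csv"
    pd.DataFrame(
        [{"r_raw": trim.r_raw, "r_trimmed": trim.r_trimmed, "n_removed": trim.n_removed}]
    ).to_csv(p, index=False)
    outputs[p.name] = p

    p = report_dir / "rule_regression.csv"
    reg = regression.coef.reset_index()
    reg.to_csv(p, index=False)
    outputs[p.name] = p
    p = report_dir / "rule_regression_summary.csv"
    pd.DataFrame(
        [
            {
                "intercept": regression.intercept,
                "r_squared": regression.r_squared,
                "F_model": regression.f_model,
                "p_model": regression.p_model,
                "F_increment": regression.f_increment,
                "p_increment": regression.p_increment,
            }
        ]
    ).to_csv(p, index=False)
    outputs[p.name] = p

    if dropped is not None:
        p = report_dir / "misfit_exclusions.csv"
        pd.DataFrame(
            [{"form_id": k, "dropped_item_ids": ";".join(v)} for k, v in dropped.items()]
        ).to_csv(p, index=False)
        outputs[p.name] = p

    for stat, fname in (("p", "difficulty_boxplot.png"), ("r_pw", "part_whole_boxplot.png")):
        fig, ax = plt.subplots(figsize=(8, 4.5))
        groups = [
            (form_id, frame[stat].dropna().to_numpy())
            for form_id, frame in ctt.item_stats.groupby("form_id")
        ]
        ax.boxplot([g[1] for g in groups], tick_labels=[g[0] for g in groups])
        ax.set_xlabel("test set")
        ax.set_ylabel("item difficulty p" if stat == "p" else "part-whole correlation")
        fig.tight_layout()
        fp = report_dir / fname
        fig.savefig(fp, dpi=100)
        plt.close(fig)
        outputs[fname] = fp
    return outputs
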