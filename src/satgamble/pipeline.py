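"""End-to-end pipeline: simulate → validate → elicit → fit → sensitivity →
rls, with one master seed, a config hash on every artifact, and a log of
how many respondents each filter retained."""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import choice, cohort, elicit, io, rls as rls_mod, stats, weighting
from .core import BinnedLSDistribution, Context, State

#: Illustrative binned life-satisfaction shares for a contemporary UK-like
#: population (synthetic stand-in for an official release: most mass at
#: 7–8, ~94% at 5 or above).
EXAMPLE_LS_SHARES: tuple[float, ...] = (0.06, 0.10, 0.50, 0.34)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_respondents": 300,
    "respondents_path": None,  # load instead of simulating when set
    "distribution_path": None,  # EXAMPLE_LS_SHARES when unset
    "population": {},  # overrides for cohort.PopulationSpec fields
    "drop_order_violations": True,
    "drop_attention_fails": False,
    "quantile_method": elicit.DEFAULT_QUANTILE_METHOD,
    "cpt_presets": ["median", "extreme"],
    "weighting_mode": "indifference",
    "rls_methods": ["mean_utility", "median_participant"],
}


def config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _merged_config(config: Mapping | None) -> dict:
    merged = {**DEFAULT_CONFIG, **(config or {})}
    merged["population"] = {
        **DEFAULT_CONFIG["population"],
        **(merged.get("population") or {}),
    }
    return merged


def load_or_simulate(cfg: dict) -> tuple[list, pd.DataFrame | None]:
    if cfg["respondents_path"]:
        return io.read_respondents(cfg["respondents_path"]), None
    pop = cohort.PopulationSpec(**cfg["population"])
    return cohort.simulate_cohort(cfg["n_respondents"], pop, seed=cfg["seed"])


def load_distribution(cfg: dict) -> BinnedLSDistribution:
    if cfg["distribution_path"]:
        return io.read_distribution(cfg["distribution_path"])
    return BinnedLSDistribution(shares=EXAMPLE_LS_SHARES)


def apply_filters(respondents: list, cfg: dict) -> tuple[list, dict]:
    kept = list(respondents)
    log = {"n_input": len(kept)}
    if cfg["drop_order_violations"]:
        kept = [r for r in kept if not r.order_violation]
        log["n_after_order_filter"] = len(kept)
    if cfg["drop_attention_fails"]:
        kept = [r for r in kept if not r.attention_fail]
        log["n_after_attention_filter"] = len(kept)
    log["n_retained"] = len(kept)
    return kept, log


def _curve_to_json(curve) -> dict:
    return {s.name: curve.utilities[s] for s in sorted(curve.utilities)}


def _jsonable(value):
    if isinstance(value, float) and math.isinf(value):
        return "inf"
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def _frame_json(df: pd.DataFrame) -> list[dict]:
    return [
        {k: _jsonable(v) for k, v in row.items()}
        for row in df.to_dict(orient="records")
    ]


def run_pipeline(config: Mapping | None, out_dir: str | Path) -> Path:
    """Run every stage and write all artifacts under ``out_dir``.

    Outputs are deterministic functions of the config (byte-identical JSON
    on re-runs); every artifact directory carries a ``run.json`` with the
    config, its hash, the master seed and the filter log.
    """
    cfg = _merged_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_info: dict = {"config": cfg, "config_hash": config_hash(cfg), "seed": cfg["seed"]}

    # -- simulate / load ----------------------------------------------------
    respondents, truth = load_or_simulate(cfg)
    io.write_respondents(respondents, out / "respondents.csv")
    if truth is not None:
        truth.to_csv(out / "ground_truth.csv", index=False)

    # -- validate -----------------------------------------------------------
    report = stats.validation_report(respondents)
    io.write_json({k: _jsonable(v) for k, v in report.items()}, out / "validation.json")

    kept, filter_log = apply_filters(respondents, cfg)
    run_info["filters"] = filter_log

    # -- elicit -------------------------------------------------------------
    summary = elicit.summarize_lambda(kept, quantile_method=cfg["quantile_method"])
    summary.to_csv(out / "lambda_summary.csv", index=False)

    x_positions = rls_mod.vignette_x_positions(kept)
    curves = {
        ctx.value: elicit.curves_for_cohort(
            kept, context=ctx, include_death=False, reporting=True
        )
        for ctx in Context
    }
    io.write_json(
        {
            ctx: {pid: _curve_to_json(c) for pid, c in cs.items()}
            for ctx, cs in curves.items()
        },
        out / "curves_no_death.json",
    )

    # -- fit ----------------------------------------------------------------
    init_curves = elicit.curves_for_cohort(
        kept, context=Context.PERSONAL, include_death=True, reporting=False
    )
    fits, observations = choice.fit_cohort(kept, init_curves=init_curves)
    fit_rows = [
        {
            "participant": f.participant,
            "sigma": f.sigma,
            **{f"U_{s.name}": f.utilities[s] for s in choice.FREE_STATES},
            "loglik": f.loglik,
            "mcfadden_r2": f.mcfadden_r2,
            "pct_correct": f.pct_correct,
            "converged": f.converged,
            "monotone": f.monotone,
        }
        for f in fits.values()
    ]
    pd.DataFrame(fit_rows).to_csv(out / "choice_fits.csv", index=False)

    # -- rls ----------------------------------------------------------------
    dist = load_distribution(cfg)
    table = rls_mod.rls_table(
        curves, x_positions, dist, methods=cfg["rls_methods"]
    )
    table.to_csv(out / "rls.csv", index=False)

    # -- sensitivity --------------------------------------------------------
    sensitivity: dict = {}
    residual_frames = [weighting.residuals_by_probability(fits, observations, None)]
    for preset in cfg["cpt_presets"]:
        params = weighting.PRESETS[preset]
        w6 = weighting.weight(1e-6, params)
        weighted_curves = {
            ctx.value: weighting.weighted_curves_for_cohort(
                kept,
                params,
                context=ctx,
                include_death=False,
                reporting=True,
                mode=cfg["weighting_mode"],
            )
            for ctx in Context
        }
        wtable = rls_mod.rls_table(
            weighted_curves, x_positions, dist, methods=cfg["rls_methods"]
        )
        wtable.to_csv(out / f"rls_weighted_{preset}.csv", index=False)
        sensitivity[preset] = {
            "delta": params.delta,
            "gamma": params.gamma,
            "w_1e-6": w6,
            "overweight_factor_1e-6": w6 / 1e-6,
            "rls": _frame_json(wtable),
        }
        transform = lambda p, _pr=params: weighting.effective_probability(p, _pr)
        cpt_fits, _ = choice.fit_cohort(
            kept, init_curves=init_curves, prob_transform=transform
        )
        frame = weighting.residuals_by_probability(cpt_fits, observations, params)
        frame["model"] = f"cpt_{preset}"
        residual_frames.append(frame)
    io.write_json(sensitivity, out / "sensitivity.json")
    pd.concat(residual_frames, ignore_index=True).to_csv(
        out / "residuals_by_probability.csv", index=False
    )

    io.write_json(run_info, out / "run.json")
    return out
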