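"""End-to-end analysis pipeline: climate -> line summaries -> filters ->
trade-off fits -> Pareto front -> gradient inference, with a reproducible
machine-readable report.

Species are processed fully independently.  All thresholds are carried in
a RunConfig that round-trips losslessly through YAML/JSON and is echoed
verbatim into the report; all randomness flows from one seed, with
per-test child seeds derived deterministically and recorded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate import aridity_summaries
from .inference import (
    DEFAULT_TAILS,
    front_covariate_test,
    trait_climate_regression,
)
from .pareto import identify_front
from .records import (
    AnchorRule,
    BROMUS_STYLE_ANCHOR,
    IDENTITY_ANCHOR,
    anchor_emergence_time,
    apply_viability_filters,
    population_summaries,
    summarize_lines,
    validate_records,
)
from .tradeoff import (
    cooks_influence,
    deviation_decomposition,
    fit_tradeoff,
    residualize_on_mass,
    screen_seed_outcomes,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

ANCHOR_PRESETS = {"identity": IDENTITY_ANCHOR, "bromus_style": BROMUS_STYLE_ANCHOR}


@dataclass
class RunConfig:
    """Run configuration; every threshold is echoed into the report."""

    records_path: str | None = None
    climate_path: str | None = None
    scenario: str | None = None  # alternative to records/climate paths
    scenario_overrides: dict = field(default_factory=dict)
    anchor_rules: dict = field(default_factory=dict)  # species_id -> preset name
    viability_threshold: float = 0.5
    min_lines: int = 10
    cooks_threshold: float = 7.0
    permutations: int = 10_000
    tails: dict = field(default_factory=lambda: dict(DEFAULT_TAILS))
    dominance_rule: str = "weak"
    persistence_denominator: str = "viable"
    historical_window: tuple = (1985, 2014)
    collection_start: tuple = (2014, 5)
    run_screens: bool = True
    rng_seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["historical_window"] = list(self.historical_window)
        d["collection_start"] = list(self.collection_start)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("historical_window", "collection_start"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _anchor_rule(config: RunConfig, species: str) -> AnchorRule:
    name = config.anchor_rules.get(species, "identity")
    if isinstance(name, dict):
        return AnchorRule(**name)
    return ANCHOR_PRESETS[name]


def _apply_anchor(records: pd.DataFrame, rule: AnchorRule) -> pd.DataFrame:
    if rule == IDENTITY_ANCHOR:
        return records
    out = records.copy()
    emerged = out["fate"] == "emerged"
    out.loc[emerged, "emergence_day"] = [
        anchor_emergence_time(int(d), rule) for d in out.loc[emerged, "emergence_day"]
    ]
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict("records"))
    return obj


def _fit_dict(fit) -> dict:
    d = dict(fit.__dict__)
    return _jsonable(d)


def _tradeoff_block(lines: pd.DataFrame, cooks_threshold: float) -> dict:
    """Raw / deviation / mass-residualized fits plus influence screening."""
    out: dict = {}
    fit_raw = fit_tradeoff(lines)
    _cent, fit_dev = deviation_decomposition(lines)
    fit_mass = residualize_on_mass(lines)
    cooks_raw = cooks_influence(lines, threshold=cooks_threshold)
    cooks_dev = cooks_influence(
        _cent,
        response="dev_mean_sqrt_emergence",
        predictor="dev_persistence_fraction",
        threshold=cooks_threshold,
    )
    flagged = sorted(
        set(cooks_raw.loc[cooks_raw["influential"], "maternal_line_id"])
        | set(cooks_dev.loc[cooks_dev["influential"], "maternal_line_id"])
    )
    fit_raw.influential_lines = list(flagged)
    fit_raw.cooks_threshold = cooks_threshold
    out["raw"] = _fit_dict(fit_raw)
    out["deviation"] = _fit_dict(fit_dev)
    out["mass_residualized"] = _fit_dict(fit_mass)
    out["influential_lines"] = list(flagged)
    out["max_cooks_d"] = float(cooks_raw["cooks_d"].max())
    if flagged:
        kept = lines[~lines["maternal_line_id"].isin(flagged)]
        out["without_influential"] = {
            "raw": _fit_dict(fit_tradeoff(kept)),
            "deviation": _fit_dict(deviation_decomposition(kept)[1]),
            "mass_residualized": _fit_dict(residualize_on_mass(kept)),
        }
    return out


def _gradient_block(pops: pd.DataFrame, config: RunConfig, seed_seq) -> dict:
    out: dict = {"permutation": {}, "regression": {}}
    front = identify_front(pops, rule=config.dominance_rule)
    alt_rule = "strict" if config.dominance_rule == "weak" else "weak"
    front_alt = identify_front(pops, rule=alt_rule)
    out["front"] = {
        "rule": front.dominance_rule,
        "front_ids": list(front.front_ids),
        "dominated_by": _jsonable(front.dominated_by),
        "directions": front.directions,
        "weights": front.weights,
        f"front_ids_{alt_rule}": list(front_alt.front_ids),
    }
    children = seed_seq.spawn(len(config.tails))
    for (covariate, tail), child in zip(sorted(config.tails.items()), children):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        if covariate not in pops.columns:
            continue
        try:
            res = front_covariate_test(
                pops,
                front,
                covariate=covariate,
                tail=tail,
                B=config.permutations,
                seed=child_seed,
            )
            out["permutation"][covariate] = _jsonable(dict(res.__dict__))
        except ValueError as exc:
            out["permutation"][covariate] = {"error": str(exc)}
        for trait in ("mean_sqrt_emergence", "persistence_fraction"):
            try:
                reg = trait_climate_regression(pops, covariate=covariate, trait=trait)
                out["regression"][f"{trait}~{covariate}"] = _jsonable(dict(reg.__dict__))
            except ValueError as exc:
                out["regression"][f"{trait}~{covariate}"] = {"error": str(exc)}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the report dictionary.

    Stages per species: anchor emergence times -> line summaries ->
    viability filters -> seed-level screens -> trade-off fits (raw,
    deviation, mass-residualized, with/without influential lines) ->
    population summaries -> Pareto front -> permutation tests and
    trait-aridity regressions.
    """
    if config.scenario is not None:
        from .simulate import generate_study, scenario_preset

        truth = scenario_preset(
            config.scenario, rng_seed=config.rng_seed, **config.scenario_overrides
        )
        records, climate_df, _ = generate_study(truth)
    else:
        if config.records_path is None:
            raise ValueError("config needs either records_path or scenario")
        records = pd.read_csv(config.records_path)
        climate_df = (
            pd.read_csv(config.climate_path) if config.climate_path else None
        )
    records = validate_records(records)

    aridity = None
    if climate_df is not None:
        aridity = aridity_summaries(
            climate_df,
            historical_window=config.historical_window,
            collection_start=config.collection_start,
        )

    report: dict = {
        "config": config.to_dict(),
        "versions": {
            "seedpareto": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "species": {},
    }
    ss = np.random.SeedSequence(config.rng_seed)
    species_list = sorted(records["species_id"].unique())
    children = ss.spawn(len(species_list))
    for species, child in zip(species_list, children):
        sub = records[records["species_id"] == species]
        sub = _apply_anchor(sub, _anchor_rule(config, species))
        lines = summarize_lines(
            sub,
            pool_treatments=True,
            persistence_denominator=config.persistence_denominator,
        )
        retained, excl_log = apply_viability_filters(
            lines,
            line_threshold=config.viability_threshold,
            min_lines=config.min_lines,
        )
        if retained.empty:
            raise ValueError(f"species {species!r}: no lines retained after filters")
        block: dict = {
            "n_lines_input": int(len(lines)),
            "n_lines_retained": int(len(retained)),
            "exclusions": _jsonable(excl_log),
        }
        if config.run_screens:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                block["screens"] = _jsonable(screen_seed_outcomes(sub))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            block["tradeoff"] = _tradeoff_block(retained, config.cooks_threshold)
        pops = population_summaries(retained, aridity=aridity)
        block["populations"] = _jsonable(pops)
        if aridity is not None:
            block["gradient"] = _gradient_block(pops, config, child)
        report["species"][species] = block
        block["_tables"] = {"lines": lines, "retained": retained, "pops": pops}

    report["report_hash"] = _analysis_hash(report)
    if config.output_dir is not None:
        _write_outputs(report, config, aridity)
    for block in report["species"].values():
        block.pop("_tables", None)
    return report


def _analysis_hash(report: dict) -> str:
    """Hash of the deterministic analysis sections (excludes versions)."""
    config = {k: v for k, v in report["config"].items() if k != "output_dir"}
    payload = {
        "config": config,
        "species": {
            k: {kk: vv for kk, vv in v.items() if kk != "_tables"}
            for k, v in report["species"].items()
        },
    }
    text = json.dumps(_jsonable(payload), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


def _write_outputs(report: dict, config: RunConfig, aridity) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    clean = {
        k: ({kk: vv for kk, vv in v.items() if kk != "_tables"})
        for k, v in report["species"].items()
    }
    with open(out / "report.json", "w") as fh:
        json.dump(
            _jsonable({**report, "species": clean}), fh, sort_keys=True, indent=2
        )
    if aridity is not None:
        aridity.to_csv(out / "aridity_summaries.csv", index=False)
    excl_lines = []
    for species, block in report["species"].items():
        tables = block.get("_tables", {})
        if "lines" in tables:
            tables["lines"].to_csv(out / f"{species}_line_summaries.csv", index=False)
            tables["retained"].to_csv(out / f"{species}_lines_retained.csv", index=False)
            tables["pops"].to_csv(out / f"{species}_population_summaries.csv", index=False)
        for e in block["exclusions"]:
            excl_lines.append(
                f"{species}\t{e['level']}\t{e['population_id']}\t"
                f"{e['maternal_line_id']}\t{e['reason']}"
            )
    (out / "exclusions.log").write_text(
        "species\tlevel\tpopulation\tline\treason\n" + "\n".join(excl_lines) + "\n"
    )
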