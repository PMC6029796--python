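"""End-to-end orchestration: generate -> estimate -> cost -> psa.

Each stage writes its artifacts under the output directory, and a manifest
records the resolved configuration digest, the seed, and every artifact
path, so a run is fully auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import load_parameters
from .costs import net_cost
from .effects import (
    LosEffectModel,
    RateEffectModel,
    adjusted_means,
    intervention_contrast,
)
from .psa import run_psa
from .reporting import effect_report, ledger_frame, psa_report, render_cost_ledger
from .synthetic import GeneratorConfig, generate, read_extract, write_extract

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("generate", "estimate", "cost", "psa")

log = logging.getLogger("hinhcost")


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    ``stages`` selects which stages execute (in canonical order).  When the
    estimate stage runs without the generate stage, ``episodes_path`` and
    ``monthly_path`` must point to existing extracts.
    """

    stages: tuple = STAGES
    outdir: str | Path = "hinhcost_output"
    params_path: str | Path | None = None  # None -> packaged baseline config
    episodes_path: str | Path | None = None
    monthly_path: str | Path | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_trials: int = 10_000
    n_draws: int = 10_000  # simulation draws for effect-model intervals
    seed: int = 0
    count_sampler: str = "poisson"
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)
        if "estimate" in self.stages and "generate" not in self.stages:
            for path in (self.episodes_path, self.monthly_path):
                if path is None or not Path(path).exists():
                    raise ValueError(
                        "estimate stage without generate stage requires existing "
                        "episodes_path and monthly_path"
                    )

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload["outdir"] = str(payload["outdir"])
        for key in ("params_path", "episodes_path", "monthly_path"):
            if payload[key] is not None:
                payload[key] = str(payload[key])
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and return the artifact manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_gen, rng_est, rng_psa = (np.random.default_rng(s) for s in seeds)

    params, specs = load_parameters(config.params_path, config.count_sampler)

    episodes = monthly = None
    if "generate" in config.stages:
        log.info("generating synthetic extracts")
        episodes, monthly = generate(config.generator, rng=rng_gen)
        episodes_path = outdir / "episodes.csv"
        monthly_path = outdir / "monthly_counts.csv"
        write_extract(episodes, episodes_path)
        write_extract(monthly, monthly_path)
        artifacts["episodes"] = str(episodes_path)
        artifacts["monthly_counts"] = str(monthly_path)

    if "estimate" in config.stages:
        if episodes is None:
            episodes = read_extract(config.episodes_path, "episodes")
            monthly = read_extract(config.monthly_path, "monthly")
        log.info("fitting effect models")
        models = {
            "ed_rate": RateEffectModel("presentations", n_draws=config.n_draws).fit(monthly),
            "admission_rate": RateEffectModel("admissions", n_draws=config.n_draws).fit(monthly),
            "ed_los": LosEffectModel("ed", n_draws=config.n_draws).fit(episodes),
            "inpatient_los": LosEffectModel("inpatient", n_draws=config.n_draws).fit(episodes),
        }
        contrasts, means = {}, {}
        for name, model in models.items():
            means[name] = adjusted_means(model, rng=np.random.default_rng(rng_est.integers(2**31)))
            contrasts[name] = intervention_contrast(
                model, rng=np.random.default_rng(rng_est.integers(2**31))
            )
        report = effect_report(models, contrasts, means)
        effects_path = outdir / "effects_report.json"
        _write_json(effects_path, report)
        artifacts["effects_report"] = str(effects_path)

    breakdown = None
    if "cost" in config.stages:
        log.info("evaluating deterministic cost ledger")
        breakdown = net_cost(params)
        ledger_path = outdir / "cost_ledger.txt"
        ledger_csv = outdir / "cost_ledger.csv"
        ledger_path.write_text(render_cost_ledger(breakdown, params) + "\n", encoding="utf-8")
        ledger_frame(breakdown, params).to_csv(ledger_csv, index=False)
        artifacts["cost_ledger_text"] = str(ledger_path)
        artifacts["cost_ledger_csv"] = str(ledger_csv)

    if "psa" in config.stages:
        log.info("running probabilistic sensitivity analysis (%d trials)", config.n_trials)
        result = run_psa(params, specs, n_trials=config.n_trials, rng=rng_psa, seed=config.seed)
        summary_path = outdir / "psa_summary.json"
        _write_json(summary_path, psa_report(result))
        draws_path = outdir / "psa_draws.csv"
        frame = result.inputs.copy()
        frame["net_cost"] = result.draws
        frame.to_csv(draws_path, index=False)
        contrib_path = outdir / "variance_contributions.csv"
        result.contributions.rename_axis("parameter").to_csv(contrib_path)
        artifacts["psa_summary"] = str(summary_path)
        artifacts["psa_draws"] = str(draws_path)
        artifacts["variance_contributions"] = str(contrib_path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "config_digest": config.digest(),
        "artifacts": artifacts,
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest
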