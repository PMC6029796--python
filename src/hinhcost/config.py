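"""Load and save parameter sets and distribution specs (YAML or JSON).

The packaged default configuration carries the published baseline values of
the HiNH cost analysis, keyed by the conventional parameter letters ``a``-``m``
plus named program-cost items, together with the assumed sampling
distribution of every uncertain parameter.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .costs import ParameterSet
from .psa import DistributionSpec

__all__ = [
    "load_config",
    "load_parameters",
    "default_config_text",
    "build_parameter_set",
    "build_distribution_specs",
]


def default_config_text() -> str:
    """Raw YAML text of the packaged baseline configuration."""
    return (
        resources.files("hinhcost.data")
        .joinpath("default_parameters.yaml")
        .read_text(encoding="utf-8")
    )


def load_config(path: str | Path | None = None) -> dict:
    """Read a configuration mapping from YAML/JSON; ``None`` loads the default."""
    if path is None:
        return yaml.safe_load(default_config_text())
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def build_parameter_set(cfg: dict) -> ParameterSet:
    kwargs = dict(cfg["program_costs"])
    kwargs["equipment_life"] = cfg.get("equipment_life", 1.0)
    kwargs["discount_rate"] = cfg.get("discount_rate", 0.0)
    kwargs.update(cfg["utilisation"])
    kwargs.update(cfg.get("unit_costs", {}))
    return ParameterSet(**kwargs)


def build_distribution_specs(
    cfg: dict, params: ParameterSet, count_sampler: str = "poisson"
) -> list[DistributionSpec]:
    """Turn the ``distributions`` block into sampling specs.

    ``count_sampler`` selects how the monthly rates ``a`` and ``b`` are
    varied: ``"poisson"`` (mean = baseline; a Poisson has no free variance,
    the tabulated s.e. describes the regression estimate) or ``"normal"``
    (mean = baseline, sd = tabulated s.e.).
    """
    if count_sampler not in ("poisson", "normal"):
        raise ValueError("count_sampler must be 'poisson' or 'normal'")
    specs = []
    for name, entry in cfg.get("distributions", {}).items():
        entry = dict(entry)
        kind = entry.pop("kind")
        if kind == "poisson" and count_sampler == "normal":
            kind = "normal"
        elif kind == "poisson":
            entry.pop("se", None)
        base = entry.pop("base", None)
        if base is None:
            base = float(getattr(params, name))
        specs.append(DistributionSpec(name=name, kind=kind, base=base, **entry))
    return specs


def load_parameters(
    path: str | Path | None = None, count_sampler: str = "poisson"
) -> tuple[ParameterSet, list[DistributionSpec]]:
    """One-stop loader: ``(ParameterSet, distribution specs)``."""
    cfg = load_config(path)
    params = build_parameter_set(cfg)
    return params, build_distribution_specs(cfg, params, count_sampler)
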