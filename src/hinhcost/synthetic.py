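"""Synthetic hospital-utilisation data with the structure the analysis assumes.

Emulates the episode-level (ED information system style) and month-level
extracts behind a two-hospital, two-period controlled design:

* monthly ED presentation counts are Poisson with mean
  ``rate x beds/1000``, where the rate carries multiplicative hospital, period
  and intervention effects on the log scale;
* admissions are a per-episode Bernoulli thinning of presentations, so
  monthly admission counts are Poisson as well and never exceed
  presentations;
* ED and inpatient lengths of stay are gamma distributed around cell means
  that carry their own multiplicative effects (log-link structure), with a
  fixed shape so the coefficient of variation is constant across cells;
* patient covariates (age group, gender, triage, diagnosis group, day, time)
  are drawn independently from configurable marginal mixes, optionally with
  multiplicative LOS effects so that covariate adjustment is non-trivial.

The intervention effect enters only the (intervention hospital, post period)
cell — the realized difference-in-differences interaction.  Episode- and
month-level outputs come from one coherent draw: the monthly table is an
aggregation of the episode table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "ExtractFormatError",
    "generate",
    "generate_episodes",
    "generate_monthly_counts",
    "write_extract",
    "read_extract",
    "EPISODE_COLUMNS",
    "MONTHLY_COLUMNS",
    "CATEGORY_LEVELS",
]

HOSPITALS = ("control", "intervention")
YEARS = ("pre", "post")

CATEGORY_LEVELS = {
    "hospital": list(HOSPITALS),
    "year": list(YEARS),
    "age_group": ["<65", "65-74", "75-84", "85-94", ">=95"],
    "gender": ["male", "female"],
    "triage": ["ATS1-2", "ATS3-5"],
    "diagnosis_group": [
        "injury_poisoning",
        "respiratory",
        "circulatory",
        "digestive",
        "genitourinary",
        "musculoskeletal_skin",
        "mental_neurological",
        "other",
    ],
    "attendance_day": ["weekday", "weekend"],
    "attendance_time": ["working", "after"],
}

COVARIATES = (
    "age_group",
    "gender",
    "triage",
    "diagnosis_group",
    "attendance_day",
    "attendance_time",
)

EPISODE_COLUMNS = [
    "hospital",
    "year",
    "month_index",
    *COVARIATES,
    "ed_los_hours",
    "admitted",
    "inpatient_los_hours",
]

MONTHLY_COLUMNS = [
    "hospital",
    "year",
    "month_index",
    "n_presentations",
    "n_admissions",
    "exposure_beds",
]


def _default_covariate_mix() -> dict:
    # marginal frequencies of a 449-episode pre-period ED cohort
    n = 449.0
    return {
        "age_group": {
            "<65": 29 / n,
            "65-74": 58 / n,
            "75-84": 137 / n,
            "85-94": 193 / n,
            ">=95": 32 / n,
        },
        "gender": {"male": 168 / n, "female": 281 / n},
        "triage": {"ATS1-2": 80 / n, "ATS3-5": 369 / n},
        "diagnosis_group": {
            "injury_poisoning": 104 / n,
            "respiratory": 51 / n,
            "circulatory": 42 / n,
            "digestive": 40 / n,
            "genitourinary": 22 / n,
            "musculoskeletal_skin": 38 / n,
            "mental_neurological": 23 / n,
            "other": 129 / n,
        },
        "attendance_day": {"weekday": 339 / n, "weekend": 110 / n},
        "attendance_time": {"working": 284 / n, "after": 165 / n},
    }


def _as_pair(value, keys):
    """Broadcast a scalar to a dict over ``keys``; validate dict keys."""
    if np.isscalar(value):
        return {k: float(value) for k in keys}
    if set(value) != set(keys):
        raise ValueError(f"expected keys {keys}, got {tuple(value)}")
    return {k: float(value[k]) for k in keys}


RATE_KEYS = ("presentations", "admissions")
LOS_KEYS = ("ed", "inpatient")


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic extract generator.

    Defaults describe the reference (control hospital, pre period) cell of
    the published analysis and its multiplicative effect ratios, so the
    realized intervention-cell rates and LOS means reproduce the published
    adjusted means.  Rates are per 1,000 RACF beds per month; LOS in hours.
    """

    months_per_period: int = 3
    beds_per_catchment: float = 1000.0
    baseline_rates: dict = field(
        default_factory=lambda: {"presentations": 74.92, "admissions": 34.38}
    )
    hospital_rate_ratio: dict = field(
        default_factory=lambda: {"presentations": 0.94, "admissions": 1.17}
    )
    year_rate_ratio: dict = field(
        default_factory=lambda: {"presentations": 0.90, "admissions": 1.24}
    )
    intervention_rate_ratio: dict = field(
        default_factory=lambda: {"presentations": 0.83, "admissions": 0.53}
    )
    baseline_los_means: dict = field(
        default_factory=lambda: {"ed": 4.19, "inpatient": 86.24}
    )
    hospital_los_ratio: dict = field(
        default_factory=lambda: {"ed": 1.37, "inpatient": 1.10}
    )
    year_los_ratio: dict = field(default_factory=lambda: {"ed": 2.28, "inpatient": 0.85})
    intervention_los_ratio: dict = field(
        default_factory=lambda: {"ed": 0.53, "inpatient": 0.81}
    )
    los_shape: float = 1.0  # gamma shape; 1.0 gives coefficient of variation 1
    covariate_mix: dict = field(default_factory=_default_covariate_mix)
    covariate_effects: dict = field(default_factory=dict)  # LOS multipliers, off by default
    seed: int = 0

    def __post_init__(self):
        if self.months_per_period < 1:
            raise ValueError("months_per_period must be >= 1")
        if self.beds_per_catchment <= 0:
            raise ValueError("beds_per_catchment must be positive")
        if self.los_shape <= 0:
            raise ValueError("los_shape must be positive")
        for name in ("baseline_rates", "hospital_rate_ratio", "year_rate_ratio", "intervention_rate_ratio"):
            setattr(self, name, _as_pair(getattr(self, name), RATE_KEYS))
            if any(v <= 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} entries must be strictly positive")
        for name in ("baseline_los_means", "hospital_los_ratio", "year_los_ratio", "intervention_los_ratio"):
            setattr(self, name, _as_pair(getattr(self, name), LOS_KEYS))
            if any(v <= 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} entries must be strictly positive")
        for col, mix in self.covariate_mix.items():
            if col not in CATEGORY_LEVELS:
                raise ValueError(f"unknown covariate {col!r}")
            unknown = set(mix) - set(CATEGORY_LEVELS[col])
            if unknown:
                raise ValueError(f"unknown levels {sorted(unknown)} for {col!r}")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"negative probability in mix for {col!r}")
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"probabilities for {col!r} must sum to 1")

    # -- realized cell parameters -------------------------------------------------

    def cell_rate(self, outcome: str, hospital: str, year: str) -> float:
        """Events per 1,000 beds per month in one design cell."""
        r = self.baseline_rates[outcome]
        if hospital == "intervention":
            r *= self.hospital_rate_ratio[outcome]
        if year == "post":
            r *= self.year_rate_ratio[outcome]
        if hospital == "intervention" and year == "post":
            r *= self.intervention_rate_ratio[outcome]
        return r

    def cell_los_mean(self, outcome: str, hospital: str, year: str) -> float:
        mu = self.baseline_los_means[outcome]
        if hospital == "intervention":
            mu *= self.hospital_los_ratio[outcome]
        if year == "post":
            mu *= self.year_los_ratio[outcome]
        if hospital == "intervention" and year == "post":
            mu *= self.intervention_los_ratio[outcome]
        return mu

    def cell_admission_prob(self, hospital: str, year: str) -> float:
        p = self.cell_rate("admissions", hospital, year) / self.cell_rate(
            "presentations", hospital, year
        )
        if p > 1:
            raise ValueError(
                f"admission rate exceeds presentation rate in cell ({hospital}, {year})"
            )
        return p


class ExtractFormatError(ValueError):
    """Raised when a CSV extract violates the documented schema."""


def _los_multipliers(config: GeneratorConfig, frame: pd.DataFrame) -> np.ndarray:
    mult = np.ones(len(frame))
    for col, effects in config.covariate_effects.items():
        if col not in CATEGORY_LEVELS:
            raise ValueError(f"unknown covariate {col!r} in covariate_effects")
        for level, factor in effects.items():
            mult[frame[col].to_numpy() == level] *= factor
    return mult


def generate(config: GeneratorConfig, rng: np.random.Generator | None = None):
    """Draw one coherent dataset: ``(episodes, monthly_counts)`` DataFrames.

    The monthly table is the per-(cell, month) aggregation of the episode
    table, so admissions can never exceed presentations and both levels obey
    the same underlying draw.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = []
    beds = config.beds_per_catchment
    for hospital in HOSPITALS:
        for year in YEARS:
            pres_mean = config.cell_rate("presentations", hospital, year) * beds / 1000.0
            p_admit = config.cell_admission_prob(hospital, year)
            mu_ed = config.cell_los_mean("ed", hospital, year)
            mu_ip = config.cell_los_mean("inpatient", hospital, year)
            for month in range(config.months_per_period):
                n = int(rng.poisson(pres_mean))
                cell = pd.DataFrame(
                    {
                        "hospital": np.repeat(hospital, n),
                        "year": np.repeat(year, n),
                        "month_index": np.repeat(month, n),
                    }
                )
                for col in COVARIATES:
                    mix = config.covariate_mix.get(col)
                    if mix is None:
                        raise ValueError(f"covariate_mix missing {col!r}")
                    levels = list(mix)
                    cell[col] = rng.choice(levels, size=n, p=list(mix.values()))
                shape = config.los_shape
                mult = _los_multipliers(config, cell)
                cell["ed_los_hours"] = rng.gamma(shape, mu_ed * mult / shape, size=n)
                admitted = rng.random(n) < p_admit
                cell["admitted"] = admitted
                ip = np.full(n, np.nan)
                n_adm = int(admitted.sum())
                if n_adm:
                    ip[admitted] = rng.gamma(
                        shape, mu_ip * mult[admitted] / shape, size=n_adm
                    )
                cell["inpatient_los_hours"] = ip
                frames.append(cell)
    episodes = pd.concat(frames, ignore_index=True)[EPISODE_COLUMNS]

    grid = pd.MultiIndex.from_product(
        [HOSPITALS, YEARS, range(config.months_per_period)],
        names=["hospital", "year", "month_index"],
    )
    grouped = episodes.groupby(["hospital", "year", "month_index"], sort=False)
    monthly = pd.DataFrame(
        {
            "n_presentations": grouped.size(),
            "n_admissions": grouped["admitted"].sum(),
        }
    ).reindex(grid, fill_value=0)
    monthly = monthly.reset_index()
    monthly["n_presentations"] = monthly["n_presentations"].astype(int)
    monthly["n_admissions"] = monthly["n_admissions"].astype(int)
    monthly["exposure_beds"] = beds
    return episodes, monthly[MONTHLY_COLUMNS]


def generate_episodes(config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Episode-level extract (one row per ED presentation)."""
    return generate(config, rng)[0]


def generate_monthly_counts(config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Month-level extract of presentation and admission counts with exposure."""
    return generate(config, rng)[1]


# -- CSV extract round trip -------------------------------------------------------


def write_extract(frame: pd.DataFrame, path: str | Path) -> None:
    """Write an episode or monthly extract as a UTF-8 CSV with header."""
    frame.to_csv(path, index=False, encoding="utf-8")


def _validate_categories(frame: pd.DataFrame, columns) -> None:
    bad_lines = []
    messages = []
    for col in columns:
        if col not in CATEGORY_LEVELS:
            continue
        valid = set(CATEGORY_LEVELS[col])
        mask = ~frame[col].isin(valid)
        if mask.any():
            for idx in frame.index[mask]:
                # +2: one for the header row, one for 1-based numbering
                bad_lines.append(idx + 2)
                messages.append(f"line {idx + 2}: invalid {col}={frame.at[idx, col]!r}")
    if bad_lines:
        raise ExtractFormatError(
            "malformed rows in extract:\n" + "\n".join(messages)
        )


def read_extract(path: str | Path, kind: str = "episodes") -> pd.DataFrame:
    """Read an extract written by :func:`write_extract`.

    ``kind`` is ``"episodes"`` or ``"monthly"``.  Unknown category values and
    schema violations raise :class:`ExtractFormatError` with the offending
    line numbers.  An empty file (header only, or no bytes) yields an empty
    frame with the documented columns.
    """
    if kind not in ("episodes", "monthly"):
        raise ValueError("kind must be 'episodes' or 'monthly'")
    columns = EPISODE_COLUMNS if kind == "episodes" else MONTHLY_COLUMNS
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    if frame.empty:
        return pd.DataFrame(columns=columns)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ExtractFormatError(f"extract is missing columns: {missing}")
    frame = frame[columns]
    _validate_categories(frame, columns)
    if kind == "episodes":
        frame["admitted"] = frame["admitted"].astype(bool)
        bad = frame.index[frame["ed_los_hours"] <= 0].tolist()
        bad += frame.index[
            frame["admitted"] & ~(frame["inpatient_los_hours"] > 0)
        ].tolist()
        bad += frame.index[
            ~frame["admitted"] & frame["inpatient_los_hours"].notna()
        ].tolist()
        if bad:
            lines = ", ".join(str(i + 2) for i in sorted(set(bad)))
            raise ExtractFormatError(f"invalid LOS/admission values at lines: {lines}")
    else:
        bad = frame.index[frame["n_admissions"] > frame["n_presentations"]].tolist()
        bad += frame.index[frame["exposure_beds"] <= 0].tolist()
        if bad:
            lines = ", ".join(str(i + 2) for i in sorted(set(bad)))
            raise ExtractFormatError(f"invalid monthly counts at lines: {lines}")
    return frame
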