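"""Synthetic sepsis-cohort generation and dataset IO.

Emulates the structure of a retrospective therapeutic-drug-monitoring (TDM)
cohort of adult sepsis patients on biapenem: covariates drawn from truncated
normal marginals matching the modeling cohort's summary statistics, 1-h
infusions of 300–600 mg given 2–4 times daily, sparse trough-weighted
sampling (about 1.5 samples per patient) after the third dose, additive
observation noise and a 0.3 mg/L lower limit of quantitation (LLOQ).

Datasets are tabulated in NONMEM-dialect long format (one row per dose or
observation event) and round-trip losslessly through CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pkmodel import (
    CovariateRecord,
    DomainError,
    DoseEvent,
    Regimen,
    conc_profile,
    individual_params,
)
from .population import PopulationModel

__all__ = [
    "ContinuousCovariate",
    "CovariateSummary",
    "SamplingScheme",
    "Observation",
    "SubjectRecord",
    "sepsis_cohort_summary",
    "default_regimen_mix",
    "sample_covariates",
    "cockcroft_gault",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "filter_estimable",
]


class ConfigError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass(frozen=True)
class ContinuousCovariate:
    """Truncated-normal marginal: mean/sd with hard range [minimum, maximum]."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigError(f"sd must be > 0, got {self.sd!r}")
        if not self.minimum < self.maximum:
            raise ConfigError(
                f"need minimum < maximum, got {self.minimum!r} >= {self.maximum!r}"
            )


@dataclass(frozen=True)
class CovariateSummary:
    """Marginal summaries of the cohort covariates.

    ``continuous`` maps covariate name to its truncated-normal spec;
    ``categorical`` maps category name to a frequency table.
    """

    continuous: dict[str, ContinuousCovariate]
    categorical: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, freqs in self.categorical.items():
            total = sum(freqs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigError(f"{name!r} frequencies sum to {total}, not 1")
            if any(not 0 <= f <= 1 for f in freqs.values()):
                raise ConfigError(f"{name!r} frequencies must lie in [0, 1]")


def sepsis_cohort_summary() -> CovariateSummary:
    """Covariate summary of the modeling cohort (n=245 adult sepsis patients)."""
    return CovariateSummary(
        continuous={
            "age": ContinuousCovariate(59.13, 19.01, 18.0, 97.0),
            "weight": ContinuousCovariate(63.40, 11.34, 36.8, 100.0),
            "alb": ContinuousCovariate(34.68, 5.30, 3.5, 55.1),
            "bun": ContinuousCovariate(9.84, 8.90, 0.4, 66.9),
            "scr": ContinuousCovariate(153.86, 214.21, 28.0, 1655.0),
            "egfr": ContinuousCovariate(104.16, 65.24, 2.6, 332.9),
            "clcr": ContinuousCovariate(88.91, 60.14, 3.5, 295.5),
        },
        categorical={
            "sex": {"male": 0.637, "female": 0.363},
            "septic_shock": {"no": 0.731, "yes": 0.269},
            "immunocompromised": {"no": 0.861, "yes": 0.139},
            "infection_site": {
                "respiratory": 0.441,
                "intra-abdominal": 0.486,
                "other": 0.073,
            },
        },
    )


def default_regimen_mix() -> list[tuple[Regimen, float]]:
    """Label-range regimens: 300–600 mg, 2–4 times daily, 1-h infusion."""
    return [
        (Regimen(300.0, 6.0, 1.0), 0.35),
        (Regimen(300.0, 8.0, 1.0), 0.35),
        (Regimen(300.0, 12.0, 1.0), 0.15),
        (Regimen(600.0, 12.0, 1.0), 0.15),
    ]


@dataclass(frozen=True)
class SamplingScheme:
    """Sparse TDM sampling model.

    The number of samples per subject is 1 + Binomial(extra_samples_max,
    p_extra); with the defaults it averages 1.5.  Each sample time is tied to
    a dosing interval at or after ``min_dose_index`` (counted from 1), with
    the offset drawn uniformly from the last ``trough_window`` fraction of the
    interval — a trough-weighted scheme.
    """

    mean_samples: float = 1.5
    extra_samples_max: int = 1
    min_dose_index: int = 3
    trough_window: float = 0.25
    lloq: float = 0.3
    windows: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.lloq <= 0:
            raise ConfigError("lloq must be > 0")
        if not 0 < self.trough_window <= 1:
            raise ConfigError("trough_window must be in (0, 1]")
        if self.windows is not None:
            for lo, hi in self.windows:
                if not 0 <= lo < hi <= 1:
                    raise ConfigError("sampling windows must satisfy 0 <= lo < hi <= 1")

    def offset_fraction(self, k: int, u: float) -> float:
        """Within-interval offset (fraction of the interval) of the k-th sample.

        Default: trough-weighted, uniform over the last ``trough_window`` of
        the interval.  With explicit ``windows`` the k-th sample draws
        uniformly from windows[k % len(windows)] — e.g. an early
        (distribution-phase) window plus a trough window gives the richer
        peak/trough design used for identifiability studies.
        """
        if self.windows is None:
            return 1.0 - self.trough_window * u
        lo, hi = self.windows[k % len(self.windows)]
        return lo + (hi - lo) * u

    @property
    def p_extra(self) -> float:
        if self.extra_samples_max == 0:
            return 0.0
        return (self.mean_samples - 1.0) / self.extra_samples_max


@dataclass(frozen=True)
class Observation:
    time: float
    conc: float
    blq: bool


@dataclass(frozen=True)
class SubjectRecord:
    """One patient: covariates, dose history and observed concentrations."""

    id: int
    covariates: CovariateRecord
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]

    def usable_observations(self) -> list[Observation]:
        """Quantifiable (non-BLQ) observations."""
        return [o for o in self.observations if not o.blq]


def sample_covariates(
    n: int, summary: CovariateSummary, seed: int | np.random.Generator = 0
) -> list[CovariateRecord]:
    """Draw n covariate vectors from independent truncated-normal marginals."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols: dict[str, np.ndarray] = {}
    for name in sorted(summary.continuous):
        spec = summary.continuous[name]
        a = (spec.minimum - spec.mean) / spec.sd
        b = (spec.maximum - spec.mean) / spec.sd
        cols[name] = stats.truncnorm.rvs(
            a, b, loc=spec.mean, scale=spec.sd, size=n, random_state=rng
        )
    cats: dict[str, np.ndarray] = {}
    for name in sorted(summary.categorical):
        freqs = summary.categorical[name]
        levels = sorted(freqs)
        probs = np.array([freqs[k] for k in levels])
        cats[name] = rng.choice(levels, size=n, p=probs / probs.sum())
    records = []
    for i in range(n):
        records.append(
            CovariateRecord(
                clcr=float(cols["clcr"][i]),
                bun=float(cols["bun"][i]),
                age=float(cols["age"][i]),
                weight=float(cols["weight"][i]),
                alb=float(cols["alb"][i]),
                scr=float(cols["scr"][i]),
                egfr=float(cols["egfr"][i]),
                female=bool(cats["sex"][i] == "female") if "sex" in cats else False,
                septic_shock=bool(cats["septic_shock"][i] == "yes")
                if "septic_shock" in cats
                else False,
                immunocompromised=bool(cats["immunocompromised"][i] == "yes")
                if "immunocompromised" in cats
                else False,
                infection_site=str(cats["infection_site"][i])
                if "infection_site" in cats
                else "respiratory",
            )
        )
    return records


def sample_covariate_table(
    n: int, summary: CovariateSummary, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Columnar continuous-covariate draw (fast path for large simulations)."""
    cols: dict[str, np.ndarray] = {}
    for name in sorted(summary.continuous):
        spec = summary.continuous[name]
        a = (spec.minimum - spec.mean) / spec.sd
        b = (spec.maximum - spec.mean) / spec.sd
        cols[name] = stats.truncnorm.rvs(
            a, b, loc=spec.mean, scale=spec.sd, size=n, random_state=rng
        )
    return cols


def cockcroft_gault(age: float, weight: float, scr: float, female: bool = False) -> float:
    """Cockcroft–Gault creatinine clearance, mL/min; scr in µmol/L."""
    if scr <= 0:
        raise DomainError("serum creatinine must be > 0")
    if age <= 0 or weight <= 0:
        raise DomainError("age and weight must be > 0")
    clcr = ((140.0 - age) * weight) / (72.0 * scr / 88.4)
    return 0.85 * clcr if female else clcr


def _draw_etas(model: PopulationModel, rng: np.random.Generator) -> dict[str, float]:
    return {
        name: float(rng.normal(0.0, math.sqrt(var))) if var > 0 else 0.0
        for name, var in model.omega.items()
    }


def generate_dataset(
    n: int,
    model: PopulationModel,
    regimen_mix: list[tuple[Regimen, float]] | None = None,
    scheme: SamplingScheme | None = None,
    summary: CovariateSummary | None = None,
    seed: int | np.random.Generator = 0,
) -> list[SubjectRecord]:
    """Simulate a TDM dataset of `n` subjects under `model`.

    Per subject: covariates sampled, a regimen assigned by the mix weights,
    etas drawn from N(0, omega), sparse sample times drawn per the scheme,
    and observed concentrations formed as model prediction plus residual
    noise (truncated at zero).  Values below the LLOQ are retained but
    flagged BLQ.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    regimen_mix = regimen_mix if regimen_mix is not None else default_regimen_mix()
    scheme = scheme or SamplingScheme()
    summary = summary or sepsis_cohort_summary()
    weights = np.array([w for _, w in regimen_mix], dtype=float)
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ConfigError(f"regimen weights sum to {weights.sum()}, not 1")

    covs = sample_covariates(n, summary, rng)
    subjects = []
    for i, cov in enumerate(covs):
        reg = regimen_mix[int(rng.choice(len(regimen_mix), p=weights))][0]
        typ = model.typical(cov)
        etas = _draw_etas(model, rng)
        ind = individual_params(typ, etas.get("cl", 0.0), etas.get("q", 0.0))

        n_extra = (
            rng.binomial(scheme.extra_samples_max, scheme.p_extra)
            if scheme.extra_samples_max > 0
            else 0
        )
        n_samples = 1 + int(n_extra)
        max_start_index = max(scheme.min_dose_index, 1)
        # sample within intervals starting at dose `min_dose_index` (1-based)
        dose_indices = rng.integers(
            max_start_index, max_start_index + 2, size=n_samples
        )
        n_doses_needed = int(dose_indices.max()) + 1
        doses = tuple(reg.dose_events(n_doses_needed))
        offsets = np.array(
            [scheme.offset_fraction(k, rng.random()) for k in range(n_samples)]
        )
        times = np.sort((dose_indices - 1 + offsets) * reg.interval)
        f = conc_profile(ind, doses, times)
        var = model.residual_var(f)
        y = f + rng.normal(0.0, np.sqrt(var)) if var.max() > 0 else f.copy()
        y = np.maximum(y, 0.0)
        obs = tuple(
            Observation(float(t), float(c), bool(c < scheme.lloq))
            for t, c in zip(times, y)
        )
        subjects.append(SubjectRecord(id=i + 1, covariates=cov, doses=doses, observations=obs))
    return subjects


# ---- tabular IO ----------------------------------------------------------

_COV_COLUMNS = {
    "CLCR": "clcr",
    "BUN": "bun",
    "AGE": "age",
    "WT": "weight",
    "ALB": "alb",
    "SCR": "scr",
    "EGFR": "egfr",
    "SEX": "female",
    "SHOCK": "septic_shock",
    "IMMUNO": "immunocompromised",
    "SITE": "infection_site",
}

_COLUMNS = ["ID", "TIME", "AMT", "DUR", "EVID", "DV", "MDV", "BLQ"] + list(_COV_COLUMNS)


def write_dataset(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subjects as a NONMEM-dialect long-format event table."""
    rows = []
    for s in subjects:
        cov = s.covariates
        covvals = {
            "CLCR": cov.clcr,
            "BUN": cov.bun,
            "AGE": cov.age if cov.age is not None else np.nan,
            "WT": cov.weight if cov.weight is not None else np.nan,
            "ALB": cov.alb if cov.alb is not None else np.nan,
            "SCR": cov.scr if cov.scr is not None else np.nan,
            "EGFR": cov.egfr if cov.egfr is not None else np.nan,
            "SEX": int(cov.female),
            "SHOCK": int(cov.septic_shock),
            "IMMUNO": int(cov.immunocompromised),
            "SITE": cov.infection_site,
        }
        for d in s.doses:
            rows.append(
                {
                    "ID": s.id,
                    "TIME": d.start_time,
                    "AMT": d.amount,
                    "DUR": d.duration,
                    "EVID": 1,
                    "DV": np.nan,
                    "MDV": 1,
                    "BLQ": 0,
                    **covvals,
                }
            )
        for o in s.observations:
            rows.append(
                {
                    "ID": s.id,
                    "TIME": o.time,
                    "AMT": 0.0,
                    "DUR": np.nan,
                    "EVID": 0,
                    "DV": o.conc,
                    "MDV": 0,
                    "BLQ": int(o.blq),
                    **covvals,
                }
            )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)


class ParseError(ValueError):
    pass


def read_dataset(df: pd.DataFrame) -> list[SubjectRecord]:
    """Parse an event table back into subject records (inverse of write_dataset)."""
    missing = [c for c in ("ID", "TIME", "AMT", "EVID", "DV", "CLCR", "BUN") if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")
    subjects = []
    for sid, grp in df.groupby("ID", sort=True):
        doses: list[DoseEvent] = []
        observations: list[Observation] = []
        first = grp.iloc[0]
        try:
            cov = CovariateRecord(
                clcr=float(first["CLCR"]),
                bun=float(first["BUN"]),
                age=float(first["AGE"]) if "AGE" in grp and pd.notna(first.get("AGE")) else None,
                weight=float(first["WT"]) if "WT" in grp and pd.notna(first.get("WT")) else None,
                alb=float(first["ALB"]) if "ALB" in grp and pd.notna(first.get("ALB")) else None,
                scr=float(first["SCR"]) if "SCR" in grp and pd.notna(first.get("SCR")) else None,
                egfr=float(first["EGFR"]) if "EGFR" in grp and pd.notna(first.get("EGFR")) else None,
                female=bool(int(first["SEX"])) if "SEX" in grp else False,
                septic_shock=bool(int(first["SHOCK"])) if "SHOCK" in grp else False,
                immunocompromised=bool(int(first["IMMUNO"])) if "IMMUNO" in grp else False,
                infection_site=str(first["SITE"]) if "SITE" in grp else "respiratory",
            )
        except (ValueError, DomainError) as exc:
            raise ParseError(f"bad covariates for subject {sid} (row {grp.index[0]}): {exc}")
        for idx, row in grp.iterrows():
            evid = int(row["EVID"])
            if evid == 1:
                dur = float(row["DUR"]) if pd.notna(row.get("DUR")) else 0.0
                if dur <= 0:
                    raise ParseError(f"row {idx}: dosing row needs DUR > 0")
                try:
                    doses.append(DoseEvent(float(row["TIME"]), float(row["AMT"]), dur))
                except DomainError as exc:
                    raise ParseError(f"row {idx}: {exc}")
            elif evid == 0:
                if pd.isna(row["DV"]):
                    raise ParseError(f"row {idx}: observation row needs DV")
                blq = bool(int(row["BLQ"])) if "BLQ" in grp else False
                observations.append(Observation(float(row["TIME"]), float(row["DV"]), blq))
            else:
                raise ParseError(f"row {idx}: unsupported EVID {evid}")
        subjects.append(
            SubjectRecord(
                id=int(sid), covariates=cov, doses=tuple(doses), observations=tuple(observations)
            )
        )
    return subjects


def filter_estimable(subjects: list[SubjectRecord]) -> list[SubjectRecord]:
    """Subjects with at least one quantifiable (non-BLQ) observation.

    The estimator excludes BLQ records (M1 convention), so subjects whose
    every sample fell below the LLOQ carry no likelihood contribution.
    """
    return [s for s in subjects if s.usable_observations()]
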