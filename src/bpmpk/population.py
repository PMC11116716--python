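"""Population model container: fixed effects, covariate structure, random effects.

A :class:`PopulationModel` bundles the structural typical values, the
covariate effects on them, the inter-individual variability (IIV) variances
and the residual-error model.  The shipped final model (creatinine clearance
on CL, blood urea nitrogen on Q, additive residual error) is packaged as a
YAML fixture and loaded with :func:`final_model`.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .pkmodel import CovariateRecord, DomainError, StructuralParams, ThetaVector

__all__ = [
    "CovariateEffect",
    "PopulationModel",
    "final_model",
    "load_model",
    "save_model",
]

_PARAM_NAMES_2CPT = ("cl", "v1", "q", "v2")
_PARAM_NAMES_1CPT = ("cl", "v1")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate effect on one structural parameter.

    Forms: ``linear``  P = TV * (1 + coef*(x - ref));
           ``power``   P = TV * (x/ref)**coef;
           ``categorical`` P = TV * (1 + coef*flag).
    """

    parameter: str
    covariate: str
    form: str = "linear"
    ref: float = 0.0
    coef: float = 0.0

    def factor(self, x: float) -> float:
        if self.form == "linear":
            return 1.0 + self.coef * (x - self.ref)
        if self.form == "power":
            if x <= 0 or self.ref <= 0:
                raise DomainError(
                    f"power form needs positive {self.covariate} and ref"
                )
            return (x / self.ref) ** self.coef
        if self.form == "categorical":
            return 1.0 + self.coef * x
        raise DomainError(f"unknown covariate form {self.form!r}")

    def key(self) -> tuple[str, str]:
        return (self.parameter, self.covariate)


@dataclass
class PopulationModel:
    """Fixed effects + covariate model + IIV variances + residual variance.

    ``omega`` maps structural-parameter names to IIV *variances* on the log
    scale (exponential IIV model); ``sigma_add`` / ``sigma_prop`` are the
    additive (mg²/L²) and proportional (dimensionless) residual variances —
    the observation variance is ``sigma_add + sigma_prop * f²`` which covers
    the additive, proportional and combined residual-error models.
    """

    theta: dict[str, float]
    effects: list[CovariateEffect] = field(default_factory=list)
    omega: dict[str, float] = field(default_factory=dict)
    sigma_add: float = 0.0
    sigma_prop: float = 0.0
    residual_kind: str = "additive"
    n_compartments: int = 2
    fu: float = 1.0

    def __post_init__(self) -> None:
        names = self.param_names()
        for name in names:
            if name not in self.theta or self.theta[name] <= 0:
                raise DomainError(f"theta[{name!r}] must be present and > 0")
        for k, v in self.omega.items():
            if k not in names:
                raise DomainError(f"omega key {k!r} is not a structural parameter")
            if v < 0:
                raise DomainError("omega variances must be >= 0")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise DomainError("residual variances must be >= 0")
        if self.residual_kind not in ("additive", "proportional", "combined"):
            raise DomainError(f"unknown residual_kind {self.residual_kind!r}")
        for e in self.effects:
            if e.parameter not in names:
                raise DomainError(
                    f"covariate effect targets unknown parameter {e.parameter!r}"
                )

    # ---- structure -------------------------------------------------------

    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES_2CPT if self.n_compartments == 2 else _PARAM_NAMES_1CPT

    def eta_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.omega))

    def copy(self) -> "PopulationModel":
        return copy.deepcopy(self)

    def with_effect(self, effect: CovariateEffect) -> "PopulationModel":
        m = self.copy()
        m.effects = [e for e in m.effects if e.key() != effect.key()] + [effect]
        return m

    def without_effect(self, key: tuple[str, str]) -> "PopulationModel":
        m = self.copy()
        m.effects = [e for e in m.effects if e.key() != key]
        return m

    # ---- evaluation ------------------------------------------------------

    def typical(self, cov: CovariateRecord) -> StructuralParams:
        """Typical-value structural parameters for one covariate vector."""
        values = dict(self.theta)
        for e in self.effects:
            fac = e.factor(cov.get(e.covariate))
            if fac <= 0:
                raise DomainError(
                    f"covariate {e.covariate!r}={cov.get(e.covariate)} drives "
                    f"{e.parameter!r} non-positive"
                )
            values[e.parameter] = values[e.parameter] * fac
        if self.n_compartments == 1:
            # degenerate peripheral compartment: tiny Q keeps one closed form
            return StructuralParams(values["cl"], values["v1"], 1e-9, 1.0)
        return StructuralParams(values["cl"], values["v1"], values["q"], values["v2"])

    def typical_arrays(self, cov_table: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Vectorized typical values from a columnar covariate table."""
        n = len(next(iter(cov_table.values())))
        out = {k: np.full(n, v, dtype=float) for k, v in self.theta.items()}
        for e in self.effects:
            x = np.asarray(cov_table[e.covariate], dtype=float)
            if e.form == "linear":
                fac = 1.0 + e.coef * (x - e.ref)
            elif e.form == "power":
                fac = (x / e.ref) ** e.coef
            else:
                fac = 1.0 + e.coef * x
            out[e.parameter] = out[e.parameter] * fac
        return out

    def residual_var(self, f: np.ndarray) -> np.ndarray:
        """Observation variance given predictions f."""
        return self.sigma_add + self.sigma_prop * np.square(f)

    # ---- ThetaVector bridge ---------------------------------------------

    def to_theta_vector(self) -> ThetaVector:
        """Final-model view: requires linear CLCr-on-CL and BUN-on-Q effects."""
        by_key = {e.key(): e for e in self.effects}
        e_cl = by_key.get(("cl", "clcr"))
        e_q = by_key.get(("q", "bun"))
        if e_cl is None or e_q is None or self.n_compartments != 2:
            raise DomainError(
                "to_theta_vector requires the two-compartment model with "
                "clcr-on-cl and bun-on-q effects"
            )
        return ThetaVector(
            th1_cl=self.theta["cl"],
            th2_v1=self.theta["v1"],
            th3_q=self.theta["q"],
            th4_v2=self.theta["v2"],
            th5_clcr_slope=e_cl.coef,
            th6_bun_slope=e_q.coef,
            clcr_ref=e_cl.ref,
            bun_ref=e_q.ref,
        )

    @classmethod
    def from_theta_vector(
        cls,
        theta: ThetaVector,
        omega_cl: float,
        omega_q: float,
        sigma_add: float,
        fu: float = 1.0,
    ) -> "PopulationModel":
        return cls(
            theta={
                "cl": theta.th1_cl,
                "v1": theta.th2_v1,
                "q": theta.th3_q,
                "v2": theta.th4_v2,
            },
            effects=[
                CovariateEffect("cl", "clcr", "linear", theta.clcr_ref, theta.th5_clcr_slope),
                CovariateEffect("q", "bun", "linear", theta.bun_ref, theta.th6_bun_slope),
            ],
            omega={"cl": omega_cl, "q": omega_q},
            sigma_add=sigma_add,
            residual_kind="additive",
            fu=fu,
        )


# ---- config serialization ------------------------------------------------


def _model_to_dict(model: PopulationModel) -> dict:
    return {
        "n_compartments": model.n_compartments,
        "theta": dict(model.theta),
        "effects": [
            {
                "parameter": e.parameter,
                "covariate": e.covariate,
                "form": e.form,
                "ref": float(e.ref),
                "coef": float(e.coef),
            }
            for e in model.effects
        ],
        "omega": dict(model.omega),
        "sigma": {
            "kind": model.residual_kind,
            "add": float(model.sigma_add),
            "prop": float(model.sigma_prop),
        },
        "variance_scale": "variance",
        "fu": float(model.fu),
    }


def _model_from_dict(d: dict) -> PopulationModel:
    scale = d.get("variance_scale", "variance")
    omega = {k: float(v) for k, v in d.get("omega", {}).items()}
    sigma = d.get("sigma", {})
    sigma_add = float(sigma.get("add", 0.0))
    sigma_prop = float(sigma.get("prop", 0.0))
    if scale == "sd":
        omega = {k: v * v for k, v in omega.items()}
        sigma_add, sigma_prop = sigma_add**2, sigma_prop**2
    elif scale != "variance":
        raise DomainError(f"unknown variance_scale {scale!r}")
    return PopulationModel(
        theta={k: float(v) for k, v in d["theta"].items()},
        effects=[
            CovariateEffect(
                parameter=e["parameter"],
                covariate=e["covariate"],
                form=e.get("form", "linear"),
                ref=float(e.get("ref", 0.0)),
                coef=float(e.get("coef", 0.0)),
            )
            for e in d.get("effects", [])
        ],
        omega=omega,
        sigma_add=sigma_add,
        sigma_prop=sigma_prop,
        residual_kind=sigma.get("kind", "additive"),
        n_compartments=int(d.get("n_compartments", 2)),
        fu=float(d.get("fu", 1.0)),
    )


def save_model(model: PopulationModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> PopulationModel:
    with open(path) as fh:
        return _model_from_dict(yaml.safe_load(fh))


def final_model() -> PopulationModel:
    """The packaged final biapenem sepsis model."""
    ref = importlib.resources.files("bpmpk").joinpath("data/final_model.yaml")
    return _model_from_dict(yaml.safe_load(ref.read_text()))
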