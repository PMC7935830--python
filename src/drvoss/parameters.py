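"""Population parameters, covariates and regimens for the darunavir model.

The package is built around a fixed one-compartment population-PK model of
ritonavir/cobicistat-boosted darunavir with first-order absorption and
first-order elimination.  Inter-individual variability is log-normal on
CL/F, V/F and ka; residual error combines an exponential and an additive
component.  Covariate effects are proportional shifts of the typical value:
sex and CYP3A5*3 genotype act on clearance, SLCO3A1 rs8027174 genotype on
volume.

Parameter sets can be loaded from YAML/JSON config files keyed by the
:class:`PopulationParameters` field names; the published learning-set
estimates ship with the package as the default named set.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "PopulationParameters",
    "CovariateProfile",
    "Regimen",
    "IndividualParameters",
    "load_parameters",
    "default_parameters",
]


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed and random effects of the population model (apparent oral scale).

    Attributes
    ----------
    cl_pop : float
        Typical apparent clearance CL/F (L/h) for the reference subject
        (male, CYP3A5 expresser, SLCO3A1 GG).
    v_pop : float
        Typical apparent volume of distribution V/F (L).
    ka_pop : float
        Typical first-order absorption rate constant (1/h).
    theta_sex, theta_cyp3a5 : float
        Proportional covariate effects on CL/F (dimensionless).
    theta_slco3a1 : float
        Proportional covariate effect on V/F (dimensionless).
    omega_cl, omega_v, omega_ka : float
        Log-scale inter-individual standard deviations.
    sigma_exp : float
        Exponential (log-scale proportional) residual SD.
    sigma_add : float
        Additive residual SD (mg/L).
    """

    cl_pop: float
    v_pop: float
    ka_pop: float
    theta_sex: float
    theta_cyp3a5: float
    theta_slco3a1: float
    omega_cl: float
    omega_v: float
    omega_ka: float
    sigma_exp: float
    sigma_add: float

    def __post_init__(self) -> None:
        for name in ("cl_pop", "v_pop", "ka_pop"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("omega_cl", "omega_v", "omega_ka", "sigma_exp", "sigma_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("theta_sex", "theta_cyp3a5", "theta_slco3a1"):
            if 1.0 + getattr(self, name) <= 0:
                raise ValueError(
                    f"(1 + {name}) must stay positive so covariate-adjusted "
                    "parameters remain positive"
                )
        for name in (f.name for f in dataclasses.fields(self)):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def omegas(self):
        return (self.omega_cl, self.omega_v, self.omega_ka)

    def replace(self, **changes) -> "PopulationParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParameters":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = names - set(d)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class CovariateProfile:
    """Per-subject covariates entering the parameter model.

    ``cyp3a5_flag`` is 1 for CYP3A5 non-expressers (*3/*3 homozygotes;
    reference group = *1 carriers) and ``slco3a1_flag`` is 1 for rs8027174
    T-allele carriers (GT/TT; reference GG).  Both codings are assumptions
    of this package (the source estimates do not restate them) and can be
    changed at the genotype-translation layer in
    :mod:`drvoss.population`.  ``race`` is carried only to drive modal
    imputation of missing genotypes; ``None`` flags mean "genotype missing,
    not yet imputed" and are rejected by the parameter model.
    """

    female: int
    cyp3a5_flag: int | None = 0
    slco3a1_flag: int | None = 0
    race: str = "Caucasian"

    def __post_init__(self) -> None:
        if self.female not in (0, 1):
            raise ValueError("female indicator must be 0 or 1")
        for name in ("cyp3a5_flag", "slco3a1_flag"):
            val = getattr(self, name)
            if val is not None and val not in (0, 1):
                raise ValueError(f"{name} must be 0, 1 or None (missing)")

    @property
    def resolved(self) -> bool:
        return self.cyp3a5_flag is not None and self.slco3a1_flag is not None


@dataclass(frozen=True)
class Regimen:
    """Steady-state oral dosing regimen: ``dose`` mg every ``tau`` hours."""

    dose: float
    tau: float

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValueError("dose must be positive")
        if self.tau not in (12.0, 24.0, 12, 24):
            raise ValueError("tau must be 12 or 24 h")

    @property
    def daily_dose(self) -> float:
        return self.dose * 24.0 / self.tau


@dataclass(frozen=True)
class IndividualParameters:
    """Individual PK parameters: typical value x covariate factors x exp(eta)."""

    cl: float
    v: float
    ka: float
    eta: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v > 0 and self.ka > 0):
            raise ValueError("individual CL, V and ka must be strictly positive")


#: Published learning-set estimates (reduced model without AAG); the
#: package-wide default parameter set.
LEARNING_SET = PopulationParameters(
    cl_pop=12.6,
    v_pop=137.0,
    ka_pop=0.545,
    theta_sex=-0.198,
    theta_cyp3a5=-0.192,
    theta_slco3a1=0.991,
    omega_cl=0.238,
    omega_v=0.353,
    omega_ka=0.575,
    sigma_exp=0.306,
    sigma_add=0.611,
)


def default_parameters() -> PopulationParameters:
    """Return the learning-set parameter estimates shipped with the package."""
    with resources.files("drvoss.data").joinpath("learning_set.yaml").open() as fh:
        return PopulationParameters.from_dict(yaml.safe_load(fh))


def load_parameters(path: str | Path) -> PopulationParameters:
    """Load a parameter set from a YAML or JSON file keyed by field names."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a parameter mapping")
    return PopulationParameters.from_dict(data)
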