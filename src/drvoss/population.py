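"""Synthetic virtual populations with the structure of the clinical datasets.

The generator resamples covariates and regimens from the learning-set
frequency table (127 HIV-positive adults on boosted darunavir), draws
log-normal individual parameters, and simulates steady-state concentration
profiles with combined exponential + additive residual error.  A
validation-like mode emulates the sparse external dataset: one sample per
subject at a random post-intake time.

Everything is a pure function of its inputs and a seed, so downstream
stages (MAP estimation, design evaluation, diagnostics) are fully testable
with no data download.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import individual_parameters, steady_state_conc
from .parameters import CovariateProfile, IndividualParameters, PopulationParameters, Regimen

__all__ = [
    "CovariateFrequencyTable",
    "TruncatedLogNormalTAD",
    "sample_covariates",
    "draw_individual",
    "apply_residual_error",
    "simulate_profiles",
    "sample_validation_like",
    "OBS_FLOOR",
]

#: positivity floor for observed concentrations (mg/L), below any plausible LLOQ
OBS_FLOOR = 0.001

CYP3A5_GENOTYPES = ("*1/*1", "*1/*3", "*3/*3")
SLCO3A1_GENOTYPES = ("GG", "GT", "TT")


def _check_dist(name: str, probs) -> np.ndarray:
    """Validate a categorical distribution, renormalising away rounding slack.

    Published frequency tables are printed to one decimal per cent, so a
    column can sum to e.g. 100.1%; deviations up to 0.5% are renormalised,
    anything larger is treated as an invalid distribution.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"{name}: proportions must lie in [0, 1]")
    total = p.sum()
    if abs(total - 1.0) > 5e-3:
        raise ValueError(f"{name}: proportions must sum to 1 (got {total:.12f})")
    return p / total


@dataclass(frozen=True)
class CovariateFrequencyTable:
    """Marginal covariate/regimen frequencies used for resampling subjects.

    Defaults are the learning-set summary frequencies.  Genotype
    distributions carry an explicit "missing" mass; missing draws are
    imputed with the modal observed genotype (the by-race modal genotype is
    not published, so the overall mode is used for every race).
    """

    p_female: float = 0.331
    # (*1/*1, *1/*3, *3/*3, missing)
    cyp3a5: tuple[float, ...] = (0.260, 0.260, 0.457, 0.024)
    # (GG, GT, TT, missing) — rescaled below to sum to 1 if needed
    slco3a1: tuple[float, ...] = (0.827, 0.142, 0.0, 0.031)
    races: tuple[str, ...] = ("Caucasian", "African", "Other")
    p_race: tuple[float, ...] = (0.528, 0.433, 0.039)
    regimens: tuple[Regimen, ...] = (
        Regimen(600.0, 12.0),
        Regimen(800.0, 24.0),
        Regimen(1200.0, 24.0),
    )
    p_regimen: tuple[float, ...] = (0.079, 0.913, 0.008)
    #: genotype group to which the CL covariate effect applies
    cyp3a5_flag_genotypes: tuple[str, ...] = ("*3/*3",)
    #: genotype group to which the V covariate effect applies (T-carriers)
    slco3a1_flag_genotypes: tuple[str, ...] = ("GT", "TT")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female must lie in [0, 1]")
        _check_dist("cyp3a5", self.cyp3a5)
        _check_dist("slco3a1", self.slco3a1)
        _check_dist("race", self.p_race)
        _check_dist("regimen", self.p_regimen)
        if len(self.races) != len(self.p_race):
            raise ValueError("races and p_race length mismatch")
        if len(self.regimens) != len(self.p_regimen):
            raise ValueError("regimens and p_regimen length mismatch")

    def modal_genotype(self, locus: str) -> str:
        """Most frequent observed genotype at a locus (imputation target)."""
        if locus == "cyp3a5":
            return CYP3A5_GENOTYPES[int(np.argmax(self.cyp3a5[:3]))]
        if locus == "slco3a1":
            return SLCO3A1_GENOTYPES[int(np.argmax(self.slco3a1[:3]))]
        raise ValueError(f"unknown locus {locus!r}")


def _flag(genotype: str, flag_group: tuple[str, ...]) -> int:
    return int(genotype in flag_group)


def sample_covariates(
    n: int,
    freq: CovariateFrequencyTable | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> list[tuple[CovariateProfile, Regimen]]:
    """Draw ``n`` virtual subjects (covariates + regimen) from the table.

    Categorical draws are independent; genotypes drawn as "missing" are
    imputed with the modal genotype for the drawn race before the covariate
    flags are derived, so every returned profile is fully resolved.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    freq = freq or CovariateFrequencyTable()
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed

    female = rng.random(n) < freq.p_female
    race_idx = rng.choice(len(freq.races), size=n, p=_check_dist("race", freq.p_race))
    cyp_idx = rng.choice(4, size=n, p=_check_dist("cyp3a5", freq.cyp3a5))
    slc_idx = rng.choice(4, size=n, p=_check_dist("slco3a1", freq.slco3a1))
    reg_idx = rng.choice(len(freq.regimens), size=n, p=_check_dist("regimen", freq.p_regimen))

    subjects = []
    for i in range(n):
        race = freq.races[race_idx[i]]
        cyp_gt = (
            freq.modal_genotype("cyp3a5")
            if cyp_idx[i] == 3
            else CYP3A5_GENOTYPES[cyp_idx[i]]
        )
        slc_gt = (
            freq.modal_genotype("slco3a1")
            if slc_idx[i] == 3
            else SLCO3A1_GENOTYPES[slc_idx[i]]
        )
        cov = CovariateProfile(
            female=int(female[i]),
            cyp3a5_flag=_flag(cyp_gt, freq.cyp3a5_flag_genotypes),
            slco3a1_flag=_flag(slc_gt, freq.slco3a1_flag_genotypes),
            race=race,
        )
        subjects.append((cov, freq.regimens[reg_idx[i]]))
    return subjects


def draw_individual(
    pop: PopulationParameters,
    cov: CovariateProfile,
    reg: Regimen,
    rng: np.random.Generator,
) -> IndividualParameters:
    """Draw one individual parameter set: eta ~ N(0, omega^2), independent."""
    eta = rng.normal(0.0, pop.omegas)
    return individual_parameters(pop, cov, eta)


def apply_residual_error(
    c_pred,
    pop: PopulationParameters,
    rng: np.random.Generator,
    floor: float = OBS_FLOOR,
):
    """Combined exponential + additive residual error with a positivity floor.

    ``y = c_pred * exp(e1) + e2`` with ``e1 ~ N(0, sigma_exp^2)`` and
    ``e2 ~ N(0, sigma_add^2)``; draws below ``floor`` are set to ``floor``
    (negative concentrations are nonphysical and darunavir assay LLOQs sit
    well above this floor).
    """
    c_pred = np.asarray(c_pred, dtype=float)
    if np.any(c_pred < 0):
        raise ValueError("model-predicted concentration must be nonnegative")
    e1 = rng.normal(0.0, pop.sigma_exp, size=c_pred.shape)
    e2 = rng.normal(0.0, pop.sigma_add, size=c_pred.shape)
    y = c_pred * np.exp(e1) + e2
    return np.maximum(y, floor)


def _subject_rep_rng(seed: int, subject: int, rep: int) -> np.random.Generator:
    """Counter-based per-(subject, replicate) stream.

    Each stream is keyed only by (master seed, subject, replicate) and the
    parameter draw happens before any observation noise, so two sampling
    strategies run under the same master seed share identical eta draws —
    a deliberate variance-reduction device for strategy comparisons.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed), subject, rep)))


def simulate_profiles(
    pop: PopulationParameters,
    subjects: list[tuple[CovariateProfile, Regimen]],
    n_rep: int,
    times,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate ``n_rep`` replicate profiles per subject at the given times.

    For each (subject, replicate): a fresh eta draw, noise-free
    concentrations at the requested times after dose, residual error, and
    the true AUC24 (daily dose / true CL).  ``times=[]`` yields one
    parameter-only row per (subject, replicate) — AUC-only mode.

    Returns a long-format DataFrame with NONMEM-style columns
    ``ID, REP, TAD, DV, CPRED, AMT, II, SEX, CYP3A5, SLCO3A1, CL, V, KA,
    AUC24`` (``CPRED`` is the noise-free individual prediction, ``DV`` the
    observed concentration).
    """
    times = np.asarray(list(times), dtype=float)
    if times.size and (times.min() < 0 or times.max() > 24):
        raise ValueError("sampling times must lie within [0, 24] h")
    rows = []
    for sid, (cov, reg) in enumerate(subjects, start=1):
        for rep in range(1, n_rep + 1):
            rng = _subject_rep_rng(rng_seed, sid, rep)
            ind = draw_individual(pop, cov, reg, rng)
            auc = reg.daily_dose / ind.cl
            base = (
                sid, rep, reg.dose, reg.tau, cov.female,
                cov.cyp3a5_flag, cov.slco3a1_flag, ind.cl, ind.v, ind.ka, auc,
            )
            if times.size == 0:
                rows.append((base[0], base[1], np.nan, np.nan, np.nan) + base[2:])
                continue
            cpred = steady_state_conc(reg.dose, reg.tau, ind.cl, ind.v, ind.ka, times)
            dv = apply_residual_error(cpred, pop, rng)
            for t, c, y in zip(times, cpred, dv):
                rows.append((base[0], base[1], t, y, c) + base[2:])
    return pd.DataFrame(
        rows,
        columns=[
            "ID", "REP", "TAD", "DV", "CPRED", "AMT", "II",
            "SEX", "CYP3A5", "SLCO3A1", "CL", "V", "KA", "AUC24",
        ],
    )


@dataclass(frozen=True)
class TruncatedLogNormalTAD:
    """Truncated log-normal model for random post-intake sampling delays.

    Parameterised directly by the published summaries: ``mu = ln(median)``
    and ``sigma`` solved so the 97.5th percentile of the untruncated
    distribution matches the range maximum; support truncated to
    [lo, hi].
    """

    median: float
    lo: float
    hi: float

    @property
    def mu(self) -> float:
        return float(np.log(self.median))

    @property
    def sigma(self) -> float:
        return float((np.log(self.hi) - self.mu) / stats.norm.ppf(0.975))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        dist = stats.lognorm(s=self.sigma, scale=np.exp(self.mu))
        u = rng.uniform(dist.cdf(self.lo), dist.cdf(self.hi), size=n)
        return dist.ppf(u)


#: default post-intake delay models per dosing interval (validation-set summaries)
DEFAULT_TAD_MODELS = {
    24.0: TruncatedLogNormalTAD(median=14.8, lo=2.0, hi=31.5),
    12.0: TruncatedLogNormalTAD(median=13.7, lo=2.0, hi=25.8),
}


def sample_validation_like(
    pop: PopulationParameters,
    n_subjects: int,
    tad_distribution: dict[float, TruncatedLogNormalTAD] | None = None,
    rng_seed: int = 0,
    freq: CovariateFrequencyTable | None = None,
) -> pd.DataFrame:
    """Simulate a sparse external-validation-style dataset.

    One observation per subject at a random post-intake time drawn from a
    per-regimen truncated log-normal delay model.  Delays may exceed one
    dosing interval (a sample taken after a skipped visit); the steady-state
    profile is periodic so the concentration is evaluated at ``t mod tau``.
    """
    tad_models = tad_distribution or DEFAULT_TAD_MODELS
    master = np.random.default_rng(np.random.SeedSequence((int(rng_seed), 910)))
    subjects = sample_covariates(n_subjects, freq, master)
    rows = []
    for sid, (cov, reg) in enumerate(subjects, start=1):
        rng = _subject_rep_rng(rng_seed, sid, 1)
        ind = draw_individual(pop, cov, reg, rng)
        tad = float(tad_models[float(reg.tau)].sample(rng, 1)[0])
        cpred = steady_state_conc(reg.dose, reg.tau, ind.cl, ind.v, ind.ka, tad)
        dv = float(apply_residual_error(cpred, pop, rng))
        rows.append(
            (
                sid, 1, tad, dv, float(cpred), reg.dose, reg.tau, cov.female,
                cov.cyp3a5_flag, cov.slco3a1_flag, ind.cl, ind.v, ind.ka,
                reg.daily_dose / ind.cl,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ID", "REP", "TAD", "DV", "CPRED", "AMT", "II",
            "SEX", "CYP3A5", "SLCO3A1", "CL", "V", "KA", "AUC24",
        ],
    )
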