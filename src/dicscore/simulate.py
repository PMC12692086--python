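"""Synthetic AML cohort generator.

Emulates the statistical frame of a diagnostic AML cohort: two subgroups
(APL/M3 and non-M3), Bernoulli bleeding outcomes at the stated
prevalence, Bernoulli genetic positivity at the stated rate, and
log-normal laboratory marginals whose *pooled* (mixture) median and IQR
width match the published subgroup summaries while bleeders and
non-bleeders are separated on the log scale by the shift that yields a
configured per-marker ROC AUC.

Model
-----
For a marker with risk direction "high", non-bleeders draw
``exp(N(mu0, sigma))`` and bleeders ``exp(N(mu0 + delta, sigma))`` with

    delta = sqrt(2) * sigma * Phi^{-1}(AUC),

the equal-variance binormal shift whose pairwise AUC is exactly the
target (for "low" direction the shift is negative and the target AUC is
understood after direction normalization).  Given the bleeding
prevalence, ``(mu0, sigma)`` are solved numerically so that the mixture
median and natural-scale IQR width (q75 - q25) equal the configured
summaries; with zero shift this reduces to a plain log-normal quantile
fit.

Markers are drawn independently given the outcome class, except INR,
which is derived deterministically from the simulated PT (see
:data:`INR_PT_DIVISOR`) so the two never contradict each other.
"""

from __future__ import annotations

import functools
import hashlib
import json
import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import brentq, root
from scipy.stats import norm

from .cohort import Cohort, PatientRecord, Subgroup
from .evaluation import MarkerDirection

__all__ = [
    "MarkerSpec",
    "SubgroupConfig",
    "CohortConfig",
    "ClassConditionalLogNormal",
    "INR_PT_DIVISOR",
    "lognormal_from_quartiles",
    "shift_for_auc",
    "fit_class_conditional",
    "generate_cohort",
    "default_config",
    "load_config",
]

#: z-deviate of the 75th percentile of the standard normal.
_Z75 = float(norm.ppf(0.75))

#: INR is derived from simulated PT as pt_seconds / INR_PT_DIVISOR: the
#: mid-point of the 11.5-13.5 s PT normal range with ISI taken as 1.
INR_PT_DIVISOR = 12.5

#: PatientRecord fields a MarkerSpec may target (INR is derived, not drawn).
_MARKER_FIELDS = (
    "pt_seconds",
    "d_dimer_ng_ml",
    "fibrinogen_mg_dl",
    "platelet_1e9_l",
    "ldh",
    "hemoglobin_g_dl",
)


class MarkerSpec(BaseModel):
    """Target marginal summary and discrimination for one lab marker."""

    model_config = ConfigDict(frozen=True)

    name: str
    median: float = Field(gt=0)
    q25: float = Field(gt=0)
    q75: float = Field(gt=0)
    target_auc: float = Field(ge=0.5, lt=1.0)
    direction: MarkerDirection

    @model_validator(mode="after")
    def _check(self):
        if self.name not in _MARKER_FIELDS:
            raise ValueError(f"marker name must be one of {_MARKER_FIELDS}")
        if not (self.q25 < self.median < self.q75):
            raise ValueError(
                f"{self.name}: quartiles must satisfy q25 < median < q75, "
                f"got ({self.q25}, {self.median}, {self.q75})"
            )
        return self


class SubgroupConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n: int = Field(gt=0)
    bleeding_prevalence: float = Field(ge=0.0, le=1.0)
    genetic_positive_rate: float = Field(ge=0.0, le=1.0)
    #: odds multiplier for genetic positivity among bleeders relative to
    #: non-bleeders; 1.0 = independence (no conditional rates are published)
    genetic_bleeding_odds_ratio: float = Field(default=1.0, gt=0.0)
    markers: tuple[MarkerSpec, ...]


class CohortConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    m3: SubgroupConfig
    non_m3: SubgroupConfig
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def lognormal_from_quartiles(median: float, q25: float, q75: float) -> tuple[float, float]:
    """Fit a log-normal to (q25, median, q75) by quantile matching.

    Returns ``(mu, sigma)`` of the log-scale normal: ``mu = ln(median)``
    and ``sigma = ln(q75/q25) / (2 z_0.75)``.  The fitted distribution's
    median reproduces the input exactly and its quartiles reproduce the
    input IQR *ratio* exactly.
    """
    if not (0 < q25 < median < q75):
        raise ValueError(
            f"quartiles must satisfy 0 < q25 < median < q75, got ({q25}, {median}, {q75})"
        )
    return math.log(median), math.log(q75 / q25) / (2 * _Z75)


def shift_for_auc(sigma: float, target_auc: float) -> float:
    """Log-scale mean shift between classes yielding a given binormal AUC.

    Under equal-variance normals ``AUC = Phi(delta / (sigma sqrt 2))``, so
    ``delta = sqrt(2) sigma Phi^{-1}(AUC)``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not (0.5 <= target_auc < 1.0):
        raise ValueError(f"target_auc must be in [0.5, 1), got {target_auc}")
    return math.sqrt(2.0) * sigma * float(norm.ppf(target_auc))


class ClassConditionalLogNormal(BaseModel):
    """Solved per-class sampling parameters for one marker.

    Non-bleeders: ``exp(N(mu0, sigma))``; bleeders:
    ``exp(N(mu0 + delta, sigma))`` where ``delta`` carries the risk
    direction's sign.
    """

    model_config = ConfigDict(frozen=True)

    mu0: float
    sigma: float
    delta: float

    @property
    def mu1(self) -> float:
        return self.mu0 + self.delta

    @property
    def auc(self) -> float:
        """Direction-normalized pairwise AUC (exact, binormal closed form)."""
        return float(norm.cdf(abs(self.delta) / (self.sigma * math.sqrt(2.0))))

    def optimal_cutoff(self) -> float:
        """Population Youden-optimal threshold: the equal-variance binormal
        optimum is the midpoint of the class means (natural scale)."""
        return math.exp(self.mu0 + self.delta / 2.0)

    def population_youden(self, cutoff: float, direction: MarkerDirection) -> float:
        """Population Youden index of a given threshold."""
        x = math.log(cutoff)
        if MarkerDirection(direction) == MarkerDirection.HIGH_RISK:
            sens = 1.0 - norm.cdf((x - self.mu1) / self.sigma)
            spec = norm.cdf((x - self.mu0) / self.sigma)
        else:
            sens = norm.cdf((x - self.mu1) / self.sigma)
            spec = 1.0 - norm.cdf((x - self.mu0) / self.sigma)
        return float(sens + spec - 1.0)


def _mixture_quantile(p: float, mu0: float, sigma: float, delta: float,
                      prevalence: float) -> float:
    """Log-scale quantile of the two-class mixture."""
    def cdf(x):
        return ((1 - prevalence) * norm.cdf((x - mu0) / sigma)
                + prevalence * norm.cdf((x - mu0 - delta) / sigma))
    lo = min(mu0, mu0 + delta) - 10 * sigma
    hi = max(mu0, mu0 + delta) + 10 * sigma
    return brentq(lambda x: cdf(x) - p, lo, hi, xtol=1e-12)


@functools.lru_cache(maxsize=512)
def fit_class_conditional(spec: MarkerSpec, prevalence: float) -> ClassConditionalLogNormal:
    """Solve per-class log-normal parameters for one marker.

    Finds ``(mu0, sigma)`` such that the bleeding/non-bleeding *mixture*
    at the given prevalence has median ``spec.median`` and natural-scale
    IQR width ``spec.q75 - spec.q25``, with the class shift tied to sigma
    through the binormal AUC relation.  With prevalence 0/1 or AUC 0.5
    this reduces to the plain quantile fit.
    """
    mu_single, sigma_single = lognormal_from_quartiles(spec.median, spec.q25, spec.q75)
    sign = 1.0 if spec.direction == MarkerDirection.HIGH_RISK else -1.0
    z_auc = float(norm.ppf(spec.target_auc))
    degenerate = prevalence <= 0.0 or prevalence >= 1.0 or z_auc == 0.0

    target_iqr = spec.q75 - spec.q25

    if degenerate:
        # single-class (or shiftless) marginal: match median exactly and the
        # natural-scale IQR width
        def width(sig):
            a = _Z75 * sig
            return spec.median * (math.exp(a) - math.exp(-a)) - target_iqr
        sigma = brentq(width, 1e-9, 10 * sigma_single + 1.0, xtol=1e-12)
        delta = sign * math.sqrt(2.0) * sigma * z_auc
        mu0 = mu_single - (delta if prevalence >= 1.0 else 0.0)
        return ClassConditionalLogNormal(mu0=mu0, sigma=sigma, delta=delta)

    def equations(params):
        mu0, log_sigma = params
        sigma = math.exp(log_sigma)
        delta = sign * math.sqrt(2.0) * sigma * z_auc
        med = _mixture_quantile(0.5, mu0, sigma, delta, prevalence)
        lo = _mixture_quantile(0.25, mu0, sigma, delta, prevalence)
        hi = _mixture_quantile(0.75, mu0, sigma, delta, prevalence)
        return [
            math.exp(med) - spec.median,
            (math.exp(hi) - math.exp(lo)) - target_iqr,
        ]

    sol = root(equations, x0=[mu_single, math.log(sigma_single)], tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"class-conditional fit failed for {spec.name}: {sol.message}")
    mu0, log_sigma = sol.x
    sigma = math.exp(log_sigma)
    delta = sign * math.sqrt(2.0) * sigma * z_auc
    return ClassConditionalLogNormal(mu0=float(mu0), sigma=float(sigma), delta=float(delta))


def _genetic_class_rates(rate: float, odds_ratio: float, prevalence: float
                         ) -> tuple[float, float]:
    """Per-class genetic-positivity probabilities (non-bleeder, bleeder)
    with a given odds ratio, marginalizing back to the overall rate."""
    if odds_ratio == 1.0 or rate in (0.0, 1.0) or prevalence in (0.0, 1.0):
        return rate, rate

    def marginal(p0):
        odds1 = odds_ratio * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        return (1 - prevalence) * p0 + prevalence * p1 - rate

    p0 = brentq(marginal, 1e-12, 1 - 1e-12, xtol=1e-14)
    odds1 = odds_ratio * p0 / (1 - p0)
    return p0, odds1 / (1 + odds1)


def _generate_subgroup(cfg: SubgroupConfig, subgroup: Subgroup, prefix: str,
                       rng: np.random.Generator) -> list[PatientRecord]:
    n = cfg.n
    bleeding = rng.random(n) < cfg.bleeding_prevalence
    p0, p1 = _genetic_class_rates(cfg.genetic_positive_rate,
                                  cfg.genetic_bleeding_odds_ratio,
                                  cfg.bleeding_prevalence)
    genetic = rng.random(n) < np.where(bleeding, p1, p0)

    values: dict[str, np.ndarray] = {}
    for spec in cfg.markers:
        params = fit_class_conditional(spec, cfg.bleeding_prevalence)
        mu = np.where(bleeding, params.mu1, params.mu0)
        values[spec.name] = np.exp(rng.normal(mu, params.sigma))

    records = []
    width = len(str(n))
    for i in range(n):
        labs = {name: float(v[i]) for name, v in values.items()}
        if "pt_seconds" in labs:
            labs["inr"] = labs["pt_seconds"] / INR_PT_DIVISOR
        records.append(
            PatientRecord(
                patient_id=f"{prefix}-{i + 1:0{width}d}",
                subgroup=subgroup,
                genetic_positive=bool(genetic[i]),
                bleeding=bool(bleeding[i]),
                **labs,
            )
        )
    return records


def generate_cohort(config: CohortConfig, seed: Optional[int] = None) -> Cohort:
    """Draw a synthetic two-subgroup AML cohort.

    Deterministic given the config and seed (an explicit ``seed`` argument
    overrides ``config.seed``).  M3 records come first, then non-M3;
    within a subgroup the draw order is bleeding, genetics, then each
    marker in config order, so outputs are byte-stable.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    records = _generate_subgroup(config.m3, Subgroup.M3, "M3", rng)
    records += _generate_subgroup(config.non_m3, Subgroup.NON_M3, "NM3", rng)
    return Cohort(
        records=records,
        provenance=f"generated:seed={seed},config={config.config_hash()}",
    )


def default_config(seed: int = 0) -> CohortConfig:
    """Study-frame defaults: subgroup sizes, bleeding prevalences, genetic
    positivity rates, and per-marker pooled medians/IQRs with the
    univariate discrimination targets, as published for a 190-patient AML
    cohort (61 APL / 129 non-M3).

    D-dimer summaries published in mg/L are carried here in the canonical
    ng/mL (x1000).
    """
    m3_markers = (
        MarkerSpec(name="pt_seconds", median=13.80, q25=12.60, q75=15.15,
                   target_auc=0.639, direction=MarkerDirection.HIGH_RISK),
        MarkerSpec(name="d_dimer_ng_ml", median=13500.0, q25=5990.0, q75=31130.0,
                   target_auc=0.510, direction=MarkerDirection.HIGH_RISK),
        MarkerSpec(name="platelet_1e9_l", median=30.6, q25=19.3, q75=49.8,
                   target_auc=0.564, direction=MarkerDirection.LOW_RISK),
        MarkerSpec(name="fibrinogen_mg_dl", median=167.0, q25=106.0, q75=274.5,
                   target_auc=0.727, direction=MarkerDirection.LOW_RISK),
        MarkerSpec(name="ldh", median=321.0, q25=219.75, q75=536.50,
                   target_auc=0.594, direction=MarkerDirection.HIGH_RISK),
        MarkerSpec(name="hemoglobin_g_dl", median=9.70, q25=8.40, q75=11.40,
                   target_auc=0.531, direction=MarkerDirection.LOW_RISK),
    )
    non_m3_markers = (
        MarkerSpec(name="pt_seconds", median=12.90, q25=12.05, q75=14.00,
                   target_auc=0.553, direction=MarkerDirection.HIGH_RISK),
        MarkerSpec(name="d_dimer_ng_ml", median=2370.0, q25=1130.0, q75=6680.0,
                   target_auc=0.572, direction=MarkerDirection.HIGH_RISK),
        MarkerSpec(name="platelet_1e9_l", median=48.2, q25=29.3, q75=85.5,
                   target_auc=0.621, direction=MarkerDirection.LOW_RISK),
        MarkerSpec(name="fibrinogen_mg_dl", median=378.0, q25=308.50, q75=482.50,
                   target_auc=0.565, direction=MarkerDirection.LOW_RISK),
        MarkerSpec(name="ldh", median=478.0, q25=257.0, q75=868.0,
                   target_auc=0.756, direction=MarkerDirection.HIGH_RISK),
        MarkerSpec(name="hemoglobin_g_dl", median=8.70, q25=7.47, q75=9.75,
                   target_auc=0.517, direction=MarkerDirection.LOW_RISK),
    )
    return CohortConfig(
        m3=SubgroupConfig(
            n=61,
            bleeding_prevalence=0.508,       # 31/61 DIC with bleeding
            genetic_positive_rate=9 / 61,    # secondary abnormalities beyond t(15;17)
            markers=m3_markers,
        ),
        non_m3=SubgroupConfig(
            n=129,
            bleeding_prevalence=0.132,       # 17/129
            genetic_positive_rate=47 / 129,  # any detected abnormality
            markers=non_m3_markers,
        ),
        seed=seed,
    )


def load_config(path) -> CohortConfig:
    """Load a CohortConfig from a YAML or JSON file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CohortConfig.model_validate(data)
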