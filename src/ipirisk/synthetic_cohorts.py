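"""Synthetic prevention-trial and observational cohorts.

Generates cohorts that mimic a three-arm diabetes-prevention randomized
trial (lifestyle / metformin / placebo) and an older, leaner observational
cohort without randomized arms.  Covariates are drawn from a Gaussian
copula with configurable marginals; incident-diabetes times follow a
proportional-hazards model with a constant baseline hazard; observed times
are subject to administrative censoring and random dropout.

The generating hazard structure is parameterized per standard-deviation of
each continuous predictor, with arm-specific slopes for age, fasting
glucose, and BMI ("conditional on treatment") and shared slopes for HbA1c,
log-triglycerides, and sex.  Arm main effects and the baseline hazard are
usually set by :func:`calibrate_generating_model` so that marginal 3-year
incidences hit stated targets (e.g. a 0.227 placebo risk with 58%/31%
relative reductions for lifestyle and metformin).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

SCHEMA_VERSION = 1

TRIAL_ARMS = ("lifestyle", "metformin", "placebo")
ALL_ARMS = TRIAL_ARMS + ("none",)

#: columns of the cohort table, in on-disk order
COHORT_COLUMNS = [
    "id", "age", "sex", "race_ethnicity", "fpg", "hba1c", "bmi",
    "triglycerides", "arm", "time", "event",
]

#: predictor columns eligible for injected missingness (never outcome/arm)
PREDICTOR_COLUMNS = ["age", "sex", "fpg", "hba1c", "bmi", "triglycerides"]

#: continuous covariates with arm-specific generating slopes
INTERACTED = ("age", "fpg", "bmi")

_NORMAL_IQR = 2.0 * stats.norm.ppf(0.75)  # IQR of a standard normal


@dataclass
class CovariateSpec:
    """Marginal distribution of one continuous covariate, in native units.

    ``mean``/``sd`` are the moments of the *untruncated* distribution; for a
    lognormal family they are native-scale moments from which the log-scale
    location and scale are recovered by moment matching.  Truncation bounds
    are applied through the copula quantile transform, so wide bounds leave
    the marginal moments essentially untouched.
    """

    name: str
    mean: float
    sd: float
    family: str = "normal"  # "normal" | "lognormal"
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"covariate {self.name!r}: sd must be > 0, got {self.sd}")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"covariate {self.name!r}: unknown family {self.family!r}")
        if self.lower is not None and self.upper is not None and self.lower >= self.upper:
            raise ValueError(f"covariate {self.name!r}: truncation bounds out of order")
        if self.family == "lognormal" and (self.lower is not None and self.lower <= 0):
            raise ValueError(f"covariate {self.name!r}: lognormal requires positive support")

    @classmethod
    def lognormal_from_quartiles(
        cls, name: str, median: float, q1: float, q3: float,
        lower: float | None = None, upper: float | None = None,
    ) -> "CovariateSpec":
        """Build a lognormal spec from a printed median and quartiles."""
        mu = np.log(median)
        sigma = (np.log(q3) - np.log(q1)) / _NORMAL_IQR
        mean = float(np.exp(mu + sigma**2 / 2))
        sd = float(mean * np.sqrt(np.expm1(sigma**2)))
        return cls(name=name, mean=mean, sd=sd, family="lognormal", lower=lower, upper=upper)

    def log_params(self) -> tuple[float, float]:
        """(mu, sigma) of log X for a lognormal spec, by moment matching."""
        if self.family != "lognormal":
            raise ValueError(f"covariate {self.name!r} is not lognormal")
        sigma2 = np.log1p((self.sd / self.mean) ** 2)
        mu = np.log(self.mean) - sigma2 / 2
        return float(mu), float(np.sqrt(sigma2))

    def observed_moments(self) -> tuple[float, float]:
        """Mean and SD of the *truncated* marginal actually generated."""
        if self.family == "normal":
            if self.lower is None and self.upper is None:
                return self.mean, self.sd
            a = -np.inf if self.lower is None else (self.lower - self.mean) / self.sd
            b = np.inf if self.upper is None else (self.upper - self.mean) / self.sd
            d = stats.truncnorm(a, b, loc=self.mean, scale=self.sd)
            return float(d.mean()), float(d.std())
        mu, sigma = self.log_params()
        d = stats.lognorm(s=sigma, scale=np.exp(mu))
        return float(d.mean()), float(d.std())

    def from_uniform(self, u: np.ndarray) -> np.ndarray:
        """Quantile transform of u ~ U(0,1), honouring truncation bounds."""
        if self.family == "normal":
            dist = stats.norm(self.mean, self.sd)
        else:
            mu, sigma = self.log_params()
            dist = stats.lognorm(s=sigma, scale=np.exp(mu))
        lo = dist.cdf(self.lower) if self.lower is not None else 0.0
        hi = dist.cdf(self.upper) if self.upper is not None else 1.0
        return dist.ppf(lo + u * (hi - lo))


@dataclass
class GeneratingCoefficients:
    """Per-SD log-hazard generating truth.

    ``shared`` holds slopes common to every arm (hba1c, log_triglycerides,
    female); ``arm_slopes[arm]`` holds the arm-specific slopes for age, fpg
    and bmi; ``arm_main`` holds log-hazard arm main effects relative to
    placebo (placebo itself fixed at 0; the untreated "none" arm follows
    the placebo hazard).
    """

    shared: dict[str, float]
    arm_slopes: dict[str, dict[str, float]]
    arm_main: dict[str, float]

    def validate(self) -> None:
        missing: list[str] = []
        for key in ("hba1c", "log_triglycerides", "female"):
            if key not in self.shared:
                missing.append(f"shared:{key}")
        for arm in TRIAL_ARMS:
            if arm != "placebo" and arm not in self.arm_main:
                missing.append(f"arm_main:{arm}")
            slopes = self.arm_slopes.get(arm)
            if slopes is None:
                missing.extend(f"arm_slopes:{arm}:{v}" for v in INTERACTED)
                continue
            missing.extend(
                f"arm_slopes:{arm}:{v}" for v in INTERACTED if v not in slopes
            )
        if missing:
            raise ValueError(
                "generating coefficient set incomplete; missing terms: "
                + ", ".join(sorted(missing))
            )

    def main_effect(self, arm: str) -> float:
        if arm in ("placebo", "none"):
            return 0.0
        return self.arm_main[arm]

    def slopes(self, arm: str) -> dict[str, float]:
        # untreated subjects progress on the placebo (natural-history) hazard
        return self.arm_slopes["placebo" if arm == "none" else arm]


def table_generating_coefficients() -> GeneratingCoefficients:
    """Default generating truth: published per-SD hazard ratios, log scale.

    Arm main effects default to 0 and are intended to be set by
    :func:`calibrate_generating_model`.
    """
    ln = np.log
    return GeneratingCoefficients(
        shared={
            "hba1c": float(ln(1.21)),
            "log_triglycerides": float(ln(1.24)),
            "female": float(ln(1.16)),
        },
        arm_slopes={
            "lifestyle": {"age": float(ln(0.95)), "fpg": float(ln(1.47)), "bmi": float(ln(1.37))},
            "metformin": {"age": float(ln(1.02)), "fpg": float(ln(1.53)), "bmi": float(ln(0.89))},
            "placebo": {"age": float(ln(0.97)), "fpg": float(ln(1.90)), "bmi": float(ln(1.04))},
        },
        arm_main={"lifestyle": 0.0, "metformin": 0.0},
    )


# covariate order used for the copula correlation matrix
_COV_ORDER = ("age", "fpg", "hba1c", "bmi", "triglycerides")


def default_correlation() -> np.ndarray:
    """Default copula correlation: 0.2 for FPG–HbA1c, FPG–BMI, BMI–TG."""
    r = np.eye(len(_COV_ORDER))
    idx = {name: i for i, name in enumerate(_COV_ORDER)}
    for a, b in (("fpg", "hba1c"), ("fpg", "bmi"), ("bmi", "triglycerides")):
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = 0.2
    return r


@dataclass
class SimulationConfig:
    """Full generating configuration for one synthetic cohort."""

    n: int
    allocation: dict[str, float]
    covariates: list[CovariateSpec]
    correlation: np.ndarray
    coefficients: GeneratingCoefficients
    baseline_hazard: float = 0.10          # events / year under reference profile
    admin_censor_years: float = 3.2
    dropout_rate: float = 0.02             # exponential dropout, / year
    missingness: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    p_female: float = 0.67
    race_probs: dict[str, float] = field(
        default_factory=lambda: {
            "nh_white": 0.62, "nh_black": 0.16, "hispanic": 0.17, "other": 0.05,
        }
    )
    # centres and per-SD units of the standardized linear predictor; these
    # anchor the generating model and stay fixed across cohorts so that a
    # leaner population genuinely carries lower risk
    centers: dict[str, float] = field(default_factory=dict)
    std_units: dict[str, float] = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        total = sum(self.allocation.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"allocation probabilities sum to {total}, expected 1")
        unknown = set(self.allocation) - set(ALL_ARMS)
        if unknown:
            raise ValueError(f"unknown arm(s) in allocation: {sorted(unknown)}")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard rate must be > 0")
        for col, frac in self.missingness.items():
            if not 0 <= frac < 1:
                raise ValueError(f"missingness fraction for {col!r} must lie in [0, 1)")
        self._check_correlation()
        if not self.centers:
            self.centers = self._default_centers()
        if not self.std_units:
            self.std_units = self._default_std_units()

    def _check_correlation(self) -> None:
        r = self.correlation
        k = len(self.covariates)
        if r.shape != (k, k):
            raise ValueError(
                f"correlation matrix shape {r.shape} does not match {k} covariates"
            )
        if not np.allclose(r, r.T):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")
        try:
            np.linalg.cholesky(r)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "correlation matrix is not positive definite "
                f"(eigenvalues {np.linalg.eigvalsh(r).round(4)})"
            ) from exc

    def _spec(self, name: str) -> CovariateSpec:
        for spec in self.covariates:
            if spec.name == name:
                return spec
        raise KeyError(f"no covariate spec named {name!r}")

    def _default_centers(self) -> dict[str, float]:
        centers = {}
        for spec in self.covariates:
            if spec.family == "lognormal":
                mu, _ = spec.log_params()
                centers["log_" + spec.name] = mu
            else:
                centers[spec.name] = spec.observed_moments()[0]
        return centers

    def _default_std_units(self) -> dict[str, float]:
        units = {}
        for spec in self.covariates:
            if spec.family == "lognormal":
                _, sigma = spec.log_params()
                units["log_" + spec.name] = sigma
            else:
                units[spec.name] = spec.sd
        return units

    # ------------------------------------------------------------------ io

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["correlation"] = self.correlation.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        d["covariates"] = [CovariateSpec(**c) for c in d["covariates"]]
        d["coefficients"] = GeneratingCoefficients(**d["coefficients"])
        d["correlation"] = np.asarray(d["correlation"], dtype=float)
        return cls(**d)

    def save(self, path: str) -> None:
        text = (
            json.dumps(self.to_dict(), indent=2)
            if str(path).endswith(".json")
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


def default_trial_config(n: int = 2640, seed: int = 0) -> SimulationConfig:
    """Trial-like cohort: middle-aged, high-BMI, impaired fasting glucose.

    Marginal moments mirror the derivation trial: age 51 (11) y, FPG
    106 (7) mg/dL, HbA1c 5.78 (0.40) %, BMI 34 (7) kg/m2, triglycerides
    lognormal with median 144 and quartiles (101, 205) mg/dL; 67% female;
    equal allocation over the three arms.  Standardization units follow
    the published per-SD convention (age 10.6 y, BMI 6.6 kg/m2, FPG
    6.7 mg/dL).
    """
    covs = [
        CovariateSpec("age", 51.0, 11.0, lower=10.0, upper=95.0),
        # impaired-fasting-glucose entry window [95, 125] mg/dL; the
        # underlying (102.5, 10) normal yields observed moments ~106 (7)
        CovariateSpec("fpg", 102.5, 10.0, lower=95.0, upper=125.0),
        CovariateSpec("hba1c", 5.78, 0.40, lower=4.0, upper=7.5),
        CovariateSpec("bmi", 34.0, 7.0, lower=10.0, upper=70.0),
        CovariateSpec.lognormal_from_quartiles("triglycerides", 144.0, 101.0, 205.0,
                                               lower=25.0, upper=1500.0),
    ]
    cfg = SimulationConfig(
        n=n,
        allocation={"lifestyle": 1 / 3, "metformin": 1 / 3, "placebo": 1 / 3},
        covariates=covs,
        correlation=default_correlation(),
        coefficients=table_generating_coefficients(),
        seed=seed,
    )
    cfg.std_units.update({"age": 10.6, "bmi": 6.6, "fpg": 6.7})
    return cfg


def default_observational_config(n: int = 2104, seed: int = 0) -> SimulationConfig:
    """Observational cohort: older, leaner, lower fasting glucose, untreated.

    Age 64 (10) y, FPG 101 (10) mg/dL, HbA1c 5.75 (0.30) %, BMI 30 (6)
    kg/m2, triglycerides median 118 quartiles (84, 167) mg/dL; 50% female.
    The linear predictor keeps the *trial* centres and per-SD units so the
    same generating model applies to both populations.
    """
    trial = default_trial_config(seed=seed)
    covs = [
        CovariateSpec("age", 64.0, 10.0, lower=40.0, upper=95.0),
        CovariateSpec("fpg", 101.0, 10.0, lower=60.0, upper=160.0),
        CovariateSpec("hba1c", 5.75, 0.30, lower=4.0, upper=7.5),
        CovariateSpec("bmi", 30.0, 6.0, lower=10.0, upper=70.0),
        CovariateSpec.lognormal_from_quartiles("triglycerides", 118.0, 84.0, 167.0,
                                               lower=25.0, upper=1500.0),
    ]
    return SimulationConfig(
        n=n,
        allocation={"none": 1.0},
        covariates=covs,
        correlation=default_correlation(),
        coefficients=trial.coefficients,
        baseline_hazard=trial.baseline_hazard,
        seed=seed,
        p_female=0.50,
        race_probs={"nh_white": 0.32, "nh_black": 0.27, "hispanic": 0.24, "other": 0.17},
        centers=dict(trial.centers),
        std_units=dict(trial.std_units),
    )


# --------------------------------------------------------------------------
# simulation internals


def _draw_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gaussian-copula draw of the continuous covariates."""
    order = [spec.name for spec in config.covariates]
    chol = np.linalg.cholesky(config.correlation)
    z = rng.standard_normal((config.n, len(order))) @ chol.T
    u = stats.norm.cdf(z)
    cols = {
        spec.name: spec.from_uniform(u[:, j])
        for j, spec in enumerate(config.covariates)
    }
    return pd.DataFrame(cols, columns=order)


def _standardize(config: SimulationConfig, covs: pd.DataFrame, female: np.ndarray
                 ) -> dict[str, np.ndarray]:
    """Per-SD standardized covariate contributions on the generating scale."""
    z: dict[str, np.ndarray] = {}
    for name in ("age", "fpg", "hba1c", "bmi"):
        z[name] = (covs[name].to_numpy() - config.centers[name]) / config.std_units[name]
    log_tg = np.log(covs["triglycerides"].to_numpy())
    z["log_triglycerides"] = (
        (log_tg - config.centers["log_triglycerides"])
        / config.std_units["log_triglycerides"]
    )
    z["female"] = female.astype(float)
    return z


def _linear_predictor(config: SimulationConfig, z: dict[str, np.ndarray],
                      arm: np.ndarray) -> np.ndarray:
    coef = config.coefficients
    lp = (
        coef.shared["hba1c"] * z["hba1c"]
        + coef.shared["log_triglycerides"] * z["log_triglycerides"]
        + coef.shared["female"] * z["female"]
    )
    lp = lp.copy()
    for arm_name in np.unique(arm):
        mask = arm == arm_name
        slopes = coef.slopes(arm_name)
        lp[mask] += coef.main_effect(arm_name)
        for var in INTERACTED:
            lp[mask] += slopes[var] * z[var][mask]
    return lp


def _simulate(config: SimulationConfig, id_prefix: str) -> pd.DataFrame:
    config.coefficients.validate()
    rng = np.random.default_rng(config.seed)

    arms = list(config.allocation)
    probs = np.array([config.allocation[a] for a in arms])
    arm = rng.choice(np.array(arms, dtype=object), size=config.n, p=probs).astype(str)

    covs = _draw_covariates(config, rng)
    female = rng.random(config.n) < config.p_female
    race_labels = list(config.race_probs)
    race = rng.choice(
        np.array(race_labels, dtype=object),
        size=config.n,
        p=np.array([config.race_probs[r] for r in race_labels]),
    ).astype(str)

    z = _standardize(config, covs, female)
    lp = _linear_predictor(config, z, arm)

    # inverse-transform sampling of exponential event times under the PH model
    u = rng.random(config.n)
    event_time = -np.log1p(-u) / (config.baseline_hazard * np.exp(lp))
    event_time = np.maximum(event_time, 1e-12)

    if config.dropout_rate > 0:
        dropout = rng.exponential(1.0 / config.dropout_rate, size=config.n)
    else:
        dropout = np.full(config.n, np.inf)
    censor = np.minimum(dropout, config.admin_censor_years)

    time = np.minimum(event_time, censor)
    event = (event_time <= censor).astype(int)

    cohort = pd.DataFrame(
        {
            "id": [f"{id_prefix}{i + 1:06d}" for i in range(config.n)],
            "age": covs["age"],
            "sex": np.where(female, "female", "male"),
            "race_ethnicity": race,
            "fpg": covs["fpg"],
            "hba1c": covs["hba1c"],
            "bmi": covs["bmi"],
            "triglycerides": covs["triglycerides"],
            "arm": arm,
            "time": time,
            "event": event,
        },
        columns=COHORT_COLUMNS,
    )
    if any(f > 0 for f in config.missingness.values()):
        cohort = inject_missingness(
            cohort, config.missingness, seed=int(rng.integers(2**31 - 1))
        )
    return cohort


def simulate_trial_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a three-arm randomized prevention trial."""
    active = [a for a in TRIAL_ARMS if config.allocation.get(a, 0.0) > 0]
    if len(active) != 3:
        raise ValueError(
            "trial simulation needs positive allocation to lifestyle, metformin "
            f"and placebo; got allocation {config.allocation}"
        )
    if config.allocation.get("none", 0.0) > 0:
        raise ValueError('trial cohorts cannot contain arm "none"')
    return _simulate(config, id_prefix="T")


def simulate_observational_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate an untreated observational cohort (all subjects arm="none").

    Event times follow the placebo (natural-history) coefficient set.
    """
    if not np.isclose(config.allocation.get("none", 0.0), 1.0):
        raise ValueError(
            'observational simulation requires all allocation mass on arm "none"; '
            f"got {config.allocation}"
        )
    return _simulate(config, id_prefix="O")


# --------------------------------------------------------------------------
# calibration


def _marginal_risk_machinery(config: SimulationConfig, m: int):
    """Fixed covariate sample for marginal-risk evaluation (common random numbers)."""
    sample_cfg = config.replace(n=m, missingness={})
    rng = np.random.default_rng([config.seed, 202])
    covs = _draw_covariates(sample_cfg, rng)
    female = rng.random(m) < config.p_female
    z = _standardize(config, covs, female)
    coef = config.coefficients
    base = (
        coef.shared["hba1c"] * z["hba1c"]
        + coef.shared["log_triglycerides"] * z["log_triglycerides"]
        + coef.shared["female"] * z["female"]
    )

    def marginal_risk(h0: float, arm: str, main: float, horizon: float = 3.0) -> float:
        slopes = coef.slopes(arm)
        lp = base + main + sum(slopes[v] * z[v] for v in INTERACTED)
        return float(np.mean(-np.expm1(-h0 * horizon * np.exp(lp))))

    covariate_free = all(
        abs(v) < 1e-300
        for v in (
            list(coef.shared.values())
            + [s for a in TRIAL_ARMS for s in coef.arm_slopes[a].values()]
        )
    )
    return marginal_risk, covariate_free


def calibrate_generating_model(
    target_placebo_risk_3y: float,
    target_reduction_lifestyle: float,
    target_reduction_metformin: float,
    config: SimulationConfig,
    tol: float = 0.005,
    n_marginal: int = 200_000,
) -> SimulationConfig:
    """Set the baseline hazard and arm main effects to hit marginal targets.

    Solves, by bisection on the (Monte-Carlo or closed-form) marginal
    3-year event-time risk, for the constant baseline hazard giving the
    placebo target, then for each active arm's main effect giving the
    requested relative risk reduction.  The marginal risk is the
    population-average event-time CDF at 3 years, i.e. censoring-free
    cumulative incidence.
    """
    if not 0 < target_placebo_risk_3y < 1:
        raise ValueError("target placebo risk must lie in (0, 1)")
    for name, red in (
        ("lifestyle", target_reduction_lifestyle),
        ("metformin", target_reduction_metformin),
    ):
        if not 0 <= red < 1:
            raise ValueError(f"target {name} reduction must lie in [0, 1)")

    config.coefficients.validate()
    marginal_risk, covariate_free = _marginal_risk_machinery(config, n_marginal)

    if covariate_free:
        # analytic inversion of the exponential survival function
        h0 = -np.log1p(-target_placebo_risk_3y) / 3.0
        mains = {}
        for arm, red in (
            ("lifestyle", target_reduction_lifestyle),
            ("metformin", target_reduction_metformin),
        ):
            target = (1 - red) * target_placebo_risk_3y
            mains[arm] = float(np.log(np.log1p(-target) / np.log1p(-target_placebo_risk_3y)))
        h0 = float(h0)
    else:
        def placebo_gap(h0: float) -> float:
            return marginal_risk(h0, "placebo", 0.0) - target_placebo_risk_3y

        bracket = (1e-8, 10.0)
        try:
            h0 = float(optimize.brentq(placebo_gap, *bracket, xtol=1e-12))
        except ValueError as exc:
            raise RuntimeError(
                f"baseline-hazard root finding failed on bracket {bracket}"
            ) from exc

        mains = {}
        for arm, red in (
            ("lifestyle", target_reduction_lifestyle),
            ("metformin", target_reduction_metformin),
        ):
            target = (1 - red) * target_placebo_risk_3y

            def arm_gap(a: float, arm=arm, target=target) -> float:
                return marginal_risk(h0, arm, a) - target

            bracket = (-20.0, 5.0)
            try:
                mains[arm] = float(optimize.brentq(arm_gap, *bracket, xtol=1e-12))
            except ValueError as exc:
                raise RuntimeError(
                    f"main-effect root finding for arm {arm!r} failed on bracket {bracket}"
                ) from exc

    new_coef = GeneratingCoefficients(
        shared=dict(config.coefficients.shared),
        arm_slopes={a: dict(s) for a, s in config.coefficients.arm_slopes.items()},
        arm_main=mains,
    )
    out = config.replace(baseline_hazard=h0, coefficients=new_coef)

    # verify the fixed point within the stated tolerance
    check, _ = _marginal_risk_machinery(out, n_marginal)
    achieved_placebo = check(h0, "placebo", 0.0)
    if abs(achieved_placebo - target_placebo_risk_3y) > tol:
        raise RuntimeError(
            f"calibration did not converge: placebo risk {achieved_placebo:.4f} "
            f"vs target {target_placebo_risk_3y:.4f}"
        )
    return out


def generating_model(config: SimulationConfig):
    """The generating truth packaged as a fitted-model object.

    Gives oracle access to true risks and counterfactuals: coefficients,
    centres, SD units, and the exponential baseline cumulative hazard
    H0(t) = h0*t (on a fine step grid) all come straight from the
    configuration rather than from an estimation step.
    """
    from ipirisk.cox_model import FittedModel, ModelSpec

    config.coefficients.validate()
    spec = ModelSpec()
    cols = spec.columns()
    coef = config.coefficients
    bmap = {
        "hba1c": coef.shared["hba1c"],
        "log_triglycerides": coef.shared["log_triglycerides"],
        "female": coef.shared["female"],
        "arm:lifestyle": coef.main_effect("lifestyle"),
        "arm:metformin": coef.main_effect("metformin"),
    }
    for var in INTERACTED:
        for arm in TRIAL_ARMS:
            bmap[f"{var}:{arm}"] = coef.arm_slopes[arm][var]
    grid = np.arange(0.01, config.admin_censor_years + 0.01, 0.01)
    units = {
        k: config.std_units[k]
        for k in ("age", "fpg", "bmi", "hba1c", "log_triglycerides")
    }
    return FittedModel(
        beta=np.array([bmap[c] for c in cols]),
        cov=np.zeros((len(cols), len(cols))),
        columns=cols,
        centers=dict(config.centers),
        std_units=units,
        baseline_times=grid,
        baseline_h0=config.baseline_hazard * grid,
        spec=spec,
        n=0,
        n_events=0,
        max_time=float(config.admin_censor_years),
        loglik=float("nan"),
        iterations=0,
        grad_norm=0.0,
        converged=True,
    )


# --------------------------------------------------------------------------
# missingness & I/O


def inject_missingness(
    cohort: pd.DataFrame, fractions: dict[str, float], seed: int
) -> pd.DataFrame:
    """Set predictor cells missing completely at random, per-column fraction."""
    forbidden = set(fractions) - set(PREDICTOR_COLUMNS)
    if forbidden:
        raise ValueError(
            f"missingness may only target predictor columns {PREDICTOR_COLUMNS}; "
            f"got {sorted(forbidden)}"
        )
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for col in PREDICTOR_COLUMNS:  # fixed column order keeps the mask seed-stable
        frac = fractions.get(col, 0.0)
        if frac <= 0:
            continue
        mask = rng.random(len(out)) < frac
        if out[col].dtype == object:
            out.loc[mask, col] = None
        else:
            out.loc[mask, col] = np.nan
    return out


def validate_cohort(cohort: pd.DataFrame, allow_none_arm: bool = True) -> None:
    """Check the cohort-table schema invariants; raise ValueError on breach."""
    missing_cols = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort missing required columns: {missing_cols}")
    if cohort["id"].duplicated().any():
        raise ValueError("duplicated subject ids")
    if (cohort["time"] <= 0).any():
        raise ValueError("follow-up times must be > 0")
    if not cohort["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    arms = set(cohort["arm"].dropna().unique())
    allowed = set(ALL_ARMS) if allow_none_arm else set(TRIAL_ARMS)
    if not arms <= allowed:
        raise ValueError(f"unknown arm level(s): {sorted(arms - allowed)}")
    sexes = set(cohort["sex"].dropna().unique())
    if not sexes <= {"male", "female"}:
        raise ValueError(f"unknown sex level(s): {sorted(sexes - {'male', 'female'})}")


def write_cohort_csv(cohort: pd.DataFrame, path: str) -> None:
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS, na_rep="")


def read_cohort_csv(path: str) -> pd.DataFrame:
    cohort = pd.read_csv(
        path,
        dtype={"id": str, "sex": str, "race_ethnicity": str, "arm": str},
    )
    validate_cohort(cohort)
    return cohort
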