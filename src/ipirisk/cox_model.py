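"""Proportional-hazards model with arm-specific covariate effects.

Implements Cox partial-likelihood estimation from scratch (Newton–Raphson
with step-halving, Efron or Breslow tie handling), the Breslow baseline
cumulative hazard, and absolute risk prediction at a time horizon.

The "individualized" specification gives age, fasting glucose and BMI one
slope per intervention arm (the conditional-on-treatment parameterization,
a linear reparameterization of main-effect-plus-interaction coding), plus
shared effects for HbA1c, log-triglycerides and sex, and arm main effects
versus placebo.  The "nonindividualized" variant uses the same main
effects but a single shared slope per covariate.

Continuous predictors are centred at the fitting cohort's means and scaled
per standard deviation, so hazard ratios read as per-SD effects; the
baseline hazard is anchored at the mean covariate profile of a placebo
male subject.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRIAL_ARMS = ("lifestyle", "metformin", "placebo")
INTERACTED = ("age", "fpg", "bmi")
SHARED_CONTINUOUS = ("hba1c", "log_triglycerides")

#: per-SD standardization constants, native units (years, kg/m2, mg/dL, %,
#: and SD of natural-log triglycerides)
DEFAULT_STD_UNITS = {
    "age": 10.6,
    "bmi": 6.6,
    "fpg": 6.7,
    "hba1c": 0.40,
    "log_triglycerides": 0.5247,
}

MODEL_SCHEMA_VERSION = 1


@dataclass
class ModelSpec:
    """Model structure: which effects are arm-specific, and the SD units."""

    individualized: bool = True
    std_units: dict[str, float] | None = field(
        default_factory=lambda: dict(DEFAULT_STD_UNITS)
    )
    horizon: float = 3.0
    ties: str = "efron"

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method {self.ties!r}")
        if self.std_units is not None:
            bad = [k for k, v in self.std_units.items() if v <= 0]
            if bad:
                raise ValueError(f"standardization constants must be > 0: {bad}")

    def columns(self) -> list[str]:
        cols = list(SHARED_CONTINUOUS) + ["female", "arm:lifestyle", "arm:metformin"]
        if self.individualized:
            for var in INTERACTED:
                cols += [f"{var}:{arm}" for arm in TRIAL_ARMS]
        else:
            cols += list(INTERACTED)
        return cols


def _continuous_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Native predictors with triglycerides replaced by their natural log."""
    out = cohort[["age", "fpg", "bmi", "hba1c"]].astype(float).copy()
    out["log_triglycerides"] = np.log(cohort["triglycerides"].astype(float))
    return out


def build_design(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    centers: dict[str, float] | None = None,
    std_units: dict[str, float] | None = None,
    arm: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str], dict[str, float], dict[str, float]]:
    """Design matrix for fitting or prediction.

    Returns ``(X, columns, centers, std_units)``.  When ``centers`` /
    ``std_units`` are omitted they are computed from the cohort (means, and
    — if the spec does not pin SD units — cohort SDs).  ``arm`` overrides
    the cohort's own arm column (used for counterfactual prediction); arm
    "none" is scored on the placebo (no-intervention) hazard.
    """
    cont = _continuous_frame(cohort)
    fitting = centers is None
    if centers is None:
        centers = {c: float(cont[c].mean()) for c in cont.columns}
    if std_units is None:
        if spec.std_units is not None:
            std_units = dict(spec.std_units)
        else:
            std_units = {c: float(cont[c].std(ddof=1)) for c in cont.columns}
    if fitting:
        for c in cont.columns:
            if cont[c].std(ddof=0) == 0:
                raise ValueError(f"zero-variance predictor: {c!r}")

    z = {
        c: (cont[c].to_numpy() - centers[c]) / std_units[c]
        for c in cont.columns
    }

    arm_arr = np.asarray(cohort["arm"] if arm is None else arm, dtype=object)
    known = set(TRIAL_ARMS) | {"none"}
    bad = set(arm_arr) - known
    if bad:
        raise ValueError(f"unknown arm level(s): {sorted(map(str, bad))}")
    # "none" subjects follow the no-intervention (placebo) hazard
    arm_eff = np.where(arm_arr == "none", "placebo", arm_arr).astype(str)

    cols = spec.columns()
    n = len(cohort)
    X = np.zeros((n, len(cols)))
    legend = {name: j for j, name in enumerate(cols)}

    for c in SHARED_CONTINUOUS:
        X[:, legend[c]] = z[c]
    X[:, legend["female"]] = (cohort["sex"].to_numpy() == "female").astype(float)
    X[:, legend["arm:lifestyle"]] = (arm_eff == "lifestyle").astype(float)
    X[:, legend["arm:metformin"]] = (arm_eff == "metformin").astype(float)
    if spec.individualized:
        for var in INTERACTED:
            for a in TRIAL_ARMS:
                X[:, legend[f"{var}:{a}"]] = np.where(arm_eff == a, z[var], 0.0)
    else:
        for var in INTERACTED:
            X[:, legend[var]] = z[var]
    return X, cols, centers, std_units


# --------------------------------------------------------------------------
# partial likelihood


def _prepare(times, events):
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if d.sum() < 1:
        raise ValueError("at least one event is required")
    order = np.argsort(t, kind="stable")
    return t[order], d[order], order


def _loglik_grad_info(beta, X, t, d, ties):
    """Partial log-likelihood, score, and observed information (sorted data)."""
    n, p = X.shape
    lp = X @ beta
    lp = lp - lp.max()  # guard against overflow; cancels in all ratios below
    r = np.exp(lp)
    rX = r[:, None] * X
    rXX = rX[:, :, None] * X[:, None, :]

    S0s = np.cumsum(r[::-1])[::-1]
    S1s = np.cumsum(rX[::-1], axis=0)[::-1]
    S2s = np.cumsum(rXX[::-1], axis=0)[::-1]

    ev = np.flatnonzero(d == 1)
    uts, first_ev = np.unique(t[ev], return_index=True)
    # tie-group sums over the events at each unique event time
    bounds = np.append(first_ev, len(ev))
    dj = np.diff(bounds)
    s = np.add.reduceat(X[ev], bounds[:-1], axis=0)          # sum of x over ties
    T0 = np.add.reduceat(r[ev], bounds[:-1])
    T1 = np.add.reduceat(rX[ev], bounds[:-1], axis=0)
    T2 = np.add.reduceat(rXX[ev], bounds[:-1], axis=0)

    start = np.searchsorted(t, uts, side="left")
    S0 = S0s[start]
    S1 = S1s[start]
    S2 = S2s[start]

    lp_ev_sum = float(np.sum(lp[ev]))  # Σ_events lp  (tie groups together)

    if ties == "breslow":
        ll = lp_ev_sum - float(np.sum(dj * np.log(S0)))
        mu = S1 / S0[:, None]
        g = s.sum(axis=0) - (dj[:, None] * mu).sum(axis=0)
        info = np.einsum("j,jkl->kl", dj / S0, S2) - np.einsum(
            "j,jk,jl->kl", dj.astype(float), mu, mu
        )
        return ll, g, info

    # Efron: for each tie group, average the tied events out of the risk set
    ll = lp_ev_sum
    g = s.sum(axis=0).astype(float)
    info = np.zeros((p, p))
    for j in range(len(uts)):
        m = dj[j]
        frac = np.arange(m) / m
        denom = S0[j] - frac * T0[j]                        # (m,)
        num1 = S1[j][None, :] - frac[:, None] * T1[j][None, :]
        num2 = S2[j][None, :, :] - frac[:, None, None] * T2[j][None, :, :]
        ll -= float(np.sum(np.log(denom)))
        mu = num1 / denom[:, None]
        g -= mu.sum(axis=0)
        info += np.einsum("l,lkm->km", 1.0 / denom, num2) - np.einsum(
            "lk,lm->km", mu, mu
        )
    return ll, g, info


@dataclass
class CoxFit:
    """Raw partial-likelihood fit on a design matrix."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    iterations: int
    grad_norm: float
    converged: bool
    ties: str


def fit_cox(
    design: np.ndarray,
    times,
    events,
    ties: str = "efron",
    columns: list[str] | None = None,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    rel_tol: float = 1e-10,
    beta_bound: float = 50.0,
) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton–Raphson.

    Step-halving enforces monotone likelihood ascent; convergence requires
    the max absolute score below ``grad_tol`` or a relative log-likelihood
    change below ``rel_tol``.  A coefficient path diverging beyond
    ``beta_bound`` with nondecreasing likelihood is flagged as monotone
    likelihood (risk-set separation).
    """
    X = np.asarray(design, dtype=float)
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    t, d, order = _prepare(times, events)
    Xs = X[order]
    p = X.shape[1]
    names = columns if columns is not None else [f"x{j}" for j in range(p)]

    beta = np.zeros(p)
    ll, g, info = _loglik_grad_info(beta, Xs, t, d, ties)
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError as exc:
            sv = np.linalg.svd(info, compute_uv=False)
            bad = [names[j] for j in range(p)] if p else []
            raise ValueError(
                f"singular information matrix (singular values {sv.round(8)}); "
                f"columns: {bad}"
            ) from exc
        # step-halving until the likelihood does not decrease
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, g_new, info_new = _loglik_grad_info(cand, Xs, t, d, ties)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll_prev, ll, g, info = cand, ll, ll_new, g_new, info_new
        if np.max(np.abs(g)) < grad_tol:
            break
        if abs(ll - ll_prev) < rel_tol * (abs(ll_prev) + 1e-12):
            break
        if np.max(np.abs(beta)) > beta_bound and ll >= ll_prev:
            diverging = [names[j] for j in np.flatnonzero(np.abs(beta) > beta_bound)]
            warnings.warn(
                "monotone partial likelihood: coefficient(s) diverging for "
                f"{diverging}",
                stacklevel=2,
            )
            break

    grad_norm = float(np.max(np.abs(g)))
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular information matrix at the solution") from exc
    return CoxFit(
        beta=beta,
        cov=cov,
        loglik=float(ll),
        iterations=it,
        grad_norm=grad_norm,
        converged=grad_norm < grad_tol or it < max_iter,
        ties=ties,
    )


def breslow_baseline(beta: np.ndarray, design: np.ndarray, times, events
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Breslow cumulative baseline hazard at the design's reference profile.

    H0(t) = sum over event times <= t of d_j / sum_{at risk} exp(lp); a
    right-continuous step function returned as (event_times, H0 values).
    """
    X = np.asarray(design, dtype=float)
    t, d, order = _prepare(times, events)
    Xs = X[order]
    r = np.exp(Xs @ beta)
    S0s = np.cumsum(r[::-1])[::-1]
    ev = np.flatnonzero(d == 1)
    uts, first_ev = np.unique(t[ev], return_index=True)
    dj = np.diff(np.append(first_ev, len(ev)))
    start = np.searchsorted(t, uts, side="left")
    increments = dj / S0s[start]
    return uts, np.cumsum(increments)


# --------------------------------------------------------------------------
# fitted-model container


@dataclass
class FittedModel:
    """A fitted risk model, sufficient for standalone prediction."""

    beta: np.ndarray
    cov: np.ndarray
    columns: list[str]
    centers: dict[str, float]
    std_units: dict[str, float]
    baseline_times: np.ndarray
    baseline_h0: np.ndarray
    spec: ModelSpec
    n: int
    n_events: int
    max_time: float
    loglik: float
    iterations: int
    grad_norm: float
    converged: bool

    def h0(self, horizon: float) -> float:
        """Baseline cumulative hazard at the horizon (step-function lookup)."""
        if horizon > self.max_time:
            warnings.warn(
                f"horizon {horizon} beyond last observed time {self.max_time:.3g}; "
                "using the last baseline step",
                stacklevel=2,
            )
        idx = np.searchsorted(self.baseline_times, horizon, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.baseline_h0[idx])

    def linear_predictor(self, cohort: pd.DataFrame, arm=None) -> np.ndarray:
        X, _, _, _ = build_design(
            cohort, self.spec, centers=self.centers, std_units=self.std_units,
            arm=arm if arm is None else np.asarray(arm, dtype=object),
        )
        return X @ self.beta

    def predict_risk_frame(self, cohort: pd.DataFrame, arm=None,
                           horizon: float | None = None) -> np.ndarray:
        """3-year (or other horizon) absolute risk for each row of a cohort."""
        h = self.spec.horizon if horizon is None else horizon
        lp = self.linear_predictor(cohort, arm=arm)
        return -np.expm1(-self.h0(h) * np.exp(lp))

    # ---------------------------------------------------------------- io

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "beta": dict(zip(self.columns, map(float, self.beta))),
            "cov": np.asarray(self.cov).tolist(),
            "columns": list(self.columns),
            "centers": {k: float(v) for k, v in self.centers.items()},
            "std_units": {k: float(v) for k, v in self.std_units.items()},
            "baseline_times": np.asarray(self.baseline_times).tolist(),
            "baseline_h0": np.asarray(self.baseline_h0).tolist(),
            "spec": {
                "individualized": self.spec.individualized,
                "std_units": self.spec.std_units,
                "horizon": self.spec.horizon,
                "ties": self.spec.ties,
            },
            "n": self.n,
            "n_events": self.n_events,
            "max_time": self.max_time,
            "loglik": self.loglik,
            "iterations": self.iterations,
            "grad_norm": self.grad_norm,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {d.get('schema_version')}")
        spec = ModelSpec(**d["spec"])
        cols = list(d["columns"])
        return cls(
            beta=np.array([d["beta"][c] for c in cols]),
            cov=np.asarray(d["cov"], dtype=float),
            columns=cols,
            centers=dict(d["centers"]),
            std_units=dict(d["std_units"]),
            baseline_times=np.asarray(d["baseline_times"], dtype=float),
            baseline_h0=np.asarray(d["baseline_h0"], dtype=float),
            spec=spec,
            n=int(d["n"]),
            n_events=int(d["n_events"]),
            max_time=float(d["max_time"]),
            loglik=float(d["loglik"]),
            iterations=int(d["iterations"]),
            grad_norm=float(d["grad_norm"]),
            converged=bool(d["converged"]),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_model(cohort: pd.DataFrame, spec: ModelSpec | None = None) -> FittedModel:
    """Fit the full risk model (design → partial likelihood → baseline)."""
    if spec is None:
        spec = ModelSpec()
    trial_arms = set(cohort["arm"].unique())
    if not trial_arms <= set(TRIAL_ARMS):
        raise ValueError(
            f"model fitting requires trial arms only; found {sorted(trial_arms)}"
        )
    X, cols, centers, std_units = build_design(cohort, spec)
    times = cohort["time"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=int)
    fit = fit_cox(X, times, events, ties=spec.ties, columns=cols)
    bt, bh = breslow_baseline(fit.beta, X, times, events)
    return FittedModel(
        beta=fit.beta,
        cov=fit.cov,
        columns=cols,
        centers=centers,
        std_units=std_units,
        baseline_times=bt,
        baseline_h0=bh,
        spec=spec,
        n=len(cohort),
        n_events=int(events.sum()),
        max_time=float(times.max()),
        loglik=fit.loglik,
        iterations=fit.iterations,
        grad_norm=fit.grad_norm,
        converged=fit.converged,
    )


def predict_risk(
    fitted: FittedModel,
    subject: pd.Series | dict,
    arm: str,
    horizon: float | None = None,
) -> float:
    """Absolute risk at the horizon for one subject under a chosen arm.

    The arm is counterfactual: it need not match the subject's observed
    arm, and arm "none" is scored on the no-intervention (placebo) hazard.
    """
    row = pd.DataFrame([dict(subject)])
    missing = [c for c in ("age", "sex", "fpg", "hba1c", "bmi", "triglycerides")
               if c not in row.columns or pd.isna(row[c]).any()]
    if missing:
        raise ValueError(f"subject is missing required predictor(s): {missing}")
    return float(
        fitted.predict_risk_frame(row, arm=np.array([arm], dtype=object),
                                  horizon=horizon)[0]
    )


# --------------------------------------------------------------------------
# reporting


_DISPLAY = {
    "hba1c": "Glycated hemoglobin",
    "log_triglycerides": "Triglycerides",
    "female": "Sex: Female",
    "arm:lifestyle": "Arm: Lifestyle (vs placebo)",
    "arm:metformin": "Arm: Metformin (vs placebo)",
    "age": "Age",
    "fpg": "Fasting glucose",
    "bmi": "Body mass index",
}


def _label(col: str) -> str:
    if ":" in col and not col.startswith("arm:"):
        var, arm = col.split(":")
        return f"{_DISPLAY[var]} — {arm}"
    return _DISPLAY.get(col, col)


def hazard_ratio_table(fitted: FittedModel, z: float = 1.96) -> pd.DataFrame:
    """Per-SD hazard ratios with Wald 95% CIs, plus reference rows."""
    se = np.sqrt(np.diag(fitted.cov))
    rows = []
    for j, col in enumerate(fitted.columns):
        b = fitted.beta[j]
        rows.append(
            {
                "term": col,
                "label": _label(col),
                "hr": float(np.exp(b)),
                "ci_lower": float(np.exp(b - z * se[j])),
                "ci_upper": float(np.exp(b + z * se[j])),
                "coef": float(b),
                "se": float(se[j]),
            }
        )
    rows.append(
        {
            "term": "male",
            "label": "Sex: Male",
            "hr": 1.0,
            "ci_lower": np.nan,
            "ci_upper": np.nan,
            "coef": 0.0,
            "se": np.nan,
        }
    )
    return pd.DataFrame(rows)


def format_hr_table(table: pd.DataFrame) -> str:
    """Human-readable hazard-ratio listing: 'HR (lo, hi)' per row."""
    lines = []
    for _, r in table.iterrows():
        if r["term"] == "male":
            lines.append(f"{r['label']:<40s} 1.00 (reference)")
        else:
            lines.append(
                f"{r['label']:<40s} {r['hr']:.2f} ({r['ci_lower']:.2f}, {r['ci_upper']:.2f})"
            )
    return "\n".join(lines)
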