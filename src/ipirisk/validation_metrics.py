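"""Validation of 3-year risk predictions under right censoring.

Binary classification metrics at a fixed horizon require a policy for
subjects censored before the horizon.  The default is inverse probability
of censoring weighting (IPCW): subjects with an event by the horizon get
weight 1/G(T-), subjects still under observation at the horizon get
weight 1/G(horizon-), and subjects censored earlier get weight 0, where G
is the Kaplan-Meier estimate of the censoring distribution.  A simple
"exclude" scheme (drop censored-before-horizon subjects, unit weights) is
available for sensitivity analysis; the two agree exactly when no
censoring occurs before the horizon.

Metrics: time-horizon concordance, decile calibration against
Kaplan-Meier observed risk with Greenwood intervals, categorical net
reclassification improvement with full reclassification matrices,
decision-curve net benefit (true-positive rate minus false-positive rate
times the odds of the threshold, both rates per subject screened),
equal-opportunity / equalized-odds fairness gaps, Brier score and index
of prediction accuracy, plus stratified k-fold cross-validation and an
individualized-vs-nonindividualized model comparison driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ipirisk.cox_model import FittedModel, ModelSpec, fit_model
from ipirisk.gower_impute import GowerSpace, impute_knn

# --------------------------------------------------------------------------
# Kaplan-Meier machinery


def kaplan_meier(times, events) -> pd.DataFrame:
    """Kaplan-Meier estimate with Greenwood variance.

    Returns one row per unique event time: time, n at risk, events,
    survival, and Greenwood variance of survival.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    ev = np.flatnonzero(d == 1)
    uts, first = np.unique(t[ev], return_index=True)
    dj = np.diff(np.append(first, len(ev)))
    n_at_risk = len(t) - np.searchsorted(t, uts, side="left")
    frac = 1.0 - dj / n_at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = dj / (n_at_risk * (n_at_risk - dj))
    gw_terms = np.where(np.isfinite(gw_terms), gw_terms, 0.0)
    var = surv**2 * np.cumsum(gw_terms)
    return pd.DataFrame(
        {"time": uts, "n_at_risk": n_at_risk, "events": dj,
         "survival": surv, "greenwood_var": var}
    )


def km_survival_at(km: pd.DataFrame, horizon: float) -> float:
    """Step-function lookup of S(horizon); 1.0 before the first event."""
    idx = np.searchsorted(km["time"].to_numpy(), horizon, side="right") - 1
    return 1.0 if idx < 0 else float(km["survival"].iloc[idx])


def _censoring_survival(times, events):
    """KM of the censoring distribution, evaluable just before t (left limits)."""
    t = np.asarray(times, dtype=float)
    c = 1 - np.asarray(events, dtype=int)  # censoring indicator
    km = kaplan_meier(t, c)
    ct = km["time"].to_numpy()
    cs = km["survival"].to_numpy()

    def g_minus(x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if len(ct) == 0:  # no censoring at all
            return np.ones(len(x))
        idx = np.searchsorted(ct, x, side="left") - 1
        return np.where(idx < 0, 1.0, cs[np.clip(idx, 0, len(cs) - 1)])

    return g_minus


# --------------------------------------------------------------------------
# horizon labels


@dataclass
class HorizonLabels:
    """Binary status at the horizon plus censoring weights.

    ``label`` is 1 for event-by-horizon, 0 for event-free-at-horizon
    (including subjects censored at exactly the horizon), and 0 with zero
    weight for subjects censored earlier.  ``n_effective`` is the
    denominator for per-subject-screened rates (all subjects for IPCW,
    retained subjects for the exclude scheme).
    """

    label: np.ndarray
    weight: np.ndarray
    included: np.ndarray
    horizon: float
    scheme: str
    n_excluded: int
    n_effective: int
    notes: list[str] = field(default_factory=list)

    def prevalence(self) -> float:
        return float(np.sum(self.weight * self.label) / self.n_effective)


def horizon_labels(times, events, horizon: float, scheme: str = "ipcw") -> HorizonLabels:
    """Classify subjects at the horizon and compute censoring weights."""
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if scheme not in ("ipcw", "exclude"):
        raise ValueError(f"unknown censoring scheme {scheme!r}")
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    n = len(t)

    is_event = (t <= horizon) & (d == 1)
    at_horizon = t >= horizon  # censored exactly at the horizon counts event-free
    excluded = ~is_event & ~at_horizon

    label = is_event.astype(float)
    included = ~excluded

    notes: list[str] = []
    if scheme == "exclude":
        weight = included.astype(float)
        n_eff = int(included.sum())
    else:
        g_minus = _censoring_survival(t, d)
        eval_at = np.where(is_event, t, horizon)  # G(T-) for events, G(h-) otherwise
        g = g_minus(eval_at)
        with np.errstate(divide="ignore"):
            weight = np.where(g > 0, 1.0 / g, 0.0)
        weight = np.where(included, weight, 0.0)
        zero_g = int(np.sum(included & (g <= 0)))
        if zero_g:
            notes.append(f"{zero_g} subject(s) had zero censoring survival; excluded")
        included = included & (weight > 0)
        n_eff = n
    return HorizonLabels(
        label=label,
        weight=weight,
        included=included,
        horizon=float(horizon),
        scheme=scheme,
        n_excluded=int((~included).sum()),
        n_effective=n_eff,
        notes=notes,
    )


# --------------------------------------------------------------------------
# discrimination


def _concordance_value(risks, label, weight) -> float:
    cases = label == 1
    w_case = weight[cases]
    w_ctrl = weight[~cases]
    r_case = risks[cases]
    r_ctrl = risks[~cases]
    if w_case.sum() == 0 or w_ctrl.sum() == 0:
        return float("nan")
    order = np.argsort(r_ctrl, kind="stable")
    r_ctrl_s = r_ctrl[order]
    cumw = np.concatenate([[0.0], np.cumsum(w_ctrl[order])])
    lo = cumw[np.searchsorted(r_ctrl_s, r_case, side="left")]
    hi = cumw[np.searchsorted(r_ctrl_s, r_case, side="right")]
    num = float(np.sum(w_case * (lo + 0.5 * (hi - lo))))
    denom = float(w_case.sum() * w_ctrl.sum())
    return num / denom


def concordance(
    risks,
    labels: HorizonLabels,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Weighted time-horizon C-statistic with a percentile bootstrap CI.

    The probability a case carries a higher predicted risk than a noncase
    (ties count one half), weighting case-noncase pairs by the product of
    their censoring weights.
    """
    r = np.asarray(risks, dtype=float)
    mask = labels.included
    value = _concordance_value(r[mask], labels.label[mask], labels.weight[mask])
    if np.isnan(value):
        return {"c": float("nan"), "ci": (float("nan"), float("nan")),
                "note": "undefined: needs at least one case and one noncase"}
    ci = (float("nan"), float("nan"))
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        idx_all = np.flatnonzero(mask)
        stats = np.empty(n_boot)
        for b in range(n_boot):
            take = rng.choice(idx_all, size=len(idx_all), replace=True)
            stats[b] = _concordance_value(r[take], labels.label[take], labels.weight[take])
        stats = stats[~np.isnan(stats)]
        if len(stats):
            ci = (float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5)))
    return {"c": float(value), "ci": ci}


# --------------------------------------------------------------------------
# calibration


def calibration_by_decile(risks, times, events, horizon: float, n_bins: int = 10
                          ) -> pd.DataFrame:
    """Observed (Kaplan-Meier) vs mean predicted risk within decile bins.

    Bin edges are the interior quantiles of the predicted risks; a
    prediction equal to an edge falls in the lower bin.  Observed risk is
    1 - KM survival at the horizon within the bin, with a Greenwood
    normal-approximation interval.
    """
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if len(r) < 20:
        raise ValueError("calibration requires at least 20 subjects")
    edges = np.quantile(r, np.arange(1, n_bins) / n_bins)
    bins = np.searchsorted(edges, r, side="left")
    rows = []
    for b in range(n_bins):
        mask = bins == b
        if mask.sum() == 0:
            continue
        km = kaplan_meier(t[mask], d[mask])
        flagged = False
        h_eval = horizon
        at_risk_at_h = np.sum(t[mask] >= horizon)
        if at_risk_at_h == 0 and len(km) > 0:
            h_eval = float(km["time"].max())
            flagged = True
        surv = km_survival_at(km, h_eval)
        idx = np.searchsorted(km["time"].to_numpy(), h_eval, side="right") - 1
        var = float(km["greenwood_var"].iloc[idx]) if idx >= 0 else 0.0
        se = np.sqrt(var)
        rows.append(
            {
                "bin": b,
                "n": int(mask.sum()),
                "mean_predicted": float(r[mask].mean()),
                "observed": 1.0 - surv,
                "observed_se": se,
                "ci_lower": max(0.0, 1.0 - surv - 1.96 * se),
                "ci_upper": min(1.0, 1.0 - surv + 1.96 * se),
                "truncated_at": h_eval if flagged else np.nan,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# net benefit


def net_benefit(risks, labels: HorizonLabels, threshold: float) -> dict:
    """Decision-curve net benefit at a threshold probability.

    NB = TPR - FPR * odds(threshold), with TPR and FPR per subject
    screened, so 100*NB reads as net true positives per 100 screened.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    r = np.asarray(risks, dtype=float)
    w = labels.weight
    y = labels.label
    n = labels.n_effective
    odds = threshold / (1.0 - threshold)
    cls = (r >= threshold).astype(float)
    tpr = float(np.sum(w * y * cls) / n)
    fpr = float(np.sum(w * (1 - y) * cls) / n)
    prevalence = float(np.sum(w * y) / n)
    nb = tpr - fpr * odds
    nb_all = prevalence - (1 - prevalence) * odds
    return {
        "threshold": threshold,
        "net_benefit": nb,
        "tpr": tpr,
        "fpr": fpr,
        "treat_all": nb_all,
        "treat_none": 0.0,
        "prevalence": prevalence,
    }


def net_benefit_curve(risks, labels: HorizonLabels,
                      thresholds=None) -> pd.DataFrame:
    if thresholds is None:
        thresholds = np.arange(0.01, 0.501, 0.01)
    return pd.DataFrame([net_benefit(risks, labels, float(t)) for t in thresholds])


# --------------------------------------------------------------------------
# net reclassification improvement


def _categorize(r: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    return np.searchsorted(cuts, r, side="right")


def _nri_components(new_cat, old_cat, label, weight):
    up = (new_cat > old_cat).astype(float)
    down = (new_cat < old_cat).astype(float)
    w_case = weight * label
    w_ctrl = weight * (1 - label)
    sc, sn = w_case.sum(), w_ctrl.sum()
    if sc == 0 or sn == 0:
        return float("nan"), float("nan")
    ev = float(np.sum(w_case * up) - np.sum(w_case * down)) / sc
    ne = float(np.sum(w_ctrl * down) - np.sum(w_ctrl * up)) / sn
    return ev, ne


def nri(
    risks_new,
    risks_old,
    labels: HorizonLabels,
    categories=(0.10, 0.20),
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Categorical net reclassification improvement, new vs standard model.

    Event NRI = P(up|case) - P(down|case); nonevent NRI = P(down|noncase)
    - P(up|noncase); overall is their sum.  Reclassification matrices
    (weighted counts, old category x new category) are returned separately
    for cases and noncases.
    """
    cuts = np.asarray(categories, dtype=float)
    if len(cuts) == 0:
        raise ValueError("categories must be nonempty")
    if not (np.all(np.diff(cuts) > 0) and np.all((cuts > 0) & (cuts < 1))):
        raise ValueError("categories must be strictly increasing within (0, 1)")
    rn = np.asarray(risks_new, dtype=float)
    ro = np.asarray(risks_old, dtype=float)
    if rn.shape != ro.shape:
        raise ValueError("both models must score the same subjects")
    new_cat = _categorize(rn, cuts)
    old_cat = _categorize(ro, cuts)
    w = labels.weight
    y = labels.label

    ev, ne = _nri_components(new_cat, old_cat, y, w)
    overall = ev + ne

    k = len(cuts) + 1
    mat_events = np.zeros((k, k))
    mat_nonevents = np.zeros((k, k))
    np.add.at(mat_events, (old_cat, new_cat), w * y)
    np.add.at(mat_nonevents, (old_cat, new_cat), w * (1 - y))
    cat_labels = (
        [f"<{cuts[0]:g}"]
        + [f"[{a:g},{b:g})" for a, b in zip(cuts[:-1], cuts[1:])]
        + [f">={cuts[-1]:g}"]
    )

    ci = (float("nan"), float("nan"))
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        idx_all = np.arange(len(rn))
        stats = np.empty(n_boot)
        for b in range(n_boot):
            take = rng.choice(idx_all, size=len(idx_all), replace=True)
            e_b, n_b = _nri_components(new_cat[take], old_cat[take], y[take], w[take])
            stats[b] = e_b + n_b
        stats = stats[~np.isnan(stats)]
        if len(stats):
            ci = (float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5)))

    def as_frame(m):
        return pd.DataFrame(m, index=pd.Index(cat_labels, name="old"),
                            columns=pd.Index(cat_labels, name="new"))

    return {
        "event_nri": ev,
        "nonevent_nri": ne,
        "overall_nri": overall,
        "ci": ci,
        "matrix_events": as_frame(mat_events),
        "matrix_nonevents": as_frame(mat_nonevents),
        "categories": tuple(map(float, cuts)),
    }


# --------------------------------------------------------------------------
# fairness


def fairness_metrics(risks, labels: HorizonLabels, groups, threshold: float = 0.20
                     ) -> dict:
    """Equal-opportunity and equalized-odds gaps across subgroups.

    Per-group TPR (among cases) and FPR (among noncases) at the decision
    threshold; equal-opportunity gap is the largest pairwise TPR
    difference, equalized odds additionally considers FPR differences.
    Groups without cases (or noncases) are excluded from the respective
    gap and flagged.
    """
    r = np.asarray(risks, dtype=float)
    g = np.asarray(groups)
    w = labels.weight
    y = labels.label
    cls = (r >= threshold).astype(float)
    per_group = {}
    flags = []
    for grp in pd.unique(g):
        mask = g == grp
        wc = w[mask] * y[mask]
        wn = w[mask] * (1 - y[mask])
        tpr = float(np.sum(wc * cls[mask]) / wc.sum()) if wc.sum() > 0 else float("nan")
        fpr = float(np.sum(wn * cls[mask]) / wn.sum()) if wn.sum() > 0 else float("nan")
        if np.isnan(tpr):
            flags.append(f"group {grp!r} has no cases: TPR undefined")
        if np.isnan(fpr):
            flags.append(f"group {grp!r} has no noncases: FPR undefined")
        per_group[grp] = {"tpr": tpr, "fpr": fpr, "n": int(mask.sum())}
    tprs = [v["tpr"] for v in per_group.values() if not np.isnan(v["tpr"])]
    fprs = [v["fpr"] for v in per_group.values() if not np.isnan(v["fpr"])]
    gap_tpr = max(tprs) - min(tprs) if len(tprs) >= 2 else 0.0
    gap_fpr = max(fprs) - min(fprs) if len(fprs) >= 2 else 0.0
    return {
        "threshold": threshold,
        "per_group": per_group,
        "equal_opportunity_gap": gap_tpr,
        "equalized_odds_gap": max(gap_tpr, gap_fpr),
        "flags": flags,
    }


# --------------------------------------------------------------------------
# Brier / IPA


def brier_ipa(risks, labels: HorizonLabels) -> dict:
    """Weighted Brier score and index of prediction accuracy.

    IPA = 1 - Brier(model)/Brier(null), the null model predicting the
    weighted prevalence for everyone.
    """
    r = np.asarray(risks, dtype=float)
    if len(r) == 0:
        raise ValueError("empty input")
    w = labels.weight
    y = labels.label
    n = labels.n_effective
    brier = float(np.sum(w * (y - r) ** 2) / n)
    prev = labels.prevalence()
    if prev <= 0:
        return {"brier": brier, "ipa": float("nan"),
                "note": "IPA undefined: zero prevalence"}
    brier_null = float(np.sum(w * (y - prev) ** 2) / n)
    return {"brier": brier, "ipa": 1.0 - brier / brier_null}


# --------------------------------------------------------------------------
# report assembly


def validation_report(
    risks,
    cohort: pd.DataFrame,
    horizon: float = 3.0,
    scheme: str = "ipcw",
    threshold: float = 0.20,
    seed: int = 0,
    n_boot: int = 1000,
    nb_thresholds=None,
) -> dict:
    """All single-model metrics for one cohort's predicted risks."""
    t = cohort["time"].to_numpy(dtype=float)
    d = cohort["event"].to_numpy(dtype=int)
    labels = horizon_labels(t, d, horizon, scheme=scheme)
    report = {
        "n": len(cohort),
        "horizon": horizon,
        "scheme": scheme,
        "prevalence": labels.prevalence(),
        "c_statistic": concordance(risks, labels, n_boot=n_boot, seed=seed),
        "calibration": calibration_by_decile(risks, t, d, horizon),
        "net_benefit": net_benefit(risks, labels, threshold),
        "net_benefit_curve": net_benefit_curve(risks, labels, nb_thresholds),
        "brier_ipa": brier_ipa(risks, labels),
    }
    for grouping in ("race_ethnicity", "sex"):
        if grouping in cohort.columns:
            report[f"fairness_{grouping}"] = fairness_metrics(
                risks, labels, cohort[grouping].to_numpy(), threshold
            )
            report[f"c_by_{grouping}"] = {
                str(grp): concordance(
                    np.asarray(risks)[cohort[grouping].to_numpy() == grp],
                    horizon_labels(
                        t[cohort[grouping].to_numpy() == grp],
                        d[cohort[grouping].to_numpy() == grp],
                        horizon, scheme=scheme,
                    ),
                    n_boot=0,
                )["c"]
                for grp in pd.unique(cohort[grouping])
            }
    return report


# --------------------------------------------------------------------------
# cross-validation and model comparison


def _stratified_folds(events: np.ndarray, k: int, rng: np.random.Generator
                      ) -> np.ndarray:
    """Fold ids, event-stratified, sizes differing by at most one."""
    n = len(events)
    order = np.concatenate(
        [rng.permutation(np.flatnonzero(events == 1)),
         rng.permutation(np.flatnonzero(events == 0))]
    )
    fold = np.empty(n, dtype=int)
    fold[order] = np.arange(n) % k
    return fold


def _fit_with_imputation(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[FittedModel, pd.DataFrame]:
    complete = impute_knn(cohort)
    return fit_model(complete, spec), complete


def crossvalidate(
    cohort: pd.DataFrame,
    spec: ModelSpec | None = None,
    k: int = 10,
    seed: int = 0,
    horizon: float = 3.0,
    threshold: float = 0.20,
    n_boot: int = 200,
) -> tuple[np.ndarray, dict]:
    """Stratified k-fold cross-validation with in-fold imputation.

    Imputation and model fitting happen inside each training fold; the
    held-out fold is imputed against training donors only, scored, and
    the pooled out-of-fold risks feed a single validation report.
    Returns ``(out_of_fold_risks, report)``.
    """
    if spec is None:
        spec = ModelSpec()
    if k < 2:
        raise ValueError("k must be >= 2")
    events = cohort["event"].to_numpy(dtype=int)
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(events, k, rng)
    per_fold_events = [events[fold == f].sum() for f in range(k)]
    if min(per_fold_events) < 1:  # one reshuffle retry
        fold = _stratified_folds(events, k, rng)
        per_fold_events = [events[fold == f].sum() for f in range(k)]
        if min(per_fold_events) < 1:
            raise ValueError("a cross-validation fold contains no events")

    oof = np.full(len(cohort), np.nan)
    fold_c = []
    base = cohort.reset_index(drop=True)
    for f in range(k):
        test_mask = fold == f
        train = base.loc[~test_mask]
        test = base.loc[test_mask]
        train_complete = impute_knn(train)
        fitted = fit_model(train_complete, spec)
        test_complete = impute_knn(test, reference=train)
        risks_f = fitted.predict_risk_frame(test_complete, horizon=horizon)
        oof[test_mask] = risks_f
        lab_f = horizon_labels(
            test["time"].to_numpy(float), test["event"].to_numpy(int), horizon
        )
        fold_c.append(_concordance_value(risks_f, lab_f.label, lab_f.weight))

    report = validation_report(
        oof, base, horizon=horizon, threshold=threshold, seed=seed, n_boot=n_boot
    )
    report["fold_c_statistics"] = fold_c
    report["mean_fold_c"] = float(np.nanmean(fold_c))
    report["fold_sizes"] = [int(np.sum(fold == f)) for f in range(k)]
    return oof, report


def compare_models(
    cohort_dev: pd.DataFrame,
    cohort_val: pd.DataFrame | None = None,
    seed: int = 0,
    k: int = 10,
    horizon: float = 3.0,
    threshold: float = 0.20,
    categories=(0.10, 0.20),
    n_boot: int = 200,
) -> dict:
    """Individualized vs nonindividualized model comparison.

    Fits both specifications on the development cohort, cross-validates
    internally, optionally validates externally, and computes the NRI of
    the individualized ("new") model against the nonindividualized
    ("standard") one.  Subgroup discrimination by race/ethnicity and sex
    is part of each validation report.
    """
    spec_ind = ModelSpec(individualized=True, horizon=horizon)
    spec_std = ModelSpec(individualized=False, horizon=horizon)

    out: dict = {"models": {}}
    oof: dict[str, np.ndarray] = {}
    for name, spec in (("individualized", spec_ind), ("nonindividualized", spec_std)):
        fitted, dev_complete = _fit_with_imputation(cohort_dev, spec)
        oof_risks, internal = crossvalidate(
            cohort_dev, spec, k=k, seed=seed, horizon=horizon,
            threshold=threshold, n_boot=n_boot,
        )
        oof[name] = oof_risks
        entry = {"fitted": fitted, "internal": internal}
        if cohort_val is not None:
            val_complete = impute_knn(cohort_val, reference=cohort_dev)
            val_risks = fitted.predict_risk_frame(val_complete, horizon=horizon)
            entry["external"] = validation_report(
                val_risks, cohort_val, horizon=horizon, threshold=threshold,
                seed=seed, n_boot=n_boot,
            )
            entry["external_risks"] = val_risks
        out["models"][name] = entry

    dev_labels = horizon_labels(
        cohort_dev["time"].to_numpy(float), cohort_dev["event"].to_numpy(int), horizon
    )
    out["nri_internal"] = nri(
        oof["individualized"], oof["nonindividualized"], dev_labels,
        categories=categories, n_boot=n_boot, seed=seed,
    )
    if cohort_val is not None:
        val_labels = horizon_labels(
            cohort_val["time"].to_numpy(float), cohort_val["event"].to_numpy(int),
            horizon,
        )
        out["nri_external"] = nri(
            out["models"]["individualized"]["external_risks"],
            out["models"]["nonindividualized"]["external_risks"],
            val_labels, categories=categories, n_boot=n_boot, seed=seed,
        )
    return out
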