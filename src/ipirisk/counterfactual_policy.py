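"""Counterfactual risk, optimal-strategy assignment, and policy NNT.

For every subject the fitted model predicts 3-year diabetes risk under
each of the three intervention scenarios — lifestyle, metformin, and no
intervention (placebo) — holding covariates fixed.  The optimal strategy
is the scenario with the lowest predicted risk (ties favour lifestyle,
the guideline first-line option, then metformin).  Treatment policies
(treat everyone with lifestyle, treat everyone with metformin, treat per
the model's optimal strategy) are compared by the number needed to treat,
computed from mean predicted counterfactual risks so all policies are
evaluable on the same footing regardless of observed assignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ipirisk.cox_model import FittedModel

ARM_ORDER = ("lifestyle", "metformin", "placebo")  # tie-break priority


def counterfactual_risks(fitted: FittedModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject risk under each arm and the optimal (lowest-risk) arm.

    Pure covariate function: the subject's observed arm is ignored.
    """
    n = len(cohort)
    out = pd.DataFrame(index=cohort.index)
    out["id"] = cohort["id"].to_numpy()
    for arm in ARM_ORDER:
        out[f"risk_{arm}"] = fitted.predict_risk_frame(
            cohort, arm=np.full(n, arm, dtype=object)
        )
    risks = out[[f"risk_{a}" for a in ARM_ORDER]].to_numpy()
    # argmin returns the first minimum, and ARM_ORDER places lifestyle first
    out["optimal_arm"] = np.array(ARM_ORDER, dtype=object)[np.argmin(risks, axis=1)]
    return out


def summarize_by_optimal(risks: pd.DataFrame) -> pd.DataFrame:
    """Optimal-strategy strata with mean (SD) counterfactual risk per arm.

    One row per optimal arm present in the sample: count, percent of
    sample, and mean/SD predicted risk under lifestyle, metformin, and
    placebo (percent scale).
    """
    if len(risks) == 0:
        raise ValueError("empty counterfactual risk table")
    rows = []
    n = len(risks)
    for arm in ARM_ORDER:
        stratum = risks[risks["optimal_arm"] == arm]
        if len(stratum) == 0:
            continue
        row = {"optimal_arm": arm, "n": len(stratum),
               "pct_sample": 100.0 * len(stratum) / n}
        for a in ARM_ORDER:
            vals = 100.0 * stratum[f"risk_{a}"]
            row[f"mean_risk_{a}"] = float(vals.mean())
            row[f"sd_risk_{a}"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_policies(risks: pd.DataFrame) -> pd.DataFrame:
    """NNT to prevent one case over the horizon, for three policies.

    ARR = mean(risk under no intervention) − mean(risk under the policy's
    assignment); NNT = 1/ARR, reported as NaN (undefined) when ARR <= 0.
    """
    if len(risks) == 0:
        raise ValueError("empty counterfactual risk table")
    placebo_mean = float(risks["risk_placebo"].mean())
    assigned = {
        "all-lifestyle": risks["risk_lifestyle"].to_numpy(),
        "all-metformin": risks["risk_metformin"].to_numpy(),
        "model-guided": np.min(
            risks[[f"risk_{a}" for a in ARM_ORDER]].to_numpy(), axis=1
        ),
    }
    shares = risks["optimal_arm"].value_counts(normalize=True)
    rows = []
    for policy, r in assigned.items():
        mean_r = float(np.mean(r))
        arr = placebo_mean - mean_r
        rows.append(
            {
                "policy": policy,
                "mean_assigned_risk": mean_r,
                "mean_placebo_risk": placebo_mean,
                "arr": arr,
                "nnt": 1.0 / arr if arr > 0 else float("nan"),
                "share_optimal_lifestyle": float(shares.get("lifestyle", 0.0)),
                "share_optimal_metformin": float(shares.get("metformin", 0.0)),
                "share_optimal_placebo": float(shares.get("placebo", 0.0)),
            }
        )
    return pd.DataFrame(rows)
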