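"""Replication experiments on the default synthetic generators.

Each function regenerates its inputs from scratch (phantoms or
cohorts), runs the method under study, and returns the summary
statistic: pooled held-out detection metrics, cohort ICS distribution
summaries, 6-year POCE cumulative incidences, recovered hazard ratios,
and the recovered multivariate age coefficient for sqrt(ICS).  All are
deterministic given ``seed_start`` (replicate r uses seed
``seed_start + r``).
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from .cohort import CohortConfig, generate_cohort, generate_covariates, generate_ics
from .detect import (DetectionMetrics, TrainingConfig, evaluate_detection,
                     extract_features, metrics_from_confusion, predict_mask,
                     train_detector)
from .phantom import BurdenModel, PhantomConfig, simulate_pullback
from .survival import (DEFAULT_ADJUSTMENT, SQRT_ICS_CANDIDATES,
                       build_multivariate, cox_fit, poce_cumulative_incidence)


def detection_benchmark(n_train: int = 20, n_test: int = 10,
                        seed_start: int = 1,
                        config: Optional[TrainingConfig] = None) -> DetectionMetrics:
    """Train on ``n_train`` default phantoms, evaluate per A-line on
    ``n_test`` held-out ones; returns pooled confusion metrics."""
    geom, burden = PhantomConfig(), BurdenModel()
    feats, labels = [], []
    for s in range(seed_start, seed_start + n_train):
        pb, mask, _ = simulate_pullback(geom, burden, s)
        feats.append(extract_features(pb))
        labels.append(mask.mask.ravel())
    model = train_detector(pd.concat(feats, ignore_index=True),
                           np.concatenate(labels), config, seed=seed_start)
    tp = fp = tn = fn = 0
    for s in range(seed_start + n_train, seed_start + n_train + n_test):
        pb, mask, _ = simulate_pullback(geom, burden, s)
        m = evaluate_detection(predict_mask(model, pb), mask)
        tp, fp, tn, fn = tp + m.tp, fp + m.fp, tn + m.tn, fn + m.fn
    return metrics_from_confusion(tp, fp, tn, fn)


def ics_distribution_benchmark(n_cohorts: int = 50,
                               seed_start: int = 1) -> Dict[str, float]:
    """Median over cohorts of the per-cohort median ICS and sqrt(ICS)."""
    meds, smeds = [], []
    for s in range(seed_start, seed_start + n_cohorts):
        cfg = CohortConfig(seed=s)
        df = generate_ics(generate_covariates(cfg), cfg)
        meds.append(float(np.median(df["ics"])))
        smeds.append(float(np.median(df["sqrt_ics"])))
    return {"median_ics": float(np.median(meds)),
            "median_sqrt_ics": float(np.median(smeds))}


def incidence_benchmark(n_cohorts: int = 200,
                        seed_start: int = 1) -> Dict[str, float]:
    """Mean 6-year POCE cumulative incidence (%) over threshold-scenario
    cohorts: overall and within the ICS >= 85 group."""
    overall, high = [], []
    for s in range(seed_start, seed_start + n_cohorts):
        cohort, events = generate_cohort(CohortConfig(seed=s))
        overall.append(poce_cumulative_incidence(events))
        sel = (cohort["ics"] >= 85).to_numpy()
        high.append(poce_cumulative_incidence(events[sel]))
    return {"overall_pct": 100.0 * float(np.mean(overall)),
            "high_group_pct": 100.0 * float(np.mean(high))}


def effect_recovery_benchmark(scenario: str, n_cohorts: int = 200,
                              seed_start: int = 1) -> float:
    """Geometric-mean fitted POCE hazard ratio over replicate cohorts.

    Threshold scenario: ICS >= 85 group indicator, diabetes-stratified
    baseline.  Continuous scenario: ICS per 100 units.  Both adjusted
    with the default covariate set.
    """
    exposure = "group_high" if scenario == "threshold" else "ics_per100"
    log_hrs = []
    for s in range(seed_start, seed_start + n_cohorts):
        cohort, events = generate_cohort(CohortConfig(seed=s, scenario=scenario))
        cov = cohort[["id"] + list(DEFAULT_ADJUSTMENT)].copy()
        if scenario == "threshold":
            cov["group_high"] = (cohort["ics"] >= 85).astype(float)
            fit = cox_fit(events, cov, strata="diabetes")
        else:
            cov["ics_per100"] = cohort["ics"] / 100.0
            fit = cox_fit(events, cov)
        log_hrs.append(float(fit.coefficients[exposure]))
    return float(np.exp(np.mean(log_hrs)))


def age_coefficient_benchmark(n_cohorts: int = 200,
                              seed_start: int = 1) -> Dict[str, float]:
    """Mean multivariate age coefficient for sqrt(ICS) across replicates
    where age passes the p < 0.1 univariate screen."""
    coefs = []
    for s in range(seed_start, seed_start + n_cohorts):
        cfg = CohortConfig(seed=s)
        df = generate_ics(generate_covariates(cfg), cfg)
        df["vessel_lad"] = (df["study_vessel"] == "LAD").astype(float)
        cand = df[list(SQRT_ICS_CANDIDATES)].astype(float)
        res = build_multivariate(df["sqrt_ics"].to_numpy(), cand)
        if "age" in res.fit.coefficients.index:
            coefs.append(float(res.fit.coefficients["age"]))
    return {"mean_age_coef": float(np.mean(coefs)),
            "n_selected": len(coefs), "n_cohorts": n_cohorts}
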