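"""Train/validation split construction, prediction intervals and power.

A replication attempt of an effect estimated with sampling error is not
expected to reproduce the point estimate: the 95% prediction interval
quantifies the range a replication of given size should fall in if the
underlying effect is identical. Correlations use the Fisher-z variance
``1/(n-3)`` per study; standardized mean differences use the usual
large-sample variance of d. Power helpers cover the analytic two-sample
t test and simulation through the full mixed-model pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import SubjectMeta, age_group

__all__ = ["SplitAssignment", "PredictionInterval", "stratified_split",
           "prediction_interval_r", "prediction_interval_d",
           "power_twosample", "power_lme_sim"]


@dataclass
class SplitAssignment:
    assignment: pd.Series        # per-subject "train"/"validation", by id
    strata: pd.Series            # per-subject stratum label, by id

    def ids(self, part: str) -> list:
        return self.assignment[self.assignment == part].index.tolist()


@dataclass
class PredictionInterval:
    lo: float
    hi: float
    level: float
    kind: str

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


def stratified_split(meta: list[SubjectMeta] | pd.DataFrame,
                     train_frac: float = 0.7, seed: int = 0) -> SplitAssignment:
    """Random train/validation assignment stratified by site x age group
    (children 6-11, adolescents 12-17, adults 18+) x diagnosis.

    Within each stratum of size n, round(train_frac * n) subjects go to
    the training set; singleton strata go to training with a warning.
    """
    import warnings

    if isinstance(meta, pd.DataFrame):
        df = meta.copy()
    else:
        df = pd.DataFrame([m.__dict__ for m in meta])
    df = df.set_index("id")
    strata = (df["site"].astype(str) + "/" + df["age"].map(age_group)
              + "/" + df["group"].astype(str))
    rng = np.random.default_rng(seed)
    assignment = pd.Series("validation", index=df.index, dtype=object)
    for label in sorted(strata.unique()):
        ids = strata.index[strata == label].to_numpy()
        n = len(ids)
        if n == 1:
            warnings.warn(f"stratum {label} has a single subject; "
                          "assigned to train")
            assignment[ids] = "train"
            continue
        n_train = int(round(train_frac * n))
        picked = rng.choice(ids, size=n_train, replace=False)
        assignment[picked] = "train"
    return SplitAssignment(assignment=assignment, strata=strata)


def prediction_interval_r(r: float, n_orig: int, n_rep: int,
                          level: float = 0.95) -> PredictionInterval:
    """Prediction interval for a replicated correlation via Fisher z.

    Half-width is ``z_(1+level)/2 * sqrt(1/(n_orig-3) + 1/(n_rep-3))`` on
    the z scale, transformed back with tanh, so bounds always lie inside
    (-1, 1).
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be below 1")
    if min(n_orig, n_rep) <= 3:
        raise ValueError("sample sizes must exceed 3")
    z = np.arctanh(r)
    zq = sps.norm.ppf(0.5 * (1.0 + level))
    half = zq * np.sqrt(1.0 / (n_orig - 3) + 1.0 / (n_rep - 3))
    return PredictionInterval(lo=float(np.tanh(z - half)),
                              hi=float(np.tanh(z + half)),
                              level=level, kind="correlation")


def _var_d(d: float, n1: int, n2: int) -> float:
    return (n1 + n2) / (n1 * n2) + d ** 2 / (2.0 * (n1 + n2))


def prediction_interval_d(d: float, n1_orig: int, n2_orig: int,
                          n1_rep: int, n2_rep: int,
                          level: float = 0.95) -> PredictionInterval:
    """Prediction interval for a replicated standardized mean difference.

    Uses the large-sample variance of d in each study,
    ``(n1+n2)/(n1 n2) + d²/(2(n1+n2))``, and a normal quantile on the sum
    of the two variances.
    """
    if min(n1_orig, n2_orig, n1_rep, n2_rep) < 2:
        raise ValueError("all group sizes must be >= 2")
    zq = sps.norm.ppf(0.5 * (1.0 + level))
    half = zq * np.sqrt(_var_d(d, n1_orig, n2_orig)
                        + _var_d(d, n1_rep, n2_rep))
    return PredictionInterval(lo=float(d - half), hi=float(d + half),
                              level=level, kind="smd")


def power_twosample(d: float, n1: int, n2: int,
                    alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test at effect size d.

    Exact noncentral-t computation with noncentrality
    ``d sqrt(n1 n2 / (n1 + n2))`` and df = n1 + n2 - 2.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    return float(power)


def power_lme_sim(make_cohort_features, n_sim: int = 100,
                  alpha: float = 0.05, seed: int = 0) -> dict:
    """Monte-Carlo power of the mixed-model mean test through simulation.

    ``make_cohort_features(seed)`` must return a feature table (as built
    by :func:`restspectra.stats.make_feature_table`) drawn from the
    generative model of interest; the group mean test is run on each of
    ``n_sim`` draws and the rejection fraction at ``alpha`` reported with
    a 95% binomial (Wilson) interval.
    """
    from .stats import group_tests

    if n_sim < 10:
        raise ValueError("n_sim too small for a meaningful power estimate")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(n_sim)]
    rejections = 0
    for s in child_seeds:
        table = make_cohort_features(s)
        res = group_tests(table, reml_confirm=False)
        rejections += res.p_mean < alpha
    power = rejections / n_sim
    lo, hi = _wilson(rejections, n_sim)
    return {"power": power, "ci_low": lo, "ci_high": hi, "n_sim": n_sim}


def _wilson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    z = sps.norm.ppf(0.5 * (1 + level))
    phat = k / n
    denom = 1 + z ** 2 / n
    centre = phat + z ** 2 / (2 * n)
    margin = z * np.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2))
    return (centre - margin) / denom, (centre + margin) / denom
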