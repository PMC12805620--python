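"""Cross-validated Cox risk scores, stratification and permutation testing.

The protocol: overall survival is right-censored at a 60-month horizon;
a ridge-penalised Cox proportional-hazards model is trained with
patient-level two-fold cross-validation, each patient receiving a risk
score (the linear predictor) from the model *not* trained on them;
per-fold validation performance is Harrell's concordance index; the
discovery fold's median risk score is the cutoff that stratifies that
fold's validation patients (at or below the cutoff -> low risk);
pooled out-of-fold groups are compared with Kaplan-Meier curves and a
log-rank statistic whose significance comes from a label-permutation
test.  A conventional multivariate Cox adjustment and a
confounder-association battery (Spearman / Mann-Whitney with Cohen's d
/ one-way ANOVA) complete the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .config import PipelineConfig

LOW, HIGH = "low", "high"


def right_censor(records: pd.DataFrame, horizon: float = 60.0) -> pd.DataFrame:
    """Administratively right-censor survival records at ``horizon``.

    ``records`` needs ``os_months`` (> 0) and ``os_event`` columns;
    times beyond the horizon are truncated and their events cleared.
    A time exactly at the horizon keeps its event.
    """
    if (records["os_months"] <= 0).any():
        bad = records.loc[records["os_months"] <= 0, "patient_id"] \
            if "patient_id" in records else records.index[records["os_months"] <= 0]
        raise ValueError(f"non-positive survival time(s) for: {list(bad)[:5]}")
    out = records.copy()
    over = out["os_months"] > horizon
    out.loc[over, "os_event"] = 0
    out.loc[over, "os_months"] = horizon
    return out


def harrell_c(risk, time, event) -> float:
    """Harrell's concordance index of risk scores against survival.

    A pair is comparable when the strictly shorter time is an observed
    event (pairs tied on time are not compared).  A comparable pair is
    concordant when the shorter-lived patient has the higher risk; tied
    risks count half.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    # comparable[i, j]: t_i < t_j and patient i had the event
    shorter = time[:, None] < time[None, :]
    comparable = shorter & (event[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs: cannot compute a concordance index")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    concordant = (comparable & higher).sum() + 0.5 * (comparable & tied).sum()
    return float(concordant / n_comp)


def harrell_c_oracle(risk, time, event) -> float:
    """O(n^2) pair-enumeration restatement of :func:`harrell_c`."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j or not (time[i] < time[j] and event[i] == 1):
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def median_stratify(discovery_scores, validation_scores) -> list[str]:
    """Assign risk groups by the discovery-set median cutoff.

    Scores at or below the discovery median are low risk; above, high.
    """
    disc = np.asarray(discovery_scores, float)
    if not len(disc):
        raise ValueError("empty discovery set")
    cutoff = float(np.median(disc))
    return [LOW if s <= cutoff else HIGH for s in np.asarray(validation_scores, float)]


# ---------------------------------------------------------------------------
# cross-validated Cox risk scores


@dataclass
class CVResult:
    """Out-of-fold risk scores and per-fold diagnostics."""

    assignments: pd.DataFrame          # patient_id-indexed: fold, risk_score, group
    fold_cindex: list[float]           # validation C-index per fold
    fold_cutoff: list[float]           # discovery-median cutoff per fold
    fold_coefs: list[pd.Series] = field(default_factory=list)

    @property
    def cindex_mean(self) -> float:
        return float(np.mean(self.fold_cindex))

    @property
    def cindex_sd(self) -> float:
        return float(np.std(self.fold_cindex, ddof=0))


def _fit_cox(X: pd.DataFrame, time, event, ridge: float) -> pd.Series:
    """Ridge-penalised Cox fit; returns one coefficient per X column.

    Constant columns carry no information and get coefficient 0.  If
    Newton iterations fail on an ill-conditioned design the penalty is
    escalated (x10, up to twice) before giving up.
    """
    from lifelines.exceptions import ConvergenceError
    keep = [c for c in X.columns if X[c].nunique() > 1]
    df = X[keep].copy()
    df["_time"] = np.asarray(time, float)
    df["_event"] = np.asarray(event, int)
    last_err: Exception | None = None
    for pen in (ridge, ridge * 10 + 0.1, ridge * 100 + 1.0):
        cph = CoxPHFitter(penalizer=pen, l1_ratio=0.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_time", event_col="_event")
            return cph.params_.reindex(X.columns, fill_value=0.0)
        except ConvergenceError as err:
            last_err = err
    raise last_err


def _standardize(train: pd.DataFrame, *others: pd.DataFrame):
    mu = train.mean()
    sd = train.std(ddof=0).replace(0.0, 1.0)   # constant columns pass through
    return [(d - mu) / sd for d in (train, *others)]


def cox_cv(X: pd.DataFrame, records: pd.DataFrame,
           n_folds: int = 2, seed: int = 0, ridge: float = 0.1) -> CVResult:
    """Patient-level k-fold cross-validated Cox risk scores.

    ``X`` is a patient-indexed feature matrix; ``records`` a clinical
    table with ``patient_id, os_months, os_event``.  Within each fold
    the features are z-scored with discovery-fold statistics, a
    ridge-penalised Cox model is fitted on the discovery patients, and
    the validation patients receive its linear predictor as risk score,
    a group from the discovery-median cutoff, and contribute to that
    fold's validation C-index.
    """
    surv = records.set_index("patient_id").loc[X.index]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    folds = np.array_split(order, n_folds)

    fold_of = pd.Series(index=X.index, dtype=int)
    risk = pd.Series(index=X.index, dtype=float)
    group = pd.Series(index=X.index, dtype=object)
    fold_ci, fold_cut, fold_coefs = [], [], []
    for f, val_ix in enumerate(folds):
        val = X.index[val_ix]
        disc = X.index.difference(val, sort=False)
        for part, name in ((disc, "discovery"), (val, "validation")):
            if surv.loc[part, "os_event"].sum() < 1:
                raise ValueError(
                    f"fold {f}: {name} set has no events; try another seed or fewer folds")
        Xd, Xv = _standardize(X.loc[disc], X.loc[val])
        coefs = _fit_cox(Xd, surv.loc[disc, "os_months"], surv.loc[disc, "os_event"], ridge)
        disc_scores = Xd.to_numpy() @ coefs.to_numpy()
        val_scores = Xv.to_numpy() @ coefs.to_numpy()
        cutoff = float(np.median(disc_scores))
        fold_of[val] = f
        risk[val] = val_scores
        group[val] = median_stratify(disc_scores, val_scores)
        fold_ci.append(harrell_c(val_scores, surv.loc[val, "os_months"],
                                 surv.loc[val, "os_event"]))
        fold_cut.append(cutoff)
        fold_coefs.append(coefs)
    assignments = pd.DataFrame({"fold": fold_of, "risk_score": risk, "group": group})
    assignments.index.name = "patient_id"
    return CVResult(assignments, fold_ci, fold_cut, fold_coefs)


# ---------------------------------------------------------------------------
# Kaplan-Meier, log-rank, permutation


def km_estimate(time, event) -> pd.DataFrame:
    """Product-limit survival curve: columns ``time, survival, at_risk``."""
    time = np.asarray(time, float)
    if not len(time):
        raise ValueError("km_estimate needs at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(time, np.asarray(event, int))
    sf = kmf.survival_function_
    ev = kmf.event_table
    return pd.DataFrame({
        "time": sf.index.to_numpy(float),
        "survival": sf.iloc[:, 0].to_numpy(float),
        "at_risk": ev["at_risk"].reindex(sf.index).to_numpy(float),
    })


def _logrank_stat(time, event, g1_mask) -> float:
    """Two-group log-rank chi-square with hypergeometric variance."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    g1 = np.asarray(g1_mask, bool)
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], g1[order]
    n = len(t)
    # at-risk counts just before each time, then collapse to unique event times
    uniq, first = np.unique(t, return_index=True)
    at_risk = n - first
    at_risk1 = np.concatenate([np.cumsum(g[::-1])[::-1], [0]])[first]
    d_tot = np.add.reduceat(e, first)
    d1 = np.add.reduceat(e * g, first)
    keep = d_tot > 0
    nj, n1j, dj, d1j = at_risk[keep], at_risk1[keep], d_tot[keep], d1[keep]
    exp1 = dj * n1j / nj
    with np.errstate(invalid="ignore", divide="ignore"):
        var = dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / np.maximum(nj - 1, 1)
    v = var.sum()
    if v <= 0:
        return 0.0
    return float((d1j - exp1).sum() ** 2 / v)


def logrank(time, event, groups) -> dict[str, float]:
    """Two-group log-rank test: ``{"statistic": chi2_1df, "p": tail}``."""
    labels = pd.unique(pd.Series(groups))
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    if np.asarray(event).sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    stat = _logrank_stat(time, event, np.asarray(groups) == labels[0])
    return {"statistic": stat, "p": float(stats.chi2.sf(stat, df=1))}


def permutation_p(time, event, groups, n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p-value of the log-rank statistic.

    Group labels are permuted against the fixed (time, event) pairs;
    the add-one estimate ``(1 + #{perm >= observed}) / (n_perm + 1)``
    avoids zero p-values.
    """
    groups = np.asarray(groups)
    labels = pd.unique(pd.Series(groups))
    if len(labels) != 2:
        raise ValueError("permutation test needs exactly 2 groups")
    g1 = groups == labels[0]
    obs = _logrank_stat(time, event, g1)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += _logrank_stat(time, event, rng.permutation(g1)) >= obs
    return (1 + exceed) / (n_perm + 1)


def permutation_p_refit(X: pd.DataFrame, records: pd.DataFrame,
                        config: "PipelineConfig | None" = None,
                        n_perm: int = 100, seed: int = 0) -> float:
    """Full-refit randomization test of outcome/feature independence.

    The pooled label-permutation test (:func:`permutation_p`) is mildly
    anti-conservative when applied to cross-validated risk groups: each
    fold's labels are functions of the *other* fold's outcomes (the
    pre-validation effect), so pooled labels and outcomes are not
    exchangeable even under the null.  This variant permutes the
    (time, event) pairs against the feature rows and reruns the entire
    cross-validation and stratification per permutation, which makes
    the test exact by construction — at the cost of ``2 * n_perm`` Cox
    fits.  Intended for final confirmatory analyses at modest ``n_perm``.
    """
    config = config or PipelineConfig()
    rec = records.reset_index(drop=True)

    def _stat(r: pd.DataFrame) -> float:
        cv = cox_cv(X, r, n_folds=config.n_folds, seed=config.random_seed,
                    ridge=config.ridge)
        surv = r.set_index("patient_id").loc[cv.assignments.index]
        g1 = (cv.assignments["group"] == LOW).to_numpy()
        if g1.all() or not g1.any():
            return 0.0
        return _logrank_stat(surv["os_months"], surv["os_event"], g1)

    obs = _stat(rec)
    rng = np.random.default_rng(seed)
    exceed = 0
    outcome = rec[["os_months", "os_event"]].to_numpy()
    for _ in range(n_perm):
        shuffled = rec.copy()
        shuffled[["os_months", "os_event"]] = outcome[rng.permutation(len(rec))]
        exceed += _stat(shuffled) >= obs
    return (1 + exceed) / (n_perm + 1)


# ---------------------------------------------------------------------------
# end-to-end stratification


@dataclass
class StratificationReport:
    cv: CVResult
    km_curves: dict[str, pd.DataFrame]
    logrank_statistic: float
    permutation_pvalue: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "cindex_mean": self.cv.cindex_mean,
            "cindex_sd": self.cv.cindex_sd,
            "fold_cindex": list(map(float, self.cv.fold_cindex)),
            "fold_cutoff": list(map(float, self.cv.fold_cutoff)),
            "logrank_statistic": float(self.logrank_statistic),
            "permutation_pvalue": float(self.permutation_pvalue),
            "n_permutations": int(self.n_permutations),
            "group_sizes": self.cv.assignments["group"].value_counts().to_dict(),
        }


def stratify_cohort(X: pd.DataFrame, records: pd.DataFrame,
                    config: PipelineConfig | None = None) -> StratificationReport:
    """Full protocol: censor, cross-validate, pool, test.

    Returns pooled out-of-fold Kaplan-Meier curves per risk group, the
    log-rank statistic and its permutation p-value, and the per-fold
    validation C-indices.
    """
    config = config or PipelineConfig()
    rec = right_censor(records, config.censor_horizon_months)
    cv = cox_cv(X, rec, n_folds=config.n_folds, seed=config.random_seed,
                ridge=config.ridge)
    surv = rec.set_index("patient_id").loc[cv.assignments.index]
    t = surv["os_months"].to_numpy()
    e = surv["os_event"].to_numpy()
    g = cv.assignments["group"].to_numpy()
    curves = {lab: km_estimate(t[g == lab], e[g == lab])
              for lab in (LOW, HIGH) if (g == lab).any()}
    if len(curves) == 2:
        lr = logrank(t, e, g)["statistic"]
        p = permutation_p(t, e, g, n_perm=config.n_permutations,
                          seed=config.random_seed)
    else:    # degenerate: all patients on one side of every cutoff
        lr, p = 0.0, 1.0
    return StratificationReport(cv, curves, lr, p, config.n_permutations)


# ---------------------------------------------------------------------------
# multivariate adjustment and confounder battery


def multivariate_cox(data: pd.DataFrame, duration_col: str = "os_months",
                     event_col: str = "os_event", ridge: float = 0.0) -> pd.DataFrame:
    """Multivariate Cox PH fit on the full cohort.

    ``data`` holds the duration/event columns plus numerically encoded
    covariates (the risk marker as binary group or continuous score).
    Returns per-covariate hazard ratios with Wald 95% CIs and p-values.
    Collinear designs are rejected, naming the dependent columns.
    """
    covs = [c for c in data.columns if c not in (duration_col, event_col)]
    Xm = data[covs].to_numpy(float)
    const = [c for c in covs if data[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate column(s): {', '.join(const)}")
    if np.linalg.matrix_rank(Xm - Xm.mean(0)) < len(covs):
        corr = np.corrcoef(Xm, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"singular design: columns {covs[i]!r} and {covs[j]!r} are collinear")
    cph = CoxPHFitter(penalizer=ridge)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(data[[duration_col, event_col, *covs]],
                duration_col=duration_col, event_col=event_col)
    s = cph.summary
    return pd.DataFrame({
        "HR": s["exp(coef)"],
        "CI95_low": s["exp(coef) lower 95%"],
        "CI95_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled-SD convention."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / max(na + nb - 2, 1))
    if pooled == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / pooled)


def confounder_battery(risk_scores: pd.Series, clinical: pd.DataFrame,
                       variables: dict[str, str]) -> pd.DataFrame:
    """Association of the risk score with candidate confounders.

    ``variables`` maps clinical column -> type: ``continuous``
    (Spearman correlation), ``binary`` (Mann-Whitney U plus Cohen's d)
    or ``categorical`` (one-way ANOVA).  Variables with a single
    observed level are skipped with a warning.
    """
    clin = clinical.set_index("patient_id").loc[risk_scores.index] \
        if "patient_id" in clinical else clinical.loc[risk_scores.index]
    rows = []
    for var, kind in variables.items():
        col = clin[var]
        score = risk_scores
        if kind == "continuous":
            rho, p = stats.spearmanr(score, pd.to_numeric(col))
            rows.append({"variable": var, "test": "spearman",
                         "statistic": float(rho), "p": float(p),
                         "effect_size": float(rho)})
            continue
        levels = [lv for lv in pd.unique(col.dropna())]
        if len(levels) < 2:
            warnings.warn(f"confounder {var!r} has a single level; skipped")
            continue
        if kind == "binary":
            if len(levels) != 2:
                raise ValueError(f"binary variable {var!r} has {len(levels)} levels")
            a = score[col == levels[0]].to_numpy()
            b = score[col == levels[1]].to_numpy()
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({"variable": var, "test": "mannwhitney",
                         "statistic": float(u), "p": float(p),
                         "effect_size": cohens_d(a, b)})
        elif kind == "categorical":
            grps = [score[col == lv].to_numpy() for lv in levels]
            f, p = stats.f_oneway(*grps)
            # eta-squared as the effect size for multi-level factors
            grand = score.to_numpy().mean()
            ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in grps)
            ss_t = ((score.to_numpy() - grand) ** 2).sum()
            rows.append({"variable": var, "test": "anova",
                         "statistic": float(f), "p": float(p),
                         "effect_size": float(ss_b / ss_t) if ss_t else 0.0})
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
    return pd.DataFrame(rows)


def permutation_importance(X: pd.DataFrame, records: pd.DataFrame,
                           n_repeats: int = 5, seed: int = 0,
                           ridge: float = 0.1) -> pd.Series:
    """Mean drop in full-fit C-index when one feature is permuted.

    A light, model-agnostic alternative to attribution methods: a
    single Cox fit on all patients, then each column is shuffled
    ``n_repeats`` times and the C-index degradation recorded.
    """
    surv = records.set_index("patient_id").loc[X.index]
    t, e = surv["os_months"].to_numpy(), surv["os_event"].to_numpy()
    (Xs,) = _standardize(X)
    coefs = _fit_cox(Xs, t, e, ridge)
    base = harrell_c(Xs.to_numpy() @ coefs.to_numpy(), t, e)
    rng = np.random.default_rng(seed)
    drops = {}
    for c in X.columns:
        d = []
        for _ in range(n_repeats):
            Xp = Xs.copy()
            Xp[c] = rng.permutation(Xp[c].to_numpy())
            d.append(base - harrell_c(Xp.to_numpy() @ coefs.to_numpy(), t, e))
        drops[c] = float(np.mean(d))
    return pd.Series(drops, name="cindex_drop").sort_values(ascending=False)
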