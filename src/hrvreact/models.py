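"""Group comparisons and GLS reactivity models.

The central model regresses each phase-level HRV outcome on a group
factor, the protocol time factor (relax1 reference), their interaction,
and the subject's baseline value of the same outcome, optionally
adjusted for BMI, smoking and physical activity:

    outcome = group x time + baseline [+ BMI + smoking + LTPA]

Estimation is feasible generalized least squares with an exchangeable
(compound-symmetric) within-subject correlation: ordinary least squares,
a moment estimate of the common correlation rho from residual
cross-products, closed-form GLS under the implied block covariance, and
iteration to convergence of rho.  Wald confidence intervals use a t
reference with residual degrees of freedom.

Simple two- and multi-group comparisons (Student/Welch t, Mann-Whitney,
Yates-corrected chi-square, one-way ANOVA with Tukey HSD) delegate to
scipy.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import HRVSummary
from .schedule import PHASE_LABELS

log = logging.getLogger(__name__)

TIME_REFERENCE = "relax1"
TIME_CONTRASTS = ("stress1", "relax2", "stress2", "relax3")


# --------------------------------------------------------------------------
# Long-format table construction


def build_long_table(
    summaries: list[HRVSummary],
    subjects,
    outcome: str,
    group_attr: str = "group",
    reference_group: str = "control",
) -> pd.DataFrame:
    """Long-format modelling table: one row per subject x phase.

    ``outcome`` names an HRVSummary metric attribute (``hr_bpm``,
    ``rr_mean_s``, ``rmssd_s``, ``sdnn_s``).  The subject's baseline-window
    value of the same metric is carried as a covariate on every row.
    Subjects without a valid baseline are excluded with a warning;
    incomplete phases are dropped listwise with a log entry.
    """
    by_subject: dict[str, dict[str, HRVSummary]] = {}
    for s in summaries:
        by_subject.setdefault(s.subject_id, {})[s.window] = s
    subj_map = {s.id: s for s in subjects}
    rows = []
    for sid, wins in by_subject.items():
        if sid not in subj_map:
            continue
        subj = subj_map[sid]
        base = wins.get("baseline")
        if base is None or getattr(base, outcome) is None:
            warnings.warn(f"subject {sid} lacks a baseline value; excluded",
                          stacklevel=2)
            continue
        for phase in PHASE_LABELS:
            summ = wins.get(phase)
            if summ is None or getattr(summ, outcome) is None:
                log.info("subject %s phase %s missing; row dropped", sid, phase)
                continue
            rows.append(
                {
                    "subject_id": sid,
                    "group": getattr(subj, group_attr),
                    "time": phase,
                    "value": getattr(summ, outcome),
                    "baseline": getattr(base, outcome),
                    "bmi": subj.bmi,
                    "smoker": subj.smoker,
                    "physically_active": subj.physically_active,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["group"] = df["group"].astype(str)
    return df


# --------------------------------------------------------------------------
# Feasible GLS


@dataclass
class GLSFit:
    """Coefficients, within-subject correlation and fit diagnostics."""

    params: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p
    rho: float
    sigma2: float
    n_obs: int
    df_resid: int
    converged: bool
    n_iter: int
    term_names: list[str] = field(default_factory=list)

    def estimate(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "p"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.set_index("term").loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def _design_matrix(
    df: pd.DataFrame,
    reference_group: str,
    covariates: tuple[str, ...],
) -> tuple[np.ndarray, list[str]]:
    groups = [g for g in pd.unique(df["group"]) if g != reference_group]
    groups.sort()
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["(Intercept)"]
    cols.append(df["baseline"].to_numpy(float))
    names.append("baseline")
    for g in groups:
        cols.append((df["group"] == g).to_numpy(float))
        names.append(f"group[{g}]")
    for t in TIME_CONTRASTS:
        cols.append((df["time"] == t).to_numpy(float))
        names.append(f"time[{t}]")
    for c in covariates:
        cols.append(df[c].to_numpy(float))
        names.append(c)
    for g in groups:
        gm = (df["group"] == g).to_numpy(float)
        for t in TIME_CONTRASTS:
            cols.append(gm * (df["time"] == t).to_numpy(float))
            names.append(f"group[{g}]:time[{t}]")
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"design matrix rank deficient; aliased columns: {aliased}")


def _estimate_rho(resid: np.ndarray, idx: list[np.ndarray], df_resid: int) -> float:
    sigma2 = float(resid @ resid) / df_resid
    num = 0.0
    pairs = 0
    for ix in idx:
        r = resid[ix]
        m = r.size
        if m < 2:
            continue
        s = float(r.sum())
        num += (s * s - float(r @ r)) / 2.0
        pairs += m * (m - 1) // 2
    if pairs == 0 or sigma2 <= 0:
        return 0.0
    return num / (pairs * sigma2)


def _whiten(
    X: np.ndarray, y: np.ndarray, idx: list[np.ndarray], rho: float
) -> tuple[np.ndarray, np.ndarray]:
    Xw, yw = X.copy(), y.copy()
    a = 1.0 / math.sqrt(1.0 - rho)
    for ix in idx:
        m = ix.size
        u = math.sqrt((1.0 - rho) / (1.0 + (m - 1) * rho))
        c = 1.0 - u
        yb = y[ix].mean()
        Xb = X[ix].mean(axis=0)
        yw[ix] = a * (y[ix] - c * yb)
        Xw[ix] = a * (X[ix] - c * Xb)
    return Xw, yw


def fit_gls(
    df: pd.DataFrame,
    reference_group: str = "control",
    covariates: tuple[str, ...] = (),
    rho: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
    ci_level: float = 0.95,
) -> GLSFit:
    """Feasible GLS of ``value`` on group x time + baseline (+ covariates).

    ``df`` must hold columns subject_id, group, time, value, baseline,
    plus any requested covariates.  Set ``rho`` to fix the exchangeable
    correlation (rho=0 reproduces ordinary least squares exactly).
    """
    needed = {"subject_id", "group", "time", "value", "baseline", *covariates}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"long table lacks columns {sorted(missing)}")
    work = df.dropna(subset=["value", "baseline", *covariates]).copy()
    X, names = _design_matrix(work, reference_group, covariates)
    _check_rank(X, names)
    y = work["value"].to_numpy(float)
    n, p = X.shape
    df_resid = n - p
    codes, _ = pd.factorize(work["subject_id"])
    idx = [np.flatnonzero(codes == k) for k in range(codes.max() + 1)]
    max_m = max(ix.size for ix in idx)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fixed_rho = rho is not None
    rho_hat = float(rho) if fixed_rho else 0.0
    converged = fixed_rho
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - X @ beta
        if not fixed_rho:
            new_rho = _estimate_rho(resid, idx, df_resid)
            lo = -1.0 / (max_m - 1) + 1e-6 if max_m > 1 else 0.0
            new_rho = float(np.clip(new_rho, lo, 0.99))
        else:
            new_rho = rho_hat
        Xw, yw = _whiten(X, y, idx, new_rho)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        if fixed_rho or abs(new_rho - rho_hat) < tol:
            rho_hat = new_rho
            converged = True
            break
        rho_hat = new_rho
    Xw, yw = _whiten(X, y, idx, rho_hat)
    rw = yw - Xw @ beta
    sigma2 = float(rw @ rw) / df_resid
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df_resid)
    tvals = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    params = pd.DataFrame(
        {
            "term": names,
            "estimate": beta,
            "se": se,
            "ci_low": beta - tcrit * se,
            "ci_high": beta + tcrit * se,
            "p": pvals,
        }
    )
    if not converged:
        log.warning("GLS rho iteration did not converge after %d steps", it)
    return GLSFit(
        params=params,
        rho=rho_hat,
        sigma2=sigma2,
        n_obs=n,
        df_resid=df_resid,
        converged=converged,
        n_iter=it,
        term_names=names,
    )


# --------------------------------------------------------------------------
# Two-group and multi-group tests


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p: float
    detail: dict = field(default_factory=dict)


def chi_square_yates(table) -> TestResult:
    """Yates-continuity-corrected chi-square on a 2x2 table.

    Degenerate tables (a zero row/column making expected counts zero)
    yield a flagged result with NaN statistics instead of an error.
    """
    t = np.asarray(table, dtype=float)
    try:
        chi2, p, dof, _ = stats.chi2_contingency(t, correction=True)
    except ValueError as exc:
        return TestResult(
            "chi_square_yates", math.nan, math.nan,
            {"note": f"degenerate table: {exc}"},
        )
    return TestResult("chi_square_yates", float(chi2), float(p), {"dof": dof})


def two_group_tests(x, y, label: str = "") -> list[TestResult]:
    """Student's t and Mann-Whitney U for one continuous variable.

    Both conventions are reported because descriptive tables and methods
    sections commonly disagree on which was used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = []
    if np.std(x) == 0 and np.std(y) == 0 and np.mean(x) == np.mean(y):
        out.append(TestResult("student_t", 0.0, 1.0, {"note": "zero variance",
                                                      "variable": label}))
    else:
        t, p = stats.ttest_ind(x, y, equal_var=True)
        out.append(TestResult("student_t", float(t), float(p), {"variable": label}))
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    out.append(TestResult("mann_whitney", float(u), float(p), {"variable": label}))
    return out


def baseline_comparisons(
    subjects, summaries: list[HRVSummary], group_attr: str = "group"
) -> list[TestResult]:
    """Between-group tests per HRV metric per window plus covariates.

    Continuous variables get Student's t and Mann-Whitney; 2x2
    categorical tables (smoking, physical activity) get Yates-corrected
    chi-square.
    """
    groups = sorted({getattr(s, group_attr) for s in subjects}, reverse=True)
    if len(groups) != 2:
        raise ValueError("baseline comparisons need exactly two groups")
    g1, g2 = groups  # e.g. FM first, control second
    by_id = {s.id: s for s in subjects}
    results: list[TestResult] = []
    metrics = ("hr_bpm", "rr_mean_s", "rmssd_s", "sdnn_s")
    windows = sorted({s.window for s in summaries})
    for window in windows:
        for metric in metrics:
            vals: dict[str, list[float]] = {g1: [], g2: []}
            for s in summaries:
                if s.window != window or s.subject_id not in by_id:
                    continue
                v = getattr(s, metric)
                if v is not None:
                    vals[getattr(by_id[s.subject_id], group_attr)].append(v)
            if min(len(vals[g1]), len(vals[g2])) >= 2:
                for r in two_group_tests(
                    vals[g1], vals[g2], label=f"{metric}@{window}"
                ):
                    results.append(r)
    for attr in ("smoker", "physically_active"):
        rows = []
        for g in (g1, g2):
            yes = sum(
                1
                for s in subjects
                if getattr(s, group_attr) == g and getattr(s, attr) is True
            )
            no = sum(
                1
                for s in subjects
                if getattr(s, group_attr) == g and getattr(s, attr) is False
            )
            rows.append([yes, no])
        res = chi_square_yates(rows)
        results.append(
            TestResult(res.method, res.statistic, res.p,
                       {"variable": attr, "table": rows})
        )
    return results


def anova_tukey(values, group_labels) -> list[TestResult]:
    """One-way ANOVA with all-pairs Tukey HSD.

    Groups with fewer than two observations are excluded with a warning.
    Tukey p-values come from the studentized-range distribution; for two
    groups they coincide with the pooled-variance t-test.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    keep_labels = []
    samples = []
    for lab in pd.unique(labels):
        x = values[labels == lab]
        x = x[np.isfinite(x)]
        if x.size < 2:
            warnings.warn(f"group {lab!r} has <2 observations; excluded",
                          stacklevel=2)
            continue
        keep_labels.append(lab)
        samples.append(x)
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least two groups with >=2 observations")
    f, p = stats.f_oneway(*samples)
    out = [TestResult("anova", float(f), float(p),
                      {"groups": [str(g) for g in keep_labels]})]
    hsd = stats.tukey_hsd(*samples)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            out.append(
                TestResult(
                    "tukey_hsd",
                    float(hsd.statistic[i, j]),
                    float(hsd.pvalue[i, j]),
                    {"pair": (str(keep_labels[i]), str(keep_labels[j]))},
                )
            )
    return out


# --------------------------------------------------------------------------
# Model-level simulation (for calibration and error-rate studies)


def simulate_long_outcomes(
    n_fm: int = 51,
    n_control: int = 31,
    rho: float = 0.3,
    sigma: float = 5.0,
    baseline_mean: tuple[float, float] = (72.3, 64.5),
    baseline_sd: tuple[float, float] = (12.7, 7.8),
    baseline_slope: float = 0.92,
    time_effects: dict | None = None,
    interaction_effects: dict | None = None,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Simulate a long table directly from the linear model.

    Errors are exchangeable within subject with correlation ``rho``
    (shared subject component plus white noise); used for type-I-error
    and coefficient-recovery studies at the model level, without signal
    synthesis.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    time_effects = time_effects or {
        "stress1": 11.5, "relax2": 2.5, "stress2": 11.7, "relax3": 0.6
    }
    interaction_effects = interaction_effects or {}
    tau = sigma * math.sqrt(rho)
    eps = sigma * math.sqrt(1.0 - rho)
    rows = []
    for g, n, mu_b, sd_b in (
        ("FM", n_fm, baseline_mean[0], baseline_sd[0]),
        ("control", n_control, baseline_mean[1], baseline_sd[1]),
    ):
        for i in range(n):
            sid = f"{g}{i:03d}"
            b = rng.normal(mu_b, sd_b)
            u = rng.normal(0.0, tau)
            for phase in PHASE_LABELS:
                mean = baseline_slope * b + time_effects.get(phase, 0.0)
                if g == "FM":
                    mean += interaction_effects.get(phase, 0.0)
                rows.append(
                    {
                        "subject_id": sid,
                        "group": g,
                        "time": phase,
                        "value": mean + u + rng.normal(0.0, eps),
                        "baseline": b,
                    }
                )
    return pd.DataFrame(rows)
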