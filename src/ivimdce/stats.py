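"""Cohort-level staging statistics.

Stratified two-group comparison (Shapiro-Wilk normality, pooled
Student's t-test), empirical ROC analysis with an optimal cut-off
(Youden's J by default) and likelihood ratios, DeLong comparison of
paired AUCs, forward-stepwise multiple logistic regression, and
Spearman rank correlation with Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .errors import FitError, ValidationError

#: Parameters whose *low* values predict the high-stage class; ve runs
#: the other way (higher in high stage).
LOWER_IN_HIGH_STAGE = ("mean_D", "mean_f", "mean_Dstar", "mean_Ktrans",
                       "mean_kep", "mean_vp")
HIGHER_IN_HIGH_STAGE = ("mean_ve",)


# ---------------------------------------------------------------- grouping

def stratify(records) -> tuple[list, list]:
    """Partition subject records into (low, high) stage groups.

    Accepts anything with a ``stage_group`` attribute or mapping key.
    """
    low, high = [], []
    for r in records:
        grp = r.stage_group if hasattr(r, "stage_group") else r["stage_group"]
        if grp == "low":
            low.append(r)
        elif grp == "high":
            high.append(r)
        else:
            raise ValidationError(f"stage_group: unknown label {grp!r}")
    return low, high


def stratify_frame(table, column: str):
    """(low values, high values) of one cohort-table column."""
    low = table.loc[table["stage_group"] == "low", column].to_numpy(float)
    high = table.loc[table["stage_group"] == "high", column].to_numpy(float)
    if low.size == 0 or high.size == 0:
        raise FitError("stratify: one stage group is empty")
    return low, high


# ------------------------------------------------------------- normality/t

def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000 non-constant samples."""
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValidationError("values: Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValidationError("values: constant input, W undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def t_test_two_sample(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sided Student's t-test (pooled variance; Welch by flag)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("x/y: need n >= 2 per group")
    if not welch and np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValidationError("x/y: zero pooled variance")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def t_test_from_summary(m1, s1, n1, m2, s2, n2) -> tuple[float, float]:
    """Pooled Student's t from group summary statistics (mean, SD, n)."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("n1/n2: need n >= 2 per group")
    if s1 == 0 and s2 == 0:
        raise ValidationError("s1/s2: zero pooled variance")
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(t), float(p)


# -------------------------------------------------------------------- ROC

@dataclass
class RocResult:
    """Empirical ROC curve and its optimal operating point.

    ``direction`` records which tail predicts the positive (high
    stage) class: "higher" means values >= cut-off are called
    positive, "lower" means values <= cut-off are.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str
    optimal_cutoff: float
    sens: float
    spec: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    lr_pos: float
    lr_neg: float
    lr_pos_ci: tuple[float, float]
    lr_neg_ci: tuple[float, float]
    criterion: str = "youden"


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _lr_ci(lr: float, a: int, m: int, b: int, n: int,
           alpha: float = 0.05) -> tuple[float, float]:
    """Log-method CI for a likelihood ratio (a/m)/(b/n)."""
    if lr <= 0 or not np.isfinite(lr) or a == 0 or b == 0:
        return (0.0, np.inf)
    se = np.sqrt(1 / a - 1 / m + 1 / b - 1 / n)
    z = sps.norm.ppf(1 - alpha / 2)
    return float(lr * np.exp(-z * se)), float(lr * np.exp(z * se))


def roc_analysis(values, labels, direction: str = "higher",
                 criterion: str = "youden") -> RocResult:
    """Empirical ROC of a continuous marker against a binary label.

    ``labels`` is truthy for the positive (high-stage) class;
    ``direction="lower"`` flags markers whose *low* values predict the
    positive class.  Candidate cut-offs are the midpoints between
    consecutive distinct marker values (plus the extremes); the optimal
    one maximizes Youden's J (or overall accuracy with
    ``criterion="accuracy"``), ties broken toward higher specificity.
    AUC is the trapezoid over the empirical curve, identical to the
    Mann-Whitney statistic.  Sens/spec CIs are Clopper-Pearson;
    likelihood-ratio CIs use the log method.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValidationError("values/labels: need paired 1-D arrays")
    if y.all() or not y.any():
        raise FitError("roc_analysis: both classes must be present")
    if direction not in ("higher", "lower"):
        raise ValidationError("direction: must be 'higher' or 'lower'")
    if criterion not in ("youden", "accuracy"):
        raise ValidationError("criterion: must be 'youden' or 'accuracy'")

    score = v if direction == "higher" else -v
    n_pos = int(y.sum())
    n_neg = int((~y).sum())

    uniq = np.unique(score)
    cuts = np.concatenate([
        [uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]
    ])
    # predicted positive: score >= cut
    sens = np.array([(score[y] >= c).mean() for c in cuts])
    spec = np.array([(score[~y] < c).mean() for c in cuts])

    # trapezoid AUC over the empirical curve (FPR, TPR), lexicographic
    # so vertical segments are traversed bottom-up
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))

    if criterion == "youden":
        obj = sens + spec - 1.0
    else:
        obj = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
    best = np.flatnonzero(obj == obj.max())
    i = best[np.argmax(spec[best])]  # tie-break: higher specificity

    tp = int(round(sens[i] * n_pos))
    tn = int(round(spec[i] * n_neg))
    fn, fp = n_pos - tp, n_neg - tn
    s, c = float(sens[i]), float(spec[i])
    lr_pos = s / (1 - c) if c < 1 else np.inf
    lr_neg = (1 - s) / c if c > 0 else np.inf
    cutoff = float(cuts[i] if direction == "higher" else -cuts[i])

    return RocResult(
        thresholds=cuts if direction == "higher" else -cuts,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        direction=direction,
        optimal_cutoff=cutoff,
        sens=s, spec=c,
        sens_ci=_clopper_pearson(tp, n_pos),
        spec_ci=_clopper_pearson(tn, n_neg),
        lr_pos=float(lr_pos), lr_neg=float(lr_neg),
        lr_pos_ci=_lr_ci(lr_pos, tp, n_pos, fp, n_neg),
        lr_neg_ci=_lr_ci(lr_neg, fn, n_pos, tn, n_neg),
        criterion=criterion,
    )


# ---------------------------------------------------------------- DeLong

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_placements(score: np.ndarray, y: np.ndarray):
    """Per-subject placement values V10 (positives) and V01 (negatives)."""
    pos, neg = score[y], score[~y]
    m, n = pos.size, neg.size
    allr = _midrank(np.concatenate([pos, neg]))
    rp, rn = _midrank(pos), _midrank(neg)
    v10 = (allr[:m] - rp) / n
    v01 = 1.0 - (allr[m:] - rn) / m
    auc = v10.mean()
    return auc, v10, v01


def compare_auc(values_a, values_b, labels) -> tuple[float, float]:
    """DeLong paired test for the difference of two correlated AUCs.

    Both markers are measured on the same subjects.  Returns
    (auc_a − auc_b, two-sided p).  Identical curves give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not (a.shape == b.shape == y.shape):
        raise ValidationError("values_a/values_b/labels: lengths must match")
    if y.all() or not y.any():
        raise FitError("compare_auc: both classes must be present")

    auc_a, v10a, v01a = _delong_placements(a, y)
    auc_b, v10b, v01b = _delong_placements(b, y)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return float(diff), 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return float(diff), float(2 * sps.norm.sf(abs(z)))


# ------------------------------------------------------- stepwise logistic

@dataclass
class StepwiseResult:
    """Outcome of forward-stepwise logistic selection."""

    selected: list[str]
    selection_order: list[str]
    coefficients: dict[str, float]
    wald_p: dict[str, float]
    deviance: float
    penalized: bool = False


def _fit_logit(X: np.ndarray, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
            disp=0, maxiter=200)


def stepwise_logistic(
    features, labels, feature_names=None,
    p_enter: float = 0.05, p_remove: float = 0.10,
) -> StepwiseResult:
    """Forward selection with backward pruning by likelihood-ratio test.

    Features are z-standardized internally.  A candidate enters when
    its LR-test p against the current model is the smallest and below
    ``p_enter``; after each entry, any included feature whose removal
    LR p exceeds ``p_remove`` is dropped.  Exactly collinear candidates
    are skipped.  On (quasi-)perfect separation the final model is
    refit with an L2 ridge penalty and flagged ``penalized``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(float)
    if X.ndim != 2:
        raise ValidationError("features: expected a 2-D (n, p) array")
    n, p = X.shape
    if y.shape != (n,):
        raise ValidationError("labels: length must match features")
    if n <= p:
        raise ValidationError("features: need n > number of candidates")
    names = list(feature_names) if feature_names is not None else [
        f"x{j}" for j in range(p)]
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValidationError("features: constant column")
    Xs = (X - X.mean(axis=0)) / sd

    def llf(cols):
        if not cols:
            ybar = y.mean()
            return n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
        return _fit_logit(Xs[:, cols], y).llf

    selected: list[int] = []
    order: list[int] = []
    penalized = False
    try:
        changed = True
        while changed:
            changed = False
            cur_llf = llf(selected)
            # forward step
            best_j, best_p = None, 1.0
            for j in range(p):
                if j in selected:
                    continue
                cols = selected + [j]
                if np.linalg.matrix_rank(Xs[:, cols]) < len(cols):
                    continue  # collinear with the current model
                lr = 2 * (llf(cols) - cur_llf)
                pval = sps.chi2.sf(max(lr, 0.0), 1)
                if pval < best_p:
                    best_j, best_p = j, pval
            if best_j is not None and best_p < p_enter:
                selected.append(best_j)
                order.append(best_j)
                changed = True
            # backward step
            if len(selected) > 1:
                full = llf(selected)
                worst_j, worst_p = None, 0.0
                for j in selected:
                    rest = [k for k in selected if k != j]
                    lr = 2 * (full - llf(rest))
                    pval = sps.chi2.sf(max(lr, 0.0), 1)
                    if pval > worst_p:
                        worst_j, worst_p = j, pval
                if worst_j is not None and worst_p > p_remove:
                    selected.remove(worst_j)
                    changed = True
        if selected:
            fit = _fit_logit(Xs[:, selected], y)
            converged = fit.mle_retvals.get("converged", True)
            if (not converged or not np.all(np.isfinite(fit.bse))
                    or np.any(fit.bse > 1e3) or np.any(np.abs(fit.params) > 50)):
                raise RuntimeError("separation suspected")  # triggers fallback
            coefs = dict(zip([names[j] for j in selected], fit.params[1:]))
            wald = dict(zip([names[j] for j in selected], fit.pvalues[1:]))
            dev = float(-2 * fit.llf)
        else:
            coefs, wald, dev = {}, {}, float(-2 * llf([]))
    except Exception:
        # separation or non-convergence: penalized (ridge) fallback
        penalized = True
        warnings.warn("perfect separation detected; refitting with an L2 "
                      "penalty", RuntimeWarning, stacklevel=2)
        from sklearn.linear_model import LogisticRegression

        cols = selected or list(range(p))
        lr = LogisticRegression(C=1.0, max_iter=1000)  # default L2 ridge
        lr.fit(Xs[:, cols], y)
        coefs = dict(zip([names[j] for j in cols], lr.coef_[0]))
        wald = {names[j]: np.nan for j in cols}
        pred = lr.predict_proba(Xs[:, cols])[:, 1].clip(1e-12, 1 - 1e-12)
        dev = float(-2 * np.sum(y * np.log(pred) + (1 - y) * np.log(1 - pred)))
        selected = cols

    return StepwiseResult(
        selected=[names[j] for j in selected],
        selection_order=[names[j] for j in order],
        coefficients=coefs,
        wald_p=wald,
        deviance=dev,
        penalized=penalized,
    )


# ---------------------------------------------------------------- Spearman

@dataclass
class CorrelationResult:
    """One tested parameter pair's Spearman correlation."""

    pair: tuple[str, str]
    rho: float
    p_raw: float
    p_adjusted: float
    m: int
    significant: bool


def spearman_with_bonferroni(pairs, alpha: float = 0.05) -> list[CorrelationResult]:
    """Spearman rho (midrank ties) per named pair, Bonferroni-adjusted.

    ``pairs`` is a list of (name_x, name_y, x, y); m is the number of
    pairs actually tested, p_adjusted = min(1, m·p_raw).  A constant
    vector leaves that pair's rho undefined (NaN), still counted in m.
    """
    m = len(pairs)
    if m == 0:
        raise ValidationError("pairs: nothing to test")
    out = []
    for name_x, name_y, x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValidationError(f"pair ({name_x}, {name_y}): need equal-length vectors")
        if x.size < 5:
            raise ValidationError(f"pair ({name_x}, {name_y}): need n >= 5")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValidationError(f"pair ({name_x}, {name_y}): non-finite values")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(CorrelationResult((name_x, name_y), np.nan, np.nan,
                                         np.nan, m, False))
            continue
        rho, p = sps.spearmanr(x, y)
        p_adj = min(1.0, m * float(p))
        out.append(CorrelationResult((name_x, name_y), float(rho), float(p),
                                     p_adj, m, p_adj < alpha))
    return out
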