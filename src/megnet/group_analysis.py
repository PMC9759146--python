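"""Group-level statistics: ANOVA with Bonferroni bookkeeping, ROC discrimination.

The analysis layer compares three subject groups (cognitively impaired
patients, non-impaired patients, healthy controls) band by band: a regional
functional-connectivity statistic per band (Bonferroni family of
3 groups x 7 bands = 21 tests) and the four network metrics per band
(3 x 7 x 4 = 84 tests). Distributional gates (Kolmogorov-Smirnov normality,
Levene homogeneity) are warnings, not hard stops. Discrimination of the
impaired group uses single-predictor logistic regression and ROC analysis
with the AUC computed by the Mann-Whitney pair-counting identity and the
operating point chosen by Youden's J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ThresholdedNetwork

__all__ = [
    "ComparisonResult",
    "RocResult",
    "anova_oneway",
    "bonferroni",
    "correction_count",
    "normality_ks",
    "homogeneity_levene",
    "clinical_correlation",
    "logistic_fit",
    "roc_analysis",
    "regional_fc",
    "compare_bands",
    "roc_table",
]

GT_PARAMETERS = ("SA", "DA", "LA", "CA")


@dataclass
class ComparisonResult:
    """One band x parameter three-group comparison."""

    band: str
    parameter: str
    F: float
    p_raw: float
    p_bonferroni: float
    group_means: dict[str, float] = field(default_factory=dict)
    pairwise_p: dict[str, float] = field(default_factory=dict)  # "A_vs_B" etc.


@dataclass
class RocResult:
    """ROC discrimination summary at the Youden-optimal cutoff."""

    predictor: str
    auc: float
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    cutoff: float
    flipped: bool = False  # True if orientation was reversed so AUC >= 0.5


def anova_oneway(*groups) -> dict[str, float]:
    """Classical one-way ANOVA over two or more samples.

    Returns F, p_raw and the between/within degrees of freedom. Zero
    within-group variance yields F=0, p=1 when the means agree and
    F=inf, p=0 otherwise.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    n_total = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = len(gs) - 1, n_total - len(gs)
    if ssw == 0:
        if ssb == 0:
            return {"F": 0.0, "p_raw": 1.0, "df_between": df_b, "df_within": df_w}
        return {"F": np.inf, "p_raw": 0.0, "df_between": df_b, "df_within": df_w}
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return {"F": float(F), "p_raw": p, "df_between": df_b, "df_within": df_w}


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if not 0 <= p_raw <= 1:
        raise ValueError("p_raw must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


def correction_count(n_groups: int, n_bands: int, n_parameters: int = 1) -> int:
    """Size of the Bonferroni family: groups x bands x parameters.

    With 3 groups and 7 bands the functional-connectivity family is 21
    tests; adding the 4 network parameters gives 84 for the graph-theory
    family.
    """
    if min(n_groups, n_bands, n_parameters) < 1:
        raise ValueError("all factors must be >= 1")
    return n_groups * n_bands * n_parameters


def normality_ks(sample) -> dict[str, float]:
    """Kolmogorov-Smirnov test against a normal with the sample's moments."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) sample")
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return {"D": float(res.statistic), "p": float(res.pvalue)}


def homogeneity_levene(*groups) -> dict[str, float]:
    """Levene test of homogeneity of variance across groups."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 3 for g in gs):
        raise ValueError("need >= 2 groups with n >= 3 each")
    res = stats.levene(*gs)
    return {"W": float(res.statistic), "p": float(res.pvalue)}


def clinical_correlation(metric, clinical, method: str = "pearson") -> dict[str, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(metric, dtype=float)
    y = np.asarray(clinical, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must be paired")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": float(r), "p": float(p)}


def logistic_fit(predictor, labels) -> dict[str, float]:
    """Single-predictor maximum-likelihood logistic regression.

    Returns the slope, intercept, Wald 95% CI for the slope, and its
    p-value. On (quasi-)complete separation, where the ML estimate
    diverges, falls back to a small ridge penalty with a warning.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    x = np.asarray(predictor, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(x) < 10:
        raise ValueError("need n >= 10 for a logistic fit")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0)
        if not np.isfinite(fit.bse).all() or np.abs(fit.params[1]) > 1e3:
            raise ValueError("separation")
        ci = fit.conf_int()
        return {
            "coef": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "ci95": (float(ci[1][0]), float(ci[1][1])),
            "p": float(fit.pvalues[1]),
            "penalized": False,
        }
    except Exception:
        warnings.warn("logistic fit separated; using a small ridge penalty", stacklevel=2)
        fit = sm.Logit(y, X).fit_regularized(method="l1", alpha=np.array([0.0, 1e-4]), disp=0)
        # Wald quantities from the penalized point estimate via the observed information
        eta = X @ fit.params
        p_hat = 1 / (1 + np.exp(-eta))
        Winfo = (X * (p_hat * (1 - p_hat))[:, None]).T @ X + 1e-8 * np.eye(2)
        se = np.sqrt(np.diag(np.linalg.inv(Winfo)))
        z = fit.params[1] / se[1]
        return {
            "coef": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "ci95": (float(fit.params[1] - 1.96 * se[1]), float(fit.params[1] + 1.96 * se[1])),
            "p": float(2 * stats.norm.sf(abs(z))),
            "penalized": True,
        }


def roc_analysis(predictor, labels, name: str = "predictor") -> RocResult:
    """ROC discrimination of binary labels by a scalar predictor.

    AUC by the Mann-Whitney pair-counting identity (ties count 1/2);
    orientation is flipped when needed so AUC >= 0.5. Sensitivity,
    specificity and accuracy are evaluated at the cutoff maximizing
    Youden's J = sensitivity + specificity - 1 (earliest cutoff on ties).
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = x[y == 1], x[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    auc = wins / (len(pos) * len(neg))
    flipped = auc < 0.5
    if flipped:
        x = -x
        pos, neg = -pos, -neg
        auc = 1.0 - auc
    cuts = np.concatenate([[-np.inf], (np.sort(np.unique(x))[:-1] + np.sort(np.unique(x))[1:]) / 2, [np.inf]])
    best = None
    for c in cuts:
        sens = (pos > c).mean()
        spec = (neg <= c).mean()
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            acc = ((pos > c).sum() + (neg <= c).sum()) / len(x)
            best = (j, c, sens, spec, acc)
    _, cutoff, sens, spec, acc = best
    return RocResult(
        predictor=name,
        auc=float(auc),
        sensitivity=100.0 * float(sens),
        specificity=100.0 * float(spec),
        accuracy=100.0 * float(acc),
        cutoff=float(-cutoff if flipped else cutoff),
        flipped=flipped,
    )


def regional_fc(net: ThresholdedNetwork, role: str) -> float:
    """Regional FC statistic: mean positive-connection weight incident to a role.

    Operationalizes a region's connectivity as the mean weight of retained
    positive edges with at least one endpoint whose node role matches
    *role* ("frontal", "pcc", ...). Returns 0 when no such edge survives.
    """
    if not net.node_roles:
        raise ValueError("network carries no node roles")
    idx = {i for i, r in enumerate(net.node_roles) if r == role}
    if not idx:
        raise ValueError(f"no nodes with role {role!r}")
    w = [wt for i, j, wt, sign, _ in net.edges if sign > 0 and (i in idx or j in idx)]
    return float(np.mean(w)) if w else 0.0


def _pairwise_t(groups: dict[str, np.ndarray], labels: tuple[str, str, str]) -> dict[str, float]:
    """Post-hoc pairwise Student t-tests, Bonferroni-corrected within the trio."""
    a, b, c = labels
    pairs = {f"{a}_vs_{b}": (a, b), f"{b}_vs_{c}": (b, c), f"{a}_vs_{c}": (a, c)}
    out = {}
    for key, (g1, g2) in pairs.items():
        with warnings.catch_warnings():
            # near-constant metrics (e.g. saturated degree) trip scipy's
            # catastrophic-cancellation warning; the NaN fallback below covers it
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(groups[g1], groups[g2], equal_var=True)
        p = float(res.pvalue)
        if not np.isfinite(p):  # both groups constant and equal
            p = 1.0
        out[key] = bonferroni(p, 3)
    return out


def compare_bands(
    table: pd.DataFrame,
    parameters: tuple[str, ...],
    m: int,
    group_order: tuple[str, str, str] = ("impaired", "non_impaired", "control"),
    gate_warnings: bool = True,
) -> list[ComparisonResult]:
    """Per band x parameter one-way ANOVA across groups with Bonferroni.

    *table* has one row per subject x band with a ``group`` and ``band``
    column plus one column per parameter; *m* is the Bonferroni family size
    (use :func:`correction_count`). KS-normality and Levene gates emit
    warnings only.
    """
    results = []
    for band in pd.unique(table["band"]):
        sub = table[table["band"] == band]
        for param in parameters:
            groups = {g: sub.loc[sub["group"] == g, param].to_numpy(dtype=float) for g in group_order}
            if any(len(v) < 2 for v in groups.values()):
                raise ValueError(f"band {band}, parameter {param}: every group needs n >= 2")
            if gate_warnings:
                try:
                    lev = homogeneity_levene(*groups.values())
                    if lev["p"] < 0.05:
                        warnings.warn(
                            f"{band}/{param}: Levene p={lev['p']:.3g} (heterogeneous variances)",
                            stacklevel=2,
                        )
                except ValueError:
                    pass
            res = anova_oneway(*groups.values())
            results.append(
                ComparisonResult(
                    band=str(band),
                    parameter=param,
                    F=res["F"],
                    p_raw=res["p_raw"],
                    p_bonferroni=bonferroni(res["p_raw"], m),
                    group_means={g: float(v.mean()) for g, v in groups.items()},
                    pairwise_p=_pairwise_t(groups, group_order),
                )
            )
    return results


def roc_table(predictors: dict[str, np.ndarray], labels) -> pd.DataFrame:
    """ROC metrics for several predictors, one row each (AUC, sens/spec/acc %)."""
    rows = []
    for name, x in predictors.items():
        r = roc_analysis(x, labels, name=name)
        rows.append(
            {
                "indicator": name,
                "auc": r.auc,
                "sensitivity_pct": r.sensitivity,
                "specificity_pct": r.specificity,
                "accuracy_pct": r.accuracy,
                "cutoff": r.cutoff,
            }
        )
    return pd.DataFrame(rows)
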