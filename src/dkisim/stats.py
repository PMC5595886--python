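"""Group-discrimination and agreement statistics.

Implements the statistical layer of the analysis: two-sample Student
t-tests on ROI values, empirical ROC analysis with Youden-index optimal
thresholds and DeLong AUC inference, DeLong comparison of paired AUCs
(significance at alpha = 0.0167 for the three pairwise marker
comparisons), two-way intraclass correlation coefficients for intra- and
inter-observer agreement, and Pearson/Spearman correlations with the
conventional strength categories (little/none <= 0.24, fair 0.25-0.49,
moderate/good 0.5-0.74, good/excellent 0.75-1.0, on |r|).

AUC variance and the paired-AUC test use DeLong's placement-value
estimator; sensitivity/specificity confidence intervals are exact
Clopper-Pearson; the AUC confidence interval is DeLong-based on the logit
scale.  t-tests and correlations delegate to scipy, ICC to pingouin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AucComparison",
    "CorrelationResult",
    "GroupComparison",
    "IccResult",
    "RocResult",
    "agreement_band",
    "correlate",
    "correlation_category",
    "ddct_fold_change",
    "delong_compare",
    "empirical_auc",
    "icc",
    "roc_analysis",
    "stats_report",
    "t_test_groups",
]

AUC_COMPARISON_ALPHA = 0.0167  # Bonferroni-style level for 3 pairwise AUC tests


# ---------------------------------------------------------------- t-test


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    p_value: float


def t_test_groups(
    values_a,
    values_b,
    parameter: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Two-sided two-sample Student t-test (pooled variance by default).

    Each argument is either a sample vector or a ``(mean, sd, n)`` summary
    triple; the two forms may be mixed.
    """

    def as_summary(v):
        v = np.asarray(v, dtype=float)
        if v.shape == (3,) and v[2] == round(v[2]) and v[2] >= 2:
            return float(v[0]), float(v[1]), int(v[2])
        if v.size < 2:
            raise ValueError("each group needs n >= 2")
        return float(v.mean()), float(v.std(ddof=1)), int(v.size)

    ma, sa, na = as_summary(values_a)
    mb, sb, nb = as_summary(values_b)
    if sa == 0 and sb == 0:
        raise ValueError("zero variance in both groups")
    t, p = sps.ttest_ind_from_stats(
        ma, sa, na, mb, sb, nb, equal_var=not welch
    )
    return GroupComparison(
        parameter=parameter,
        mean_a=ma, sd_a=sa, n_a=na,
        mean_b=mb, sd_b=sb, n_b=nb,
        t_stat=float(t), p_value=float(p),
    )


# ------------------------------------------------------------------ ROC


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci_95: tuple[float, float]
    threshold: float
    direction: str  # 'greater': positive if score > threshold; 'less': <=
    sensitivity: float
    sensitivity_ci_95: tuple[float, float]
    specificity: float
    specificity_ci_95: tuple[float, float]
    p_vs_half: float
    auc_se: float


def _check_two_class(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if not labels.any() or labels.all():
        raise ValueError("both classes must be present")
    return labels


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values via midranks (O(N log N)).

    For positive i: V10_i = (overall midrank - within-positive midrank) / n;
    symmetrically for negatives.  Ties get half credit.
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    tr = sps.rankdata(np.concatenate([pos, neg]))
    rp = sps.rankdata(pos)
    rn = sps.rankdata(neg)
    v10 = (tr[:m] - rp) / n
    v01 = 1.0 - (tr[m:] - rn) / m
    return v10, v01


def empirical_auc(scores, labels, positive_direction: str = "greater") -> float:
    """Mann-Whitney empirical AUC with half-credit for ties.

    ``positive_direction='greater'`` treats higher scores as more
    positive-like; ``'less'`` treats lower scores as more positive-like
    (equivalently, the AUC of the negated scores).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    if positive_direction == "less":
        scores = -scores
    elif positive_direction != "greater":
        raise ValueError("positive_direction must be 'greater' or 'less'")
    v10, _ = _placements(scores, labels)
    return float(v10.mean())


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_analysis(
    scores,
    labels,
    positive_direction: str = "greater",
) -> RocResult:
    """Empirical ROC analysis of one marker.

    The operating threshold maximises the Youden index (sensitivity +
    specificity - 1) over all observed score values; ties break to the
    threshold with higher sensitivity, then to the lower threshold value.
    ``labels`` flags the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    if positive_direction not in ("greater", "less"):
        raise ValueError("positive_direction must be 'greater' or 'less'")

    work = -scores if positive_direction == "less" else scores
    auc, var = _delong_variance(work, labels)
    se = float(np.sqrt(var))

    # logit-scale DeLong CI (degenerates gracefully at auc in {0, 1})
    if 0.0 < auc < 1.0 and se > 0:
        logit = np.log(auc / (1 - auc))
        half = 1.96 * se / (auc * (1 - auc))
        lo = 1 / (1 + np.exp(-(logit - half)))
        hi = 1 / (1 + np.exp(-(logit + half)))
    else:
        lo = hi = auc
    z = (auc - 0.5) / se if se > 0 else np.inf * np.sign(auc - 0.5)
    p_half = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0

    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    # vectorised exhaustive scan over all observed values as thresholds
    cand = np.unique(scores)
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    if positive_direction == "greater":
        sens = m - np.searchsorted(pos_sorted, cand, side="right")  # pos > t
        spec = np.searchsorted(neg_sorted, cand, side="right")  # neg <= t
    else:
        sens = np.searchsorted(pos_sorted, cand, side="right")  # pos <= t
        spec = n - np.searchsorted(neg_sorted, cand, side="right")  # neg > t
    sens = sens / m
    spec = spec / n
    youden = sens + spec - 1.0
    # max Youden; ties -> higher sensitivity, then lower threshold
    order = np.lexsort((cand, -sens, -youden))
    best = order[0]

    k_sens = int(round(sens[best] * m))
    k_spec = int(round(spec[best] * n))
    return RocResult(
        auc=auc,
        auc_ci_95=(float(lo), float(hi)),
        threshold=float(cand[best]),
        direction=positive_direction,
        sensitivity=float(sens[best]),
        sensitivity_ci_95=_clopper_pearson(k_sens, m),
        specificity=float(spec[best]),
        specificity_ci_95=_clopper_pearson(k_spec, n),
        p_vs_half=p_half,
        auc_se=se,
    )


@dataclass(frozen=True)
class AucComparison:
    pair: tuple[str, str]
    auc_x: float
    auc_y: float
    auc_difference: float
    z_stat: float
    p_value: float
    alpha: float = AUC_COMPARISON_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def delong_compare(
    scores_x,
    scores_y,
    labels,
    direction_x: str = "greater",
    direction_y: str = "greater",
    names: tuple[str, str] = ("x", "y"),
) -> AucComparison:
    """DeLong test for two correlated AUCs measured on the same subjects.

    Placement-value covariance of the paired empirical AUCs; two-sided
    normal test on the AUC difference.
    """
    x = np.asarray(scores_x, dtype=float)
    y = np.asarray(scores_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired score vectors must have equal length")
    labels = _check_two_class(labels)
    if direction_x == "less":
        x = -x
    if direction_y == "less":
        y = -y

    v10x, v01x = _placements(x, labels)
    v10y, v01y = _placements(y, labels)
    auc_x, auc_y = float(v10x.mean()), float(v10y.mean())
    m, n = len(v10x), len(v01x)

    def cov(a, b):
        return float(np.cov(a, b, ddof=1)[0, 1]) if len(a) > 1 else 0.0

    var = (
        cov(v10x, v10x) / m + cov(v01x, v01x) / n
        + cov(v10y, v10y) / m + cov(v01y, v01y) / n
        - 2 * cov(v10x, v10y) / m - 2 * cov(v01x, v01y) / n
    )
    diff = auc_x - auc_y
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else (1.0 if diff == 0 else 0.0)
    if diff == 0 and not np.isfinite(z):
        z, p = 0.0, 1.0
    return AucComparison(
        pair=names, auc_x=auc_x, auc_y=auc_y,
        auc_difference=diff, z_stat=float(z), p_value=p,
    )


# ------------------------------------------------------------------ ICC


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_95: tuple[float, float]
    design: str
    agreement_band: str


def agreement_band(value: float) -> str:
    if value > 0.8:
        return "excellent"
    if value >= 0.6:
        return "substantial"
    return "lower"


def icc(table, design: str = "ICC2") -> IccResult:
    """Intraclass correlation of a complete targets x raters table.

    ``table`` is wide: one row per target, one column per rater/repeat.
    ``design`` is a pingouin ICC type: ICC1/ICC2/ICC3 (single measurement)
    or ICC1k/ICC2k/ICC3k (average of the k columns).  The default ICC2 is
    the two-way random-effects absolute-agreement single-measurement
    coefficient.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a complete 2D targets x raters layout")
    if np.isnan(arr).any():
        raise ValueError("incomplete layout (NaN entries)")
    if np.allclose(arr, arr[:, [0]]):
        return IccResult(icc=1.0, ci_95=(1.0, 1.0), design=design,
                         agreement_band="excellent")

    import pingouin as pg

    # our design names -> pingouin/McGraw-Wong type labels
    type_map = {
        "ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)",
        "ICC1k": "ICC(1,k)", "ICC2k": "ICC(A,k)", "ICC3k": "ICC(C,k)",
    }
    if design not in type_map:
        raise ValueError(f"unknown ICC design {design!r}")
    long = pd.DataFrame(arr).reset_index().melt(
        id_vars="index", var_name="rater", value_name="rating"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(
            data=long, targets="index", raters="rater", ratings="rating"
        )
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    row = res[res["Type"] == type_map[design]].iloc[0]
    value = float(row["ICC"])
    ci = tuple(float(v) for v in row[ci_col])
    return IccResult(icc=value, ci_95=ci, design=design,
                     agreement_band=agreement_band(value))


# --------------------------------------------------------- correlations


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p_value: float
    category: str


def correlation_category(r: float) -> str:
    a = abs(r)
    if a <= 0.24:
        return "little/none"
    if a <= 0.49:
        return "fair"
    if a <= 0.74:
        return "moderate/good"
    return "good/excellent"


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with two-sided p-value and the
    conventional |r| strength category."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(
        method=method, r=float(r), p_value=float(p),
        category=correlation_category(float(r)),
    )


def ddct_fold_change(delta_delta_ct: float) -> float:
    """Relative expression fold change from qPCR: 2^(-ddCt)."""
    if not np.isfinite(delta_delta_ct):
        raise ValueError("ddCt must be finite")
    return float(2.0 ** (-delta_delta_ct))


# ----------------------------------------------------------- full report

PARAM_DIRECTIONS = {"adc": "less", "diffusivity": "less", "kurtosis": "greater"}
DIFFUSIVITY_SCALE = 1e3  # report D and ADC in 1e-3 mm2/s


def stats_report(
    consensus: pd.DataFrame,
    measurements: pd.DataFrame,
    histology: pd.DataFrame,
    positive_group: str = "emt",
) -> dict:
    """Assemble the full statistics report from the measurement tables.

    ``consensus`` has one row per tumor with columns group/adc/diffusivity/
    kurtosis; ``measurements`` is the long observer x repeat table;
    ``histology`` has one row per tumor with cellularity/ki67/ecadherin.
    Diffusion parameters are reported in 1e-3 mm2/s.
    """
    df = consensus.copy()
    for c in ("adc", "diffusivity"):
        df[c] = df[c] * DIFFUSIVITY_SCALE
    labels = (df["group"] == positive_group).to_numpy()
    groups = sorted(df["group"].unique(), key=lambda g: g == positive_group)

    report: dict = {"groups": groups, "positive_group": positive_group}

    comparisons = {}
    for p in ("adc", "diffusivity", "kurtosis"):
        a = df.loc[df["group"] == groups[0], p].to_numpy()
        b = df.loc[df["group"] == groups[1], p].to_numpy()
        try:
            c = t_test_groups(a, b, parameter=p)
            t_stat, p_val = c.t_stat, c.p_value
        except ValueError:
            # degenerate (noise-free, spread-free) cohorts: separation limit
            t_stat = 0.0 if a.mean() == b.mean() else float(np.inf) * np.sign(a.mean() - b.mean())
            p_val = 1.0 if a.mean() == b.mean() else 0.0
        comparisons[p] = {
            f"{groups[0]}_mean": float(a.mean()), f"{groups[0]}_sd": float(a.std(ddof=1)),
            f"{groups[1]}_mean": float(b.mean()), f"{groups[1]}_sd": float(b.std(ddof=1)),
            "t": t_stat, "p": p_val,
        }
    report["group_comparison"] = comparisons

    rocs = {}
    roc_objects = {}
    for p, direction in PARAM_DIRECTIONS.items():
        r = roc_analysis(df[p].to_numpy(), labels, positive_direction=direction)
        roc_objects[p] = r
        rocs[p] = {
            "auc": r.auc, "auc_ci_95": list(r.auc_ci_95),
            "threshold": r.threshold, "direction": direction,
            "sensitivity_pct": 100 * r.sensitivity,
            "sensitivity_ci_95_pct": [100 * v for v in r.sensitivity_ci_95],
            "specificity_pct": 100 * r.specificity,
            "specificity_ci_95_pct": [100 * v for v in r.specificity_ci_95],
            "p_vs_half": r.p_vs_half,
        }
    report["roc"] = rocs

    pairs = [("adc", "diffusivity"), ("adc", "kurtosis"), ("diffusivity", "kurtosis")]
    report["auc_comparisons"] = {
        f"{a}_vs_{b}": {
            "auc_difference": cmp.auc_difference,
            "z": cmp.z_stat, "p": cmp.p_value,
            "alpha": cmp.alpha, "significant": cmp.significant,
        }
        for a, b in pairs
        for cmp in [
            delong_compare(
                df[a].to_numpy(), df[b].to_numpy(), labels,
                direction_x=PARAM_DIRECTIONS[a], direction_y=PARAM_DIRECTIONS[b],
                names=(a, b),
            )
        ]
    }

    icc_table = {}
    for p in ("adc", "diffusivity", "kurtosis"):
        wide = measurements.pivot_table(
            index="tumor_id", columns=["observer", "repeat"], values=p
        )
        entries = {}
        for obs in (1, 2):
            sub = wide[obs].to_numpy()
            r = icc(sub)
            entries[f"intra_observer_{obs}"] = {
                "icc": r.icc, "ci_95": list(r.ci_95), "band": r.agreement_band,
            }
        inter = np.column_stack([wide[(1, 1)].to_numpy(), wide[(2, 1)].to_numpy()])
        r = icc(inter)
        entries["inter_observer"] = {
            "icc": r.icc, "ci_95": list(r.ci_95), "band": r.agreement_band,
        }
        icc_table[p] = entries
    report["icc"] = icc_table

    hist = histology.set_index("tumor_id")
    joined = df.set_index("tumor_id").join(hist, rsuffix="_h")
    correlations = {}
    for p in ("adc", "diffusivity", "kurtosis"):
        entry = {}
        for cov, method in (
            ("cellularity", "pearson"),
            ("ki67", "spearman"),
            ("ecadherin", "spearman"),
        ):
            c = correlate(joined[p], joined[cov], method=method)
            entry[cov] = {
                "method": method, "r": c.r, "p": c.p_value, "category": c.category,
            }
        correlations[p] = entry
    report["histology_correlations"] = correlations
    return report
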