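"""Diagnostic-test evaluation battery for paired physiological indices.

Implements the statistics used to judge a computed pressure index against
invasive reference measurements on the same vessels:

* confusion counts and the five standard metrics (sensitivity,
  specificity, PPV, NPV, accuracy) with Clopper-Pearson exact binomial CIs,
* empirical ROC/AUC (Mann-Whitney, ties half-credit) with DeLong variance,
  and the paired DeLong test for comparing two correlated AUCs,
* Bland-Altman limits of agreement,
* Fisher r-to-z comparison of two correlation coefficients (plus a
  Steiger dependent-correlation variant),
* decision-curve analysis (net benefit against treat-all / treat-none).

Orientation convention: these indices fall with disease severity, so a
*lower* value is *positive*; classification uses cutoff-inclusive
positivity (value <= cutoff) and ROC scores are ``1 - value``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidParameterError


def round_half_up_percent(x: float) -> int:
    """Round a proportion to a whole percent, halves away from zero."""
    return int(math.floor(100.0 * x + 0.5))


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidParameterError("counts must be non-negative")
        if self.total == 0:
            raise InvalidParameterError("at least one pair is required")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with an exact (Clopper-Pearson) two-sided 95% CI."""

    value: float | None
    ci_low: float | None
    ci_high: float | None
    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.value is not None

    @property
    def percent(self) -> int | None:
        return None if self.value is None else round_half_up_percent(self.value)


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate
    accuracy: ProportionEstimate
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        out: dict = {"tp": self.counts.tp, "fp": self.counts.fp,
                     "fn": self.counts.fn, "tn": self.counts.tn}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m: ProportionEstimate = getattr(self, name)
            out[name] = {"value": m.value, "ci95": [m.ci_low, m.ci_high],
                         "percent": m.percent,
                         "k": m.numerator, "n": m.denominator}
        return out


def confusion_from_pairs(index_values, reference_values,
                         index_cutoff: float = 0.89,
                         reference_cutoff: float = 0.89) -> ConfusionCounts:
    """Cross-classify paired values; positive means value <= cutoff."""
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError(
            f"length mismatch: {x.shape[0]} index vs {y.shape[0]} reference")
    ip = x <= index_cutoff
    rp = y <= reference_cutoff
    return ConfusionCounts(tp=int(np.sum(ip & rp)), fp=int(np.sum(ip & ~rp)),
                           fn=int(np.sum(~ip & rp)), tn=int(np.sum(~ip & ~rp)))


def _proportion(k: int, n: int, alpha: float = 0.05) -> ProportionEstimate:
    if n == 0:
        return ProportionEstimate(None, None, None, k, n)
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    return ProportionEstimate(k / n, float(lo), float(hi), k, n)


def diagnostic_metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """The five standard metrics with exact binomial 95% CIs.

    A metric with a zero denominator is returned as undefined (value None),
    never as 0.
    """
    c = counts
    return DiagnosticMetrics(
        sensitivity=_proportion(c.tp, c.tp + c.fn),
        specificity=_proportion(c.tn, c.tn + c.fp),
        ppv=_proportion(c.tp, c.tp + c.fp),
        npv=_proportion(c.tn, c.tn + c.fn),
        accuracy=_proportion(c.tp + c.tn, c.total),
        counts=c,
    )


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    orientation: str = "lower index value indicates disease; score = 1 - index"


def _placement_values(scores_pos: np.ndarray, scores_neg: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive), V01 (per negative), AUC."""
    diff = scores_pos[:, None] - scores_neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def _split_scores(values, labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape:
        raise InvalidParameterError("values and labels must have equal length")
    if y.all() or (~y).all():
        raise InvalidParameterError("both classes must be present")
    scores = 1.0 - v
    return scores[y], scores[~y]


def auc_empirical(index_values, reference_labels) -> ROCResult:
    """Empirical ROC for a falling index against binary disease labels.

    AUC is the Mann-Whitney statistic (ties count one half); its standard
    error comes from the DeLong placement-value variance, and the 95% CI is
    the normal interval clipped to [0, 1].
    """
    sp, sn = _split_scores(index_values, reference_labels)
    v10, v01, auc = _placement_values(sp, sn)
    m, n = sp.size, sn.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = math.sqrt(var)
    z = stats.norm.ppf(0.975)
    thresholds = np.concatenate([[np.inf], np.unique(np.concatenate([sp, sn]))[::-1]])
    tpr = np.array([(sp >= t).mean() for t in thresholds])
    fpr = np.array([(sn >= t).mean() for t in thresholds])
    return ROCResult(auc=auc, se=se,
                     ci_low=max(0.0, auc - z * se),
                     ci_high=min(1.0, auc + z * se),
                     fpr=fpr, tpr=tpr)


@dataclass(frozen=True)
class DeLongComparison:
    auc_a: float
    auc_b: float
    z: float | None
    p_value: float | None

    @property
    def defined(self) -> bool:
        return self.z is not None


def delong_compare(index_a, index_b, reference_labels) -> DeLongComparison:
    """Paired DeLong test for two correlated AUCs on the same subjects.

    Uses the placement-value covariance of DeLong, DeLong & Clarke-Pearson
    (1988); returns z and a two-sided normal p.  A degenerate variance is
    flagged undefined rather than reported as z = 0/0.
    """
    sp_a, sn_a = _split_scores(index_a, reference_labels)
    sp_b, sn_b = _split_scores(index_b, reference_labels)
    v10a, v01a, auc_a = _placement_values(sp_a, sn_a)
    v10b, v01b, auc_b = _placement_values(sp_b, sn_b)
    m, n = sp_a.size, sn_a.size
    if m < 2 or n < 2:
        return DeLongComparison(auc_a, auc_b, None, None)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0:
        if auc_a == auc_b:
            return DeLongComparison(auc_a, auc_b, 0.0, 1.0)
        return DeLongComparison(auc_a, auc_b, None, None)
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongComparison(auc_a, auc_b, float(z), float(p))


# ---------------------------------------------------------------------------
# agreement and correlation comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(values_a, values_b) -> BlandAltmanResult:
    """Bias and 95% limits of agreement (bias +/- 1.96 * sd of differences)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("paired vectors must have equal length")
    if a.size < 2:
        raise InvalidParameterError("Bland-Altman needs n >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd,
                             loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd, n=a.size)


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    r2: float
    z: float
    p_value: float


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int
                     ) -> CorrelationComparison:
    """Compare two independent-sample correlations by Fisher r-to-z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); p two-sided.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise InvalidParameterError(f"|r| must be < 1, got {r}")
        if n <= 3:
            raise InvalidParameterError(f"n must exceed 3, got {n}")
    z = (math.atanh(r1) - math.atanh(r2)) / \
        math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(r1, r2, float(z), float(p))


def steiger_z_dependent(r12: float, r13: float, r23: float, n: int
                        ) -> CorrelationComparison:
    """Steiger's test for two dependent correlations sharing one variable.

    Compares r12 with r13 when both are measured on the same n subjects and
    the two comparators are themselves correlated r23.  Provided as an
    alternative to the independent-samples comparison; not used by default.
    """
    for r in (r12, r13, r23):
        if not abs(r) < 1:
            raise InvalidParameterError(f"|r| must be < 1, got {r}")
    if n <= 3:
        raise InvalidParameterError(f"n must exceed 3, got {n}")
    z12, z13 = math.atanh(r12), math.atanh(r13)
    rbar = (r12 + r13) / 2.0
    # Steiger (1980) eq. 14 covariance of the two z-transforms
    num = r23 * (1 - 2 * rbar ** 2) - 0.5 * rbar ** 2 * \
        (1 - 2 * rbar ** 2 - r23 ** 2)
    cov = num / (1 - rbar ** 2) ** 2
    z = (z12 - z13) * math.sqrt((n - 3) / (2.0 * (1 - cov)))
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(r12, r13, float(z), float(p))


# ---------------------------------------------------------------------------
# decision-curve analysis
# ---------------------------------------------------------------------------

@dataclass
class DCAResult:
    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray
    prevalence: float


def decision_curve(index_values, reference_labels, index_cutoff: float = 0.89,
                   thresholds=None) -> DCAResult:
    """Net benefit of the <=-cutoff classifier across threshold probabilities.

    NB(pt) = TP/n - (FP/n) * pt/(1-pt), with TP/FP from the fixed cutoff
    rule; treat-all NB = prevalence - (1-prevalence)*pt/(1-pt); treat-none
    is identically zero.
    """
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    pt = np.asarray(thresholds, dtype=float)
    if np.any((pt <= 0) | (pt >= 1)):
        raise InvalidParameterError("thresholds must lie strictly in (0, 1)")
    v = np.asarray(index_values, dtype=float)
    y = np.asarray(reference_labels, dtype=bool)
    if v.shape != y.shape:
        raise InvalidParameterError("values and labels must have equal length")
    n = v.size
    pos = v <= index_cutoff
    tp = float(np.sum(pos & y))
    fp = float(np.sum(pos & ~y))
    prev = float(y.mean())
    w = pt / (1.0 - pt)
    return DCAResult(
        thresholds=pt,
        net_benefit_model=tp / n - (fp / n) * w,
        net_benefit_all=prev - (1.0 - prev) * w,
        net_benefit_none=np.zeros_like(pt),
        prevalence=prev,
    )


def net_benefit_from_counts(tp: int, fp: int, n: int, pt: float) -> float:
    """Net benefit from raw counts at one threshold probability."""
    if not 0 < pt < 1:
        raise InvalidParameterError("threshold probability must be in (0, 1)")
    return tp / n - (fp / n) * pt / (1.0 - pt)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def evaluate_pairs(index_values, reference_values, reference_cutoff: float,
                   index_cutoff: float = 0.89,
                   dca_thresholds=None) -> dict:
    """Run the whole battery of one index against one invasive reference.

    Returns a JSON-serializable report: confusion counts + metrics with
    CIs, AUC with DeLong CI, Bland-Altman agreement, Pearson correlation,
    and the decision-curve table.
    """
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    counts = confusion_from_pairs(x, y, index_cutoff, reference_cutoff)
    metrics = diagnostic_metrics(counts)
    labels = y <= reference_cutoff
    report: dict = {
        "n": int(x.size),
        "index_cutoff": index_cutoff,
        "reference_cutoff": reference_cutoff,
        "metrics": metrics.as_dict(),
    }
    if labels.any() and not labels.all():
        roc = auc_empirical(x, labels)
        report["roc"] = {"auc": roc.auc, "se": roc.se,
                         "ci95": [roc.ci_low, roc.ci_high],
                         "orientation": roc.orientation}
        dca = decision_curve(x, labels, index_cutoff, dca_thresholds)
        report["dca"] = {
            "thresholds": dca.thresholds.tolist(),
            "net_benefit_model": dca.net_benefit_model.tolist(),
            "net_benefit_all": dca.net_benefit_all.tolist(),
            "prevalence": dca.prevalence,
        }
    ba = bland_altman(x, y)
    report["bland_altman"] = {"bias": ba.bias, "sd": ba.sd,
                              "loa": [ba.loa_low, ba.loa_high]}
    if x.size > 3 and np.std(x) > 0 and np.std(y) > 0:
        r, p = stats.pearsonr(x, y)
        report["correlation"] = {"pearson_r": float(r), "p_value": float(p)}
    return report
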