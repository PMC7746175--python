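"""Held-out performance assessment of the recovery predictor.

Predicted and real NFHAS changes are compared four ways: a simple linear
regression of real on predicted change (its R measures fit quality), an
error histogram, a quadrant cross-classification of real vs predicted
direction of change (improve / not improve), and per-quadrant paired
t-tests contrasting baseline and follow-up kinematics (ROM, speed, ROM CV)
at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "QUADRANT_LABELS",
    "PairedTestResult",
    "RegressionFit",
    "EvaluationReport",
    "fit_performance_regression",
    "assign_quadrants",
    "paired_t_test",
    "error_histogram",
    "evaluate_predictions",
    "quadrant_paired_tests",
]

#: real-direction / predicted-direction quadrants, +1 = improvement.
QUADRANT_LABELS = ("1 1", "1 -1", "-1 1", "-1 -1")


@dataclass(frozen=True)
class RegressionFit:
    r: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test on pre vs post values of one kinematic variable.

    The primary mean difference is post - pre (positive = increase after
    rehabilitation); pre - post is carried alongside for comparability
    with conventions that report the opposite sign.
    """

    variable: str
    mean_difference: float  # post - pre
    mean_difference_pre_post: float  # pre - post
    standard_error: float
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    n_pairs: int
    zero_variance: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value outside [0, 1]")
        if not self.ci_low <= self.mean_difference <= self.ci_high:
            raise ValueError("CI must contain the mean difference")


@dataclass
class EvaluationReport:
    r: float
    slope: float
    intercept: float
    mse: float
    n: int
    quadrant_counts: dict[str, int]
    quadrant_percentages: dict[str, float]
    histogram_counts: list[int]
    histogram_edges: list[float]
    paired_tests: dict[str, list[dict]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def fit_performance_regression(
    predicted: np.ndarray, actual: np.ndarray
) -> RegressionFit:
    """Least-squares line of actual on predicted change; R is Pearson's r."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.size != a.size or p.size < 3:
        raise ValueError("need >= 3 (predicted, actual) pairs")
    if np.std(p) == 0 or np.std(a) == 0:
        raise ValueError("degenerate input: zero variance")
    fit = stats.linregress(p, a)
    return RegressionFit(r=float(fit.rvalue), slope=float(fit.slope), intercept=float(fit.intercept))


def assign_quadrants(
    real_changes: np.ndarray, predicted_changes: np.ndarray
) -> tuple[list[str], dict[str, float]]:
    """Cross-classify real vs predicted direction of NFHAS change.

    Improvement means change > 0; an exactly zero change counts as
    non-improvement.  Returns per-sample labels and the percentage of the
    sample in each quadrant (summing to 100).
    """
    real = np.asarray(real_changes, dtype=float)
    pred = np.asarray(predicted_changes, dtype=float)
    if real.size != pred.size or real.size == 0:
        raise ValueError("equal-length nonempty change vectors required")
    labels = [
        f"{1 if r > 0 else -1} {1 if p > 0 else -1}" for r, p in zip(real, pred)
    ]
    pct = {
        lab: 100.0 * labels.count(lab) / len(labels) for lab in QUADRANT_LABELS
    }
    return labels, pct


def paired_t_test(
    pre: np.ndarray, post: np.ndarray, alpha: float = 0.05, variable: str = ""
) -> PairedTestResult:
    """Two-sided paired t-test between pre- and post-rehabilitation values.

    Statistics are computed on the differences post - pre.  When the
    differences have zero variance the t statistic is infinite in the
    limit; the result is flagged and p reported as 0 for a nonzero mean
    difference (1 for identical pairs).
    """
    x = np.asarray(pre, dtype=float)
    y = np.asarray(post, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired test requires >= 2 pairs of equal length")
    d = y - x
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return PairedTestResult(
            variable=variable,
            mean_difference=mean,
            mean_difference_pre_post=-mean,
            standard_error=0.0,
            t_statistic=0.0 if mean == 0 else float(np.sign(mean) * np.inf),
            p_value=1.0 if mean == 0 else 0.0,
            ci_low=mean,
            ci_high=mean,
            n_pairs=n,
            zero_variance=True,
        )
    se = sd / np.sqrt(n)
    t_stat = mean / se
    p = 2.0 * stats.t.sf(abs(t_stat), n - 1)
    half = stats.t.ppf(1 - alpha / 2, n - 1) * se
    return PairedTestResult(
        variable=variable,
        mean_difference=mean,
        mean_difference_pre_post=-mean,
        standard_error=float(se),
        t_statistic=float(t_stat),
        p_value=float(min(p, 1.0)),
        ci_low=mean - float(half),
        ci_high=mean + float(half),
        n_pairs=n,
    )


def error_histogram(
    predictions: np.ndarray, targets: np.ndarray, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of prediction - target over the observed range."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    errors = np.asarray(predictions, dtype=float) - np.asarray(targets, dtype=float)
    lo, hi = float(errors.min()), float(errors.max())
    if lo == hi:  # all errors identical: widen to a unit band around them
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(errors, bins=n_bins, range=(lo, hi))
    return counts, edges


def quadrant_paired_tests(
    labels: list[str],
    pre_values: dict[str, np.ndarray],
    post_values: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> dict[str, list[PairedTestResult]]:
    """Paired t-tests per quadrant group for each kinematic variable.

    ``pre_values``/``post_values`` map variable names (e.g. "rom_F") to
    per-patient vectors aligned with ``labels``.  Groups with fewer than
    two members are skipped.
    """
    labels_arr = np.asarray(labels)
    out: dict[str, list[PairedTestResult]] = {}
    for quadrant in QUADRANT_LABELS:
        mask = labels_arr == quadrant
        if mask.sum() < 2:
            continue
        results = []
        for var in pre_values:
            results.append(
                paired_t_test(
                    pre_values[var][mask], post_values[var][mask], alpha, variable=var
                )
            )
        out[quadrant] = results
    return out


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (extra output; tests use raw alpha)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def evaluate_predictions(
    predicted: np.ndarray,
    actual: np.ndarray,
    n_bins: int = 20,
    paired_tests: dict[str, list[PairedTestResult]] | None = None,
) -> EvaluationReport:
    """Assemble the full report for one set of held-out predictions."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    fit = fit_performance_regression(predicted, actual)
    labels, pct = assign_quadrants(actual, predicted)
    counts, edges = error_histogram(predicted, actual, n_bins)
    report = EvaluationReport(
        r=fit.r,
        slope=fit.slope,
        intercept=fit.intercept,
        mse=float(np.mean((predicted - actual) ** 2)),
        n=predicted.size,
        quadrant_counts={lab: labels.count(lab) for lab in QUADRANT_LABELS},
        quadrant_percentages=pct,
        histogram_counts=counts.tolist(),
        histogram_edges=edges.tolist(),
    )
    if paired_tests:
        report.paired_tests = {
            quad: [asdict(r) for r in results] for quad, results in paired_tests.items()
        }
    return report
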