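"""Evaluation statistics for adhesion metrics.

Cohen's kappa with an asymptotic confidence interval, the Mann-Whitney
AUC, DeLong's paired ROC comparison, and the two-way random-effects
intraclass correlation ICC(2,1) used to assess robustness of the
adhesion percentage to independent tumor delineations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass
class ContingencyTable:
    """Square k x k table of paired categorical ratings."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contingency table must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("contingency table is empty")


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    p_observed: float
    p_expected: float


@dataclass
class PairedScores:
    """Two scores per case plus the binary condition-of-interest label."""

    labels: np.ndarray
    scores_a: np.ndarray
    scores_b: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(bool)
        self.scores_a = np.asarray(self.scores_a, dtype=float)
        self.scores_b = np.asarray(self.scores_b, dtype=float)
        if not (len(self.labels) == len(self.scores_a) == len(self.scores_b)):
            raise ValueError("labels and score vectors must have equal length")
        if self.labels.all() or not self.labels.any():
            raise ValueError("both classes must be present")


def cohens_kappa(table: ContingencyTable, col_mapping: list[int] | None = None) -> KappaResult:
    """Unweighted Cohen's kappa with the Fleiss-Cohen-Everitt SE.

    kappa = (P_o - P_e) / (1 - P_e) with P_o the diagonal proportion
    and P_e the chance agreement from the margins. ``col_mapping``
    optionally re-pairs categories: column ``col_mapping[i]`` counts as
    agreement with row i (default: same-index diagonal, i.e. the table
    layout defines the pairing). The 95% CI is kappa +/- 1.96 SE with
    the asymptotic variance of Fleiss, Cohen & Everitt (1969).
    """
    counts = table.counts
    k = counts.shape[0]
    if col_mapping is not None:
        if sorted(col_mapping) != list(range(k)):
            raise ValueError("col_mapping must be a permutation of the column indices")
        counts = counts[:, col_mapping]
    n = counts.sum()
    p = counts / n
    pi = p.sum(axis=1)  # row margins
    pj = p.sum(axis=0)  # column margins
    po = float(np.trace(p))
    pe = float(pi @ pj)
    if pe >= 1.0:
        raise ValueError("degenerate margins: expected agreement is 1")
    kappa = (po - pe) / (1.0 - pe)

    t1 = sum(p[i, i] * ((1 - pe) - (pi[i] + pj[i]) * (1 - po)) ** 2 for i in range(k))
    t2 = (1 - po) ** 2 * sum(
        p[i, j] * (pj[i] + pi[j]) ** 2 for i in range(k) for j in range(k) if i != j
    )
    t3 = (po * pe - 2 * pe + po) ** 2
    var = (t1 + t2 - t3) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    return KappaResult(
        kappa=float(kappa),
        se=se,
        ci95=(float(kappa - 1.96 * se), float(kappa + 1.96 * se)),
        p_observed=po,
        p_expected=pe,
    )


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic.

    AUC = (#{pos > neg} + 0.5 * #ties) / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))


def _delong_structural(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the DeLong structural components V10 (per positive) and
    V01 (per negative)."""
    cmp_ = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_.mean(axis=1)
    v01 = cmp_.mean(axis=0)
    return float(cmp_.mean()), v10, v01


def delong_test(inp: PairedScores) -> dict:
    """DeLong's test for two correlated AUCs on the same cases.

    Estimates var(AUC_a), var(AUC_b) and their covariance from the
    structural components, then z = (AUC_a - AUC_b) / sd(difference)
    against the standard normal (two-sided). A zero-variance difference
    (e.g. identical score vectors) is flagged degenerate with z = 0,
    p = 1.
    """
    lab = inp.labels
    m, n = int(lab.sum()), int((~lab).sum())
    auc = np.empty(2)
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for i, s in enumerate((inp.scores_a, inp.scores_b)):
        auc[i], v10[i], v01[i] = _delong_structural(s[lab], s[~lab])
    s10 = np.cov(v10)  # 2x2, ddof=1
    s01 = np.cov(v01)
    cov_auc = s10 / m + s01 / n
    var_diff = cov_auc[0, 0] + cov_auc[1, 1] - 2 * cov_auc[0, 1]
    degenerate = var_diff <= 0
    if degenerate:
        z, p = 0.0, 1.0
    else:
        z = float((auc[0] - auc[1]) / np.sqrt(var_diff))
        p = float(2 * norm.sf(abs(z)))
    return {
        "auc_a": float(auc[0]),
        "auc_b": float(auc[1]),
        "var_a": float(cov_auc[0, 0]),
        "var_b": float(cov_auc[1, 1]),
        "cov_ab": float(cov_auc[0, 1]),
        "z": z,
        "p": p,
        "degenerate": bool(degenerate),
    }


def icc_two_way(measurements) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measure.

    From the two-way ANOVA mean squares of an n-subject x m-rater grid:

        ICC = (MS_R - MS_E) /
              (MS_R + (m - 1) MS_E + (m / n)(MS_C - MS_E))

    with MS_R the between-subject, MS_C the between-rater and MS_E the
    residual mean square. Absolute agreement: a constant rater offset
    lowers the ICC (unlike the consistency form).
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n>=2 subjects x m>=2 raters grid")
    if not np.isfinite(x).all():
        raise ValueError("missing entries are not supported")
    n, m = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = m * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 0:
        raise ValueError("zero total variance")
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (m - 1)
    ms_e = ss_err / ((n - 1) * (m - 1))
    return float((ms_r - ms_e) / (ms_r + (m - 1) * ms_e + (m / n) * (ms_c - ms_e)))
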