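"""The four geographical detectors for spatial stratified heterogeneity.

Heterogeneity of a numeric outcome ``y`` over a categorical partition of the
records is measured by the q statistic,

    q = 1 - SSW / SST,        SSW = sum_h N_h * sigma_h^2,   SST = N * sigma^2,

with population variances (divisor ``N_h`` resp. ``N``) so that the
within/total form and the stratum-variance form coincide exactly.  q is the
share of the total variance explained by the stratification: 0 means the
partition carries no information about y, 1 means y is constant within every
stratum.

Four detectors build on this:

* **factor detector** — q of a single factor's partition plus a significance
  test (seeded permutation by default, analytic noncentral-F as cross-check);
* **risk (influence) detector** — pairwise Welch t comparisons of stratum
  means to locate high-risk strata;
* **ecological detector** — an F ratio of two factors' within-strata variance
  sums, asking which factor explains more;
* **interaction detector** — q of the overlay (common refinement) of two
  factors, classified against the individual q values and their sum into
  weaken / enhance / independent / nonlinear-enhance types.

Both functional entry points (:func:`compute_q`, :func:`risk_detector`, ...)
and scikit-learn style estimators (:class:`FactorDetector`, ...) are provided;
the estimators wrap the functions and expose fitted attributes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .records import Stratification, stratification_from_labels

__all__ = [
    "QResult",
    "RiskComparison",
    "EcoResult",
    "InteractionResult",
    "compute_q",
    "q_significance",
    "risk_detector",
    "ecological_detector",
    "overlay",
    "classify_interaction",
    "interaction_detector",
    "explained_share",
    "WEAKEN_NONLINEAR",
    "WEAKEN_SINGLE",
    "ENHANCE_BI",
    "INDEPENDENT",
    "ENHANCE_NONLINEAR",
    "INTERACTION_TYPES",
    "FactorDetector",
    "RiskDetector",
    "EcologicalDetector",
    "InteractionDetector",
]

# Interaction type labels, named as the field names them.
WEAKEN_NONLINEAR = "Weaken, nonlinear"
WEAKEN_SINGLE = "Weaken, single"
ENHANCE_BI = "Enhance, bi"
INDEPENDENT = "Independent"
ENHANCE_NONLINEAR = "Enhance, nonlinear"
INTERACTION_TYPES = (
    WEAKEN_NONLINEAR,
    WEAKEN_SINGLE,
    ENHANCE_BI,
    INDEPENDENT,
    ENHANCE_NONLINEAR,
)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class StratumStat:
    label: str
    n: int
    mean: float
    variance: float  # population variance (divisor n)


@dataclass
class QResult:
    """q value with its variance-decomposition parts."""

    q: float
    sst: float
    ssw: float
    per_stratum: list[StratumStat]
    n_used: int
    degenerate: bool = False        # SST == 0 (constant outcome)
    p_value: float | None = None

    @property
    def explained_percent(self) -> float:
        """The q value expressed as the percent of heterogeneity explained."""
        return explained_share(self.q)

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "sst": self.sst,
            "ssw": self.ssw,
            "n_used": self.n_used,
            "degenerate": self.degenerate,
            "p_value": self.p_value,
            "per_stratum": [
                {"label": s.label, "n": s.n, "mean": s.mean, "variance": s.variance}
                for s in self.per_stratum
            ],
        }


@dataclass
class PairComparison:
    stratum_a: str
    stratum_b: str
    mean_a: float
    mean_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool


@dataclass
class RiskComparison:
    """All pairwise Welch comparisons of stratum means for one factor."""

    pairs: list[PairComparison]
    confidence: float

    def significant_pairs(self) -> list[PairComparison]:
        return [p for p in self.pairs if p.significant]

    def to_dict(self) -> dict:
        return {
            "confidence": self.confidence,
            "pairs": [vars(p) for p in self.pairs],
        }


@dataclass
class EcoResult:
    """F comparison of two factors' within-strata variance sums."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    dominant: str                    # source name of stronger factor, or "tie"
    ssw_a: float
    ssw_b: float

    def to_dict(self) -> dict:
        return vars(self).copy()


@dataclass
class InteractionResult:
    """q values of two factors and their overlay, with the interaction type."""

    q_a: float
    q_b: float
    q_ab: float
    type_label: str
    q_sum: float = field(init=False)

    def __post_init__(self):
        self.q_sum = self.q_a + self.q_b

    def to_dict(self) -> dict:
        return {
            "q_a": self.q_a,
            "q_b": self.q_b,
            "q_ab": self.q_ab,
            "q_sum": self.q_sum,
            "type_label": self.type_label,
        }


def explained_share(q: float) -> float:
    """Percent of outcome heterogeneity explained by a stratification (100*q)."""
    return 100.0 * q


# ---------------------------------------------------------------------------
# Factor detector
# ---------------------------------------------------------------------------

def _as_strat(strat) -> Stratification:
    if isinstance(strat, Stratification):
        return strat
    return stratification_from_labels(strat)


def _aligned(values, strat: Stratification) -> tuple[np.ndarray, np.ndarray]:
    """Select and validate the outcome values covered by the stratification."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if strat.n == 0:
        raise ValueError("stratification covers no records")
    if strat.index.max(initial=-1) >= len(values):
        raise ValueError("stratification indexes beyond the values array")
    y = values[strat.index]
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite outcome values")
    return y, strat.labels.astype(str)


def _group_stats(y: np.ndarray, labels: np.ndarray):
    """Per-stratum (labels, counts, sums, sums of squares) via one sort."""
    order = np.argsort(labels, kind="stable")
    ys = y[order]
    ls = labels[order]
    uniq, starts, counts = np.unique(ls, return_index=True, return_counts=True)
    sums = np.add.reduceat(ys, starts)
    sqs = np.add.reduceat(ys * ys, starts)
    return uniq, counts, sums, sqs


def compute_q(values, strat) -> QResult:
    """The q statistic of a stratification: the explained variance share.

    Uses population variances throughout, so ``q = 1 - ssw/sst`` with
    ``sst = N*sigma^2`` and ``ssw = sum_h N_h*sigma_h^2``.  A constant outcome
    (``sst == 0``) yields q = 0 with the ``degenerate`` flag set.
    """
    strat = _as_strat(strat)
    y, labels = _aligned(values, strat)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 records to decompose variance")
    uniq, counts, sums, sqs = _group_stats(y, labels)
    means = sums / counts
    variances = sqs / counts - means**2
    variances = np.maximum(variances, 0.0)          # guard tiny negatives
    sst = float(np.sum(y * y) - n * y.mean() ** 2)
    sst = max(sst, 0.0)
    ssw = float(np.sum(counts * variances))
    per = [
        StratumStat(str(l), int(c), float(m), float(v))
        for l, c, m, v in zip(uniq, counts, means, variances)
    ]
    if sst <= 0.0:
        return QResult(q=0.0, sst=sst, ssw=0.0, per_stratum=per, n_used=n,
                       degenerate=True)
    q = 1.0 - ssw / sst
    q = float(min(max(q, 0.0), 1.0))
    return QResult(q=q, sst=sst, ssw=ssw, per_stratum=per, n_used=n)


def _permutation_pvalue(y, labels, q_obs, n_perm, rng) -> float:
    """p = (1 + #{q_perm >= q_obs}) / (1 + n_perm) under label shuffling.

    Exploits that for fixed y the permutation only changes the stratum sums:
    q_perm = (sum_h S_h^2/N_h - N*ybar^2) / SST, so only group sums of
    permuted y are needed.  Vectorised over all permutations at once.
    """
    n = len(y)
    _, counts, _, _ = _group_stats(y, labels)
    sst = np.sum(y * y) - n * y.mean() ** 2
    # permute y rows; group boundaries fixed by sorting labels once
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    perms = np.empty((n_perm, n), dtype=float)
    for i in range(n_perm):
        perms[i] = y[rng.permutation(n)]
    gsums = np.add.reduceat(perms, starts, axis=1)
    ssb = (gsums**2 / counts).sum(axis=1) - n * y.mean() ** 2
    q_perm = ssb / sst
    exceed = int(np.sum(q_perm >= q_obs - 1e-12))
    return (1 + exceed) / (1 + n_perm)


def _ncf_pvalue(y, labels) -> float:
    """Analytic q-transform test: F = (N-H)/(H-1) * q/(1-q) compared with a
    noncentral F(H-1, N-H, lambda) distribution (the standard analytic test
    in the geographical-detector literature)."""
    n = len(y)
    uniq, counts, sums, _ = _group_stats(y, labels)
    h = len(uniq)
    if h < 2 or n - h < 1:
        return 1.0
    res = compute_q_from_arrays(y, labels)
    q = res.q
    if q >= 1.0:
        return 0.0
    f_val = (n - h) / (h - 1) * q / (1 - q)
    means = sums / counts
    sigma2 = y.var()           # population variance
    if sigma2 <= 0:
        return 1.0
    lam = (np.sum(means**2) -
           (np.sum(np.sqrt(counts) * means)) ** 2 / n) / sigma2
    return float(stats.ncf.sf(f_val, h - 1, n - h, lam))


def compute_q_from_arrays(y: np.ndarray, labels: np.ndarray) -> QResult:
    """q directly from aligned value/label arrays (no index selection)."""
    return compute_q(y, stratification_from_labels(labels))


def q_significance(values, strat, method: str = "permutation",
                   n_perm: int = 999, seed: int | None = None) -> float:
    """Significance of an observed q value.

    ``method="permutation"`` (default) randomly relabels records and reports
    the add-one permutation p-value; ``method="noncentral_f"`` applies the
    analytic noncentral-F transform test.  A degenerate decomposition
    (constant outcome) yields p = 1.
    """
    strat = _as_strat(strat)
    y, labels = _aligned(values, strat)
    res = compute_q_from_arrays(y, labels)
    if res.degenerate:
        return 1.0
    if method == "permutation":
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        return _permutation_pvalue(y, labels, res.q, n_perm, rng)
    if method == "noncentral_f":
        return _ncf_pvalue(y, labels)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Risk (influence) detector
# ---------------------------------------------------------------------------

def risk_detector(values, strat, confidence: float = 0.95,
                  fdr: bool = False) -> RiskComparison:
    """Pairwise Welch comparisons of stratum means.

    For every unordered pair of strata with at least 2 members each, computes
    Welch's t on the stratum means with Satterthwaite degrees of freedom and
    flags significance at the given confidence level (two-sided).  With
    ``fdr=True`` p-values are Benjamini-Hochberg adjusted before flagging.
    """
    strat = _as_strat(strat)
    y, labels = _aligned(values, strat)
    uniq, counts, sums, sqs = _group_stats(y, labels)
    means = sums / counts
    # sample variances (ddof=1) for the Welch statistic
    with np.errstate(invalid="ignore"):
        svar = (sqs - counts * means**2) / np.maximum(counts - 1, 1)
    svar = np.maximum(svar, 0.0)
    eligible = np.flatnonzero(counts >= 2)
    pairs: list[PairComparison] = []
    raw_p = []
    for i, j in itertools.combinations(eligible, 2):
        se2_i = svar[i] / counts[i]
        se2_j = svar[j] / counts[j]
        denom = np.sqrt(se2_i + se2_j)
        if denom == 0.0:
            t = 0.0 if means[i] == means[j] else np.inf * np.sign(means[i] - means[j])
            df = float(counts[i] + counts[j] - 2)
        else:
            t = (means[i] - means[j]) / denom
            df = (se2_i + se2_j) ** 2 / (
                se2_i**2 / (counts[i] - 1) + se2_j**2 / (counts[j] - 1)
            )
        p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        raw_p.append(p)
        pairs.append(
            PairComparison(
                stratum_a=str(uniq[i]), stratum_b=str(uniq[j]),
                mean_a=float(means[i]), mean_b=float(means[j]),
                t_statistic=float(t), degrees_of_freedom=float(df),
                p_value=p, significant=False,
            )
        )
    alpha = 1.0 - confidence
    if pairs:
        adj = stats.false_discovery_control(raw_p) if fdr else np.asarray(raw_p)
        for pair, p in zip(pairs, adj):
            pair.significant = bool(p <= alpha)
    return RiskComparison(pairs=pairs, confidence=confidence)


# ---------------------------------------------------------------------------
# Ecological detector
# ---------------------------------------------------------------------------

def ecological_detector(values, strat_a, strat_b,
                        confidence: float = 0.95) -> EcoResult:
    """Compare the explanatory strength of two factors by their SSW ratio.

    F = [N_a (N_b - 1) SSW_a] / [N_b (N_a - 1) SSW_b], referred to an
    F(N_a - 1, N_b - 1) distribution (two-sided).  When significant, the
    factor with the smaller within-strata variance sum dominates.
    """
    strat_a = _as_strat(strat_a)
    strat_b = _as_strat(strat_b)
    res_a = compute_q(values, strat_a)
    res_b = compute_q(values, strat_b)
    n_a, n_b = res_a.n_used, res_b.n_used
    name_a = "+".join(strat_a.source)
    name_b = "+".join(strat_b.source)
    if res_b.ssw == 0.0:
        return EcoResult(f_statistic=float("inf"), df_num=n_a - 1,
                         df_den=n_b - 1, p_value=0.0, dominant=name_b,
                         ssw_a=res_a.ssw, ssw_b=res_b.ssw)
    f = (n_a * (n_b - 1) * res_a.ssw) / (n_b * (n_a - 1) * res_b.ssw)
    dist = stats.f(n_a - 1, n_b - 1)
    p = float(2 * min(dist.cdf(f), dist.sf(f)))
    p = min(p, 1.0)
    alpha = 1.0 - confidence
    if p <= alpha:
        dominant = name_a if res_a.ssw < res_b.ssw else name_b
    else:
        dominant = "tie"
    return EcoResult(f_statistic=float(f), df_num=n_a - 1, df_den=n_b - 1,
                     p_value=p, dominant=dominant,
                     ssw_a=res_a.ssw, ssw_b=res_b.ssw)


# ---------------------------------------------------------------------------
# Interaction detector
# ---------------------------------------------------------------------------

def overlay(strat_a: Stratification, strat_b: Stratification) -> Stratification:
    """Superposition of two stratifications: the common refinement whose
    strata are the non-empty joint (a-label, b-label) cells, over the records
    covered by both."""
    strat_a = _as_strat(strat_a)
    strat_b = _as_strat(strat_b)
    common, ia, ib = np.intersect1d(strat_a.index, strat_b.index,
                                    return_indices=True)
    if len(common) == 0:
        raise ValueError("stratifications share no records")
    la = strat_a.labels[ia].astype(str)
    lb = strat_b.labels[ib].astype(str)
    labels = np.array([f"{a}&{b}" for a, b in zip(la, lb)], dtype=object)
    return Stratification(
        source=tuple(strat_a.source) + tuple(strat_b.source),
        index=common,
        labels=labels,
    )


def classify_interaction(q_a: float, q_b: float, q_ab: float,
                         tolerance: float = 1e-9) -> InteractionResult:
    """Classify an interaction from the three q values.

    Discriminants (in resolution order):

    * ``|q_ab - (q_a + q_b)| <= tolerance``   -> Independent
    * ``q_ab > q_a + q_b``                    -> Enhance, nonlinear
    * ``q_ab >= max(q_a, q_b)``               -> Enhance, bi
    * ``q_ab >= min(q_a, q_b)``               -> Weaken, single
    * otherwise                               -> Weaken, nonlinear

    Exact equality with the min or max resolves to the adjacent category
    nearer Independent, since the field's published rule uses strict
    inequalities and leaves boundaries undefined.
    """
    for name, q in (("q_a", q_a), ("q_b", q_b), ("q_ab", q_ab)):
        if not (0.0 <= q <= 1.0):
            raise ValueError(f"{name}={q} outside [0, 1]")
    q_sum = q_a + q_b
    lo, hi = min(q_a, q_b), max(q_a, q_b)
    if abs(q_ab - q_sum) <= tolerance:
        label = INDEPENDENT
    elif q_ab > q_sum:
        label = ENHANCE_NONLINEAR
    elif q_ab >= hi:
        label = ENHANCE_BI
    elif q_ab >= lo:
        label = WEAKEN_SINGLE
    else:
        label = WEAKEN_NONLINEAR
    return InteractionResult(q_a=q_a, q_b=q_b, q_ab=q_ab, type_label=label)


def interaction_detector(values, strat_a, strat_b,
                         tolerance: float = 1e-9) -> InteractionResult:
    """q(A), q(B) and q(A∩B) on the records shared by both stratifications,
    classified into the interaction type."""
    strat_a = _as_strat(strat_a)
    strat_b = _as_strat(strat_b)
    both = overlay(strat_a, strat_b)
    # restrict the marginal stratifications to the shared records so the
    # three q values decompose the same SST
    common, ia, ib = np.intersect1d(strat_a.index, strat_b.index,
                                    return_indices=True)
    sa = Stratification(strat_a.source, common, strat_a.labels[ia])
    sb = Stratification(strat_b.source, common, strat_b.labels[ib])
    q_a = compute_q(values, sa).q
    q_b = compute_q(values, sb).q
    q_ab = compute_q(values, both).q
    return classify_interaction(q_a, q_b, q_ab, tolerance=tolerance)


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------

def _label_column(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("expected a single column of stratum labels")
    return X


def _two_label_columns(X) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected two columns of stratum labels")
    return X[:, 0], X[:, 1]


class FactorDetector(BaseEstimator):
    """Factor detector: q statistic of one categorical factor.

    Parameters
    ----------
    method : {"permutation", "noncentral_f"}, default="permutation"
        Significance test for q.
    n_perm : int, default=999
        Number of permutations for the permutation test.
    random_state : int or None
        Seed for the permutation test.

    Attributes
    ----------
    q_ : float
        Explained-variance share of the factor's partition.
    p_value_ : float
        Significance of ``q_``.
    result_ : QResult
        Full decomposition (SST, SSW, per-stratum statistics).
    """

    def __init__(self, method: str = "permutation", n_perm: int = 999,
                 random_state: int | None = None):
        self.method = method
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y):
        labels = _label_column(X)
        strat = stratification_from_labels(labels)
        self.result_ = compute_q(y, strat)
        self.result_.p_value = q_significance(
            y, strat, method=self.method, n_perm=self.n_perm,
            seed=self.random_state,
        )
        self.q_ = self.result_.q
        self.p_value_ = self.result_.p_value
        self.n_used_ = self.result_.n_used
        return self

    def score(self, X, y):
        """q of this stratification on new data (higher = more explained)."""
        return compute_q(y, stratification_from_labels(_label_column(X))).q


class RiskDetector(BaseEstimator):
    """Risk detector: pairwise Welch comparison of stratum means.

    Attributes
    ----------
    comparison_ : RiskComparison
    significant_pairs_ : list of PairComparison
    """

    def __init__(self, confidence: float = 0.95, fdr: bool = False):
        self.confidence = confidence
        self.fdr = fdr

    def fit(self, X, y):
        labels = _label_column(X)
        self.comparison_ = risk_detector(
            y, stratification_from_labels(labels),
            confidence=self.confidence, fdr=self.fdr,
        )
        self.significant_pairs_ = self.comparison_.significant_pairs()
        return self


class EcologicalDetector(BaseEstimator):
    """Ecological detector: which of two factors explains more of y.

    ``X`` must supply two columns of stratum labels.

    Attributes
    ----------
    f_statistic_, p_value_ : float
    dominant_ : str
    """

    def __init__(self, confidence: float = 0.95):
        self.confidence = confidence

    def fit(self, X, y):
        a, b = _two_label_columns(X)
        self.result_ = ecological_detector(
            y, stratification_from_labels(a, source="X1"),
            stratification_from_labels(b, source="X2"),
            confidence=self.confidence,
        )
        self.f_statistic_ = self.result_.f_statistic
        self.p_value_ = self.result_.p_value
        self.dominant_ = self.result_.dominant
        return self


class InteractionDetector(BaseEstimator):
    """Interaction detector: overlay q of two factors and its type label.

    ``X`` must supply two columns of stratum labels.

    Attributes
    ----------
    q_a_, q_b_, q_ab_ : float
    type_label_ : str
    """

    def __init__(self, tolerance: float = 1e-9):
        self.tolerance = tolerance

    def fit(self, X, y):
        a, b = _two_label_columns(X)
        self.result_ = interaction_detector(
            y, stratification_from_labels(a, source="X1"),
            stratification_from_labels(b, source="X2"),
            tolerance=self.tolerance,
        )
        self.q_a_ = self.result_.q_a
        self.q_b_ = self.result_.q_b
        self.q_ab_ = self.result_.q_ab
        self.type_label_ = self.result_.type_label
        return self
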