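"""Predictor screening, AICc model tuning, and threshold-based evaluation.

Covers the standard niche-modelling workflow around the fitted model:
collinearity screening by Spearman rank correlation, a shadow-feature
random-forest relevance screen, AICc selection over the regularization
multiplier x feature-class grid, AUC and the true skill statistic
(TSS = sensitivity + specificity - 1), three cloglog threshold rules
(MTSS / PTSS / ETSS) and their TSS-weighted average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .maxent import MaxentConfig, MaxentModel, fit

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Screening


@dataclass
class ScreeningReport:
    rho: pd.DataFrame
    pvalues: pd.DataFrame
    retained: list[str]
    dropped: list[tuple[str, str]]  # (variable, reason)
    flagged_constant: list[str] = field(default_factory=list)


def spearman_screen(
    table: pd.DataFrame, r_thresh: float = 0.8, p_thresh: float = 0.001
) -> ScreeningReport:
    """Iteratively drop one member of each highly correlated variable pair.

    While any pair has |rho| > ``r_thresh`` with p < ``p_thresh``, the pair
    with the largest |rho| is examined and the member with the larger mean
    absolute correlation to all other remaining variables is dropped
    (deterministic). Constant columns cannot be ranked and are flagged and
    excluded from testing but kept in the retained list.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    cols = list(table.columns)
    constant = [c for c in cols if table[c].nunique() <= 1]
    if constant:
        logger.warning("constant columns excluded from correlation screen: %s", constant)
    active = [c for c in cols if c not in constant]

    if len(active) >= 2:
        rho, p = stats.spearmanr(table[active].to_numpy())
        if len(active) == 2:  # scipy collapses the 2-column case to scalars
            rho = np.array([[1.0, rho], [rho, 1.0]])
            p = np.array([[0.0, p], [p, 0.0]])
    else:
        rho = np.ones((len(active), len(active)))
        p = np.zeros_like(rho)
    rho_full = pd.DataFrame(rho, index=active, columns=active)
    p_full = pd.DataFrame(p, index=active, columns=active)

    dropped: list[tuple[str, str]] = []
    remaining = list(active)
    while len(remaining) > 1:
        sub_r = rho_full.loc[remaining, remaining].abs()
        sub_p = p_full.loc[remaining, remaining]
        np.fill_diagonal(sub_r.values, 0.0)
        offending = (sub_r > r_thresh) & (sub_p < p_thresh)
        if not offending.to_numpy().any():
            break
        # pair with the largest |rho| among offenders
        masked = sub_r.where(offending)
        a = masked.max().idxmax()
        b = masked[a].idxmax()
        mean_abs = sub_r.mean()
        victim = a if mean_abs[a] >= mean_abs[b] else b
        partner = b if victim == a else a
        dropped.append(
            (victim, f"|rho|={sub_r.loc[a, b]:.3f} with {partner} "
                     f"(p={sub_p.loc[a, b]:.2e})")
        )
        remaining.remove(victim)
    retained = [c for c in cols if c in remaining or c in constant]
    return ScreeningReport(rho_full, p_full, retained, dropped, constant)


def shadow_importance_screen(
    table: pd.DataFrame,
    labels: np.ndarray,
    seed: int | None = None,
    n_rounds: int = 20,
    alpha: float = 0.01,
    n_estimators: int = 200,
) -> list[str]:
    """Shadow-feature relevance screen (simplified Boruta).

    Each round appends a row-permuted "shadow" copy of every column, fits a
    random-forest classifier on presence-vs-background labels, and scores a
    real column a hit when its impurity importance exceeds the maximum shadow
    importance. A column is confirmed when its hit count beats a fair coin in
    a one-sided binomial test at level ``alpha``.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    rng = np.random.default_rng(seed)
    cols = list(table.columns)
    hits = np.zeros(len(cols), dtype=int)
    X = table.to_numpy(dtype=float)
    for r in range(n_rounds):
        shadow = X.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        Xr = np.hstack([X, shadow])
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        clf.fit(Xr, labels)
        imp = clf.feature_importances_
        real, sh = imp[: len(cols)], imp[len(cols):]
        hits += (real > sh.max()).astype(int)
    confirmed = [
        c for c, h in zip(cols, hits)
        if stats.binomtest(int(h), n_rounds, 0.5, alternative="greater").pvalue < alpha
    ]
    return confirmed


# ---------------------------------------------------------------------------
# AICc tuning


def aicc(model: MaxentModel, presence: pd.DataFrame) -> float:
    """Sample-size-corrected AIC from the normalized raw likelihood.

    lnL = sum over presences of ln raw(x); k = number of nonzero
    coefficients; AICc = 2k - 2 lnL + 2k(k+1)/(n-k-1). Undefined (+inf)
    when n - k - 1 <= 0.
    """
    n = len(presence)
    k = model.n_nonzero
    if n - k - 1 <= 0:
        return float("inf")
    raw = model.predict_raw(presence)
    lnl = float(np.log(np.maximum(raw, 1e-300)).sum())
    return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class TuningResult:
    table: pd.DataFrame          # rm, fc, aicc, k, lnl per combo
    best_rm: float
    best_fc: str
    best_model: MaxentModel


def tune(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    rm_list: list[float],
    fc_list: list[str],
    config: MaxentConfig | None = None,
    categorical: set[str] | frozenset[str] = frozenset(),
) -> TuningResult:
    """Fit every (rm, fc) combination and pick the smallest AICc.

    Ties break toward fewer parameters, then smaller rm, then fc order.
    Combinations with undefined AICc (more parameters than presences allow)
    are recorded as +inf and excluded from selection.
    """
    if not rm_list or not fc_list:
        raise ValueError("rm_list and fc_list must be non-empty")
    base = config or MaxentConfig()
    rows = []
    models: dict[tuple[float, str], MaxentModel] = {}
    for fc_i, fc in enumerate(fc_list):
        for rm in rm_list:
            cfg = MaxentConfig(
                rm=rm, fc=fc, n_background=base.n_background,
                max_iter=base.max_iter, convergence=base.convergence,
                prevalence=base.prevalence, n_hinge_knots=base.n_hinge_knots,
                seed=base.seed,
            )
            model = fit(presence, background, cfg, categorical)
            a = aicc(model, presence)
            raw = model.predict_raw(presence)
            rows.append({
                "rm": rm, "fc": cfg.fc, "fc_order": fc_i, "aicc": a,
                "k": model.n_nonzero,
                "lnl": float(np.log(np.maximum(raw, 1e-300)).sum()),
            })
            models[(rm, cfg.fc)] = model
    table = pd.DataFrame(rows)
    finite = table[np.isfinite(table["aicc"])]
    if finite.empty:
        raise ValueError("AICc undefined for every combination (too few presences)")
    best = finite.sort_values(["aicc", "k", "rm", "fc_order"], kind="stable").iloc[0]
    return TuningResult(
        table=table.drop(columns="fc_order"),
        best_rm=float(best["rm"]),
        best_fc=str(best["fc"]),
        best_model=models[(float(best["rm"]), str(best["fc"]))],
    )


# ---------------------------------------------------------------------------
# Threshold-independent and threshold-dependent metrics


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC: probability a random presence outscores a random
    background point, ties counting one half."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("need non-empty score sets")
    ranks = stats.rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


@dataclass
class EvalMetrics:
    sensitivity: float
    specificity: float

    @property
    def tss(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def confusion_at(
    threshold: float, presence_scores: np.ndarray, background_scores: np.ndarray
) -> EvalMetrics:
    """Sensitivity (presences at or above threshold) and specificity
    (background below threshold) at one cloglog threshold."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    return EvalMetrics(
        sensitivity=float((p >= threshold).mean()) if p.size else 0.0,
        specificity=float((b < threshold).mean()) if b.size else 0.0,
    )


@dataclass
class ThresholdSet:
    """The three cloglog threshold rules and their TSS-weighted average.

    mtss — threshold maximizing sensitivity + specificity;
    ptss — 10th percentile of presence scores (linear interpolation);
    etss — threshold where sensitivity and specificity are closest;
    weighted — sum(t_r * TSS_r) / sum(TSS_r) over the three rules, falling
    back (flagged) to the plain mean when no rule achieves positive TSS.
    """

    mtss: float
    ptss: float
    etss: float
    tss_at_mtss: float
    tss_at_ptss: float
    tss_at_etss: float
    weighted: float
    weighted_fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "mtss": self.mtss, "ptss": self.ptss, "etss": self.etss,
            "tss_at_mtss": self.tss_at_mtss, "tss_at_ptss": self.tss_at_ptss,
            "tss_at_etss": self.tss_at_etss, "weighted": self.weighted,
            "weighted_fallback": self.weighted_fallback,
        }


def thresholds(
    presence_scores: np.ndarray,
    background_scores: np.ndarray,
    presence_percentile: float = 10.0,
    weighting: str = "tss",
) -> ThresholdSet:
    """Compute MTSS, PTSS and ETSS thresholds and the weighted average.

    Candidate thresholds are the observed scores; on ties the smallest
    maximizer (MTSS) or smallest minimizer (ETSS) is taken, making the rules
    deterministic. ``weighting`` is "tss" (default) or "mean".
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("need non-empty score sets")
    candidates = np.unique(np.concatenate([p, b]))
    sens = (p[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (b[None, :] < candidates[:, None]).mean(axis=1)
    tss = sens + spec - 1.0

    mtss = float(candidates[np.argmax(tss)])  # argmax returns first = smallest
    etss = float(candidates[np.argmin(np.abs(sens - spec))])
    ptss = float(np.percentile(p, presence_percentile))

    t_m = confusion_at(mtss, p, b).tss
    t_p = confusion_at(ptss, p, b).tss
    t_e = confusion_at(etss, p, b).tss

    ts = np.array([mtss, ptss, etss])
    ws = np.array([t_m, t_p, t_e])
    fallback = False
    if weighting == "mean" or ws.sum() <= 0:
        fallback = ws.sum() <= 0 and weighting != "mean"
        weighted = float(ts.mean())
    else:
        weighted = float((ts * ws).sum() / ws.sum())
    return ThresholdSet(mtss, ptss, etss, t_m, t_p, t_e, weighted, fallback)
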