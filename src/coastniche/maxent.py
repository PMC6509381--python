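"""L1-regularized maximum-entropy presence-only niche model.

The model is the Gibbs distribution over the background that has maximum
entropy subject to (relaxed) feature-expectation constraints from the
presence sample. Fitting minimizes the convex penalized log loss

    f(lambda) = -(1/m) sum_i lambda . f(x_i)  +  log Z_bg(lambda)
                + sum_j beta_j |lambda_j|

over presence rows x_i, where Z_bg is the partition sum over the training
background and beta_j = rm * sqrt(s_j^2 / m) with s_j^2 the feature variance
over presences and m the presence count (regularization multiplier ``rm``
scales all penalties). The raw output exp(lambda.f(x) - log Z) sums to 1 over
the training background; the cloglog output 1 - exp(-e^H raw) (H = entropy of
the raw distribution) is the [0,1] suitability that downstream thresholding
uses. Features outside the training range are clamped to [0,1] when
projecting, the standard behaviour when transferring a model to new
conditions.

The optimizer is L-BFGS-B on the split lambda = u - v (u, v >= 0), which
turns the L1 term into a smooth bound-constrained problem; the contract is
the objective value, not the algorithm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .grids import EnvironmentalStack
from .occurrences import OccurrenceSet

logger = logging.getLogger(__name__)

VALID_FEATURE_CLASSES = frozenset("LQH")


@dataclass
class FeatureDef:
    """One transformed feature of one layer, scaled to [0,1] on training data.

    ``kind``: linear | quadratic | forward_hinge | reverse_hinge | indicator.
    ``lo``/``hi`` are the layer's training-background range; ``knot`` is the
    hinge knot (strictly inside the range) or the category code.
    """

    kind: str
    layer: str
    lo: float = 0.0
    hi: float = 1.0
    knot: float | None = None

    def label(self) -> str:
        if self.kind in ("forward_hinge", "reverse_hinge"):
            return f"{self.kind}({self.layer}@{self.knot:.6g})"
        if self.kind == "indicator":
            return f"indicator({self.layer}={self.knot:.6g})"
        return f"{self.kind}({self.layer})"


@dataclass
class MaxentConfig:
    rm: float = 1.0
    fc: str = "LQH"
    n_background: int = 10_000
    max_iter: int = 1_000
    convergence: float = 1e-5
    prevalence: float = 0.5  # tau, used only by the optional logistic output
    n_hinge_knots: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        self.fc = "".join(sorted(set(self.fc.upper()), key="LQH".index))
        if not set(self.fc) <= VALID_FEATURE_CLASSES or not self.fc:
            raise ValueError(f"fc must be a non-empty subset of L,Q,H; got {self.fc!r}")
        if self.rm <= 0:
            raise ValueError("regularization multiplier must be > 0")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


def sample_background(
    stack: EnvironmentalStack, n: int, seed: int | np.random.Generator | None = None
) -> OccurrenceSet:
    """Draw ``n`` distinct unmasked cells uniformly without replacement,
    returned as points at cell centers. If fewer than ``n`` cells are
    available, all of them are used (logged)."""
    keep = ~stack.grid.nodata_mask
    flat = np.flatnonzero(keep.ravel())
    if flat.size == 0:
        raise ValueError("no unmasked cells to sample background from")
    rng = np.random.default_rng(seed)
    if n >= flat.size:
        if n > flat.size:
            logger.info("requested %d background points but only %d unmasked cells; using all",
                        n, flat.size)
        idx = flat
    else:
        idx = rng.choice(flat, size=n, replace=False)
    rows, cols = np.unravel_index(idx, stack.grid.shape)
    x, y = stack.grid.cell_center(rows, cols)
    return OccurrenceSet(x=x, y=y, species="background", source="background")


def build_features(
    background: pd.DataFrame,
    fc: str = "LQH",
    n_hinge_knots: int = 50,
    categorical: set[str] | frozenset[str] = frozenset(),
) -> list[FeatureDef]:
    """Derive feature definitions from the training background.

    Continuous layers get, per the feature-class string: L — the min-max
    scaled identity; Q — the square of the scaled identity; H — forward and
    reverse hinges at ``n_hinge_knots`` evenly spaced interior knots.
    Categorical layers get one indicator per observed level regardless of
    ``fc``. Constant layers are skipped with a warning.
    """
    fc = "".join(sorted(set(fc.upper()), key="LQH".index))
    defs: list[FeatureDef] = []
    for name in background.columns:
        col = background[name].to_numpy(dtype=float)
        if name in categorical:
            for code in np.unique(col):
                defs.append(FeatureDef("indicator", name, knot=float(code)))
            continue
        lo, hi = float(col.min()), float(col.max())
        if hi <= lo:
            logger.warning("layer %r is constant on the background; features skipped", name)
            continue
        if "L" in fc:
            defs.append(FeatureDef("linear", name, lo, hi))
        if "Q" in fc:
            defs.append(FeatureDef("quadratic", name, lo, hi))
        if "H" in fc:
            knots = lo + (hi - lo) * np.arange(1, n_hinge_knots + 1) / (n_hinge_knots + 1)
            for k in knots:
                defs.append(FeatureDef("forward_hinge", name, lo, hi, float(k)))
                defs.append(FeatureDef("reverse_hinge", name, lo, hi, float(k)))
    return defs


def featurize(table: pd.DataFrame, defs: list[FeatureDef]) -> np.ndarray:
    """Evaluate feature definitions on rows of layer values.

    All features are clamped to [0,1]; rows outside the training range of a
    layer are thereby projected onto the range boundary (MaxEnt clamping).
    """
    n = len(table)
    X = np.empty((n, len(defs)), dtype=float)
    scaled_cache: dict[str, np.ndarray] = {}
    for j, d in enumerate(defs):
        x = table[d.layer].to_numpy(dtype=float)
        if d.kind == "indicator":
            X[:, j] = (x == d.knot).astype(float)
            continue
        if d.kind in ("linear", "quadratic"):
            key = d.layer
            if key not in scaled_cache:
                scaled_cache[key] = np.clip((x - d.lo) / (d.hi - d.lo), 0.0, 1.0)
            z = scaled_cache[key]
            X[:, j] = z if d.kind == "linear" else z * z
        elif d.kind == "forward_hinge":
            X[:, j] = np.clip((x - d.knot) / (d.hi - d.knot), 0.0, 1.0)
        elif d.kind == "reverse_hinge":
            X[:, j] = np.clip((d.knot - x) / (d.knot - d.lo), 0.0, 1.0)
        else:  # pragma: no cover
            raise ValueError(f"unknown feature kind {d.kind!r}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values; check input table")
    return X


@dataclass
class MaxentModel:
    features: list[FeatureDef]
    lambdas: np.ndarray
    betas: np.ndarray
    logZ: float
    entropy: float
    config: MaxentConfig
    converged: bool = True
    objective: float = float("nan")

    @property
    def n_nonzero(self) -> int:
        """Count of active (nonzero) coefficients — the parameter count k
        used by AICc."""
        return int((np.abs(self.lambdas) > 1e-8).sum())

    def predict_raw(self, table: pd.DataFrame) -> np.ndarray:
        X = featurize(table, self.features)
        return np.exp(X @ self.lambdas - self.logZ)

    def predict_cloglog(self, table: pd.DataFrame) -> np.ndarray:
        return 1.0 - np.exp(-np.exp(self.entropy) * self.predict_raw(table))

    def predict_logistic(self, table: pd.DataFrame) -> np.ndarray:
        tau = self.config.prevalence
        q = np.exp(self.entropy) * self.predict_raw(table) * tau / (1.0 - tau)
        return q / (1.0 + q)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "features": [asdict(d) for d in self.features],
            "lambdas": self.lambdas.tolist(),
            "betas": self.betas.tolist(),
            "logZ": self.logZ,
            "entropy": self.entropy,
            "config": asdict(self.config),
            "converged": self.converged,
            "objective": self.objective,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "MaxentModel":
        return cls(
            features=[FeatureDef(**f) for f in d["features"]],
            lambdas=np.asarray(d["lambdas"], dtype=float),
            betas=np.asarray(d["betas"], dtype=float),
            logZ=float(d["logZ"]),
            entropy=float(d["entropy"]),
            config=MaxentConfig(**d["config"]),
            converged=bool(d["converged"]),
            objective=float(d["objective"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def penalized_objective(
    lam: np.ndarray, X_presence: np.ndarray, X_background: np.ndarray, betas: np.ndarray
) -> float:
    """The penalized MaxEnt log loss at ``lam`` (used by fit and by oracle
    tests; kept separate so an independent minimizer can evaluate it)."""
    return float(
        -(X_presence @ lam).mean()
        + logsumexp(X_background @ lam)
        + betas @ np.abs(lam)
    )


def fit(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    config: MaxentConfig | None = None,
    categorical: set[str] | frozenset[str] = frozenset(),
    defs: list[FeatureDef] | None = None,
) -> MaxentModel:
    """Fit the penalized maximum-entropy model.

    ``presence`` and ``background`` are layer-value tables with identical
    columns; features are built from the background unless ``defs`` is given.
    """
    if config is None:
        config = MaxentConfig()
    if len(presence) < 2:
        raise ValueError("need at least 2 presence records to fit")
    if defs is None:
        defs = build_features(background, config.fc, config.n_hinge_knots, categorical)
    if not defs:
        raise ValueError("no usable features (all layers constant?)")
    X_p = featurize(presence, defs)
    X_b = featurize(background, defs)

    m = X_p.shape[0]
    s2 = X_p.var(axis=0)
    betas = config.rm * np.sqrt(np.maximum(s2, 1e-4) / m)

    mean_p = X_p.mean(axis=0)
    k = len(defs)

    def value_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        u, v = theta[:k], theta[k:]
        lam = u - v
        scores = X_b @ lam
        lz = logsumexp(scores)
        p = np.exp(scores - lz)
        f = -(mean_p @ lam) + lz + betas @ (u + v)
        g_smooth = -mean_p + p @ X_b
        grad = np.concatenate([g_smooth + betas, -g_smooth + betas])
        return f, grad

    theta0 = np.zeros(2 * k)
    res = optimize.minimize(
        value_and_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * k),
        options={
            "maxiter": config.max_iter,
            "ftol": config.convergence,
            "gtol": 1e-9,
            "maxcor": 20,
        },
    )
    lam = res.x[:k] - res.x[k:]
    # u/v splitting can leave tiny paired residues; snap them to zero
    lam[np.abs(lam) < 1e-10] = 0.0
    converged = bool(res.success) or res.status == 1  # status 1 = maxiter
    if not res.success:
        logger.warning("MaxEnt optimizer stopped without full convergence: %s",
                       res.message)

    scores_b = X_b @ lam
    logZ = float(logsumexp(scores_b))
    p_b = np.exp(scores_b - logZ)
    entropy = float(-(p_b * np.log(np.maximum(p_b, 1e-300))).sum())
    return MaxentModel(
        features=defs,
        lambdas=lam,
        betas=betas,
        logZ=logZ,
        entropy=entropy,
        config=config,
        converged=bool(res.success),
        objective=float(res.fun),
    )


@dataclass
class CVResult:
    folds: pd.DataFrame        # per-fold: fold, n_test, auc, tss, threshold
    models: list[MaxentModel] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(self.folds["auc"].mean())

    @property
    def mean_tss(self) -> float:
        return float(self.folds["tss"].mean())


def cross_validate(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    config: MaxentConfig | None = None,
    k: int = 10,
    seed: int | np.random.Generator | None = None,
    categorical: set[str] | frozenset[str] = frozenset(),
) -> CVResult:
    """k-fold cross-validation of the presence data against a shared
    background: each fold holds out ~1/k of the presences, the model is
    trained on the rest, and test AUC and TSS (at the training MTSS
    threshold) are computed from held-out presence vs background scores."""
    from .evaluation import auc as _auc, confusion_at, thresholds as _thresholds

    if config is None:
        config = MaxentConfig()
    n = len(presence)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available presences")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    rows = []
    models: list[MaxentModel] = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx, assume_unique=True)
        model = fit(presence.iloc[train_idx], background, config, categorical)
        bg_scores = model.predict_cloglog(background)
        train_scores = model.predict_cloglog(presence.iloc[train_idx])
        test_scores = model.predict_cloglog(presence.iloc[test_idx])
        ts = _thresholds(train_scores, bg_scores)
        metrics = confusion_at(ts.mtss, test_scores, bg_scores)
        rows.append({
            "fold": i,
            "n_test": len(test_idx),
            "auc": _auc(test_scores, bg_scores),
            "tss": metrics.tss,
            "threshold": ts.mtss,
        })
        models.append(model)
    return CVResult(folds=pd.DataFrame(rows), models=models)
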