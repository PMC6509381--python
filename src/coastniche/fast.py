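"""Extended FAST variance-based global sensitivity analysis.

Each input factor is driven along a periodic search curve
``x_j(s) = InvCDF_j(1/2 + (1/pi) arcsin(sin(w_j s + phi_j)))`` with
``s`` sweeping (-pi, pi]. In the block for factor i, that factor carries the
high frequency ``w_max`` while the complementary factors get low distinct
frequencies (<= w_max / 2M), so the variance the model output shows at the
harmonics of ``w_max`` is attributable to factor i alone. Reading the Fourier
spectrum of the output gives the first-order index S_F (variance at
``p*w_max``, p = 1..M) and the total index S_T (one minus the variance in the
low-frequency band belonging to everything-but-i). The difference S_T - S_F
measures a factor's involvement in interactions.

One block needs Ns = 2*M*w_max + 1 model runs and the full analysis
Ns * m runs for m factors; with the interference factor M = 4, the default
maximum frequency 416 and 15 factors that is 49,935 runs. Random phases
phi_j are seeded so repeats with different seeds give the spread of the
estimates. Factors are sampled independently from their fitted marginal
distributions — spatial correlation between layers is deliberately ignored,
as in the classic Simlab workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grids import EnvironmentalStack

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Input distributions


@dataclass
class DistributionSpec:
    """Fitted marginal distribution of one input factor.

    ``family`` is uniform | normal | lognormal | empirical | categorical |
    degenerate. ``gof`` holds the chi-square statistic and p-value of the
    accepted fit (NaN for empirical/categorical/degenerate). The inverse CDF
    is what the FAST search curve needs.
    """

    variable: str
    family: str
    params: dict
    gof_stat: float = float("nan")
    gof_p: float = float("nan")
    alpha: float = 0.01
    degenerate: bool = False

    def ppf(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        q = np.clip(q, 1e-12, 1 - 1e-12)
        if self.family == "uniform":
            return self.params["lo"] + q * (self.params["hi"] - self.params["lo"])
        if self.family == "normal":
            return stats.norm.ppf(q, self.params["mean"], self.params["sd"])
        if self.family == "lognormal":
            return stats.lognorm.ppf(q, self.params["s"], 0.0, self.params["scale"])
        if self.family == "empirical":
            grid = np.asarray(self.params["quantiles"])
            return np.interp(q, np.linspace(0, 1, grid.size), grid)
        if self.family == "categorical":
            codes = np.asarray(self.params["codes"], dtype=float)
            cum = np.cumsum(self.params["probs"])
            return codes[np.minimum(np.searchsorted(cum, q, side="right"),
                                    codes.size - 1)]
        if self.family == "degenerate":
            return np.full_like(q, self.params["value"])
        raise ValueError(f"unknown family {self.family!r}")


def _chi_square_gof(data: np.ndarray, ppf, n_params: int, bins: int) -> tuple[float, float]:
    """Chi-square goodness of fit on equiprobable bins of the fitted CDF."""
    edges = ppf(np.linspace(0.0, 1.0, bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    observed, _ = np.histogram(data, bins=edges)
    expected = data.size / bins
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = bins - 1 - n_params
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else float("nan")
    return chi2, p


def fit_distribution(
    data: np.ndarray,
    variable: str,
    categorical: bool = False,
    families: Sequence[str] = ("uniform", "normal", "lognormal"),
    alpha: float = 0.01,
    bins: int = 20,
) -> DistributionSpec:
    """Fit one factor's marginal; best family by chi-square GOF, empirical
    fallback when every parametric family is rejected at level ``alpha``."""
    data = np.asarray(data, dtype=float)
    data = data[np.isfinite(data)]
    if data.size < 30:
        raise ValueError(f"{variable}: need >= 30 values to fit a distribution")
    if np.ptp(data) == 0:
        logger.warning("%s is constant; flagged degenerate (sensitivity will be 0)", variable)
        return DistributionSpec(variable, "degenerate", {"value": float(data[0])},
                                alpha=alpha, degenerate=True)
    if categorical:
        codes, counts = np.unique(data, return_counts=True)
        return DistributionSpec(
            variable, "categorical",
            {"codes": codes.tolist(), "probs": (counts / counts.sum()).tolist()},
            alpha=alpha,
        )

    candidates: list[tuple[float, float, str, dict]] = []
    for family in families:
        if family == "uniform":
            lo, hi = float(data.min()), float(data.max())
            ppf = lambda q, lo=lo, hi=hi: lo + np.asarray(q) * (hi - lo)
            stat, p = _chi_square_gof(data, ppf, 2, bins)
            candidates.append((p, stat, family, {"lo": lo, "hi": hi}))
        elif family == "normal":
            mu, sd = float(data.mean()), float(data.std(ddof=1))
            stat, p = _chi_square_gof(
                data, lambda q: stats.norm.ppf(q, mu, sd), 2, bins)
            candidates.append((p, stat, family, {"mean": mu, "sd": sd}))
        elif family == "lognormal" and data.min() > 0:
            s, _, scale = stats.lognorm.fit(data, floc=0)
            stat, p = _chi_square_gof(
                data, lambda q: stats.lognorm.ppf(q, s, 0.0, scale), 2, bins)
            candidates.append((p, stat, family, {"s": float(s), "scale": float(scale)}))
    accepted = [c for c in candidates if np.isfinite(c[0]) and c[0] > alpha]
    if accepted:
        p, stat, family, params = max(accepted, key=lambda c: c[0])
        return DistributionSpec(variable, family, params, stat, p, alpha)
    logger.info("%s: all parametric families rejected; using empirical quantiles", variable)
    grid = np.quantile(data, np.linspace(0, 1, 1001))
    return DistributionSpec(variable, "empirical", {"quantiles": grid.tolist()},
                            alpha=alpha)


def fit_distributions(
    stack: EnvironmentalStack,
    region_mask: np.ndarray | None = None,
    families: Sequence[str] = ("uniform", "normal", "lognormal"),
    alpha: float = 0.01,
    bins: int = 20,
) -> list[DistributionSpec]:
    """Fit marginals for every layer from unmasked (optionally region-limited)
    cells. Layer kind decides categorical handling."""
    keep = ~stack.grid.nodata_mask
    if region_mask is not None:
        keep = keep & np.asarray(region_mask, dtype=bool)
    if keep.sum() < 30:
        raise ValueError("need at least 30 unmasked cells to fit distributions")
    return [
        fit_distribution(layer.values[keep], name,
                         categorical=layer.kind == "categorical",
                         families=families, alpha=alpha, bins=bins)
        for name, layer in stack.layers.items()
    ]


# ---------------------------------------------------------------------------
# Design


@dataclass
class FASTConfig:
    M: int = 4
    omega_max: int = 416
    m: int = 15
    seed: int | None = None
    n_repeats: int = 5

    @property
    def ns(self) -> int:
        """Model runs per factor block: 2*M*omega_max + 1 (odd)."""
        return 2 * self.M * self.omega_max + 1

    @property
    def n_total(self) -> int:
        return self.ns * self.m

    @property
    def max_complementary(self) -> int:
        return self.omega_max // (2 * self.M)


def sample_size(M: int, omega_max: int, m: int) -> int:
    """Total model runs N = (2*M*omega_max + 1) * m."""
    if min(M, omega_max, m) < 1:
        raise ValueError("M, omega_max and m must all be >= 1")
    return (2 * M * omega_max + 1) * m


@dataclass
class FASTDesign:
    blocks: list[np.ndarray]          # m arrays of shape (Ns, m)
    frequencies: np.ndarray           # (m, m): freq of factor j in block i
    s: np.ndarray                     # the Ns curve parameter values
    phases: np.ndarray                # (m, m) random phases
    variables: list[str]


def efast_design(dists: Sequence[DistributionSpec], config: FASTConfig,
                 seed: int | np.random.Generator | None = None) -> FASTDesign:
    """Build the m resampled search-curve blocks of the extended FAST design.

    In block i the factor of interest carries ``omega_max``; the others get
    distinct integer frequencies spread evenly across the admissible band
    (up to floor(omega_max/2M)). Spreading, rather than packing at 1, 2, ...,
    keeps the complementary search curves close to mutually independent; when
    the factors fit in half the band, only 1..floor(band/2) is used so that
    complementary harmonics up to order 2M still fall below the omega/2
    read-out cutoff. When there are more complementary factors than the band
    holds, frequencies cycle with a warning (the aliasing bias this
    introduces is documented). Random phases are drawn per block from the
    seeded generator.
    """
    m = len(dists)
    if m != config.m:
        raise ValueError(f"config.m={config.m} but {m} distributions supplied")
    band = config.max_complementary
    if band < 1:
        raise ValueError(
            f"omega_max={config.omega_max} too small for M={config.M}: "
            f"need omega_max >= {2 * config.M} so complementary factors get a frequency"
        )
    if m - 1 > band:
        logger.warning(
            "%d complementary factors share only %d distinct frequencies; "
            "cycling assignment (some aliasing between factors)", m - 1, band,
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ns = config.ns
    s = -np.pi + 2 * np.pi * (np.arange(ns) + 1) / ns  # (-pi, pi]

    half_band = max(band // 2, 1)
    if m - 1 <= half_band and m > 1:
        compl = np.unique(np.floor(np.linspace(1, half_band, m - 1)).astype(int))
        assert compl.size == m - 1
    elif m - 1 <= band and m > 1:
        compl = np.unique(np.floor(np.linspace(1, band, m - 1)).astype(int))
        assert compl.size == m - 1
    else:
        compl = 1 + np.arange(max(m - 1, 0)) % band
    freqs = np.zeros((m, m), dtype=int)
    phases = rng.uniform(0, 2 * np.pi, size=(m, m))
    blocks: list[np.ndarray] = []
    for i in range(m):
        w = np.empty(m, dtype=int)
        w[i] = config.omega_max
        others = [j for j in range(m) if j != i]
        for rank, j in enumerate(others):
            w[j] = compl[rank]
        freqs[i] = w
        angle = np.outer(s, w) + phases[i][None, :]
        q = 0.5 + np.arcsin(np.sin(angle)) / np.pi
        block = np.empty((ns, m), dtype=float)
        for j, dist in enumerate(dists):
            block[:, j] = dist.ppf(q[:, j])
        blocks.append(block)
    return FASTDesign(blocks, freqs, s, phases, [d.variable for d in dists])


# ---------------------------------------------------------------------------
# Index estimation


def _spectrum(y: np.ndarray) -> np.ndarray:
    """Per-frequency variance 2|c_j|^2, j = 1..(Ns-1)/2, from the DFT of the
    output along the search curve."""
    y = np.asarray(y, dtype=float)
    ns = y.size
    c = np.fft.rfft(y) / ns
    power = 2.0 * np.abs(c[1:]) ** 2
    return power[: (ns - 1) // 2]


def first_order_index(y_block: np.ndarray, omega_high: int, M: int) -> float:
    """S_F: share of output variance at the harmonics p*omega_high, p=1..M."""
    y_block = np.asarray(y_block, dtype=float)
    ns = y_block.size
    if ns % 2 == 0 or ns < 2 * M * omega_high + 1:
        raise ValueError(f"need an odd block of >= {2 * M * omega_high + 1} runs, got {ns}")
    if np.ptp(y_block) == 0:
        logger.warning("constant model output; S_F set to 0")
        return 0.0
    power = _spectrum(y_block)
    v_total = power.sum()
    if v_total <= 0:
        return 0.0
    harmonics = omega_high * np.arange(1, M + 1) - 1  # power[j-1] is freq j
    return float(power[harmonics].sum() / v_total)


def total_index(y_block: np.ndarray, omega_high: int, M: int) -> float:
    """S_T: one minus the variance share in the low-frequency band
    (frequencies <= omega_high/2) that belongs to the complementary factors
    and their interactions among themselves."""
    y_block = np.asarray(y_block, dtype=float)
    ns = y_block.size
    if ns % 2 == 0 or ns < 2 * M * omega_high + 1:
        raise ValueError(f"need an odd block of >= {2 * M * omega_high + 1} runs, got {ns}")
    if np.ptp(y_block) == 0:
        logger.warning("constant model output; S_T set to 0")
        return 0.0
    power = _spectrum(y_block)
    v_total = power.sum()
    if v_total <= 0:
        return 0.0
    cutoff = omega_high // 2
    v_complementary = power[:cutoff].sum()
    return float(1.0 - v_complementary / v_total)


@dataclass
class SensitivityResult:
    """Per-factor sensitivity indices with repeat spread and ranks.

    ``diff = S_T - S_F`` is the interaction involvement. Ranks are descending
    with ties sharing the smallest rank (competition ranking, the convention
    of published sensitivity tables). ``*_spread`` is the standard deviation
    over phase-seed repeats.
    """

    variables: list[str]
    s_f: np.ndarray
    s_t: np.ndarray
    s_f_spread: np.ndarray
    s_t_spread: np.ndarray
    flags: list[str] = field(default_factory=list)

    @property
    def diff(self) -> np.ndarray:
        return self.s_t - self.s_f

    @staticmethod
    def _rank(values: np.ndarray) -> np.ndarray:
        return stats.rankdata(-np.asarray(values), method="min").astype(int)

    def to_frame(self, include_sum: bool = True) -> pd.DataFrame:
        df = pd.DataFrame({
            "variable": self.variables,
            "S_F": self.s_f,
            "S_F_spread": self.s_f_spread,
            "rank_SF": self._rank(self.s_f),
            "S_T": self.s_t,
            "S_T_spread": self.s_t_spread,
            "rank_ST": self._rank(self.s_t),
            "diff": self.diff,
            "rank_diff": self._rank(self.diff),
        })
        for col in ("rank_SF", "rank_ST", "rank_diff"):
            df[col] = df[col].astype("Int64")
        if include_sum:
            total = {
                "variable": "Sum",
                "S_F": self.s_f.sum(), "S_F_spread": np.nan, "rank_SF": pd.NA,
                "S_T": self.s_t.sum(), "S_T_spread": np.nan, "rank_ST": pd.NA,
                "diff": self.diff.sum(), "rank_diff": pd.NA,
            }
            df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
            for col in ("rank_SF", "rank_ST", "rank_diff"):
                df[col] = df[col].astype("Int64")
        return df

    @property
    def sums(self) -> dict[str, float]:
        return {"S_F": float(self.s_f.sum()), "S_T": float(self.s_t.sum()),
                "diff": float(self.diff.sum())}


def interaction_effect(result: SensitivityResult) -> pd.DataFrame:
    """The S_T - S_F column with its competition ranks."""
    return pd.DataFrame({
        "variable": result.variables,
        "diff": result.diff,
        "rank_diff": SensitivityResult._rank(result.diff),
    })


def efast_indices(
    func: Callable[[np.ndarray], np.ndarray],
    dists: Sequence[DistributionSpec],
    config: FASTConfig,
    n_repeats: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> SensitivityResult:
    """Estimate S_F and S_T for a vectorised model ``func`` mapping an
    (n, m) factor array to n outputs. Repeats re-randomise the phases; the
    reported indices are means over repeats and the spread their std."""
    n_repeats = config.n_repeats if n_repeats is None else n_repeats
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m = len(dists)
    sf = np.zeros((n_repeats, m))
    st = np.zeros((n_repeats, m))
    flags: set[str] = set()
    for r in range(n_repeats):
        design = efast_design(dists, config, seed=rng)
        for i, block in enumerate(design.blocks):
            y = np.asarray(func(block), dtype=float)
            if y.shape != (config.ns,):
                raise ValueError("model output length must equal the block size")
            if np.ptp(y) == 0:
                flags.add(f"constant output in block {design.variables[i]}")
            sf[r, i] = first_order_index(y, config.omega_max, config.M)
            st[r, i] = total_index(y, config.omega_max, config.M)
    return SensitivityResult(
        variables=[d.variable for d in dists],
        s_f=sf.mean(axis=0),
        s_t=st.mean(axis=0),
        s_f_spread=sf.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(m),
        s_t_spread=st.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(m),
        flags=sorted(flags),
    )


def run_gsa(
    model,
    stack: EnvironmentalStack,
    config: FASTConfig | None = None,
    region_mask: np.ndarray | None = None,
    n_repeats: int | None = None,
    dists: Sequence[DistributionSpec] | None = None,
    seed: int | np.random.Generator | None = None,
) -> SensitivityResult:
    """Global sensitivity analysis of a fitted suitability model.

    Marginals are fitted from the stack (within ``region_mask`` if given),
    the eFAST design is generated, and the model's cloglog prediction is the
    analysed output. Factors are sampled independently from their marginals.
    """
    if config is None:
        config = FASTConfig(m=stack.n_layers)
    if dists is None:
        dists = fit_distributions(stack, region_mask)
    if len(dists) != config.m:
        raise ValueError(f"stack has {len(dists)} factors but config.m={config.m}")
    names = [d.variable for d in dists]

    def predict(block: np.ndarray) -> np.ndarray:
        return model.predict_cloglog(pd.DataFrame(block, columns=names))

    return efast_indices(predict, dists, config, n_repeats=n_repeats, seed=seed)
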