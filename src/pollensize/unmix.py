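"""Compound-distribution estimation of per-species pollen proportions.

Dwarf and tree birch pollen cannot be told apart grain by grain, but each
species' grain size is well described by a normal distribution with known
mean and SD (measured on modern reference material). A fossil sample with
pollen from several species therefore shows a mixture of those normals, and
the species proportions can be recovered by asking which mixing weights make
the theoretical compound distribution most similar to the observed size
distribution.

Given observations x₁…xₙ and K ≤ 4 fixed components (μᵢ, σᵢ), the model is

    f(x; p) = Σᵢ pᵢ · N(x; μᵢ, σᵢ),    p on the simplex,

and only p is estimated. The default dissimilarity is the per-observation
negative log-likelihood (smooth and statistically principled); a binned L2
distance between the empirical and theoretical densities is available as a
more literal "curve similarity" alternative. Optimization uses differential
evolution over K raw non-negative weights normalized to the simplex,
seeded and fully deterministic, with a quasi-Newton polish.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .errors import GateError, InvalidInputError, UnsupportedError
from .sizestats import PooledSeries, zscore_filter

logger = logging.getLogger(__name__)

MAX_COMPONENTS = 4
_PDF_FLOOR = 1e-300


@dataclass(frozen=True)
class SpeciesComponent:
    """One birch species' size distribution: name, mean and SD (μm or μm²)."""

    name: str
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise InvalidInputError(f"sigma must be > 0 for component {self.name!r}")


@dataclass
class MixtureSpec:
    """Fixed components plus a proportion vector on the simplex."""

    components: list[SpeciesComponent]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.components)
        if not 1 <= k <= MAX_COMPONENTS:
            raise InvalidInputError(f"1 <= K <= {MAX_COMPONENTS} components required, got {k}")
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (k,):
            raise InvalidInputError("proportions must have one entry per component")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidInputError("proportions must be >= 0 and sum to 1 within 1e-9")
        self.proportions = p

    @property
    def k(self) -> int:
        return len(self.components)


@dataclass
class FitConfig:
    """Optimizer and gating configuration for proportion fitting.

    Defaults mirror common DEoptim settings: population 10 per free weight,
    F=0.8, CR=0.9, 200 generations. ``allow_shift`` adds one shared location
    offset (bounded by ``shift_bounds``, μm) to all component means, to
    absorb preparation-related swelling; off by default.
    """

    objective: str = "nll"  # "nll" | "hist_l2"
    min_obs: int = 25
    generations: int = 200
    popsize: int = 10
    mutation: float = 0.8
    recombination: float = 0.9
    seed: int = 0
    allow_shift: bool = False
    shift_bounds: tuple[float, float] = (-3.0, 3.0)
    hist_bins: int = 30


@dataclass
class UnmixResult:
    proportions: np.ndarray
    objective: float
    n_obs: int
    converged: bool
    seed: int
    generations: int
    population_size: int
    component_names: list[str] = field(default_factory=list)
    shift: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidInputError("result proportions must lie on the simplex")
        if not math.isfinite(self.objective):
            raise InvalidInputError("objective must be finite")
        self.proportions = np.clip(p, 0.0, None)


def mixture_pdf(x: np.ndarray | float, spec: MixtureSpec) -> np.ndarray | float:
    """Density of the compound distribution Σ pᵢ·N(x; μᵢ, σᵢ)."""
    xs = np.asarray(x, dtype=float)
    mus = np.array([c.mu for c in spec.components])
    sig = np.array([c.sigma for c in spec.components])
    z = (xs[..., None] - mus) / sig
    dens = (spec.proportions / (sig * np.sqrt(2 * np.pi)) * np.exp(-0.5 * z**2)).sum(axis=-1)
    return dens if xs.ndim else float(dens)


def _hist_l2(obs: np.ndarray, spec: MixtureSpec, bins: int) -> float:
    mus = np.array([c.mu for c in spec.components])
    sig = np.array([c.sigma for c in spec.components])
    lo = min(obs.min(), (mus - 4 * sig).min())
    hi = max(obs.max(), (mus + 4 * sig).max())
    hist, edges = np.histogram(obs, bins=bins, range=(lo, hi), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    model = np.asarray(mixture_pdf(centers, spec))
    return float(np.sqrt(np.mean((hist - model) ** 2)))


def objective(
    observations: np.ndarray,
    spec: MixtureSpec,
    method: str = "nll",
    hist_bins: int = 30,
) -> float:
    """Dissimilarity between observations and the compound distribution.

    ``"nll"``: mean negative log density over observations (lower = better);
    densities are floored at machine tininess so stray observations far from
    every component degrade, but never break, the objective.
    ``"hist_l2"``: root-mean-square distance between the empirical histogram
    density and the model density at bin centers.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise InvalidInputError("objective requires at least one observation")
    if method == "nll":
        dens = np.asarray(mixture_pdf(obs, spec))
        n_floored = int(np.count_nonzero(dens < _PDF_FLOOR))
        if n_floored:
            logger.debug("floored %d zero-density observations", n_floored)
        return float(-np.log(np.maximum(dens, _PDF_FLOOR)).mean())
    if method == "hist_l2":
        return _hist_l2(obs, spec, hist_bins)
    raise InvalidInputError(f"unknown objective method {method!r}")


def _canonical_order(components: list[SpeciesComponent]) -> np.ndarray:
    return np.array(
        sorted(range(len(components)), key=lambda i: (components[i].mu, components[i].name))
    )


def fit_proportions(
    observations: np.ndarray,
    components: list[SpeciesComponent],
    config: FitConfig | None = None,
) -> UnmixResult:
    """Estimate mixing proportions by seeded differential evolution.

    The search runs over K raw weights in (0, 1] normalized by their sum
    (simplex reparameterization keeps the box constraints trivial), followed
    by an L-BFGS-B polish. Components are canonically ordered internally so
    permuting the component list permutes the result exactly. For K = 1 the
    answer is (1.0) by construction and no optimization runs.
    """
    config = config or FitConfig()
    obs = np.asarray(observations, dtype=float)
    k = len(components)
    if k > MAX_COMPONENTS:
        raise UnsupportedError(f"at most {MAX_COMPONENTS} components supported, got {k}")
    if k < 1:
        raise InvalidInputError("at least one component required")
    if obs.size < config.min_obs:
        raise GateError(
            f"sample has {obs.size} observations, below the minimum of {config.min_obs}"
        )
    degenerate = bool(np.ptp(obs) == 0)
    names = [c.name for c in components]
    if k == 1:
        spec = MixtureSpec(components=components, proportions=np.array([1.0]))
        return UnmixResult(
            proportions=np.array([1.0]),
            objective=objective(obs, spec, config.objective, config.hist_bins),
            n_obs=obs.size,
            converged=not degenerate,
            seed=config.seed,
            generations=0,
            population_size=0,
            component_names=names,
        )

    order = _canonical_order(components)
    comps = [components[i] for i in order]

    def loss(params: np.ndarray) -> float:
        w = params[:k]
        s = w.sum()
        if s <= 0:
            return 1e12
        shift = params[k] if config.allow_shift else 0.0
        shifted = [
            SpeciesComponent(c.name, c.mu + shift, c.sigma) for c in comps
        ] if shift else comps
        spec = MixtureSpec(components=shifted, proportions=w / s)
        return objective(obs, spec, config.objective, config.hist_bins)

    bounds = [(1e-9, 1.0)] * k
    if config.allow_shift:
        bounds.append(config.shift_bounds)
    result = differential_evolution(
        loss,
        bounds=bounds,
        strategy="best1bin",
        maxiter=config.generations,
        popsize=config.popsize,
        mutation=config.mutation,
        recombination=config.recombination,
        tol=1e-10,
        seed=config.seed,
        polish=True,
        init="latinhypercube",
    )
    w = result.x[:k]
    p_sorted = w / w.sum()
    proportions = np.empty(k)
    proportions[order] = p_sorted
    shift = float(result.x[k]) if config.allow_shift else 0.0
    return UnmixResult(
        proportions=proportions,
        objective=float(result.fun),
        n_obs=obs.size,
        converged=bool(result.success) and not degenerate,
        seed=config.seed,
        generations=int(result.nit),
        population_size=config.popsize * len(bounds),
        component_names=names,
        shift=shift,
    )


def unmix_record(
    pooled: list[PooledSeries],
    components: list[SpeciesComponent],
    config: FitConfig | None = None,
    zscore_threshold: float = 2.5,
    zscore_passes: int = 2,
) -> pd.DataFrame:
    """Fit proportions for each pooled stratigraphic sample.

    Each pooled unit is z-score filtered, gated on the minimum grain count,
    and fitted; gated-out units appear in the output with NaN proportions
    and a reason code, so the stratigraphic table keeps one row per unit.
    Per-unit seeds are derived deterministically from the configured seed.
    """
    config = config or FitConfig()
    names = [c.name for c in components]
    rows = []
    for i, unit in enumerate(pooled):
        row: dict = {
            "sample_id": unit.pooled_id,
            "depth": unit.depth,
            "n_raw": unit.n,
        }
        if unit.n == 0:
            row.update(n=0, reason="empty", converged=False)
            rows.append(row)
            continue
        values = zscore_filter(unit.values, threshold=zscore_threshold, passes=zscore_passes)
        row["n"] = values.size
        unit_cfg = FitConfig(**{**config.__dict__, "seed": (config.seed * 9973 + i) % (2**31)})
        if values.size < config.min_obs:
            row.update(reason="below_min_count", converged=False)
        else:
            fit = fit_proportions(values, components, unit_cfg)
            row.update(
                {f"p_{n}": p for n, p in zip(names, fit.proportions)},
                objective=fit.objective,
                converged=fit.converged,
                seed=fit.seed,
                reason="",
            )
        rows.append(row)
    columns = ["sample_id", "depth", "n_raw", "n"] + [f"p_{n}" for n in names] + [
        "objective",
        "converged",
        "seed",
        "reason",
    ]
    return pd.DataFrame(rows).reindex(columns=columns)
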