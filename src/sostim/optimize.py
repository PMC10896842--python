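"""Stimulation-paradigm search: GA waveform fitting and protocol selection.

For every cell of the (montage × waveform family × Δt) search grid, a
genetic algorithm tunes the waveform parameters so that the paradigm's
forward-modelled CD matches the average global-SO CD under a weighted
objective

    ε = Σᵢ ωᵢ d(xᵢ, xᵢ*) / Σᵢ ωᵢ,

where ωᵢ are ANOVA-F feature weights and d is the squared difference
(an absolute-difference variant is available). Candidate protocols are
then scored with the weighted correlation coefficient (WCC) and the
weighted mean squared error (WMSE), classified with the sleep-trained
global/non-global classifier, and the paradigm with the highest "global"
posterior probability is selected as the stimulation protocol.

The GA uses tournament selection, blend crossover, bounded Gaussian
mutation and elitism; it terminates when the average relative change of
the best fitness over a 50-generation stall window drops to 1e-6 or the
generation count reaches 100 × (number of parameters).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .cd import CDMatrix, TransferModel, flatten_cd, make_cd
from .classify import FeatureWeights, SOClassifier, posterior as clf_posterior
from .montage import Montage, Paradigm, enumerate_montages  # noqa: F401  (re-export)
from .waveforms import PARAM_NAMES, Waveform, bin_many, default_bounds


# ---------------------------------------------------------------------------
# weighted metrics


def _check_xyw(x, y, w):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y and w must have equal lengths")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must not be all zero")
    return x, y, w


def weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def weighted_cov(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    mx, my = weighted_mean(x, w), weighted_mean(y, w)
    return float(np.sum(w * (x - mx) * (y - my)) / np.sum(w))


def wcc(x, y, w) -> float:
    """Weighted correlation coefficient cov(x,y;w)/√(cov(x,x;w)·cov(y,y;w))."""
    x, y, w = _check_xyw(x, y, w)
    vx, vy = weighted_cov(x, x, w), weighted_cov(y, y, w)
    if vx <= 0 or vy <= 0:
        raise ValueError("WCC undefined: zero weighted variance in an input")
    return weighted_cov(x, y, w) / np.sqrt(vx * vy)


def wmse(x, y, w, mode: str = "squared") -> float:
    """Weighted mean error Σ wᵢ d(yᵢ, xᵢ) / Σ wᵢ with d squared (default)
    or absolute difference."""
    x, y, w = _check_xyw(x, y, w)
    d = (y - x) ** 2 if mode == "squared" else np.abs(y - x)
    if mode not in ("squared", "absolute"):
        raise ValueError(f"unknown error mode {mode!r}")
    return float(np.sum(w * d) / np.sum(w))


def objective_epsilon(x_sim, x_target, w: FeatureWeights | np.ndarray,
                      mode: str = "squared") -> float:
    """GA fitness: weighted mean discrepancy between simulated and target CD."""
    wv = w.w if isinstance(w, FeatureWeights) else np.asarray(w, dtype=float)
    return wmse(x_target, x_sim, wv, mode=mode)


# ---------------------------------------------------------------------------
# genetic algorithm


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters; termination rules are stall-based or a hard cap."""

    population: int = 200
    crossover_fraction: float = 0.8
    mutation_sigma: float = 0.1      # × parameter range, per-gene Gaussian
    mutation_rate: float = 0.15      # per-gene mutation probability
    elitism: int = 2
    tournament: int = 3
    stall_generations: int = 50
    stall_tolerance: float = 1e-6
    max_generations_per_param: int = 100
    #: hard generation cap overriding 100 × n_params; the initial random
    #: population counts as generation 1
    max_generations: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 10:
            raise ValueError("population must be at least 10")
        if self.stall_tolerance <= 0:
            raise ValueError("stall tolerance must be positive")


@dataclass
class GAResult:
    waveform: Waveform
    fitness: float
    trace: np.ndarray          # best fitness per generation
    generations: int
    terminated_by: str         # "stall" | "max_generations"


def _stalled(trace: list[float], window: int, tol: float) -> bool:
    """Average relative change of best fitness over the stall window ≤ tol."""
    if len(trace) <= window:
        return False
    recent = np.array(trace[-(window + 1):])
    denom = np.maximum(np.abs(recent[:-1]), 1e-300)
    rel = np.abs(np.diff(recent)) / denom
    return bool(rel.mean() <= tol)


def run_ga(kind: str, montage: Montage, dt: int, target: CDMatrix,
           tm: TransferModel, weights: FeatureWeights,
           cfg: GAConfig | None = None, mode: str = "squared",
           bounds=None) -> GAResult:
    """Optimize one waveform family against a target CD for one montage/Δt.

    Minimises ``objective_epsilon`` over the family's bounded parameter
    space. Deterministic given ``cfg.seed``. The per-generation best
    fitness trace is non-increasing (elitism).
    """
    cfg = cfg or GAConfig()
    if target.dt != dt:
        raise ValueError(f"target dt {target.dt} ms does not match paradigm dt {dt} ms")
    bounds = np.asarray(bounds if bounds is not None else default_bounds(kind), float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(~np.isfinite(bounds)):
        raise ValueError("every parameter needs finite [lo, hi] bounds")
    if np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("bounds must satisfy lo < hi for every parameter")
    n_params = len(PARAM_NAMES[kind])
    if bounds.shape[0] != n_params:
        raise ValueError(f"{kind} needs {n_params} bound pairs")
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    tvec = np.asarray(tm.vector(montage), dtype=float)
    x_target = flatten_cd(target)
    wv = weights.w
    if len(wv) != x_target.size:
        raise ValueError("feature weights length does not match target CD")

    def fitness(pop: np.ndarray) -> np.ndarray:
        binned = bin_many(kind, pop, dt)            # (p, m)
        sim = binned[:, :, None] * tvec[None, None, :]  # (p, m, n)
        diff = sim.reshape(pop.shape[0], -1) - x_target[None, :]
        d = diff**2 if mode == "squared" else np.abs(diff)
        return d @ wv / wv.sum()

    rng = np.random.default_rng(cfg.seed)
    pop = lo + span * rng.random((cfg.population, n_params))
    fit = fitness(pop)
    max_gen = (cfg.max_generations if cfg.max_generations is not None
               else cfg.max_generations_per_param * n_params)
    trace: list[float] = [float(fit.min())]
    terminated_by = "max_generations"
    for _ in range(max(max_gen - 1, 0)):
        order = np.argsort(fit)
        elite = pop[order[: cfg.elitism]]
        n_children = cfg.population - cfg.elitism
        # tournament selection
        idx = rng.integers(0, cfg.population, size=(2 * n_children, cfg.tournament))
        winners = idx[np.arange(2 * n_children), fit[idx].argmin(axis=1)]
        pa, pb = pop[winners[:n_children]], pop[winners[n_children:]]
        # blend (intermediate) crossover on a fraction of pairs
        do_x = rng.random(n_children) < cfg.crossover_fraction
        alpha = rng.random((n_children, n_params))
        children = np.where(do_x[:, None], pa + alpha * (pb - pa), pa)
        # bounded Gaussian mutation
        mutate = rng.random(children.shape) < cfg.mutation_rate
        noise = rng.normal(0.0, cfg.mutation_sigma, children.shape) * span
        children = np.clip(children + mutate * noise, lo, hi)
        pop = np.vstack([elite, children])
        fit = fitness(pop)
        trace.append(float(fit.min()))
        if _stalled(trace, cfg.stall_generations, cfg.stall_tolerance):
            terminated_by = "stall"
            break
    best = pop[int(np.argmin(fit))]
    wf = Waveform(kind=kind, params=tuple(best),
                  bounds=tuple(map(tuple, bounds)))
    return GAResult(waveform=wf, fitness=float(fit.min()),
                    trace=np.array(trace), generations=len(trace) - 1,
                    terminated_by=terminated_by)


# ---------------------------------------------------------------------------
# grid search and protocol selection


@dataclass
class ProtocolResult:
    """One optimised grid cell, with classification and fit metrics."""

    paradigm: Paradigm
    fitness: float
    cd: CDMatrix | None
    posterior: float = float("nan")
    predicted_global: bool = False
    wcc: float = float("nan")
    wmse: float = float("nan")
    generations: int = 0
    terminated_by: str = ""
    failed: bool = False
    failure_reason: str = ""

    def to_record(self) -> dict:
        rec = {
            "paradigm": self.paradigm.key,
            "montage": list(self.paradigm.montage.electrodes),
            "polarities": list(self.paradigm.montage.polarities),
            "waveform_kind": self.paradigm.waveform.kind,
            "params": list(self.paradigm.waveform.params),
            "dt_ms": self.paradigm.dt,
            "fitness": self.fitness,
            "posterior": self.posterior,
            "predicted_global": bool(self.predicted_global),
            "wcc": self.wcc,
            "wmse": self.wmse,
            "generations": self.generations,
            "terminated_by": self.terminated_by,
            "failed": bool(self.failed),
            "failure_reason": self.failure_reason,
        }
        return rec


def _cell_seed(master_seed: int, cell_index: int) -> int:
    """Stable per-cell seed independent of evaluation order."""
    return int(np.random.SeedSequence([master_seed, cell_index]).generate_state(1)[0]
               % (2**31 - 1))


def optimize_grid(montages: list[Montage], kinds: list[str], dts: list[int],
                  target: CDMatrix | dict[int, CDMatrix], tm: TransferModel,
                  weights: FeatureWeights | dict[int, FeatureWeights],
                  cfg: GAConfig | None = None,
                  mode: str = "squared") -> list[ProtocolResult]:
    """One GA run per (montage, waveform kind, Δt) grid cell.

    ``target`` and ``weights`` may be single objects (one Δt) or dicts
    keyed by Δt. Failed cells are recorded with their failure reason
    rather than dropped.
    """
    cfg = cfg or GAConfig()
    if not montages or not kinds or not dts:
        raise ValueError("empty search grid")
    results: list[ProtocolResult] = []
    cell = 0
    for dt in dts:
        tgt = target[dt] if isinstance(target, dict) else target
        wts = weights[dt] if isinstance(weights, dict) else weights
        for kind in kinds:
            for montage in montages:
                seed = _cell_seed(cfg.seed, cell)
                cell += 1
                cell_cfg = GAConfig(**{**asdict(cfg), "seed": seed})
                placeholder = Paradigm(
                    montage=montage,
                    waveform=Waveform(kind, [b[0] for b in default_bounds(kind)]),
                    dt=dt)
                try:
                    ga = run_ga(kind, montage, dt, tgt, tm, wts,
                                cfg=cell_cfg, mode=mode)
                    if not np.isfinite(ga.fitness):
                        raise ArithmeticError("non-finite GA fitness")
                    paradigm = Paradigm(montage=montage, waveform=ga.waveform, dt=dt)
                    cd = make_cd(
                        np.outer(bin_many(kind, np.asarray(ga.waveform.params)[None],
                                          dt)[0], tm.vector(montage)),
                        dt, tm.regions)
                    results.append(ProtocolResult(
                        paradigm=paradigm, fitness=ga.fitness, cd=cd,
                        generations=ga.generations,
                        terminated_by=ga.terminated_by))
                except (KeyError, ValueError, ArithmeticError) as exc:
                    results.append(ProtocolResult(
                        paradigm=placeholder, fitness=float("inf"), cd=None,
                        failed=True, failure_reason=str(exc)))
    return results


def score_results(results: list[ProtocolResult],
                  target: CDMatrix | dict[int, CDMatrix],
                  weights: FeatureWeights | dict[int, FeatureWeights],
                  model: SOClassifier, mode: str = "squared") -> None:
    """Attach posterior, predicted class, WCC and WMSE to each result in place."""
    for r in results:
        if r.failed or r.cd is None:
            continue
        tgt = target[r.paradigm.dt] if isinstance(target, dict) else target
        wts = weights[r.paradigm.dt] if isinstance(weights, dict) else weights
        x = flatten_cd(r.cd)
        xt = flatten_cd(tgt)
        r.posterior = float(clf_posterior(model, x))
        r.predicted_global = r.posterior >= 0.5
        try:
            r.wcc = wcc(xt, x, wts.w)
        except ValueError:
            r.wcc = float("nan")
        r.wmse = wmse(xt, x, wts.w, mode=mode)


def select_protocol(results: list[ProtocolResult],
                    model: SOClassifier | None = None,
                    target: CDMatrix | dict[int, CDMatrix] | None = None,
                    weights: FeatureWeights | dict[int, FeatureWeights] | None = None,
                    ) -> tuple[ProtocolResult, bool]:
    """Pick the protocol with the highest "global" posterior probability.

    If ``model`` (plus target/weights) is given, results are scored
    first; otherwise they must already carry posteriors. Returns
    ``(result, any_global)``: when no paradigm is classified global, the
    best posterior overall is returned with ``any_global=False``. Posterior
    ties break by weighted fit error, then by stable paradigm key.
    """
    ok = [r for r in results if not r.failed and r.cd is not None]
    if not ok:
        raise ValueError("no successful grid cells to select from")
    if model is not None:
        if target is None or weights is None:
            raise ValueError("scoring requires target and weights")
        score_results(ok, target, weights, model)
    if any(np.isnan(r.posterior) for r in ok):
        raise ValueError("results carry no posteriors; pass a classifier model")
    # posterior ties (common once the bagged ensemble saturates) break by
    # weighted fit error, then by stable paradigm key for determinism
    ranked = sorted(ok, key=lambda r: (
        -r.posterior,
        r.wmse if np.isfinite(r.wmse) else np.inf,
        r.paradigm.key,
    ))
    globals_ = [r for r in ranked if r.predicted_global]
    if globals_:
        return globals_[0], True
    return ranked[0], False


def write_results_jsonl(path, results: list[ProtocolResult]) -> None:
    with open(path, "w") as f:
        for r in results:
            f.write(json.dumps(r.to_record()) + "\n")
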