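"""Ensemble-optimization inference of oligomeric-state fractions.

Given a per-state pool of candidate conformers with precomputed model
curves and one experimental curve, the analysis proceeds as in ensemble
optimization method (EOM/GAJOE-style) studies of self-associating
flexible proteins:

1. ``refine_pool`` — per state, keep the conformers with the lowest
   single-model chi^2 against the data (full-scale: 10000 -> ~2000).
2. ``best_single`` — the per-state chi^2 minima (the "can one rigid
   species explain the curve?" comparison).
3. ``eom_select`` — a genetic algorithm over multisets of size N drawn
   with replacement from the merged refined pool; fitness is the chi^2 of
   the equal-weight ensemble-average curve with its analytic scale
   factor. Full-scale N = 1000; desk-scale default 50.
4. ``extract_fractions`` — per-state selection-frequency fractions,
   averaged over independent GA runs with their run-to-run SD (three runs
   by convention).

An auxiliary intensity-share metric (each state's share of the scaled
zero-angle ensemble intensity) is reported alongside the primary
number-fraction readout, since larger oligomers contribute
disproportionately to the intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .builder import ConformerPool, _mix_seed
from .profile_io import ScatteringProfile
from .scatter import FitStat, chi2_fit

ORDERS = (1, 2, 3, 4, 5)


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters.

    ensemble_size: selected multiset size N (full-scale 1000; desk 50).
    population: candidate ensembles per generation.
    generations: iteration cap; patience: early stop after this many
    generations without improvement. init_top: half of the initial
    candidates are drawn from this many best single conformers, half
    uniformly from the whole pool (mutation can reach everything).
    chi2_stop implements the discrepancy principle: once the reduced
    chi^2 is at the noise level (<= chi2_stop) further descent only fits
    noise, which drags the composition toward degenerate mixtures, so
    refinement halts there (None disables). n_runs independent repeats
    give the run-to-run SD of the fractions.
    """

    ensemble_size: int = 50
    population: int = 100
    generations: int = 500
    mutation_rate: float = 0.05
    crossover_rate: float = 0.5
    elitism: int = 2
    n_runs: int = 3
    seed: int = 0
    patience: int = 100
    init_top: int = 100
    chi2_stop: float | None = 1.0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1 or self.population < 2:
            raise ValueError("ensemble_size >= 1 and population >= 2 required")
        for rate in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class EnsembleSolution:
    """A GA-selected multiset of conformers and its fit."""

    selected: np.ndarray           # indices into the merged pool
    curve: np.ndarray              # equal-weight ensemble-average intensity
    fit: FitStat
    state_counts: dict[int, int]   # per oligomer order
    run_seed: int
    intensity_share: dict[int, float] = field(default_factory=dict)

    @property
    def ensemble_size(self) -> int:
        return int(self.selected.size)


@dataclass
class OligomerDistribution:
    """Per-state number fractions with across-run SD."""

    fraction: dict[int, float]
    sd: dict[int, float]
    n_runs: int
    best_chi2: float

    def to_dict(self) -> dict:
        return {"fraction": {str(k): v for k, v in self.fraction.items()},
                "sd": {str(k): v for k, v in self.sd.items()},
                "n_runs": self.n_runs, "best_chi2": self.best_chi2}


# ---------------------------------------------------------------------------
# pool refinement


def _state_chi2(pool: ConformerPool, data: ScatteringProfile, order: int) -> np.ndarray:
    return np.array([chi2_fit(data, pool.curves[order][i]).chi2
                     for i in range(pool.curves[order].shape[0])])


def refine_pool(pool: ConformerPool, data: ScatteringProfile, keep: int = 40) -> ConformerPool:
    """Per state, retain the ``keep`` conformers with the lowest chi^2.

    Sorting is stable by conformer index, so ties preserve pool order.
    Full-scale keep is ~2000 of 10000 per state (a 20% retention
    ratio); the desk default 40 keeps the same ratio of a 200-per-state
    pool.
    """
    if keep < 1:
        raise ValueError("keep must be >= 1")
    if not np.allclose(pool.q_grid, data.q):
        raise ValueError("pool curves are not on the data's Q grid")
    keep_idx = {}
    for order in pool.orders:
        chi2 = _state_chi2(pool, data, order)
        k = min(keep, chi2.size)
        keep_idx[order] = np.sort(np.argsort(chi2, kind="stable")[:k])
    return pool.subset(keep_idx)


def best_single(pool: ConformerPool, data: ScatteringProfile) -> dict[int, tuple[int, FitStat]]:
    """Per-state argmin-chi^2 single conformer: {order: (index, FitStat)}."""
    out = {}
    for order in pool.orders:
        chi2 = _state_chi2(pool, data, order)
        i = int(np.argmin(chi2))
        out[order] = (i, chi2_fit(data, pool.curves[order][i]))
    return out


# ---------------------------------------------------------------------------
# genetic algorithm


def _merged(pool: ConformerPool):
    """Stack all state curves; returns (matrix, order-per-row, rg-per-row)."""
    mats, orders, rgs = [], [], []
    for o in pool.orders:
        mats.append(pool.curves[o])
        orders.append(np.full(pool.curves[o].shape[0], o))
        rgs.append(pool.rg[o])
    return np.vstack(mats), np.concatenate(orders), np.concatenate(rgs)


def _chi2_of_mean(curve: np.ndarray, intensity: np.ndarray, inv_var: np.ndarray,
                  n_dof: int) -> tuple[float, float]:
    denom = np.sum(curve * curve * inv_var)
    c = np.sum(curve * intensity * inv_var) / denom
    resid2 = np.sum((intensity - c * curve) ** 2 * inv_var)
    return float(resid2 / n_dof), float(c)


def _batch_chi2(P: np.ndarray, pop_arr: np.ndarray, intensity: np.ndarray,
                inv_var: np.ndarray, n_dof: int, sum_d2: float) -> np.ndarray:
    """Reduced chi^2 (analytic scale) of the mean curve of each candidate."""
    means = P[pop_arr].mean(axis=1) if pop_arr.ndim == 2 else P[pop_arr]
    denom = np.einsum("ij,ij,j->i", means, means, inv_var)
    num = means @ (intensity * inv_var)
    return (sum_d2 - num * num / denom) / n_dof


def _exchange_descent(P: np.ndarray, sel: np.ndarray, intensity: np.ndarray,
                      inv_var: np.ndarray, n_dof: int, sum_d2: float,
                      chi2_stop: float | None, max_passes: int = 60) -> np.ndarray:
    """Coordinate descent over ensemble slots: replace each member with
    the pool curve that most lowers chi^2, until a local optimum or the
    discrepancy-principle floor is reached."""
    sel = sel.copy()
    N = sel.size
    i_w = intensity * inv_var
    total = P[sel].sum(axis=0)
    mean = total / N
    cur = float((sum_d2 - (mean @ i_w) ** 2
                 / np.einsum("j,j,j->", mean, mean, inv_var)) / n_dof)
    floor = -np.inf if chi2_stop is None else chi2_stop
    for _ in range(max_passes):
        if cur <= floor:
            break
        improved = False
        for slot in range(N):
            if cur <= floor:
                break
            base = total - P[sel[slot]]
            cands = (base[None, :] + P) / N
            denom = np.einsum("ij,ij,j->i", cands, cands, inv_var)
            num = cands @ i_w
            chis = (sum_d2 - num * num / denom) / n_dof
            j = int(np.argmin(chis))
            if chis[j] < cur - 1e-12:
                total = base + P[j]
                sel[slot] = j
                cur = float(chis[j])
                improved = True
        if not improved:
            break
    return sel


def eom_select(pool: ConformerPool, data: ScatteringProfile,
               config: GAConfig) -> EnsembleSolution:
    """Genetic-algorithm selection of the best-fitting ensemble.

    Candidates are multisets of ``ensemble_size`` conformers drawn with
    replacement from the merged pool; fitness is -chi^2 of the equal-
    weight average curve (analytic scale). Operators: elitist survival,
    tournament parent selection (size 2), uniform crossover, per-slot
    mutation to a uniformly random pool member. The winner is polished by
    an exchange descent (best single-member replacements). Refinement
    halts at the ``chi2_stop`` discrepancy floor: fitting below the noise
    level only absorbs noise into the composition.

    The initial population contains one candidate made of N copies of
    the best single conformer, so with elitism and a descent that only
    improves, the final ensemble can never fit worse than the best
    single model. Deterministic for a given seed.
    """
    P, row_orders, _ = _merged(pool)
    m = P.shape[0]
    if m < 1:
        raise ValueError("empty pool")
    if not np.allclose(pool.q_grid, data.q):
        raise ValueError("pool curves are not on the data's Q grid")
    rng = np.random.default_rng(config.seed)
    N, pop_n = config.ensemble_size, config.population
    intensity, inv_var = data.intensity, 1.0 / data.sigma ** 2
    n_dof = max(len(intensity) - 1, 1)
    sum_d2 = float(np.sum(intensity * intensity * inv_var))
    floor = -np.inf if config.chi2_stop is None else config.chi2_stop

    single_chi2 = _batch_chi2(P, np.arange(m), intensity, inv_var, n_dof, sum_d2)
    top = np.argsort(single_chi2, kind="stable")[:min(config.init_top, m)]
    best_single_idx = int(top[0])

    # mixed initialization: half from the best singles, half uniform over
    # the pool; one candidate is N copies of the overall best single
    pop = np.empty((pop_n, N), dtype=np.intp)
    n_top = pop_n // 2
    pop[:n_top] = rng.choice(top, size=(n_top, N))
    pop[n_top:] = rng.integers(0, m, size=(pop_n - n_top, N))
    pop[0, :] = best_single_idx

    chi2s = _batch_chi2(P, pop, intensity, inv_var, n_dof, sum_d2)
    best_chi2 = chi2s.min()
    stall = 0
    for _ in range(config.generations):
        if best_chi2 <= floor:
            break
        order_idx = np.argsort(chi2s, kind="stable")
        elite = pop[order_idx[:config.elitism]]
        n_children = pop_n - config.elitism
        cand = rng.integers(0, pop_n, size=(n_children, 2, 2))
        winners = np.where(chi2s[cand[:, :, 0]] <= chi2s[cand[:, :, 1]],
                           cand[:, :, 0], cand[:, :, 1])
        pa, pb = pop[winners[:, 0]], pop[winners[:, 1]]
        do_cross = rng.random(n_children) < config.crossover_rate
        mask = rng.random((n_children, N)) < 0.5
        kids = np.where(mask, pa, pb)
        kids[~do_cross] = pa[~do_cross]
        mut = rng.random((n_children, N)) < config.mutation_rate
        kids[mut] = rng.integers(0, m, size=int(mut.sum()))
        pop = np.vstack([elite, kids])
        chi2s = _batch_chi2(P, pop, intensity, inv_var, n_dof, sum_d2)
        gen_best = chi2s.min()
        if gen_best < best_chi2 - 1e-12:
            best_chi2, stall = gen_best, 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    winner = pop[int(np.argmin(chi2s))]
    winner = _exchange_descent(P, winner, intensity, inv_var, n_dof, sum_d2,
                               config.chi2_stop)
    mean_curve = P[winner].mean(axis=0)
    fit = chi2_fit(data, mean_curve)
    counts = {o: int(np.sum(row_orders[winner] == o)) for o in pool.orders}
    # intensity share at Q -> 0 of the scaled ensemble
    i0 = P[winner][:, 0]
    share_tot = i0.sum()
    share = {o: float(i0[row_orders[winner] == o].sum() / share_tot)
             for o in pool.orders}
    return EnsembleSolution(selected=np.sort(winner), curve=mean_curve, fit=fit,
                            state_counts=counts, run_seed=config.seed,
                            intensity_share=share)


def extract_fractions(solutions: list[EnsembleSolution]) -> OligomerDistribution:
    """Across-run mean and SD of selection-frequency fractions."""
    if not solutions:
        raise ValueError("need at least one run")
    sizes = {s.ensemble_size for s in solutions}
    if len(sizes) != 1:
        raise ValueError("inconsistent ensemble sizes across runs")
    n = sizes.pop()
    orders = sorted(set().union(*[s.state_counts for s in solutions]))
    counts = np.array([[s.state_counts.get(o, 0) for o in orders]
                       for s in solutions])
    per_run = counts / n
    mean = per_run.mean(axis=0)
    sd = per_run.std(axis=0, ddof=0)
    sd[counts.max(axis=0) == counts.min(axis=0)] = 0.0  # identical runs: exactly 0
    return OligomerDistribution(
        fraction={o: float(mean[j]) for j, o in enumerate(orders)},
        sd={o: float(sd[j]) for j, o in enumerate(orders)},
        n_runs=len(solutions),
        best_chi2=float(min(s.fit.chi2 for s in solutions)))


def rg_histogram(rg_by_state: dict[int, np.ndarray], bin_width: float = 2.0) -> pd.DataFrame:
    """Binned Rg counts per state and overall.

    Returns a tidy DataFrame with columns (state, bin_left, bin_right,
    count); state "all" aggregates every model. Empty input gives an
    empty table.
    """
    cols = ["state", "bin_left", "bin_right", "count"]
    values = [v for v in rg_by_state.values() if len(v)]
    if not values:
        return pd.DataFrame(columns=cols)
    allrg = np.concatenate(values)
    lo = np.floor(allrg.min() / bin_width) * bin_width
    hi = np.ceil(allrg.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    rows = []
    for state, rg in list(rg_by_state.items()) + [("all", allrg)]:
        counts, _ = np.histogram(rg, bins=edges)
        for j, c in enumerate(counts):
            rows.append((str(state), float(edges[j]), float(edges[j + 1]), int(c)))
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# orchestration


def fit_report(data: ScatteringProfile, pool: ConformerPool,
               config: GAConfig, keep: int = 40) -> dict:
    """Full flexible-oligomer analysis of one curve.

    refine -> best_single -> n_runs x eom_select -> extract_fractions ->
    rg histograms; returns a JSON-serializable report dict.
    """
    refined = refine_pool(pool, data, keep=keep)
    singles = best_single(refined, data)
    solutions = []
    for run in range(config.n_runs):
        run_cfg = GAConfig(**{**asdict(config),
                              "seed": _mix_seed(config.seed, run)})
        solutions.append(eom_select(refined, data, run_cfg))
    dist = extract_fractions(solutions)
    hist = rg_histogram(refined.rg)
    chi2_vs_rg = []
    for o in refined.orders:
        chi2 = _state_chi2(refined, data, o)
        for i in range(chi2.size):
            chi2_vs_rg.append({"state": o, "rg": float(refined.rg[o][i]),
                               "chi2": float(chi2[i])})
    mean_share = {o: float(np.mean([s.intensity_share.get(o, 0.0)
                                    for s in solutions]))
                  for o in refined.orders}
    return {
        "label": data.label,
        "config": asdict(config),
        "keep_per_state": keep,
        "pool_n_per_state": pool.n_per_state(),
        "best_single_chi2": {str(o): singles[o][1].chi2 for o in refined.orders},
        "ensemble_chi2_per_run": [s.fit.chi2 for s in solutions],
        "run_seeds": [s.run_seed for s in solutions],
        "state_counts_per_run": [{str(k): v for k, v in s.state_counts.items()}
                                 for s in solutions],
        "distribution": dist.to_dict(),
        "intensity_share": {str(k): v for k, v in mean_share.items()},
        "rg_histogram": hist.to_dict(orient="records"),
        "chi2_vs_rg": chi2_vs_rg,
    }
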