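"""Morris elementary-effects screening of the AtoSC model, from scratch.

Each sample point is a full parameter vector; its "output" is the set of
Hill features (fmin, fmax, K, n, fold change) fitted to the steady-state
k_ap dose-response curve simulated at that parameter vector.  The screening
follows the radial-trajectory Morris design with the Campolongo
spread-maximising subset selection: R candidate trajectories are generated
on a p-level grid in the unit hypercube, the r most spread-out are kept,
and one-at-a-time steps of size delta = p / (2(p-1)) yield elementary
effects

    EE_i = (y(x + delta e_i) - y(x)) / (+-delta),

summarised per parameter as mu (signed mean), mu* (mean absolute, the
influence measure) and sigma (SD across trajectories, flagging
nonlinearity/interactions).  mu* is normalised per output column by the
column maximum for heatmap comparison across features.
"""

from __future__ import annotations

import itertools
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .doseresponse import fit_hill, sweep_dose_response, SweepError
from .model import PARAM_FILE_KEYS, TCSParameters

__all__ = [
    "FEATURES",
    "ParameterSpace",
    "MorrisDesign",
    "MorrisResult",
    "MorrisEvaluationError",
    "default_space",
    "generate_candidate_trajectories",
    "trajectory_distance_matrix",
    "select_optimal_trajectories",
    "select_exhaustive",
    "evaluate_feature_map",
    "elementary_effects",
    "aggregate_and_normalise",
    "rank_parameters",
    "run_morris",
]

FEATURES = ("fmin", "fmax", "K", "n", "fold_change")

# The screened parameters: every TCS rate constant and the three totals.
# k_ap is excluded (it is the swept dose proxy), as are the reporter
# cascade constants (held fixed; they only rescale the output).
SCREEN_NAMES = (
    "C", "k_ad", "k_b1", "k_b2", "k_b3", "k_bnd", "k_d1", "k_d2", "k_d3",
    "k_lgexp", "k_ph", "k_pmgexp", "k_pt", "k_unbnd", "pato", "S",
)


class MorrisEvaluationError(RuntimeError):
    """Too many feature-map evaluations failed to trust the screening."""


@dataclass(frozen=True)
class ParameterSpace:
    """Named box in parameter space with per-parameter sampling scale."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray
    scale: tuple  # "linear" or "log10" per parameter

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "scale", tuple(self.scale))
        k = len(self.names)
        if not (len(self.lower) == len(self.upper) == len(self.scale) == k):
            raise ValueError("names, lower, upper, scale must have equal length")
        if np.any(self.lower >= self.upper):
            raise ValueError("require lower < upper elementwise")
        for nm, lo, sc in zip(self.names, self.lower, self.scale):
            if sc not in ("linear", "log10"):
                raise ValueError(f"unknown scale {sc!r} for {nm}")
            if sc == "log10" and lo <= 0:
                raise ValueError(f"log10 scale requires lower > 0 ({nm})")
        unknown = set(self.names) - set(PARAM_FILE_KEYS)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")

    @property
    def k(self) -> int:
        return len(self.names)

    def map_unit(self, points: np.ndarray) -> np.ndarray:
        """Map unit-hypercube coordinates to parameter values (uniform on
        the declared scale)."""
        u = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty_like(u)
        for j, sc in enumerate(self.scale):
            if sc == "linear":
                out[:, j] = self.lower[j] + u[:, j] * (self.upper[j] - self.lower[j])
            else:
                lo, hi = math.log10(self.lower[j]), math.log10(self.upper[j])
                out[:, j] = 10.0 ** (lo + u[:, j] * (hi - lo))
        return out if np.asarray(points).ndim == 2 else out[0]

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "scale": list(self.scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSpace":
        return cls(tuple(d["names"]), d["lower"], d["upper"], tuple(d["scale"]))


def default_space(base: TCSParameters | None = None, decades: float = 1.0) -> ParameterSpace:
    """Two-decade log-uniform box centred on the nominal parameter set.

    These bounds are the package's stand-in design (the study's exact
    bounds are not published in the main text); override from config for a
    different screen.
    """
    base = base or TCSParameters()
    lower, upper = [], []
    for name in SCREEN_NAMES:
        nominal = getattr(base, PARAM_FILE_KEYS[name])
        lower.append(nominal / 10.0**decades)
        upper.append(nominal * 10.0**decades)
    return ParameterSpace(SCREEN_NAMES, lower, upper, ("log10",) * len(SCREEN_NAMES))


@dataclass(frozen=True)
class MorrisDesign:
    """Sampling design: p-level grid, R candidates, r selected, fixed seed."""

    p: int = 4
    R: int = 1000
    r: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.p < 4 or self.p % 2:
            raise ValueError("p must be even and >= 4")
        if not 1 <= self.r <= self.R:
            raise ValueError("require 1 <= r <= R")

    @property
    def delta(self) -> float:
        return self.p / (2.0 * (self.p - 1))


def generate_candidate_trajectories(space: ParameterSpace, design: MorrisDesign) -> np.ndarray:
    """R radial trajectories of k+1 points each in the unit hypercube.

    Each trajectory starts at a random grid point (levels restricted so
    every +delta step stays inside [0,1]), then changes one coordinate at a
    time by +-delta in a random order with random per-coordinate sign.
    Fully reproducible from the design seed.
    """
    k = space.k
    rng = np.random.default_rng(design.seed)
    delta = design.delta
    n_base_levels = design.p // 2  # levels l/(p-1) with l + delta*(p-1) <= p-1
    levels = np.arange(n_base_levels) / (design.p - 1)
    J = np.ones((k + 1, k))
    B = np.tril(J, -1)
    trajs = np.empty((design.R, k + 1, k))
    for t in range(design.R):
        x_base = rng.choice(levels, size=k)
        signs = rng.choice([-1.0, 1.0], size=k)
        perm = rng.permutation(k)
        # staircase of 0/delta increments, sign-flipped per coordinate:
        # negative-direction coordinates start at x_base + delta and step down
        steps = (delta / 2.0) * ((2.0 * B - J) * signs + J)
        traj = x_base + steps
        # apply the coordinate-change order: row l+1 flips coordinate perm[l]
        reordered = np.empty_like(traj)
        reordered[0] = traj[0]
        current = traj[0].copy()
        for step_idx, coord in enumerate(perm):
            current = current.copy()
            current[coord] = traj[k, coord]  # final value of that coordinate
            reordered[step_idx + 1] = current
        trajs[t] = reordered
    if trajs.min() < -1e-12 or trajs.max() > 1 + 1e-12:
        raise AssertionError("trajectory left the unit hypercube")
    return np.clip(trajs, 0.0, 1.0)


def trajectory_distance_matrix(trajectories: np.ndarray) -> np.ndarray:
    """Pairwise trajectory distances: sum of Euclidean distances between
    every point pair of the two trajectories (the Campolongo distance)."""
    R, npts, k = trajectories.shape
    flat = trajectories.reshape(R * npts, k)
    D = np.zeros((R, R))
    for m in range(R):
        d = cdist(trajectories[m], flat)  # (npts, R*npts)
        D[m] = d.reshape(npts, R, npts).sum(axis=(0, 2))
    np.fill_diagonal(D, 0.0)
    return D


def _spread(D2: np.ndarray, subset: np.ndarray) -> float:
    """Campolongo criterion: sqrt of the sum of squared pairwise distances."""
    sub = D2[np.ix_(subset, subset)]
    return math.sqrt(sub.sum() / 2.0)


def select_optimal_trajectories(
    candidates: np.ndarray, r: int, return_indices: bool = False
):
    """Pick the r-subset (approximately) maximising pairwise spread.

    Small instances (up to ~10k subsets) are solved exactly by
    enumeration.  Beyond that, exhaustive search over C(R, r) subsets is
    infeasible, so the search is the standard greedy construction (best
    pair, then best single extension) followed by single-swap hill climbing
    until no swap improves the criterion.  Deterministic given the
    candidate order; ties resolve to the lowest index.
    """
    R = len(candidates)
    if r > R:
        raise ValueError(f"cannot select {r} from {R} candidates")
    if r == R:
        idx = np.arange(R)
        return (candidates, idx) if return_indices else candidates
    if math.comb(R, r) <= 10_000:
        return select_exhaustive(candidates, r, return_indices=return_indices)
    D = trajectory_distance_matrix(candidates)
    D2 = D * D

    if r == 1:
        idx = [0]
    else:
        # greedy: seed with the farthest pair
        m, l = np.unravel_index(np.argmax(D2), D2.shape)
        chosen = [min(m, l), max(m, l)]
        while len(chosen) < r:
            mask = np.ones(R, dtype=bool)
            mask[chosen] = False
            gains = D2[:, chosen].sum(axis=1)
            gains[~mask] = -np.inf
            chosen.append(int(np.argmax(gains)))
        idx = sorted(chosen)

    # single-swap hill climbing
    idx = list(idx)
    improved = True
    while improved:
        improved = False
        current = _spread(D2, np.array(idx))
        in_set = set(idx)
        best_gain, best_swap = 0.0, None
        for pos, t_out in enumerate(idx):
            others = [t for t in idx if t != t_out]
            base_sum = D2[np.ix_(others, others)].sum() / 2.0
            cross = D2[:, others].sum(axis=1)
            for t_in in range(R):
                if t_in in in_set:
                    continue
                cand = math.sqrt(base_sum + cross[t_in])
                if cand - current > best_gain + 1e-15:
                    best_gain, best_swap = cand - current, (pos, t_in)
        if best_swap is not None:
            pos, t_in = best_swap
            idx[pos] = t_in
            idx = sorted(idx)
            improved = True
    idx = np.array(sorted(idx))
    return (candidates[idx], idx) if return_indices else candidates[idx]


def select_exhaustive(candidates: np.ndarray, r: int, return_indices: bool = False):
    """Brute-force subset selection; only viable for tiny candidate sets."""
    R = len(candidates)
    D = trajectory_distance_matrix(candidates)
    D2 = D * D
    best, best_idx = -np.inf, None
    for combo in itertools.combinations(range(R), r):
        s = _spread(D2, np.array(combo))
        if s > best + 1e-15:
            best, best_idx = s, combo
    idx = np.array(best_idx)
    return (candidates[idx], idx) if return_indices else candidates[idx]


# ---------------------------------------------------------------------------
# feature map: unit point -> parameters -> dose-response -> Hill features


def _point_features(args):
    point, space_dict, base_dict, kap_grid = args
    space = ParameterSpace.from_dict(space_dict)
    base = TCSParameters.from_dict(base_dict)
    values = space.map_unit(np.asarray(point))
    overrides = {PARAM_FILE_KEYS[nm]: float(v) for nm, v in zip(space.names, values)}
    params = base.replace(**overrides)
    try:
        curve = sweep_dose_response(params, kap_grid)
        fit = fit_hill(curve)
        if not fit.converged:
            return [math.nan] * len(FEATURES)
        return [fit.fmin, fit.fmax, fit.K, fit.n, fit.fold_change]
    except (SweepError, ValueError, RuntimeError):
        return [math.nan] * len(FEATURES)


def evaluate_feature_map(
    points: np.ndarray,
    space: ParameterSpace,
    base_params: TCSParameters,
    kap_grid,
    workers: int = 1,
    max_failure_fraction: float = 0.10,
) -> np.ndarray:
    """Map unit-hypercube points to Hill features of their dose-response.

    Returns an (n_points, 5) array ordered as FEATURES; failed sweeps/fits
    appear as NaN rows.  Aborts if more than ``max_failure_fraction`` of
    the points fail (a screen dominated by failures is not interpretable).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    kap_grid = np.asarray(kap_grid, dtype=float)
    args = [(p, space.to_dict(), base_params.to_dict(), kap_grid) for p in pts]
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as ex:
            rows = list(ex.map(_point_features, args, chunksize=4))
    else:
        rows = [_point_features(a) for a in args]
    feats = np.array(rows)
    n_failed = int(np.isnan(feats).any(axis=1).sum())
    if n_failed > max_failure_fraction * len(pts):
        raise MorrisEvaluationError(
            f"{n_failed}/{len(pts)} feature evaluations failed "
            f"(> {max_failure_fraction:.0%} allowed)"
        )
    return feats


def elementary_effects(trajectory: np.ndarray, outputs: np.ndarray, delta: float) -> np.ndarray:
    """Signed elementary effects of one trajectory.

    ``trajectory`` is (k+1, k); ``outputs`` is (k+1,) or (k+1, n_out).
    Returns (k, n_out): EE of parameter i for each output; NaN where an
    endpoint feature is missing.
    """
    T = np.asarray(trajectory, dtype=float)
    Y = np.atleast_2d(np.asarray(outputs, dtype=float).T).T  # (k+1, n_out)
    k = T.shape[1]
    if T.shape[0] != k + 1 or Y.shape[0] != k + 1:
        raise ValueError("trajectory must have k+1 points with matching outputs")
    ee = np.full((k, Y.shape[1]), np.nan)
    for l in range(k):
        diff = T[l + 1] - T[l]
        i = int(np.argmax(np.abs(diff)))
        step = diff[i]
        if abs(abs(step) - delta) > 1e-9:
            raise ValueError(f"step {l} has size {step}, expected +-{delta}")
        ee[i] = (Y[l + 1] - Y[l]) / step
    return ee


@dataclass(frozen=True)
class MorrisResult:
    """Per-(parameter, output) Morris statistics."""

    parameters: tuple
    outputs: tuple
    mu: np.ndarray          # (k, n_out) signed mean EE
    mu_star: np.ndarray     # mean |EE|
    sigma: np.ndarray       # SD of EEs (ddof=1)
    n_effects: np.ndarray   # non-missing EE count per cell
    mu_star_normalised: np.ndarray = field(init=False)

    def __post_init__(self):
        col_max = self.mu_star.max(axis=0)
        if np.any(col_max <= 0):
            flat = [o for o, m in zip(self.outputs, col_max) if m <= 0]
            raise ValueError(f"output(s) {flat} have no signal; cannot normalise")
        object.__setattr__(self, "mu_star_normalised", self.mu_star / col_max)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.parameters):
            for j, o in enumerate(self.outputs):
                rows.append({
                    "parameter": p, "output": o,
                    "mu": self.mu[i, j], "mu_star": self.mu_star[i, j],
                    "sigma": self.sigma[i, j],
                    "mu_star_normalised": self.mu_star_normalised[i, j],
                    "n_effects": int(self.n_effects[i, j]),
                })
        return pd.DataFrame(rows)

    def heatmap_frame(self) -> pd.DataFrame:
        """Wide normalised-mu* table: rows parameters, columns outputs."""
        return pd.DataFrame(
            self.mu_star_normalised, index=list(self.parameters), columns=list(self.outputs)
        )


def aggregate_and_normalise(
    effects: np.ndarray, parameters, outputs=FEATURES
) -> MorrisResult:
    """Aggregate per-trajectory EEs (r, k, n_out) into Morris statistics.

    Missing EEs are excluded from the means with their counts reported;
    any cell with fewer than 2 usable effects is an error.
    """
    ee = np.asarray(effects, dtype=float)
    if ee.ndim != 3:
        raise ValueError("effects must be (r, k, n_out)")
    n_eff = np.sum(~np.isnan(ee), axis=0)
    bad = np.argwhere(n_eff < 2)
    if len(bad):
        cells = [(parameters[i], outputs[j]) for i, j in bad]
        raise ValueError(f"fewer than 2 elementary effects for cells: {cells}")
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(ee, axis=0)
        mu_star = np.nanmean(np.abs(ee), axis=0)
        sigma = np.nanstd(ee, axis=0, ddof=1)
    return MorrisResult(
        parameters=tuple(parameters), outputs=tuple(outputs),
        mu=mu, mu_star=mu_star, sigma=sigma, n_effects=n_eff,
    )


def rank_parameters(result: MorrisResult, exclude=()) -> dict:
    """Descending mu* ranking per output, after removing excluded names.

    Ties break by sigma descending, then name ascending.
    """
    unknown = set(exclude) - set(result.parameters)
    if unknown:
        raise ValueError(f"unknown parameter(s) in exclude: {sorted(unknown)}")
    keep = [i for i, p in enumerate(result.parameters) if p not in set(exclude)]
    rankings = {}
    for j, out in enumerate(result.outputs):
        order = sorted(
            keep,
            key=lambda i: (-result.mu_star[i, j], -result.sigma[i, j], result.parameters[i]),
        )
        rankings[out] = [result.parameters[i] for i in order]
    return rankings


def run_morris(
    space: ParameterSpace,
    design: MorrisDesign,
    base_params: TCSParameters | None = None,
    kap_grid=None,
    workers: int = 1,
) -> MorrisResult:
    """Full screening: sample, select, simulate, fit, aggregate."""
    from .doseresponse import default_kap_grid

    base_params = base_params or TCSParameters()
    if kap_grid is None:
        kap_grid = default_kap_grid()
    candidates = generate_candidate_trajectories(space, design)
    selected = select_optimal_trajectories(candidates, design.r)
    r, npts, k = selected.shape
    feats = evaluate_feature_map(
        selected.reshape(r * npts, k), space, base_params, kap_grid, workers=workers
    ).reshape(r, npts, len(FEATURES))
    ee = np.stack([
        elementary_effects(selected[t], feats[t], design.delta) for t in range(r)
    ])
    return aggregate_and_normalise(ee, space.names, FEATURES)
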