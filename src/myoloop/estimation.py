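"""Patient-specific estimation of regional contractile dysfunction.

Estimates, from an 18-segment longitudinal strain dataset plus LV EDV and
EF, the regional noncontractile volume fraction (NCVF) and ECM stiffness
nonlinearity (k_ECM) of every segment together with three global
parameters (LV wall area, ventricular contraction duration CD, stroke
volume).  Heart rate is fixed to the measured value.

Pipeline: quasi-random (Sobol) Monte Carlo over the sampling domain ->
selection of 40 initial candidates (20 best by the global objective + 20
per-segment recombinations of the best segmental parameter sets) ->
multi-swarm particle swarm optimization (MSPSO) with periodic subswarm
reshuffling and an energy-based stopping rule.

The objective compares four components, each normalized by its expected
measurement uncertainty and by its number of contributing samples:
segmental strain, segmental strain rate (both truncated at an
early-diastolic cutoff), EDV and EF.  Simulated strains are rescaled so
simulated and measured global strain amplitude match before comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .heart import HeartModel
from .segments import SEGMENTS_18, build_segment_model
from .strain import engineering_strain

__all__ = [
    "Uncertainty",
    "ParameterBounds",
    "ParameterVector",
    "SegmentDataset",
    "EstimationProblem",
    "EstimationResult",
    "MCResults",
    "SwarmState",
    "early_diastolic_cutoff",
    "objective",
    "segmental_error",
    "monte_carlo_init",
    "select_candidates",
    "mspso",
    "fit_patient",
]

N_SEG = 18
N_DIM = 2 * N_SEG + 3   # per-segment NCVF, k_ECM + wall area, CD, SV


@dataclass
class Uncertainty:
    """Expected measurement uncertainties used to normalize the objective."""

    strain: float = 2.0        # percentage points per sample
    strain_rate: float = 20.0  # %/s per sample
    edv: float = 10.0          # ml
    ef: float = 3.0            # percentage points


@dataclass
class ParameterBounds:
    """MC sampling domain of the estimated parameters."""

    ncvf: tuple = (0.0, 1.0)
    k_ecm: tuple = (10.0, 120.0)
    wall_area: tuple = (147.7, 274.3)   # cm^2; +/-30% of the 211 reference
    cd: tuple = (0.315, 0.585)          # s;    +/-30% of 0.45
    sv: tuple = (50.4, 93.6)            # ml;   +/-30% of 72

    def lower(self) -> np.ndarray:
        lo = np.empty(N_DIM)
        lo[:N_SEG] = self.ncvf[0]
        lo[N_SEG:2 * N_SEG] = self.k_ecm[0]
        lo[-3:] = (self.wall_area[0], self.cd[0], self.sv[0])
        return lo

    def upper(self) -> np.ndarray:
        hi = np.empty(N_DIM)
        hi[:N_SEG] = self.ncvf[1]
        hi[N_SEG:2 * N_SEG] = self.k_ecm[1]
        hi[-3:] = (self.wall_area[1], self.cd[1], self.sv[1])
        return hi

    def width(self) -> np.ndarray:
        return self.upper() - self.lower()


@dataclass
class ParameterVector:
    """Estimated parameters: regional NCVF/k_ECM plus three globals."""

    ncvf: np.ndarray           # (18,) in [0, 1]
    k_ecm: np.ndarray          # (18,)
    wall_area: float           # cm^2, total LV free wall + septal midwall
    cd: float                  # s
    sv: float                  # ml

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.ncvf, self.k_ecm,
                               [self.wall_area, self.cd, self.sv]])

    @classmethod
    def from_array(cls, x) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        if x.size != N_DIM:
            raise ValueError(f"expected {N_DIM} parameters, got {x.size}")
        return cls(ncvf=x[:N_SEG].copy(), k_ecm=x[N_SEG:2 * N_SEG].copy(),
                   wall_area=float(x[-3]), cd=float(x[-2]), sv=float(x[-1]))

    @classmethod
    def reference(cls) -> "ParameterVector":
        return cls(ncvf=np.zeros(N_SEG), k_ecm=np.full(N_SEG, 10.0),
                   wall_area=211.0, cd=0.45, sv=72.0)


@dataclass
class SegmentDataset:
    """18-segment strain traces plus global scalars (estimation surface)."""

    time: np.ndarray           # (n,) s, shared grid
    strain: np.ndarray         # (n, 18) %, shortening negative
    heart_rate: float          # bpm
    edv: float                 # ml
    ef: float                  # %
    segments: tuple = SEGMENTS_18

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if self.strain.shape != (self.time.size, len(self.segments)):
            raise ValueError("strain must be (n_time, n_segments)")
        if len(self.segments) != N_SEG:
            raise ValueError(f"expected {N_SEG} segments, "
                             f"got {len(self.segments)}")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def gls(self) -> np.ndarray:
        """Global longitudinal strain: segment average (%)."""
        return self.strain.mean(axis=1)

    @property
    def cycle_time(self) -> float:
        return 60.0 / self.heart_rate


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def early_diastolic_cutoff(gls, time, cycle_time: float) -> int:
    """Index of the early-diastolic analysis cutoff.

    The cutoff lies 10% of the cycle time after the moment of 10% global
    re-lengthening: the first sample after the peak at which |GLS| drops
    below 90% of its maximal amplitude (shortening-negative convention,
    applied to the amplitude).  If the trace never re-lengthens past that
    threshold the cutoff falls back to the end of the beat.
    """
    gls = np.asarray(gls, dtype=float)
    time = np.asarray(time, dtype=float)
    n = gls.size
    k_peak = int(np.argmax(np.abs(gls)))
    amp = abs(gls[k_peak])
    if amp <= 0:
        return n - 1
    after = np.nonzero(np.abs(gls[k_peak:]) < 0.9 * amp)[0]
    if after.size == 0:
        return n - 1
    t_cut = time[k_peak + after[0]] + 0.1 * cycle_time
    return int(min(np.searchsorted(time, t_cut - 1e-12), n - 1))


def _common_grid(sim: SegmentDataset, meas: SegmentDataset) -> np.ndarray:
    """Simulated strain resampled onto the measured time grid."""
    if sim.time.size == meas.time.size and np.allclose(sim.time, meas.time):
        return sim.strain
    out = np.empty((meas.time.size, N_SEG))
    for j in range(N_SEG):
        out[:, j] = np.interp(meas.time, sim.time, sim.strain[:, j])
    return out


def _gls_amplitude_scale(sim_strain, meas_strain) -> float:
    amp_sim = np.abs(sim_strain.mean(axis=1)).max()
    amp_meas = np.abs(meas_strain.mean(axis=1)).max()
    if amp_sim < 1e-9:
        return 1.0
    return amp_meas / amp_sim


def _component_terms(sim: SegmentDataset, meas: SegmentDataset,
                     weights: Uncertainty):
    """Per-segment strain/strain-rate error maps plus scalar terms."""
    sim_eps = _common_grid(sim, meas)
    scale = _gls_amplitude_scale(sim_eps, meas.strain)
    sim_eps = sim_eps * scale
    k_cut = early_diastolic_cutoff(meas.gls, meas.time, meas.cycle_time)
    dt = float(meas.time[1] - meas.time[0])

    d_eps = (sim_eps[:k_cut + 1] - meas.strain[:k_cut + 1]) / weights.strain
    sr_sim = np.diff(sim_eps[:k_cut + 1], axis=0) / dt
    sr_meas = np.diff(meas.strain[:k_cut + 1], axis=0) / dt
    d_sr = (sr_sim - sr_meas) / weights.strain_rate

    strain_seg = (d_eps ** 2).mean(axis=0)      # (18,) mean over samples
    sr_seg = (d_sr ** 2).mean(axis=0)
    edv_term = ((sim.edv - meas.edv) / weights.edv) ** 2
    ef_term = ((sim.ef - meas.ef) / weights.ef) ** 2
    return strain_seg, sr_seg, edv_term, ef_term


def objective(sim: SegmentDataset, meas: SegmentDataset,
              weights: Uncertainty | None = None) -> float:
    """Scalar cost: sum of the four normalized, per-sample-corrected terms."""
    if sim is None:
        raise ValueError("missing simulated dataset")
    weights = weights or Uncertainty()
    strain_seg, sr_seg, edv_term, ef_term = _component_terms(
        sim, meas, weights)
    return float(strain_seg.mean() + sr_seg.mean() + edv_term + ef_term)


def segmental_error(sim: SegmentDataset, meas: SegmentDataset,
                    segment_id: str,
                    weights: Uncertainty | None = None) -> float:
    """Strain + strain-rate error restricted to one segment."""
    weights = weights or Uncertainty()
    if segment_id not in meas.segments:
        raise KeyError(f"unknown segment {segment_id!r}")
    j = meas.segments.index(segment_id)
    strain_seg, sr_seg, _, _ = _component_terms(sim, meas, weights)
    return float(strain_seg[j] + sr_seg[j])


def _all_segmental_errors(sim, meas, weights) -> np.ndarray:
    strain_seg, sr_seg, _, _ = _component_terms(sim, meas, weights)
    return strain_seg + sr_seg


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

@dataclass
class EstimationProblem:
    """Couples a measured dataset to the forward model and objective."""

    measured: SegmentDataset
    weights: Uncertainty = field(default_factory=Uncertainty)
    bounds: ParameterBounds = field(default_factory=ParameterBounds)
    map_target: float = 92.0     # mmHg; no pressure measurements assumed
    n_beats: int = 7             # forward beats from the warm-started state
    err_tol: float = 2e-3        # forward-model local-error acceptance
    _base: HeartModel | None = None

    def _base_model(self) -> HeartModel:
        if self._base is None:
            m = build_segment_model(heart_rate=self.measured.heart_rate,
                                    map_target=self.map_target,
                                    sv_target=self.measured.edv
                                    * self.measured.ef / 100.0)
            m.run_to_steady_state(beats_max=150)
            self._base = m
        return self._base

    def simulate(self, params: ParameterVector) -> SegmentDataset:
        """Forward-simulate a parameter vector to an 18-segment dataset."""
        m = self._base_model().clone()
        m.gp[23] = self.err_tol
        # pathological candidates abort early and cost +inf instead of
        # crawling through thousands of rejected substeps
        m.eval_budget_per_step = 24
        ref_area = 0.0
        for i, name in enumerate(m.patch_names):
            if name in SEGMENTS_18:
                ref_area += m.PP[i, 1]
        m.scale_lv_wall_area(params.wall_area / ref_area)
        m.set_contraction_duration(params.cd)
        m.sv_target = params.sv
        for i, name in enumerate(m.patch_names):
            if name in SEGMENTS_18:
                j = SEGMENTS_18.index(name)
                m.set_patch(i, ncvf=float(np.clip(params.ncvf[j], 0, 1)),
                            k_ecm_nc=float(params.k_ecm[j]))
        for _ in range(self.n_beats - 1):
            m.run_beat(record=False)
        beat = m.run_beat(record=True)
        return dataset_from_beat(beat, self.measured.heart_rate)

    def cost(self, params: ParameterVector) -> tuple[float, np.ndarray]:
        """(objective, per-segment errors); infeasible runs cost inf."""
        try:
            sim = self.simulate(params)
        except (RuntimeError, FloatingPointError, ValueError):
            return math.inf, np.full(N_SEG, math.inf)
        c = objective(sim, self.measured, self.weights)
        seg = _all_segmental_errors(sim, self.measured, self.weights)
        if not np.isfinite(c):
            return math.inf, np.full(N_SEG, math.inf)
        return c, seg


def dataset_from_beat(beat, heart_rate: float) -> SegmentDataset:
    """Build a SegmentDataset from a recorded beat of a segment model."""
    idx = [beat.patch_names.index(s) for s in SEGMENTS_18]
    eps = np.empty((beat.t.size, N_SEG))
    for j, i in enumerate(idx):
        Ls = beat.patch_Ls(i)
        eps[:, j] = engineering_strain(Ls, Ls[beat.act_index])
    return SegmentDataset(time=beat.t.copy(), strain=eps,
                          heart_rate=heart_rate,
                          edv=beat.EDV, ef=beat.EF)


# ---------------------------------------------------------------------------
# Monte Carlo initialization and candidate selection
# ---------------------------------------------------------------------------

@dataclass
class MCResults:
    params: np.ndarray         # (n, N_DIM)
    costs: np.ndarray          # (n,)
    seg_errors: np.ndarray     # (n, 18)

    @property
    def feasible(self) -> np.ndarray:
        return np.isfinite(self.costs)


def monte_carlo_init(problem: EstimationProblem, n: int,
                     seed: int) -> MCResults:
    """Quasi-random (Sobol) sampling of the domain with forward evaluation."""
    if n < 1:
        raise ValueError("n must be positive")
    lo = problem.bounds.lower()
    wd = problem.bounds.width()
    sampler = qmc.Sobol(d=N_DIM, scramble=True,
                        rng=np.random.default_rng(seed))
    # draw a full Sobol block (power of two) and keep the first n points
    m = max(1, int(np.ceil(np.log2(n))))
    u = sampler.random_base2(m)[:n]
    params = lo + u * wd
    costs = np.empty(n)
    seg = np.empty((n, N_SEG))
    for k in range(n):
        costs[k], seg[k] = problem.cost(ParameterVector.from_array(params[k]))
    return MCResults(params=params, costs=costs, seg_errors=seg)


def select_candidates(mc: MCResults, seed: int,
                      n_out: int = 40) -> np.ndarray:
    """40 initial particles: 20 global best + 20 segmental recombinations.

    The recombined particles draw each segment's (NCVF, k_ECM) pair from
    that segment's 20 best MC runs by segmental error, and their global
    parameters from the 20 globally best runs.
    """
    ok = np.nonzero(mc.feasible)[0]
    if ok.size < n_out // 2:
        raise RuntimeError(
            f"only {ok.size} feasible MC candidates; need {n_out // 2}")
    rng = np.random.default_rng(seed)
    n_best = n_out // 2
    order = ok[np.argsort(mc.costs[ok])]
    best = order[:n_best]
    particles = [mc.params[i].copy() for i in best]

    seg_best = np.empty((N_SEG, n_best), dtype=np.int64)
    for j in range(N_SEG):
        so = ok[np.argsort(mc.seg_errors[ok, j])]
        seg_best[j] = so[:n_best]
    for _ in range(n_out - n_best):
        x = np.empty(N_DIM)
        for j in range(N_SEG):
            src = int(rng.choice(seg_best[j]))
            x[j] = mc.params[src, j]
            x[N_SEG + j] = mc.params[src, N_SEG + j]
        gsrc = int(rng.choice(best))
        x[-3:] = mc.params[gsrc, -3:]
        particles.append(x)
    return np.array(particles)


# ---------------------------------------------------------------------------
# Multi-swarm particle swarm optimization
# ---------------------------------------------------------------------------

@dataclass
class SwarmState:
    """Positions, velocities, personal bests and subswarm assignment."""

    x: np.ndarray              # (n, d)
    v: np.ndarray              # (n, d)
    pbest_x: np.ndarray
    pbest_f: np.ndarray
    subswarm: np.ndarray       # (n,) int
    energy: np.ndarray         # (n,) normalized step energy
    iteration: int = 0


@dataclass
class EstimationResult:
    params: ParameterVector
    cost: float
    iterations: int
    stopped_on: str            # "energy" or "max_iter"
    cost_history: np.ndarray
    mc: MCResults | None = None
    swarm: SwarmState | None = None


_CHI = 0.7298437881283576    # constriction coefficient
_C1 = 2.05
_C2 = 2.05


def mspso(cost_fn, particles: np.ndarray, bounds: ParameterBounds,
          seed: int, n_subswarms: int = 5, reshuffle_every: int = 40,
          max_iter: int = 1000, energy_tol: float = 1e-4,
          ) -> tuple[np.ndarray, float, SwarmState, np.ndarray, str]:
    """Multi-swarm PSO with constriction updates.

    Subswarm membership is randomly reassigned every ``reshuffle_every``
    iterations.  A particle's normalized energy is the mean squared
    per-iteration parameter change as a fraction of each parameter's
    sampling-domain width; iteration stops when every particle's energy
    drops below ``energy_tol`` or at ``max_iter``.
    """
    rng = np.random.default_rng(seed)
    x = np.array(particles, dtype=float)
    n, d = x.shape
    lo = bounds.lower()
    hi = bounds.upper()
    wd = bounds.width()
    x = np.clip(x, lo, hi)
    v = np.zeros_like(x)
    vmax = 0.3 * wd

    f = np.array([cost_fn(xi) for xi in x])
    pbest_x = x.copy()
    pbest_f = f.copy()
    sub = rng.permutation(np.arange(n) % n_subswarms)
    energy = np.full(n, np.inf)
    history = [float(np.min(pbest_f))]
    stopped = "max_iter"
    it = 0
    for it in range(1, max_iter + 1):
        if (it - 1) % reshuffle_every == 0 and it > 1:
            sub = rng.permutation(np.arange(n) % n_subswarms)
        # local (subswarm) best of personal bests
        lbest = np.empty_like(x)
        for s in range(n_subswarms):
            members = np.nonzero(sub == s)[0]
            if members.size == 0:
                continue
            b = members[int(np.argmin(pbest_f[members]))]
            lbest[members] = pbest_x[b]
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        v = _CHI * (v + _C1 * r1 * (pbest_x - x) + _C2 * r2 * (lbest - x))
        v = np.clip(v, -vmax, vmax)
        x_new = np.clip(x + v, lo, hi)
        energy = np.mean(((x_new - x) / wd) ** 2, axis=1)
        x = x_new
        f = np.array([cost_fn(xi) for xi in x])
        better = f < pbest_f
        pbest_x[better] = x[better]
        pbest_f[better] = f[better]
        history.append(float(np.min(pbest_f)))
        if np.all(energy < energy_tol):
            stopped = "energy"
            break
    k = int(np.argmin(pbest_f))
    state = SwarmState(x=x, v=v, pbest_x=pbest_x, pbest_f=pbest_f,
                       subswarm=sub, energy=energy, iteration=it)
    return pbest_x[k], float(pbest_f[k]), state, np.array(history), stopped


def fit_patient(measured: SegmentDataset, seed: int = 0,
                mc_n: int = 1000, max_iter: int = 1000,
                n_particles: int = 40,
                problem: EstimationProblem | None = None,
                **problem_kw) -> EstimationResult:
    """End-to-end estimation: Sobol MC -> candidate selection -> MSPSO."""
    problem = problem or EstimationProblem(measured=measured, **problem_kw)
    mc = monte_carlo_init(problem, mc_n, seed)
    particles = select_candidates(mc, seed + 1, n_out=n_particles)

    def cost_fn(xi):
        return problem.cost(ParameterVector.from_array(xi))[0]

    best_x, best_f, swarm, history, stopped = mspso(
        cost_fn, particles, problem.bounds, seed + 2, max_iter=max_iter)
    return EstimationResult(
        params=ParameterVector.from_array(best_x), cost=best_f,
        iterations=swarm.iteration, stopped_on=stopped,
        cost_history=history, mc=mc, swarm=swarm)
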