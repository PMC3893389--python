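"""Two-phase Calpha-trace reconstruction from distance/4-class/binary maps.

Phase 1 grows a random conformation (helix runs placed as ideal alpha
helices, everything else as random-direction bonds of 3.803 +/- 0.07 A).
Phase 2 refines it by Metropolis simulated annealing over a pseudo-energy

    E = a0*a1 * sum_{i<j} |d_ij - d_ij^map|            (map restraints)
      + sum_{|i-j|=1} (d_ij - D_B)^2                    (virtual bonds)
      + a2 * sum_{|i-j|>1} 10*max(0, D_CL - d_ij)       (steric clashes)
      + a3 * sum_strands dist(d_strand, [Dmin, Dmax])^2 (strand lengths)

with moves that rotate one residue about the axis through its sequence
neighbours (preserving both neighbour distances exactly).  Because a
distance map carries no chirality, each run finally mirrors the result,
re-refines the mirror briefly and keeps the lower-energy image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _anneal_kernels as _k
from .io_structures import CaTrace, SecondaryStructure
from .maps import BinaryMap, DistanceMap, MultiClassMap
from .metrics import kabsch

#: ideal alpha-helix geometry used for initial placement
HELIX_RISE = 1.5      # A per residue along the axis
HELIX_RADIUS = 2.3    # A
HELIX_TWIST = math.radians(100.0)  # per residue


@dataclass(frozen=True)
class PseudoEnergyParams:
    """Weights and geometric constants of the pseudo-energy."""

    alpha0: float = 0.2
    alpha1: float = 0.025   # distance penalty
    alpha2: float = 0.5     # clashes
    alpha3: float = 2.0     # strand length
    bond_length: float = 3.803   # D_B [A]
    bond_tolerance: float = 0.07  # [A], used for initial bond sampling
    clash_cutoff: float = 4.0    # D_CL [A]
    #: "linear" -> 10*max(0, D_CL - d); "exp10" -> 10**(D_CL - d)
    clash_form: str = "linear"

    def __post_init__(self):
        for name in ("alpha0", "alpha1", "alpha2", "alpha3", "bond_length",
                     "bond_tolerance", "clash_cutoff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.clash_form not in ("linear", "exp10"):
            raise ValueError("clash_form must be 'linear' or 'exp10'")


@dataclass
class ConstraintSet:
    """Flat-bottom pair intervals plus strand end-to-end intervals.

    ``lo[i, j] == hi[i, j]`` encodes an exact distance target; open upper
    intervals use ``hi = inf``.  Bond and clash terms are implied by the
    sequence separation and need no storage.
    """

    kind: str                 # distance | 4class | binary
    lo: np.ndarray            # (L, L)
    hi: np.ndarray            # (L, L)
    strand_a: np.ndarray      # first residue of each strand
    strand_b: np.ndarray      # last residue of each strand
    strand_lo: np.ndarray
    strand_hi: np.ndarray

    @property
    def length(self) -> int:
        return self.lo.shape[0]


@dataclass(frozen=True)
class AnnealingConfig:
    iterations_per_residue: int = 10_000
    n_runs: int = 10
    mirror_refine_iterations: int = 5_000
    theta_max_deg: float = 180.0
    theta_min_deg: float = 5.0
    t_end_frac: float = 1e-5     # final temperature as a fraction of T0
    calibration_proposals: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.iterations_per_residue < 0:
            raise ValueError("iterations_per_residue must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def strand_interval(l: int) -> tuple[float, float]:
    """Allowed end-to-end distance interval for a strand of ``l`` residues.

    D_min/max = 3.436*l - 0.05107*l -/+ 0.04*l^2, floored at 0.
    """
    if l < 2:
        raise ValueError("a strand needs at least 2 residues")
    base = 3.436 * l - 0.05107 * l
    return max(base - 0.04 * l * l, 0.0), max(base + 0.04 * l * l, 0.0)


def build_constraints(
    map_obj: DistanceMap | MultiClassMap | BinaryMap,
    ss: SecondaryStructure,
    params: PseudoEnergyParams | None = None,
) -> ConstraintSet:
    """Translate a map of any kind plus secondary structure into constraints.

    Distance maps give exact per-pair targets; 4-class maps give the class
    interval [t_{k-1}, t_k) (the open top class is penalized only below its
    lower cutoff); binary maps give d <= threshold for contacts and
    d > threshold for non-contacts.  Strand intervals come from every
    maximal E-run.
    """
    n = map_obj.length
    if n != len(ss):
        raise ValueError(f"map length {n} != secondary-structure length {len(ss)}")
    if isinstance(map_obj, DistanceMap):
        kind = "distance"
        lo = map_obj.values.copy()
        hi = map_obj.values.copy()
    elif isinstance(map_obj, MultiClassMap):
        kind = "4class"
        edges_lo = np.array([0.0, *map_obj.thresholds])
        edges_hi = np.array([*map_obj.thresholds, np.inf])
        lo = edges_lo[map_obj.classes]
        hi = edges_hi[map_obj.classes]
    elif isinstance(map_obj, BinaryMap):
        kind = "binary"
        thr = map_obj.threshold
        lo = np.where(map_obj.contacts, 0.0, thr)
        hi = np.where(map_obj.contacts, thr, np.inf)
    else:
        raise TypeError(f"unsupported map type {type(map_obj).__name__}")
    # strand end-to-end intervals: the interval formula is parameterized by
    # the number of virtual bonds spanned (run length - 1).  Parameterizing
    # by residue count would demand end-to-end distances no bond geometry
    # can reach for short strands (e.g. 12.9 A from three 3.87 A bonds), so
    # native strands could never satisfy their own constraint.
    runs = [(a, b) for a, b in ss.strand_runs() if b - a >= 3]
    sa = np.array([a for a, _ in runs], dtype=np.int64)
    sb = np.array([b - 1 for _, b in runs], dtype=np.int64)
    ivals = [strand_interval(b - a - 1) for a, b in runs]
    slo = np.array([x[0] for x in ivals], dtype=float)
    shi = np.array([x[1] for x in ivals], dtype=float)
    return ConstraintSet(kind, np.ascontiguousarray(lo, float),
                         np.ascontiguousarray(hi, float), sa, sb, slo, shi)


def _kernel_args(constraints: ConstraintSet, params: PseudoEnergyParams):
    return (
        constraints.lo, constraints.hi,
        constraints.strand_a, constraints.strand_b,
        constraints.strand_lo, constraints.strand_hi,
        params.alpha0 * params.alpha1, params.alpha2, params.alpha3,
        params.bond_length, params.clash_cutoff,
        1 if params.clash_form == "exp10" else 0,
    )


def pseudo_energy(
    trace: CaTrace,
    constraints: ConstraintSet,
    params: PseudoEnergyParams | None = None,
) -> float:
    """Pseudo-energy of a conformation under a constraint set (>= 0)."""
    params = params or PseudoEnergyParams()
    if len(trace) != constraints.length:
        raise ValueError("trace length does not match constraints")
    coords = np.ascontiguousarray(trace.coords, dtype=float)
    return float(_k.total_energy(coords, *_kernel_args(constraints, params)))


def init_conformation(
    ss: SecondaryStructure,
    seed: int,
    params: PseudoEnergyParams | None = None,
) -> CaTrace:
    """Sequential random growth with helix runs placed as ideal helices.

    Consecutive distances are drawn uniformly from bond_length +/-
    bond_tolerance; each maximal H-run is laid out as an ideal alpha helix
    (rise 1.5 A, radius 2.3 A, 100 deg/residue) with a random rigid
    orientation continuing from the preceding residue.
    """
    params = params or PseudoEnergyParams()
    rng = np.random.default_rng(seed)
    n = len(ss)
    coords = np.zeros((n, 3))
    segments = ss.segments
    pos = np.zeros(3)
    placed = 0
    for state, a, b in segments:
        if state == "H":
            run = b - a
            # local ideal helix including a virtual residue at index -1 so the
            # bond into the helix also follows helix geometry
            m = np.arange(-1, run)
            local = np.stack([
                HELIX_RADIUS * np.cos(HELIX_TWIST * m),
                HELIX_RADIUS * np.sin(HELIX_TWIST * m),
                HELIX_RISE * m,
            ], axis=1)
            local -= local[0]
            R = _random_rotation(rng)
            pts = (local @ R.T) + pos
            coords[a:b] = pts[1:]
            pos = coords[b - 1].copy()
            placed = b
        else:
            for i in range(a, b):
                if placed == 0 and i == a == 0:
                    coords[0] = 0.0
                    pos = coords[0].copy()
                    placed = 1
                    continue
                length = rng.uniform(params.bond_length - params.bond_tolerance,
                                     params.bond_length + params.bond_tolerance)
                direction = _random_unit(rng)
                coords[i] = pos + length * direction
                pos = coords[i].copy()
                placed = i + 1
    return CaTrace(coords, "X" * n)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def anneal(
    start: CaTrace,
    constraints: ConstraintSet,
    params: PseudoEnergyParams | None = None,
    config: AnnealingConfig | None = None,
    seed: int = 0,
    n_iterations: int | None = None,
    t0: float | None = None,
    t0_scale: float = 1.0,
) -> tuple[CaTrace, float]:
    """Refine a conformation by simulated annealing; returns (trace, energy).

    ``n_iterations`` defaults to iterations_per_residue * L.  The starting
    temperature is calibrated so that roughly half of the uphill proposals
    from the start conformation would be accepted (times ``t0_scale``),
    unless ``t0`` is given.
    """
    params = params or PseudoEnergyParams()
    config = config or AnnealingConfig()
    coords = np.ascontiguousarray(start.coords, dtype=float).copy()
    args = _kernel_args(constraints, params)
    n_iters = (config.iterations_per_residue * len(start)
               if n_iterations is None else int(n_iterations))
    if n_iters <= 0:
        e = float(_k.total_energy(coords, *args))
        return start.with_coords(coords), e
    if t0 is None:
        t0 = t0_scale * float(_k.calibrate_t0(
            coords, *args, config.calibration_proposals,
            math.radians(config.theta_max_deg),
            np.uint32(seed ^ 0x5DEECE66)))
        t0 = max(t0, 1e-12)
    energy = float(_k.anneal_kernel(
        coords, *args, n_iters, t0, config.t_end_frac,
        math.radians(config.theta_max_deg), math.radians(config.theta_min_deg),
        np.uint32(seed),
    ))
    return start.with_coords(coords), energy


def mirror(trace: CaTrace) -> CaTrace:
    """Mirror image (z -> -z); shares the exact same distance map."""
    coords = trace.coords.copy()
    coords[:, 2] = -coords[:, 2]
    return trace.with_coords(coords)


@dataclass
class RunResult:
    trace: CaTrace
    energy: float
    rmsd: float | None = None


@dataclass
class ReconstructionResult:
    best: CaTrace                 # lowest energy over all runs (blind mode)
    best_energy: float
    runs: list[RunResult] = field(default_factory=list)
    best_by_rmsd: CaTrace | None = None   # evaluation mode only
    best_rmsd: float | None = None


def reconstruct(
    map_obj: DistanceMap | MultiClassMap | BinaryMap,
    ss: SecondaryStructure,
    params: PseudoEnergyParams | None = None,
    config: AnnealingConfig | None = None,
    native: CaTrace | None = None,
) -> ReconstructionResult:
    """Full best-of-n reconstruction pipeline.

    Each run: random init -> anneal (iterations_per_residue * L moves) ->
    mirror the result, refine the mirror for mirror_refine_iterations moves
    and keep the lower-energy image.  Blind mode returns the lowest-energy
    conformation over runs; when ``native`` is given the per-run RMSD and
    the best-by-RMSD conformation are also reported (evaluation mode).
    """
    params = params or PseudoEnergyParams()
    config = config or AnnealingConfig()
    constraints = build_constraints(map_obj, ss, params)
    seeds = np.random.SeedSequence(config.seed).generate_state(3 * config.n_runs)
    seeds = (seeds % np.uint32(2**31)).astype(np.uint32)
    runs: list[RunResult] = []
    for r in range(config.n_runs):
        s_init, s_anneal, s_refine = seeds[3 * r: 3 * r + 3]
        start = init_conformation(ss, int(s_init), params)
        refined, energy = anneal(start, constraints, params, config,
                                 seed=int(s_anneal))
        # chirality step: refine the mirror image briefly (gentle moves, low
        # temperature so the converged fold is polished, not melted), then
        # keep the lower-energy image
        mirrored = mirror(refined)
        if config.mirror_refine_iterations > 0:
            refine_cfg = replace(config, theta_max_deg=30.0)
            mirrored, m_energy = anneal(
                mirrored, constraints, params, refine_cfg, seed=int(s_refine),
                n_iterations=config.mirror_refine_iterations,
                t0_scale=0.1,
            )
        else:
            m_energy = pseudo_energy(mirrored, constraints, params)
        if m_energy < energy:
            refined, energy = mirrored, m_energy
        rr = RunResult(refined, energy)
        if native is not None:
            rr.rmsd = kabsch(refined, native).rmsd
        runs.append(rr)
    best_run = min(runs, key=lambda rr: rr.energy)
    result = ReconstructionResult(best_run.trace, best_run.energy, runs)
    if native is not None:
        by_rmsd = min(runs, key=lambda rr: rr.rmsd)
        result.best_by_rmsd = by_rmsd.trace
        result.best_rmsd = by_rmsd.rmsd
    return result
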