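"""Synthetic fixtures: protein-like Calpha folds, MSAs and template hits.

Everything the pipeline consumes can be generated here deterministically
from a seed, so tests and benchmarks run with no external data.  Folds are
geometric, not physical: helices are ideal alpha helices, strands are
zigzag segments with a 3.4 A rise per bond, coils are self-avoiding walks
with the canonical 3.803 A virtual bond, and compactness comes from a
centroid-biased growth that always respects the 4 A clash floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .encoders import TemplateHit
from .io_structures import AA1, CaTrace, Msa, SecondaryStructure
from .maps import distance_map
from .reconstruct import HELIX_RADIUS, HELIX_RISE, HELIX_TWIST, _random_rotation, _random_unit

BOND = 3.803
STRAND_RISE = 3.4
#: lateral zigzag half-amplitude making the strand bond exactly 3.803 A
STRAND_ZIG = math.sqrt(BOND**2 - STRAND_RISE**2) / 2.0
CLASH_FLOOR = 4.0
#: placement margin above the clash floor
_MARGIN = 0.1

#: amino-acid propensities by secondary-structure state (helix formers,
#: strand formers, coil/turn formers), used to draw synthetic sequences
_STATE_AA = {
    "H": "AELMQKRH",
    "E": "VIYFWTC",
    "C": "GPNDS",
}


@dataclass(frozen=True)
class FoldSpec:
    """Layout of a synthetic fold: run-length encoded secondary structure."""

    ss_layout: tuple[tuple[str, int], ...]
    compactness: float = 1.0   # >1 = tighter target radius
    seed: int = 0

    def __post_init__(self):
        if not self.ss_layout:
            raise ValueError("empty layout")
        for state, run in self.ss_layout:
            if state not in "HEC":
                raise ValueError(f"unknown state {state!r}")
            if run < 1:
                raise ValueError("run lengths must be >= 1")
            if state == "H" and run < 4:
                raise ValueError("helix runs must be >= 4 residues")
            if state == "E" and run < 2:
                raise ValueError("strand runs must be >= 2 residues")

    @property
    def length(self) -> int:
        return sum(r for _, r in self.ss_layout)


@dataclass(frozen=True)
class MsaSpec:
    """Controls for the synthetic alignment generator."""

    n_sequences: int = 50
    mutation_rate: float = 0.3
    gap_rate: float = 0.05
    #: (col_j, col_k, co_mutation_probability) triples
    correlated_pairs: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        for r in (self.mutation_rate, self.gap_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        for _, _, p in self.correlated_pairs:
            if not 0.0 <= p <= 1.0:
                raise ValueError("co-mutation probabilities must be in [0, 1]")


def _helix_local(run: int) -> np.ndarray:
    """Ideal helix points for indices -1..run-1 (index -1 = virtual lead-in)."""
    m = np.arange(-1, run)
    pts = np.stack([
        HELIX_RADIUS * np.cos(HELIX_TWIST * m),
        HELIX_RADIUS * np.sin(HELIX_TWIST * m),
        HELIX_RISE * m,
    ], axis=1)
    return pts - pts[0]


def _strand_local(run: int) -> np.ndarray:
    """Zigzag strand points for indices -1..run-1 (3.4 A rise per bond)."""
    m = np.arange(-1, run)
    pts = np.stack([
        STRAND_RISE * m,
        STRAND_ZIG * np.where(m % 2 == 0, 1.0, -1.0),
        np.zeros_like(m, dtype=float),
    ], axis=1)
    return pts - pts[0]


def _min_dist_ok(new_pts: np.ndarray, placed: np.ndarray, start_index: int) -> bool:
    """True when every (new, existing) pair with |i-j| > 1 clears the floor."""
    if len(placed) == 0:
        return True
    d = np.linalg.norm(new_pts[:, None, :] - placed[None, :, :], axis=-1)
    for a in range(new_pts.shape[0]):
        i = start_index + a
        for j in range(placed.shape[0]):
            if abs(i - j) <= 1:
                continue
            if d[a, j] <= CLASH_FLOOR + _MARGIN:
                return False
    return True


def make_fold(spec: FoldSpec) -> tuple[CaTrace, SecondaryStructure]:
    """Generate a compact, clash-free synthetic fold and its 3-state string.

    Growth can dead-end in a pocket where no clash-free continuation
    exists; the builder then restarts deterministically with a sub-seed.
    """
    last_error: Exception | None = None
    for attempt in range(50):
        try:
            return _make_fold_once(spec, attempt)
        except RuntimeError as exc:
            last_error = exc
    raise RuntimeError(f"fold generation failed repeatedly: {last_error}")


def _make_fold_once(spec: FoldSpec, attempt: int) -> tuple[CaTrace, SecondaryStructure]:
    rng = np.random.default_rng([spec.seed, attempt])
    ss = "".join(state * run for state, run in spec.ss_layout)
    n = len(ss)
    if n < 2:
        raise ValueError("fold must have at least 2 residues")
    target_radius = 3.0 * n ** (1.0 / 3.0) / max(spec.compactness, 1e-6)
    coords: list[np.ndarray] = []

    def grow_segment(local: np.ndarray, tries: int = 60) -> None:
        placed = np.array(coords) if coords else np.zeros((0, 3))
        origin = coords[-1] if coords else np.zeros(3)
        best = None
        best_score = np.inf
        for t in range(tries):
            R = _random_rotation(rng)
            pts = (local @ R.T) + origin
            body = pts[1:] if coords else pts[1:] - pts[1]
            if not _min_dist_ok(body, placed, len(coords)):
                continue
            centroid = (placed.sum(axis=0) + body.sum(axis=0)) / (len(placed) + len(body))
            radius = float(np.max(np.linalg.norm(body - centroid, axis=1)))
            score = max(radius - target_radius, 0.0) + 0.1 * radius
            if score < best_score:
                best, best_score = body, score
            if best is not None and t >= tries // 2:
                break
        if best is None:
            # fall back to any clash-free orientation, however extended
            for _ in range(2000):
                R = _random_rotation(rng)
                pts = (local @ R.T) + origin
                body = pts[1:] if coords else pts[1:] - pts[1]
                if _min_dist_ok(body, placed, len(coords)):
                    best = body
                    break
            if best is None:
                raise RuntimeError("could not place segment without clashes")
        coords.extend(best)

    def grow_coil(run: int) -> None:
        for _ in range(run):
            if not coords:
                coords.append(np.zeros(3))
                continue
            placed = np.array(coords)
            origin = coords[-1]
            centroid = placed.mean(axis=0)
            best = None
            best_score = np.inf
            for t in range(60):
                step = origin + BOND * _random_unit(rng)
                if not _min_dist_ok(step[None, :], placed, len(coords)):
                    continue
                r = float(np.linalg.norm(step - centroid))
                score = max(r - target_radius, 0.0) + 0.1 * r
                if score < best_score:
                    best, best_score = step, score
            if best is None:
                for _ in range(2000):
                    step = origin + BOND * _random_unit(rng)
                    if _min_dist_ok(step[None, :], placed, len(coords)):
                        best = step
                        break
                if best is None:
                    raise RuntimeError("could not extend coil without clashes")
            coords.append(best)

    for state, run in spec.ss_layout:
        if state == "H":
            grow_segment(_helix_local(run))
        elif state == "E":
            grow_segment(_strand_local(run))
        else:
            grow_coil(run)

    seq = "".join(
        rng.choice(list(_STATE_AA[s])) if rng.random() < 0.7
        else rng.choice(list(AA1))
        for s in ss
    )
    return CaTrace(np.array(coords), seq), SecondaryStructure(ss)


def default_layout(length: int, rng: np.random.Generator) -> tuple[tuple[str, int], ...]:
    """A plausible mixed alpha/beta layout summing to ``length``."""
    layout: list[tuple[str, int]] = []
    remaining = length
    toggle = 0
    while remaining > 0:
        coil = int(rng.integers(2, 5))
        coil = min(coil, remaining)
        layout.append(("C", coil))
        remaining -= coil
        if remaining <= 0:
            break
        if toggle % 2 == 0:
            run = int(rng.integers(6, 13))
            state = "H"
        else:
            run = int(rng.integers(3, 7))
            state = "E"
        run = min(run, remaining)
        if (state == "H" and run < 4) or (state == "E" and run < 2):
            layout.append(("C", run))
        else:
            layout.append((state, run))
        remaining -= run
        toggle += 1
    return tuple(layout)


def make_fold_suite(
    n_folds: int, length: int, seed: int
) -> list[tuple[CaTrace, SecondaryStructure]]:
    """Deterministic suite of mixed alpha/beta folds of a given length."""
    ss_rng = np.random.default_rng(seed)
    suite = []
    for i in range(n_folds):
        layout = default_layout(length, ss_rng)
        spec = FoldSpec(layout, seed=int(ss_rng.integers(0, 2**31)))
        suite.append(make_fold(spec))
    return suite


# coupled residue pairs used to imprint a correlated-mutation signal
_COUPLED = [("A", "V"), ("L", "I"), ("F", "W"), ("D", "K"), ("E", "R"),
            ("S", "T"), ("Y", "F"), ("K", "D")]


def make_msa(query: str, spec: MsaSpec) -> Msa:
    """Mutate the query row-wise into an alignment with optional co-mutation.

    Columns named in ``correlated_pairs`` co-mutate: with the stated
    probability a row draws one coupled residue pair for both columns,
    producing a positive Gobel correlation signal; all other columns mutate
    independently at ``mutation_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    ncol = len(query)
    corr_cols = {}
    for j, k, p in spec.correlated_pairs:
        if not (0 <= j < ncol and 0 <= k < ncol):
            raise ValueError("correlated column out of range")
        corr_cols[j] = (j, k, p)
    rows = [query.upper()]
    for _ in range(spec.n_sequences - 1):
        row = list(query.upper())
        for j, k, p in corr_cols.values():
            if rng.random() < p:
                a, b = _COUPLED[int(rng.integers(len(_COUPLED)))]
                row[j], row[k] = a, b
        for c in range(ncol):
            skip = any(c in (j, k) for j, k, _ in corr_cols.values())
            if skip:
                continue
            if rng.random() < spec.mutation_rate:
                row[c] = AA1[int(rng.integers(len(AA1)))]
            if rng.random() < spec.gap_rate:
                row[c] = "-"
        rows.append("".join(row))
    return Msa(rows, query_index=0)


def make_templates(
    native: CaTrace,
    n: int,
    noise: float,
    coverage: float,
    id_range: tuple[float, float] = (0.2, 0.9),
    seed: int = 0,
) -> list[TemplateHit]:
    """Noisy, partially covered copies of the native map as template hits.

    Each hit perturbs the native distance map by Uniform(+/-noise), blanks
    random contiguous residue blocks down to the requested coverage, draws
    a sequence identity from ``id_range`` capped at 0.95, and attaches
    random X-ray/NMR quality metadata.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    nat = distance_map(native).values
    L = nat.shape[0]
    hits = []
    for _ in range(n):
        iu, ju = np.triu_indices(L, k=1)
        vals = nat.copy()
        eps = rng.uniform(-noise, noise, size=len(iu)) if noise > 0 else 0.0
        vals[iu, ju] = np.maximum(vals[iu, ju] + eps, 0.1)
        vals[ju, iu] = vals[iu, ju]
        covered = np.ones(L, dtype=bool)
        n_uncovered = int(round((1.0 - coverage) * L))
        while n_uncovered > 0:
            block = int(rng.integers(1, max(2, n_uncovered + 1)))
            start = int(rng.integers(0, L))
            end = min(start + block, L)
            newly = int(np.sum(covered[start:end]))
            covered[start:end] = False
            n_uncovered -= newly
            if newly == 0 and not covered.any():
                break
        dist = vals.copy()
        dist[~covered, :] = np.nan
        dist[:, ~covered] = np.nan
        id_p = min(float(rng.uniform(*id_range)), 0.95)
        if rng.random() < 0.8:
            hit = TemplateHit(dist, id_p=id_p, coverage=float(covered.mean()),
                              experiment="X-ray",
                              resolution=float(rng.uniform(1.2, 3.5)),
                              r_factor=float(rng.uniform(0.15, 0.28)))
        else:
            hit = TemplateHit(dist, id_p=id_p, coverage=float(covered.mean()),
                              experiment="NMR", resolution=2.0,
                              r_factor=float(rng.uniform(0.2, 0.4)))
        hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Structural annotations and ready-made training examples
# ---------------------------------------------------------------------------

def structural_classes(trace: CaTrace) -> tuple[np.ndarray, np.ndarray]:
    """Geometry-derived stand-ins for the solvent-accessibility (2-class)
    and contact-density (4-class) annotations the predictors consume.

    Burial correlates with the number of 12 A contacts at sequence
    separation > 2: residues above the median count are "buried"; the
    contact-density class is the within-protein quartile of the same
    count.  These are synthetic labels for fixture purposes, not DSSP
    output.
    """
    v = distance_map(trace).values
    n = len(trace)
    mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) > 2
    counts = ((v <= 12.0) & mask).sum(axis=1)
    rsa = (counts <= np.median(counts)).astype(int)  # 0 buried, 1 exposed
    qs = np.quantile(counts, [0.25, 0.5, 0.75])
    cd = np.searchsorted(qs, counts, side="right")
    return rsa, np.clip(cd, 0, 3)


def make_training_example(
    length: int,
    seed: int,
    variant: str = "classical",
    msa_rows: int = 30,
) -> tuple[np.ndarray, np.ndarray, CaTrace, SecondaryStructure]:
    """One synthetic protein as (input grid, target map values, trace, ss)."""
    from .encoders import (FeatureSet, correlation_matrix, input_grid,
                           residue_features)

    rng = np.random.default_rng(seed)
    layout = default_layout(length, rng)
    trace, ss = make_fold(FoldSpec(layout, seed=int(rng.integers(0, 2**31))))
    msa = make_msa(trace.sequence,
                   MsaSpec(n_sequences=msa_rows, mutation_rate=0.25,
                           gap_rate=0.03, seed=int(rng.integers(0, 2**31))))
    rsa, cd = structural_classes(trace)
    profile_kind = "complementarity" if variant == "complementarity" else "classical"
    rf = residue_features(msa, ss, rsa, cd, profile_kind)
    corr = correlation_matrix(msa) if variant == "correlation" else None
    hits = (make_templates(trace, n=3, noise=1.0, coverage=0.8,
                           seed=int(rng.integers(0, 2**31)))
            if variant == "template" else [])
    fs = FeatureSet(rf, variant, corr, hits)
    X = input_grid(fs)
    target = distance_map(trace).values
    return X, target, trace, ss
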