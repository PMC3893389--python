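"""Real-valued, binary and 4-class Calpha distance maps.

The real-valued map is the central object: a symmetric L x L matrix of
Euclidean Calpha-Calpha distances in Angstrom.  Binary contact maps
(cutoff 12 A by default) and 4-class maps (cutoffs 8/13/19 A) are
quantizations of it.  Controlled uniform noise can be injected into the
distances; noisy coarse maps are defined as "perturb distances first, then
threshold".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_structures import CaTrace

BINARY_THRESHOLD = 12.0
FOURCLASS_THRESHOLDS = (8.0, 13.0, 19.0)
#: floor applied to perturbed distances so they stay physical
NOISE_FLOOR = 0.1


@dataclass
class DistanceMap:
    """Symmetric matrix of Calpha-Calpha distances [A]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance map must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance map entries must be finite")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("distance map must be symmetric")
        v = 0.5 * (v + v.T)  # enforce exact symmetry
        np.fill_diagonal(v, 0.0)
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryMap:
    """Thresholded contact map; contact <=> distance <= threshold."""

    contacts: np.ndarray
    threshold: float = BINARY_THRESHOLD

    def __post_init__(self) -> None:
        c = np.asarray(self.contacts, dtype=bool)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("contact map must be square")
        if not np.array_equal(c, c.T):
            raise ValueError("contact map must be symmetric")
        self.contacts = c

    def __len__(self) -> int:
        return self.contacts.shape[0]

    @property
    def length(self) -> int:
        return self.contacts.shape[0]


@dataclass
class MultiClassMap:
    """Distance map quantized into len(thresholds)+1 ordinal classes."""

    classes: np.ndarray
    thresholds: tuple[float, ...] = FOURCLASS_THRESHOLDS

    def __post_init__(self) -> None:
        c = np.asarray(self.classes, dtype=np.int64)
        t = tuple(float(x) for x in self.thresholds)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("class map must be square")
        if not np.array_equal(c, c.T):
            raise ValueError("class map must be symmetric")
        if c.min() < 0 or c.max() > len(t):
            raise ValueError("class labels out of range")
        self.classes = c
        self.thresholds = t

    def __len__(self) -> int:
        return self.classes.shape[0]

    @property
    def length(self) -> int:
        return self.classes.shape[0]


def distance_map(trace: CaTrace) -> DistanceMap:
    """Euclidean Calpha-Calpha distance map of a trace."""
    diff = trace.coords[:, None, :] - trace.coords[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    return DistanceMap(0.5 * (d + d.T))


def binarize(dmap: DistanceMap, threshold: float = BINARY_THRESHOLD) -> BinaryMap:
    """Contact map: contact <=> distance <= threshold (boundary inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return BinaryMap(dmap.values <= threshold, threshold)


def quantize_4class(
    dmap: DistanceMap, thresholds: tuple[float, ...] = FOURCLASS_THRESHOLDS
) -> MultiClassMap:
    """Quantize by half-open intervals [0,t0), [t0,t1), [t1,t2), [t2,inf)."""
    t = tuple(float(x) for x in thresholds)
    if any(b <= a for a, b in zip(t, t[1:])) or t[0] <= 0:
        raise ValueError("thresholds must be positive and strictly increasing")
    classes = np.searchsorted(np.asarray(t), dmap.values, side="right")
    return MultiClassMap(classes, t)


def add_noise(dmap: DistanceMap, amplitude: float, seed: int) -> DistanceMap:
    """Perturb each unordered pair by one draw from Uniform(-amplitude, +amplitude).

    Both (i, j) and (j, i) receive the same perturbed value, the result is
    clamped to >= 0.1 A, and the diagonal is untouched.  Reproducible for a
    fixed seed.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    n = dmap.length
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    eps = rng.uniform(-amplitude, amplitude, size=len(iu))
    out = dmap.values.copy()
    out[iu, ju] = np.maximum(out[iu, ju] + eps, NOISE_FLOOR)
    out[ju, iu] = out[iu, ju]
    return DistanceMap(out)


# ---------------------------------------------------------------------------
# Plain-text square-matrix I/O (shared by all three map kinds)
# ---------------------------------------------------------------------------

def write_map_text(m: DistanceMap | BinaryMap | MultiClassMap) -> str:
    """Serialize a map as whitespace-separated rows with a '#' header."""
    if isinstance(m, DistanceMap):
        header = "# kind=distance"
        body = m.values
        fmt = "%.4f"
    elif isinstance(m, BinaryMap):
        header = f"# kind=binary threshold={m.threshold:g}"
        body = m.contacts.astype(int)
        fmt = "%d"
    elif isinstance(m, MultiClassMap):
        ts = ",".join(f"{t:g}" for t in m.thresholds)
        header = f"# kind=4class thresholds={ts}"
        body = m.classes
        fmt = "%d"
    else:
        raise TypeError(f"unsupported map type {type(m).__name__}")
    rows = [" ".join(fmt % x for x in row) for row in body]
    return header + "\n" + "\n".join(rows) + "\n"


def read_map_text(text: str) -> DistanceMap | BinaryMap | MultiClassMap:
    """Parse a map written by :func:`write_map_text` (or any plain matrix).

    A bare matrix with no header is interpreted as a distance map.
    """
    kind = "distance"
    meta: dict[str, str] = {}
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            kind = meta.get("kind", kind)
            continue
        rows.append([float(x) for x in line.split()])
    if not rows:
        raise ValueError("no matrix rows found")
    mat = np.array(rows)
    if kind == "binary":
        return BinaryMap(mat.astype(bool), float(meta.get("threshold", BINARY_THRESHOLD)))
    if kind == "4class":
        ts = tuple(
            float(x)
            for x in meta.get("thresholds", "8,13,19").split(",")
        )
        return MultiClassMap(mat.astype(int), ts)
    return DistanceMap(mat)
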