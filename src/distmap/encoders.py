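"""Input encodings for the distance-map predictors.

Per-pair input vectors concatenate, in fixed order, the per-residue blocks
[profile_j, profile_k, ss_j, ss_k, rsa_j, rsa_k, cd_j, cd_k] giving 58
units with 20-way amino-acid profiles ("classical") or 32 with the 7-class
physicochemical clustering ("complementarity"); the "correlation" variant
appends the Gobel correlated-mutation signal (59 units) and the "template"
variant appends the weighted template distance and coverage (60 units).
The filtering network consumes an 18-unit vector of local and global map
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io_structures import AA1, GAP_CHARS, Msa, SecondaryStructure
from .maps import DistanceMap

log = logging.getLogger(__name__)

AA_INDEX = {a: i for i, a in enumerate(AA1)}

#: 7-class physicochemical clustering of the amino acids
COMPLEMENTARITY_CLASSES = (
    "AFILMV",   # hydrophobic
    "NQSTWY",   # polar
    "DE",       # negatively charged
    "HKR",      # positively charged
    "C",        # cysteine
    "G",        # glycine
    "P",        # proline
)
_CLASS_OF = {a: c for c, group in enumerate(COMPLEMENTARITY_CLASSES) for a in group}

#: fraction of gaps above which an MSA column is dropped from the
#: correlated-mutation analysis
GAP_DISCARD_FRACTION = 0.2

VARIANT_DIMS = {"classical": 58, "complementarity": 32,
                "correlation": 59, "template": 60}


@dataclass
class TemplateHit:
    """One template's aligned distance map plus quality metadata.

    ``distances`` is the L x L map aligned to the query with NaN marking
    residue pairs the template does not cover.
    """

    distances: np.ndarray
    id_p: float          # sequence identity to the query, fraction
    coverage: float      # fraction of query residues aligned (non-gap)
    experiment: str      # "X-ray" | "NMR"
    resolution: float    # A
    r_factor: float

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 2 or self.distances.shape[0] != self.distances.shape[1]:
            raise ValueError("template distance map must be square")
        if not 0.0 <= self.id_p <= 1.0:
            raise ValueError("sequence identity must be a fraction in [0, 1]")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be a fraction in [0, 1]")
        if self.experiment not in ("X-ray", "NMR"):
            raise ValueError("experiment must be 'X-ray' or 'NMR'")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def quality(self) -> float:
        """q_p = 1 / (resolution + Rfactor/20) for X-ray, /10 for NMR."""
        denom = 20.0 if self.experiment == "X-ray" else 10.0
        return 1.0 / (self.resolution + self.r_factor / denom)

    @property
    def weight(self) -> float:
        """w_p = q_p * id_p^3 (identity cubed favours close homologues)."""
        return self.quality * self.id_p**3


# ---------------------------------------------------------------------------
# Column profiles
# ---------------------------------------------------------------------------

def column_profile(msa: Msa, j: int) -> np.ndarray:
    """Amino-acid frequencies over non-gap symbols of column ``j`` (sums to 1).

    An all-gap column degrades to a one-hot at the query residue (uniform
    when the query itself has no residue there).
    """
    col = msa.column(j)
    counts = np.zeros(len(AA1))
    for ch in col:
        if ch in AA_INDEX:
            counts[AA_INDEX[ch]] += 1
    total = counts.sum()
    if total == 0:
        q = msa.rows[msa.query_index][j]
        if q in AA_INDEX:
            counts[AA_INDEX[q]] = 1.0
            return counts
        return np.full(len(AA1), 1.0 / len(AA1))
    return counts / total


def complementarity_profile(msa: Msa, j: int) -> np.ndarray:
    """7-class frequencies: the 20-way profile aggregated through the
    physicochemical class map."""
    p20 = column_profile(msa, j)
    out = np.zeros(7)
    for a, idx in AA_INDEX.items():
        out[_CLASS_OF[a]] += p20[idx]
    return out


# ---------------------------------------------------------------------------
# Correlated mutations (Gobel)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _pam70() -> dict[tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("PAM70")
    table = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


def _column_usable(col: str) -> bool:
    gaps = sum(ch in GAP_CHARS for ch in col)
    if gaps / len(col) > GAP_DISCARD_FRACTION:
        return False
    residues = {ch for ch in col if ch in AA_INDEX}
    return len(residues) > 1  # completely conserved columns carry no signal


def gobel_correlation(msa: Msa, j: int, k: int) -> float:
    """Gobel correlated-mutation score between MSA columns j and k.

    Pearson correlation, over all sequence pairs (a < b), of the PAM70
    substitution scores s_j(a,b) and s_k(a,b), with uniform sequence
    weights.  Completely conserved columns and columns with > 20% gaps
    return 0, as do pairs with undefined variance.
    """
    if msa.n_rows < 2:
        return 0.0
    colj, colk = msa.column(j), msa.column(k)
    if not (_column_usable(colj) and _column_usable(colk)):
        return 0.0
    pam = _pam70()
    sj, sk = [], []
    m = msa.n_rows
    for a in range(m):
        if colj[a] not in AA_INDEX or colk[a] not in AA_INDEX:
            continue
        for b in range(a + 1, m):
            if colj[b] not in AA_INDEX or colk[b] not in AA_INDEX:
                continue
            sj.append(pam[(colj[a], colj[b])])
            sk.append(pam[(colk[a], colk[b])])
    if len(sj) < 2:
        return 0.0
    sj_arr = np.asarray(sj)
    sk_arr = np.asarray(sk)
    sj_arr -= sj_arr.mean()
    sk_arr -= sk_arr.mean()
    s1 = float(np.sqrt(np.mean(sj_arr**2)))
    s2 = float(np.sqrt(np.mean(sk_arr**2)))
    if s1 == 0.0 or s2 == 0.0:
        return 0.0
    return float(np.mean(sj_arr * sk_arr) / (s1 * s2))


# ---------------------------------------------------------------------------
# Template features (weighted averages over hits)
# ---------------------------------------------------------------------------

def template_pair_features(
    hits: list[TemplateHit], j: int, k: int
) -> tuple[float, float]:
    """Weighted template distance and coverage for residue pair (j, k).

    d_jk^T = sum_p w_p d_jk^p / sum_p w_p over the templates covering the
    pair, and c_jk^T the matching weighted coverage; (0, 0) when no
    template covers the pair (c^T = 0 signals "no template information").
    """
    wsum = 0.0
    dsum = 0.0
    csum = 0.0
    for hit in hits:
        d = hit.distances[j, k]
        if np.isnan(d):
            continue
        w = hit.weight
        wsum += w
        dsum += w * d
        csum += w * hit.coverage
    if wsum == 0.0:
        return 0.0, 0.0
    return dsum / wsum, csum / wsum


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

@dataclass
class ResidueFeatures:
    """Per-residue feature blocks shared by every pair containing it."""

    profile: np.ndarray    # (L, 20) or (L, 7)
    ss_onehot: np.ndarray  # (L, 3) over H/E/C
    rsa_onehot: np.ndarray  # (L, 2): buried 0-25%, exposed 25-100%
    cd_onehot: np.ndarray  # (L, 4): contact-density class

    def __post_init__(self):
        n = self.profile.shape[0]
        for name in ("ss_onehot", "rsa_onehot", "cd_onehot"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ValueError(f"{name} length mismatch")
            if not np.allclose(arr.sum(axis=1), 1.0):
                raise ValueError(f"{name} rows must sum to 1 (one-hot)")
        if np.any(self.profile < 0) or not np.allclose(self.profile.sum(axis=1), 1.0):
            raise ValueError("profiles must be probability vectors")

    @property
    def length(self) -> int:
        return self.profile.shape[0]


def residue_features(
    msa: Msa,
    ss: SecondaryStructure,
    rsa_classes: np.ndarray,
    cd_classes: np.ndarray,
    profile_kind: str = "classical",
) -> ResidueFeatures:
    """Assemble per-residue blocks from an alignment and annotations."""
    L = msa.n_cols
    if len(ss) != L or len(rsa_classes) != L or len(cd_classes) != L:
        raise ValueError("feature lengths disagree with the alignment width")
    if profile_kind == "complementarity":
        prof = np.stack([complementarity_profile(msa, j) for j in range(L)])
    else:
        prof = np.stack([column_profile(msa, j) for j in range(L)])
    ss_idx = np.array(["HEC".index(s) for s in ss.states])
    ss1 = np.eye(3)[ss_idx]
    rsa1 = np.eye(2)[np.asarray(rsa_classes, int)]
    cd1 = np.eye(4)[np.asarray(cd_classes, int)]
    return ResidueFeatures(prof, ss1, rsa1, cd1)


@dataclass
class FeatureSet:
    """Everything :func:`build_pair_input` may need for one protein."""

    residues: ResidueFeatures
    variant: str = "classical"
    correlation: np.ndarray | None = None   # (L, L), Gobel signal
    template_hits: list[TemplateHit] = field(default_factory=list)

    def __post_init__(self):
        if self.variant not in VARIANT_DIMS:
            raise ValueError(f"unknown variant {self.variant!r}")
        expected_profile = 7 if self.variant == "complementarity" else 20
        if self.residues.profile.shape[1] != expected_profile:
            raise ValueError(
                f"variant {self.variant!r} needs {expected_profile}-way profiles"
            )
        if self.variant == "correlation" and self.correlation is None:
            raise ValueError("correlation variant needs a correlation matrix")

    @property
    def length(self) -> int:
        return self.residues.length


def correlation_matrix(msa: Msa) -> np.ndarray:
    """Symmetric matrix of Gobel correlations for all column pairs."""
    L = msa.n_cols
    out = np.zeros((L, L))
    for j in range(L):
        for k in range(j + 1, L):
            out[j, k] = out[k, j] = gobel_correlation(msa, j, k)
    return out


def build_pair_input(fs: FeatureSet, j: int, k: int) -> np.ndarray:
    """Input vector for residue pair (j, k) in the declared variant."""
    r = fs.residues
    parts = [r.profile[j], r.profile[k], r.ss_onehot[j], r.ss_onehot[k],
             r.rsa_onehot[j], r.rsa_onehot[k], r.cd_onehot[j], r.cd_onehot[k]]
    if fs.variant == "correlation":
        parts.append(np.array([fs.correlation[j, k]]))
    elif fs.variant == "template":
        d_t, c_t = template_pair_features(fs.template_hits, j, k)
        parts.append(np.array([d_t, c_t]))
    vec = np.concatenate(parts)
    assert vec.shape[0] == VARIANT_DIMS[fs.variant]
    return vec


def input_grid(fs: FeatureSet) -> np.ndarray:
    """(L, L, D) grid of pair input vectors for the 2D-RNN."""
    L = fs.length
    D = VARIANT_DIMS[fs.variant]
    grid = np.empty((L, L, D))
    for j in range(L):
        for k in range(L):
            grid[j, k] = build_pair_input(fs, j, k)
    return grid


# ---------------------------------------------------------------------------
# Filtering-network features
# ---------------------------------------------------------------------------

FILTER_DIM = 18
_PATCH_HALF = 5
_PATCH_OFFSETS = tuple(o for a in range(11, 78, 11) for o in (-a, a))


def _patch_mean(values: np.ndarray, j: int, k: int) -> float | None:
    """Mean of the 11x11 patch centred at (j, k), clipped at the edges."""
    n = values.shape[0]
    j0, j1 = max(j - _PATCH_HALF, 0), min(j + _PATCH_HALF + 1, n)
    k0, k1 = max(k - _PATCH_HALF, 0), min(k + _PATCH_HALF + 1, n)
    if j0 >= j1 or k0 >= k1:
        return None
    return float(values[j0:j1, k0:k1].mean())


def filter_features(pred: DistanceMap, j: int, k: int) -> np.ndarray:
    """18-unit filter input: [d_jk, |j-k|, L, 15 patch means].

    The 15 global units are means of 11x11 patches: one centred at (j, k)
    and 14 more whose centres slide along the diagonal of constant
    sequence separation at offsets +/-11..77; patches falling entirely off
    the map reuse the central patch mean.
    """
    v = pred.values
    n = v.shape[0]
    central = _patch_mean(v, j, k)
    patches = [central]
    for off in _PATCH_OFFSETS:
        m = _patch_mean(v, j + off, k + off)
        patches.append(central if m is None else m)
    out = np.array([v[j, k], abs(j - k), float(n), *patches])
    assert out.shape[0] == FILTER_DIM
    return out


# ---------------------------------------------------------------------------
# Template-hit TSV I/O
# ---------------------------------------------------------------------------

def read_template_hits(tsv_text: str, read_map) -> list[TemplateHit]:
    """Parse a template hit list from TSV.

    Columns: identity_percent, coverage, experiment, resolution, r_factor,
    map_path.  ``read_map`` maps a path to an aligned L x L distance matrix
    (NaN = uncovered); it is injected so callers control file access.
    """
    hits = []
    for line in tsv_text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"expected 6 TSV columns, got {len(parts)}: {line!r}")
        idp, cov, exp, res, rf, path = parts
        hits.append(TemplateHit(
            distances=np.asarray(read_map(path), dtype=float),
            id_p=float(idp) / 100.0,
            coverage=float(cov),
            experiment=exp,
            resolution=float(res),
            r_factor=float(rf),
        ))
    return hits
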