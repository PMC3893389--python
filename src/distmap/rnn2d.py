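"""Grid-to-grid 2D recursive neural network for distance-map prediction.

Four hidden planes sweep the L x L grid from its four corners; the hidden
state of plane p at cell (j, k) is a tanh unit fed by the cell input and
the plane's own states at the two upstream neighbours, so the output at
(j, k) can depend on every input cell.  The output unit is linear on the
distance (a scaled-tanh alternative is available), the prediction is
symmetrized and clamped at zero.  A small residual filtering network
post-processes the raw map from 18 per-pair summary features.

Training is plain batched gradient descent over two-protein blocks with a
three-regime gradient-norm rescaling (boost tiny gradients, pass
mid-range, clip large), epoch shuffling, learning-rate halving after a
patience of non-improving epochs, and periodic checkpoints that are
ensembled by output averaging.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .encoders import FILTER_DIM, filter_features
from .maps import DistanceMap
from .metrics import map_rmsd

#: sweep directions (dj, dk) of the four hidden planes: NW, NE, SW, SE corners
PLANE_DIRECTIONS = ((1, 1), (1, -1), (-1, 1), (-1, -1))
#: distance ceiling of the scaled-tanh output alternative [A]
TANH_OUTPUT_SCALE = 60.0


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class Rnn2dModel:
    """Parameters of the four-plane 2D-RNN plus the filtering network."""

    input_dim: int
    hidden_dim: int = 7
    output_mode: str = "linear"       # "linear" | "scaled_tanh"
    filter_hidden: int = 8
    Wx: np.ndarray = None  # (4, H, D)
    Wh: np.ndarray = None  # (4, H, H)  upstream neighbour along j
    Wv: np.ndarray = None  # (4, H, H)  upstream neighbour along k
    b: np.ndarray = None   # (4, H)
    Vx: np.ndarray = None  # (D,)
    Vh: np.ndarray = None  # (4, H)
    c: float = 0.0
    Wf: np.ndarray = None  # (F, 18)
    bf: np.ndarray = None  # (F,)
    vf: np.ndarray = None  # (F,)
    cf: float = 0.0

    def __post_init__(self):
        if self.output_mode not in ("linear", "scaled_tanh"):
            raise ValueError("output_mode must be 'linear' or 'scaled_tanh'")
        if self.Wx is None:
            self._zero_init()

    def _zero_init(self) -> None:
        D, H, F = self.input_dim, self.hidden_dim, self.filter_hidden
        self.Wx = np.zeros((4, H, D))
        self.Wh = np.zeros((4, H, H))
        self.Wv = np.zeros((4, H, H))
        self.b = np.zeros((4, H))
        self.Vx = np.zeros(D)
        self.Vh = np.zeros((4, H))
        self.c = 0.0
        self.Wf = np.zeros((F, FILTER_DIM))
        self.bf = np.zeros(F)
        self.vf = np.zeros(F)
        self.cf = 0.0

    @classmethod
    def random_init(cls, input_dim: int, hidden_dim: int = 7, seed: int = 0,
                    output_mode: str = "linear", output_bias: float = 0.0,
                    filter_hidden: int = 8) -> "Rnn2dModel":
        """Zero-mean uniform init with per-unit fan-in scaling.

        The output bias can be preset (e.g. to the mean target distance) so
        the linear output unit starts in the right range.  The filter
        network's output weights start at zero, making the freshly
        initialized filter an exact pass-through of the raw distance.
        """
        rng = np.random.default_rng(seed)
        m = cls(input_dim, hidden_dim, output_mode, filter_hidden)

        def u(shape, fan_in):
            s = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-s, s, size=shape)

        D, H = input_dim, hidden_dim
        m.Wx = u((4, H, D), D + 2 * H)
        m.Wh = u((4, H, H), D + 2 * H)
        m.Wv = u((4, H, H), D + 2 * H)
        m.b = np.zeros((4, H))
        m.Vx = u(D, D + 4 * H)
        m.Vh = u((4, H), D + 4 * H)
        m.c = float(output_bias)
        m.Wf = u((filter_hidden, FILTER_DIM), FILTER_DIM)
        m.bf = np.zeros(filter_hidden)
        m.vf = np.zeros(filter_hidden)   # residual filter: identity at init
        m.cf = 0.0
        return m

    # -- trainable parameter bookkeeping (filter excluded: trained separately)
    _CORE = ("Wx", "Wh", "Wv", "b", "Vx", "Vh", "c")

    def core_params(self) -> list:
        return [getattr(self, n) for n in self._CORE]

    def copy(self) -> "Rnn2dModel":
        return copy.deepcopy(self)

    def save(self, path: str) -> None:
        meta = dict(input_dim=self.input_dim, hidden_dim=self.hidden_dim,
                    output_mode=self.output_mode, filter_hidden=self.filter_hidden,
                    version=1)
        np.savez(path, meta=json.dumps(meta), Wx=self.Wx, Wh=self.Wh,
                 Wv=self.Wv, b=self.b, Vx=self.Vx, Vh=self.Vh,
                 c=np.array(self.c), Wf=self.Wf, bf=self.bf, vf=self.vf,
                 cf=np.array(self.cf))

    @classmethod
    def load(cls, path: str) -> "Rnn2dModel":
        z = np.load(path, allow_pickle=False)
        meta = json.loads(str(z["meta"]))
        m = cls(meta["input_dim"], meta["hidden_dim"], meta["output_mode"],
                meta["filter_hidden"])
        for n in ("Wx", "Wh", "Wv", "b", "Vx", "Vh", "Wf", "bf", "vf"):
            setattr(m, n, z[n])
        m.c = float(z["c"])
        m.cf = float(z["cf"])
        return m


# ---------------------------------------------------------------------------
# Numba kernels: plane recurrences and backprop
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_planes(X, Wx, Wh, Wv, b):
    L = X.shape[0]
    H = Wx.shape[1]
    planes = np.zeros((4, L, L, H))
    acts = np.zeros((4, L, L, H))
    dirs = ((1, 1), (1, -1), (-1, 1), (-1, -1))
    for p in range(4):
        dj, dk = dirs[p]
        j0 = 0 if dj == 1 else L - 1
        k0 = 0 if dk == 1 else L - 1
        for jj in range(L):
            j = j0 + dj * jj
            for kk in range(L):
                k = k0 + dk * kk
                a = Wx[p] @ X[j, k] + b[p]
                jp = j - dj
                if 0 <= jp < L:
                    a += Wh[p] @ planes[p, jp, k]
                kp = k - dk
                if 0 <= kp < L:
                    a += Wv[p] @ planes[p, j, kp]
                acts[p, j, k] = a
                planes[p, j, k] = np.tanh(a)
    return planes, acts


@njit(cache=True)
def _output_grid(X, planes, Vx, Vh, c):
    L = X.shape[0]
    O = np.empty((L, L))
    for j in range(L):
        for k in range(L):
            o = c + Vx @ X[j, k]
            for p in range(4):
                o += Vh[p] @ planes[p, j, k]
            O[j, k] = o
    return O


@njit(cache=True)
def _backward(X, planes, dO, Wh, Wv, Vx, Vh):
    """Gradients of sum(dO * O) w.r.t. all core parameters."""
    L = X.shape[0]
    H = planes.shape[3]
    D = X.shape[2]
    dWx = np.zeros((4, H, D))
    dWh = np.zeros((4, H, H))
    dWv = np.zeros((4, H, H))
    db = np.zeros((4, H))
    dVx = np.zeros(D)
    dVh = np.zeros((4, H))
    dc = 0.0
    for j in range(L):
        for k in range(L):
            g = dO[j, k]
            dc += g
            dVx += g * X[j, k]
            for p in range(4):
                dVh[p] += g * planes[p, j, k]
    dirs = ((1, 1), (1, -1), (-1, 1), (-1, -1))
    for p in range(4):
        dj, dk = dirs[p]
        # reverse sweep: start from the last-visited corner
        j0 = L - 1 if dj == 1 else 0
        k0 = L - 1 if dk == 1 else 0
        dh = np.zeros((L, L, H))
        for jj in range(L):
            j = j0 - dj * jj
            for kk in range(L):
                k = k0 - dk * kk
                g = dO[j, k] * Vh[p] + dh[j, k]
                da = g * (1.0 - planes[p, j, k] ** 2)
                db[p] += da
                for h in range(H):
                    for d in range(D):
                        dWx[p, h, d] += da[h] * X[j, k, d]
                jp = j - dj
                if 0 <= jp < L:
                    for h in range(H):
                        for h2 in range(H):
                            dWh[p, h, h2] += da[h] * planes[p, jp, k, h2]
                    dh[jp, k] += Wh[p].T @ da
                kp = k - dk
                if 0 <= kp < L:
                    for h in range(H):
                        for h2 in range(H):
                            dWv[p, h, h2] += da[h] * planes[p, j, kp, h2]
                    dh[j, kp] += Wv[p].T @ da
    return dWx, dWh, dWv, db, dVx, dVh, dc


# ---------------------------------------------------------------------------
# Forward / loss / gradient
# ---------------------------------------------------------------------------

def _raw_output(model: Rnn2dModel, X: np.ndarray):
    planes, _ = _forward_planes(X, model.Wx, model.Wh, model.Wv, model.b)
    O = _output_grid(X, planes, model.Vx, model.Vh, model.c)
    return planes, O


def forward(model: Rnn2dModel, inputs: np.ndarray) -> DistanceMap:
    """Predicted distance map for an (L, L, D) grid of pair inputs."""
    X = np.ascontiguousarray(inputs, dtype=float)
    if X.ndim != 3 or X.shape[0] != X.shape[1]:
        raise ValueError("inputs must be a square (L, L, D) grid")
    if X.shape[2] != model.input_dim:
        raise ValueError(
            f"input dim {X.shape[2]} does not match model dim {model.input_dim}"
        )
    _, O = _raw_output(model, X)
    if model.output_mode == "scaled_tanh":
        O = TANH_OUTPUT_SCALE * 0.5 * (np.tanh(O) + 1.0)
    P = 0.5 * (O + O.T)
    P = np.maximum(P, 0.0)
    np.fill_diagonal(P, 0.0)
    return DistanceMap(P)


def loss(pred: DistanceMap, target: DistanceMap) -> float:
    """Squared error summed over residue pairs i < j."""
    p, t = pred.values, target.values
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    iu, ju = np.triu_indices(p.shape[0], k=1)
    d = p[iu, ju] - t[iu, ju]
    return float(np.sum(d * d))


def loss_and_grad(model: Rnn2dModel, X: np.ndarray, target: np.ndarray):
    """Training loss and analytic core-parameter gradients for one protein."""
    X = np.ascontiguousarray(X, dtype=float)
    T = np.asarray(target, dtype=float)
    planes, O = _raw_output(model, X)
    if model.output_mode == "scaled_tanh":
        S = TANH_OUTPUT_SCALE * 0.5 * (np.tanh(O) + 1.0)
    else:
        S = O
    P = 0.5 * (S + S.T)
    relu_mask = P > 0.0
    Pc = np.where(relu_mask, P, 0.0)
    L = X.shape[0]
    iu, ju = np.triu_indices(L, k=1)
    resid = Pc[iu, ju] - T[iu, ju]
    value = float(np.sum(resid * resid))
    # gradient back through clamp -> symmetrize -> (optional tanh) -> O
    dP = np.zeros((L, L))
    g = 2.0 * resid * relu_mask[iu, ju]
    dP[iu, ju] = g
    dS = 0.5 * (dP + dP.T)
    if model.output_mode == "scaled_tanh":
        dO = dS * TANH_OUTPUT_SCALE * 0.5 * (1.0 - np.tanh(O) ** 2)
    else:
        dO = dS
    grads = _backward(X, planes, dO, model.Wh, model.Wv, model.Vx, model.Vh)
    return value, grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 1000
    proteins_per_batch: int = 2
    checkpoint_every: int = 5
    lr: float = 1e-3
    lr_halving_patience: int = 50
    shuffle: bool = True
    momentum: float = 0.9   # heavy-ball momentum; 0 recovers plain descent
    seed: int = 0
    #: three-regime gradient-norm rescaling: norms below ``boost_below`` are
    #: scaled up to it, norms above ``clip_above`` are scaled down to it,
    #: anything between passes unchanged
    boost_below: float = 1e-8
    clip_above: float = 100.0
    max_length: int = 200   # training grids are O(L^2); cap protein length

    def __post_init__(self):
        for name in ("epochs", "proteins_per_batch", "checkpoint_every",
                     "lr_halving_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class TrainResult:
    model: Rnn2dModel
    checkpoints: list[tuple[int, Rnn2dModel]] = field(default_factory=list)
    loss_history: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)


def _rescale(grads: list[np.ndarray], cfg: TrainConfig) -> list[np.ndarray]:
    norm = np.sqrt(sum(float(np.sum(np.asarray(g) ** 2)) for g in grads))
    if norm == 0.0:
        return grads
    if norm < cfg.boost_below:
        scale = cfg.boost_below / norm
    elif norm > cfg.clip_above:
        scale = cfg.clip_above / norm
    else:
        scale = 1.0
    return [np.asarray(g) * scale for g in grads]


def train(dataset: list[tuple[np.ndarray, np.ndarray]],
          config: TrainConfig | None = None,
          model: Rnn2dModel | None = None) -> TrainResult:
    """Train a 2D-RNN on (input grid, target map-values) pairs.

    Weights are updated per block of ``proteins_per_batch`` proteins; the
    dataset is reshuffled every epoch; the learning rate is halved when the
    epoch loss has not improved for ``lr_halving_patience`` consecutive
    epochs; model checkpoints are kept every ``checkpoint_every`` epochs.
    """
    if not dataset:
        raise ValueError("empty dataset")
    cfg = config or TrainConfig()
    dataset = [(X, T) for X, T in dataset if X.shape[0] <= cfg.max_length]
    if not dataset:
        raise ValueError(f"all proteins exceed the {cfg.max_length}-residue cap")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        D = dataset[0][0].shape[2]
        mean_t = float(np.mean([T[np.triu_indices(T.shape[0], 1)].mean()
                                for _, T in dataset]))
        model = Rnn2dModel.random_init(D, seed=cfg.seed, output_bias=mean_t)
    else:
        model = model.copy()
    lr = cfg.lr
    best = np.inf
    stale = 0
    result = TrainResult(model)
    order = np.arange(len(dataset))
    vel = [np.zeros_like(np.asarray(p, dtype=float)) for p in model.core_params()]
    for epoch in range(1, cfg.epochs + 1):
        if cfg.shuffle:
            rng.shuffle(order)
        epoch_loss = 0.0
        for s in range(0, len(order), cfg.proteins_per_batch):
            block = order[s:s + cfg.proteins_per_batch]
            total = None
            for idx in block:
                X, T = dataset[idx]
                value, grads = loss_and_grad(model, X, T)
                epoch_loss += value
                if total is None:
                    total = [np.array(g, dtype=float) for g in grads]
                else:
                    for acc, g in zip(total, grads):
                        acc += g
            total = _rescale(total, cfg)
            for i in range(7):
                vel[i] = cfg.momentum * vel[i] + total[i]
            model.Wx -= lr * vel[0]
            model.Wh -= lr * vel[1]
            model.Wv -= lr * vel[2]
            model.b -= lr * vel[3]
            model.Vx -= lr * vel[4]
            model.Vh -= lr * vel[5]
            model.c -= lr * float(vel[6])
        result.loss_history.append(epoch_loss)
        result.lr_history.append(lr)
        if epoch_loss < best - 1e-12:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.lr_halving_patience:
                lr *= 0.5
                stale = 0
        if epoch % cfg.checkpoint_every == 0:
            result.checkpoints.append((epoch, model.copy()))
    result.model = model
    return result


# ---------------------------------------------------------------------------
# Ensembling
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Average-of-members predictor (>= 1 member)."""

    members: list[Rnn2dModel]

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")


def ensemble_from_training(result: TrainResult, last: int = 3) -> EnsembleModel:
    """Combine the last ``last`` checkpoints of one training run."""
    members = [m for _, m in result.checkpoints[-last:]] or [result.model]
    return EnsembleModel(members)


def combine_folds(fold_results: list[TrainResult], last: int = 3) -> EnsembleModel:
    """Pool the last checkpoints of every cross-validation fold."""
    members = []
    for r in fold_results:
        members.extend(m for _, m in r.checkpoints[-last:])
        if not r.checkpoints:
            members.append(r.model)
    return EnsembleModel(members)


def train_kfold(dataset, config: TrainConfig | None = None,
                k: int = 5) -> tuple[EnsembleModel, list[TrainResult]]:
    """k-fold training: each fold trains on the other folds' proteins."""
    cfg = config or TrainConfig()
    n = len(dataset)
    if n < k:
        raise ValueError("fewer proteins than folds")
    idx = np.arange(n)
    np.random.default_rng(cfg.seed).shuffle(idx)
    folds = np.array_split(idx, k)
    results = []
    for f, held in enumerate(folds):
        train_idx = np.setdiff1d(idx, held)
        sub = [dataset[i] for i in train_idx]
        results.append(train(sub, cfg))
    return combine_folds(results), results


def predict(ensemble: EnsembleModel, inputs: np.ndarray) -> DistanceMap:
    """Mean of member outputs, symmetrized and clamped like forward()."""
    acc = None
    for m in ensemble.members:
        out = forward(m, inputs).values
        acc = out if acc is None else acc + out
    return DistanceMap(acc / len(ensemble.members))


# ---------------------------------------------------------------------------
# Filtering network
# ---------------------------------------------------------------------------

def _filter_matrix(raw: DistanceMap) -> np.ndarray:
    L = raw.length
    F = np.empty((L, L, FILTER_DIM))
    for j in range(L):
        for k in range(L):
            F[j, k] = filter_features(raw, j, k)
    return F


def filter_refine(model: Rnn2dModel, raw: DistanceMap) -> DistanceMap:
    """Residual filtering pass: d'_jk = d_jk + v . tanh(Wf f_jk + bf) + cf.

    With the filter parameters at their initial zeros this is an exact
    pass-through of the raw map.  Output is symmetrized and clamped >= 0.
    """
    F = _filter_matrix(raw)
    hidden = np.tanh(F @ model.Wf.T + model.bf)
    out = raw.values + hidden @ model.vf + model.cf
    out = 0.5 * (out + out.T)
    out = np.maximum(out, 0.0)
    np.fill_diagonal(out, 0.0)
    return DistanceMap(out)


def train_filter(model: Rnn2dModel,
                 dataset: list[tuple[DistanceMap, np.ndarray]],
                 epochs: int = 200, lr: float = 1e-6,
                 seed: int = 0) -> Rnn2dModel:
    """Fit the filter on (raw prediction, target values) pairs.

    The 2D-RNN is frozen; this is plain gradient descent on the summed
    squared error of the filtered map.  Returns a new model with updated
    filter parameters.
    """
    model = model.copy()
    rng = np.random.default_rng(seed)
    s = 1.0 / np.sqrt(FILTER_DIM)
    if not model.Wf.any():
        model.Wf = rng.uniform(-s, s, size=model.Wf.shape)
    feats = [(_filter_matrix(raw), raw.values, T) for raw, T in dataset]
    for _ in range(epochs):
        for F, rawv, T in feats:
            L = rawv.shape[0]
            hidden = np.tanh(F @ model.Wf.T + model.bf)
            out = rawv + hidden @ model.vf + model.cf
            out = 0.5 * (out + out.T)
            mask = out > 0
            outc = np.where(mask, out, 0.0)
            iu, ju = np.triu_indices(L, k=1)
            resid = np.zeros((L, L))
            r = 2.0 * (outc[iu, ju] - T[iu, ju]) * mask[iu, ju]
            resid[iu, ju] = r
            dout = 0.5 * (resid + resid.T)
            dvf = np.einsum("jk,jkf->f", dout, hidden)
            dcf = float(dout.sum())
            dh = dout[..., None] * model.vf * (1.0 - hidden ** 2)
            dWf = np.einsum("jkf,jkg->fg", dh, F)
            dbf = dh.sum(axis=(0, 1))
            model.vf -= lr * dvf
            model.cf -= lr * dcf
            model.Wf -= lr * dWf
            model.bf -= lr * dbf
    return model
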