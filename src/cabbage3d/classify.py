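"""Supervised plant-type classification by trait-fused set abstraction.

The encoder follows the hierarchical set-abstraction recipe: farthest-point
sampling picks representative centroids, each centroid gathers its
radius-ball neighborhood (multi-scale grouping concatenates several radii),
a shared per-point MLP lifts the grouped relative coordinates (plus any
features from the previous stage) and a symmetric max-pool collapses each
group; a final global stage pools everything into a 1024-dimensional
embedding.  The ten architecture traits, z-scored with training-split
statistics, are concatenated onto the embedding (1034 dimensions) and only
the fully connected head sees them.  Everything runs in numpy on CPU with
hand-written backprop (see :mod:`cabbage3d.nn`).

Two practical conventions make inference a pure function of the point set:
the encoder's FPS chains start at the point farthest from the centroid (a
geometric choice, so permuting the input rows cannot change which points are
selected), and max-pooling makes group order irrelevant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import InsufficientPointsError, ValidationError
from .nn import MLP, Adam, SGD, cross_entropy_grad, max_pool, max_pool_backward, softmax
from .preprocess import fps_indices
from .traits import TRAIT_NAMES, TraitVector

__all__ = [
    "SAStage",
    "NetConfig",
    "ClassifierModel",
    "EvalReport",
    "encode",
    "fuse_features",
    "train_classifier",
    "evaluate",
    "trait_baseline",
    "TraitBaseline",
]

EMBED_DIM = 1024
N_TRAITS = len(TRAIT_NAMES)


@dataclass
class SAStage:
    """One set-abstraction stage: sampling, grouping and the per-point MLP.

    ``radii`` holds one entry for single-scale grouping and several for
    multi-scale grouping; each radius is a fraction of the unit-normalized
    cloud scale and owns its own MLP branch of widths ``mlp``.
    """

    n_centroids: int
    radii: tuple = (0.3,)
    max_neighbors: int = 32
    mlp: tuple = (32, 64)

    def __post_init__(self):
        if self.n_centroids < 1 or self.max_neighbors < 1 or not self.radii:
            raise ValidationError("SAStage counts must be positive")


@dataclass
class NetConfig:
    """Architecture + training hyperparameters of the fusion classifier.

    Defaults are desk-scale (512 points, two local stages, short schedule) so
    the model trains in minutes on one CPU; :meth:`paper_scale` returns the
    full-size configuration (4096 points, multi-scale grouping, batch 8,
    200 epochs, Adam at 1e-3 with 1e-4 weight decay and dropout 0.5).
    """

    grouping: str = "ssg"
    n_points: int = 512
    sa_stages: tuple = (
        SAStage(64, (0.3,), 32, (32, 64)),
        SAStage(16, (0.7,), 16, (64, 128)),
    )
    global_mlp: tuple = (256, EMBED_DIM)
    head: tuple = (128,)
    dropout: float = 0.5
    n_classes: int = 4
    use_traits: bool = True
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 8
    epochs: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.grouping not in ("ssg", "msg"):
            raise ValidationError("grouping must be 'ssg' or 'msg'")
        if self.global_mlp[-1] != EMBED_DIM:
            raise ValidationError(f"final encoder width must be {EMBED_DIM}")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must be in [0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ValidationError("optimizer must be 'adam' or 'sgd'")
        if self.grouping == "ssg" and any(len(s.radii) != 1 for s in self.sa_stages):
            raise ValidationError("ssg stages must have exactly one radius")

    @property
    def head_in(self) -> int:
        return EMBED_DIM + (N_TRAITS if self.use_traits else 0)

    @classmethod
    def paper_scale(cls) -> "NetConfig":
        return cls(
            grouping="msg",
            n_points=4096,
            sa_stages=(
                SAStage(512, (0.1, 0.2, 0.4), 32, (32, 32, 64)),
                SAStage(128, (0.2, 0.4, 0.8), 64, (64, 64, 128)),
            ),
            global_mlp=(256, 512, EMBED_DIM),
            head=(512, 256),
            dropout=0.5,
            batch_size=8,
            epochs=200,
            learning_rate=1e-3,
            weight_decay=1e-4,
        )


@dataclass
class EvalReport:
    """Confusion matrix (rows = true) and the derived classification metrics."""

    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    class_names: tuple = ()

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int,
                         class_names=()) -> "EvalReport":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.size == 0:
            raise ValidationError("cannot evaluate an empty dataset")
        cm = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(cm, (y_true, y_pred), 1)
        tp = np.diag(cm).astype(float)
        fp = cm.sum(axis=0) - tp
        fn = cm.sum(axis=1) - tp
        with np.errstate(invalid="ignore", divide="ignore"):
            precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
            recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
            pr = precision + recall
            f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
        if ((tp + fp) == 0).any() or ((tp + fn) == 0).any():
            warnings.warn("zero-denominator metric reported as 0", stacklevel=2)
        return cls(cm, float(tp.sum() / cm.sum()), precision, recall, f1,
                   float(precision.mean()), float(recall.mean()), float(f1.mean()),
                   tuple(class_names))


# ---------------------------------------------------------------------------
# geometry cache

def _canonical_points(pc: PointCloud, n_points: int) -> np.ndarray:
    """Center, unit-scale (max norm) and FPS-downsample to ``n_points``."""
    coords = pc.coords - pc.coords.mean(axis=0)
    scale = np.linalg.norm(coords, axis=1).max()
    if scale <= 0:
        raise InsufficientPointsError("degenerate cloud (zero extent)")
    coords = coords / scale
    n = coords.shape[0]
    if n < n_points:
        raise InsufficientPointsError(
            f"cloud has {n} points; encoder needs at least {n_points}")
    if n > n_points:
        first = int(np.argmax(np.linalg.norm(coords, axis=1)))
        idx = np.sort(fps_indices(coords, n_points, first))
        coords = coords[idx]
    return coords


def _build_graph(points: np.ndarray, cfg: NetConfig):
    """Per-cloud FPS centroids and capped radius-ball neighbor indices."""
    graph = []
    pts = points
    for stage in cfg.sa_stages:
        m = min(stage.n_centroids, pts.shape[0])
        first = int(np.argmax(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
        cent_idx = fps_indices(pts, m, first) if m < pts.shape[0] \
            else np.arange(pts.shape[0])
        centroids = pts[cent_idx]
        tree = cKDTree(pts)
        nbrs_per_radius = []
        k = stage.max_neighbors
        for r in stage.radii:
            dist, idx = tree.query(centroids, k=k, distance_upper_bound=r)
            if k == 1:
                dist, idx = dist[:, None], idx[:, None]
            nbr = np.where(np.isfinite(dist), idx, -1)
            # empty balls fall back to the nearest point; remaining slots are
            # padded by cycling valid entries (duplicates are harmless under
            # max-pooling)
            _, nearest = tree.query(centroids, k=1)
            out = np.empty((m, k), dtype=np.intp)
            for i in range(m):
                valid = nbr[i][nbr[i] >= 0]
                if valid.size == 0:
                    valid = np.array([nearest[i]])
                reps = int(np.ceil(k / valid.size))
                out[i] = np.tile(valid, reps)[:k]
            nbrs_per_radius.append(out)
        graph.append({"cent": cent_idx, "nbrs": nbrs_per_radius,
                      "points": centroids})
        pts = centroids
    return graph


# ---------------------------------------------------------------------------
# model

class ClassifierModel:
    """Trained fusion classifier: encoder stages, head, and trait statistics."""

    def __init__(self, cfg: NetConfig, class_names=("FULL", "HIGHLY_LEAN",
                                                    "TIGHT", "ROUND_SPREAD")):
        self.cfg = cfg
        self.class_names = tuple(class_names)
        rng = np.random.default_rng(cfg.seed)
        self.branches: list[list[MLP]] = []
        c_in = 0  # features carried from the previous stage
        for stage in cfg.sa_stages:
            stage_branches = []
            for _ in stage.radii:
                stage_branches.append(MLP([3 + c_in, *stage.mlp], rng))
            self.branches.append(stage_branches)
            c_in = stage.mlp[-1] * len(stage.radii)
        self.global_mlp = MLP([3 + c_in, *cfg.global_mlp], rng)
        self.head = MLP([cfg.head_in, *cfg.head, cfg.n_classes], rng,
                        final_relu=False)
        self.trait_mean = np.zeros(N_TRAITS)
        self.trait_sd = np.ones(N_TRAITS)

    # -- plumbing ----------------------------------------------------------
    @property
    def all_layers(self):
        layers = []
        for stage in self.branches:
            for mlp in stage:
                layers.extend(mlp.dense_layers)
        layers.extend(self.global_mlp.dense_layers)
        layers.extend(self.head.dense_layers)
        return layers

    def zero_grad(self):
        for stage in self.branches:
            for mlp in stage:
                mlp.zero_grad()
        self.global_mlp.zero_grad()
        self.head.zero_grad()

    # -- forward / backward ------------------------------------------------
    def _encode_batch(self, points: np.ndarray, graphs, train: bool = False):
        """points: (B, N, 3) canonical clouds with per-sample graphs."""
        B = points.shape[0]
        feats = None
        pts = points
        cache = []
        for s, stage in enumerate(self.cfg.sa_stages):
            cent_idx = np.stack([g[s]["cent"] for g in graphs])        # (B, M)
            centroids = np.take_along_axis(pts, cent_idx[..., None], 1)  # (B, M, 3)
            branch_outs = []
            branch_cache = []
            for b, radius in enumerate(stage.radii):
                nbr = np.stack([g[s]["nbrs"][b] for g in graphs])       # (B, M, K)
                Bi = np.arange(B)[:, None, None]
                grp_pts = pts[Bi, nbr]                                  # (B, M, K, 3)
                rel = (grp_pts - centroids[:, :, None, :]) / radius
                if feats is None:
                    x = rel
                else:
                    x = np.concatenate([rel, feats[Bi, nbr]], axis=-1)
                h = self.branches[s][b].forward(x, train=train)         # (B,M,K,W)
                pooled, arg = max_pool(h, axis=2)
                branch_outs.append(pooled)
                branch_cache.append((nbr, arg, h.shape[2], x.shape[-1]))
            new_feats = np.concatenate(branch_outs, axis=-1)
            cache.append((pts.shape[1], feats.shape[-1] if feats is not None else 0,
                          branch_cache))
            pts = centroids
            feats = new_feats
        x = np.concatenate([pts, feats], axis=-1)                       # (B, M, 3+C)
        h = self.global_mlp.forward(x, train=train)                     # (B, M, 1024)
        emb, arg = max_pool(h, axis=1)
        if train:
            self._enc_cache = (cache, arg, h.shape[1], x.shape[-1])
        return emb

    def _encode_backward(self, demb: np.ndarray, graphs):
        cache, g_arg, g_size, g_in = self._enc_cache
        dh = max_pool_backward(demb, g_arg, axis=1, size=g_size)
        dx = self.global_mlp.backward(dh)
        dfeats = dx[..., 3:]  # gradient w.r.t. the last stage's features
        B = demb.shape[0]
        for s in range(len(self.cfg.sa_stages) - 1, -1, -1):
            n_prev, c_prev, branch_cache = cache[s]
            dprev = np.zeros((B, n_prev, c_prev)) if c_prev else None
            offset = 0
            for b, (nbr, arg, ksize, in_dim) in enumerate(branch_cache):
                w = self.cfg.sa_stages[s].mlp[-1]
                dpooled = dfeats[..., offset:offset + w]
                offset += w
                dgrp = max_pool_backward(dpooled, arg, axis=2, size=ksize)
                dxin = self.branches[s][b].backward(dgrp)  # (B, M, K, in_dim)
                if dprev is not None:
                    Bi = np.arange(B)[:, None, None]
                    np.add.at(dprev, (Bi, nbr), dxin[..., 3:])
            dfeats = dprev

    def forward(self, points, graphs, traits_z, train=False,
                dropout_rng: np.random.Generator | None = None):
        emb = self._encode_batch(points, graphs, train=train)
        if self.cfg.use_traits:
            if traits_z is None:
                raise ValidationError("model fuses traits but none were given")
            x = np.concatenate([emb, traits_z], axis=-1)
        else:
            x = emb
        # dropout on the fused vector entering the fully connected head
        if train and self.cfg.dropout > 0:
            mask = (dropout_rng.random(x.shape) >= self.cfg.dropout)
            x = x * mask / (1.0 - self.cfg.dropout)
            self._drop_mask = mask
        logits = self.head.forward(x, train=train)
        return logits, emb

    def backward(self, dlogits, graphs):
        dx = self.head.backward(dlogits)
        if self.cfg.dropout > 0 and getattr(self, "_drop_mask", None) is not None:
            dx = dx * self._drop_mask / (1.0 - self.cfg.dropout)
            self._drop_mask = None
        demb = dx[:, :EMBED_DIM]
        self._encode_backward(demb, graphs)

    # -- inference ---------------------------------------------------------
    def standardize_traits(self, traits: np.ndarray) -> np.ndarray:
        return (np.asarray(traits, dtype=float) - self.trait_mean) / self.trait_sd

    def predict_proba(self, clouds, traits=None) -> np.ndarray:
        points = np.stack([_canonical_points(pc, self.cfg.n_points)
                           for pc in clouds])
        graphs = [_build_graph(p, self.cfg) for p in points]
        tz = self.standardize_traits(traits) if self.cfg.use_traits else None
        logits, _ = self.forward(points, graphs, tz, train=False)
        return softmax(logits)

    def predict(self, clouds, traits=None) -> np.ndarray:
        return np.argmax(self.predict_proba(clouds, traits), axis=1)

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict:
        state = {"trait_mean": self.trait_mean, "trait_sd": self.trait_sd}
        for i, layer in enumerate(self.all_layers):
            state[f"W{i}"] = layer.W
            state[f"b{i}"] = layer.b
        return state

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load_state(self, state) -> None:
        self.trait_mean = np.asarray(state["trait_mean"])
        self.trait_sd = np.asarray(state["trait_sd"])
        for i, layer in enumerate(self.all_layers):
            layer.W = np.asarray(state[f"W{i}"])
            layer.b = np.asarray(state[f"b{i}"])
            layer.dW = np.zeros_like(layer.W)
            layer.db = np.zeros_like(layer.b)

    @classmethod
    def from_file(cls, path, cfg: NetConfig, class_names=None) -> "ClassifierModel":
        model = cls(cfg, class_names or ("FULL", "HIGHLY_LEAN", "TIGHT",
                                         "ROUND_SPREAD"))
        with np.load(path) as state:
            model.load_state(state)
        return model


# ---------------------------------------------------------------------------
# public operations

def encode(pc: PointCloud, model: ClassifierModel) -> np.ndarray:
    """1024-dimensional embedding of a single cloud; order-invariant."""
    points = _canonical_points(pc, model.cfg.n_points)[None]
    graph = [_build_graph(points[0], model.cfg)]
    return model._encode_batch(points, graph, train=False)[0]


def fuse_features(embedding: np.ndarray, traits, stats=None,
                  trait_names=TRAIT_NAMES) -> np.ndarray:
    """Concatenate a 1024-dim embedding with the 10 z-scored traits (1034).

    ``traits`` may be a :class:`TraitVector` or an array in TraitVector
    order; ``trait_names`` must match the canonical order exactly (a
    permuted schema is an error, not a silent reorder).  ``stats`` is an
    optional ``(mean, sd)`` pair fitted on the training split.
    """
    embedding = np.asarray(embedding, dtype=float).ravel()
    if embedding.shape != (EMBED_DIM,):
        raise ValidationError(f"embedding must have length {EMBED_DIM}")
    if tuple(trait_names) != TRAIT_NAMES:
        raise ValidationError(f"trait order must be {TRAIT_NAMES}")
    if isinstance(traits, TraitVector):
        tvals = traits.as_array()
    else:
        tvals = np.asarray(traits, dtype=float).ravel()
    if tvals.shape != (N_TRAITS,) or not np.isfinite(tvals).all():
        raise ValidationError(f"need {N_TRAITS} finite trait values")
    if stats is not None:
        mean, sd = stats
        tvals = (tvals - np.asarray(mean)) / np.asarray(sd)
    return np.concatenate([embedding, tvals])


def train_classifier(clouds, labels, cfg: NetConfig, traits=None,
                     class_names=None, verbose=False):
    """Train the fusion classifier; returns (model, per-epoch log).

    ``labels`` are integer class ids; ``traits`` is the (n, 10) raw trait
    matrix (required unless ``cfg.use_traits`` is False) and is z-scored with
    statistics of this training split only.
    """
    labels = np.asarray(labels, dtype=int)
    present = np.unique(labels)
    if present.size < 2:
        raise ValidationError("training needs at least 2 classes")
    if present.size < cfg.n_classes and verbose:
        warnings.warn("some classes absent from the training split")
    model = ClassifierModel(cfg, class_names or tuple(str(c) for c
                                                      in range(cfg.n_classes)))
    if cfg.use_traits:
        if traits is None:
            raise ValidationError("cfg.use_traits requires a trait matrix")
        traits = np.asarray(traits, dtype=float)
        model.trait_mean = traits.mean(axis=0)
        sd = traits.std(axis=0, ddof=1)
        model.trait_sd = np.where(sd > 0, sd, 1.0)
        traits_z = model.standardize_traits(traits)
    else:
        traits_z = None

    points = np.stack([_canonical_points(pc, cfg.n_points) for pc in clouds])
    graphs = [_build_graph(p, cfg) for p in points]

    layers = model.all_layers
    if cfg.optimizer == "adam":
        opt = Adam(layers, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    else:
        opt = SGD(layers, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(clouds)
    log = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            bp = points[idx]
            bg = [graphs[i] for i in idx]
            bt = traits_z[idx] if traits_z is not None else None
            logits, _ = model.forward(bp, bg, bt, train=True, dropout_rng=rng)
            loss, dlogits = cross_entropy_grad(logits, labels[idx])
            model.zero_grad()
            model.backward(dlogits, bg)
            opt.step()
            losses.append(loss)
            correct += int((np.argmax(logits, axis=1) == labels[idx]).sum())
        log.append({"epoch": epoch, "loss": float(np.mean(losses)),
                    "train_accuracy": correct / n})
        if verbose:
            print(f"epoch {epoch:3d}  loss {log[-1]['loss']:.4f}  "
                  f"acc {log[-1]['train_accuracy']:.3f}")
    return model, log


def evaluate(model, clouds, labels, traits=None) -> EvalReport:
    """Confusion matrix and accuracy/precision/recall/F1 on a labeled set."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValidationError("cannot evaluate an empty dataset")
    if isinstance(model, TraitBaseline):
        pred = model.predict(traits)
        n_classes = model.cfg.n_classes
        names = model.class_names
    else:
        pred = model.predict(clouds, traits)
        n_classes = model.cfg.n_classes
        names = model.class_names
    return EvalReport.from_predictions(labels, pred, n_classes, names)


# ---------------------------------------------------------------------------
# traits-only baseline

class TraitBaseline:
    """Small fully connected classifier on the 10 z-scored traits alone."""

    def __init__(self, cfg: NetConfig, class_names):
        self.cfg = cfg
        self.class_names = tuple(class_names)
        rng = np.random.default_rng(cfg.seed)
        self.mlp = MLP([N_TRAITS, 32, cfg.n_classes], rng, final_relu=False)
        self.trait_mean = np.zeros(N_TRAITS)
        self.trait_sd = np.ones(N_TRAITS)

    def predict_proba(self, traits) -> np.ndarray:
        z = (np.asarray(traits, float) - self.trait_mean) / self.trait_sd
        return softmax(self.mlp.forward(z))

    def predict(self, traits) -> np.ndarray:
        return np.argmax(self.predict_proba(traits), axis=1)


def trait_baseline(traits, labels, seed: int = 0, epochs: int = 200,
                   n_classes: int = 4,
                   class_names=("FULL", "HIGHLY_LEAN", "TIGHT", "ROUND_SPREAD")):
    """Train the traits-only control classifier; returns (model, log)."""
    traits = np.asarray(traits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValidationError("training needs at least 2 classes")
    cfg = NetConfig(n_classes=n_classes, use_traits=True, seed=seed,
                    epochs=epochs, dropout=0.0)
    model = TraitBaseline(cfg, class_names)
    model.trait_mean = traits.mean(axis=0)
    sd = traits.std(axis=0, ddof=1)
    model.trait_sd = np.where(sd > 0, sd, 1.0)
    z = (traits - model.trait_mean) / model.trait_sd
    opt = Adam(model.mlp.dense_layers, lr=1e-2)
    rng = np.random.default_rng(seed + 1)
    n = len(labels)
    log = []
    batch = min(32, n)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            logits = model.mlp.forward(z[idx], train=True)
            loss, dlogits = cross_entropy_grad(logits, labels[idx])
            model.mlp.zero_grad()
            model.mlp.backward(dlogits)
            opt.step()
            losses.append(loss)
        log.append({"epoch": epoch, "loss": float(np.mean(losses))})
    return model, log
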