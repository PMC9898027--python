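"""Pairwise learning-to-rank of tile fibrosis severity (RankNet objective).

A convolutional scorer maps a grayscale tile to a raw scalar s. Training
never sees absolute grades: supervision consists of pairwise comparisons
("which of these two regions is more fibrotic?"), and the modeled
probability that tile a outranks tile b is the logistic of the score
difference,

    P(a > b) = 1 / (1 + exp(-(s_a - s_b))),

optimized with binary cross-entropy. Because experts disagree, labels come
from several simulated annotators who each report the ground-truth ordering
with a configurable concordance; the majority vote is the training label.
Rounds alternate training with model-guided pair selection (uncertainty
sampling picks the pairs the current model finds hardest), a scaled-down
human-in-the-loop protocol.

After training, raw scores are min-max normalized against a declared
reference tile set and clipped to [0, 1]: the Continuous Index of Fibrosis
(CIF), with 1 the most fibrotic.

The backbone is a deliberately small 2-block CNN implemented directly on
numpy (im2col convolutions, manual backprop, Adam); the ranking objective,
not the backbone, carries the method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import CalibrationError, DataError, InvalidArgumentError


@dataclass(frozen=True)
class PairwiseComparison:
    tile_a_id: int
    tile_b_id: int
    label: int  # 1 if a is more severe, else 0
    annotator_id: int | None = None
    round_index: int = 0


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 8
    batch_size: int = 64
    learning_rate: float = 2e-3
    heldout_frac: float = 0.2
    seed: int = 0
    augment: bool = True  # random D4 flips/rotations; fiber texture is isotropic


@dataclass
class TrainingRound:
    round_index: int
    n_train_pairs: int
    n_heldout_pairs: int
    heldout_accuracy: float
    final_loss: float


# ---------------------------------------------------------------------------
# RankNet math
# ---------------------------------------------------------------------------

def pairwise_probability(s_a, s_b):
    """P(a ranks above b) = logistic(s_a - s_b); antisymmetric by design."""
    s_a = np.asarray(s_a, dtype=np.float64)
    s_b = np.asarray(s_b, dtype=np.float64)
    if not (np.all(np.isfinite(s_a)) and np.all(np.isfinite(s_b))):
        raise InvalidArgumentError("scores must be finite")
    d = s_a - s_b
    # numerically stable logistic
    out = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))),
                   np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))
    return out if out.ndim else float(out)


def pairwise_loss(s_a, s_b, labels):
    """Mean binary cross-entropy of pairwise probabilities.

    loss = mean(-[y ln P + (1-y) ln(1-P)]) with P = logistic(s_a - s_b),
    evaluated in the numerically stable softplus form.
    """
    s_a = np.atleast_1d(np.asarray(s_a, dtype=np.float64))
    s_b = np.atleast_1d(np.asarray(s_b, dtype=np.float64))
    y = np.atleast_1d(np.asarray(labels, dtype=np.float64))
    if s_a.size == 0:
        raise InvalidArgumentError("empty batch")
    if not (np.all(np.isfinite(s_a)) and np.all(np.isfinite(s_b))):
        raise InvalidArgumentError("scores must be finite")
    d = s_a - s_b
    softplus = np.logaddexp(0.0, d)  # ln(1 + e^d)
    # y*softplus(-d) + (1-y)*softplus(d), using softplus(-d) = softplus(d) - d
    losses = y * (softplus - d) + (1.0 - y) * softplus
    return float(losses.mean())


# ---------------------------------------------------------------------------
# Tile preprocessing
# ---------------------------------------------------------------------------

def preprocess_tiles(
    tile_pixels: np.ndarray, input_size: int = 32, dark_threshold: float = 130.0
) -> np.ndarray:
    """Downscale uint8 tiles to two input_size channels on [-0.5, 0.5].

    Channel 0 is the block-mean intensity; channel 1 is the per-block
    fraction of pixels darker than dark_threshold (midway between fiber and
    background gray), which preserves the fiber-mass signal that plain
    averaging conflates with bright fat or dark vessel regions.
    tile_pixels: [n, S, S] (or a single [S, S] tile). S is cropped to the
    largest multiple of input_size before block reduction.
    """
    x = np.asarray(tile_pixels, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    n, s, s2 = x.shape
    if min(s, s2) < input_size:
        raise InvalidArgumentError(
            f"tile size {s}x{s2} smaller than network input {input_size}"
        )
    f = min(s, s2) // input_size
    crop = f * input_size
    blocks = x[:, :crop, :crop].reshape(n, input_size, f, input_size, f)
    mean_ch = blocks.mean(axis=(2, 4)) / 255.0 - 0.5
    dark_ch = (blocks < dark_threshold).mean(axis=(2, 4)) - 0.5
    out = np.stack([mean_ch, dark_ch], axis=-1)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Numpy CNN backbone
# ---------------------------------------------------------------------------

def _conv_forward(x, w, b):
    """Valid 3x3 convolution. x: [N,H,W,Cin], w: [Cin*9, Cout] -> [N,H-2,W-2,Cout]."""
    patches = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(1, 2))
    # patches: [N, H-2, W-2, Cin, 3, 3] -> flatten window dims
    n, ho, wo = patches.shape[:3]
    cols = patches.reshape(n, ho, wo, -1)
    out = cols @ w + b
    return out, cols


def _conv_backward(dout, cols, w, x_shape):
    """Gradients of valid 3x3 conv. Returns (dx, dw, db)."""
    n, ho, wo, cout = dout.shape
    cols2 = cols.reshape(-1, cols.shape[-1])
    dout2 = dout.reshape(-1, cout)
    dw = cols2.T @ dout2
    db = dout2.sum(axis=0)
    dcols = dout2 @ w.T  # [N*ho*wo, Cin*9]
    cin = x_shape[-1]
    dcols = dcols.reshape(n, ho, wo, cin, 3, 3)
    dx = np.zeros(x_shape)
    for di in range(3):
        for dj in range(3):
            dx[:, di : di + ho, dj : dj + wo, :] += dcols[:, :, :, :, di, dj]
    return dx, dw, db


def _pool_forward(a: np.ndarray) -> np.ndarray:
    """2x2 average pool (odd remainder cropped)."""
    n, h, w, c = a.shape
    h2, w2 = h // 2, w // 2
    return a[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c).mean(axis=(2, 4))


def _pool_backward(dpooled: np.ndarray, in_shape) -> np.ndarray:
    n, h, w, c = in_shape
    h2, w2 = dpooled.shape[1], dpooled.shape[2]
    da = np.zeros(in_shape)
    da[:, : 2 * h2, : 2 * w2, :] = (
        np.repeat(np.repeat(dpooled, 2, axis=1), 2, axis=2) / 4.0
    )
    return da


class ConvScorer:
    """Small CNN: [conv3x3 -> ReLU -> avgpool2]* -> conv3x3 -> ReLU -> GAP -> linear.

    One block per entry of ``channels``; pooling follows every block except
    the last. Weights and Adam state live in plain numpy arrays.
    """

    def __init__(
        self,
        input_size: int = 32,
        channels: tuple[int, ...] = (8, 16),
        seed: int = 0,
        in_channels: int = 2,
    ):
        self.input_size = input_size
        self.channels = tuple(channels)
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        he = lambda fan_in, shape: rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        self.params: dict[str, np.ndarray] = {}
        cin = in_channels
        for i, cout in enumerate(self.channels):
            self.params[f"w{i}"] = he(9 * cin, (9 * cin, cout))
            self.params[f"b{i}"] = np.zeros(cout)
            cin = cout
        self.params["w_out"] = he(cin, (cin,)) * 0.1
        self.params["b_out"] = np.zeros(1)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def copy(self) -> "ConvScorer":
        clone = ConvScorer(self.input_size, self.channels, seed=0, in_channels=self.in_channels)
        clone.params = {k: v.copy() for k, v in self.params.items()}
        clone._adam_m = {k: v.copy() for k, v in self._adam_m.items()}
        clone._adam_v = {k: v.copy() for k, v in self._adam_v.items()}
        clone._adam_t = self._adam_t
        return clone

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: [N, H, W, C] (or [N, H, W] single-channel) tiles -> raw scores [N]."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        a = x[..., None] if x.ndim == 3 else x  # [N,H,W,C]
        if a.shape[-1] != self.in_channels:
            raise InvalidArgumentError(
                f"expected {self.in_channels} input channels, got {a.shape[-1]}"
            )
        p = self.params
        blocks = []
        n_blocks = len(self.channels)
        for i in range(n_blocks):
            x_in = a
            z, cols = _conv_forward(x_in, p[f"w{i}"], p[f"b{i}"])
            a = np.maximum(z, 0.0)
            pre_pool_shape = a.shape
            if i < n_blocks - 1:
                a = _pool_forward(a)
            blocks.append((x_in.shape, cols, z, pre_pool_shape))
        gap = a.mean(axis=(1, 2))  # [N, c_last]
        scores = gap @ p["w_out"] + p["b_out"][0]
        if not want_cache:
            return scores
        return scores, (blocks, a, gap)

    def backward(self, cache, dscores: np.ndarray) -> dict[str, np.ndarray]:
        blocks, a_last, gap = cache
        p = self.params
        grads: dict[str, np.ndarray] = {}
        grads["w_out"] = gap.T @ dscores
        grads["b_out"] = np.array([dscores.sum()])
        dgap = dscores[:, None] * p["w_out"][None, :]
        h, w = a_last.shape[1], a_last.shape[2]
        da = np.broadcast_to(dgap[:, None, None, :] / (h * w), a_last.shape)
        n_blocks = len(self.channels)
        for i in range(n_blocks - 1, -1, -1):
            x_in_shape, cols, z, pre_pool_shape = blocks[i]
            if i < n_blocks - 1:
                da = _pool_backward(da, pre_pool_shape)
            dz = da * (z > 0)
            da, grads[f"w{i}"], grads[f"b{i}"] = _conv_backward(
                dz, cols, p[f"w{i}"], x_in_shape
            )
        return grads

    def adam_step(self, grads: dict[str, np.ndarray], lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def score(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        out = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(out) if out else np.empty(0)


@dataclass
class RankingModel:
    """Convolutional scorer plus frozen normalization anchors.

    CIF score = clip((s - norm_low) / (norm_high - norm_low), 0, 1).
    """

    scorer: ConvScorer
    input_size: int = 32
    norm_low: float | None = None
    norm_high: float | None = None
    training_meta: list = field(default_factory=list)

    @property
    def calibrated(self) -> bool:
        return self.norm_low is not None and self.norm_high is not None


def make_model(
    input_size: int = 32,
    channels: tuple[int, ...] = (8, 16),
    seed: int = 0,
    in_channels: int = 2,
) -> RankingModel:
    return RankingModel(
        scorer=ConvScorer(input_size, channels, seed, in_channels=in_channels),
        input_size=input_size,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _random_d4(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply an independent random D4 symmetry (rotation/flip) per image."""
    g = rng.integers(0, 8, size=len(x))
    out = np.empty_like(x)
    for k in range(4):
        sel = g == k
        if sel.any():
            out[sel] = np.rot90(x[sel], k, axes=(1, 2))
        sel = g == k + 4
        if sel.any():
            out[sel] = np.rot90(x[sel][:, :, ::-1], k, axes=(1, 2))
    return out


def pairwise_accuracy(s_a: np.ndarray, s_b: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of pairs ordered correctly; exact score ties count 0.5."""
    s_a, s_b = np.asarray(s_a), np.asarray(s_b)
    y = np.asarray(labels)
    pred = np.where(s_a > s_b, 1.0, 0.0)
    ties = s_a == s_b
    correct = np.where(ties, 0.5, (pred == y).astype(float))
    return float(correct.mean())


def train_round(
    model: RankingModel,
    pairs: list[PairwiseComparison],
    tile_images: np.ndarray,
    config: TrainConfig,
    round_index: int = 0,
    eval_pairs: list[PairwiseComparison] | None = None,
) -> tuple[RankingModel, TrainingRound]:
    """One round of RankNet training with a held-out pair evaluation.

    tile_images are preprocessed tiles indexed by the pair tile ids. The
    model is copied, trained for config.epochs, and returned with the round's
    held-out pairwise accuracy. Zero epochs leave the weights untouched.
    By default a fraction config.heldout_frac of ``pairs`` is withheld for
    evaluation; passing ``eval_pairs`` (disjoint from the training pairs)
    instead trains on all of ``pairs`` and evaluates on ``eval_pairs``.
    """
    if len(pairs) == 0:
        raise InvalidArgumentError("empty pair list")
    ids = {p.tile_a_id for p in pairs} | {p.tile_b_id for p in pairs}
    if len(ids) < 2:
        raise DataError("degenerate pair set: fewer than 2 distinct tiles")
    rng = np.random.default_rng(config.seed)
    if eval_pairs is None:
        order = rng.permutation(len(pairs))
        n_held = int(round(config.heldout_frac * len(pairs)))
        held_idx, train_idx = order[:n_held], order[n_held:]
        held_pairs = [pairs[i] for i in held_idx]
    else:
        train_idx = np.arange(len(pairs))
        held_pairs = eval_pairs
    pa = np.array([p.tile_a_id for p in pairs])
    pb = np.array([p.tile_b_id for p in pairs])
    py = np.array([p.label for p in pairs], dtype=np.float64)

    scorer = model.scorer.copy()
    final_loss = float("nan")
    for _ in range(config.epochs):
        perm = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(perm), config.batch_size):
            bi = perm[start : start + config.batch_size]
            if len(bi) == 0:
                continue
            xa = tile_images[pa[bi]]
            xb = tile_images[pb[bi]]
            y = py[bi]
            xab = np.concatenate([xa, xb], axis=0)
            if config.augment:
                xab = _random_d4(xab, rng)
            scores, cache = scorer.forward(xab, want_cache=True)
            s_a, s_b = scores[: len(bi)], scores[len(bi) :]
            epoch_losses.append(pairwise_loss(s_a, s_b, y) * len(bi))
            d = s_a - s_b
            g = (1.0 / (1.0 + np.exp(-d)) - y) / len(bi)
            dscores = np.concatenate([g, -g])
            grads = scorer.backward(cache, dscores)
            scorer.adam_step(grads, config.learning_rate)
        if epoch_losses:
            final_loss = float(np.sum(epoch_losses) / len(perm))

    if held_pairs:
        s_all = scorer.score(tile_images)
        ha = np.array([p.tile_a_id for p in held_pairs])
        hb = np.array([p.tile_b_id for p in held_pairs])
        hy = np.array([p.label for p in held_pairs], dtype=np.float64)
        acc = pairwise_accuracy(s_all[ha], s_all[hb], hy)
    else:
        acc = float("nan")
    new_model = replace(
        model,
        scorer=scorer,
        training_meta=model.training_meta
        + [{"round": round_index, "n_pairs": len(pairs), "heldout_accuracy": acc}],
    )
    report = TrainingRound(
        round_index=round_index,
        n_train_pairs=len(train_idx),
        n_heldout_pairs=len(held_pairs),
        heldout_accuracy=acc,
        final_loss=final_loss,
    )
    return new_model, report


def select_pairs(
    model: RankingModel | None,
    n_tiles: int,
    n_pairs: int,
    strategy: str = "uniform",
    seed: int = 0,
    tile_images: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Propose unlabeled tile pairs for the next annotation round.

    uniform: distinct pairs sampled without replacement. uncertainty: from a
    candidate pool, keep the pairs with the smallest current score gap
    |s_a - s_b| (the comparisons the model is least sure about).
    """
    if n_tiles < 2:
        raise InvalidArgumentError("need at least 2 candidate tiles")
    max_pairs = n_tiles * (n_tiles - 1) // 2
    if n_pairs > max_pairs:
        warnings.warn(
            f"requested {n_pairs} pairs but only {max_pairs} distinct pairs exist; truncating"
        )
        n_pairs = max_pairs
    rng = np.random.default_rng(seed)

    def sample_distinct(k: int) -> list[tuple[int, int]]:
        if max_pairs <= 200_000:
            all_pairs = [(i, j) for i in range(n_tiles) for j in range(i + 1, n_tiles)]
            idx = rng.choice(max_pairs, size=k, replace=False)
            return [all_pairs[i] for i in idx]
        seen: set[tuple[int, int]] = set()
        out: list[tuple[int, int]] = []
        while len(out) < k:
            i, j = rng.integers(n_tiles), rng.integers(n_tiles)
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            out.append(key)
        return out

    if strategy == "uniform":
        return sample_distinct(n_pairs)
    if strategy == "uncertainty":
        if model is None or tile_images is None:
            raise InvalidArgumentError("uncertainty strategy needs a model and tile images")
        pool = sample_distinct(min(max_pairs, max(4 * n_pairs, n_pairs)))
        s = model.scorer.score(tile_images)
        gaps = np.array([abs(s[i] - s[j]) for i, j in pool])
        order = np.argsort(gaps, kind="stable")
        return [pool[i] for i in order[:n_pairs]]
    raise InvalidArgumentError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Simulated annotators
# ---------------------------------------------------------------------------

@dataclass
class AnnotationReport:
    inter_annotator_agreement: float
    majority_vs_oracle_accuracy: float
    n_pairs: int
    n_annotators: int


def simulate_annotators(
    pairs: list[tuple[int, int]],
    oracle_labels: np.ndarray,
    concordance: float = 0.884,
    n_annotators: int = 3,
    seed: int = 0,
    round_index: int = 0,
) -> tuple[list[PairwiseComparison], AnnotationReport]:
    """Noisy expert labels: each annotator reports the oracle ordering with
    probability = concordance, independently; majority vote becomes the
    training label.

    The default concordance of 0.884 matches the observed agreement level of
    expert pairwise ranking of fibrosis severity. concordance <= 0.5 is
    rejected (labels would carry no signal).
    """
    if not 0.5 < concordance <= 1.0:
        raise InvalidArgumentError("concordance must lie in (0.5, 1]")
    if n_annotators < 1:
        raise InvalidArgumentError("need at least one annotator")
    oracle_labels = np.asarray(oracle_labels, dtype=int)
    if len(oracle_labels) != len(pairs):
        raise InvalidArgumentError("oracle_labels length must match pairs")
    rng = np.random.default_rng(seed)
    votes = np.empty((len(pairs), n_annotators), dtype=int)
    for a in range(n_annotators):
        agree = rng.random(len(pairs)) < concordance
        votes[:, a] = np.where(agree, oracle_labels, 1 - oracle_labels)
    majority = (votes.sum(axis=1) * 2 > n_annotators).astype(int)

    agreements = []
    for a in range(n_annotators):
        for b in range(a + 1, n_annotators):
            agreements.append(float((votes[:, a] == votes[:, b]).mean()))
    report = AnnotationReport(
        inter_annotator_agreement=float(np.mean(agreements)) if agreements else 1.0,
        majority_vs_oracle_accuracy=float((majority == oracle_labels).mean()),
        n_pairs=len(pairs),
        n_annotators=n_annotators,
    )
    comparisons = [
        PairwiseComparison(int(i), int(j), int(majority[k]), round_index=round_index)
        for k, (i, j) in enumerate(pairs)
    ]
    return comparisons, report


# ---------------------------------------------------------------------------
# Calibration and scoring
# ---------------------------------------------------------------------------

def save_model(model: RankingModel, path) -> None:
    """Checkpoint: npz of weights plus a JSON sidecar with norm anchors."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, **model.scorer.params)
    sidecar = {
        "input_size": model.input_size,
        "channels": list(model.scorer.channels),
        "in_channels": model.scorer.in_channels,
        "norm_low": model.norm_low,
        "norm_high": model.norm_high,
        "training_meta": model.training_meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path) -> RankingModel:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    scorer = ConvScorer(
        meta["input_size"], tuple(meta["channels"]), seed=0,
        in_channels=meta.get("in_channels", 2),
    )
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        scorer.params = {k: z[k].copy() for k in z.files}
    return RankingModel(
        scorer=scorer,
        input_size=meta["input_size"],
        norm_low=meta["norm_low"],
        norm_high=meta["norm_high"],
        training_meta=meta["training_meta"],
    )


def calibrate(model: RankingModel, reference_images: np.ndarray) -> RankingModel:
    """Fit min-max normalization anchors on a declared reference tile set."""
    raw = model.scorer.score(reference_images)
    low, high = float(raw.min()), float(raw.max())
    if low == high:
        raise CalibrationError("all reference raw scores equal; cannot normalize")
    return replace(model, norm_low=low, norm_high=high)


def score_tiles(model: RankingModel, tile_images: np.ndarray) -> np.ndarray:
    """CIF scores in [0, 1]: clipped min-max of raw scores (order-preserving)."""
    if not model.calibrated:
        raise CalibrationError("model has no normalization anchors; call calibrate()")
    raw = model.scorer.score(tile_images)
    return np.clip((raw - model.norm_low) / (model.norm_high - model.norm_low), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Human-in-the-loop protocol
# ---------------------------------------------------------------------------

def train_ranker(
    tile_images: np.ndarray,
    tile_severity: np.ndarray,
    rounds: int = 3,
    pairs_per_round: int = 700,
    config: TrainConfig | None = None,
    concordance: float = 0.884,
    n_annotators: int = 3,
    seed: int = 0,
    n_eval_pairs: int = 300,
) -> tuple[RankingModel, list[TrainingRound], list[AnnotationReport]]:
    """Scaled-down human-in-the-loop ranking protocol.

    Round 1 trains on uniformly sampled pairs; later rounds add
    uncertainty-selected pairs (the comparisons the current model is least
    sure about) labeled by the simulated annotator panel, and training
    always runs on the accumulated pair set. Ranking accuracy is evaluated
    after every round on a fixed held-out set of uniformly sampled,
    annotator-labeled pairs that never enters training — uncertainty-picked
    pairs are concentrated near decision boundaries and would not measure
    accuracy on the natural comparison distribution. Returns the calibrated
    model plus per-round reports.
    """
    if rounds < 1:
        raise InvalidArgumentError("rounds must be >= 1")
    tile_images = np.asarray(tile_images, dtype=np.float64)
    tile_severity = np.asarray(tile_severity, dtype=np.float64)
    if len(tile_images) != len(tile_severity):
        raise InvalidArgumentError("tile_images and tile_severity must align")
    cfg = config if config is not None else TrainConfig()
    in_ch = tile_images.shape[-1] if tile_images.ndim == 4 else 1
    model = make_model(
        input_size=tile_images.shape[1], seed=seed, in_channels=in_ch
    )

    def oracle_labels(pairs):
        return np.array(
            [1 if tile_severity[i] >= tile_severity[j] else 0 for i, j in pairs]
        )

    eval_proposed = select_pairs(
        None, len(tile_images), n_eval_pairs, "uniform", seed=seed + 99
    )
    eval_set = {(min(i, j), max(i, j)) for i, j in eval_proposed}
    eval_pairs, _ = simulate_annotators(
        eval_proposed, oracle_labels(eval_proposed), concordance=concordance,
        n_annotators=n_annotators, seed=seed + 98, round_index=-1,
    )

    all_pairs: list[PairwiseComparison] = []
    round_reports: list[TrainingRound] = []
    annotation_reports: list[AnnotationReport] = []
    for r in range(rounds):
        strategy = "uniform" if r == 0 else "uncertainty"
        proposed = select_pairs(
            model,
            n_tiles=len(tile_images),
            n_pairs=pairs_per_round,
            strategy=strategy,
            seed=seed + 1000 * (r + 1),
            tile_images=tile_images,
        )
        proposed = [
            (i, j) for i, j in proposed if (min(i, j), max(i, j)) not in eval_set
        ]
        labeled, ann_report = simulate_annotators(
            proposed,
            oracle_labels(proposed),
            concordance=concordance,
            n_annotators=n_annotators,
            seed=seed + 2000 * (r + 1),
            round_index=r,
        )
        annotation_reports.append(ann_report)
        all_pairs.extend(labeled)
        model, report = train_round(
            model,
            all_pairs,
            tile_images,
            replace(cfg, seed=seed + 3000 * (r + 1)),
            round_index=r,
            eval_pairs=eval_pairs,
        )
        round_reports.append(report)
    model = calibrate(model, tile_images)
    return model, round_reports, annotation_reports
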