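"""Noise2Inverse: self-supervised denoising of tomographic reconstructions.

The projection angles are split into K interleaved, disjoint subsets and
each subset is reconstructed on its own.  Because FBP with the
``pi/n_used`` weighting is linear and angle-additive, each sub-tomogram is
an unbiased estimate of the full reconstruction whose noise is independent
of the other subsets' noise.  Training a network to map the mean of all
but one sub-tomograms to the held-out one (the X:1 strategy) therefore
minimises, in expectation, the loss against the unknown noise-free image
plus a constant equal to the noise variance — no clean data needed.

Inference averages the network output over all K held-out configurations.
A separate model is trained per signal type, since attenuation and
electron-density reconstructions have very different noise power spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

from .network import Adam, ConvNet, NetConfig
from .recon import Tomogram, reconstruct_attenuation, reconstruct_electron_density
from .retrieval import SinogramPair

__all__ = [
    "SplitSet",
    "TrainingRun",
    "split_sinogram",
    "make_split_set",
    "make_training_pairs",
    "train",
    "train_and_select",
    "denoise",
    "select_epoch",
]


def split_sinogram(sino: SinogramPair, K: int) -> list[np.ndarray]:
    """Interleaved angle split: angle i goes to subset ``i mod K``.

    Interleaving keeps each subset's angular coverage near-uniform, so every
    sub-reconstruction sees the object from all directions.
    """
    n = sino.n_angles
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n // 2:
        raise ValueError(f"K={K} too large for {n} angles (need K <= n/2)")
    return [np.arange(n)[j::K] for j in range(K)]


@dataclass
class SplitSet:
    """K sub-tomograms from disjoint interleaved angle subsets."""

    K: int
    subsets: list[Tomogram]
    source: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.subsets) != self.K:
            raise ValueError("subset count does not match K")
        all_idx = np.concatenate(
            [np.asarray(t.provenance["angle_indices"]) for t in self.subsets]
        )
        if np.unique(all_idx).size != all_idx.size:
            raise ValueError("angle subsets are not pairwise disjoint")

    @property
    def signal_type(self) -> str:
        return self.subsets[0].signal_type


def make_split_set(
    sino: SinogramPair,
    K: int,
    signal_type: str,
    phase_sensitivity: float = 1.0,
) -> SplitSet:
    """Split the sinogram and reconstruct every subset with the filter
    matching ``signal_type``."""
    indices = split_sinogram(sino, K)
    if signal_type == "attenuation":
        subs = [reconstruct_attenuation(sino, idx) for idx in indices]
    elif signal_type == "electron_density":
        subs = [
            reconstruct_electron_density(sino, idx, phase_sensitivity=phase_sensitivity)
            for idx in indices
        ]
    else:
        raise ValueError(f"unknown signal_type {signal_type!r}")
    return SplitSet(K=K, subsets=subs, source={"n_angles": int(sino.n_angles)})


def make_training_pairs(
    splits: SplitSet, strategy: str = "X:1"
) -> list[tuple[np.ndarray, np.ndarray]]:
    """K (input, target) image pairs.

    ``X:1`` (default): input = mean of all subsets except j, target = subset
    j.  ``1:X``: the reverse (implemented behind the same interface; off by
    default).
    """
    if splits.K < 2:
        raise ValueError("need at least two splits")
    data = [t.data for t in splits.subsets]
    pairs = []
    for j in range(splits.K):
        others = np.mean([data[i] for i in range(splits.K) if i != j], axis=0)
        if strategy == "X:1":
            pairs.append((others, data[j]))
        elif strategy == "1:X":
            pairs.append((data[j], others))
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    return pairs


@dataclass
class TrainingRun:
    """A trained Noise2Inverse model plus its full training trace."""

    model: ConvNet
    strategy: str
    epochs_trained: int
    loss_history: list[float]
    seed: int
    K: int
    signal_type: str
    norm_mean: float
    norm_std: float
    checkpoints: list[list[np.ndarray]] = field(default_factory=list)
    checkpoint_epochs: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.loss_history) != self.epochs_trained:
            raise ValueError("loss_history length must equal epochs_trained")


def _dihedral(patch: np.ndarray, op: int) -> np.ndarray:
    """One of the 8 square symmetries (seeded data augmentation)."""
    if op & 1:
        patch = patch[::-1]
    if op & 2:
        patch = patch[:, ::-1]
    if op & 4:
        patch = patch.T
    return np.ascontiguousarray(patch)


def _normalizer(pairs) -> tuple[float, float]:
    """Per-volume affine normalisation (zero mean, unit variance) computed
    from the training inputs and shared by inputs and targets."""
    stacked = np.stack([p[0] for p in pairs])
    mean = float(stacked.mean())
    std = float(stacked.std())
    return mean, max(std, 1e-12)


def train(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    net_config: NetConfig | None = None,
    epochs: int = 250,
    seed: int = 0,
    lr: float = 5e-3,
    patch_size: int = 32,
    patches_per_pair: int = 6,
    augment: bool = True,
    grad_clip: float | None = 1.0,
    strategy: str = "X:1",
    K: int | None = None,
    signal_type: str = "attenuation",
    keep_checkpoints: bool = True,
    checkpoint_every: int = 1,
) -> TrainingRun:
    """Train the denoising network on (input, target) image pairs.

    Minimises the mean squared error over randomly cropped patches, with
    the eight square symmetries as optional data augmentation (``augment``;
    helps on the short slice stacks this pipeline trains on).  The crop
    sequence, augmentation, shuffling and initialisation are all driven by
    ``seed``, so a run is reproducible.  The per-epoch mean loss and
    (optionally) a parameter checkpoint per epoch are recorded for later
    epoch selection.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if net_config is None:
        net_config = NetConfig()

    mean, std = _normalizer(pairs)
    # promote 2D images to single-slice stacks [slice, h, w]
    norm_pairs = []
    for x, t in pairs:
        xs, ts = (x - mean) / std, (t - mean) / std
        if xs.ndim == 2:
            xs, ts = xs[None], ts[None]
        norm_pairs.append((xs, ts))
    n_slices, h, w = norm_pairs[0][0].shape
    ps = min(patch_size, h, w)

    rng = np.random.default_rng(seed)
    net = ConvNet(net_config, seed=int(rng.integers(2**31)))
    opt = Adam(lr=lr)
    half = epochs // 2  # constant lr, then linear decay to lr/10

    loss_history: list[float] = []
    checkpoints: list[list[np.ndarray]] = []
    checkpoint_epochs: list[int] = []
    order = np.arange(len(norm_pairs))
    for epoch in range(epochs):
        if epoch >= half and epochs > half:
            frac = (epoch - half) / max(epochs - half, 1)
            opt.lr = lr * (1.0 - 0.9 * frac)
        rng.shuffle(order)
        epoch_loss = 0.0
        for j in order:
            x_img, t_img = norm_pairs[j]
            slices = rng.integers(0, n_slices, size=patches_per_pair)
            rows = rng.integers(0, h - ps + 1, size=patches_per_pair)
            cols = rng.integers(0, w - ps + 1, size=patches_per_pair)
            ops = rng.integers(0, 8, size=patches_per_pair) if augment else \
                np.zeros(patches_per_pair, dtype=int)
            x = np.stack(
                [_dihedral(x_img[s, r : r + ps, c : c + ps], o)
                 for s, r, c, o in zip(slices, rows, cols, ops)]
            )[:, None]
            t = np.stack(
                [_dihedral(t_img[s, r : r + ps, c : c + ps], o)
                 for s, r, c, o in zip(slices, rows, cols, ops)]
            )[:, None]
            y, cache = net.forward(x, want_cache=True)
            resid = y - t
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training loss became non-finite; lower the learning rate"
                )
            grads = net.backward(2.0 * resid / resid.size, cache)
            if grad_clip is not None:
                norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
                if norm > grad_clip:
                    grads = [g * (grad_clip / norm) for g in grads]
            opt.step(net.parameters(), grads)
            epoch_loss += loss
        loss_history.append(epoch_loss / len(norm_pairs))
        if keep_checkpoints and (
            (epoch + 1) % checkpoint_every == 0 or epoch == epochs - 1
        ):
            checkpoints.append(net.copy_parameters())
            checkpoint_epochs.append(epoch)

    return TrainingRun(
        model=net,
        strategy=strategy,
        epochs_trained=epochs,
        loss_history=loss_history,
        seed=seed,
        K=K if K is not None else len(pairs),
        signal_type=signal_type,
        norm_mean=mean,
        norm_std=std,
        checkpoints=checkpoints,
        checkpoint_epochs=checkpoint_epochs,
    )


def _apply_model(run: TrainingRun, image: np.ndarray) -> np.ndarray:
    x = (image - run.norm_mean) / run.norm_std
    if x.ndim == 2:
        y = run.model(x[None, None])[0, 0]
    else:  # slice stack: slices form the batch
        y = run.model(x[:, None])[:, 0]
    return y * run.norm_std + run.norm_mean


def denoise(run: TrainingRun, splits: SplitSet) -> Tomogram:
    """Split-averaged inference: mean over the K held-out configurations of
    the network applied to each X:1 input."""
    if splits.K != run.K:
        raise ValueError(f"run was trained with K={run.K}, splits have K={splits.K}")
    pairs = make_training_pairs(splits, strategy=run.strategy)
    out = np.mean([_apply_model(run, x) for x, _ in pairs], axis=0)
    return Tomogram(
        data=out,
        signal_type=splits.signal_type,
        provenance={
            "method": "noise2inverse",
            "K": splits.K,
            "strategy": run.strategy,
            "epochs": run.epochs_trained,
        },
    )


def select_epoch(
    run: TrainingRun,
    splits: SplitSet,
    reference: Tomogram | np.ndarray,
    metric: str = "psnr",
) -> int:
    """Pick the checkpoint maximising an IQA metric against a reference.

    The reference is a high-quality tomogram (a high-dose scan in the lab,
    the synthetic ground truth here); maximising image quality over epochs
    stops training before the network overfits the noise.  Ties resolve to
    the earliest epoch.  Returns an index into ``run.checkpoints``; the
    corresponding epoch number is ``run.checkpoint_epochs[index]``.
    """
    from . import iqa  # local import: iqa has no dependency on this module

    metrics: dict[str, Callable] = {"psnr": iqa.psnr, "ssim": iqa.ssim}
    if metric not in metrics:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(metrics)}")
    if not run.checkpoints:
        raise ValueError("run kept no checkpoints")
    ref = reference.data if isinstance(reference, Tomogram) else np.asarray(reference)

    saved = run.model.copy_parameters()
    scores = []
    try:
        for params in run.checkpoints:
            run.model.set_parameters(params)
            out = denoise(run, splits).data
            scores.append(metrics[metric](out, ref))
    finally:
        run.model.set_parameters(saved)
    scores = np.asarray(scores)
    return int(np.argmax(scores))  # argmax returns the first (earliest) maximum


def train_and_select(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    splits: SplitSet,
    reference: Tomogram | np.ndarray,
    restarts: int = 3,
    metric: str = "psnr",
    seed: int = 0,
    checkpoint_every: int = 10,
    selection_slices: int = 2,
    **train_kwargs,
) -> TrainingRun:
    """Train with restarts and reference-guided model selection.

    The emulated protocol selects its model by maximising an IQA metric
    against a reference image (a high-dose scan in the lab, the synthetic
    ground truth here): that guards against both noise overfitting over
    epochs and the occasional initialisation that converges to a poor
    optimum.  ``restarts`` sub-seeded runs are trained with periodic
    checkpoints; the (restart, epoch) pair maximising the metric wins, and
    the returned run carries the winning parameters.

    On slice stacks the metric is evaluated on the first
    ``selection_slices`` slices only (model quality varies with the
    checkpoint, not the slice), which keeps selection cheap.
    """
    from . import iqa

    metrics: dict[str, Callable] = {"psnr": iqa.psnr, "ssim": iqa.ssim}
    if metric not in metrics:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(metrics)}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    ref = reference.data if isinstance(reference, Tomogram) else np.asarray(reference)

    strategy = train_kwargs.get("strategy", "X:1")
    inputs = [x for x, _ in make_training_pairs(splits, strategy=strategy)]
    if ref.ndim == 3 and selection_slices:
        sel = slice(0, min(selection_slices, ref.shape[0]))
        inputs = [x[sel] for x in inputs]
        ref_sel = ref[sel]
    else:
        ref_sel = ref

    sub_seeds = np.random.SeedSequence(seed).generate_state(restarts) % (2**31)
    best_run, best_score, best_idx = None, -np.inf, 0
    for s in sub_seeds:
        run = train(
            pairs, seed=int(s), keep_checkpoints=True,
            checkpoint_every=checkpoint_every, **train_kwargs,
        )
        for ci, params in enumerate(run.checkpoints):
            run.model.set_parameters(params)
            out = np.mean([_apply_model(run, x) for x in inputs], axis=0)
            score = metrics[metric](out, ref_sel)
            if score > best_score:
                best_run, best_score, best_idx = run, score, ci
    best_run.model.set_parameters(best_run.checkpoints[best_idx])
    best_run.epochs_trained = best_run.checkpoint_epochs[best_idx] + 1
    best_run.loss_history = best_run.loss_history[: best_run.epochs_trained]
    return best_run
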