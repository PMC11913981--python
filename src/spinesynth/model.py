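"""The 3D paired-translation GAN: losses, patch sampling, training, inference.

Two generators are trained in sequence: network 1 maps (T2w FSE, axial Dixon
fat/water) to T1w FSE; network 2 maps (T2w FSE, T1w FSE) to STIR.  At
deployment the two are chained — network 2 consumes the *synthetic* T1w from
network 1, never a native one.  The generator objective combines an L1
reconstruction term, a structural-similarity term and a least-squares
adversarial term from a patch discriminator:

    L_total = 10 * L1(x_hat, x) + 10 * (1 - SSIM(x_hat, x)) + mean((D(x_hat) - 1)^2)
    L_D     = 0.5 * mean(D(x_hat)^2) + 0.5 * mean((D(x) - 1)^2)

Three positional-embedding channels (a 0->1 gradient per axis, defined on the
volume borders before cropping) are appended to the input stack so the fully
convolutional network knows where a training patch sits in the body.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .nn import Adam, Discriminator, Generator, Tensor, crop as t_crop, uniform_filter
from .volume import ImageVolume, color_jitter, crop_to_record, pad_to_multiple

__all__ = [
    "GeneratorConfig",
    "LossWeights",
    "TrainConfig",
    "TrainingPatch",
    "TASKS",
    "position_embeddings",
    "build_generator",
    "build_discriminator",
    "ssim3d",
    "ssim_loss",
    "generator_loss",
    "discriminator_loss",
    "sample_patch",
    "train",
    "validate_l1",
    "save_checkpoint",
    "load_checkpoint",
    "infer",
    "two_stage_infer",
]

#: task -> (input modalities, target modality)
TASKS = {
    "t1w": (("t2w", "dixon_fat", "dixon_water"), "t1w"),
    "stir": (("t2w", "t1w"), "stir"),
}

#: full-scale training patch per task
TASK_PATCH_SIZE = {"t1w": (16, 192, 192), "stir": (16, 256, 256)}


@dataclass
class GeneratorConfig:
    in_channels: int
    base_channels: int = 32
    levels: int = 4
    groupnorm_groups: int = 8
    out_channels: int = 1


@dataclass
class LossWeights:
    """L1 and SSIM are weighted 10:1 against the adversarial term."""

    l1: float = 10.0
    ssim: float = 10.0
    adv: float = 1.0


@dataclass
class TrainConfig:
    learning_rate: float = 2e-5
    batch_size: int = 3
    patch_size: tuple = (16, 192, 192)
    epochs: int = 30
    replication_factor: int = 3
    resolution_range: tuple | None = (0.5, 1.0)
    jitter: bool = True
    input_modalities: tuple | None = None  # None -> the task's default inputs
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s % 8 for s in self.patch_size):
            raise ValueError(f"patch_size {self.patch_size} must be divisible by 8")


@dataclass
class TrainingPatch:
    inputs: np.ndarray  # (C, D, H, W): modalities then 3 embedding channels
    target: np.ndarray  # (1, D, H, W)
    subject: str = ""
    offset: tuple = (0, 0, 0)


# ---------------------------------------------------------------------------
# positional embeddings
# ---------------------------------------------------------------------------

def position_embeddings(original_shape, crop_offset, crop_size, clip: bool = True) -> np.ndarray:
    """Three gradient channels locating a crop within the original volume.

    Channel ``a`` varies linearly along axis ``a``: voxel ``i`` holds
    ``(crop_offset[a] + i) / (original_shape[a] - 1)``, so a full-volume crop
    runs exactly 0 -> 1.  An axis of length 1 yields an all-zero channel.
    ``clip`` clamps to [0, 1] for crops extending past the original borders
    (padded full-volume inference).
    """
    original_shape = np.asarray(original_shape, dtype=int)
    crop_offset = np.asarray(crop_offset, dtype=float)
    crop_size = np.asarray(crop_size, dtype=int)
    channels = np.zeros((3, *crop_size), dtype=np.float32)
    for a in range(3):
        if original_shape[a] <= 1:
            continue
        ramp = (crop_offset[a] + np.arange(crop_size[a])) / (original_shape[a] - 1)
        if clip:
            ramp = np.clip(ramp, 0.0, 1.0)
        shape = [1, 1, 1]
        shape[a] = crop_size[a]
        channels[a] = np.broadcast_to(ramp.reshape(shape).astype(np.float32), tuple(crop_size))
    return channels


def build_generator(cfg: GeneratorConfig, rng=None) -> Generator:
    return Generator(
        cfg.in_channels,
        base_channels=cfg.base_channels,
        levels=cfg.levels,
        groups=cfg.groupnorm_groups,
        out_channels=cfg.out_channels,
        rng=rng,
    )


def build_discriminator(cfg: GeneratorConfig, rng=None) -> Discriminator:
    # critic sees the input stack plus the candidate target volume
    return Discriminator(
        cfg.in_channels + cfg.out_channels,
        base_channels=cfg.base_channels,
        groups=cfg.groupnorm_groups,
        rng=rng,
    )


# ---------------------------------------------------------------------------
# SSIM: numpy metric and differentiable loss term
# ---------------------------------------------------------------------------

def ssim3d(a: np.ndarray, b: np.ndarray, window: int = 7, data_range: float = 1.0) -> float:
    """Mean local SSIM over cubic windows (uniform weights, sample covariance).

    Constants follow the standard definition: ``C1 = (0.01 L)^2``,
    ``C2 = (0.03 L)^2`` with ``L = data_range``.  Border voxels whose window
    leaves the volume are excluded from the mean.  A volume smaller than the
    window falls back to a single global window.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("ssim3d expects identically shaped volumes")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    if min(a.shape) < window:
        mu_a, mu_b = a.mean(), b.mean()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        cov = ((a - mu_a) * (b - mu_b)).sum() / (a.size - 1)
        return float(
            ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
            / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
        )
    n = window ** a.ndim
    cov_norm = n / (n - 1)
    filt = lambda x: ndimage.uniform_filter(x, size=window, mode="reflect")
    ua, ub = filt(a), filt(b)
    uaa, ubb, uab = filt(a * a), filt(b * b), filt(a * b)
    va = cov_norm * (uaa - ua * ua)
    vb = cov_norm * (ubb - ub * ub)
    cov = cov_norm * (uab - ua * ub)
    s = ((2 * ua * ub + c1) * (2 * cov + c2)) / ((ua**2 + ub**2 + c1) * (va + vb + c2))
    pad = (window - 1) // 2
    core = s[tuple(slice(pad, dim - pad) for dim in s.shape)]
    return float(core.mean())


def ssim_loss(a: Tensor, b: Tensor, window: int = 7) -> Tensor:
    """Differentiable mean SSIM of two NCDHW tensors scaled in [-1, 1].

    Works on a [0, 1] rescale with ``data_range`` 1 and the same windowed
    statistics as :func:`ssim3d` (interior windows only), so its value matches
    the metric on matching inputs.
    """
    a01 = (a + 1.0) * 0.5
    b01 = (b + 1.0) * 0.5
    c1 = 0.01**2
    c2 = 0.03**2
    spatial = a.data.shape[2:]
    if min(spatial) < window:
        # single global window (population statistics are adequate here)
        mu_a, mu_b = a01.mean(), b01.mean()
        va = (a01 * a01).mean() - mu_a * mu_a
        vb = (b01 * b01).mean() - mu_b * mu_b
        cov = (a01 * b01).mean() - mu_a * mu_b
        return ((mu_a * mu_b * 2.0 + c1) * (cov * 2.0 + c2)) / (
            (mu_a.square() + mu_b.square() + c1) * (va + vb + c2)
        )
    n = window ** len(spatial)
    cov_norm = n / (n - 1)
    ua, ub = uniform_filter(a01, window), uniform_filter(b01, window)
    va = (uniform_filter(a01 * a01, window) - ua * ua) * cov_norm
    vb = (uniform_filter(b01 * b01, window) - ub * ub) * cov_norm
    cov = (uniform_filter(a01 * b01, window) - ua * ub) * cov_norm
    s = ((ua * ub * 2.0 + c1) * (cov * 2.0 + c2)) / (
        (ua.square() + ub.square() + c1) * (va + vb + c2)
    )
    pad = (window - 1) // 2
    slices = (slice(None), slice(None)) + tuple(slice(pad, d - pad) for d in spatial)
    return t_crop(s, slices).mean()


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def generator_loss(
    x_hat: Tensor | np.ndarray,
    x: Tensor | np.ndarray,
    d_scores: Tensor | np.ndarray,
    weights: LossWeights = LossWeights(),
    ssim_window: int = 7,
) -> Tensor:
    """``w_l1 * L1 + w_ssim * (1 - SSIM) + w_adv * mean((D - 1)^2)``."""
    x_hat = x_hat if isinstance(x_hat, Tensor) else Tensor(x_hat)
    x = x if isinstance(x, Tensor) else Tensor(x)
    d_scores = d_scores if isinstance(d_scores, Tensor) else Tensor(d_scores)
    if x_hat.data.shape != x.data.shape:
        raise ValueError("prediction and target shapes differ")
    l1 = (x_hat - x).abs().mean()
    ssim = ssim_loss(x_hat, x, window=ssim_window)
    adv = (d_scores - 1.0).square().mean()
    return weights.l1 * l1 + weights.ssim * (1.0 - ssim) + weights.adv * adv


def discriminator_loss(d_fake: Tensor | np.ndarray, d_real: Tensor | np.ndarray) -> Tensor:
    """Least-squares GAN critic loss with real/fake targets 1/0."""
    d_fake = d_fake if isinstance(d_fake, Tensor) else Tensor(d_fake)
    d_real = d_real if isinstance(d_real, Tensor) else Tensor(d_real)
    return 0.5 * d_fake.square().mean() + 0.5 * (d_real - 1.0).square().mean()


# ---------------------------------------------------------------------------
# patch sampling
# ---------------------------------------------------------------------------

def _study_shape(study: dict) -> tuple:
    shapes = {m: v.shape for m, v in study.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"study modalities are not on a common grid: {shapes}")
    return next(iter(shapes.values()))


def _pad_study(study: dict, patch_size) -> dict:
    """Pad every modality with -1 so each axis is at least the patch size."""
    shape = np.asarray(_study_shape(study))
    need = np.maximum(0, np.asarray(patch_size) - shape)
    if not need.any():
        return study
    before = need // 2
    after = need - before
    pad = list(zip(before.tolist(), after.tolist()))
    return {
        m: ImageVolume(np.pad(v.data, pad, constant_values=-1.0), v.affine)
        for m, v in study.items()
    }


def sample_patch(
    study: dict,
    task: str,
    cfg: TrainConfig,
    rng: np.random.Generator,
    subject: str = "",
) -> TrainingPatch:
    """Random fixed-size crop with jittered inputs and appended embeddings.

    Inputs are photometrically jittered per channel (brightness/contrast in
    [0.8, 1.2]); the regression target is never jittered.  The embedding
    channels are computed in the frame of the full (pre-crop) volume.
    """
    in_mods = cfg.input_modalities or TASKS[task][0]
    target_mod = TASKS[task][1]
    study = _pad_study(study, cfg.patch_size)
    shape = np.asarray(_study_shape(study))
    patch = np.asarray(cfg.patch_size)
    offset = np.array([rng.integers(0, shape[a] - patch[a] + 1) for a in range(3)])
    sl = tuple(slice(offset[a], offset[a] + patch[a]) for a in range(3))

    chans = []
    for mod in in_mods:
        if mod not in study:
            raise ValueError(f"study is missing input modality {mod!r}")
        vol = study[mod]
        if cfg.jitter:
            vol = color_jitter(vol, rng.uniform(0.8, 1.2), rng.uniform(0.8, 1.2))
        chans.append(vol.data[sl])
    emb = position_embeddings(shape, offset, patch)
    inputs = np.concatenate(
        [np.asarray(chans, dtype=np.float32), emb], axis=0
    )
    target = np.asarray(study[target_mod].data[sl], dtype=np.float32)[None]
    return TrainingPatch(inputs, target, subject, tuple(int(o) for o in offset))


def _resample_inplane(study: dict, resolution: float) -> dict:
    """Resample the sagittal in-plane axes (1, 2) to ``resolution`` mm."""
    from .volume import resample

    out = {}
    for m, v in study.items():
        sp = v.spacing
        out[m] = resample(v, (sp[0], resolution, resolution), order=1)
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    generator: Generator
    discriminator: Discriminator
    history: dict
    task: str
    train_config: TrainConfig
    generator_config: GeneratorConfig
    loss_weights: LossWeights


def validate_l1(generator, studies, task: str, cfg: TrainConfig) -> float:
    """Mean per-subject L1 between generated and target center patches."""
    in_mods = cfg.input_modalities or TASKS[task][0]
    errs = []
    for name, study in studies.items():
        study_p = _pad_study(study, cfg.patch_size)
        shape = np.asarray(_study_shape(study_p))
        patch = np.asarray(cfg.patch_size)
        offset = (shape - patch) // 2
        sl = tuple(slice(offset[a], offset[a] + patch[a]) for a in range(3))
        chans = [study_p[m].data[sl] for m in in_mods]
        emb = position_embeddings(shape, offset, patch)
        x = np.concatenate([np.asarray(chans, dtype=np.float32), emb], axis=0)[None]
        y = np.asarray(study_p[TASKS[task][1]].data[sl], dtype=np.float32)
        pred = generator(Tensor(x)).data[0, 0]
        errs.append(float(np.mean(np.abs(pred - y))))
    return float(np.mean(errs))


def train(
    train_studies: dict,
    task: str,
    cfg: TrainConfig,
    gen_cfg: GeneratorConfig | None = None,
    weights: LossWeights = LossWeights(),
    val_studies: dict | None = None,
) -> TrainResult:
    """Alternating LSGAN training of generator and patch discriminator.

    ``train_studies`` maps subject id -> {modality: ImageVolume} on a common
    grid with intensities in [-1, 1].  Data replication draws
    ``replication_factor`` entries per subject, each optionally resampled to a
    random sagittal in-plane resolution from ``resolution_range``.  The run is
    bit-reproducible given ``cfg.seed``.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; choose from {sorted(TASKS)}")
    if not train_studies:
        raise ValueError("need at least one training subject")
    rng = np.random.default_rng(cfg.seed)
    in_mods = cfg.input_modalities or TASKS[task][0]
    if gen_cfg is None:
        gen_cfg = GeneratorConfig(in_channels=len(in_mods) + 3)
    if gen_cfg.in_channels != len(in_mods) + 3:
        raise ValueError(
            f"generator expects {gen_cfg.in_channels} channels but task supplies "
            f"{len(in_mods)} modalities + 3 embeddings"
        )
    G = build_generator(gen_cfg, rng=np.random.default_rng(rng.integers(2**31)))
    D = build_discriminator(gen_cfg, rng=np.random.default_rng(rng.integers(2**31)))
    opt_g = Adam(G.parameters(), lr=cfg.learning_rate)
    opt_d = Adam(D.parameters(), lr=cfg.learning_rate)

    # replication with per-entry in-plane resolution
    entries = []
    for name in sorted(train_studies):
        for _ in range(max(1, cfg.replication_factor)):
            res = (
                float(rng.uniform(*cfg.resolution_range))
                if cfg.resolution_range is not None
                else None
            )
            entries.append((name, res))
    cache: dict = {}

    def get_study(name, res):
        key = (name, None if res is None else round(res, 3))
        if key not in cache:
            s = train_studies[name]
            cache[key] = s if res is None else _resample_inplane(s, res)
        return cache[key]

    history: dict = {"l1": [], "ssim": [], "adv": [], "total": [], "d_loss": [], "val_l1": []}
    if val_studies:
        history["val_l1_initial"] = validate_l1(G, val_studies, task, cfg)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(entries))
        comp_sums = np.zeros(5)
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            batch_ids = order[start : start + cfg.batch_size]
            patches = []
            for idx in batch_ids:
                name, res = entries[idx]
                patches.append(sample_patch(get_study(name, res), task, cfg, rng, name))
            x = Tensor(np.stack([p.inputs for p in patches]))
            y = Tensor(np.stack([p.target for p in patches]))

            # generator step
            x_hat = G(x)
            d_for_g = D(x, x_hat)
            l1 = (x_hat - y).abs().mean()
            ssim = ssim_loss(x_hat, y)
            adv = (d_for_g - 1.0).square().mean()
            g_loss = weights.l1 * l1 + weights.ssim * (1.0 - ssim) + weights.adv * adv
            if not np.isfinite(g_loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite generator loss at epoch {epoch}"
                )
            opt_g.zero_grad()
            opt_d.zero_grad()
            g_loss.backward()
            opt_g.step()

            # discriminator step on the detached prediction
            d_fake = D(Tensor(x.data), Tensor(x_hat.data))
            d_real = D(Tensor(x.data), Tensor(y.data))
            d_loss = discriminator_loss(d_fake, d_real)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            comp_sums += [
                float(l1.data),
                float(ssim.data),
                float(adv.data),
                float(g_loss.data),
                float(d_loss.data),
            ]
            n_batches += 1
        means = comp_sums / n_batches
        for key, val in zip(("l1", "ssim", "adv", "total", "d_loss"), means):
            history[key].append(float(val))
        if val_studies:
            history["val_l1"].append(validate_l1(G, val_studies, task, cfg))

    return TrainResult(G, D, history, task, cfg, gen_cfg, weights)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(result: TrainResult, path: str | Path) -> None:
    """Serialize generator weights + all configs + seed into one .npz archive."""
    meta = {
        "task": result.task,
        "train_config": asdict(result.train_config),
        "generator_config": asdict(result.generator_config),
        "loss_weights": asdict(result.loss_weights),
    }
    arrays = {f"G.{k}": v for k, v in result.generator.state().items()}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


@dataclass
class Checkpoint:
    generator: Generator
    task: str
    train_config: TrainConfig
    generator_config: GeneratorConfig
    loss_weights: LossWeights


def load_checkpoint(path: str | Path) -> Checkpoint:
    with np.load(str(path)) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k[2:]: npz[k] for k in npz.files if k.startswith("G.")}
    tcfg_d = meta["train_config"]
    tcfg_d["patch_size"] = tuple(tcfg_d["patch_size"])
    if tcfg_d.get("resolution_range") is not None:
        tcfg_d["resolution_range"] = tuple(tcfg_d["resolution_range"])
    if tcfg_d.get("input_modalities") is not None:
        tcfg_d["input_modalities"] = tuple(tcfg_d["input_modalities"])
    tcfg = TrainConfig(**tcfg_d)
    gcfg = GeneratorConfig(**meta["generator_config"])
    G = build_generator(gcfg)
    G.load_state(state)
    return Checkpoint(G, meta["task"], tcfg, gcfg, LossWeights(**meta["loss_weights"]))


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def infer(ckpt: Checkpoint | TrainResult, study: dict, task: str | None = None) -> ImageVolume:
    """Full-volume inference: pad to divisible-by-8, forward, crop back.

    The positional embeddings are computed in the frame of the unpadded
    volume (clipped in the pad margin) so patch-trained weights see the
    coordinates they were trained with.  Output lands on the T2w grid with
    values in [-1, 1].
    """
    task = task or ckpt.task
    cfg = ckpt.train_config
    in_mods = cfg.input_modalities or TASKS[task][0]
    missing = [m for m in in_mods if m not in study]
    if missing:
        raise ValueError(f"study is missing required input modalities: {missing}")
    G = ckpt.generator
    multiple = max(8, G.required_divisor)
    ref = study[in_mods[0]]
    padded, rec = pad_to_multiple(ref, multiple)
    chans = [padded.data]
    for mod in in_mods[1:]:
        p, _ = pad_to_multiple(study[mod], multiple)
        chans.append(p.data)
    emb = position_embeddings(
        rec.original_shape, -rec.pad_before, padded.shape, clip=True
    )
    x = np.concatenate([np.asarray(chans, dtype=np.float32), emb], axis=0)[None]
    out = G(Tensor(x)).data[0, 0]
    out_vol = crop_to_record(ImageVolume(out, padded.affine), rec)
    return ImageVolume(out_vol.data, ref.affine.copy())


def two_stage_infer(ckpt_t1w, ckpt_stir, study: dict):
    """Chained inference: synthesize T1w, then STIR from the synthetic T1w.

    Stage 2 never sees a native T1w — only the stage-1 output plus the T2w.
    Returns ``(t1w_synth, stir_synth)`` on the T2w grid.
    """
    t1w_synth = infer(ckpt_t1w, study, task="t1w")
    stage2_study = {"t2w": study["t2w"], "t1w": t1w_synth}
    stir_synth = infer(ckpt_stir, stage2_study, task="stir")
    return t1w_synth, stir_synth
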