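"""Network building blocks and optimizer for the 3D translation GAN.

The generator is a fully convolutional 3D encoder–decoder of residual blocks
(conv -> group norm of 8 -> SiLU), downsampling by 2 per level via strided
convolution and upsampling by nearest-neighbour + convolution, with
*addition* skip connections.  The discriminator is a strided 3D patch critic
producing a grid of realism scores.  Optimization uses Adam.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv3d, group_norm, upsample2

__all__ = ["Module", "Conv3d", "GroupNorm3d", "ResBlock", "Generator", "Discriminator", "Adam"]


class Module:
    """Parameter container with ordered named parameters."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                params[name] = value
            elif isinstance(value, Module):
                for sub, p in value.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state/parameter name mismatch: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(np.float32).copy()

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1, padding: int = 1, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel**3
        scale = np.sqrt(2.0 / fan_in)  # He initialization for SiLU-family nets
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(cout, cin, kernel, kernel, kernel)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class GroupNorm3d(Module):
    def __init__(self, channels: int, groups: int = 8):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.groups = min(groups, channels)
        if channels % self.groups:
            raise ValueError(f"groups {groups} must divide channels {channels}")

    def __call__(self, x: Tensor) -> Tensor:
        return group_norm(x, self.gamma, self.beta, self.groups)


class ResBlock(Module):
    """Pre-activation residual block: x + conv(silu(gn(x)))."""

    def __init__(self, channels: int, groups: int = 8, rng=None):
        self.gn1 = GroupNorm3d(channels, groups)
        self.conv1 = Conv3d(channels, channels, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.conv1(self.gn1(x).silu())


class Generator(Module):
    """3D encoder–decoder with addition skips; tanh output in [-1, 1]."""

    def __init__(self, in_channels: int, base_channels: int = 32, levels: int = 4,
                 groups: int = 8, out_channels: int = 1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.levels = levels
        widths = [base_channels * 2**l for l in range(levels)]
        self.widths = widths
        self.stem = Conv3d(in_channels, widths[0], rng=rng)
        self.enc_blocks = [ResBlock(w, groups, rng=rng) for w in widths]
        self.down = [
            Conv3d(widths[l], widths[l + 1], stride=2, rng=rng) for l in range(levels - 1)
        ]
        self.mid = ResBlock(widths[-1], groups, rng=rng)
        self.up = [
            Conv3d(widths[l + 1], widths[l], rng=rng) for l in reversed(range(levels - 1))
        ]
        self.dec_blocks = [ResBlock(widths[l], groups, rng=rng) for l in reversed(range(levels - 1))]
        self.head_norm = GroupNorm3d(widths[0], groups)
        self.head = Conv3d(widths[0], out_channels, rng=rng)

    @property
    def required_divisor(self) -> int:
        return 2 ** (self.levels - 1)

    def __call__(self, x: Tensor) -> Tensor:
        div = self.required_divisor
        spatial = x.data.shape[2:]
        if any(s % div for s in spatial):
            need = tuple(-(-s // div) * div for s in spatial)
            raise ValueError(
                f"spatial shape {spatial} not divisible by {div}; pad to {need} first"
            )
        h = self.stem(x)
        skips = []
        for l in range(self.levels - 1):
            h = self.enc_blocks[l](h)
            skips.append(h)
            h = self.down[l](h)
        h = self.enc_blocks[-1](h)
        h = self.mid(h)
        for i in range(self.levels - 1):
            h = upsample2(h)
            h = self.up[i](h)
            h = h + skips[-(i + 1)]  # addition, not concatenation
            h = self.dec_blocks[i](h)
        return self.head(self.head_norm(h).silu()).tanh()


class Discriminator(Module):
    """Strided 3D patch critic: (input stack, candidate target) -> score grid."""

    def __init__(self, in_channels: int, base_channels: int = 32, layers: int = 3,
                 groups: int = 8, rng=None):
        rng = rng or np.random.default_rng(0)
        chans = [base_channels * 2**l for l in range(layers)]
        self.convs = []
        self.norms = []
        cin = in_channels
        for i, c in enumerate(chans):
            self.convs.append(Conv3d(cin, c, stride=2, rng=rng))
            self.norms.append(GroupNorm3d(c, groups) if i > 0 else None)
            cin = c
        self.norms = [n for n in self.norms if n is not None]
        self.final = Conv3d(cin, 1, rng=rng)

    def __call__(self, inputs: Tensor, candidate: Tensor) -> Tensor:
        h = concat([inputs, candidate], axis=1)
        for i, conv in enumerate(self.convs):
            h = conv(h)
            if i > 0:
                h = self.norms[i - 1](h)
            h = h.silu()
        return self.final(h)


class Adam:
    """Adam with Pix2Pix-style betas (0.5, 0.999)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 2e-5,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
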