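"""U-Net-style encoder--decoder assembled from a genome.

Encoder level ``i`` (shallowest first) applies two 3x3 conv+ReLU layers at
``filters[i]`` channels followed by dropout; 2x2 max pooling sits between
levels, so the deepest level is the bottleneck.  The decoder mirrors the
encoder with learned 2x2 transposed-convolution upsampling; when the
genome's skip flag is set, each decoder level concatenates the matching
encoder feature map before its convolutions.  A 1x1 convolution produces
single-channel logits; the sigmoid lives in the loss / prediction path.
"""

from __future__ import annotations

import numpy as np

from ..genome import Genome
from .layers import Conv1x1, Conv3x3, Dropout, Layer, MaxPool2, ReLU, UpConv2x2

__all__ = ["UNet", "check_divisibility"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # Overflow-free logistic for float32 logits.
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def check_divisibility(height: int, width: int, depth: int) -> None:
    """Input sides must be divisible by 2**(depth-1) to pool and re-expand."""
    need = 2 ** (depth - 1)
    if height % need or width % need:
        raise ValueError(
            f"input {height}x{width} not divisible by {need} "
            f"(required for depth {depth})"
        )


class _ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU -> dropout."""

    def __init__(self, c_in: int, c_out: int, rate: float,
                 rng: np.random.Generator) -> None:
        self.conv1 = Conv3x3(c_in, c_out, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv3x3(c_out, c_out, rng)
        self.relu2 = ReLU()
        self.drop = Dropout(rate, rng)
        self.layers: list[Layer] = [self.conv1, self.relu1, self.conv2,
                                    self.relu2, self.drop]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UNet:
    """A realizable network for one genome.

    Parameters
    ----------
    genome : Genome
        Architecture description; ``len(genome.filters)`` encoder levels.
    seed : int
        Seeds weight initialization and dropout sampling.
    """

    def __init__(self, genome: Genome, seed: int = 0) -> None:
        if len(genome.filters) != genome.depth:
            raise ValueError("genome filters length must equal its depth")
        self.genome = genome
        rng = np.random.default_rng(seed)
        f = genome.filters
        d = genome.depth
        rate = genome.dropout_rate
        self.enc_blocks = []
        c_prev = 1
        for i in range(d):
            self.enc_blocks.append(_ConvBlock(c_prev, f[i], rate, rng))
            c_prev = f[i]
        self.pools = [MaxPool2() for _ in range(d - 1)]
        self.ups = []
        self.dec_blocks = []
        for i in range(d - 2, -1, -1):
            self.ups.append(UpConv2x2(f[i + 1], f[i], rng))
            c_in = 2 * f[i] if genome.use_skip else f[i]
            self.dec_blocks.append(_ConvBlock(c_in, f[i], rate, rng))
        self.head = Conv1x1(f[0], 1, rng)
        self._skip_channels = [f[i] for i in range(d - 2, -1, -1)]

    # -- graph traversal ---------------------------------------------------

    def _all_layers(self) -> list[Layer]:
        layers: list[Layer] = []
        for block in self.enc_blocks:
            layers.extend(block.layers)
        layers.extend(self.pools)
        for up, block in zip(self.ups, self.dec_blocks):
            layers.append(up)
            layers.extend(block.layers)
        layers.append(self.head)
        return layers

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self._all_layers())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Images (B, H, W) in [0, 1] -> logits (B, H, W)."""
        check_divisibility(x.shape[1], x.shape[2], self.genome.depth)
        h = np.ascontiguousarray(x, dtype=np.float32)[..., None]
        skips = []
        d = self.genome.depth
        for i in range(d):
            h = self.enc_blocks[i].forward(h, train)
            if i < d - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        self._used_skip = self.genome.use_skip
        for j, (up, block) in enumerate(zip(self.ups, self.dec_blocks)):
            h = up.forward(h, train)
            if self.genome.use_skip:
                h = np.concatenate([h, skips[-(j + 1)]], axis=-1)
            h = block.forward(h, train)
        logits = self.head.forward(h, train)
        return logits[..., 0]

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        dy = self.head.backward(dlogits[..., None])
        d = self.genome.depth
        # Decoder index j consumes the skip from encoder level d-2-j.
        dskip_by_level: dict[int, np.ndarray] = {}
        for j in range(len(self.dec_blocks) - 1, -1, -1):
            dy = self.dec_blocks[j].backward(dy)
            if self._used_skip:
                c = self._skip_channels[j]
                dskip_by_level[d - 2 - j] = dy[..., c:]
                dy = dy[..., :c]
            dy = self.ups[j].backward(dy)
        for i in range(d - 1, -1, -1):
            if i < d - 1:
                dy = self.pools[i].backward(dy)
                if self._used_skip:
                    dy = dy + dskip_by_level[i]
            dy = self.enc_blocks[i].backward(dy)

    def init_head_bias(self, prior: float) -> None:
        """Set the output bias to the logit of a foreground prior.

        Starting calibrated to the class balance skips the early epochs a
        sigmoid head otherwise spends learning the base rate, which
        matters for the short trainings used as fitness evaluations.
        """
        prior = float(np.clip(prior, 1e-4, 1 - 1e-4))
        self.head.params["b"][...] = np.log(prior / (1.0 - prior))

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Per-pixel probabilities via the sigmoid head, batched."""
        out = np.empty(x.shape, dtype=np.float32)
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start : start + batch_size], train=False)
            out[start : start + batch_size] = _sigmoid(logits)
        return out

    # -- checkpointing -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for li, layer in enumerate(self._all_layers()):
            for k, v in layer.params.items():
                state[f"{li}:{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self._all_layers()):
            for k in layer.params:
                layer.params[k][...] = state[f"{li}:{k}"]
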