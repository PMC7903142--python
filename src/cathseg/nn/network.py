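"""The light U-Net graph: wiring, forward/backward, layer registry.

The network is an encoder-decoder with a single convolution block
(conv -> batch-norm -> ReLU) per step instead of the classic two, which
is what makes it "light".  Downsampling is a stride-2 convolution block,
upsampling a bare stride-2 transposed convolution, and each decoder
level concatenates the matching encoder feature map (skip connection)
before its convolution block.  The head is a 3x3 convolution with a
per-channel sigmoid emitting two complementary full-scale probability
maps (channel 0: catheter, channel 1: background).

The ordered layer registry counts every convolution, every batch
normalization and every activation as one layer; concatenations are
wiring, not layers.  With the default 6-entry channel progression the
registry holds 55 layers.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2d, ConvTranspose2d, Layer, ReLU, Sigmoid

__all__ = ["LightUNet"]


class LightUNet:
    """Encoder-decoder segmentation network over NHWC float32 tensors.

    Parameters
    ----------
    channels_per_level:
        Feature-map counts, one per spatial resolution from full
        resolution down to the bottleneck; ``len - 1`` stride-2
        downsamplings are applied.
    in_channels:
        Input image channels (1 for grayscale fluoroscopy).
    n_output_maps:
        Output probability maps (2: catheter and background).
    rng:
        ``numpy.random.Generator`` used for weight initialisation.
    """

    def __init__(self, channels_per_level, in_channels=1, n_output_maps=2, kernel_size=3, rng=None):
        rng = rng or np.random.default_rng(0)
        self.channels_per_level = tuple(int(c) for c in channels_per_level)
        self.in_channels = int(in_channels)
        self.n_output_maps = int(n_output_maps)
        self.kernel_size = int(kernel_size)
        if len(self.channels_per_level) < 2:
            raise ValueError("channels_per_level needs at least two levels")
        ch = self.channels_per_level
        k = self.kernel_size
        self.depth = len(ch) - 1  # number of downsamplings
        self.layers: list[Layer] = []

        def block(tag, c_in, c_out, stride):
            self.layers.append(Conv2d(f"{tag}_conv", c_in, c_out, k=k, stride=stride, rng=rng))
            self.layers.append(BatchNorm2d(f"{tag}_bn", c_out))
            self.layers.append(ReLU(f"{tag}_relu"))

        prev = self.in_channels
        for i in range(self.depth):
            block(f"enc{i}", prev, ch[i], stride=1)
            block(f"down{i}", ch[i], ch[i + 1], stride=2)
            prev = ch[i + 1]
        block("bottleneck", ch[-1], ch[-1], stride=1)
        for i in range(self.depth - 1, -1, -1):
            self.layers.append(ConvTranspose2d(f"up{i}_tconv", ch[i + 1], ch[i], k=k, rng=rng))
            block(f"dec{i}", 2 * ch[i], ch[i], stride=1)
        self.layers.append(
            Conv2d("head_conv", ch[0], self.n_output_maps, k=k, stride=1, rng=rng)
        )
        self.layers.append(Sigmoid("head_sigmoid"))
        self._by_name = {l.name: l for l in self.layers}
        self._skip_channels: list[int] = []

    # ------------------------------------------------------------------ wiring
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the network; returns (N, H, W, n_output_maps) probabilities."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        h, w = x.shape[1], x.shape[2]
        div = 2**self.depth
        if h % div or w % div:
            raise ValueError(f"input size {h}x{w} must be divisible by {div}")
        skips = []
        out = x
        for i in range(self.depth):
            out = self._run_block(f"enc{i}", out, training)
            skips.append(out)
            out = self._run_block(f"down{i}", out, training)
        out = self._run_block("bottleneck", out, training)
        for i in range(self.depth - 1, -1, -1):
            out = self._by_name[f"up{i}_tconv"].forward(out, training)
            out = np.concatenate([skips[i], out], axis=-1)
            out = self._run_block(f"dec{i}", out, training)
        out = self._by_name["head_conv"].forward(out, training)
        out = self._by_name["head_sigmoid"].forward(out, training)
        if training:
            self._skip_channels = [s.shape[-1] for s in skips]
        return out

    def _run_block(self, tag, x, training):
        x = self._by_name[f"{tag}_conv"].forward(x, training)
        x = self._by_name[f"{tag}_bn"].forward(x, training)
        return self._by_name[f"{tag}_relu"].forward(x, training)

    def backward(self, dout: np.ndarray) -> None:
        """Backpropagate loss gradient w.r.t. the output probabilities."""
        d = self._by_name["head_sigmoid"].backward(dout)
        d = self._by_name["head_conv"].backward(d)
        dskips = [None] * self.depth
        for i in range(self.depth):
            d = self._back_block(f"dec{i}", d)
            c = self._skip_channels[i]
            dskips[i], d = d[..., :c], d[..., c:]
            d = self._by_name[f"up{i}_tconv"].backward(np.ascontiguousarray(d))
        d = self._back_block("bottleneck", d)
        for i in range(self.depth - 1, -1, -1):
            d = self._back_block(f"down{i}", d)
            d = d + dskips[i]
            # the first conv's input gradient is never consumed
            d = self._back_block(f"enc{i}", d, need_dx=(i > 0))

    def _back_block(self, tag, d, need_dx=True):
        d = self._by_name[f"{tag}_relu"].backward(d)
        d = self._by_name[f"{tag}_bn"].backward(d)
        return self._by_name[f"{tag}_conv"].backward(d, need_dx=need_dx)

    # --------------------------------------------------------------- inventory
    def __getitem__(self, name: str) -> Layer:
        return self._by_name[name]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def parameter_layers(self):
        """Layers that actually hold parameters (convs and batch-norms)."""
        return [l for l in self.layers if l.params]

    def count_parameters(self, trainable_only: bool = False) -> int:
        return sum(
            l.n_params()
            for l in self.parameter_layers()
            if (l.trainable or not trainable_only)
        )

    def set_trainable(self, layer_indices) -> None:
        """Freeze everything except the given registry indices."""
        idx = set(int(i) for i in layer_indices)
        for i, layer in enumerate(self.layers):
            layer.trainable = i in idx

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for layer in self.layers:
            for key, val in layer.params.items():
                state[f"{layer.name}.{key}"] = val.copy()
            if isinstance(layer, BatchNorm2d):
                state[f"{layer.name}.running_mean"] = layer.running_mean.copy()
                state[f"{layer.name}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for layer in self.layers:
            for key in layer.params:
                layer.params[key] = np.asarray(state[f"{layer.name}.{key}"], dtype=np.float32)
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = np.asarray(
                    state[f"{layer.name}.running_mean"], dtype=np.float32
                )
                layer.running_var = np.asarray(
                    state[f"{layer.name}.running_var"], dtype=np.float32
                )
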