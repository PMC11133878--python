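"""Spatial and temporal implicit neural representations.

The spatial INR maps a (normalized) voxel coordinate to the attenuation of
the reference frame through a multiresolution hash encoding followed by a
small MLP with periodic (sine) activations.  The temporal INR maps a frame
index to the time-varying weights of the motion basis components, one small
MLP per basis component and Cartesian direction.

Coordinates and frame indices are rescaled to [-1, 1] before encoding.  At
each encoder level the enclosing grid cell is located, corner features are
fetched through a spatial hash (XOR of coordinate-prime products modulo the
table size; levels below the collision threshold are indexed directly) and
multilinearly interpolated; level features are concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, linear_sine
from .geometry import VolumeGrid
from . import kernels

__all__ = [
    "HashEncoderConfig",
    "HashEncoder",
    "SineMLP",
    "SpatialINR",
    "TemporalINR",
    "init_params",
]


@dataclass
class HashEncoderConfig:
    n_levels: int = 8
    table_size_log2: int = 23
    features_per_level: int = 2
    base_resolution: int = 16
    finest_resolution: int = 256

    def growth_factor(self) -> float:
        if self.n_levels == 1:
            return 1.0
        return float(
            np.exp(np.log(self.finest_resolution / self.base_resolution) / (self.n_levels - 1))
        )


class HashEncoder:
    """Multiresolution hash encoding for d-dimensional inputs in [-1, 1]^d."""

    def __init__(self, config: HashEncoderConfig, dim: int, rng: np.random.Generator,
                 dtype=np.float64):
        if dim not in (1, 2, 3):
            raise ValueError("dim must be 1, 2 or 3")
        self.config = config
        self.dim = dim
        b = config.growth_factor()
        res = np.unique(
            np.round(config.base_resolution * b ** np.arange(config.n_levels)).astype(np.int64)
        )
        # np.unique sorts; pad in the rare case rounding collapsed levels
        while len(res) < config.n_levels:
            res = np.append(res, res[-1] + 1)
        self.level_res = res.astype(np.int64)
        table_cap = 2 ** config.table_size_log2
        sizes = []
        hashed = []
        for r in self.level_res:
            n_nodes = (int(r) + 1) ** dim
            if n_nodes <= table_cap:
                sizes.append(n_nodes)
                hashed.append(0)
            else:
                sizes.append(table_cap)
                hashed.append(1)
        self.level_off = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
        self.level_hashed = np.array(hashed, dtype=np.uint8)
        total = int(self.level_off[-1])
        self.tables = Tensor(
            rng.uniform(-1e-4, 1e-4, size=(total, config.features_per_level)).astype(dtype),
            requires_grad=True,
        )

    @property
    def n_features(self) -> int:
        return self.config.n_levels * self.config.features_per_level

    def encode(self, coords: Tensor) -> Tensor:
        """coords (n, dim) in [-1, 1] -> features (n, n_levels * features)."""
        nf = self.config.features_per_level
        aux = (self.level_res, self.level_off, self.level_hashed, nf)
        tables, cs = self.tables, coords
        out = kernels.hash_encode_fwd(cs.data, tables.data, *aux)
        need_cg = cs.requires_grad

        def vjp(g):
            gt = np.zeros_like(tables.data)
            gc = np.zeros_like(cs.data)
            kernels.hash_encode_bwd(
                np.ascontiguousarray(g), cs.data, tables.data, *aux, gt, gc, need_cg
            )
            return (gt, gc if need_cg else None)

        return Tensor._from_op(out, (tables, cs), vjp)

    def encode_numpy(self, coords: np.ndarray) -> np.ndarray:
        nf = self.config.features_per_level
        return kernels.hash_encode_fwd(
            np.ascontiguousarray(coords), self.tables.data,
            self.level_res, self.level_off, self.level_hashed, nf,
        )


class SineMLP:
    """Fully connected network with sine activations (SIREN-style).

    ``widths`` lists layer sizes input->output.  Every layer but the last
    applies ``sin(omega0 * z)``; the output layer is linear.
    ``siren_init=True`` uses the SIREN initialization (first layer
    U(-1/fan_in, 1/fan_in), later layers U(-sqrt(6/fan_in)/omega0, ...) and
    a zero output bias); otherwise every layer uses the uniform fan-in rule
    U(-sqrt(k), sqrt(k)) with k = 1/fan_in (biases always use the latter).
    """

    def __init__(self, widths, rng: np.random.Generator, omega0: float = 30.0,
                 siren_init: bool = True, dtype=np.float64):
        self.widths = list(widths)
        self.omega0 = float(omega0)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        n_layers = len(self.widths) - 1
        for i in range(n_layers):
            fan_in, fan_out = self.widths[i], self.widths[i + 1]
            k = np.sqrt(1.0 / fan_in)
            if siren_init and i == 0:
                bound = 1.0 / fan_in
            elif siren_init:
                # hidden AND output layers share the SIREN bound; the output
                # bias starts at zero so the field starts near zero mean
                # (attenuation is ~1e-2/mm; a default U(-sqrt(k), sqrt(k))
                # bias would dominate it and slow the image fit badly)
                bound = np.sqrt(6.0 / fan_in) / self.omega0
            else:
                bound = k
            W = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(dtype)
            b = rng.uniform(-k, k, size=(1, fan_out)).astype(dtype)
            if siren_init and i == n_layers - 1:
                b = np.zeros((1, fan_out), dtype=dtype)
            self.weights.append(Tensor(W, requires_grad=True))
            self.biases.append(Tensor(b, requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        n_layers = len(self.weights)
        h = x
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            omega = None if i == n_layers - 1 else self.omega0
            h = linear_sine(h, W, b, omega)
        return h

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        out = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            out[f"{prefix}.W{i}"] = W
            out[f"{prefix}.b{i}"] = b
        return out


class SpatialINR:
    """Coordinate -> attenuation field for the reference frame.

    World coordinates are mapped affinely from the reconstruction bounding
    box onto [-1, 1]^d; arbitrary (non-integer) positions are valid queries,
    which is what warped-coordinate evaluation relies on.
    """

    def __init__(self, fov_grid: VolumeGrid, rng: np.random.Generator,
                 encoder_config: HashEncoderConfig | None = None,
                 hidden: int = 32, omega0: float = 30.0, siren_init: bool = True,
                 dtype=np.float64):
        cfg = encoder_config or HashEncoderConfig(
            n_levels=8, table_size_log2=23, finest_resolution=max(fov_grid.shape)
        )
        self.encoder = HashEncoder(cfg, fov_grid.ndim, rng, dtype=dtype)
        self.mlp = SineMLP(
            [self.encoder.n_features, hidden, hidden, 1], rng,
            omega0=omega0, siren_init=siren_init, dtype=dtype,
        )
        lo, hi = fov_grid.bounds()
        self._center = ((lo + hi) / 2.0).astype(np.float64)
        self._half = ((hi - lo) / 2.0).astype(np.float64)
        self.dtype = dtype

    def normalize(self, world: np.ndarray) -> np.ndarray:
        return ((world - self._center) / self._half).astype(self.dtype)

    @property
    def inv_half(self) -> np.ndarray:
        return 1.0 / self._half

    def forward_norm(self, coords: Tensor) -> Tensor:
        """Normalized coords (n, d) -> attenuation (n, 1)."""
        return self.mlp(self.encoder.encode(coords))

    def eval_world(self, world: np.ndarray) -> np.ndarray:
        """Tape-free evaluation at world-mm coordinates (n, d) -> (n,)."""
        feats = self.encoder.encode_numpy(self.normalize(world))
        h = feats
        n_layers = len(self.mlp.weights)
        for i, (W, b) in enumerate(zip(self.mlp.weights, self.mlp.biases)):
            h = h @ W.data + b.data
            if i < n_layers - 1:
                h = np.sin(self.mlp.omega0 * h)
        return h[:, 0]

    def render(self, grid: VolumeGrid) -> np.ndarray:
        return self.eval_world(grid.voxel_centers()).reshape(grid.shape)

    def parameters(self) -> dict[str, Tensor]:
        out = {"spatial.tables": self.encoder.tables}
        out.update(self.mlp.parameters("spatial"))
        return out


class TemporalINR:
    """Frame index -> motion-basis weights w_{i,k}(t).

    One MLP per (basis level i, Cartesian direction k); output ordering is
    (i=1..L) x (k = x[,y],z), i.e. index m = i * n_dirs + k.  The frame index
    t in [0, n_frames-1] is rescaled to [-1, 1]; fractional t is allowed.
    """

    def __init__(self, n_frames: int, n_levels_motion: int, n_dirs: int,
                 rng: np.random.Generator,
                 encoder_config: HashEncoderConfig | None = None,
                 hidden: int = 32, omega0: float = 30.0, dtype=np.float64):
        cfg = encoder_config or HashEncoderConfig(
            n_levels=12, table_size_log2=19, finest_resolution=max(n_frames, 32)
        )
        self.n_frames = int(n_frames)
        self.n_levels_motion = int(n_levels_motion)
        self.n_dirs = int(n_dirs)
        self.encoder = HashEncoder(cfg, 1, rng, dtype=dtype)
        n_out = self.n_levels_motion * self.n_dirs
        # "pytorch-default" uniform init for the temporal MLPs
        self.mlps = [
            SineMLP([self.encoder.n_features, hidden, hidden, 1], rng,
                    omega0=omega0, siren_init=False, dtype=dtype)
            for _ in range(n_out)
        ]
        self.dtype = dtype

    @property
    def n_outputs(self) -> int:
        return self.n_levels_motion * self.n_dirs

    def normalize(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        if np.any(t < 0) or np.any(t > self.n_frames - 1):
            raise ValueError("frame index outside the scan")
        if self.n_frames == 1:
            return np.zeros((len(t), 1), dtype=self.dtype)
        return (2.0 * t / (self.n_frames - 1) - 1.0).reshape(-1, 1).astype(self.dtype)

    def forward(self, t) -> Tensor:
        """t scalar or (B,) -> weights (B, n_outputs)."""
        feats = self.encoder.encode(Tensor(self.normalize(t)))
        return concat([mlp(feats) for mlp in self.mlps], axis=1)

    def eval_numpy(self, t) -> np.ndarray:
        feats = self.encoder.encode_numpy(self.normalize(t))
        cols = []
        for mlp in self.mlps:
            h = feats
            n_layers = len(mlp.weights)
            for i, (W, b) in enumerate(zip(mlp.weights, mlp.biases)):
                h = h @ W.data + b.data
                if i < n_layers - 1:
                    h = np.sin(mlp.omega0 * h)
            cols.append(h)
        return np.concatenate(cols, axis=1)

    def parameters(self) -> dict[str, Tensor]:
        out = {"temporal.tables": self.encoder.tables}
        for m, mlp in enumerate(self.mlps):
            out.update(mlp.parameters(f"temporal.mlp{m}"))
        return out


def init_params(
    fov_grid: VolumeGrid,
    n_frames: int,
    seed: int,
    n_levels_motion: int = 3,
    spatial_config: HashEncoderConfig | None = None,
    temporal_config: HashEncoderConfig | None = None,
    omega0: float = 30.0,
    siren_init: bool = True,
    dtype=np.float64,
) -> tuple[SpatialINR, TemporalINR]:
    """Reproducible initial spatial/temporal INR pair for a reconstruction."""
    rng = np.random.default_rng(seed)
    spatial = SpatialINR(fov_grid, rng, encoder_config=spatial_config,
                         omega0=omega0, siren_init=siren_init, dtype=dtype)
    temporal = TemporalINR(n_frames, n_levels_motion, fov_grid.ndim, rng,
                           encoder_config=temporal_config, omega0=omega0, dtype=dtype)
    return spatial, temporal
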