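"""Self-organizing (Kohonen) map: grid planning, init, batch and
sequential training, BMU lookup, quantization error, (de)serialization.

The map is a 2-D lattice of neurons (hexagonal by default), each carrying
a weight vector of the input dimensionality.  Competition picks the best
matching unit (BMU) by Euclidean distance; cooperation spreads each
update over a Gaussian neighborhood on the lattice whose radius shrinks
over training.  The final radius is the Viscovery-style *tension*
parameter: small tension lets the map conform tightly to the data.

Batch mode (the default) freezes the weights per epoch, computes all
BMUs, then replaces each weight by the neighborhood-weighted mean of the
data — deterministic given the initial state.  Sequential mode applies
the classic per-sample update w_j += eta * h * (x - w_j).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class SOMConfig:
    """Training configuration.

    tension is the final neighborhood radius in grid units (admissible
    0.3–2 in the Viscovery convention, 0.5 default).  sigma0 is the
    initial radius; None means max(rows, cols) / 2.  eta0 only matters
    in sequential mode (linear decay eta0 -> 0.01).
    """

    rows: int
    cols: int
    lattice: Literal["hex", "rect"] = "hex"
    tension: float = 0.5
    epochs: int = 50
    mode: Literal["batch", "sequential"] = "batch"
    init: Literal["linear", "random"] = "linear"
    seed: int | None = None
    eta0: float = 0.5
    sigma0: float | None = None

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.tension <= 0:
            raise ValueError("tension must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lattice not in ("hex", "rect"):
            raise ValueError(f"unknown lattice {self.lattice!r}")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def initial_sigma(self) -> float:
        if self.sigma0 is not None:
            return self.sigma0
        return max(self.rows, self.cols) / 2.0

    def sigma_at(self, epoch: int) -> float:
        """Exponential decay from initial sigma to tension over epochs."""
        s0, sf = self.initial_sigma(), self.tension
        if self.epochs == 1 or s0 == sf:
            return sf
        frac = epoch / (self.epochs - 1)
        return s0 * (sf / s0) ** frac


def grid_coordinates(rows: int, cols: int, lattice: str) -> np.ndarray:
    """Planar coordinates of each neuron, row-major.

    For the hexagonal lattice odd rows are offset by half a unit and row
    spacing is sqrt(3)/2, so each interior neuron has six neighbors at
    distance 1.  For the rectangular lattice coordinates are integer and
    the four axial neighbors are at distance 1.
    """
    r, c = np.divmod(np.arange(rows * cols), cols)
    if lattice == "hex":
        x = c + 0.5 * (r % 2)
        y = r * (math.sqrt(3) / 2.0)
    else:
        x, y = c.astype(float), r.astype(float)
    return np.column_stack([x, y])


@dataclass
class SOMap:
    """A neuron grid with one weight vector per neuron."""

    weights: np.ndarray  # (n_neurons, d)
    rows: int
    cols: int
    lattice: str = "hex"
    trained: bool = False
    grid: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != self.rows * self.cols:
            raise ValueError("weight count does not match grid size")
        self.grid = grid_coordinates(self.rows, self.cols, self.lattice)

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    @property
    def d(self) -> int:
        return self.weights.shape[1]

    def grid_distances(self) -> np.ndarray:
        """Pairwise lattice distances between neuron positions."""
        return cdist(self.grid, self.grid)

    def lattice_neighbors(self) -> list[np.ndarray]:
        """Indices of immediate lattice neighbors for each neuron."""
        dist = self.grid_distances()
        return [
            np.flatnonzero((dist[j] > 0) & (dist[j] < 1.01))
            for j in range(self.n_neurons)
        ]

    def save(self, csv_path: str | Path, config: SOMConfig | None = None) -> None:
        """CSV of (neuron, row, col, weights...) plus a JSON config sidecar."""
        csv_path = Path(csv_path)
        header = "neuron,row,col," + ",".join(
            f"w{i}" for i in range(self.d)
        )
        rows_idx, cols_idx = np.divmod(np.arange(self.n_neurons), self.cols)
        body = np.column_stack([np.arange(self.n_neurons), rows_idx, cols_idx,
                                self.weights])
        np.savetxt(csv_path, body, delimiter=",", header=header, comments="",
                   fmt=["%d", "%d", "%d"] + ["%.17g"] * self.d)
        meta = {"rows": self.rows, "cols": self.cols, "lattice": self.lattice,
                "trained": self.trained}
        if config is not None:
            meta["config"] = {k: v for k, v in config.__dict__.items()}
        csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "SOMap":
        csv_path = Path(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        body = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
        m = cls(weights=body[:, 3:], rows=meta["rows"], cols=meta["cols"],
                lattice=meta["lattice"], trained=meta.get("trained", False))
        return m


def plan_grid(
    data: np.ndarray, target_neurons: int = 1000, lattice: str = "hex"
) -> tuple[int, int]:
    """Choose (rows, cols) near a target neuron count.

    The product is kept within 5% of target_neurons and the aspect ratio
    cols/rows approximates the square root of the ratio of the two
    leading eigenvalues of the data covariance (clamped to [1, 5]), so
    elongated data get an elongated map.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need at least 2 data rows to plan a grid")
    if target_neurons < 4:
        raise ValueError("target_neurons must be >= 4")
    cov = np.cov(data, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
    if len(eig) < 2 or eig[1] <= 0:
        ratio = 1.0
    else:
        ratio = float(np.clip(eig[0] / eig[1], 1.0, 25.0))
    aspect = float(np.clip(math.sqrt(ratio), 1.0, 5.0))
    lo = int(math.ceil(0.95 * target_neurons))
    hi = int(math.floor(1.05 * target_neurons))
    best: tuple[float, float, int, int] | None = None
    for rows in range(1, hi + 1):
        for cols in range(max(rows, (lo + rows - 1) // rows), hi // rows + 1):
            n = rows * cols
            if not lo <= n <= hi:
                continue
            key = (abs(cols / rows - aspect), abs(n - target_neurons), rows, cols)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError(f"no grid with product within 5% of {target_neurons}")
    return best[2], best[3]


def initialize(config: SOMConfig, data: np.ndarray) -> SOMap:
    """Initial weights: per-variable uniform random, or PCA-plane linear.

    Linear init spreads the grid over the first two principal axes of
    the data (deterministic); degenerate data collapse to the mean.
    """
    data = np.asarray(data, dtype=float)
    n_neurons, d = config.n_neurons, data.shape[1]
    if config.init == "random":
        rng = np.random.default_rng(config.seed)
        lo, hi = data.min(axis=0), data.max(axis=0)
        weights = rng.uniform(lo, hi, size=(n_neurons, d))
    else:
        mean = data.mean(axis=0)
        centered = data - mean
        # SVD of the centered data gives principal axes; fixed sign for
        # determinism across LAPACK builds.
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        weights = np.tile(mean, (n_neurons, 1))
        grid = grid_coordinates(config.rows, config.cols, config.lattice)
        for axis in range(min(2, len(s))):
            if s[axis] <= 1e-12:
                continue
            vec = vt[axis]
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
            sd = s[axis] / math.sqrt(max(len(data) - 1, 1))
            g = grid[:, axis]
            span = g.max() - g.min()
            u = np.zeros_like(g) if span == 0 else 2 * (g - g.min()) / span - 1
            weights = weights + np.outer(u * 2.0 * sd, vec)
    return SOMap(weights=weights, rows=config.rows, cols=config.cols,
                 lattice=config.lattice)


def find_bmu(m: SOMap, x: np.ndarray) -> int:
    """Best matching unit: argmin_j ||x - w_j||, ties to the lowest index."""
    x = np.asarray(x, dtype=float)
    if x.shape != (m.d,):
        raise ValueError(f"input has dimension {x.shape}, map expects ({m.d},)")
    dist2 = np.einsum("jd,jd->j", m.weights - x, m.weights - x)
    return int(np.argmin(dist2))


def bmu_indices(m: SOMap, data: np.ndarray) -> np.ndarray:
    """Vectorized BMU lookup for a whole dataset."""
    data = np.asarray(data, dtype=float)
    d2 = cdist(data, m.weights, metric="sqeuclidean")
    return np.argmin(d2, axis=1)


def neighborhood(grid_dist: np.ndarray | float, sigma: float) -> np.ndarray | float:
    """Gaussian lattice kernel exp(-d^2 / (2 sigma^2)); 1 at the winner."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return np.exp(-np.square(grid_dist) / (2.0 * sigma * sigma))


def train_batch(m: SOMap, data: np.ndarray, config: SOMConfig) -> SOMap:
    """Batch training: per epoch, freeze weights, find all BMUs, then set
    each weight to the kernel-weighted mean of the data.

    A neuron whose total kernel mass underflows to zero keeps its
    previous weight (never divides by zero).
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("cannot train on empty data")
    weights = m.weights.copy()
    grid_d = m.grid_distances()
    n_neurons = m.n_neurons
    for epoch in range(config.epochs):
        sigma = config.sigma_at(epoch)
        kernel = neighborhood(grid_d, sigma)  # (n_neurons, n_neurons)
        d2 = cdist(data, weights, metric="sqeuclidean")
        bmus = np.argmin(d2, axis=1)
        # per-BMU sufficient statistics, then smooth across the lattice
        counts = np.bincount(bmus, minlength=n_neurons).astype(float)
        sums = np.zeros_like(weights)
        np.add.at(sums, bmus, data)
        denom = kernel @ counts
        numer = kernel @ sums
        ok = denom > 1e-300
        weights[ok] = numer[ok] / denom[ok, None]
    out = SOMap(weights=weights, rows=m.rows, cols=m.cols, lattice=m.lattice)
    out.trained = True
    return out


def train_sequential(m: SOMap, data: np.ndarray, config: SOMConfig) -> SOMap:
    """Classic per-sample updates with linearly decaying learning rate.

    Presentation order is reshuffled each epoch from the config seed;
    sigma follows the same schedule as batch mode, held per epoch.
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("cannot train on empty data")
    rng = np.random.default_rng(config.seed)
    weights = m.weights.copy()
    grid_d = m.grid_distances()
    n = len(data)
    total_steps = config.epochs * n
    step = 0
    for epoch in range(config.epochs):
        sigma = config.sigma_at(epoch)
        order = rng.permutation(n)
        for i in order:
            frac = step / max(total_steps - 1, 1)
            eta = config.eta0 + (0.01 - config.eta0) * frac
            x = data[i]
            bmu = np.argmin(np.einsum("jd,jd->j", weights - x, weights - x))
            h = neighborhood(grid_d[bmu], sigma)
            weights += (eta * h)[:, None] * (x - weights)
            step += 1
    out = SOMap(weights=weights, rows=m.rows, cols=m.cols, lattice=m.lattice)
    out.trained = True
    return out


def train(data: np.ndarray, config: SOMConfig) -> SOMap:
    """initialize + train in the configured mode."""
    m = initialize(config, data)
    if config.mode == "batch":
        return train_batch(m, data, config)
    return train_sequential(m, data, config)


def quantization_error(m: SOMap, data: np.ndarray) -> float:
    """Mean Euclidean distance from each input to its BMU."""
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("quantization error of empty data is undefined")
    d = cdist(data, m.weights)
    return float(d.min(axis=1).mean())


def distortion(m: SOMap, data: np.ndarray, sigma: float) -> float:
    """Smoothed SOM distortion sum_i sum_j h(j, bmu_i) ||x_i - w_j||^2."""
    data = np.asarray(data, dtype=float)
    d2 = cdist(data, m.weights, metric="sqeuclidean")
    bmus = np.argmin(d2, axis=1)
    kernel = neighborhood(m.grid_distances(), sigma)
    return float(np.sum(kernel[bmus] * d2))
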