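"""Map products: U-matrix, component planes, hit counts, heatmap export.

The U-matrix value of a neuron is the mean Euclidean distance between
its weight vector and those of its immediate lattice neighbors; ridges
of large values mark cluster boundaries on the map.  A component plane
is the map colored by one input variable's weight component.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np

from .som import SOMap, bmu_indices


def u_matrix(m: SOMap) -> np.ndarray:
    """Per-neuron mean weight-space distance to lattice neighbors."""
    values = np.zeros(m.n_neurons)
    for j, nbrs in enumerate(m.lattice_neighbors()):
        if len(nbrs) == 0:
            warnings.warn("single-neuron map: U-matrix is all zeros")
            continue
        values[j] = np.linalg.norm(m.weights[nbrs] - m.weights[j], axis=1).mean()
    return values


def component_planes(m: SOMap) -> list[np.ndarray]:
    """One per-neuron value array per input variable (d planes)."""
    return [m.weights[:, v].copy() for v in range(m.d)]


def hit_counts(m: SOMap, data: np.ndarray) -> np.ndarray:
    """Number of data points whose BMU is each neuron."""
    bmus = bmu_indices(m, data)
    return np.bincount(bmus, minlength=m.n_neurons)


def to_grid(values: np.ndarray, m: SOMap) -> np.ndarray:
    """Reshape a per-neuron vector to the (rows, cols) grid, row-major."""
    values = np.asarray(values, dtype=float)
    if values.shape != (m.n_neurons,):
        raise ValueError("values are not aligned to the neuron grid")
    return values.reshape(m.rows, m.cols)


def expanded_u_matrix(m: SOMap) -> np.ndarray:
    """(2r-1) x (2c-1) presentation: edges between rect-lattice neighbors
    on odd positions, neuron means on even positions."""
    if m.lattice != "rect":
        raise ValueError("expanded form is defined for the rect lattice")
    W = m.weights.reshape(m.rows, m.cols, m.d)
    out = np.zeros((2 * m.rows - 1, 2 * m.cols - 1))
    for r in range(m.rows):
        for c in range(m.cols - 1):
            out[2 * r, 2 * c + 1] = np.linalg.norm(W[r, c] - W[r, c + 1])
    for r in range(m.rows - 1):
        for c in range(m.cols):
            out[2 * r + 1, 2 * c] = np.linalg.norm(W[r, c] - W[r + 1, c])
    um = u_matrix(m).reshape(m.rows, m.cols)
    out[::2, ::2] = um
    for r in range(m.rows - 1):
        for c in range(m.cols - 1):
            out[2 * r + 1, 2 * c + 1] = 0.25 * (
                out[2 * r, 2 * c + 1] + out[2 * r + 2, 2 * c + 1]
                + out[2 * r + 1, 2 * c] + out[2 * r + 1, 2 * c + 2]
            )
    return out


def export_heatmap(
    values: np.ndarray, m: SOMap, path: str | Path, title: str | None = None
) -> list[Path]:
    """Write a CSV matrix (always) and a PNG heatmap (when matplotlib
    renders).  Returns the paths written.  NaNs are rejected by neuron id
    so a bad value cannot slip into a figure silently."""
    values = np.asarray(values, dtype=float)
    bad = np.flatnonzero(np.isnan(values))
    if bad.size:
        raise ValueError(f"NaN value at neuron(s) {bad.tolist()}")
    grid = to_grid(values, m)
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        for row in grid:
            w.writerow([repr(v) for v in row])
    written = [csv_path]
    try:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover - plotting is optional
        return written
    fig, ax = plt.subplots(figsize=(6, 6 * m.rows / max(m.cols, 1)))
    im = ax.imshow(grid, cmap="viridis", origin="upper")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    png_path = path.with_suffix(".png")
    fig.savefig(png_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(png_path)
    return written
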