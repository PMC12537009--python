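"""Synthetic two-channel 3D immunofluorescence stacks of synaptic puncta.

Channel A emulates presynaptic ribbon (Ctbp2/RIBEYE) puncta, channel B
postsynaptic (Homer1) puncta.  Punctum volumes are log-normal with a
controllable mean/SD; a configurable fraction of A puncta receives a B
partner displaced by a small offset (juxtaposed synapses), while remaining
B puncta are "orphans" placed far from every A punctum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = ["PunctaStack", "simulate_puncta_stack"]


@dataclass
class PunctaStack:
    """Two-channel voxel volume plus the generator's per-punctum truth."""

    channel_a: np.ndarray  # (z, y, x), a.u.
    channel_b: np.ndarray
    voxel_size: tuple  # (x, y, z) um
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError("channels must share one voxel grid")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("volume mean must be > 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _paint_sphere(stack: np.ndarray, center_um, radius_um, voxel_size, amplitude) -> int:
    """Add `amplitude` to voxels whose centers lie inside the sphere; return count."""
    dx, dy, dz = voxel_size
    cz, cy, cx = center_um[2], center_um[1], center_um[0]
    nz, ny, nx = stack.shape
    z0 = max(0, int((cz - radius_um) / dz) - 1)
    z1 = min(nz, int((cz + radius_um) / dz) + 2)
    y0 = max(0, int((cy - radius_um) / dy) - 1)
    y1 = min(ny, int((cy + radius_um) / dy) + 2)
    x0 = max(0, int((cx - radius_um) / dx) - 1)
    x1 = min(nx, int((cx + radius_um) / dx) + 2)
    zz = (np.arange(z0, z1) + 0.5) * dz
    yy = (np.arange(y0, y1) + 0.5) * dy
    xx = (np.arange(x0, x1) + 0.5) * dx
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    mask = (Z - cz) ** 2 + (Y - cy) ** 2 + (X - cx) ** 2 <= radius_um**2
    region = stack[z0:z1, y0:y1, x0:x1]
    region[mask] = np.maximum(region[mask], amplitude)  # saturating, not additive
    return int(mask.sum())


def simulate_puncta_stack(
    n_ribbon: int,
    pairing_fraction: float = 0.967,
    vol_a: tuple[float, float] = (0.16, 0.09),
    vol_b: tuple[float, float] = (0.36, 0.16),
    voxel_size: tuple[float, float, float] = (0.08, 0.08, 0.16),
    pair_offset: float = 0.3,
    seed: int | np.random.Generator = 0,
    *,
    n_orphan_b: int = 2,
    box_um: tuple[float, float, float] = (14.0, 11.0, 6.0),
    grid_spacing: float = 2.2,
    margin: float = 1.0,
    jitter: float = 0.35,
    amplitude: float = 150.0,
    noise_sd: float = 4.0,
) -> PunctaStack:
    """Generate a two-channel stack with known per-punctum ground truth.

    Puncta are spheres whose volumes are drawn log-normally to match the
    requested (mean, SD) in um^3.  Centers sit on a jittered 3D grid, which
    guarantees a minimum separation of ``grid_spacing - 2*jitter`` between
    puncta of the same channel and keeps orphan B puncta beyond any sane
    juxtaposition cutoff from every A punctum.  Each A punctum is paired
    (Bernoulli with ``pairing_fraction``) with a B partner displaced by
    ``pair_offset`` um in a random direction.

    Raises if the grid cannot host the requested number of puncta.
    """
    if not 0.0 <= pairing_fraction <= 1.0:
        raise ValueError("pairing_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bx, by, bz = box_um
    nodes = [
        np.array([margin + i * grid_spacing for i in range(int((b - 2 * margin) / grid_spacing) + 1)])
        for b in (bx, by, bz)
    ]
    grid = np.array(list(product(nodes[0], nodes[1], nodes[2])))
    needed = n_ribbon + n_orphan_b
    if needed > len(grid):
        raise ValueError(
            f"cannot place {needed} puncta on a {len(grid)}-node grid; enlarge box_um"
        )
    chosen = rng.choice(len(grid), size=needed, replace=False)
    centers = grid[chosen] + rng.uniform(-jitter, jitter, size=(needed, 3))

    mu_a, s_a = _lognormal_params(*vol_a)
    mu_b, s_b = _lognormal_params(*vol_b)

    shape = (
        int(np.ceil(bz / voxel_size[2])),
        int(np.ceil(by / voxel_size[1])),
        int(np.ceil(bx / voxel_size[0])),
    )
    ch_a = np.zeros(shape)
    ch_b = np.zeros(shape)

    rows_a, rows_b = [], []
    for i in range(n_ribbon):
        c = centers[i]
        v = float(rng.lognormal(mu_a, s_a))
        r = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
        nvox = _paint_sphere(ch_a, c, r, voxel_size, amplitude)
        paired = bool(rng.random() < pairing_fraction)
        rows_a.append(
            {"center": tuple(c), "volume": v, "radius": r, "paired": paired, "voxels": nvox}
        )
        if paired:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cb = c + pair_offset * u
            cb = np.clip(cb, 0.3, np.array(box_um) - 0.3)
            vb = float(rng.lognormal(mu_b, s_b))
            rb = (3.0 * vb / (4.0 * np.pi)) ** (1.0 / 3.0)
            nv = _paint_sphere(ch_b, cb, rb, voxel_size, amplitude)
            rows_b.append(
                {"center": tuple(cb), "volume": vb, "radius": rb, "orphan": False, "voxels": nv}
            )
    for i in range(n_orphan_b):
        c = centers[n_ribbon + i]
        vb = float(rng.lognormal(mu_b, s_b))
        rb = (3.0 * vb / (4.0 * np.pi)) ** (1.0 / 3.0)
        nv = _paint_sphere(ch_b, c, rb, voxel_size, amplitude)
        rows_b.append(
            {"center": tuple(c), "volume": vb, "radius": rb, "orphan": True, "voxels": nv}
        )

    if noise_sd > 0:
        ch_a += rng.normal(0.0, noise_sd, size=shape)
        ch_b += rng.normal(0.0, noise_sd, size=shape)

    truth = {
        "a": rows_a,
        "b": rows_b,
        "pairing_fraction": pairing_fraction,
        "n_paired": sum(r["paired"] for r in rows_a),
        "pair_offset": pair_offset,
        "amplitude": amplitude,
        "noise_sd": noise_sd,
        "box_um": box_um,
    }
    return PunctaStack(channel_a=ch_a, channel_b=ch_b, voxel_size=voxel_size, truth=truth)
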