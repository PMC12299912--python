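"""TSVD-regularized Born inversion and image post-processing.

Offline stage: the Born operator is decomposed once, ``L = U S V^H``.
Online stage: a measured differential channel vector dS is inverted with the
truncated pseudo-inverse

    deltaO = sum_{n=1}^{nT} (u_n^H dS / s_n) v_n

where nT is the truncation index (default 50 of the 55 channels), the only
regularization parameter.  Images are the per-voxel magnitude |deltaO|,
optionally smoothed slice-wise with a normalized 3x3 box blur.

Shaped after the model/results pattern: :class:`TSVDBorn` is built from an
operator; ``fit`` returns a :class:`TSVDResult` carrying the contrast map,
diagnostics and plotting/localization helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .forward import BornOperator
from .scenario import ContrastMap, ImagingGrid

DEFAULT_NT = 50


@dataclass(frozen=True)
class OperatorSVD:
    """Economy SVD of a Born operator: U (ch x r), s (r,), V (vox x r)."""

    U: np.ndarray
    s: np.ndarray
    V: np.ndarray
    operator: BornOperator

    @property
    def rank(self) -> int:
        return self.s.size


def decompose(operator: BornOperator) -> OperatorSVD:
    """Economy singular value decomposition of the operator matrix."""
    M = operator.matrix
    if not np.all(np.isfinite(M)):
        raise ValueError("operator contains non-finite entries")
    U, s, Vh = np.linalg.svd(M, full_matrices=False)
    return OperatorSVD(U, s, Vh.conj().T, operator)


def reconstruct(svd: OperatorSVD, dS: np.ndarray, nt: int = DEFAULT_NT) -> ContrastMap:
    """Truncated-SVD contrast reconstruction (complex map)."""
    if not 1 <= nt <= svd.rank:
        raise ValueError(f"nt must be in [1, {svd.rank}], got {nt}")
    dS = np.asarray(dS, complex)
    coeff = (svd.U[:, :nt].conj().T @ dS) / svd.s[:nt]
    return ContrastMap(svd.operator.grid, svd.V[:, :nt] @ coeff, kind="complex")


def magnitude_image(cmap: ContrastMap) -> ContrastMap:
    """Per-voxel modulus of a complex contrast map."""
    return ContrastMap(cmap.grid, np.abs(cmap.values), kind="magnitude")


def box_blur(image: np.ndarray) -> np.ndarray:
    """3x3 ones kernel normalized by 9, reflect-padded, on a 2-D slice."""
    image = np.asarray(image, float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("box_blur needs a 2-D slice at least 3x3")
    return uniform_filter(image, size=3, mode="reflect")


def blur_slices(grid: ImagingGrid, values: np.ndarray) -> np.ndarray:
    """Apply the box blur per XY slice; returns per-voxel values again."""
    box = grid.embed(np.asarray(values, float))
    for k in range(grid.zs.size):
        box[:, :, k] = box_blur(box[:, :, k])
    return box[grid.mask]


@dataclass(frozen=True)
class Localization:
    """Peak of a (blurred) magnitude image; ``found=False`` for all-zero images."""

    found: bool
    position: tuple | None = None  # (x, y, z) mm
    value: float = 0.0


def localize(cmap: ContrastMap, blur: bool = True) -> Localization:
    """Coordinates and value of the image maximum.

    Ties break toward the lowest flat voxel index (C order over the masked
    grid), deterministically.  An identically zero image is flagged as
    "no detection" rather than returning a coordinate.
    """
    vals = np.abs(cmap.values) if np.iscomplexobj(cmap.values) else np.asarray(cmap.values)
    if blur:
        vals = blur_slices(cmap.grid, vals)
    if not np.any(vals > 0):
        return Localization(found=False)
    i = int(np.argmax(vals))
    return Localization(True, tuple(cmap.grid.centers[i]), float(vals[i]))


class TSVDBorn:
    """TSVD Born inversion model for one operator (offline stage).

    Parameters
    ----------
    operator : BornOperator
    svd : OperatorSVD, optional
        Reuse a cached decomposition; computed on construction otherwise.
    """

    def __init__(self, operator: BornOperator, svd: OperatorSVD | None = None):
        self.operator = operator
        self.svd = svd if svd is not None else decompose(operator)

    def fit(self, dS: np.ndarray, nt: int = DEFAULT_NT) -> "TSVDResult":
        """Invert one differential channel vector (online stage)."""
        cmap = reconstruct(self.svd, dS, nt)
        return TSVDResult(self, np.asarray(dS, complex), cmap, nt)

    def truncation_sweep(self, dS: np.ndarray, nt_list) -> pd.DataFrame:
        """Residual / solution-norm table over truncation indices (L-curve data)."""
        rows = []
        for nt in nt_list:
            res = self.fit(dS, int(nt))
            rows.append(
                dict(nt=int(nt), residual=res.residual_norm, solution_norm=res.solution_norm)
            )
        return pd.DataFrame(rows)


class TSVDResult:
    """Reconstruction result: contrast map, diagnostics, images."""

    def __init__(self, model: TSVDBorn, dS: np.ndarray, cmap: ContrastMap, nt: int):
        self.model = model
        self.dS = dS
        self.contrast = cmap
        self.nt = nt

    @property
    def grid(self) -> ImagingGrid:
        return self.contrast.grid

    @property
    def residual_norm(self) -> float:
        """Data misfit ||L deltaO - dS||_2."""
        return float(
            np.linalg.norm(self.model.operator.matrix @ self.contrast.values - self.dS)
        )

    @property
    def solution_norm(self) -> float:
        return float(np.linalg.norm(self.contrast.values))

    def magnitude(self, blur: bool = False) -> ContrastMap:
        mag = magnitude_image(self.contrast)
        if not blur:
            return mag
        return ContrastMap(self.grid, blur_slices(self.grid, mag.values), "blurred-magnitude")

    def localize(self, blur: bool = True) -> Localization:
        return localize(self.contrast, blur=blur)

    def slice_image(self, plane: str = "xy", coord: float | None = None, blur: bool = True):
        """Extract a 2-D image slice.

        Returns ``(axis1, axis2, image)`` where image is NaN outside the head
        mask.  ``plane`` is ``"xy"`` (at height ``coord``, default the peak z)
        or ``"xz"`` (at ``y = coord``, default the peak y).
        """
        g = self.grid
        vals = self.magnitude(blur=False).values
        if blur:
            vals = blur_slices(g, vals)
        box = g.embed(vals, fill=np.nan)
        box[~g.mask] = np.nan
        loc = self.localize(blur=blur)
        ref = loc.position if loc.found else (0.0, 0.0, float(g.zs[0]))
        if plane == "xy":
            z = ref[2] if coord is None else coord
            k = int(np.argmin(np.abs(g.zs - z)))
            return g.xs, g.ys, box[:, :, k]
        if plane == "xz":
            y = ref[1] if coord is None else coord
            j = int(np.argmin(np.abs(g.ys - y)))
            return g.xs, g.zs, box[:, j, :]
        raise ValueError("plane must be 'xy' or 'xz'")

    def plot_slice(self, plane="xy", coord=None, blur=True, ax=None, title=None):
        """Heatmap of a slice (matplotlib); returns the axes."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        a1, a2, img = self.slice_image(plane=plane, coord=coord, blur=blur)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        pc = ax.pcolormesh(a1, a2, img.T, shading="nearest", cmap="viridis")
        ax.set_aspect("equal")
        ax.set_xlabel(f"{plane[0]} (mm)")
        ax.set_ylabel(f"{plane[1]} (mm)")
        if title:
            ax.set_title(title)
        plt.colorbar(pc, ax=ax, label="|deltaO| (rel. contrast)")
        return ax

    def save(self, path) -> None:
        """Raw map + grid metadata as NPZ."""
        g = self.grid
        np.savez(
            path,
            values=self.contrast.values,
            xs=g.xs,
            ys=g.ys,
            zs=g.zs,
            mask=g.mask,
            spacing=g.spacing,
            nt=self.nt,
            dS=self.dS,
        )

    def summary(self) -> str:
        loc = self.localize()
        lines = [
            "TSVD Born reconstruction",
            f"  truncation index nT : {self.nt} / rank {self.model.svd.rank}",
            f"  grid                : {self.grid.n_voxels} voxels @ {self.grid.spacing} mm",
            f"  residual ||L x - b||: {self.residual_norm:.4e}",
            f"  solution norm ||x|| : {self.solution_norm:.4e}",
        ]
        if loc.found:
            x, y, z = loc.position
            lines.append(
                f"  peak |deltaO|       : {loc.value:.4e} at ({x:.1f}, {y:.1f}, {z:.1f}) mm"
            )
        else:
            lines.append("  peak |deltaO|       : no detection (all-zero image)")
        return "\n".join(lines)
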