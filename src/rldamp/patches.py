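"""Nonlocal self-similarity machinery: exemplars, block matching, grouping.

Coordinates are 0-based ``(row, col)`` of a patch's top-left corner; patches
are ``p x p`` and vectorized row-major.  Stacking the ``N`` patches most
similar to an exemplar column-wise yields a near-low-rank ``p**2 x N`` group
matrix — the object the residual denoiser shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import AggregationError, DimensionError, ParameterError

__all__ = [
    "PatchGroup",
    "select_exemplars",
    "block_match",
    "group_to_matrix",
    "aggregate_groups",
]


@dataclass
class PatchGroup:
    """A group of mutually similar patches and its column-stacked matrix.

    ``member_coords[0]`` is always the exemplar itself; ``matrix`` has shape
    ``(p*p, N)`` with column ``j`` the row-major vectorized patch at
    ``member_coords[j]``.
    """

    ref_coord: tuple[int, int]
    member_coords: list[tuple[int, int]]
    matrix: np.ndarray
    patch_size: int
    distances: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.member_coords and tuple(self.member_coords[0]) != tuple(self.ref_coord):
            raise ParameterError("member_coords[0] must equal ref_coord")


def select_exemplars(
    shape: tuple[int, int], patch_size: int, stride: int
) -> list[tuple[int, int]]:
    """Regular grid of exemplar top-left corners with the given stride.

    The last valid corner index (``side - patch_size``) is always included
    so every pixel is covered by at least one extracted patch.
    """
    rows, cols = shape
    p = patch_size
    if p > min(rows, cols):
        raise ParameterError(f"patch size {p} exceeds image side {min(rows, cols)}")
    if stride < 1:
        raise ParameterError(f"stride must be >= 1, got {stride}")

    def axis_corners(side: int) -> list[int]:
        last = side - p
        corners = list(range(0, last + 1, stride))
        if corners[-1] != last:
            corners.append(last)
        return corners

    return [(r, c) for r in axis_corners(rows) for c in axis_corners(cols)]


def _candidate_range(ref: int, half_lo: int, half_hi: int, last: int) -> tuple[int, int]:
    lo = max(0, ref - half_lo)
    hi = min(last, ref + half_hi)
    return lo, hi


def block_match(
    image: np.ndarray,
    ref_coord: tuple[int, int],
    patch_size: int,
    window: int,
    num_similar: int,
    *,
    _patch_view: np.ndarray | None = None,
    _patch_norms: np.ndarray | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Find the ``num_similar`` patches closest (Euclidean) to the exemplar.

    Candidates are all patches whose top-left corner lies inside an
    (approximately) ``window x window`` region centered on the exemplar,
    clipped at the borders.  Ties are broken by row-major candidate order
    (stable sort), the exemplar is always first.  If the window holds fewer
    than ``num_similar`` candidates it is expanded to the whole image;
    a deficit after that raises an error.

    Returns ``(coords, distances)``; distances follow list order and are
    non-decreasing after the leading exemplar (distance 0).
    """
    p = patch_size
    rows, cols = image.shape
    if window < p:
        raise ParameterError(f"search window {window} smaller than patch size {p}")
    rr, cc = ref_coord
    last_r, last_c = rows - p, cols - p
    if not (0 <= rr <= last_r and 0 <= cc <= last_c):
        raise ParameterError(f"exemplar {ref_coord} out of bounds for shape {image.shape}")

    # all patches, shape (last_r+1, last_c+1, p*p); shared across calls when provided
    if _patch_view is None:
        _patch_view = sliding_window_view(image, (p, p)).reshape(last_r + 1, last_c + 1, p * p)
    ref_patch = _patch_view[rr, cc]

    half = (window - p) // 2
    for half_lo, half_hi in (( half, window - p - half), (max(last_r, last_c), max(last_r, last_c))):
        r0, r1 = _candidate_range(rr, half_lo, half_hi, last_r)
        c0, c1 = _candidate_range(cc, half_lo, half_hi, last_c)
        n_cand = (r1 - r0 + 1) * (c1 - c0 + 1)
        if n_cand >= num_similar:
            break
    if n_cand < num_similar:
        raise ParameterError(
            f"only {n_cand} candidate patches available, {num_similar} requested"
        )

    cand = _patch_view[r0 : r1 + 1, c0 : c1 + 1]  # (nr, nc, p*p)
    # ||cand - ref||^2 = ||cand||^2 - 2 cand.ref + ||ref||^2, clipped at 0
    if _patch_norms is None:
        cand_norms = np.einsum("ijk,ijk->ij", cand, cand)
    else:
        cand_norms = _patch_norms[r0 : r1 + 1, c0 : c1 + 1]
    rp2 = ref_patch @ ref_patch
    d2 = (cand_norms - 2.0 * (cand @ ref_patch) + rp2).ravel()
    # exact duplicates must have distance exactly 0 (tie-break contract):
    # clamp values below the cancellation noise floor of the expansion
    d2[d2 <= 1e-10 * (rp2 + cand_norms.ravel())] = 0.0
    np.maximum(d2, 0.0, out=d2)
    nr, nc = cand.shape[:2]
    ref_flat = (rr - r0) * nc + (cc - c0)
    d2[ref_flat] = -1.0  # force exemplar strictly first under stable sort
    order = np.argsort(d2, kind="stable")[:num_similar]
    coords = [(r0 + int(k) // nc, c0 + int(k) % nc) for k in order]
    dist = np.sqrt(np.maximum(d2[order], 0.0))
    return coords, dist


def group_to_matrix(
    image: np.ndarray, coords: list[tuple[int, int]], patch_size: int
) -> np.ndarray:
    """Stack patches at ``coords`` as columns: exact extraction, no normalization."""
    p = patch_size
    rows, cols = image.shape
    out = np.empty((p * p, len(coords)), dtype=image.dtype)
    for j, (r, c) in enumerate(coords):
        if not (0 <= r <= rows - p and 0 <= c <= cols - p):
            raise IndexError(f"patch corner {(r, c)} out of bounds for shape {image.shape}")
        out[:, j] = image[r : r + p, c : c + p].ravel()
    return out


def aggregate_groups(groups: list[PatchGroup], shape: tuple[int, int]) -> np.ndarray:
    """Overlap-average patch groups back into a raster.

    Each output pixel is the mean of every patch value covering it; a pixel
    covered by no patch signals a mis-configured exemplar grid and raises
    :class:`AggregationError`.
    """
    acc = np.zeros(shape, dtype=float)
    cnt = np.zeros(shape, dtype=float)
    for g in groups:
        p = g.patch_size
        for j, (r, c) in enumerate(g.member_coords):
            if not (0 <= r <= shape[0] - p and 0 <= c <= shape[1] - p):
                raise DimensionError(f"patch corner {(r, c)} invalid for shape {shape}")
            acc[r : r + p, c : c + p] += g.matrix[:, j].reshape(p, p)
            cnt[r : r + p, c : c + p] += 1.0
    if np.any(cnt == 0):
        n_uncovered = int(np.sum(cnt == 0))
        raise AggregationError(f"{n_uncovered} pixels covered by no patch")
    return acc / cnt


def patch_view(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Precomputed sliding view of all patches, for repeated block matching."""
    p = patch_size
    rows, cols = image.shape
    return sliding_window_view(image, (p, p)).reshape(rows - p + 1, cols - p + 1, p * p)
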