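"""Angle-distance (A-D) image of a chain's SSE pairs.

Every unordered pair of SSE vectors becomes one point: the inter-vector angle
on the y-axis and the Euclidean distance of the geometric centers on the
x-axis, both normalized to [0, 1].  The image is dissected into a 10×10 block
grid; during matching a point is only paired with the other image's points in
its own block and the nearest 24 blocks, which prunes most candidate pairings.

Because angles and centroid distances are internal coordinates, the image is
invariant under any rigid-body transformation of the chain.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import Config, DEFAULT
from .structure_io import SSEVector, torsion, vector_angle

__all__ = ["ADPoint", "ADImage", "build_ad_image", "block_neighborhood",
           "dump_image_tsv"]


@dataclass
class ADPoint:
    sse_a: int                # SSE indices, a < b
    sse_b: int
    angle: float              # degrees in [0, 180] between SSE vectors
    dist: float               # Å between SSE centroids
    dihedral: float           # degrees in [0, 180] about the centroid axis
    chain_sep: int            # residues strictly between the two spans
    norm_xy: tuple[float, float]
    block: tuple[int, int]


class ADImage:
    def __init__(self, chain_id: str, points: list[ADPoint], sses: list[SSEVector],
                 n_blocks: int):
        self.chain_id = chain_id
        self.points = points
        self.sses = sses
        self.n_blocks = n_blocks
        # geometric center of each point's SSE pair, used by edge scoring
        self.centers = np.array([
            0.5 * (sses[p.sse_a].centroid + sses[p.sse_b].centroid) for p in points
        ]).reshape(len(points), 3)

    def __len__(self) -> int:
        return len(self.points)


def _pair_dihedral(a: SSEVector, b: SSEVector) -> float:
    """Dihedral formed by the two SSE vectors about the centroid-connecting
    axis: torsion(end_a, centroid_a, centroid_b, end_b), folded to [0, 180]."""
    end_a = a.centroid + a.direction * (a.length / 2.0)
    end_b = b.centroid + b.direction * (b.length / 2.0)
    try:
        t = torsion(end_a, a.centroid, b.centroid, end_b)
    except (ValueError, ZeroDivisionError, FloatingPointError):
        return 0.0
    if not np.isfinite(t):
        return 0.0
    return abs(t)


def build_ad_image(sses: list[SSEVector], chain_id: str = "",
                   config: Config = DEFAULT) -> ADImage:
    """A-D image with one point per unordered SSE pair (E(E-1)/2 points)."""
    if len(sses) < 2:
        raise ValueError(f"too few SSEs to build an A-D image ({len(sses)} < 2)")
    nb = config.n_blocks
    points: list[ADPoint] = []
    for i in range(len(sses)):
        for j in range(i + 1, len(sses)):
            a, b = sses[i], sses[j]
            angle = vector_angle(a.direction, b.direction)
            dist = float(np.linalg.norm(a.centroid - b.centroid))
            sep = max(0, b.first_pos - a.last_pos - 1)
            nx = min(dist / config.d_norm, 1.0)
            ny = angle / 180.0
            block = (min(int(nx * nb), nb - 1), min(int(ny * nb), nb - 1))
            points.append(ADPoint(
                sse_a=i, sse_b=j, angle=angle, dist=dist,
                dihedral=_pair_dihedral(a, b), chain_sep=sep,
                norm_xy=(nx, ny), block=block))
    return ADImage(chain_id, points, sses, nb)


def block_neighborhood(point: ADPoint, image: ADImage,
                       reach: int | None = None,
                       config: Config = DEFAULT) -> list[int]:
    """Indices of ``image``'s points whose block lies within Chebyshev distance
    ``reach`` (default: own block + nearest 24) of the query point's block."""
    if reach is None:
        reach = config.block_reach
    bx, by = point.block
    return [k for k, p in enumerate(image.points)
            if abs(p.block[0] - bx) <= reach and abs(p.block[1] - by) <= reach]


def dump_image_tsv(image: ADImage, path) -> None:
    """Write the image points as TSV (sse_a, sse_b, angle, dist) for plotting."""
    with open(path, "w") as fh:
        fh.write("sse_a\tsse_b\tangle\tdist\n")
        for p in image.points:
            fh.write(f"{p.sse_a}\t{p.sse_b}\t{p.angle:.4f}\t{p.dist:.4f}\n")
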