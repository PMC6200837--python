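"""Hindered diffusion near a wall and constant-volume compression geometry.

A sphere of radius ``a`` diffusing parallel to a flat wall at distance
``z`` (centre to wall) is slowed by hydrodynamic drag; the leading-order
(method-of-reflections) correction is

    D_par / D_0  =  1 - 9a/(16z),

valid for z > 9a/16.  When a cell of height h0 is squeezed at constant
volume so its footprint area grows by a fraction f, the height drops to
h0/(1+f); with the tracer centred, the wall distance is half the height.
These closed forms bound how much of an observed diffusivity drop can be
attributed to wall friction alone.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "hindered_ratio",
    "compressed_height_decrease",
    "compression_slowdown",
    "HindranceResult",
    "CompressionReport",
]


@dataclass
class HindranceResult:
    """Parallel-wall drag correction for one (a, z) geometry."""

    a: float  # particle radius, μm
    z: float  # wall–particle-centre distance, μm
    ratio: float  # D_par / D_0
    lambda_par: float  # drag correction factor, 1/ratio


def hindered_ratio(a: float, z: float) -> HindranceResult:
    """Leading-order parallel diffusivity ratio D_par/D_0 = 1 − 9a/(16z).

    Raises
    ------
    ValueError
        If z <= 9a/16, where the truncated expansion breaks down.
    """
    if a < 0:
        raise ValueError("particle radius a must be >= 0")
    if z <= 0:
        raise ValueError("wall distance z must be positive")
    if z <= 9.0 * a / 16.0:
        raise ValueError(
            f"z = {z:g} <= 9a/16 = {9 * a / 16:g}: truncated wall correction "
            "is outside its validity domain"
        )
    ratio = 1.0 - 9.0 * a / (16.0 * z)
    return HindranceResult(a=a, z=z, ratio=ratio, lambda_par=1.0 / ratio)


def compressed_height_decrease(area_increase: float) -> float:
    """Fractional height decrease at constant volume.

    A footprint-area increase by a fraction ``f`` implies a height factor
    1/(1+f), i.e. a fractional decrease 1 − 1/(1+f).  Exact inverse
    relation: (1 − decrease) * (1 + f) = 1.
    """
    if area_increase <= -1:
        raise ValueError("area_increase must exceed -1")
    return 1.0 - 1.0 / (1.0 + area_increase)


@dataclass
class CompressionReport:
    """Wall-friction slowdown estimates for a compressed cell.

    Two conventions are reported because the headline number depends on
    the reference state:

    * ``decrease_vs_unconfined``: 9a/(16z) at the compressed half-height —
      compressed cell relative to an unconfined (bulk) tracer;
    * ``decrease_vs_uncompressed``: 1 − ratio(z)/ratio(z0) — compressed
      relative to the uncompressed but already wall-confined cell.
    """

    a: float
    h0: float
    h: float
    z0: float
    z: float
    height_decrease: float
    ratio_uncompressed: float  # D_par/D_0 at z0
    ratio_compressed: float  # D_par/D_0 at z
    decrease_vs_unconfined: float
    decrease_vs_uncompressed: float
    convention: str = (
        "z is half the cell height (particle centred); decreases are "
        "reported both vs an unconfined tracer and vs the uncompressed "
        "confined cell"
    )


def compression_slowdown(
    a: float, h0: float = 1.0, area_increase: float = 0.72
) -> CompressionReport:
    """Estimate the wall-friction slowdown caused by squeezing a cell.

    Parameters
    ----------
    a : float
        Tracer radius, μm.
    h0 : float
        Uncompressed cell height, μm (≈ cell width for a rod-shaped cell).
    area_increase : float
        Fractional footprint-area increase under compression.
    """
    height_decrease = compressed_height_decrease(area_increase)
    h = h0 / (1.0 + area_increase)
    z0, z = h0 / 2.0, h / 2.0
    r0 = hindered_ratio(a, z0)
    r1 = hindered_ratio(a, z)
    return CompressionReport(
        a=a,
        h0=h0,
        h=h,
        z0=z0,
        z=z,
        height_decrease=height_decrease,
        ratio_uncompressed=r0.ratio,
        ratio_compressed=r1.ratio,
        decrease_vs_unconfined=9.0 * a / (16.0 * z),
        decrease_vs_uncompressed=1.0 - r1.ratio / r0.ratio,
    )
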