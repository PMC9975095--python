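"""Optical-fractionator arithmetic.

The optical fractionator estimates a total cell number from a systematic
subsample: N = ΣQ⁻ / (ssf · asf · hsf), where ΣQ⁻ is the number of cells
counted in the dissectors, ssf the section sampling fraction (one section
every ``period``), asf the area sampling fraction (counting frame over
sampling grid, squared side ratio) and hsf the height sampling fraction
(dissector height over section thickness). Used here to benchmark the
automated counts against stereology-style estimates; coefficient-of-error
machinery is out of scope.
"""

from __future__ import annotations

from .datatypes import FractionatorParams


def sampling_fractions(
    section_period: int,
    grid_side_um: float,
    frame_side_um: float,
    dissector_height_um: float,
    section_thickness_um: float,
) -> tuple[float, float, float]:
    """(ssf, asf, hsf) from the sampling design.

    ssf = 1/period (e.g. every fifth section → 0.2); asf = (frame/grid)²
    (50 µm frame on a 100 µm grid → 0.25); hsf = dissector height /
    section thickness.
    """
    if section_period < 1:
        raise ValueError("section period must be a positive integer")
    if grid_side_um <= 0 or frame_side_um <= 0:
        raise ValueError("grid and frame sides must be positive")
    if frame_side_um > grid_side_um:
        raise ValueError("counting frame cannot exceed the sampling grid")
    if dissector_height_um <= 0 or section_thickness_um <= 0:
        raise ValueError("heights must be positive")
    if dissector_height_um > section_thickness_um:
        raise ValueError("dissector height cannot exceed section thickness")
    ssf = 1.0 / section_period
    asf = (frame_side_um / grid_side_um) ** 2
    hsf = dissector_height_um / section_thickness_um
    return ssf, asf, hsf


def fractionator_estimate(params: FractionatorParams) -> float:
    """N̂ = ΣQ⁻ / (ssf · asf · hsf)."""
    denom = params.ssf * params.asf * params.hsf
    if denom == 0:
        raise ValueError("sampling fractions must be non-zero")
    return params.q_counted / denom
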