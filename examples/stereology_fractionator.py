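"""Optical-fractionator arithmetic used to benchmark automated counts.

Computes the sampling fractions of a typical design — every fifth section,
a 50 µm counting frame on a 100 µm grid, a 7.5 µm dissector in 15 µm
sections — and the total-count estimate N = ΣQ⁻ / (ssf·asf·hsf).
"""

from gliamorph import FractionatorParams
from gliamorph.stereology import fractionator_estimate, sampling_fractions

ssf, asf, hsf = sampling_fractions(
    section_period=5,
    grid_side_um=100.0,
    frame_side_um=50.0,
    dissector_height_um=7.5,
    section_thickness_um=15.0,
)
print(f"ssf = {ssf}   (every fifth section)")
print(f"asf = {asf}  (50 µm frame on a 100 µm grid)")
print(f"hsf = {hsf}   (7.5 µm dissector in 15 µm sections)")

q = 100
estimate = fractionator_estimate(FractionatorParams(ssf, asf, hsf, q))
print(f"counted {q} cells -> estimated total N = {estimate:.0f}")
print("(each sampled cell stands for 1/(ssf·asf·hsf) = "
      f"{1/(ssf*asf*hsf):.0f} cells)")
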