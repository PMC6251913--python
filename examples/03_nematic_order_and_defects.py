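"""Director field, nematic order parameter q, and disclination defects.

Renders a texture containing a +1/2 disclination, recovers the director
field from windowed FFT second moments, fills in the order parameter q and
locates the defect from the winding of the director angle.
"""

import numpy as np

import actent as ae

tex = ae.TextureSpec(
    image_shape=(220, 220),
    pixel_size_um=0.2,
    pattern=("defect", +0.5, (110, 110)),
    seed=0,
)
image, truth = ae.render_texture(tex)

field = ae.compute_director_field(image, tex.pixel_size_um, window_size_um=3.5)
field = ae.compute_order_parameter(field)
defects = ae.locate_defects(field)

print(f"windows with a defined director : {np.isfinite(field.angle).sum()}")
print(f"spatial mean order parameter    : {np.nanmean(field.q):.3f}")
for pos, s in zip(defects.positions_um, defects.charges):
    print(f"defect: charge {s:+.1f} at ({pos[0]:.1f}, {pos[1]:.1f}) um "
          f"(true core at 22.0, 22.0)")
print("q is high in the smoothly aligned regions and the detector finds the")
print("single prescribed half-integer disclination near its true core.")
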