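"""Simulate circular-array photoacoustic data and reconstruct by FBP.

A disk phantom inside the unit detection circle is propagated to the
ring analytically (closed-form circular means + Abel-type time
transform), then inverted with the filtered-backprojection formula.
"""

import numpy as np

from cspapi import (
    Disk, DiskPhantom, ImageGrid, SensorGeometry, TimeGrid,
    fbp, forward_pressure, rasterize, relative_l2_error,
    nyquist_sensor_count,
)

phantom = DiskPhantom([
    Disk(center=(0.25, -0.1), radius=0.22, amplitude=1.0),
    Disk(center=(-0.3, 0.2), radius=0.15, amplitude=0.8),
])
geometry = SensorGeometry(R=1.0, n=256)
grid = TimeGrid(q=1024)

pressure = forward_pressure(phantom, geometry, grid)
image = fbp(pressure, ImageGrid(Nr=128))
reference = rasterize(phantom, ImageGrid(Nr=128))

err = relative_l2_error(image.values, reference.values)
print(f"detector data:        {pressure.values.shape} (sensors x time)")
print(f"reconstruction error: {err:.3f} relative l2 vs the phantom raster")
print(f"peak amplitude:       {image.values.max():.3f} (true 1.0 inside the overlap-free disk)")
print(f"Nyquist sensor count for Nr=128: {nyquist_sensor_count(128)} "
      f"(the 64-sensor instrument ring is undersampled on purpose)")
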