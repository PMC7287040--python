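"""Project channel HFO rates onto a volumetric heatmap.

Paints max-normalized qHFO rates into 9 mm cubes centered on each bipolar
channel's two contacts of a toy electrode shaft, smooths with a 4 mm FWHM
Gaussian, and prints the heatmap's hot spot.  With real data the template
would be the patient's brain mask and the output a NIfTI overlay.
"""

import numpy as np
import pandas as pd

from hfopipe.imaging import rates_to_volume, smooth_volume
from hfopipe.seeg_io import BipolarChannel, VolumeImage

# a 6-contact shaft entering along x at y=z=30 mm, contacts 1.5 mm apart
contacts = [np.array([20.0 + 1.5 * i, 30.0, 30.0]) for i in range(6)]
channels = [
    BipolarChannel(name=f"E{i+1}-E{i+2}", anode=("E", i + 1),
                   cathode=("E", i + 2), anode_xyz=contacts[i],
                   cathode_xyz=contacts[i + 1])
    for i in range(5)
]
# the deepest two channels carry the highest rates
table = pd.DataFrame({"qhfo_norm": [1.0, 0.7, 0.2, 0.05, 0.0]},
                     index=[ch.name for ch in channels])

template = VolumeImage(grid=np.zeros((60, 60, 60)), affine=np.eye(4),
                       interpretation="heatmap")
heat = rates_to_volume(table, channels, template)
smoothed = smooth_volume(heat)

hot = tuple(int(i) for i in
            np.unravel_index(smoothed.grid.argmax(), smoothed.grid.shape))
print(f"painted voxels > 0: {(heat.grid > 0).sum()} "
      f"(9 mm cubes on a 1 mm grid, overlaps keep the maximum)")
print(f"hot spot after 4 mm FWHM smoothing: voxel {hot} "
      f"(mm, identity affine), value {smoothed.grid.max():.2f}")
print(f"voxels above half maximum: {(smoothed.grid > 0.5).sum()}")
print("the hot spot sits at the deepest contacts, matching the rate table")
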