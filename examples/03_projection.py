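"""Project the hypercube to 3D and the 3D scene to stereo images."""

import numpy as np

from hyperrigid import (
    CameraParams,
    assess_rigidity,
    default_motion_spec,
    generate_trajectory,
    horizontal_disparity,
    make_hypercube,
    project_3d_to_stereo,
    project_4d_to_3d,
    project_trajectory_4d,
)

tesseract = make_hypercube(4, 100.0)
params = CameraParams()  # perspective 4D projection, 150 cm viewing distance

proj = project_4d_to_3d(tesseract.vertices, params)
outer = np.abs(proj[tesseract.vertices[:, 3] > 0]).max()
inner = np.abs(proj[tesseract.vertices[:, 3] < 0]).max()
print(f"4D perspective projection: outer cell half-size {outer:.1f} cm, "
      f"inner {inner:.1f} cm")
# The w = +50 cell projects larger than the w = -50 cell: the familiar
# nested-cube appearance of a tesseract.

rigid = generate_trajectory(
    tesseract, default_motion_spec(4, "rigid", jitter_amplitude=0.0), seed=3
)
report = assess_rigidity(project_trajectory_4d(rigid, params), tol=1e-3)
print(f"rigid 4D motion assessed in 3D after projection: "
      f"is_rigid={report.is_rigid}")
# Dimension reduction destroys rigidity: judging the hypercube's rigidity
# from its 3D projection requires recovering 4D structure.

left, right = project_3d_to_stereo(np.array([[0.0, 0.0, 30.0], [0.0, 0.0, -30.0]]))
d = horizontal_disparity(left, right)
print(f"stereo disparity (px): near point {d[0]:+.2f}, far point {d[1]:+.2f}")
# Points nearer than the fixation distance have positive disparity, points
# beyond it negative - the binocular depth cue delivered by the headset.
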