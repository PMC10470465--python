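"""Build cube and hypercube wireframes and apply the irregularity shift."""

import numpy as np

from hyperrigid import make_hypercube, perturb_vertices

cube = make_hypercube(3, side_length=100.0)
tesseract = make_hypercube(4, side_length=100.0)
print(f"cube:      {cube.n_vertices} vertices, {cube.n_edges} edges")
print(f"hypercube: {tesseract.n_vertices} vertices, {tesseract.n_edges} edges")
# A wireframe d-cube always has 2^d vertices and d*2^(d-1) edges; these are
# the stimulus objects of the rigidity-judgment task.

for level in (0.12, 0.18, 0.24):
    pert = perturb_vertices(tesseract, level, seed=42)
    shift = np.linalg.norm(pert.vertices - tesseract.vertices, axis=1)
    print(f"irregularity {level}: every vertex shifted by {shift.mean():.1f} cm "
          f"(spread {shift.std():.2e})")
# Each vertex moves by exactly level * side_length in a random 3D direction
# (the w coordinate of 4D objects is untouched), making the object irregular
# while keeping the perturbation magnitude controlled.
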