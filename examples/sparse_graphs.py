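"""Randomly sparsified cell networks with spatially clustered gaps.

A smooth Gaussian random field over the lattice sets per-node link-removal
probabilities (troughs of the field lose links, crests keep them), so the
removed links cluster into poorly connected regions instead of scattering.
Node "holes" remove the cells in the field's lowest decile altogether.
"""

import numpy as np

from cawave.graph import (build_dense_grid, link_removal_probabilities,
                          punch_holes, sample_gaussian_field, sparsify)

g0 = build_dense_grid(25, 25)
print(f"dense lattice: {g0.n_nodes} cells, {g0.n_edges} links")

field = sample_gaussian_field(25, 25, seed=7)
print(f"field correlation length c0 = {field.c0:.2f} lattice units")

for p in (0.5, 1.0):
    probs = link_removal_probabilities(field, p)
    g = sparsify(g0, probs, seed=11)
    frac = 100 * (1 - g.n_edges / g0.n_edges)
    print(f"removal scale p = {p}: {g.n_edges} links kept "
          f"({frac:.0f}% removed)")

holed = punch_holes(sparsify(g0, link_removal_probabilities(field, 1.0), seed=11),
                    field, 0.10)
print(f"with holes at the 10% field quantile: {holed.n_nodes} cells remain")
deg = holed.degrees()
print(f"degree range after sparsification: {deg.min()} - {deg.max()}")
# waves travel easily through densely linked regions and are deflected or
# blocked by the sparse ones.
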