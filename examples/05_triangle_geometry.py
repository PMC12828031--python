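"""Fluorophore triangle from pairwise FRET separations.

Three pairwise separations define the planar triangle formed by the three
fluorescent-protein barrels; its angles can be compared with barrel
centroids from a structural model.
"""

from cascadeflim import embed_triangle, triangle_from_separations

# pairwise separations (nm) extracted from FRET efficiencies
tri = triangle_from_separations(6.41, 7.21, 6.25, vertices=("N", "M", "C"))
for v, a in zip(tri.vertices, tri.angles_deg):
    print(f"angle at {v}: {a:6.2f} deg")
print(f"opening angle at the middle barrel: {tri.angle_at('M'):.2f} deg")
coords = embed_triangle(tri)
for v, p in coords.items():
    print(f"{v}: ({p[0]:.2f}, {p[1]:.2f}) nm")
# A well-formed triangle (no degenerate flag, angles summing to 180 deg)
# is consistent with a trigonal arrangement of the three barrels.
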