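"""Score one tissue patch's 16 tiles from raw nuclei centroids.

Builds a single 1792 px patch (20x) with a lymphocyte-rich upper-left
tile and a necrotic lower-right tile, then prints the per-tile labels
and the patch's three-feature vector.
"""

import numpy as np
import pandas as pd

from gpstils import classify_tile, count_tile, score_patches, tile_grid

rng = np.random.default_rng(0)


def scatter(n, cls, x_lo, x_hi, y_lo, y_hi):
    return pd.DataFrame({"slide_id": "S1",
                         "x": rng.uniform(x_lo, x_hi, n),
                         "y": rng.uniform(y_lo, y_hi, n),
                         "cell_class": cls})


nuclei = pd.concat([
    scatter(30, "neoplastic", 0, 448, 0, 448),      # tumour-cell-rich tile
    scatter(8, "lymphocyte", 0, 448, 0, 448),       # ... with infiltrate -> TILs
    scatter(12, "stromal", 448, 896, 0, 448),       # stroma-dominant tile
    scatter(6, "lymphocyte", 448, 896, 0, 448),     # ... with infiltrate -> sTILs
    scatter(20, "necrotic", 1344, 1792, 1344, 1792),  # necrotic corner
    scatter(5, "neoplastic", 1344, 1792, 1344, 1792),
], ignore_index=True)

print("tile  category  necrotic  n_total")
for i, bounds in enumerate(tile_grid(0, 0)):
    counts = count_tile(nuclei, bounds)
    label = classify_tile(counts)
    if counts.n_total:
        print(f"{i:4d}  {label.category:8s}  {str(label.necrotic_flag):8s}  {counts.n_total}")

patches = pd.DataFrame({"slide_id": ["S1"], "x0": [0], "y0": [0], "pattern": ["acinar"]})
print("\npatch vector (TILs, sTILs, necrotic tile counts):")
print(score_patches(nuclei, patches).to_string(index=False))
# One TILs tile (>=20 neoplastic, >=5 lymphocytes), one sTILs tile
# (>=5 lymphocytes, stromal > neoplastic) and one necrotic tile
# (>=15 necrotic nuclei); the 13 near-empty tiles are not considered.
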