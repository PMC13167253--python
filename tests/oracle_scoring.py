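"""Independent brute-force calcium scorer used as a cross-check oracle.

Pure-python flood fill, written without reference to the package's
component-labeling path: per slice and per artery label, 8-connected
regions of voxels >= the HU threshold are grown with an explicit stack,
regions under the pixel minimum are dropped, and Agatston/volume scores
are accumulated with the textbook formulas.
"""

from __future__ import annotations

import math

ARTERIES = {1: "RCA", 2: "LAD", 3: "LCX", 4: "LM"}
NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def weight_of(max_hu: float) -> int:
    if max_hu < 200:
        return 1
    if max_hu < 300:
        return 2
    if max_hu < 400:
        return 3
    return 4


def flood_fill_score(voxels, labels, pixel_spacing, slice_thickness,
                     threshold=130.0, min_pixels=3):
    """Return (lesions, per-artery agatston, per-artery volume score).

    ``lesions`` is a set of (artery, slice, pixel_count, max_hu) tuples.
    """
    n_slices, n_rows, n_cols = voxels.shape
    pixel_area = pixel_spacing[0] * pixel_spacing[1]
    voxel_volume = pixel_area * slice_thickness

    lesions = set()
    agatston = {a: 0.0 for a in ARTERIES.values()}
    volume = {a: 0.0 for a in ARTERIES.values()}
    ag_terms = {a: [] for a in ARTERIES.values()}
    px_counts = {a: 0 for a in ARTERIES.values()}

    for s in range(n_slices):
        seen = [[False] * n_cols for _ in range(n_rows)]
        for r0 in range(n_rows):
            for c0 in range(n_cols):
                lab = int(labels[s, r0, c0])
                if (seen[r0][c0] or lab == 0
                        or voxels[s, r0, c0] < threshold):
                    continue
                stack = [(r0, c0)]
                seen[r0][c0] = True
                members = []
                while stack:
                    r, c = stack.pop()
                    members.append((r, c))
                    for dr, dc in NEIGHBORS8:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < n_rows and 0 <= cc < n_cols
                                and not seen[rr][cc]
                                and int(labels[s, rr, cc]) == lab
                                and voxels[s, rr, cc] >= threshold):
                            seen[rr][cc] = True
                            stack.append((rr, cc))
                if len(members) < min_pixels:
                    continue
                artery = ARTERIES[lab]
                max_hu = max(float(voxels[s, r, c]) for r, c in members)
                lesions.add((artery, s, len(members), round(max_hu, 6)))
                ag_terms[artery].append(
                    len(members) * pixel_area * weight_of(max_hu)
                )
                px_counts[artery] += len(members)

    for a in ARTERIES.values():
        agatston[a] = math.fsum(ag_terms[a])
        volume[a] = px_counts[a] * voxel_volume
    return lesions, agatston, volume
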