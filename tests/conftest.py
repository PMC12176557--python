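import numpy as np
import pandas as pd
import pytest

import metresponse as mr


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 12-patient synthetic cohort (tables only)."""
    cfg = mr.CohortConfig(n_patients=12, seed=42)
    lesions, clinical, truth = mr.generate_cohort(cfg)
    return cfg, lesions, clinical, truth


def make_lesion_row(
    patient_id="A",
    timepoint="t0",
    site_code=5,
    lesion_index=1,
    volume_mm3=100.0,
    centroid=(0.0, 0.0, 0.0),
):
    return {
        "patient_id": patient_id,
        "timepoint": timepoint,
        "site_code": site_code,
        "lesion_index": lesion_index,
        "volume_mm3": volume_mm3,
        "x_mm": centroid[0],
        "y_mm": centroid[1],
        "z_mm": centroid[2],
    }


def lesion_frame(rows):
    return pd.DataFrame(rows)


def flood_fill_components(binary, connectivity=26):
    """Brute-force BFS flood fill, independent of scipy labelling."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    shape = binary.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            v = queue.pop()
            comp.append(v)
            for d in offsets:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[ax] < shape[ax] for ax in range(3)):
                    if binary[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
        comps.append(sorted(comp))
    return comps
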