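"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mpam.extinction import load_extinction_table


@pytest.fixture(scope="session")
def ext():
    return load_extinction_table()


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def perpendicular_profile_diameter(
    mask: np.ndarray, centerline: np.ndarray, n_points: int = 20, step: float = 0.05
) -> float:
    """Mean full-width-half-maximum of mask profiles normal to the centerline.

    At ``n_points`` interior centerline samples, the binary mask is sampled
    along the local normal with bilinear interpolation; the width is the
    distance between the outward half-maximum (0.5) crossings on each side.
    Bilinear sampling averages the staircase boundary, making this the
    profile-FWHM width oracle, independent of any distance transform.
    """
    from scipy.ndimage import map_coordinates

    path = centerline.astype(float)
    if len(path) < 5:
        raise ValueError("centerline too short for a profile oracle")
    lo, hi = int(0.2 * len(path)), int(0.8 * len(path))
    idx = np.linspace(lo, hi - 1, n_points).astype(int)
    img = mask.astype(float)
    chords = []
    for i in idx:
        a = path[max(i - 3, 0)]
        b = path[min(i + 3, len(path) - 1)]
        tang = b - a
        norm = np.linalg.norm(tang)
        if norm == 0:
            continue
        tang /= norm
        normal = np.array([-tang[1], tang[0]])
        extents = []
        for sign in (+1.0, -1.0):
            dist = 0.0
            while True:
                p = path[i] + sign * (dist + step) * normal
                val = map_coordinates(img, [[p[0]], [p[1]]], order=1, cval=0.0)[0]
                if val < 0.5:
                    break
                dist += step
            extents.append(dist)
        chords.append(extents[0] + extents[1])
    return float(np.mean(chords))


def spreadsheet_oef_mro2(rows: list[dict]) -> tuple[float, float, float, float]:
    """Plain-arithmetic recomputation of saO2/svO2/OEF/MRO2 from table rows.

    Flow-weighted class means computed with explicit loops, no numpy/pandas.
    """
    def weighted_mean(cls):
        num = den = 0.0
        for r in rows:
            if r["class"] == cls:
                num += r["so2"] * r["flow_ul_min"]
                den += r["flow_ul_min"]
        return num / den

    sao2 = weighted_mean("arterial")
    svo2 = weighted_mean("venous")
    oef = (sao2 - svo2) / sao2
    inflow = sum(r["flow_ul_min"] for r in rows if r["class"] == "arterial")
    return sao2, svo2, oef, inflow * oef
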