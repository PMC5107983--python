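import numpy as np
import pytest


@pytest.fixture
def disk_mask():
    """Dense rasterized disk, diameter 129 px: the ideal-circle anchor."""
    n = 129
    y, x = np.mgrid[:n, :n]
    c = (n - 1) / 2.0
    return ((y - c) ** 2 + (x - c) ** 2) <= (n / 2.0) ** 2


@pytest.fixture
def dumbbell_mask():
    """Two equal disks bridged by a thin neck (mitotic-pair lookalike)."""
    m = np.zeros((40, 70), dtype=bool)
    y, x = np.mgrid[:40, :70]
    m |= (y - 20) ** 2 + (x - 18) ** 2 <= 12**2
    m |= (y - 20) ** 2 + (x - 52) ** 2 <= 12**2
    m[19:22, 18:52] = True
    return m


@pytest.fixture
def qc_scene_placements():
    """Five clean objects plus one of each plantable QC violation."""
    return [
        {"template": "circle", "center": (120, 120), "size": 56},
        {"template": "ellipse", "center": (120, 300), "size": 56},
        {"template": "L", "center": (120, 500), "size": 56},
        {"template": "cross", "center": (300, 120), "size": 56},
        {"template": "circle", "center": (300, 300), "size": 64},
        {"template": "circle", "center": (30, 400), "qc_violation": "border"},
        {"center": (500, 120), "qc_violation": "too_small"},
        {"center": (480, 320), "qc_violation": "too_big"},
        {"center": (300, 520), "qc_violation": "mitotic_pair"},
        {"center": (520, 520), "qc_violation": "full_bbox"},
    ]
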