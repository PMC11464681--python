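"""Synthetic ROI definition table and reference network partition.

The analysis operates on 37 regions of interest (4 mm spheres in MNI space)
drawn from delay-period activations in visual-working-memory experiments,
which group into six intrinsic networks: a left prefrontal-occipital network
(N1), a dorsal attention network (N2, the largest), a right frontoparietal
control network (N3), an angular-gyrus-cerebellar network (N4), a
cingulo-opercular network (N5, second largest), and a frontal-opercular
network (N6).

The coordinates below are a SYNTHETIC stand-in: labels and approximate MNI
positions drafted from the anatomical descriptions of those networks, not
measured peaks. They serve as fixture anatomy for the clustering's
anatomical-proximity term (which carries only 5% weight by default) and for
end-to-end runs on generated data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["synthetic_roi_table", "reference_partition", "NETWORK_SIZES"]

#: ROIs per network N1..N6
NETWORK_SIZES = (3, 11, 4, 4, 10, 5)

_ROIS = [
    # N1 — left prefrontal-occipital
    ("L_SFG", -22, 8, 58, 1),
    ("L_MFG", -40, 28, 32, 1),
    ("L_MOG", -30, -84, 16, 1),
    # N2 — dorsal attention
    ("L_IPS_a", -28, -58, 48, 2),
    ("L_IPS_b", -36, -46, 44, 2),
    ("R_IPS_a", 30, -56, 50, 2),
    ("R_IPS_b", 38, -44, 46, 2),
    ("L_IFJ", -44, 4, 32, 2),
    ("L_precuneus", -10, -66, 52, 2),
    ("R_precuneus", 10, -64, 54, 2),
    ("R_FEF", 28, -4, 52, 2),
    ("R_ITG", 52, -58, -12, 2),
    ("L_SPL", -20, -66, 56, 2),
    ("R_SPL", 20, -64, 58, 2),
    # N3 — right frontoparietal control
    ("R_MFG", 42, 34, 30, 3),
    ("R_IFG_tri", 48, 28, 22, 3),
    ("R_IFG_oper", 50, 14, 20, 3),
    ("R_SMG", 54, -40, 40, 3),
    # N4 — angular-gyrus-cerebellar
    ("L_AG", -44, -62, 36, 4),
    ("R_AG", 48, -60, 34, 4),
    ("L_Cereb_CrusI", -34, -70, -30, 4),
    ("L_Cereb_VII", -28, -72, -42, 4),
    # N5 — cingulo-opercular
    ("L_SMA", -6, 4, 58, 5),
    ("R_SMA", 8, 6, 56, 5),
    ("L_aInsula", -32, 22, 2, 5),
    ("R_aInsula", 34, 22, 2, 5),
    ("dmSFG", 0, 22, 46, 5),
    ("ACC", 2, 30, 28, 5),
    ("MCC", 0, 10, 36, 5),
    ("L_striatum", -14, 8, 6, 5),
    ("R_striatum", 14, 10, 6, 5),
    ("L_Cereb_VI", -26, -60, -26, 5),
    # N6 — frontal-opercular
    ("L_IFG_orb", -44, 32, -8, 6),
    ("R_IFG_orb", 46, 32, -8, 6),
    ("R_precentral", 52, 2, 38, 6),
    ("R_Rolandic", 52, -4, 12, 6),
    ("R_Heschl", 48, -16, 8, 6),
]


def synthetic_roi_table() -> pd.DataFrame:
    """37-ROI table: ``label, x_mm, y_mm, z_mm`` (synthetic coordinates)."""
    return pd.DataFrame(
        [(lab, x, y, z) for lab, x, y, z, _ in _ROIS],
        columns=["label", "x_mm", "y_mm", "z_mm"],
    )


def reference_partition() -> np.ndarray:
    """Ground-truth community label (1..6) per ROI, aligned with the table."""
    return np.array([net for *_, net in _ROIS], dtype=int)
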