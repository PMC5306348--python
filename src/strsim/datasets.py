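"""Small published reference inputs.

The degraded-tissue quantification table below is the published
dual-target qPCR result set for nine degraded tissue samples measured
with two commercial kits: Quantifiler Trio (QT; 80 bp small / 214 bp
large autosomal targets) and PowerQuant (PQ; 84 bp / 294 bp).
Concentrations are in ng/µl as printed; one PQ large-target value is
missing (below the assay range).  These pairs are the canonical input
for degradation-index and per-bp degradation estimation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "QT_TARGETS",
    "PQ_TARGETS",
    "degraded_tissue_quants",
]

#: (small, large) autosomal amplicon lengths in bp.
QT_TARGETS = (80, 214)
PQ_TARGETS = (84, 294)

_ROWS = [
    # sample, qt_small, qt_large, pq_small, pq_large
    ("D1", 119.710, 83.6300, 127.850, 27.7100),
    ("D2", 0.058, 0.0009, 0.003, np.nan),
    ("D3", 45.605, 1.5170, 59.950, 1.8600),
    ("D4", 0.437, 0.1357, 0.547, 0.0540),
    ("D5", 0.256, 0.0111, 0.333, 0.0042),
    ("D6", 0.098, 0.0079, 0.119, 0.0024),
    ("D7", 0.284, 0.0036, 0.292, 0.0034),
    ("D8", 1.437, 0.0900, 1.712, 0.0859),
    ("D9", 31.510, 0.0565, 55.710, 0.0077),
]


def degraded_tissue_quants() -> pd.DataFrame:
    """Dual-target concentrations for the nine degraded tissue samples.

    Long format: one row per (sample, kit) with columns ``sample_id``,
    ``kit_label``, ``c_small``, ``c_large``, ``x_small``, ``x_large``.
    Pairs with a missing concentration are omitted.
    """
    rows = []
    for sample, qt_s, qt_l, pq_s, pq_l in _ROWS:
        if np.isfinite(qt_s) and np.isfinite(qt_l):
            rows.append((sample, "QT", qt_s, qt_l, *QT_TARGETS))
        if np.isfinite(pq_s) and np.isfinite(pq_l):
            rows.append((sample, "PQ", pq_s, pq_l, *PQ_TARGETS))
    return pd.DataFrame(
        rows, columns=["sample_id", "kit_label", "c_small", "c_large", "x_small", "x_large"]
    )
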