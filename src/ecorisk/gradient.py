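"""Urban-rural gradient classification from two-epoch nighttime-light DN.

A cell is developed urban when its DN exceeds the threshold (default 50) in
both epochs, suburban when it crosses the threshold between epochs, and
rural when it stays below in both. The unstated bright-to-dark case is
mapped to rural and counted in a logged warning.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional

import numpy as np

log = logging.getLogger(__name__)

URBAN = 1
SUBURBAN = 2
RURAL = 3

GRADIENT_NAMES = {URBAN: "urban", SUBURBAN: "suburban", RURAL: "rural"}


class GradientError(ValueError):
    pass


def classify_gradient(
    dn_t0: np.ndarray,
    dn_t1: np.ndarray,
    threshold: float = 50.0,
    strict: bool = True,
) -> np.ndarray:
    """Classify each cell into urban (1), suburban (2) or rural (3).

    ``strict`` reads "more than" as a strict inequality (> threshold); set
    False for >=. Cells bright at t0 but dark at t1 are classified rural and
    their count is logged as a warning.
    """
    a = np.asarray(dn_t0, dtype=float)
    b = np.asarray(dn_t1, dtype=float)
    if a.shape != b.shape:
        raise GradientError(f"shape mismatch: {a.shape} vs {b.shape}")
    if strict:
        hi0, hi1 = a > threshold, b > threshold
    else:
        hi0, hi1 = a >= threshold, b >= threshold
    out = np.full(a.shape, RURAL, dtype=np.uint8)
    out[hi0 & hi1] = URBAN
    out[~hi0 & hi1] = SUBURBAN
    reversed_cells = int(np.count_nonzero(hi0 & ~hi1))
    if reversed_cells:
        log.warning(
            "%d cell(s) above the DN threshold at t0 but not t1; classified rural",
            reversed_cells,
        )
    return out


def unit_gradient_class(cell_classes: np.ndarray, unit_id: np.ndarray) -> np.ndarray:
    """Majority gradient class per assessing unit (ties -> the more urban).

    Returns a vector indexed by unit (1-based unit ids, element u-1 is unit
    u). The more-urban tie rule works because codes order urban < suburban
    < rural.
    """
    if cell_classes.shape != unit_id.shape:
        raise GradientError("cell class grid and unit grid differ in shape")
    n_units = int(unit_id.max())
    lab = unit_id.ravel()
    cls = cell_classes.ravel()
    out = np.empty(n_units, dtype=np.uint8)
    for u in range(1, n_units + 1):
        counts = np.bincount(cls[lab == u], minlength=RURAL + 1)[1:]
        out[u - 1] = int(np.argmax(counts)) + 1  # argmax takes first (more urban) tie
    return out


def gradient_means(
    values: np.ndarray,
    classes: np.ndarray,
) -> Dict[str, Optional[float]]:
    """Arithmetic mean of ``values`` within each gradient class.

    Classes with no members are reported as None (missing), never zero.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(classes)
    if v.shape != c.shape:
        raise GradientError("values and classes are not aligned")
    if v.size == 0:
        raise GradientError("empty input")
    out: Dict[str, Optional[float]] = {}
    for code, name in GRADIENT_NAMES.items():
        sel = c == code
        out[name] = float(v[sel].mean()) if sel.any() else None
    return out
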