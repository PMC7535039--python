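"""ROI algebra: recurrent / non-recurrent habitat partition and in-field rule.

The recurrent habitat is the recurrence volume (GTVr) mapped back onto the
pre-treatment image; the non-recurrent habitat is the remainder of the
gross tumor volume, GTV − GTVr.  A recurrence is "in field" when at least
95% of GTVr lies inside the 95% isodose region of the delivered plan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import ROIMask

log = logging.getLogger(__name__)

#: Fraction of GTVr that must sit inside the 95% isodose for an in-field call.
INFIELD_THRESHOLD = 0.95


class UnusableSubjectError(ValueError):
    """A subject whose habitat partition is degenerate (e.g. empty GTVnr)."""


def _check_same_grid(a: ROIMask, b: ROIMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")


def subtract_mask(a: ROIMask, b: ROIMask, role: str = "GTVnr") -> ROIMask:
    """Voxelwise set difference a − b (1 where a=1 and b=0)."""
    _check_same_grid(a, b)
    return ROIMask(data=a.data & ~b.data, role=role)


def overlap_fraction(inner: ROIMask, outer: ROIMask) -> float:
    """|inner ∩ outer| / |inner|."""
    _check_same_grid(inner, outer)
    n = inner.voxel_count
    if n == 0:
        raise ValueError("inner mask is empty")
    return int(np.count_nonzero(inner.data & outer.data)) / n


def classify_infield(gtvr: ROIMask, isodose95: ROIMask) -> bool:
    """True iff overlap_fraction(gtvr, isodose95) >= 0.95 (inclusive)."""
    return overlap_fraction(gtvr, isodose95) >= INFIELD_THRESHOLD


@dataclass
class HabitatPair:
    """The recurrent and non-recurrent habitats of one subject's tumor."""

    recurrent: ROIMask
    nonrecurrent: ROIMask
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.recurrent.shape != self.nonrecurrent.shape:
            raise ValueError("habitat masks live on different grids")
        if np.any(self.recurrent.data & self.nonrecurrent.data):
            raise ValueError("habitats overlap")


def make_habitats(gtv: ROIMask, gtvr: ROIMask, subject_id: str = "") -> HabitatPair:
    """Partition the GTV into recurrent (GTVr ∩ GTV) and non-recurrent (GTV − GTVr).

    GTVr voxels outside the GTV are clipped into the recurrent habitat
    rather than rejected (the recurrence contour is drawn on a different
    scan and copied over, so small excursions are expected); a warning is
    emitted when clipping happens.  An empty non-recurrent habitat makes
    the subject unusable for the paired analysis.
    """
    _check_same_grid(gtv, gtvr)
    rec_data = gtvr.data & gtv.data
    if rec_data.sum() == 0:
        raise UnusableSubjectError(f"subject {subject_id!r}: GTVr does not intersect GTV")
    n_outside = int(np.count_nonzero(gtvr.data & ~gtv.data))
    if n_outside:
        msg = (
            f"subject {subject_id!r}: {n_outside} GTVr voxels fall outside GTV; "
            "clipped to the GTV for the recurrent habitat"
        )
        warnings.warn(msg, stacklevel=2)
        log.warning(msg)
    nonrec = subtract_mask(gtv, gtvr, role="GTVnr")
    if nonrec.voxel_count == 0:
        raise UnusableSubjectError(
            f"subject {subject_id!r}: non-recurrent habitat is empty (GTVr covers GTV)"
        )
    return HabitatPair(
        recurrent=ROIMask(data=rec_data, role="GTVr"),
        nonrecurrent=nonrec,
        subject_id=subject_id,
    )
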