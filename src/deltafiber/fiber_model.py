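"""Additive architecture model for pentameric δ-like fibers.

The fiber is modelled as a stack of rigid components along its axis:
an N-terminal region of known length (crystallographically determined),
``n`` additional β-bracelet segments of fixed height, an internal
globular domain, and a C-terminal globular head, each contributing its
length/diameter additively.  The model predicts total fiber length,
inverts to a segment count given a measured length, and compares the
residue economy of the bracelet fold against other viral β-fiber folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "FiberArchitecture",
    "FoldClassGeometry",
    "FOLD_CLASSES",
    "SegmentCountEstimate",
    "predict_length",
    "infer_segment_count",
    "residues_per_height",
]

#: Default height of one β-bracelet segment (Å): the crystal rise,
#: 75 Å per five repeats.
DEFAULT_SEGMENT_HEIGHT = 15.0


@dataclass(frozen=True)
class FiberArchitecture:
    """Component lengths (Å) and the extra-segment count of one fiber."""

    l_crystal_region: float
    n_extra_segments: int
    h_segment: float = DEFAULT_SEGMENT_HEIGHT
    d_internal: float = 0.0
    d_head: float = 0.0

    def __post_init__(self) -> None:
        for name in ("l_crystal_region", "h_segment", "d_internal", "d_head"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_extra_segments < 0:
            raise ValueError("n_extra_segments must be >= 0")


@dataclass(frozen=True)
class FoldClassGeometry:
    """Per-chain residue cost of one axial unit for a fiber fold class."""

    fold: str
    chains: int
    residues_per_unit_per_chain: int
    unit_height: float

    def __post_init__(self) -> None:
        if self.chains not in (1, 3, 5):
            raise ValueError("chains must be 1, 3 or 5")
        if self.residues_per_unit_per_chain < 1:
            raise ValueError("residues_per_unit_per_chain must be >= 1")
        if self.unit_height <= 0:
            raise ValueError("unit_height must be > 0")


#: Registered fold classes: per-chain residues needed for one 15-Å unit.
FOLD_CLASSES: dict[str, FoldClassGeometry] = {
    "beta-bracelet": FoldClassGeometry("beta-bracelet", 5, 8, 15.0),
    "beta-spiral": FoldClassGeometry("beta-spiral", 3, 17, 15.0),
    "triple-beta-helix": FoldClassGeometry("triple-beta-helix", 3, 31, 15.0),
}


@dataclass(frozen=True)
class SegmentCountEstimate:
    n_real: float
    n_rounded: int
    warning: str | None = None


def predict_length(arch: FiberArchitecture) -> float:
    """Total fiber length (Å) from the additive component model."""
    return (arch.l_crystal_region
            + arch.n_extra_segments * arch.h_segment
            + arch.d_internal
            + arch.d_head)


def infer_segment_count(observed_length: float,
                        arch_without_n: FiberArchitecture) -> SegmentCountEstimate:
    """Invert the length model: segments implied by a measured length.

    Returns both the real-valued count and its nearest integer; a
    measured length shorter than the fixed components yields a negative
    count with a warning rather than an exception, since EM length
    distributions legitimately extend below the model floor.
    """
    if arch_without_n.h_segment <= 0:
        raise ValueError("h_segment must be > 0")
    fixed = (arch_without_n.l_crystal_region + arch_without_n.d_internal
             + arch_without_n.d_head)
    n = (observed_length - fixed) / arch_without_n.h_segment
    warning = None
    if n < 0:
        warning = ("observed length is shorter than the fixed components; "
                   "segment count is negative")
    return SegmentCountEstimate(n_real=n, n_rounded=round(n), warning=warning)


def residues_per_height(fold: FoldClassGeometry | str,
                        target_height: float) -> int:
    """Residues per chain needed to build ``target_height`` Å of fiber.

    Whole axial units are counted (a partial unit still costs a full
    unit's residues).  Built-in fold classes may be named by string.
    """
    if isinstance(fold, str):
        try:
            fold = FOLD_CLASSES[fold]
        except KeyError:
            raise ValueError(
                f"unknown fold {fold!r}; registered: {sorted(FOLD_CLASSES)}"
            ) from None
    if target_height <= 0:
        raise ValueError("target_height must be > 0")
    units = math.ceil(target_height / fold.unit_height - 1e-9)
    return units * fold.residues_per_unit_per_chain


def with_segments(arch: FiberArchitecture, n: int) -> FiberArchitecture:
    """Convenience: the same architecture with a different segment count."""
    return replace(arch, n_extra_segments=n)
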