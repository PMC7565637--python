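"""Assembly-state calculators: intact masses, gel densitometry, EM counts.

Three independent lines of evidence about how a δ-like fiber assembles
and incorporates into virions are quantified here:

* oligomeric order from a deconvolved intact (native) mass;
* fibers per capsid from Western-blot band densitometry of the capsid
  protein (CP) and the CP-δ read-through fusion, under a T=3 icosahedral
  lattice with 180 subunit positions and a pentameric fiber;
* particle statistics from negative-stain EM (fiber-bearing fraction
  and fiber-length distribution).

Band intensity is assumed proportional to protein *mass*, so molar
ratios divide intensities by molecular weight before use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "OligomerAssignment",
    "StoichiometryEstimate",
    "ParticleStats",
    "assign_oligomer_state",
    "peak_deviation",
    "estimate_fiber_stoichiometry",
    "particle_stats",
]


@dataclass(frozen=True)
class OligomerAssignment:
    observed_mass: float
    monomer_mass: float
    k: int
    theoretical_mass: float
    delta: float  # observed - theoretical, Da
    percent_dev: float  # |delta| / theoretical, %


@dataclass(frozen=True)
class StoichiometryEstimate:
    fibers_per_capsid: float
    sd: float | None
    per_replicate: tuple[float, ...]
    total_subunits: int
    fiber_order: int
    warning: str | None = None


@dataclass(frozen=True)
class ParticleStats:
    n_total: int
    n_with_fiber: int
    fraction: float  # %
    length_mean: float | None
    length_sd: float | None
    n_lengths: int


def assign_oligomer_state(observed_mass: float, monomer_mass: float,
                          k_max: int = 8) -> OligomerAssignment:
    """Assign the multimer order whose theoretical mass is nearest.

    Ties break toward the smaller k (parsimony).  An observed mass below
    half a monomer admits no valid state and is an error.
    """
    if observed_mass <= 0 or monomer_mass <= 0:
        raise ValueError("masses must be > 0")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if observed_mass < monomer_mass / 2:
        raise ValueError(
            f"observed mass {observed_mass} Da is below half a monomer "
            f"({monomer_mass} Da); no valid oligomeric state")
    k = min(range(1, k_max + 1),
            key=lambda kk: (abs(observed_mass - kk * monomer_mass), kk))
    theo = k * monomer_mass
    delta = observed_mass - theo
    return OligomerAssignment(observed_mass=observed_mass,
                              monomer_mass=monomer_mass, k=k,
                              theoretical_mass=theo, delta=delta,
                              percent_dev=round(100.0 * abs(delta) / theo, 2))


def peak_deviation(peak_mass: float, reference_mass: float) -> tuple[float, float]:
    """(delta Da, percent deviation to 2 decimals) of a peak vs a reference."""
    if reference_mass <= 0:
        raise ValueError("reference_mass must be > 0")
    delta = peak_mass - reference_mass
    return delta, round(100.0 * abs(delta) / reference_mass, 2)


def estimate_fiber_stoichiometry(
    replicates: Iterable[tuple[float, float]],
    mw_cp: float,
    mw_cpdelta: float,
    total_subunits: int = 180,
    fiber_order: int = 5,
) -> StoichiometryEstimate:
    """Fibers per capsid from (I_CP, I_CP-δ) band-intensity replicates.

    Per replicate the molar ratio r = (I_CPδ/MW_CPδ)/(I_CP/MW_CP) gives
    CP-δ copies per particle = total_subunits · r/(1+r) (CP-δ occupies
    lattice positions in place of CP), and fibers = copies/fiber_order.
    The mean and sample sd across replicates are reported.  A replicate
    with I_CP = 0 but CP-δ signal saturates at the lattice maximum.
    """
    if mw_cp <= 0 or mw_cpdelta <= 0:
        raise ValueError("molecular weights must be > 0")
    reps = list(replicates)
    if not reps:
        raise ValueError("need at least one replicate")
    fibers = []
    warning = None
    cap = total_subunits / fiber_order
    for i_cp, i_cpd in reps:
        if i_cp < 0 or i_cpd < 0:
            raise ValueError("intensities must be >= 0")
        if i_cp == 0:
            if i_cpd > 0:
                fibers.append(cap)
                warning = ("replicate with zero CP intensity: estimate "
                           "saturated at the lattice maximum")
            else:
                raise ValueError("replicate with no signal in either band")
            continue
        r = (i_cpd / mw_cpdelta) / (i_cp / mw_cp)
        copies = total_subunits * r / (1.0 + r)
        fibers.append(copies / fiber_order)
    arr = np.asarray(fibers)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else None
    return StoichiometryEstimate(fibers_per_capsid=float(arr.mean()), sd=sd,
                                 per_replicate=tuple(float(f) for f in arr),
                                 total_subunits=total_subunits,
                                 fiber_order=fiber_order, warning=warning)


def particle_stats(n_total: int, n_with_fiber: int,
                   lengths: Sequence[float] = ()) -> ParticleStats:
    """Fiber-bearing fraction (%) and fiber-length mean/sd (sample sd)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_with_fiber <= n_total:
        raise ValueError("n_with_fiber must lie in [0, n_total]")
    lengths = np.asarray(list(lengths), dtype=float)
    if lengths.size and not np.all(np.isfinite(lengths)):
        raise ValueError("lengths must be finite")
    mean = float(lengths.mean()) if lengths.size else None
    sd = float(lengths.std(ddof=1)) if lengths.size > 1 else None
    return ParticleStats(n_total=n_total, n_with_fiber=n_with_fiber,
                         fraction=100.0 * n_with_fiber / n_total,
                         length_mean=mean, length_sd=sd,
                         n_lengths=int(lengths.size))
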