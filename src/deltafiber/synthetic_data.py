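"""Ground-truth-labelled generators for every stage of the pipeline.

Each generator emits an artifact (sequence, coordinate set, peak list,
intensity table, length sample) together with a ``truth`` record of the
planted parameters, so downstream modules can be tested for parameter
recovery without any external data.  All generators are deterministic
given (seed, parameters).

What is emulated — and what is not: the sequences carry exact planted
consensus repeats with guaranteed-non-matching flanks (real flanking
domains merely tend not to match); the pentamer coordinates are exactly
C5-symmetric idealized Cα traces (optionally with a non-physical
pseudo-backbone so the H-bond census has atoms to count); mass peaks,
gel intensities and EM lengths are simple parametric noise models of
the corresponding measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .geometry import Chain, PentamerModel, Residue

__all__ = [
    "gen_repeat_sequence",
    "gen_pentamer_coords",
    "write_pentamer_pdb",
    "gen_mass_peaks",
    "gen_gel_intensities",
    "gen_em_lengths",
]

# residues that belong to no anchor or loop class: a sequence drawn from
# this pool can never satisfy a repeat's P1/P4 anchors
NONMATCHING_POOL = "GSTNQP"
X_POOL = "GSTNQ"  # small/polar filler for unconstrained strand positions
CC_HEPTAD = "LAALQSA"  # a/d = L, no charged residues (no loop-flank hits)

STRICT_LOOP_FLANK = "DEKR"
STRICT_LOOP_MIDDLE = "EDN"
RELAXED_LOOP_MIDDLE_ONLY = "QST"  # relaxed loop middles that are not strict


def _strict_unit(rng: np.random.Generator) -> str:
    p1 = rng.choice(list("VL"))
    x = rng.choice(list(X_POOL), size=3)
    p6 = rng.choice(list(STRICT_LOOP_FLANK))
    p7 = rng.choice(list(STRICT_LOOP_MIDDLE))
    p8 = rng.choice(list(STRICT_LOOP_FLANK))
    return f"{p1}{x[0]}{x[1]}V{x[2]}{p6}{p7}{p8}"


def _relaxed_unit(rng: np.random.Generator) -> str:
    # anchors hydrophobic but outside the strict classes, loop middle
    # from the relaxed-only set: matches relaxed mode, never strict
    p1 = rng.choice(list("IMF"))
    p4 = rng.choice(list("AI"))
    x = rng.choice(list(X_POOL), size=3)
    p6 = rng.choice(list(STRICT_LOOP_FLANK))
    p7 = rng.choice(list(RELAXED_LOOP_MIDDLE_ONLY))
    p8 = rng.choice(list(STRICT_LOOP_FLANK))
    return f"{p1}{x[0]}{x[1]}{p4}{x[2]}{p6}{p7}{p8}"


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NONMATCHING_POOL), size=n)) if n else ""


def gen_repeat_sequence(
    n_strict: int,
    n_relaxed: int,
    domain_lengths: dict[str, int] | None = None,
    seed: int = 0,
    max_run: int = 4,
    linker_length: int = 8,
    seq_id: str = "synthetic_delta",
) -> tuple[SeqRecord, dict]:
    """A δ-like sequence with planted bracelet repeats and labelled domains.

    Layout N→C: an ideal-heptad coiled-coil stub (``cc`` residues),
    ``n_strict`` tandem strict repeats, a non-matching spacer
    (``spacer``), ``n_relaxed`` relaxed repeats laid out in runs of at
    most ``max_run`` separated by ``linker_length``-residue non-matching
    linkers, and a non-matching tail (``tail``).  Spacer/linker/tail
    residues are drawn from a pool containing no anchor-class residue,
    so no unplanted repeat can match.  The truth record lists every
    planted repeat start and the domain boundaries (1-based inclusive).
    """
    dl = {"cc": 0, "spacer": 0, "tail": 0}
    dl.update(domain_lengths or {})
    if n_strict < 0 or n_relaxed < 0:
        raise ValueError("repeat counts must be >= 0")
    if any(v < 0 for v in dl.values()):
        raise ValueError("domain lengths must be >= 0")
    rng = np.random.default_rng(seed)

    parts: list[str] = []
    pos = 1

    cc_len = dl["cc"]
    cc_seq = (CC_HEPTAD * math.ceil(cc_len / 7))[:cc_len]
    cc_range = (1, cc_len) if cc_len else None
    parts.append(cc_seq)
    pos += cc_len

    strict_starts = [pos + 8 * i for i in range(n_strict)]
    parts.extend(_strict_unit(rng) for _ in range(n_strict))
    pos += 8 * n_strict
    b1 = (strict_starts[0], pos - 1) if n_strict else None

    spacer_len = dl["spacer"]
    parts.append(_filler(rng, spacer_len))
    ig = (pos, pos + spacer_len - 1) if (spacer_len and n_strict and n_relaxed) else None
    pos += spacer_len

    relaxed_starts: list[int] = []
    b2_start = pos if n_relaxed else None
    remaining = n_relaxed
    while remaining > 0:
        run = min(max_run, remaining)
        for i in range(run):
            relaxed_starts.append(pos + 8 * i)
        parts.extend(_relaxed_unit(rng) for _ in range(run))
        pos += 8 * run
        remaining -= run
        if remaining > 0:
            parts.append(_filler(rng, linker_length))
            pos += linker_length
    b2 = (b2_start, pos - 1) if n_relaxed else None

    tail_len = dl["tail"]
    parts.append(_filler(rng, tail_len))
    ct = (pos, pos + tail_len - 1) if tail_len else None
    pos += tail_len

    seq = "".join(parts)
    if not seq:
        raise ValueError("all domain lengths and repeat counts are zero: empty sequence")

    truth = {
        "seed": seed,
        "length": len(seq),
        "strict_starts": strict_starts,
        "relaxed_starts": relaxed_starts,
        "domains": {
            "coiled_coil": cc_range,
            "bracelet_region_1": b1,
            "internal_globular": ig,
            "bracelet_region_2": b2,
            "c_terminal_globular": ct,
        },
    }
    record = SeqRecord(Seq(seq), id=seq_id,
                       description=f"synthetic delta-like sequence seed={seed}")
    return record, truth


def gen_pentamer_coords(
    n_repeats: int,
    rise: float = 15.0,
    tilt: float = 45.0,
    strand_radius: float = 6.0,
    loop_radius: float = 9.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    ca_spacing: float = 1.5,
    backbone: bool = False,
    cb_direction: str | None = None,
) -> tuple[PentamerModel, dict]:
    """An idealized C5 pentamer: Cα coordinates with planted geometry.

    Five chains related by exact 72° rotations about ẑ.  Each repeat
    contributes five strand Cα placed on a cylinder geodesic of radius
    ``strand_radius`` whose tangent makes ``tilt`` degrees with the
    axis (so every strand atom sits at exactly the planted radius), and
    three loop Cα at ``loop_radius``.  Consecutive repeats are identical
    patterns offset axially by ``rise``, so centroid spacing equals the
    planted rise exactly before noise.  Optional isotropic Gaussian
    noise; optional non-physical pseudo-backbone (N, C, O) so the
    hydrogen-bond census has atoms to operate on; optional Cβ atoms
    placed radially ``cb_direction`` = 'inward' or 'outward' for
    side-chain orientation tests.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if strand_radius <= 0 or loop_radius <= 0:
        raise ValueError("radii must be > 0")
    rng = np.random.default_rng(seed)
    theta = math.radians(tilt)
    res_names = ["VAL", "SER", "THR", "VAL", "SER", "LYS", "GLU", "ASP"]

    # local (radius, phi-offset, z-offset) template for one repeat
    template: list[tuple[float, float, float]] = []
    for k in range(5):  # strand: geodesic on the strand cylinder
        s = (k - 2) * ca_spacing
        template.append((strand_radius,
                         s * math.sin(theta) / strand_radius,
                         rise / 2 + s * math.cos(theta)))
    strand_top = rise / 2 + 2 * ca_spacing * math.cos(theta)
    loop_step = (rise - 4 * ca_spacing * math.cos(theta)) / 4
    phi_top = 2 * ca_spacing * math.sin(theta) / strand_radius
    for j in range(3):  # loop: bulge ring between strand stacks
        template.append((loop_radius,
                         phi_top + 0.25 * (j + 1),
                         strand_top + loop_step * (j + 1)))

    chains = []
    for c in range(5):
        base = 2 * math.pi * c / 5
        residues = []
        ca_list = []
        for i in range(n_repeats):
            for k, (r, dphi, dz) in enumerate(template):
                phi = base + dphi
                ca_list.append(np.array([r * math.cos(phi), r * math.sin(phi),
                                         i * rise + dz]))
        for idx, ca in enumerate(ca_list):
            atoms = {"CA": ca.copy()}
            if cb_direction is not None:
                if cb_direction not in ("inward", "outward"):
                    raise ValueError("cb_direction must be 'inward' or 'outward'")
                rad = np.array([ca[0], ca[1], 0.0])
                rad = rad / max(np.linalg.norm(rad), 1e-9)
                sign_cb = -1.0 if cb_direction == "inward" else 1.0
                atoms["CB"] = ca + 1.53 * sign_cb * rad
            if backbone:
                nxt = ca_list[idx + 1] if idx + 1 < len(ca_list) else ca_list[idx - 1]
                e = nxt - ca
                e = e / np.linalg.norm(e)
                sign = 1.0 if idx + 1 < len(ca_list) else -1.0
                rad = np.array([ca[0], ca[1], 0.0])
                rad = rad / max(np.linalg.norm(rad), 1e-9)
                atoms["N"] = ca - 1.2 * sign * e
                atoms["C"] = ca + 1.2 * sign * e
                atoms["O"] = ca + 1.2 * sign * e + 1.23 * rad
            residues.append(Residue(idx + 1, res_names[idx % 8], atoms))
        chains.append(Chain("ABCDE"[c], residues))

    if noise_sd > 0:
        for ch in chains:
            for res in ch.residues:
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + rng.normal(0, noise_sd, 3)

    model = PentamerModel(chains, source=f"gen_pentamer_coords(seed={seed})")
    truth = {
        "seed": seed,
        "n_repeats": n_repeats,
        "axis_point": [0.0, 0.0, 0.0],
        "axis_direction": [0.0, 0.0, 1.0],
        "rise": rise if n_repeats >= 2 else None,
        "tilt": tilt,
        "strand_radius": strand_radius,
        "loop_radius": loop_radius,
        "noise_sd": noise_sd,
        "repeat_starts": [8 * i + 1 for i in range(n_repeats)],
        "strand_spans": [(8 * i + 1, 8 * i + 5) for i in range(n_repeats)],
        "backbone": "idealized non-physical pseudo-backbone" if backbone else None,
        "cb_direction": cb_direction,
    }
    return model, truth


def write_pentamer_pdb(model: PentamerModel, path: str | Path) -> None:
    """Write a model as a PDB file (via gemmi)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic pentamer"
    gm = gemmi.Model("1")
    for ch in model.chains:
        gch = gemmi.Chain(ch.id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.index, " ")
            for name, xyz in res.atoms.items():
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(name[0])
                at.pos = gemmi.Position(*xyz)
                gres.add_atom(at)
            gch.add_residue(gres)
        gm.add_chain(gch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def gen_mass_peaks(
    monomer_mass: float,
    k: int,
    adduct_offsets: tuple[float, ...] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[float], dict]:
    """Intact-mass peaks for a k-mer: one main peak plus adduct satellites."""
    if monomer_mass <= 0:
        raise ValueError("monomer_mass must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    main = k * monomer_mass + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
    peaks = [main] + [main + off for off in adduct_offsets]
    truth = {"seed": seed, "monomer_mass": monomer_mass, "k": k,
             "theoretical_mass": k * monomer_mass,
             "adduct_offsets": list(adduct_offsets), "noise_sd": noise_sd}
    return peaks, truth


def gen_gel_intensities(
    true_fibers: float,
    noise_cv: float,
    n_replicates: int,
    mw_cp: float,
    mw_cpdelta: float,
    seed: int = 0,
    total_subunits: int = 180,
    fiber_order: int = 5,
) -> tuple[list[tuple[float, float]], dict]:
    """Band-intensity replicates around a true fibers-per-capsid value.

    The stoichiometry formula is inverted to give noiseless
    mass-proportional intensities, then each band gets independent multiplicative
    log-normal noise with the requested coefficient of variation.
    """
    cap = total_subunits / fiber_order
    if not 0 <= true_fibers < cap:
        raise ValueError(f"true_fibers must lie in [0, {cap})")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    copies = fiber_order * true_fibers
    r = copies / (total_subunits - copies)  # molar ratio CP-δ : CP
    i_cp0 = 100.0
    i_cpd0 = i_cp0 * r * (mw_cpdelta / mw_cp)  # mass-proportional intensity
    sigma = math.sqrt(math.log(1.0 + noise_cv ** 2)) if noise_cv > 0 else 0.0
    reps = []
    for _ in range(n_replicates):
        if sigma > 0:
            f1 = rng.lognormal(-sigma ** 2 / 2, sigma)
            f2 = rng.lognormal(-sigma ** 2 / 2, sigma)
        else:
            f1 = f2 = 1.0
        reps.append((i_cp0 * f1, i_cpd0 * f2))
    truth = {"seed": seed, "true_fibers": true_fibers, "noise_cv": noise_cv,
             "mw_cp": mw_cp, "mw_cpdelta": mw_cpdelta,
             "total_subunits": total_subunits, "fiber_order": fiber_order}
    return reps, truth


def gen_em_lengths(mean: float, sd: float, n: int, seed: int = 0
                   ) -> tuple[np.ndarray, dict]:
    """Gaussian fiber-length sample (Å), truncated at zero."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        lengths = np.empty(0)
    elif sd == 0:
        lengths = np.full(n, float(mean))
    else:
        lengths = rng.normal(mean, sd, n)
        while np.any(lengths <= 0):  # truncation by redraw
            bad = lengths <= 0
            lengths[bad] = rng.normal(mean, sd, int(bad.sum()))
    truth = {"seed": seed, "mean": mean, "sd": sd, "n": n}
    return lengths, truth
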