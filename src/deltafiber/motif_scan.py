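"""Period-8 β-bracelet repeat detection and domain segmentation.

The β-bracelet shaft of a pentameric δ-like fiber is built from tandem
period-8 sequence repeats: a five-residue β-strand followed by a
three-residue loop.  The strand carries hydrophobic anchors at positions
P1 and P4 (consensus ``(V/L)x2Vx4V``; the trailing V is the next repeat's
P1), and the loop is ``y(E/D/N)y`` with charged flanks.  Two match modes
are supported:

* ``strict`` — the crystal-region consensus: P1 ∈ {V, L}, P4 = V, loop
  flanks charged, loop middle ∈ {E, D, N}.
* ``relaxed`` — the more variable downstream form ``φx2φx4φ`` with any
  hydrophobic anchor and a widened loop-middle class.

Every strict match is by construction also a relaxed match.  Coordinates
are 1-based inclusive throughout, following standard residue numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "AMINO_ACIDS",
    "ResidueClasses",
    "RepeatUnit",
    "HeptadAssignment",
    "DomainAnnotation",
    "WindowMatch",
    "match_repeat_window",
    "matching_starts",
    "scan_repeats",
    "assign_heptad",
    "segment_domains",
]


@dataclass(frozen=True)
class ResidueClasses:
    """Residue sets defining the bracelet consensus.

    ``strict_anchor`` applies at P1 (and the trailing P9 when scored);
    ``strict_anchor_p4`` is the exact-valine requirement at P4.
    ``relaxed_anchor`` is the hydrophobic φ class used at P1/P4/P9 in
    relaxed mode.  ``loop_flank`` (charged y) constrains P6/P8 in both
    modes; ``loop_middle`` constrains P7 in strict mode and
    ``loop_middle_relaxed`` in relaxed mode.  ``x_class`` documents the
    preferred composition of unconstrained strand positions; it is never
    scored (x positions are wildcards).
    """

    strict_anchor: frozenset = frozenset("VL")
    strict_anchor_p4: frozenset = frozenset("V")
    relaxed_anchor: frozenset = frozenset("AVLIMFWYC")
    x_class: frozenset = frozenset("AGSTNQDEKRH")
    loop_flank: frozenset = frozenset("DEKRH")
    loop_middle: frozenset = frozenset("EDN")
    loop_middle_relaxed: frozenset = frozenset("DEKRHNQST")

    def __post_init__(self) -> None:
        if not (self.strict_anchor <= self.relaxed_anchor):
            raise ValueError("strict_anchor must be a subset of relaxed_anchor")
        if not (self.strict_anchor_p4 <= self.relaxed_anchor):
            raise ValueError("strict_anchor_p4 must be a subset of relaxed_anchor")
        if not (self.loop_middle <= self.loop_middle_relaxed):
            raise ValueError("loop_middle must be a subset of loop_middle_relaxed")
        for name in ("strict_anchor", "strict_anchor_p4", "relaxed_anchor",
                     "loop_flank", "loop_middle", "loop_middle_relaxed"):
            s = getattr(self, name)
            if not s:
                raise ValueError(f"{name} must be non-empty")
            if not (s <= AMINO_ACIDS):
                raise ValueError(f"{name} contains non-amino-acid letters")

    def constrained(self, mode: str) -> dict[int, frozenset]:
        """Constrained window positions (1-based) -> allowed residue set."""
        if mode == "strict":
            return {
                1: self.strict_anchor,
                4: self.strict_anchor_p4,
                6: self.loop_flank,
                7: self.loop_middle,
                8: self.loop_flank,
                9: self.strict_anchor,
            }
        if mode == "relaxed":
            return {
                1: self.relaxed_anchor,
                4: self.relaxed_anchor,
                6: self.loop_flank,
                7: self.loop_middle_relaxed,
                8: self.loop_flank,
                9: self.relaxed_anchor,
            }
        raise ValueError(f"unknown mode {mode!r}; expected 'strict' or 'relaxed'")


DEFAULT_CLASSES = ResidueClasses()


@dataclass(frozen=True)
class WindowMatch:
    score: float
    flags: tuple[bool, ...]  # one per window position; unconstrained -> True


@dataclass(frozen=True)
class RepeatUnit:
    """One period-8 bracelet repeat anchored at strand position P1."""

    start: int  # 1-based index of P1
    strand_span: tuple[int, int]
    loop_span: tuple[int, int] | None
    mode: str
    score: float

    @property
    def end(self) -> int:
        return self.loop_span[1] if self.loop_span is not None else self.strand_span[1]


@dataclass(frozen=True)
class HeptadAssignment:
    helix_span: tuple[int, int]
    register: str  # one letter a-g per residue; a stutter repeats a letter
    insertion_positions: tuple[int, ...]  # 1-based absolute indices
    ad_hydrophobicity: float  # summed scale value at a/d positions
    ad_hydrophobic_count: int  # residues at a/d with scale value > 0


@dataclass(frozen=True)
class DomainAnnotation:
    coiled_coil: tuple[int, int] | None
    bracelet_region_1: tuple[int, int] | None
    internal_globular: tuple[int, int] | None
    bracelet_region_2: tuple[int, int] | None
    c_terminal_globular: tuple[int, int] | None
    repeats: tuple[RepeatUnit, ...]
    warning: str | None = None

    def ranges(self) -> dict[str, tuple[int, int] | None]:
        return {
            "coiled_coil": self.coiled_coil,
            "bracelet_region_1": self.bracelet_region_1,
            "internal_globular": self.internal_globular,
            "bracelet_region_2": self.bracelet_region_2,
            "c_terminal_globular": self.c_terminal_globular,
        }


def _validate_sequence(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in AMINO_ACIDS:
            raise ValueError(f"non-amino-acid character {ch!r} at {what} position {i}")
    return seq


def match_repeat_window(
    window: str,
    mode: str = "strict",
    classes: ResidueClasses = DEFAULT_CLASSES,
) -> WindowMatch:
    """Score one 8- or 9-residue window against the bracelet consensus.

    An 8-residue window is a loop-terminal repeat (strand + loop); a
    9-residue window additionally includes the next repeat's P1 anchor,
    as in the printed 9-position consensus.  The score is the fraction of
    constrained positions matched; unconstrained x positions never lower
    the score and are flagged True.
    """
    if len(window) not in (8, 9):
        raise ValueError(f"window must be 8 or 9 residues, got {len(window)}")
    window = _validate_sequence(window, "window")
    spec = classes.constrained(mode)
    flags = []
    matched = total = 0
    for pos, ch in enumerate(window, start=1):
        allowed = spec.get(pos)
        if allowed is None:
            flags.append(True)
            continue
        ok = ch in allowed
        flags.append(ok)
        total += 1
        matched += ok
    return WindowMatch(score=matched / total, flags=tuple(flags))


def _repeat_matches(seq: str, start0: int, spec: Mapping[int, frozenset],
                    require_trailing: bool) -> bool:
    """Does a repeat anchored at 0-based ``start0`` satisfy the consensus?

    The five-residue strand must fit inside the sequence; loop positions
    truncated by the sequence end are excused.  The trailing P9 anchor is
    only demanded when ``require_trailing`` (it belongs to the next
    repeat in a tandem run and is validated there).
    """
    n = len(seq)
    if start0 + 5 > n:
        return False
    positions = [1, 4, 6, 7, 8] + ([9] if require_trailing else [])
    for pos in positions:
        i = start0 + pos - 1
        if i >= n:
            if pos in (6, 7, 8, 9):
                continue  # truncated terminal loop / absent trailing anchor
            return False
        if seq[i] not in spec[pos]:
            return False
    return True


def _make_unit(seq: str, start0: int, mode: str) -> RepeatUnit:
    n = len(seq)
    start = start0 + 1
    strand = (start, start + 4)
    loop = (start + 5, start + 7) if start0 + 8 <= n else None
    return RepeatUnit(start=start, strand_span=strand, loop_span=loop,
                      mode=mode, score=1.0)


def matching_starts(
    sequence: str,
    mode: str = "strict",
    classes: ResidueClasses = DEFAULT_CLASSES,
) -> set[int]:
    """All 1-based positions where a repeat's own consensus is satisfied.

    This is the raw match set, before repeats are chained into runs and
    overlapping lattices are resolved.  Because every strict residue
    class is a subset of its relaxed counterpart, the strict match set
    is always a subset of the relaxed one.
    """
    seq = _validate_sequence(sequence)
    spec = classes.constrained(mode)
    return {s + 1 for s in range(len(seq) - 4)
            if _repeat_matches(seq, s, spec, require_trailing=False)}


def scan_repeats(
    sequence: str,
    mode: str = "strict",
    classes: ResidueClasses = DEFAULT_CLASSES,
    min_run: int = 2,
) -> list[RepeatUnit]:
    """Find non-overlapping period-8 bracelet repeats.

    Matching starts are chained into runs on an exact period-8 lattice;
    runs shorter than ``min_run`` repeats are discarded.  Where candidate
    runs on different lattice phases overlap, the longest run wins, ties
    broken toward the smaller start.  Within a run, each repeat's
    trailing anchor is supplied by the next repeat's P1; the final repeat
    of a run is accepted without one (and with its loop truncated when it
    abuts the sequence end).
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = _validate_sequence(sequence)
    if len(seq) < 8:
        raise ValueError(f"sequence shorter than one repeat period ({len(seq)} < 8)")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    matches = {s - 1 for s in matching_starts(seq, mode, classes)}

    # maximal arithmetic runs with step 8
    runs: list[tuple[int, int]] = []  # (start0, count)
    for s in sorted(matches):
        if s - 8 in matches:
            continue  # not a run head
        count = 1
        while s + 8 * count in matches:
            count += 1
        runs.append((s, count))
    runs = [(s, c) for s, c in runs if c >= min_run]

    # conflict resolution between overlapping lattices
    runs.sort(key=lambda sc: (-sc[1], sc[0]))
    occupied: list[tuple[int, int]] = []
    accepted: list[tuple[int, int]] = []
    for s, c in runs:
        span = (s, min(s + 8 * c - 1, len(seq) - 1))
        if any(span[0] <= e and b <= span[1] for b, e in occupied):
            continue
        occupied.append(span)
        accepted.append((s, c))

    units: list[RepeatUnit] = []
    for s, c in sorted(accepted):
        for k in range(c):
            units.append(_make_unit(seq, s + 8 * k, mode))
    return units


def assign_heptad(
    sequence: str,
    helix_span: tuple[int, int],
    scale: Mapping[str, float] | None = None,
    insertion_margin: float = 2.0,
) -> HeptadAssignment:
    """Assign a coiled-coil heptad register, allowing one stutter.

    All seven register phases, with and without a single-residue
    insertion at each interior position, are enumerated; the
    configuration maximising summed hydrophobicity (Kyte–Doolittle by
    default) at ``a``/``d`` positions wins.  An insertion is only
    reported when it beats the best insertion-free register by at least
    ``insertion_margin`` scale units.  The inserted residue repeats its
    predecessor's register letter (the cycle skips one step there).
    """
    lo, hi = helix_span
    if lo < 1 or hi > len(sequence) or hi < lo:
        raise ValueError(f"helix_span {helix_span} outside sequence of length {len(sequence)}")
    if hi - lo + 1 < 14:
        raise ValueError("helix_span must cover at least two heptads (14 residues)")
    scale = dict(KYTE_DOOLITTLE) if scale is None else dict(scale)
    seg = _validate_sequence(sequence[lo - 1:hi])
    n = len(seg)
    letters = "abcdefg"

    def config_score(phase: int, ins: int | None) -> tuple[float, str]:
        reg = []
        total = 0.0
        for i in range(n):
            k = i if (ins is None or i < ins) else i - 1
            letter = letters[(k + phase) % 7]
            reg.append(letter)
            # the stutter residue lies outside the heptad lattice and
            # does not contribute to the a/d score
            if letter in "ad" and i != ins:
                total += scale.get(seg[i], 0.0)
        return total, "".join(reg)

    best_no = max(((config_score(p, None), p) for p in range(7)),
                  key=lambda t: (t[0][0], -t[1]))
    best_ins = max(
        (((config_score(p, i)), p, i) for p in range(7) for i in range(1, n)),
        key=lambda t: (t[0][0], -t[1], -t[2]),
    )

    if best_ins[0][0] >= best_no[0][0] + insertion_margin:
        (score, reg), _, ins = best_ins
        insertions = (lo + ins,)
    else:
        (score, reg), _ = best_no
        insertions = ()
    count = sum(1 for i, letter in enumerate(reg)
                if letter in "ad" and scale.get(seg[i], 0.0) > 0)
    return HeptadAssignment(helix_span=(lo, hi), register=reg,
                            insertion_positions=insertions,
                            ad_hydrophobicity=score, ad_hydrophobic_count=count)


def _span(units: Sequence[RepeatUnit]) -> tuple[int, int] | None:
    if not units:
        return None
    return (min(u.start for u in units), max(u.end for u in units))


def segment_domains(
    sequence: str,
    strict_repeats: Iterable[RepeatUnit],
    relaxed_repeats: Iterable[RepeatUnit],
) -> DomainAnnotation:
    """Segment a δ-like sequence into the five-domain fiber layout.

    bracelet_region_1 is the span of the strict run; bracelet_region_2
    is the span of relaxed runs downstream of it; the coiled coil, the
    internal globular domain and the C-terminal globular domain are the
    flanking and intervening gaps.  With no repeats at all the
    annotation is empty and carries a warning flag.
    """
    seq = _validate_sequence(sequence)
    n = len(seq)
    strict = sorted(strict_repeats, key=lambda u: u.start)
    relaxed = sorted(relaxed_repeats, key=lambda u: u.start)

    b1 = _span(strict)
    if b1 is None and relaxed:
        # no strict region: the relaxed span is the only bracelet region
        b1_end_for_filter = 0
    else:
        b1_end_for_filter = b1[1] if b1 else 0
    downstream = [u for u in relaxed if u.start > b1_end_for_filter]
    b2 = _span(downstream)

    all_units = strict + downstream
    if not all_units:
        return DomainAnnotation(None, None, None, None, None, (),
                                warning="no bracelet repeats found")

    first = min(u.start for u in all_units)
    last = max(u.end for u in all_units)
    cc = (1, first - 1) if first > 1 else None
    ct = (last + 1, n) if last < n else None
    if b1 and b2 and b2[0] > b1[1] + 1:
        ig = (b1[1] + 1, b2[0] - 1)
    else:
        ig = None
    return DomainAnnotation(coiled_coil=cc, bracelet_region_1=b1,
                            internal_globular=ig, bracelet_region_2=b2,
                            c_terminal_globular=ct,
                            repeats=tuple(all_units))
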