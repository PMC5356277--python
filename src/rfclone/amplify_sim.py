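"""Simulation of the two PCR rounds and strand annealing.

Round 1 — :func:`pcr_amplify` — is ordinary double-primer exponential PCR
producing a blunt duplex.  Round 2 — :func:`linear_amplify` — uses a single
tailed primer on that duplex, producing one full-length single strand with
the cohesive-end tail at its 5' end.  :func:`anneal` pairs the two
single-strand products from the parallel reactions into a duplex whose
unpaired 5' extensions are the cohesive ends.

Priming is exact-match only: the simulation models the intended reaction,
not mispriming artifacts, so a primer body must occur exactly once on its
template or an error is raised.  Likewise annealing demands a perfect
complementary core; near-complementary strands raise a mismatch error
rather than forming a partial duplex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import (
    AmbiguousPrimingError,
    AnnealingError,
    AnnealingMismatchError,
    GeometryError,
    NoBindingError,
)
from .primer_design import Oligo
from .seqmodel import NucSeq, revcomp


@dataclass(frozen=True)
class AmpliconDuplex:
    """Blunt double-stranded PCR product; both strands stored 5'->3'."""

    top: str
    bottom: str
    blunt: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.blunt and self.bottom != revcomp(self.top):
            raise ValueError("blunt duplex requires bottom == revcomp(top)")

    def __len__(self) -> int:
        return len(self.top)


@dataclass(frozen=True)
class StrandProduct:
    """Single-strand output of a single-primer linear amplification."""

    bases: str
    origin: str  # name of the primer that produced it
    label: str = ""

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class OverhangEnd:
    """One end of a sticky duplex: which strand protrudes and by what."""

    side: Literal["left", "right"]
    strand: Literal["top", "bottom"] | None  # None == blunt
    seq: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def is_blunt(self) -> bool:
        return self.length == 0

    @property
    def protrusion(self) -> Literal["5p", "3p"] | None:
        """Chemical end of the protruding strand at this duplex end.

        Left end: the top strand's 5' terminus and the bottom strand's 3'
        terminus; right end: the reverse.  Cohesive ligation requires 5'
        protrusions on both partners.
        """
        if self.is_blunt or self.strand is None:
            return None
        if self.side == "left":
            return "5p" if self.strand == "top" else "3p"
        return "3p" if self.strand == "top" else "5p"


@dataclass(frozen=True)
class StickyDuplex:
    """Annealed strand pair with explicit overhang annotations.

    ``top`` and ``bottom`` are both written 5'->3'; drawn conventionally,
    top runs left-to-right and bottom right-to-left.  The double-stranded
    core of top is the reverse complement of the core of bottom.
    """

    top: str
    bottom: str
    left_overhang: OverhangEnd
    right_overhang: OverhangEnd
    label: str = ""

    @property
    def core(self) -> str:
        """Double-stranded core on the top strand."""
        start = self.left_overhang.length if self.left_overhang.strand == "top" else 0
        stop = len(self.top) - (
            self.right_overhang.length if self.right_overhang.strand == "top" else 0
        )
        return self.top[start:stop]

    @property
    def span(self) -> int:
        """Total extent in bp, counting single-stranded extensions once."""
        return len(self.core) + self.left_overhang.length + self.right_overhang.length


def pcr_amplify(
    template: NucSeq, fwd: Oligo, rev: Oligo, label: str = ""
) -> AmpliconDuplex:
    """Double-primer PCR on a linear or circular template.

    The forward body must match the top strand exactly once; the reverse
    body the bottom strand exactly once.  The blunt product runs from the
    forward site 5' end to the reverse site 5' end (wrapping across the
    origin on circular templates) with any primer tails appended:
    ``top = fwd.tail + segment + revcomp(rev.tail)``.
    """
    n = len(template)
    rev_on_top = revcomp(rev.body)
    if template.is_circular:
        # doubled-string trick: every wrap-around occurrence appears once
        # with a start inside the first copy
        doubled = template.bases + template.bases
        f_hits = [
            i
            for i in _find_all_starts(doubled, fwd.body)
            if i < n
        ]
        r_hits = [i for i in _find_all_starts(doubled, rev_on_top) if i < n]
        _check_unique(f_hits, fwd.name, template.id)
        _check_unique(r_hits, rev.name, template.id)
        f = f_hits[0]
        r_end = r_hits[0] + len(rev_on_top) - 1
        seg_len = (r_end - f) % n + 1
        segment = doubled[f : f + seg_len] if f + seg_len <= 2 * n else ""
        if not segment:
            raise GeometryError("amplicon longer than doubled template")
    else:
        f_hits = _find_all_starts(template.bases, fwd.body)
        r_hits = _find_all_starts(template.bases, rev_on_top)
        _check_unique(f_hits, fwd.name, template.id)
        _check_unique(r_hits, rev.name, template.id)
        f = f_hits[0]
        r_end = r_hits[0] + len(rev_on_top) - 1
        if r_end < f:
            raise GeometryError(
                f"primers {fwd.name!r}/{rev.name!r} diverge on linear template "
                f"{template.id!r}: no product"
            )
        segment = template.bases[f : r_end + 1]
    top = fwd.tail + segment + revcomp(rev.tail)
    return AmpliconDuplex(top=top, bottom=revcomp(top), blunt=True, label=label)


def _find_all_starts(text: str, pattern: str) -> list[int]:
    if not pattern:
        return []
    out = []
    start = 0
    while True:
        i = text.find(pattern, start)
        if i == -1:
            break
        out.append(i)
        start = i + 1
    return out


def _check_unique(hits: list[int], name: str, template_id: str) -> None:
    if not hits:
        raise NoBindingError(name, template_id)
    if len(hits) > 1:
        raise AmbiguousPrimingError(name, template_id, [h + 1 for h in hits])


def linear_amplify(
    template: AmpliconDuplex, primer: Oligo, label: str = ""
) -> StrandProduct:
    """Single-primer linear amplification of one duplex strand.

    The primer body must match exactly one of the two strands (in sequence;
    chemically it anneals to the complementary strand and extension copies
    it).  The modeled product is the full-length strand copy from the
    binding site to the template end, with the tail at its 5' end — the
    end product that accumulates linearly over cycles; intermediate species
    and stoichiometry are not tracked.
    """
    matches: list[tuple[str, int]] = []
    for strand_name, strand in (("top", template.top), ("bottom", template.bottom)):
        for i in _find_all_starts(strand, primer.body):
            matches.append((strand_name, i))
    if not matches:
        raise NoBindingError(primer.name, template.label or "<duplex>")
    if len(matches) > 1:
        raise AmbiguousPrimingError(
            primer.name, template.label or "<duplex>", [i + 1 for _, i in matches]
        )
    strand_name, i = matches[0]
    strand = template.top if strand_name == "top" else template.bottom
    return StrandProduct(
        bases=primer.tail + strand[i:], origin=primer.name, label=label
    )


DEFAULT_MIN_CORE = 15


def anneal(
    s1: StrandProduct, s2: StrandProduct, min_core: int = DEFAULT_MIN_CORE,
    label: str = "",
) -> StickyDuplex:
    """Pair two single strands into a duplex with annotated overhangs.

    The alignment is the maximal perfect-complement overlap between ``s1``
    (taken as the top strand) and ``s2`` (bottom strand); any unpaired
    extensions become overhang annotations.  In this cloning scheme both
    extensions are primer tails, hence 5' protrusions.

    Raises :class:`AnnealingError` when no perfect complementary core of at
    least ``min_core`` nt exists, or :class:`AnnealingMismatchError` when
    the best pairing is spoiled by internal mismatches (positions reported
    in 1-based top-strand coordinates).
    """
    top = s1.bases
    r2 = revcomp(s2.bases)  # bottom strand written in top orientation
    if min_core < 1:
        raise ValueError("min_core must be positive")
    seed = min(min_core, len(top), len(r2))

    # candidate offsets of r2 relative to top: any perfect overlap of at
    # least `seed` nt must place either r2's first `seed` bases inside top
    # (offset >= 0) or top's first `seed` bases inside r2 (offset < 0)
    candidates: set[int] = set()
    for i in _find_all_starts(top, r2[:seed]):
        candidates.add(i)
    for j in _find_all_starts(r2, top[:seed]):
        candidates.add(-j)

    best: tuple[int, int] | None = None  # (overlap, -offset) for max/tie rule
    best_d = 0
    for d in candidates:
        lo_t, hi_t = max(0, d), min(len(top), d + len(r2))
        ov = hi_t - lo_t
        if ov < seed:
            continue
        if top[lo_t:hi_t] == r2[lo_t - d : hi_t - d]:
            key = (ov, -abs(d))
            if best is None or key > best:
                best = key
                best_d = d
    if best is None:
        _raise_anneal_failure(top, r2, seed)
    d = best_d
    lo_t, hi_t = max(0, d), min(len(top), d + len(r2))

    if d > 0:
        left = OverhangEnd("left", "top", top[:d])
    elif d < 0:
        left = OverhangEnd("left", "bottom", s2.bases[len(s2.bases) + d :])
    else:
        left = OverhangEnd("left", None, "")
    r_excess = d + len(r2) - len(top)
    if r_excess > 0:
        right = OverhangEnd("right", "bottom", s2.bases[:r_excess])
    elif r_excess < 0:
        right = OverhangEnd("right", "top", top[d + len(r2) :])
    else:
        right = OverhangEnd("right", None, "")
    return StickyDuplex(
        top=top, bottom=s2.bases, left_overhang=left, right_overhang=right,
        label=label,
    )


def _raise_anneal_failure(top: str, r2: str, seed: int) -> None:
    """Distinguish a near-miss (mismatched core) from no pairing at all.

    A full offset scan is quadratic, so it is only attempted on strands
    short enough for diagnostics to be worthwhile.
    """
    if len(top) * len(r2) <= 4_000_000:
        best_matches = -1
        best_d = 0
        for d in range(-(len(r2) - 1), len(top)):
            lo_t, hi_t = max(0, d), min(len(top), d + len(r2))
            if hi_t - lo_t < seed:
                continue
            a = top[lo_t:hi_t]
            b = r2[lo_t - d : hi_t - d]
            m = sum(x == y for x, y in zip(a, b))
            if m > best_matches:
                best_matches, best_d = m, d
        if best_matches >= seed:
            d = best_d
            lo_t, hi_t = max(0, d), min(len(top), d + len(r2))
            positions = [
                lo_t + i + 1
                for i, (x, y) in enumerate(
                    zip(top[lo_t:hi_t], r2[lo_t - d : hi_t - d])
                )
                if x != y
            ]
            raise AnnealingMismatchError(positions)
    raise AnnealingError(
        f"strands share no perfect complementary core of >= {seed} nt"
    )
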