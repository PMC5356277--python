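"""Core sequence types, coordinate conventions and overhang extraction.

Conventions used throughout the toolkit:

* Coordinates are **1-based inclusive** on the top strand, matching how
  positions are written on plasmid maps (e.g. "the start codon ATG (289)").
* Circular sequences support interval arithmetic modulo their length;
  linear sequences reject out-of-range access.
* A cloning job replaces the vector *stuffer* — the interval strictly
  between junction A and junction B — with the insert.  The k bases ending
  at junction A ("5' overhang" region, side A) and the k bases starting at
  junction B ("3' overhang" region, side B) are retained vector sequence;
  they are the cohesive-end seed regions the whole method revolves around.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import (
    AlphabetError,
    AnchorAmbiguityError,
    AnchorNotFoundError,
    CoordinateError,
    GeometryError,
)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Topology = Literal["circular", "linear"]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case-insensitive).

    The result is uppercase.  Involution: ``revcomp(revcomp(s)) == s``.
    """
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    """Complement without reversal (rarely needed; kept for clarity)."""
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases (N counts toward the denominator)."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class NucSeq:
    """An uppercase DNA sequence with explicit topology.

    Parameters
    ----------
    id : str
        Short label (FASTA-style identifier).
    bases : str
        Sequence over {A, C, G, T, N}; lower case is normalised on
        construction.
    topology : {"circular", "linear"}
        Circular sequences wrap in all coordinate arithmetic.
    """

    id: str
    bases: str
    topology: Topology = "linear"

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        if not bases:
            raise AlphabetError("empty sequence not allowed")
        bad = set(bases) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    # -- 1-based coordinate arithmetic -------------------------------------

    def wrap(self, pos: int) -> int:
        """Map a 1-based position into [1, len] (circular only)."""
        n = len(self.bases)
        if self.is_circular:
            return (pos - 1) % n + 1
        if not 1 <= pos <= n:
            raise CoordinateError(
                f"position {pos} out of range 1..{n} on linear sequence {self.id!r}"
            )
        return pos

    def base_at(self, pos: int) -> str:
        """Base at 1-based position ``pos`` (wraps on circular sequences)."""
        return self.bases[self.wrap(pos) - 1]

    def fetch(self, start: int, length: int) -> str:
        """``length`` bases starting at 1-based ``start`` (wrapping if circular)."""
        if length < 0:
            raise CoordinateError(f"negative length {length}")
        n = len(self.bases)
        if self.is_circular:
            s = (start - 1) % n
            doubled = self.bases + self.bases
            if length > n:
                raise CoordinateError(
                    f"cannot fetch {length} bases from {n}-bp circular sequence"
                )
            return doubled[s : s + length]
        if not (1 <= start and start + length - 1 <= n):
            raise CoordinateError(
                f"interval [{start}, {start + length - 1}] out of range 1..{n} "
                f"on linear sequence {self.id!r}"
            )
        return self.bases[start - 1 : start + length - 1]

    def interval(self, start: int, end: int) -> str:
        """Bases of the 1-based inclusive interval [start, end].

        On circular sequences the interval runs forward from ``start`` and may
        wrap across the origin; on linear sequences ``start <= end`` is
        required.
        """
        n = len(self.bases)
        if self.is_circular:
            length = (end - start) % n + 1
            return self.fetch(start, length)
        if start > end:
            raise CoordinateError(f"start {start} > end {end} on linear sequence")
        return self.fetch(start, end - start + 1)

    def rotated(self, new_origin: int) -> "NucSeq":
        """Return the circular sequence re-written to start at 1-based position."""
        if not self.is_circular:
            raise CoordinateError("cannot rotate a linear sequence")
        i = (new_origin - 1) % len(self.bases)
        return NucSeq(self.id, self.bases[i:] + self.bases[:i], "circular")


def seq_equal(
    a: NucSeq, b: NucSeq, *, allow_flip: bool = True
) -> bool:
    """Topology-aware sequence identity.

    Circular sequences compare rotation-invariantly (a ligated circle has no
    defined origin) and, when ``allow_flip`` is set, also under strand flip
    (reverse complement).  Linear sequences compare verbatim (plus optional
    flip).
    """
    if len(a) != len(b) or a.topology != b.topology:
        return False
    if a.is_circular:
        doubled = b.bases + b.bases
        if a.bases in doubled:
            return True
        return allow_flip and revcomp(a.bases) in doubled
    if a.bases == b.bases:
        return True
    return allow_flip and a.bases == revcomp(b.bases)


@dataclass(frozen=True)
class SiteSpec:
    """An insertion junction given either as a coordinate or as an anchor.

    Anchor mode locates a short subsequence on the vector top strand (e.g. a
    start codon or an affinity-tag coding sequence) and derives the junction
    from its position.
    """

    mode: Literal["coordinate", "anchor"]
    coordinate: int | None = None
    anchor: str | None = None
    require_unique: bool = True
    # Which base of the anchor is the junction: "start", "end", or an
    # integer offset (1-based within the anchor).
    anchor_offset: Literal["start", "end"] | int = "start"

    def __post_init__(self) -> None:
        if self.mode == "coordinate":
            if self.coordinate is None or self.coordinate < 1:
                raise CoordinateError("coordinate mode requires a coordinate >= 1")
        elif self.mode == "anchor":
            if not self.anchor or len(self.anchor) < 3:
                raise ValueError("anchor mode requires an anchor of length >= 3")
            object.__setattr__(self, "anchor", self.anchor.upper())
        else:
            raise ValueError(f"unknown SiteSpec mode {self.mode!r}")

    @classmethod
    def at(cls, coordinate: int) -> "SiteSpec":
        return cls(mode="coordinate", coordinate=coordinate)

    @classmethod
    def at_anchor(
        cls,
        anchor: str,
        *,
        require_unique: bool = True,
        anchor_offset: Literal["start", "end"] | int = "start",
    ) -> "SiteSpec":
        return cls(
            mode="anchor",
            anchor=anchor,
            require_unique=require_unique,
            anchor_offset=anchor_offset,
        )


def find_all(haystack: NucSeq, needle: str, *, both_strands: bool = False) -> list[tuple[int, str]]:
    """All 1-based start positions of ``needle`` on ``haystack``.

    Returns ``(position, strand)`` pairs, strand ``"+"`` or ``"-"``; a minus
    hit is reported at the 1-based top-strand start of the reverse-complement
    occurrence.  Circular sequences are searched across the origin.
    """
    needle = needle.upper()
    n = len(haystack.bases)
    text = haystack.bases + (haystack.bases[: len(needle) - 1] if haystack.is_circular else "")
    hits: list[tuple[int, str]] = []
    targets = [(needle, "+")]
    if both_strands:
        targets.append((revcomp(needle), "-"))
    for pat, strand in targets:
        start = 0
        while True:
            i = text.find(pat, start)
            if i == -1 or i >= n:
                break
            hits.append((i + 1, strand))
            start = i + 1
    hits.sort()
    return hits


def resolve_site(vector: NucSeq, site: SiteSpec, *, both_strands: bool = False) -> int:
    """Resolve a :class:`SiteSpec` to a 1-based top-strand coordinate.

    Coordinate mode bounds-checks and returns the coordinate.  Anchor mode
    locates the anchor (wrapping across the origin on circular vectors) and
    applies the spec's ``anchor_offset`` to pick the junction base.

    Raises
    ------
    AnchorNotFoundError
        If the anchor does not occur.
    AnchorAmbiguityError
        If ``require_unique`` is set and the anchor occurs more than once;
        the error lists every occurrence.
    """
    if site.mode == "coordinate":
        pos = site.coordinate
        assert pos is not None
        if not 1 <= pos <= len(vector):
            raise CoordinateError(
                f"coordinate {pos} out of range 1..{len(vector)} on {vector.id!r}"
            )
        return pos

    assert site.anchor is not None
    hits = find_all(vector, site.anchor, both_strands=both_strands)
    if not hits:
        raise AnchorNotFoundError(site.anchor, vector.id)
    if len(hits) > 1 and site.require_unique:
        raise AnchorAmbiguityError(site.anchor, vector.id, [p for p, _ in hits])
    pos, strand = hits[0]
    if site.anchor_offset == "start":
        offset = 0
    elif site.anchor_offset == "end":
        offset = len(site.anchor) - 1
    else:
        offset = int(site.anchor_offset) - 1
    if strand == "-":
        # junction reported on the top strand; offset counts from the
        # anchor's own 5' end, which lies at the far coordinate.
        junction = pos + len(site.anchor) - 1 - offset
    else:
        junction = pos + offset
    return vector.wrap(junction)


@dataclass(frozen=True)
class Overhang:
    """A k-base vector-derived cohesive-end seed region.

    ``side`` "A" is the region immediately *before* junction A (the paper's
    "5' overhang"); side "B" the region immediately *after* junction B (the
    "3' overhang").  ``seq`` is read on the construct top strand.
    """

    seq: str
    side: Literal["A", "B"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - (DNA_ALPHABET - {"N"})
        if bad:
            raise AlphabetError(
                f"overhang contains ambiguous/non-DNA characters: {sorted(bad)}"
            )
        if self.side not in ("A", "B"):
            raise ValueError(f"overhang side must be 'A' or 'B', got {self.side!r}")

    @property
    def k(self) -> int:
        return len(self.seq)


DEFAULT_K_RANGE = (5, 8)


@dataclass(frozen=True)
class CloningJob:
    """The design problem: replace a vector interval with an insert.

    Junction A is the last retained vector base upstream of the insert
    (the overhang-A region ends at A); junction B is the first retained
    vector base downstream (the overhang-B region starts at B).  The
    stuffer — the interval strictly between A and B, running forward from
    A — is what the insert replaces and may be empty.

    ``k`` is the cohesive-end length; the method uses 5–8 nt, enforced
    unless ``relax_k`` is set (toy examples in the tests use shorter ends).
    """

    vector: NucSeq
    insert: NucSeq
    junction_a: int
    junction_b: int
    k: int = 6
    relax_k: bool = False

    def __post_init__(self) -> None:
        if not self.vector.is_circular:
            raise GeometryError("vector must be circular")
        if self.insert.is_circular:
            raise GeometryError("insert must be linear")
        n = len(self.vector)
        a = self.vector.wrap(self.junction_a)
        b = self.vector.wrap(self.junction_b)
        object.__setattr__(self, "junction_a", a)
        object.__setattr__(self, "junction_b", b)
        if a == b:
            raise GeometryError("junction A and junction B must differ")
        if self.k < 1:
            raise GeometryError(f"overhang length k={self.k} must be positive")
        lo, hi = DEFAULT_K_RANGE
        if not self.relax_k and not lo <= self.k <= hi:
            raise GeometryError(
                f"overhang length k={self.k} outside the cohesive-end policy "
                f"range {lo}..{hi} (pass relax_k=True to override)"
            )
        # the four regions (overhang A, stuffer, overhang B, backbone core)
        # must tile the vector without overlap
        if 2 * self.k + self.stuffer_len >= n:
            raise GeometryError(
                f"overhang regions (2×{self.k} nt) plus stuffer "
                f"({self.stuffer_len} nt) leave no backbone on the "
                f"{n}-bp vector"
            )
        for region, name in (
            (self.overhang_a_region, "overhang A"),
            (self.overhang_b_region, "overhang B"),
        ):
            seq = self.vector.interval(*region)
            if "N" in seq:
                raise GeometryError(f"{name} region contains ambiguous base N")

    # -- derived geometry (1-based inclusive intervals, may wrap) ----------

    @property
    def stuffer_len(self) -> int:
        return (self.junction_b - self.junction_a - 1) % len(self.vector)

    @property
    def stuffer(self) -> str:
        """The vector bases the insert replaces (may be empty)."""
        if self.stuffer_len == 0:
            return ""
        return self.vector.fetch(self.junction_a + 1, self.stuffer_len)

    @property
    def overhang_a_region(self) -> tuple[int, int]:
        a = self.junction_a
        return (self.vector.wrap(a - self.k + 1), a)

    @property
    def overhang_b_region(self) -> tuple[int, int]:
        b = self.junction_b
        return (b, self.vector.wrap(b + self.k - 1))

    @property
    def backbone_core_region(self) -> tuple[int, int]:
        """Retained backbone excluding both overhang regions."""
        return (
            self.vector.wrap(self.junction_b + self.k),
            self.vector.wrap(self.junction_a - self.k),
        )

    @property
    def backbone_core(self) -> str:
        return self.vector.interval(*self.backbone_core_region)

    @property
    def construct_len(self) -> int:
        return len(self.vector) - self.stuffer_len + len(self.insert)

    def reference_splice(self, id: str | None = None) -> NucSeq:
        """Ground-truth construct: the stuffer replaced by the insert.

        Written starting at the overhang-A region for definiteness; circular
        comparisons are rotation-invariant so the origin choice is free.
        """
        ov_a = self.vector.interval(*self.overhang_a_region)
        ov_b = self.vector.interval(*self.overhang_b_region)
        core = self.backbone_core
        bases = ov_a + self.insert.bases + ov_b + core
        return NucSeq(id or f"{self.vector.id}-{self.insert.id}", bases, "circular")


def extract_overhangs(job: CloningJob) -> tuple[Overhang, Overhang]:
    """The two cohesive-end seed regions of a job.

    Side A: the k vector bases ending at junction A; side B: the k vector
    bases starting at junction B — both on the top strand, wrapping across
    the origin where needed.  Region disjointness is enforced by
    :class:`CloningJob` construction.
    """
    ov_a = Overhang(job.vector.interval(*job.overhang_a_region), "A")
    ov_b = Overhang(job.vector.interval(*job.overhang_b_region), "B")
    return ov_a, ov_b
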