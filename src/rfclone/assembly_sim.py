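"""Cohesive-end compatibility, ligation, and construct verification.

Two sticky duplexes whose 5' protrusions are mutually complementary are
joined into the final circular construct; the result is then checked
against the reference splice (direct stuffer-for-insert replacement in the
vector), the in-silico analogue of sequencing across both junctions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import LigationError, PrimingError
from .amplify_sim import AmpliconDuplex, OverhangEnd, StickyDuplex, StrandProduct, pcr_amplify
from .primer_design import Oligo
from .seqmodel import CloningJob, NucSeq, revcomp, seq_equal


@dataclass(frozen=True)
class JunctionAnnotation:
    """Seam left by ligating two cohesive ends, in construct top-strand coords."""

    position: int  # 1-based first base of the overhang-derived duplex region
    overhang_seq: str
    upstream_fragment: str
    downstream_fragment: str


@dataclass(frozen=True)
class Construct:
    """A ligation product (circular when closed) with provenance."""

    seq: NucSeq
    junctions: tuple[JunctionAnnotation, ...]
    provenance: tuple[str, ...]
    self_circle: bool = False


def ends_compatible(e1: OverhangEnd, e2: OverhangEnd) -> bool:
    """Can two cohesive ends ligate?

    True iff both are 5' protrusions on opposite strands (so the protruding
    strands face each other when the fragments are juxtaposed), of equal
    length, and reverse-complementary.  Blunt or 3'-protruding ends are
    never cohesive-compatible here.
    """
    if e1.is_blunt or e2.is_blunt:
        return False
    if e1.protrusion != "5p" or e2.protrusion != "5p":
        return False
    if e1.strand == e2.strand:
        return False
    if e1.length != e2.length:
        return False
    return e1.seq == revcomp(e2.seq)


def ligate(
    frag1: StickyDuplex,
    frag2: StickyDuplex | None = None,
    circularize: bool = True,
    construct_id: str = "construct",
) -> Construct:
    """Join two cohesive-ended fragments (or close one on itself).

    ``frag1``'s right end must be compatible with ``frag2``'s left end;
    when circularizing, ``frag2``'s right end must also be compatible with
    ``frag1``'s left end.  Nick sealing is implicit.  Passing a single
    fragment (``frag2=None``) with ``circularize`` asks for
    self-circularization, which succeeds only when the fragment's own two
    ends are mutually complementary — the product is flagged
    ``self_circle`` since it is normally an unwanted side reaction.
    """
    if frag2 is None:
        if not circularize:
            raise LigationError("a single fragment can only be self-circularized")
        if not ends_compatible(frag1.right_overhang, frag1.left_overhang):
            raise LigationError(
                "fragment ends are not self-compatible: right "
                f"{frag1.right_overhang.seq!r} vs left {frag1.left_overhang.seq!r}"
            )
        top = frag1.top
        seq = NucSeq(construct_id, top, "circular")
        k = frag1.left_overhang.length
        junctions = (
            JunctionAnnotation(1, top[:k], frag1.label or "frag1", frag1.label or "frag1"),
        )
        return Construct(seq, junctions, (frag1.label or "frag1",), self_circle=True)

    if not ends_compatible(frag1.right_overhang, frag2.left_overhang):
        raise LigationError(
            f"junction 1 incompatible: fragment {frag1.label or '1'!r} right "
            f"overhang {frag1.right_overhang.seq!r} "
            f"({frag1.right_overhang.strand or 'blunt'}) vs fragment "
            f"{frag2.label or '2'!r} left overhang "
            f"{frag2.left_overhang.seq!r} ({frag2.left_overhang.strand or 'blunt'})"
        )
    l1, l2 = frag1.label or "1", frag2.label or "2"
    # with a bottom-5' right protrusion on frag1 and a top-5' left
    # protrusion on frag2, the joined top strand is the plain concatenation
    top = frag1.top + frag2.top
    bottom = frag2.bottom + frag1.bottom
    j1 = JunctionAnnotation(
        position=len(frag1.top) + 1,
        overhang_seq=frag2.left_overhang.seq,
        upstream_fragment=l1,
        downstream_fragment=l2,
    )
    if not circularize:
        if bottom != revcomp(top):
            raise LigationError("open ligation product strands are inconsistent")
        return Construct(NucSeq(construct_id, top, "linear"), (j1,), (l1, l2))

    if not ends_compatible(frag2.right_overhang, frag1.left_overhang):
        raise LigationError(
            f"junction 2 incompatible: fragment {l2!r} right overhang "
            f"{frag2.right_overhang.seq!r} vs fragment {l1!r} left overhang "
            f"{frag1.left_overhang.seq!r}"
        )
    # the two strand circles close at different junctions, so the bottom
    # circle is a rotation of the top circle's complement
    if len(bottom) != len(top) or revcomp(bottom) not in top + top:
        raise LigationError("circular ligation product strands are inconsistent")
    j2 = JunctionAnnotation(
        position=1,
        overhang_seq=frag1.left_overhang.seq,
        upstream_fragment=l2,
        downstream_fragment=l1,
    )
    return Construct(NucSeq(construct_id, top, "circular"), (j1, j2), (l1, l2))


@dataclass(frozen=True)
class JunctionCheck:
    side: str  # "A" or "B"
    expected_excerpt: str
    matches: bool


@dataclass(frozen=True)
class VerificationReport:
    """In-silico stand-in for colony PCR plus junction sequencing."""

    identity: bool
    junctions: tuple[JunctionCheck, ...]
    colony_pcr_bp: int | None
    parental_control_bp: int | None
    construct_len: int
    expected_len: int

    @property
    def passed(self) -> bool:
        return self.identity and all(j.matches for j in self.junctions)


def _window_present(window: str, target: NucSeq) -> bool:
    text = target.bases + (target.bases if target.is_circular else "")
    return window in text or revcomp(window) in text


def verify_construct(
    construct: Construct,
    job: CloningJob,
    junction_window: int = 30,
    colony_primer_len: int = 20,
) -> VerificationReport:
    """Check a construct against the reference splice.

    Identity is rotation-invariant and strand-flip-invariant (a ligated
    circle has neither a defined origin nor a defined top strand).  Each
    junction is checked by excerpting ``junction_window`` bases on either
    side of the seam from the reference and requiring the excerpt verbatim
    in the construct — the in-silico analogue of reading a sequencing trace
    across the junction.  The colony-PCR product size is computed with a
    forward primer on retained vector backbone just upstream of junction A
    and a reverse primer at the 3' end of the insert; on a parental
    (insert-free) plasmid the insert primer has no site and the size is
    reported as absent.
    """
    ref = job.reference_splice()
    identity = seq_equal(construct.seq, ref, allow_flip=True)

    k = job.k
    ins_len = len(job.insert)
    w = junction_window
    # reference coordinates: ovA = [1..k], insert = [k+1 .. k+ins_len],
    # ovB starts at k+ins_len+1
    seam_a = k  # last base of overhang A
    seam_b = k + ins_len  # last base of insert
    checks = []
    for side, seam in (("A", seam_a), ("B", seam_b)):
        excerpt = ref.interval(seam - w + 1, seam + w)
        checks.append(
            JunctionCheck(side, excerpt, _window_present(excerpt, construct.seq))
        )

    # colony PCR: vector-anchored forward primer ends right before the
    # overhang-A region; insert-anchored reverse primer at the insert 3' end
    fl = min(colony_primer_len, len(job.backbone_core))
    rl = min(colony_primer_len, ins_len)
    fwd_body = job.vector.interval(
        job.vector.wrap(job.junction_a - k - fl + 1), job.vector.wrap(job.junction_a - k)
    )
    rev_body = revcomp(job.insert.bases[-rl:])
    fwd = Oligo(name="colony-fwd", role=5, direction="forward", body=fwd_body)
    rev = Oligo(name="colony-rev", role=2, direction="reverse", body=rev_body)

    def product_size(target: NucSeq) -> int | None:
        try:
            return len(pcr_amplify(target, fwd, rev, label="colonyPCR"))
        except PrimingError:
            return None

    return VerificationReport(
        identity=identity,
        junctions=tuple(checks),
        colony_pcr_bp=product_size(construct.seq),
        parental_control_bp=product_size(job.vector),
        construct_len=len(construct.seq),
        expected_len=job.construct_len,
    )


def predicted_band_sizes(
    products: Sequence[AmpliconDuplex | StickyDuplex | StrandProduct | Construct],
) -> list[tuple[str, int]]:
    """Expected electrophoresis band lengths for simulated products.

    Sticky duplexes report both strand lengths and the duplex span (the
    quantities a denaturing vs native gel would show); blunt duplexes,
    single strands and constructs each contribute a single entry.
    """
    bands: list[tuple[str, int]] = []
    for i, p in enumerate(products):
        label = getattr(p, "label", "") or getattr(getattr(p, "seq", None), "id", "") or f"item{i + 1}"
        if isinstance(p, StickyDuplex):
            bands.append((f"{label}/top", len(p.top)))
            bands.append((f"{label}/bottom", len(p.bottom)))
            bands.append((f"{label}/span", p.span))
        elif isinstance(p, AmpliconDuplex):
            bands.append((label, len(p)))
        elif isinstance(p, StrandProduct):
            bands.append((label, len(p)))
        elif isinstance(p, Construct):
            bands.append((label, len(p.seq)))
        else:
            raise TypeError(f"cannot size object of type {type(p).__name__}")
    return bands
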