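"""Design of the eight-primer set for cohesive-end cloning.

The method needs four primers per template: a plain forward/reverse pair
that amplifies the double-stranded fragment, and a tailed copy of each that
is used alone in a single-primer linear amplification to append the
cohesive-end sequence.  Primer roles follow the fragment-generation scheme:

====  =======================  ==========================================
role  name                     composition (written 5'->3')
====  =======================  ==========================================
1     insert forward, plain    insert body from junction A side
2     insert reverse, plain    revcomp body from junction B side
3     insert forward, tailed   overhang A  +  body of 1
4     insert reverse, tailed   revcomp(overhang B)  +  body of 2
5     vector forward, plain    backbone body downstream of overhang B
6     vector reverse, plain    revcomp backbone body upstream of overhang A
7     vector forward, tailed   overhang B  +  body of 5
8     vector reverse, tailed   revcomp(overhang A)  +  body of 6
====  =======================  ==========================================

The tail assignment is forced by the seamless-junction requirement: after
annealing, the insert fragment carries a 5' protrusion ``overhang A`` on its
left and ``revcomp(overhang B)`` on its right, exactly complementary to the
vector fragment's protrusions, so ligation reconstitutes both junctions
without scars.

Bodies are template-homologous stretches starting at the junction; their
length is tuned within a window (default 20-32 nt, target 25) so the 3'
terminal base is G or C.  The 5' terminal base is fixed by the junction
(plain primers) or the overhang (tailed primers); when it is A/T a warning
is attached rather than shifting the junction, since moving the body start
would break seamlessness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from Bio.SeqUtils import MeltingTemp as _mt

from .errors import AlphabetError
from .seqmodel import CloningJob, NucSeq, Overhang, extract_overhangs, revcomp

GC = frozenset("GC")

DEFAULT_BODY_TARGET = 25
DEFAULT_BODY_WINDOW = (20, 32)

# fixed Tm conditions (mM monovalent salt, nM oligo) and thermodynamic
# parameter set (Allawi & SantaLucia 1997 nearest-neighbor table), recorded
# so outputs are reproducible across runs and library versions
TM_CONDITIONS = {"Na": 50.0, "dnac1": 500.0, "dnac2": 0.0, "nn_table": _mt.DNA_NN3}
MIN_TM_LENGTH = 8


@dataclass(frozen=True)
class DesignWarning:
    """Machine-readable design advisory (never fatal)."""

    code: str
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.subject}: {self.message}"


@dataclass(frozen=True)
class Oligo:
    """A primer: optional 5' tail plus a template-homologous body."""

    name: str
    role: int
    direction: Literal["forward", "reverse"]
    body: str
    tail: str = ""
    tm_body: float = float("nan")
    warnings: tuple[DesignWarning, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.role <= 8:
            raise ValueError(f"primer role must be 1..8, got {self.role}")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"bad direction {self.direction!r}")
        object.__setattr__(self, "body", self.body.upper())
        object.__setattr__(self, "tail", self.tail.upper())
        if "N" in self.body or "N" in self.tail:
            raise AlphabetError(f"oligo {self.name!r} contains ambiguous base N")

    @property
    def seq(self) -> str:
        """Full oligo sequence, 5'->3' (tail then body)."""
        return self.tail + self.body

    def __len__(self) -> int:
        return len(self.seq)


def melting_temp(seq: str, model: str = "nn") -> float:
    """Oligo melting temperature in deg C.

    ``model="nn"``: nearest-neighbor thermodynamics at 50 mM monovalent
    salt and 500 nM oligo.  ``model="gc_fallback"``: the classical
    length-and-GC formula ``64.9 + 41*(nGC - 16.4)/N``, monotone in GC
    count at fixed length.
    """
    seq = seq.upper()
    if len(seq) < MIN_TM_LENGTH:
        raise ValueError(
            f"sequence of length {len(seq)} too short for a meaningful Tm "
            f"(minimum {MIN_TM_LENGTH})"
        )
    bad = set(seq) - set("ACGT")
    if bad:
        raise AlphabetError(f"non-ACGT characters in Tm input: {sorted(bad)}")
    if model == "nn":
        return float(_mt.Tm_NN(seq, **TM_CONDITIONS))
    if model == "gc_fallback":
        n_gc = seq.count("G") + seq.count("C")
        return 64.9 + 41.0 * (n_gc - 16.4) / len(seq)
    raise ValueError(f"unknown Tm model {model!r}")


def select_body(
    template: NucSeq,
    junction: int,
    direction: Literal["forward", "reverse"],
    target_len: int = DEFAULT_BODY_TARGET,
    window: tuple[int, int] = DEFAULT_BODY_WINDOW,
) -> tuple[str, list[DesignWarning]]:
    """Pick a primer body anchored at a junction.

    Forward bodies run 5'->3' from ``junction`` along the top strand;
    reverse bodies are the reverse complement of the stretch *ending* at
    ``junction``.  The anchored end is immovable, so only the 3' terminus
    (the extension end, which matters most for priming) is tuned: among
    window lengths whose 3' base is G or C, the one closest to
    ``target_len`` wins (ties go to the shorter).  If no length qualifies
    the target-length body is returned with a rule-violation warning.
    """
    lo, hi = window
    if lo < 1 or hi < lo:
        raise ValueError(f"bad body window {window}")
    n = len(template)
    if not template.is_circular:
        # clamp to available template so linear inserts shorter than the
        # window still get a (warned) best-effort body
        if direction == "forward":
            avail = n - template.wrap(junction) + 1
        else:
            avail = template.wrap(junction)
    else:
        avail = n
    warnings: list[DesignWarning] = []
    hi_eff = min(hi, avail)
    lo_eff = min(lo, hi_eff)
    tgt = min(target_len, hi_eff)
    if hi_eff < lo:
        warnings.append(
            DesignWarning(
                "BODY_TRUNCATED",
                f"{template.id}@{junction}{direction[0]}",
                f"template supplies only {hi_eff} nt; window {lo}-{hi} relaxed",
            )
        )

    def body_of(length: int) -> str:
        if direction == "forward":
            raw = template.fetch(junction, length)
            return raw
        raw = template.fetch(template.wrap(junction) - length + 1 if not template.is_circular else junction - length + 1, length)
        return revcomp(raw)

    qualifying = []
    for length in range(lo_eff, hi_eff + 1):
        b = body_of(length)
        if b[-1] in GC:
            qualifying.append((abs(length - tgt), length))
    if qualifying:
        _, best_len = min(qualifying)  # ties break to shorter length
        body = body_of(best_len)
    else:
        body = body_of(tgt)
        warnings.append(
            DesignWarning(
                "GC_RULE_3PRIME",
                f"{template.id}@{junction}{direction[0]}",
                f"no window length ends in G/C; using target length {tgt}",
            )
        )
    if "N" in body:
        raise AlphabetError(
            f"primer body region at {template.id}:{junction} contains N"
        )
    if body[0] not in GC:
        warnings.append(
            DesignWarning(
                "GC_RULE_5PRIME",
                f"{template.id}@{junction}{direction[0]}",
                "junction-anchored 5' base is not G/C (cannot be shifted)",
            )
        )
    return body, warnings


def validate_overhangs(ov_a: Overhang, ov_b: Overhang) -> list[DesignWarning]:
    """Advisory checks on the cohesive-end pair.

    Flags the failure modes that defeat cohesive-end specificity:
    identical overhangs (the insert could go in reversed), palindromic
    overhangs (a fragment can self-ligate), and homopolymers (annotation
    only — ligation still works but slipped products are possible).
    """
    warnings: list[DesignWarning] = []
    if ov_a.seq == ov_b.seq:
        warnings.append(
            DesignWarning(
                "OVERHANG_IDENTICAL",
                "A/B",
                f"overhangs A and B are identical ({ov_a.seq}); "
                "reversed-insert ligation becomes possible",
            )
        )
    for ov in (ov_a, ov_b):
        if ov.seq == revcomp(ov.seq):
            warnings.append(
                DesignWarning(
                    "OVERHANG_PALINDROME",
                    ov.side,
                    f"overhang {ov.side} ({ov.seq}) is self-complementary; "
                    "self-ligation risk",
                )
            )
        if len(set(ov.seq)) == 1:
            warnings.append(
                DesignWarning(
                    "OVERHANG_HOMOPOLYMER",
                    ov.side,
                    f"overhang {ov.side} ({ov.seq}) is a homopolymer; "
                    "slippage possible",
                )
            )
    return warnings


@dataclass(frozen=True)
class PrimerSet:
    """The eight oligos of one cloning design plus aggregated warnings."""

    insert_fwd_plain: Oligo  # role 1
    insert_rev_plain: Oligo  # role 2
    insert_fwd_tailed: Oligo  # role 3
    insert_rev_tailed: Oligo  # role 4
    vector_fwd_plain: Oligo  # role 5
    vector_rev_plain: Oligo  # role 6
    vector_fwd_tailed: Oligo  # role 7
    vector_rev_tailed: Oligo  # role 8
    overhang_a: Overhang | None = None
    overhang_b: Overhang | None = None
    warnings: tuple[DesignWarning, ...] = ()

    def __iter__(self):
        return iter(self.all())

    def all(self) -> list[Oligo]:
        return [
            self.insert_fwd_plain,
            self.insert_rev_plain,
            self.insert_fwd_tailed,
            self.insert_rev_tailed,
            self.vector_fwd_plain,
            self.vector_rev_plain,
            self.vector_fwd_tailed,
            self.vector_rev_tailed,
        ]

    def by_role(self, role: int) -> Oligo:
        for o in self.all():
            if o.role == role:
                return o
        raise KeyError(role)


def _tm_or_nan(body: str, model: str) -> tuple[float, list[DesignWarning]]:
    if len(body) >= MIN_TM_LENGTH:
        return melting_temp(body, model), []
    return float("nan"), [
        DesignWarning(
            "BODY_TOO_SHORT_FOR_TM",
            body,
            f"body of {len(body)} nt below Tm model minimum; tm_body is NaN",
        )
    ]


def design_primer_set(
    job: CloningJob,
    target_len: int = DEFAULT_BODY_TARGET,
    window: tuple[int, int] = DEFAULT_BODY_WINDOW,
    tm_model: str = "nn",
) -> PrimerSet:
    """Design all eight primers for a cloning job.

    Plain primers carry empty tails; each tailed primer shares its body with
    its plain counterpart and prepends the appropriate cohesive-end tail
    (see module docstring).  Every advisory from body selection, tail
    terminal-base checks and overhang validation is aggregated on the
    returned set — warnings are never dropped.
    """
    ov_a, ov_b = extract_overhangs(job)
    warnings: list[DesignWarning] = list(validate_overhangs(ov_a, ov_b))

    ins, vec = job.insert, job.vector
    body_i_f, w1 = select_body(ins, 1, "forward", target_len, window)
    body_i_r, w2 = select_body(ins, len(ins), "reverse", target_len, window)
    core_start, core_end = job.backbone_core_region
    body_v_f, w3 = select_body(vec, core_start, "forward", target_len, window)
    body_v_r, w4 = select_body(vec, core_end, "reverse", target_len, window)
    warnings += w1 + w2 + w3 + w4

    tails = {
        1: "",
        2: "",
        3: ov_a.seq,
        4: revcomp(ov_b.seq),
        5: "",
        6: "",
        7: ov_b.seq,
        8: revcomp(ov_a.seq),
    }
    bodies = {
        1: body_i_f,
        2: body_i_r,
        3: body_i_f,
        4: body_i_r,
        5: body_v_f,
        6: body_v_r,
        7: body_v_f,
        8: body_v_r,
    }
    directions = {
        1: "forward",
        2: "reverse",
        3: "forward",
        4: "reverse",
        5: "forward",
        6: "reverse",
        7: "forward",
        8: "reverse",
    }
    template_ids = {r: (ins.id if r <= 4 else vec.id) for r in range(1, 9)}

    oligos: dict[int, Oligo] = {}
    for role in range(1, 9):
        body = bodies[role]
        tm, w_tm = _tm_or_nan(body, tm_model)
        o_warn: list[DesignWarning] = list(w_tm)
        full = tails[role] + body
        name = f"{template_ids[role]}-p{role}"
        if full[0] not in GC:
            o_warn.append(
                DesignWarning(
                    "GC_RULE_5PRIME",
                    name,
                    "5' terminal base of the full oligo is not G/C",
                )
            )
        if full[-1] not in GC:
            o_warn.append(
                DesignWarning("GC_RULE_3PRIME", name, "3' terminal base is not G/C")
            )
        oligos[role] = Oligo(
            name=name,
            role=role,
            direction=directions[role],
            body=body,
            tail=tails[role],
            tm_body=tm,
            warnings=tuple(o_warn),
        )
        warnings += [w for w in o_warn]

    return PrimerSet(
        insert_fwd_plain=oligos[1],
        insert_rev_plain=oligos[2],
        insert_fwd_tailed=oligos[3],
        insert_rev_tailed=oligos[4],
        vector_fwd_plain=oligos[5],
        vector_rev_plain=oligos[6],
        vector_fwd_tailed=oligos[7],
        vector_rev_tailed=oligos[8],
        overhang_a=ov_a,
        overhang_b=ov_b,
        warnings=tuple(warnings),
    )
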