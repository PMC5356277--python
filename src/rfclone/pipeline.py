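"""End-to-end orchestration of the cloning simulation.

Mirrors the bench workflow stage for stage: design the eight primers;
round-1 double-primer PCR of vector and insert (fragments "1" and "2");
round-2 single-primer linear amplifications (strands "3-1"/"3-2" from the
vector fragment, "4-1"/"4-2" from the insert fragment); annealing into the
cohesive-ended duplexes "3" and "4"; ligation into the circular construct;
verification against the reference splice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .amplify_sim import (
    AmpliconDuplex,
    StickyDuplex,
    StrandProduct,
    anneal,
    linear_amplify,
    pcr_amplify,
)
from .assembly_sim import (
    Construct,
    VerificationReport,
    ligate,
    predicted_band_sizes,
    verify_construct,
)
from .config import Config
from .primer_design import PrimerSet, design_primer_set
from .seqmodel import CloningJob

log = logging.getLogger("rfclone")


@dataclass(frozen=True)
class SimulationResult:
    """All intermediate and final products of one simulated cloning."""

    job: CloningJob
    primers: PrimerSet
    vector_amplicon: AmpliconDuplex  # fragment "1"
    insert_amplicon: AmpliconDuplex  # fragment "2"
    strands: tuple[StrandProduct, ...]  # "3-1", "3-2", "4-1", "4-2"
    vector_sticky: StickyDuplex  # fragment "3"
    insert_sticky: StickyDuplex  # fragment "4"
    construct: Construct
    report: VerificationReport
    # blunt parental duplexes carried through round 2 unpurified; cohesive
    # ligation outcompetes blunt ligation, so they are never assembled
    contaminants: tuple[AmpliconDuplex, ...] = ()

    @property
    def bands(self) -> list[tuple[str, int]]:
        return predicted_band_sizes(
            [
                self.vector_amplicon,
                self.insert_amplicon,
                *self.strands,
                self.vector_sticky,
                self.insert_sticky,
                self.construct,
            ]
        )


def simulate_cloning(job: CloningJob, config: Config | None = None) -> SimulationResult:
    """Run the full design-amplify-anneal-ligate-verify pipeline."""
    cfg = config or Config()
    ps = design_primer_set(
        job, target_len=cfg.body_target, window=cfg.body_window, tm_model=cfg.tm_model
    )
    log.info("designed 8 primers; overhang A=%s B=%s",
             ps.overhang_a.seq, ps.overhang_b.seq)

    frag1 = pcr_amplify(job.vector, ps.vector_fwd_plain, ps.vector_rev_plain, label="1")
    log.info("fragment \"1\" (vector backbone) amplified: %d bp", len(frag1))
    frag2 = pcr_amplify(job.insert, ps.insert_fwd_plain, ps.insert_rev_plain, label="2")
    log.info("fragment \"2\" (insert) amplified: %d bp", len(frag2))

    s31 = linear_amplify(frag1, ps.vector_fwd_tailed, label="3-1")
    s32 = linear_amplify(frag1, ps.vector_rev_tailed, label="3-2")
    s41 = linear_amplify(frag2, ps.insert_fwd_tailed, label="4-1")
    s42 = linear_amplify(frag2, ps.insert_rev_tailed, label="4-2")
    log.info("single-primer strands \"3-1\"/\"3-2\"/\"4-1\"/\"4-2\" produced")

    min_core = min(cfg.min_core, len(frag1.top), len(frag2.top))
    frag3 = anneal(s31, s32, min_core=min_core, label="3")
    frag4 = anneal(s41, s42, min_core=min_core, label="4")
    log.info(
        "annealed sticky fragments \"3\" (%d bp span) and \"4\" (%d bp span)",
        frag3.span, frag4.span,
    )

    construct = ligate(
        frag3, frag4, circularize=True,
        construct_id=f"{job.vector.id}-{job.insert.id}",
    )
    log.info("ligated circular construct: %d bp", len(construct.seq))
    report = verify_construct(construct, job)
    log.info("verification: identity=%s junctions=%s",
             report.identity, [j.matches for j in report.junctions])
    return SimulationResult(
        job=job,
        primers=ps,
        vector_amplicon=frag1,
        insert_amplicon=frag2,
        strands=(s31, s32, s41, s42),
        vector_sticky=frag3,
        insert_sticky=frag4,
        construct=construct,
        report=report,
        contaminants=(frag1, frag2),
    )
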