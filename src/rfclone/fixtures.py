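"""Seeded synthetic vector/insert generator.

Stands in for the genomic-DNA and cDNA inputs of a real cloning campaign:
a random circular vector with a designated stuffer interval, a random
linear insert, and the precomputed reference splice.  Same seed, same
fixture, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FixtureError
from .primer_design import validate_overhangs
from .seqmodel import CloningJob, NucSeq, extract_overhangs

_BASES = np.array(list("ACGT"))

# warnings that force overhang regeneration; homopolymers are advisory only
_FATAL_OVERHANG_CODES = {"OVERHANG_IDENTICAL", "OVERHANG_PALINDROME"}


@dataclass(frozen=True)
class FixtureJob:
    """A generated cloning problem plus its known-good answer."""

    seed: int
    vector_len: int
    insert_len: int
    k: int
    gc_fraction: float
    job: CloningJob
    expected: NucSeq


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def generate_fixture(
    seed: int,
    vector_len: int = 5000,
    insert_len: int = 1500,
    k: int = 6,
    gc_fraction: float = 0.5,
    max_retries: int = 50,
) -> FixtureJob:
    """Generate a random cloning job and its reference construct.

    The stuffer length is drawn so that the retained backbone stays long
    enough for primer bodies.  Overhang regions are redrawn (bounded
    retries) until they trigger no identity or palindrome advisory, the
    two failure modes that defeat cohesive-end specificity.
    """
    min_len = 4 * k + 20
    if vector_len < min_len or insert_len < 4:
        raise ValueError(
            f"vector_len must be >= {min_len} and insert_len >= 4 "
            f"(got {vector_len}, {insert_len})"
        )
    if not 0 < gc_fraction < 1:
        raise ValueError(f"gc_fraction must lie in (0, 1), got {gc_fraction}")
    rng = np.random.default_rng(seed)

    core_min = min(80, max(20, vector_len - 2 * k - 30))
    max_stuffer = vector_len - 2 * k - core_min
    min_stuffer = min(30, max_stuffer)
    stuffer_len = int(rng.integers(min_stuffer, max_stuffer + 1))
    junction_a = int(rng.integers(1, vector_len + 1))
    junction_b = (junction_a + stuffer_len) % vector_len + 1

    vector_arr = list(_random_bases(rng, vector_len, gc_fraction))
    insert = NucSeq("insert", _random_bases(rng, insert_len, gc_fraction), "linear")

    for _ in range(max_retries):
        vector = NucSeq("vector", "".join(vector_arr), "circular")
        job = CloningJob(
            vector=vector,
            insert=insert,
            junction_a=junction_a,
            junction_b=junction_b,
            k=k,
            relax_k=True,
        )
        ov_a, ov_b = extract_overhangs(job)
        bad = {
            w.code for w in validate_overhangs(ov_a, ov_b)
        } & _FATAL_OVERHANG_CODES
        if not bad:
            return FixtureJob(
                seed=seed,
                vector_len=vector_len,
                insert_len=insert_len,
                k=k,
                gc_fraction=gc_fraction,
                job=job,
                expected=job.reference_splice("expected"),
            )
        # redraw only the overhang regions
        for region in (job.overhang_a_region, job.overhang_b_region):
            start = region[0]
            fresh = _random_bases(rng, k, gc_fraction)
            for offset in range(k):
                pos = (start - 1 + offset) % vector_len
                vector_arr[pos] = fresh[offset]
    raise FixtureError(
        f"could not draw non-degenerate overhangs in {max_retries} attempts "
        f"(seed {seed}, k={k}, gc={gc_fraction})"
    )
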