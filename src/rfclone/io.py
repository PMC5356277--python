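"""Reading and writing sequence files and tabular exports.

FASTA records encode topology with the keyword ``circular`` in the
description (common GenBank/FASTA practice); GenBank records honor the
LOCUS line's circular flag.  All writers are deterministic: identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .assembly_sim import Construct
from .primer_design import PrimerSet
from .seqmodel import CloningJob, NucSeq


def _topology_of_record(record: SeqRecord) -> str:
    if record.annotations.get("topology") == "circular":
        return "circular"
    if "circular" in (record.description or "").lower().split():
        return "circular"
    return "linear"


def read_seqs(path: str | Path) -> list[NucSeq]:
    """Read all records from a FASTA or GenBank file as :class:`NucSeq`."""
    path = Path(path)
    fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        out.append(NucSeq(rec.id, str(rec.seq), _topology_of_record(rec)))
    if not out:
        raise ValueError(f"no sequence records found in {path}")
    return out


def read_seq(path: str | Path) -> NucSeq:
    """Read a file expected to hold exactly one sequence record."""
    seqs = read_seqs(path)
    if len(seqs) > 1:
        raise ValueError(f"{path} holds {len(seqs)} records; expected one")
    return seqs[0]


def write_fasta(seqs: Sequence[NucSeq] | NucSeq, path: str | Path) -> None:
    """Write sequences as FASTA, flagging circular topology in the header."""
    if isinstance(seqs, NucSeq):
        seqs = [seqs]
    with open(path, "w") as fh:
        for s in seqs:
            desc = " circular" if s.is_circular else ""
            fh.write(f">{s.id}{desc}\n")
            for i in range(0, len(s.bases), 70):
                fh.write(s.bases[i : i + 70] + "\n")


def write_construct_genbank(
    construct: Construct, job: CloningJob, path: str | Path
) -> None:
    """Write the final construct as GenBank with junction/overhang features.

    The construct is rotated to the reference-splice origin (overhang A
    first) before writing so the feature table is stable across runs.
    """
    ref = job.reference_splice(construct.seq.id)
    # rotate the construct onto the reference origin when possible
    doubled = construct.seq.bases * 2
    idx = doubled.find(ref.bases)
    bases = ref.bases if idx != -1 else construct.seq.bases
    k, ins_len = job.k, len(job.insert)
    rec = SeqRecord(
        Seq(bases),
        id=construct.seq.id[:16] or "construct",
        name=(construct.seq.id or "construct")[:16],
        description=f"assembled construct ({len(bases)} bp)",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    if idx != -1:
        rec.features = [
            SeqFeature(
                FeatureLocation(0, k),
                type="misc_feature",
                qualifiers={"label": ["overhang A (cohesive-end region)"]},
            ),
            SeqFeature(
                FeatureLocation(k, k + ins_len),
                type="misc_feature",
                qualifiers={"label": [f"insert {job.insert.id}"]},
            ),
            SeqFeature(
                FeatureLocation(k + ins_len, k + ins_len + k),
                type="misc_feature",
                qualifiers={"label": ["overhang B (cohesive-end region)"]},
            ),
        ]
    SeqIO.write([rec], str(path), "genbank")


PRIMER_TSV_COLUMNS = [
    "name",
    "role",
    "direction",
    "sequence_5to3",
    "body_len",
    "tail",
    "tm_body",
    "warnings",
]


def write_primer_tsv(primers: PrimerSet, path: str | Path) -> None:
    """Primer table export (one row per oligo, warnings joined by ';')."""
    with open(path, "w") as fh:
        fh.write("\t".join(PRIMER_TSV_COLUMNS) + "\n")
        for o in primers.all():
            warn = ";".join(w.code for w in o.warnings)
            tm = "" if o.tm_body != o.tm_body else f"{o.tm_body:.2f}"
            fh.write(
                "\t".join(
                    [
                        o.name,
                        str(o.role),
                        o.direction,
                        o.seq,
                        str(len(o.body)),
                        o.tail,
                        tm,
                        warn,
                    ]
                )
                + "\n"
            )


def write_primer_fasta(primers: PrimerSet, path: str | Path) -> None:
    write_fasta([NucSeq(o.name, o.seq, "linear") for o in primers.all()], path)


def write_bands_tsv(bands: Iterable[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tlength_bp\n")
        for label, bp in bands:
            fh.write(f"{label}\t{bp}\n")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
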