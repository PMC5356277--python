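"""Bench-protocol artifacts: thermocycler programs, reaction recipes,
ligation arithmetic, and the cloning-efficiency summarizer.

The touchdown amplification program starts annealing at 60 degC and drops
0.5 degC per cycle for 20 cycles (ending at 50.5 degC), then runs 10 more
cycles at a fixed 52 degC; extension time scales at 30 s/kb of amplicon.
Colony-PCR screening uses a fixed 50 degC annealing and 1 min/kb extension.
All PCR recipes total 50 uL; the single-primer (linear amplification)
recipe uses ~10x more template than the double-primer one because product
accumulation is linear rather than exponential, and carries exactly one
primer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd


# ---------------------------------------------------------------------------
# thermocycler programs

@dataclass(frozen=True)
class ThermoStep:
    """One temperature hold; ``decrement_c`` applies per cycle (touchdown)."""

    temperature_c: float
    duration_s: int
    decrement_c: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"step duration must be positive, got {self.duration_s}")
        if not 4.0 <= self.temperature_c <= 99.0:
            raise ValueError(
                f"temperature {self.temperature_c} degC outside instrument range 4-99"
            )


@dataclass(frozen=True)
class ThermoPhase:
    cycles: int
    steps: tuple[ThermoStep, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not self.steps:
            raise ValueError("phase needs at least one step")


@dataclass(frozen=True)
class ThermoProgram:
    label: str
    phases: tuple[ThermoPhase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("program needs at least one phase")

    def annealing_temperatures(self, phase_index: int, step_index: int) -> list[float]:
        """Realized temperature of one step across the cycles of a phase."""
        phase = self.phases[phase_index]
        step = phase.steps[step_index]
        return [
            step.temperature_c - c * step.decrement_c for c in range(phase.cycles)
        ]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "phases": [
                {
                    "name": p.name,
                    "cycles": p.cycles,
                    "steps": [
                        {
                            "temperature_c": s.temperature_c,
                            "duration_s": s.duration_s,
                            "decrement_c": s.decrement_c,
                        }
                        for s in p.steps
                    ],
                }
                for p in self.phases
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = [f"Program: {self.label}"]
        for p in self.phases:
            head = f"  {p.name or 'phase'} x{p.cycles}:"
            body = "; ".join(
                f"{s.temperature_c:g} degC {s.duration_s} s"
                + (f" (-{s.decrement_c:g} degC/cycle)" if s.decrement_c else "")
                for s in p.steps
            )
            lines.append(f"{head} {body}")
        return "\n".join(lines)


def _extension_seconds(amplicon_len_bp: int, s_per_kb: int) -> int:
    if amplicon_len_bp < 1:
        raise ValueError(f"amplicon length must be positive, got {amplicon_len_bp}")
    return max(1, math.ceil(s_per_kb * amplicon_len_bp / 1000))


def touchdown_program(amplicon_len_bp: int) -> ThermoProgram:
    """Touchdown amplification program for a given amplicon length.

    98 degC 5 min; 20 cycles of 98/20 s, annealing 60 degC with a -0.5
    degC/cycle step, 20 s, 72 degC extension at 30 s/kb; 10 cycles with
    annealing fixed at 52 degC; final 72 degC 10 min.  Extension times are
    rounded up to whole seconds (minimum 1 s).
    """
    ext = _extension_seconds(amplicon_len_bp, 30)
    return ThermoProgram(
        label=f"touchdown-{amplicon_len_bp}bp",
        phases=(
            ThermoPhase(1, (ThermoStep(98, 300),), "initial denaturation"),
            ThermoPhase(
                20,
                (
                    ThermoStep(98, 20),
                    ThermoStep(60, 20, decrement_c=0.5),
                    ThermoStep(72, ext),
                ),
                "touchdown",
            ),
            ThermoPhase(
                10,
                (ThermoStep(98, 20), ThermoStep(52, 20), ThermoStep(72, ext)),
                "fixed annealing",
            ),
            ThermoPhase(1, (ThermoStep(72, 600),), "final extension"),
        ),
    )


def colony_pcr_program(amplicon_len_bp: int) -> ThermoProgram:
    """Colony-screen program: 95/2 min; 25x (95/30, 50/30, 68 at 1 min/kb);
    final 68 degC 10 min."""
    ext = _extension_seconds(amplicon_len_bp, 60)
    return ThermoProgram(
        label=f"colony-pcr-{amplicon_len_bp}bp",
        phases=(
            ThermoPhase(1, (ThermoStep(95, 120),), "initial denaturation"),
            ThermoPhase(
                25,
                (ThermoStep(95, 30), ThermoStep(50, 30), ThermoStep(68, ext)),
                "amplification",
            ),
            ThermoPhase(1, (ThermoStep(68, 600),), "final extension"),
        ),
    )


# ---------------------------------------------------------------------------
# reaction recipes

@dataclass(frozen=True)
class Component:
    name: str
    amount: float
    unit: str


@dataclass(frozen=True)
class RecipeSpec:
    """A 50-uL PCR master-mix recipe."""

    kind: str  # "Reaction 1" (double-primer) | "Reaction 2a"/"2b" (single)
    components: tuple[Component, ...]
    total_volume_ul: float = 50.0

    @property
    def primer_entries(self) -> list[Component]:
        return [c for c in self.components if "primer" in c.name.lower()]


def reaction_recipe(kind: str, single_primer: str = "forward") -> RecipeSpec:
    """PCR recipe for the double-primer or single-primer reaction.

    ``kind`` is ``"double"`` or ``"single"``.  The single-primer recipe
    uses ~500 ng template (about 10x the double-primer amount, compensating
    for linear accumulation) and exactly one primer, chosen by
    ``single_primer`` ("forward" -> Reaction 2a, "reverse" -> Reaction 2b).
    """
    if kind not in ("double", "single"):
        raise ValueError(f"kind must be 'double' or 'single', got {kind!r}")
    common = [
        Component("GC reaction buffer (5x)", 10.0, "uL"),
        Component("dNTPs (10 mM)", 1.0, "uL"),
        Component("DMSO (100%)", 1.5, "uL"),
        Component("High-fidelity DNA polymerase", 1.0, "uL"),
        Component("Water", 0.0, "to 50 uL"),
    ]
    if kind == "double":
        comps = [
            Component("Template DNA", 50.0, "ng"),
            Component("Forward primer (100 uM)", 0.25, "uL"),
            Component("Reverse primer (100 uM)", 0.25, "uL"),
            *common,
        ]
        return RecipeSpec("Reaction 1", tuple(comps))
    if single_primer not in ("forward", "reverse"):
        raise ValueError("single_primer must be 'forward' or 'reverse'")
    sub = "a" if single_primer == "forward" else "b"
    comps = [
        Component("Template DNA", 500.0, "ng"),
        Component(f"{single_primer.capitalize()} primer (100 uM)", 0.25, "uL"),
        *common,
    ]
    return RecipeSpec(f"Reaction 2{sub}", tuple(comps))


# ---------------------------------------------------------------------------
# ligation arithmetic

AVG_BP_MASS_G_PER_MOL = 650.0  # average mass of one base pair of dsDNA

# vector:insert policy bounds — between 1:10 (insert excess for routine
# cloning) and 6:1 (vector excess used for very large inserts)
RATIO_POLICY_BOUNDS = ((1, 10), (6, 1))
DEFAULT_SMALL_INSERT_RATIO = (1, 3)
DEFAULT_LARGE_INSERT_RATIO = (6, 1)
DEFAULT_LARGE_INSERT_THRESHOLD_BP = 10_000


def dsdna_pmol(length_bp: int, mass_ng: float) -> float:
    """Picomoles of a linear dsDNA fragment of given length and mass."""
    if length_bp <= 0 or mass_ng < 0:
        raise ValueError("length must be positive and mass non-negative")
    return mass_ng * 1000.0 / (AVG_BP_MASS_G_PER_MOL * length_bp)


@dataclass(frozen=True)
class LigationRecipe:
    vector_len_bp: int
    vector_pmol: float
    insert_len_bp: int
    insert_pmol: float
    insert_mass_ng: float
    ratio: tuple[int, int]  # vector : insert, molar
    volume_ul: float = 20.0
    incubation_temp_c: float = 25.0  # "room temperature"
    incubation_s: int = 7200
    inactivation_temp_c: float = 65.0
    inactivation_s: int = 600

    def __post_init__(self) -> None:
        if self.vector_pmol < 0 or self.insert_pmol < 0:
            raise ValueError("pmol values must be non-negative")
        ins_per_vec = self.ratio[1] / self.ratio[0]
        lo = RATIO_POLICY_BOUNDS[1][1] / RATIO_POLICY_BOUNDS[1][0]  # 1/6
        hi = RATIO_POLICY_BOUNDS[0][1] / RATIO_POLICY_BOUNDS[0][0]  # 10
        if not lo <= ins_per_vec <= hi:
            raise ValueError(
                f"molar ratio {self.ratio[0]}:{self.ratio[1]} outside the "
                "policy bounds 6:1 .. 1:10 (vector:insert)"
            )


def ligation_mix(
    vec_len_bp: int,
    ins_len_bp: int,
    vec_mass_ng: float,
    ratio_override: tuple[int, int] | None = None,
    large_insert_threshold_bp: int = DEFAULT_LARGE_INSERT_THRESHOLD_BP,
) -> LigationRecipe:
    """Ligation setup: molar amounts, required insert mass, incubation.

    Default policy: vector:insert 1:3 (insert excess) for routine inserts;
    6:1 (vector excess) at or above the large-insert threshold, where a
    molar excess of a 20-kb insert would dominate the reaction mass.
    Conversion uses the average dsDNA mass of 650 g/mol per bp.
    """
    if vec_len_bp <= 0 or ins_len_bp <= 0 or vec_mass_ng <= 0:
        raise ValueError("lengths and vector mass must be positive")
    if ratio_override is not None:
        ratio = ratio_override
    elif ins_len_bp >= large_insert_threshold_bp:
        ratio = DEFAULT_LARGE_INSERT_RATIO
    else:
        ratio = DEFAULT_SMALL_INSERT_RATIO
    vec_pmol = dsdna_pmol(vec_len_bp, vec_mass_ng)
    ins_pmol = vec_pmol * ratio[1] / ratio[0]
    ins_mass_ng = ins_pmol * AVG_BP_MASS_G_PER_MOL * ins_len_bp / 1000.0
    return LigationRecipe(
        vector_len_bp=vec_len_bp,
        vector_pmol=vec_pmol,
        insert_len_bp=ins_len_bp,
        insert_pmol=ins_pmol,
        insert_mass_ng=ins_mass_ng,
        ratio=ratio,
    )


# ---------------------------------------------------------------------------
# cloning-efficiency summary

@dataclass(frozen=True)
class EfficiencyRow:
    """One construct's colony-screen outcome."""

    gene: str
    gene_id: str | None
    length_bp: int
    vector: str
    checked: int
    positive: int
    genome_start: int | None = None
    genome_end: int | None = None

    def __post_init__(self) -> None:
        if self.checked <= 0:
            raise ValueError(f"{self.gene}: colonies checked must be > 0")
        if not 0 <= self.positive <= self.checked:
            raise ValueError(
                f"{self.gene}: positive count {self.positive} outside "
                f"0..{self.checked}"
            )

    @property
    def percent(self) -> float:
        return 100.0 * self.positive / self.checked


_TABLE_RESOURCE = "table2_efficiency.tsv"


def load_efficiency_table(path: str | None = None) -> list[EfficiencyRow]:
    """Load an efficiency table (TSV); defaults to the packaged benchmark
    table of 46 constructs."""
    if path is None:
        ref = resources.files("rfclone.data").joinpath(_TABLE_RESOURCE)
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype={"gene_id": "string"})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": "string"})
    rows = []
    for rec in df.to_dict("records"):
        rows.append(
            EfficiencyRow(
                gene=str(rec["gene"]),
                gene_id=None if pd.isna(rec.get("gene_id")) else str(rec["gene_id"]),
                length_bp=int(rec["length_bp"]),
                vector=str(rec["vector"]),
                checked=int(rec["checked"]),
                positive=int(rec["positive"]),
                genome_start=None if pd.isna(rec.get("genome_start")) else int(rec["genome_start"]),
                genome_end=None if pd.isna(rec.get("genome_end")) else int(rec["genome_end"]),
            )
        )
    return rows


def efficiency_summary(rows: list[EfficiencyRow]) -> dict:
    """Aggregate colony-screen outcomes.

    Returns the overall efficiency ``100 * sum(positive) / sum(checked)``,
    per-row percentages, and totals.  Percentages are reported truncated
    to one decimal place, the convention used when quoting colony-count
    efficiencies (a 320/368 screen reads 86.9%, never 87.0%).
    """
    if not rows:
        raise ValueError("efficiency_summary needs at least one row")
    checked = sum(r.checked for r in rows)
    positive = sum(r.positive for r in rows)

    def trunc1(x: float) -> float:
        return math.floor(x * 10.0 + 1e-9) / 10.0

    return {
        "overall_percent": trunc1(100.0 * positive / checked),
        "per_row_percent": {r.gene: trunc1(r.percent) for r in rows},
        "totals": {
            "constructs": len(rows),
            "checked": checked,
            "positive": positive,
        },
    }
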