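# rfclone

In-silico design and simulation of **restriction-free cloning with
PCR-generated cohesive ends** — for molecular biologists who want to
replace a stretch of a circular vector with an arbitrary insert, scarlessly,
without restriction sites, DpnI treatment, or recombination kits.

## The method

To replace the vector interval between junctions A and B (the *stuffer*)
with an insert, the k = 5–8 bp vector regions flanking the stuffer — the
"5' overhang" ending at A and the "3' overhang" starting at B — are used
as cohesive-end sequences. Eight primers are designed (~25 bp bodies, G/C
terminal bases preferred):

| role | template | composition (5'→3') |
|---|---|---|
| 1 / 2 | insert | plain forward / reverse pair |
| 3 / 4 | insert | overhang A + body 1 / revcomp(overhang B) + body 2 |
| 5 / 6 | vector backbone | plain forward / reverse pair |
| 7 / 8 | vector backbone | overhang B + body 5 / revcomp(overhang A) + body 6 |

Round 1: ordinary PCR with the plain pairs produces blunt fragments "1"
(backbone, excluding both overhang regions) and "2" (insert). Round 2: each
fragment is amplified in two *single-primer* linear reactions with the
tailed primers; annealing the resulting strand pairs ("3-1"+"3-2",
"4-1"+"4-2") yields duplexes "3" and "4" whose 5' protrusions are mutually
complementary. T4 ligase then closes the circle; both junctions
reconstitute the vector sequence exactly, so the construct equals the
direct splice.

`rfclone` implements every step as a deterministic simulation: primer
construction with the terminal-base rule, exact-match PCR on circular or
linear templates, single-primer strand synthesis, maximal-perfect-overlap
annealing with overhang annotation, cohesive-end compatibility and
ligation, rotation/flip-invariant construct verification with junction
excerpts and a predicted colony-PCR product, plus the bench-protocol
artifacts (touchdown and colony-PCR thermocycler cards, 50 µL reaction
recipes, molar ligation arithmetic, and colony-screen efficiency
statistics with a packaged 46-construct benchmark table).

## Worked example

Generate a seeded synthetic job (5 kb circular vector, 1.5 kb insert,
k = 6), design the primers, and simulate the whole cloning:

```bash
rfclone fixture --seed 1 --out-dir fx
rfclone design   --job fx/job.yaml --out-dir out
rfclone simulate --job fx/job.yaml --out-dir out
```

`out/primers.tsv` (abridged):

```text
name       role  direction  sequence_5to3                       body_len  tail    tm_body
insert-p1  1     forward    GAAGTCGTACGTGATTGGCGTTAG            24                60.42
insert-p3  3     forward    TTGTCAGAAGTCGTACGTGATTGGCGTTAG      24        TTGTCA  60.42
insert-p4  4     reverse    ACGAGGACCAGAATCTATAACTTCCTCTCTG     25        ACGAGG  55.58
vector-p7  7     forward    CCTCGTGCAATGCTATATCTAAACTAAGGAC     25        CCTCGT  53.91
vector-p8  8     reverse    TGACAATACTCGATACATTTACGGCGGATTTAAG  28        TGACAA  59.17
```

Here the overhangs are `TTGTCA` (side A) and `CCTCGT` (side B): primer 3
carries overhang A, primer 4 the reverse complement of overhang B, primer
7 overhang B, primer 8 the reverse complement of overhang A — the unique
tail assignment that makes both ligation junctions seamless. The simulate
step prints

```text
construct 4162 bp; identity=True
```

and writes `construct.gb` (annotated GenBank), `bands.tsv` (expected gel
bands: backbone fragment 2650 bp, insert 1500 bp, tailed strands 2656/1506
nt, final circle 4162 bp) and `verification.json`, which reports
`identity: true`, both junction excerpts matching, a predicted colony-PCR
product of 1526 bp on the construct and **no** product on the parental
vector (the insert primer has no binding site there — the negative
control).

The bench cards and the efficiency statistics of the packaged benchmark
table come from:

```bash
rfclone program --amplicon-len 2000 --kind touchdown --out-dir prog
# touchdown x20: 98 degC 20 s; 60 degC 20 s (-0.5 degC/cycle); 72 degC 60 s
# fixed annealing x10: 98 degC 20 s; 52 degC 20 s; 72 degC 60 s
rfclone stats
# 46 constructs; 320/368 colonies positive; overall 86.9%
```

Everything is also available as a library (`rfclone.design_primer_set`,
`rfclone.simulate_cloning`, `rfclone.efficiency_summary`, …); the CLI is a
thin wrapper.

## Output schemas

- `primers.tsv`: `name, role, direction, sequence_5to3, body_len, tail,
  tm_body, warnings` (warning codes, `;`-joined).
- `bands.tsv`: `label, length_bp`; sticky duplexes contribute
  `<label>/top`, `<label>/bottom` (strand lengths) and `<label>/span`.
- `verification.json`: `identity`, per-junction `{side, matches, excerpt}`,
  `colony_pcr_bp`, `parental_control_bp`, lengths, and the full config echo.
- `construct.gb`: circular GenBank with overhang-A/insert/overhang-B
  features.
- FASTA headers carry the keyword `circular` for circular topology;
  GenBank topology uses the LOCUS flag.
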