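# Methods

## The cloning scheme being modeled

`rfclone` simulates a restriction-free cloning strategy in which the
cohesive ends needed for ligation are manufactured by PCR rather than by
restriction digestion. The design problem is: given a circular vector, an
insert, and two junctions A and B on the vector, replace the vector
interval strictly between A and B (the *stuffer*) with the insert, leaving
no scar. The two k-base vector regions flanking the stuffer — the k bases
ending at junction A ("5' overhang" region, side A) and the k bases
starting at junction B ("3' overhang" region, side B) — are retained
vector sequence and double as the cohesive-end sequences.

The workflow has four in-silico stages, mirroring the bench procedure:

1. **Primer design** (`primer_design`). Eight oligos: a plain
   forward/reverse pair per template (insert and vector backbone), plus a
   tailed copy of each. Tails are fixed by the seamless-junction
   requirement: insert-forward tail = overhang A, insert-reverse tail =
   revcomp(overhang B), vector-forward tail = overhang B, vector-reverse
   tail = revcomp(overhang A). This is the unique assignment (up to
   swapping the two fragments) for which the ligated circle equals the
   direct splice; the end-to-end property test exercises exactly this
   claim.
2. **Round-1 PCR** (`amplify_sim.pcr_amplify`). Double-primer exponential
   amplification of the insert (the whole insert) and of the vector
   backbone *excluding* both overhang regions (from B+k forward around the
   circle to A−k). Excluding the overhang regions from the double-stranded
   amplicon is essential: each overhang must enter the construct exactly
   once, carried as a single-stranded tail.
3. **Round-2 single-primer PCR and annealing**
   (`linear_amplify`/`anneal`). Each round-1 duplex is amplified twice,
   once with the tailed forward primer and once with the tailed reverse
   primer. Each reaction yields one full-length single strand (tail +
   strand copy). Annealing the two strands gives a duplex whose
   double-stranded core is the round-1 amplicon and whose unpaired 5'
   tails are the cohesive ends.
4. **Ligation and verification** (`assembly_sim`). Two ends ligate iff
   both are 5' protrusions on opposite strands, equal in length, and
   reverse-complementary. The closed circle is compared to the *reference
   splice* (stuffer replaced by insert, computed by direct string
   surgery) rotation- and strand-flip-invariantly, each junction is
   checked through a ±30 bp excerpt (the in-silico stand-in for a
   sequencing read across the seam), and a colony-PCR product size is
   predicted from a backbone-anchored forward primer and an
   insert-anchored reverse primer; on a parental, insert-free plasmid the
   insert primer has no site and the product is reported absent.

## Modeling assumptions

- **Exact-match priming.** A primer body must occur exactly once on its
  template; zero hits and multiple hits are errors. The simulation models
  the intended reaction; mispriming, polymerase errors and secondary
  structure are out of scope.
- **Single-primer PCR yields only the full-length tailed strand.**
  Accumulation is linear (~30-fold over 30 cycles), which the recipes
  acknowledge by prescribing ~10× template, but stoichiometry does not
  change sequence outcomes, so molecules are not counted.
- **Perfect-complement annealing.** The annealing alignment is the
  maximal perfect complementary overlap (minimum core 15 nt by default);
  near-complementary pairs raise a mismatch error with positions instead
  of forming a partial duplex. Determinism is preferred over a
  thermodynamic hybridization model.
- **Blunt parental duplexes are carried as contaminants but never
  ligated**, reflecting the fact that cohesive ligation outcompetes
  blunt ligation strongly enough that round-1 template removal is
  unnecessary.
- **Only two-fragment circular assembly** is modeled; multi-fragment
  assembly is a possible extension but untested.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 6 nt | cohesive-end length; policy range 5–8 nt (shorter ends anneal too weakly, longer ones stop behaving as simple protrusions). 6 is the midpoint; `relax_k` lifts the bound for toy examples. |
| `body_target`, `body_window` | 25, 20–32 nt | primer-body length target and search window. The junction-anchored end cannot move, so only the 3' end is tuned: among window lengths whose 3' base is G or C, the closest to target wins, ties to the shorter. A violating oligo gets a machine-readable warning, never a silent fix — the G/C-terminus rule is a design preference, not a correctness requirement. |
| `tm_model` | `nn` | nearest-neighbor Tm (Allawi & SantaLucia 1997 table, SantaLucia 1998 entropic salt correction) at 50 mM Na⁺, 500 nM oligo, computed via Biopython and pinned so values are stable across library versions; `gc_fallback` selects the classical 64.9 + 41·(nGC−16.4)/N formula. |
| `min_core` | 15 nt | minimum perfect complementary core for annealing; automatically reduced to the fragment length on toy inputs. |
| `large_insert_threshold_bp` | 10 000 | ligation policy switch: vector:insert 1:3 (insert excess) below, 6:1 (vector excess) at or above; the exact switch point is not prescribed by the protocol this mirrors, so it is configurable. Allowed ratios span 6:1 to 1:10. |
| `anchor_offset_a/b` | end / start | when junctions are given as anchor subsequences, which anchor base is the junction. The convention (junction A = last base of the upstream anchor, junction B = first base of the downstream anchor) keeps both anchors inside the retained sequence. |

Protocol constants (thermocycler cards, 50 µL recipes, 650 g/mol/bp for
molar conversion, 25 °C for "room temperature") are fixed in `protocol`
and echoed verbatim into exported cards. The touchdown annealing ramp is
implemented literally — start 60 °C, −0.5 °C per cycle, 20 cycles — and
therefore ends at 50.5 °C; extension times are 30 s/kb (touchdown) and
60 s/kb (colony screen), rounded up to whole seconds with a 1 s floor,
since thermocyclers take integer seconds.

Percent efficiencies are reported truncated (not rounded) to one decimal,
the convention used when quoting colony-count efficiencies: a 320/368
screen reads 86.9%.

## The synthetic-data generator

`fixtures.generate_fixture(seed, vector_len, insert_len, k, gc_fraction)`
emulates the inputs of a real cloning campaign: an i.i.d.-random circular
vector with a randomly placed stuffer (30 bp up to everything that leaves
an 80 bp primer-design backbone), and an i.i.d.-random linear insert.
Overhang regions are redrawn (bounded retries) until they are neither
identical nor self-complementary — the two degeneracies that defeat
cohesive-end specificity and that `validate_overhangs` flags. Defaults
(vector 5 kb, insert 1.5 kb, GC 0.5) match a typical expression-vector
cloning job; the test and acceptance batteries span vector 3–10 kb,
insert 0.1–20 kb and k ∈ {5..8}, the ranges over which the modeled bench
protocol was exercised.

What the generator does **not** emulate: repeats and low-complexity
regions (real genomes can break the unique-priming precondition),
biological composition (genes, promoters, codon structure), sequencing
noise, and any source of wet-lab failure. Passing round trips therefore
demonstrate the *logical* correctness of the design rules — that the
eight-primer construction reconstitutes the intended construct exactly —
not the empirical colony-level success rate, which is an experimental
quantity the packaged benchmark table records rather than predicts.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive throughout the API; circular
  arithmetic is modulo length; linear out-of-range access raises.
- Circular identity uses the doubled-string containment test (rotation
  invariant), optionally over both strands; a ligated circle has neither
  an origin nor a defined top strand.
- Annealing ties (equal maximal overlap at several offsets) break toward
  the smaller absolute shift; with a 15 nt perfect core the probability
  of a competing random alignment is ~4⁻¹⁵ per offset, so ties are
  effectively confined to adversarial inputs.
- `N` bases are accepted in inputs but rejected inside overhang regions
  and primer bodies: ambiguity cannot be primed or ligated
  deterministically.
- Empty stuffers (pure insertion, junction B immediately after A) are
  legal; empty inserts are not.
- The overhang regions, stuffer and backbone core must tile the vector
  exactly; any overlap (e.g. k too large for a short vector) is a
  geometry error at job construction, before any simulation runs.

## Known limitations

- Unique-priming failures on repetitive templates surface as
  `AmbiguousPrimingError` rather than being resolved by position or
  annealing energetics.
- Tm values are equilibrium estimates for the body only; tails are
  excluded by construction (they do not pair with template in round 2's
  first cycles).
- Band-size prediction reports sequence lengths only; open/closed
  circular forms migrate differently on a real gel but have the same
  length.
- The efficiency summarizer analyzes colony-count tables; it does not
  model why individual colonies fail (empty vector vs. junction error),
  which the benchmark table does not resolve either.
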