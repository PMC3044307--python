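# Methods

## Model and estimation

The predictor assigns each residue one of three secondary-structure states
(H = α-helix, E = extended/β-strand, C = coil) from the 17-residue window
centered on it (8 neighbors each side). Positions beyond either end of the
sequence read a boundary symbol X, which also absorbs non-canonical
residue letters; the working alphabet is therefore 21 symbols, encodable
in 5 bits.

Both parameter tables hold *information differences*: the log likelihood
ratio of an observation under state *s* versus the pooled complement ¬s,
estimated from counts with a pseudocount δ:

    info(c_s, c_¬s) = ln((c_s + δ)/(c_¬s + δ)) + ln((n_¬s + δ)/(n_s + δ))

where n_s and n_¬s are the total window counts per class. The second term
converts raw counts into conditional frequencies, so an uninformative
observation scores 0 exactly. The directional table `dir` (3 × 17 × 21)
uses singlet counts per window offset; the pair table `pairinfo`
(3 × 136 × 21 × 21) uses counts of the ordered residue types at each of
the C(17,2) = 136 unordered window-position pairs.

The combination

    I_s = (2/17) Σ_{pairs} pairinfo − (15/17) Σ_{offsets} dir

is fixed by a consistency condition: each singlet participates in 16
pairs, so if the pair information degenerates to the sum of its two
singlet terms, the expression collapses to the plain singlet sum
(2/17·16 − 15/17 = 1). Scores become probabilities via a max-shifted
softmax (overflow-safe, shift-invariant); the argmax names the state with
ties broken by the fixed priority H > E > C. Because each table entry is a
pure likelihood-ratio contrast, a model trained on data with no
sequence–structure signal produces scores near 0 for every state: the
no-information decision is near-uniform rather than majority-class. The
"chance" level a zero-signal model is compared against is therefore
bounded above by the best constant predictor (the majority-state rate) and
sits near the uniform-guess rate in practice; the acceptance suite asserts
the bound, not equality with the majority rate.

## Streaming lookup accounting

One "read" is one table-address access returning the packed 3-state value
vector. The streaming engine enumerates *ordered* window-position pairs
(j, k), j ≠ k, reading the unordered entry (min, max) with weight 1/17 —
17·16 = 272 pair reads plus 17 directional reads per residue —
algebraically identical to the 2/17-weighted unordered sum (136 reads),
which is kept as an independent reference path; the two agree to ~1e-15 in
float64 and the suite enforces 1e-12. The pair table is also addressable
as 136 independent segments (one per position pair, 3 × 21 × 21 values
each), mirroring a banked-memory layout; segmentation is an exact
partition. Per state the float64 pair table occupies 21·21·136·8 bytes =
479,808 bytes (468 KB after flooring to kilobytes).

## Correction passes

The two post-prediction scans implement minimum-run smoothing with
physically motivated defaults: a helix shorter than one α-turn
(min_helix_run = 4) is dissolved residue-by-residue into whichever of E/C
has the higher predicted probability (tie → C); a strand shorter than
min_strand_run = 2 becomes coil. Helix smoothing runs first so its E
conversions are vetted by the strand pass; since pass 1 never creates H
and pass 2 never creates H or E, the composite is idempotent. These rules
are a declared, configurable substitute for the original GOR-IV correction
heuristics, whose exact rules are unpublished; the package's contracts
(run-length postconditions, idempotence) are what downstream code may rely
on.

## Pipeline semantics

The three-stage architecture becomes one prediction worker feeding N
correction channels (default 2) through a bounded queue (default capacity
4 sequences, a configurable stand-in for unspecified hardware buffer
sizes), with sequences assigned to channels first-free. The contract
replaces hardware timing semantics: every input id is delivered exactly
once, and the result multiset is bit-identical to the serial path for
every channel count and buffer size. Output order is either FCFS
(completion order, with ordinals recorded) or input order; input order is
the file-writing default because byte-reproducible output matters more in
software than DRAM write order did in hardware.

## Quantization

Tables may be stored as int32 with `stored = round(value · scale)`,
rounding half away from zero, default scale 2^16. Information values span
a few nats, so the scaled magnitudes sit comfortably inside 32 bits
(overflow raises). The per-entry dequantization error is ≤ 0.5/scale ≈
7.6e-6 nats; a worst-case bound on the induced score perturbation is
31·(0.5/scale) ≈ 2.4e-4 nats, so argmax decisions flip only at near-ties.
On the default synthetic dataset the float and quantized models agree on
every residue; across other seeds agreement stays above 99.99%, which is
what "without affecting accuracy" is taken to mean operationally.

## Synthetic data

The generator emulates exactly the two features of real secondary-structure
data that a windowed information predictor exploits: geometric run lengths
(first-order Markov chain over H/E/C, self-transitions 0.90/0.85/0.80,
remainder split evenly, started from the stationary distribution ≈
(0.46, 0.31, 0.23)) and state-dependent residue composition. Emissions
blend a shared background with hand-set propensities (weight 3:1 for
helix formers A/E/L/M/Q/K/R/H in H, β-branched and aromatic V/I/F/Y/W/T/C
in E, breakers G/P/N/D/S in C) under a contrast knob κ ∈ [0, 1]; κ = 0
removes all learnable signal. Defaults: 300 sequences, geometric lengths
of mean 150, κ = 0.8. It does not emulate residue–residue correlation
within a state, sequence-dependent transitions, state-specific length
laws, or real DSSP statistics — so passing tests demonstrate correct
estimation and decision machinery under the model's own assumptions, not
accuracy on real proteins (historically ~64% Q3 for single-sequence GOR
variants).

## Problem sizes and numerical choices

The test and acceptance workloads use the default 300-sequence training
draw (~47k residues), 100-sequence held-out sets (~15k residues), 1000
random windows for the summation-equivalence check and 1000 random state
strings for the correction invariants; these sizes give stable Q3
estimates (binomial s.e. ≈ 0.4 percentage points) at a few seconds of
runtime. Pseudocount δ = 1 guarantees finite tables on any training set,
including single-record ones. The model file is a bespoke little-endian
binary (magic, version, geometry, quantization flag + scale, then the
tables state-major); round-trips are bit-exact and truncation, foreign
magic and version mismatches are reported explicitly.

## Known limitations

- Three-state prediction from single sequences only: no evolutionary
  profiles, no 8-state DSSP reduction, no real-database parsers.
- The correction rules and the training-database text format are declared
  stand-ins where the original package left them unspecified.
- Dataset-level Q3 is residue-pooled; no segment-overlap (SOV) metric.
- Concurrency is real threading but the contract is deterministic results,
  not cycle-level timing fidelity.
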