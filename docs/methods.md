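# Methods

This note documents the models and procedures implemented in `ampliflow`,
the parameters that matter, the numerical conventions, and the design
choices made where the design was genuinely open.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

A flow-based run is a cyclic *flow order* (e.g. `TACG` repeated) and, per
read, a *flowgram*: one non-negative real flow value per wash, printed and
processed at hundredths precision, whose rounded value is the homopolymer
length incorporated at that wash.  The `sffio` module parses the
established plain-text dump of an SFF file (key/value header declaring
`Flow Chars` and `# of Flows`; per-read blocks with `Flowgram`,
`Flow Indexes`, `Bases`, `Quality Scores`, `Clip Qual Left/Right`).  Two
dialect tolerances: flow-chars strings are reduced to their minimal
repeating unit, and flow-index columns that ever decrease are interpreted
as per-base deltas and cumulatively summed.  Clip points, 1-based inclusive
on disk, are converted once to 0-based half-open; all internal coordinates
are 0-based half-open.  Malformed read blocks are skipped, logged with id
and line number, and counted.

## Filtering

Only one criterion is mandatory: a read must match some sample's mid tag
and forward primer at its 5' end.  Matching is anchored Hamming comparison
(no indels): mid tags are designed sequences and compared literally, while
primers routinely carry degenerate positions, so IUPAC codes are honoured
on the primer side only.  Defaults allow 1 mid and 2 primer mismatches.

Optional criteria then apply in a fixed order: minimum length
(elimination), maximum length (elimination), truncation before the
(max+1)-th ambiguous base, truncation before a reverse-primer site (the
reverse complement of the sample's reverse primer, leftmost hit within the
primer-mismatch allowance), and a sliding quality window (length `w`, step
1 base): the read is cut immediately before the start of the first window
whose mean quality falls below the threshold.  After all truncations the
minimum length is re-checked; an elimination at that point is attributed to
the criterion that truncated last.  Each eliminated read is counted under
exactly one criterion (the first to fire); truncation counters are
independent, so one read may appear under several.  The common recipe
`FilterConfig.standard()` is length 200–600, no ambiguous bases, reverse
primer removal, and a 50-base window at mean quality 25.

A passing read's flowgram is cut to the flows of its retained bases using
the flow index: from the flow of the first kept base through the flow of
the last kept base inclusive, interior zero flows preserved.  If a
homopolymer spans the primer/insert junction, the shared flow is kept with
the primer's contribution inherent in its value; the synthetic generator
avoids this case by construction (reference first base ≠ primer last
base), and real primer choices normally do too.

**Binning.**  Flowgrams are positionally comparable only if their first
retained flow sits at the same offset within the flow cycle.  Because a
base is always incorporated at a flow of its own nucleotide, that phase is
determined by the first retained base's identity alone.  Filtered reads are
therefore binned by (forward primer, cycle phase) — per primer in the
common case, with phase sub-bins appearing only when inserts start with
different nucleotides.  Each bin file carries its flow order and phase in a
header line.

## Denoising distance

`distinct(center, read)` is true iff `|center − read|` exceeds the
threshold.  The comparison is **boundary inclusive** (a difference exactly
equal to the threshold is not significant), which makes the not-distinct
interval closed: with a constant distance of 0.50 and a center of 1.09,
queries in `[0.59, 1.59]` are not distinct.  A guard epsilon of 1e-9 —
seven orders of magnitude below the hundredths resolution of flow values —
absorbs binary-float representation error at that boundary and can never
change a decision at the data's native precision.

Three models: constant `j > 0`; `k·σ(n)` with a per-homopolymer-length
standard-deviation table (required non-decreasing in `n`, since flow noise
grows with signal); or a custom per-length distance table used directly.
Table lookups index by the **center's** value rounded half-down (the
center, an average, is the stabler side; which side the original approach
indexes by is not documented, and the alternative would differ only inside
a half-flow band around rounding boundaries).  Lookups beyond the table's
last entry reuse the last entry and log once.  No standard-deviation table
is hard-coded: the shipped default lives in `synthgen.DEFAULT_SD_TABLE`,
is labelled synthetic, and is a replaceable parameter.

## Clustering denoiser

Pass 1 processes reads in input order.  A read matches a cluster iff no
overlapping flow position is distinct; a length difference alone never
rejects, because reconstitution later truncates each read to its own flow
count.  "In turn" is first-match in creation order, not best-match — the
second pass's populous-first ordering only makes sense under first-match
semantics.  On joining, the center updates as a running weighted mean per
position; a read longer than the center extends it with count 1.  The
per-position member counts make `center[p]` the exact arithmetic mean of
the values of members long enough to reach `p` (verified against a
brute-force recomputation to 1e-9).

Pass 2 sorts clusters by pass-1 size (ties by creation order), freezes the
centers, and re-assigns every read first-match down the sorted list, so
reads map to the most populous cluster that accepts them; this undoes
pass-1 drift.  Exactly two passes are run.  A read matching no frozen
center — a case the procedure's description leaves open — founds a
singleton appended after the sorted list (conservation requires every read
to land somewhere); clusters left empty by pass 2 are dropped from the
output.  The match scan short-circuits at the first failing position; that
failing (center, read) value pair is recorded in the miss histogram in both
passes.

**Miss histogram.**  A 2-D grid over (center value, read value), bin width
0.01 (the native precision) on [0, 10] with clamping; written as a sparse
TSV, with an optional levelplot rendering behind matplotlib.  Dense mass
just outside the central stripe ("close misses") is the diagnostic that a
larger distance may suit the dataset.

## Trie denoiser

Each read is threaded from the root: among the current node's children
whose edge value is not distinct from the read's next flow value, the
closest wins (ties: smaller edge value, then older child — the procedure
is silent on ties, and this choice is deterministic); its edge mean and
traversal count update; otherwise a new child is created.  The last flow's
node gets a terminal mark.  There is no second iteration, which is what
makes the trie sensitive to the distance choice.  A read's denoised
flowgram is read off its root→terminal path *after all insertions*, so it
reflects final weighted means, mirroring the clustering module's frozen
final centers.  Terminal marks are never moved into descendants.  Leaf
abundance — used for chimera-checker inputs — is the sum of terminal
counts on the leaf and its ancestors, so leaf abundances may sum to more
than the read count when reads end mid-path below several leaves.

Clustering and the trie produce identical groupings for reads of identical
flowgrams; as full partitions they coincide only when no group's flowgram
is a within-threshold prefix of another's (clustering merges across
lengths over the overlap; the trie separates terminals by depth).

## Base calling (reconstitution)

A flow value `v` calls `h` copies of the flow's nucleotide, where `h` is
`v` rounded to the nearest integer with a fractional part of exactly .50
rounded **down** (the prevailing behaviour of the vendor software); the
.50 test happens on integer hundredths, never on floats.  "Insufficient
signal" is defined as a flow calling zero bases (`v ≤ 0.50` under
half-down): after every completed run of exactly `n_dropout_flows`
(default 3, i.e. a full cycle minus one for a 4-nucleotide order) such
flows, one `N` is emitted — a run of 6 yields two Ns.  Negative flow
values are clamped to zero with a warning.

Each read is reconstituted from its assigned cluster/trie flowgram
interpreted only up to the read's own filtered flow count and at its bin's
cycle phase.  This per-read truncation is what prevents the accordion
effect.  Since dropout runs in an individual read usually vanish in the
averaged center, an `N` present after filtering can legitimately become a
regular base after denoising; such conversions are tallied separately by
the evaluator.

## Change spectrum and error rates

Each filtered read is aligned to its denoised self by global
Needleman–Wunsch (match +1, mismatch −1, linear gap −1 — a deliberately
simple stand-in for a low-gap-penalty aligner; only the in/del vs
substitution classification matters, not parity with any particular
aligner).  The score recursion is row-vectorised in numpy (the in-row
dependency of a linear gap resolves to a prefix maximum), and traceback
ties break diagonal → up → left, making outputs deterministic.  Gap in the
post sequence = deletion, gap in the pre sequence = insertion, mismatched
pair = substitution; N↔base substitutions are also counted separately.
Swapping the inputs swaps insertion and deletion counts exactly.

Against references, each read is aligned to every reference with **free
end gaps on the reference side**, so 3' truncations made by filtering are
not charged as deletions; the best score wins (ties by reference file
order).  Only internal insertions and deletions are counted — the dominant
error form in flow-based data — over the total aligned read length.

## Synthetic data generator

The generator emulates: ideal integer flowgrams from mid+primer+insert
templates; Gaussian flow noise with standard deviation growing with
homopolymer length, clamped at zero, quantised to hundredths; base calls,
flow indexes and clip points derived from the *noisy* values with the same
half-down caller, so reads contain genuine in/del errors; and quality
scores with a linearly decaying mean (37 − 0.02/base), Gaussian jitter
(sd 2), clamped to [0, 40] — enough to exercise the window filter, with no
claim of platform realism.

Defaults define the standard study conditions: 5 references of length 250,
40 reads each (200 reads), flow order TACG, two samples sharing one
primer, and the synthetic sd table σ(n) = 0.08 + 0.02·n capped at 0.22.
The anchor σ(0) = 0.08 and gentle monotone growth were fixed a priori as a
moderate noise regime: strong enough that a run of 200 reads contains a
handful of real homopolymer miscalls, weak enough that reads overwhelmingly
stay within a 0.50 distance of their reference's center.  Mid tags begin
with the flow order's first nucleotide, mirroring key-anchored real reads.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: PCR chimeras and single-base PCR errors,
carry-forward/incomplete-extension (CAFIE) flow artifacts, spatial quality
effects, heavy-tailed or systematically miscalibrated flow noise, and
variable read start points.  Real 454 noise is substantially heavier than
the default table; on real data one should expect far more clusters than
references and should tune the distance on the miss histogram and change
spectrum, not on simulated recovery.

A structural property of this noise model worth stating plainly: a flow
value that rounds to the wrong integer lies, by definition, more than half
a unit from the true value — and therefore almost surely more than 0.50
from its cluster center.  At a constant distance of 0.50, erroneous reads
are thus usually *rejected* (forming singletons) rather than corrected;
correctable errors are confined to values landing exactly on the `.50`
boundary or within the center's small offset from the true integer.
Larger distances (0.7–0.9) correct substantially more errors, which is
why error-rate improvement under Gaussian noise at 0.50 is real but small,
and why singletons alongside the reference clusters are the expected
outcome, not a defect.

## Round-trip inversion

For clean (integer) flowgrams the caller inverts the ideal-flowgram
construction exactly, provided the sequence's first base is not preceded
by a full dropout-length run of empty flows in the cycle (over TACG, a
G-initial sequence opens with three zero flows, indistinguishable from
true dropout — the ambiguity real platforms resolve with a key sequence).
Accordingly the inversion tests draw first bases from the first three
cycle nucleotides, matching generated reads.  Ideal flowgrams end at the
flow that consumes the last base, without padding out the final cycle:
padding would append zero-flow runs that the dropout rule must flag as an
N, breaking inversion.

## Numerical conventions and degenerate inputs

Flow values are quantised to integer hundredths before any rounding or
boundary decision.  An empty bin denoises to empty outputs successfully;
empty sequences are skipped by the FASTA writer with a warning; an empty
kept-base interval in flowgram trimming is an error (the caller must have
eliminated the read); a distance table that is gapped, non-positive, or
(for the scaled mode) decreasing is rejected at construction; `j ≤ 0` and
`k ≤ 0` are rejected.  Identical inputs and model yield bitwise-identical
cluster maps; the generator is byte-stable for a given seed.

## Problem sizes

The test suite's standard benchmark uses 200 reads of length 250 from 5
references, denoised at four constant distances, and the aligner-oracle
checks cover all sequence pairs up to length 3 over a reduced alphabet
plus seeded samples up to length 8 — sizes chosen so the whole suite runs
in seconds while every code path is exercised at full fidelity.
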