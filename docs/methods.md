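# Methods

This note documents the models, conventions and numerical choices behind
`diagpcr`, the places where the design was genuinely open, and what the
synthetic fixtures do and do not establish about real data.

## Data model and coordinates

A `SpeciesAlignment` is a list of equal-length, species-labelled IUPAC
nucleotide sequences with `-` for gaps. All column coordinates are
0-based half-open, so span arithmetic (amplicon length, window overlap)
is free of off-by-one ambiguity. `U` is normalised to `T` at ingest
because rDNA spacer sequences are sometimes deposited as RNA, and
duplicate record ids are rejected outright: silently dropping a panel
member would corrupt any downstream specificity claim. Every record is
treated as an independent panel member; intraspecific ribotypic variants
are simply additional records of their species.

## Diagnostic columns and signature windows

For a column, the target state set is the set of characters observed
among target records; degenerate codes expand to their base sets and the
gap is a state of its own. The column is *diagnostic* against non-target
species S when the expanded target set and the expanded state set of S do
not intersect. Two consequences are intentional:

* **Indel columns count.** If the target has a base where S has a gap (or
  vice versa) the column is diagnostic — probes can be, and in practice
  are, designed across indels.
* **Degeneracy is conservative.** A degenerate panel base that *could*
  match the target removes the column from the diagnostic set, so
  ambiguity in panel sequences can only make the scanner stricter, never
  more permissive.

A probe site must contain, for every non-target species, a run of at
least 5 consecutive diagnostic columns; the run may sit at a different
position per species (requiring a single shared run is stricter than any
published criterion we know of, and is available by post-filtering on
the reported per-window run statistics). A primer site needs at least 3
diagnostic positions, not necessarily consecutive, and only one primer of
the pair has to clear that bar — the companion primer only needs
conserved target sequence. Windows meeting the primer bar against a
proper subset of species are reported with a `partial` flag.

Within a window the target must be effectively invariant. Columns where
the target mixes gap and base are never usable. Columns of pure
intraspecific base variation are disqualified by the scanner's default
(`max_variable_columns=0`) but the assay designer grants a budget of one
such column per oligo, emitting it as the IUPAC code of the base union —
the same convention that puts a single M into a real 30-mer probe. Length
constraints apply to the *degapped* window length, i.e. the number of
bases the oligo actually has.

The scanner is deliberately exhaustive — every qualifying (start, end)
window is returned, sorted — and is validated against a brute-force
enumeration oracle on random alignments in the test suite.

## Oligo thermodynamics

Two closed-form Tm models are implemented, matching the OligoCalc
calculator conventions that appear next to published oligo tables:

* basic: Wallace rule `2(A+T) + 4(G+C)` for N < 14, else
  `64.9 + 41·(GC − 16.4)/N`;
* salt-adjusted (the reference value):
  `Tm = 100.5 + 41·GC/N − 820/N + 16.6·log10[Na+]`, default
  [Na+] = 0.05 mol/L.

Both depend only on length and G+C count, so degenerate oligos yield a
closed interval evaluated at the minimum and maximum resolvable G+C
counts; non-degenerate oligos always give a zero-width interval. %GC
counts a degenerate code as G/C when its base set contains G or C
(`max_gc`, the convention that reproduces published degenerate-probe
values); `min_gc` and `expected` policies are provided. Reported values
round half-up to one decimal, with trailing `.0` printed as an integer
and degenerate Tm intervals printed as integer ranges (`68–69`), matching
oligo-table typography. Nearest-neighbor thermodynamics are deliberately
out of scope: the closed forms are pinned by the published table this
module is meant to reproduce, and four of the nine published Tm entries
differ from the closed form by up to 0.3 °C (an unrecoverable variant or
rounding of the original calculator), which the tests treat as slack
rather than forcing.

## Assay assembly and ranking

A candidate is a forward/probe/reverse window triple in alignment order
with: degapped amplicon length inside the configured interval (default
60–150 bp, preferring ~80 bp — short amplicons tolerate degraded DNA);
primer %GC 30–70 and salt-adjusted Tm 50–65 °C; probe Tm at least 5 °C
above the hotter primer (the standard hydrolysis-probe rule, compared on
interval midpoints); probe run ≥ 5 against every species; and at least
one primer fully covering every species with ≥ 3 differences. The reverse
primer is emitted bottom-strand 5′→3′ via IUPAC-aware reverse complement.
The probe is emitted on the top strand; a bottom-strand probe is the
reverse complement and has identical GC/Tm, so no information is lost.
No 3′-end mismatch weighting is applied.

Ranking is lexicographic and fully deterministic: worst-case probe run
(descending), then the summed worst-case primer mismatch counts
(descending), then |amplicon − 80| (ascending), then 5′-most coordinates.
On realistic alignments the qualifying triple space is dominated by
±1-column shift variants of the same signature and can reach millions of
triples, so the search scores the *entire* space vectorised (the rank key
packs into one 64-bit integer per triple; window lists are coordinate-
sorted so index order doubles as the positional tie-break) and
materialises only the `max_candidates` best (default 200;
`None` materialises everything, which is how the designer is checked
against a brute-force triple oracle on small alignments). Alignments
producing ≥ 2¹⁴ windows per role are refused with advice to restrict the
region, a limit far above any single-locus marker alignment.

## In-silico specificity screen

Mismatches are counted column-wise on the shared alignment against the
target consensus: a column mismatches when the record's expanded state
set does not intersect the oligo's, gaps count (a 2-base deletion inside
a primer footprint is 2 mismatches), and at columns where the target is
all-gap the oligo "expects" absence, so an insertion is a mismatch. A
record amplifies when *all three* oligos are within the per-oligo
threshold — the probe is part of the predicate because an unbound
hydrolysis probe produces no signal even if the primers extend. The
default threshold of 3 models permissive cycling conditions, which can
tolerate up to about three mismatches per oligo; a stringent preset of 1
supports sensitivity analysis. Whether a few mismatches are tolerated
per-oligo or summed across oligos is ambiguous in the field's usage; the
per-oligo reading is the permissive (safer for specificity claims) one
and is the default. Because the probe criterion plants ≥ 5 consecutive
differences, every designed assay blocks every non-target design record
at threshold 3 by construction; the suite asserts this end-to-end.
Counting is not re-alignment-based: records are screened in the
coordinate system they were designed in. Screening raw, unaligned
sequences would need a sliding-window mode, which is out of scope.

Panel metrics are plain confusion counts: inclusivity = 100·TP/(TP+FN),
specificity = 100·TN/(TN+FP), with an empty denominator reported as
undefined (`None`), never as 0.

## Duplex run interpretation

`None` encodes "no amplification" — never Cq 0 or 40 — so no arithmetic
can silently use a sentinel. A channel is *detected* when its Cq exists
and is at most `cq_cutoff` (default 39, the cycle count of the run
protocol; Cq values above `max_cycles` are input errors). The decision
tree is total over the domain including `None`:

| diagnostic | control | call |
|---|---|---|
| + | +, abs(ΔCq) ≤ 6 | TARGET_POSITIVE (DCQ_WARN if > 4) |
| + | +, abs(ΔCq) > 6 | ANOMALOUS (retest) |
| − | + | NOT_TARGET |
| + | − | ANOMALOUS (control failure, retest) |
| − | − | INVALID_DNA (re-extract) |

ΔCq = control − diagnostic (positive when the diagnostic probe fires
earlier, as for true targets); QC uses its absolute value, and swapping
channels flips its sign — a property test guards against channel
mix-ups. The warn/fail bounds of 4 and 6 cycles come from observed duplex
behaviour on real validation panels (ΔCq normally within 4 cycles,
occasionally up to 6); the exact thresholds of the original decision
chart are not published, so all of them are parameters. The distinction
between "retest" and "re-extract" arms is carried as advisory strings on
the two anomaly classes rather than extra call values. Any signal in
either channel of a no-template control invalidates the entire run and
specimen outcomes are withheld; a missing NTC validates with a warning.
Replicate wells aggregate by the median of detected replicates (mean
optional) before classification.

## Standard curves

Replicates are aggregated per concentration (mean by default, matching
the convention of averaging Cq per dilution step; median optional), then
Cq is regressed on log10(concentration) by ordinary least squares.
Not-detected replicates are excluded from the fit — mixing censored
observations into OLS would bias the slope — but drive the limit of
detection, which is the lowest concentration whose replicates satisfy the
chosen rule (`all_replicates` default, `any_replicate` optional).
Efficiency `E = 10^(−1/slope) − 1` is standard qPCR practice and is
reported as auxiliary output (undefined with a warning when the slope is
non-negative); a non-decreasing aggregated Cq with rising concentration
raises a monotonicity warning. Concentration units pass through verbatim
and are never converted. On noiseless log-linear input R² = 1 to 1e−12,
and fits match an independent normal-equations oracle to 1e−9 in the
tests. Whether R² should be computed on per-replicate points or
per-concentration averages is a genuine open choice; averages are the
default because that is how dilution series are conventionally
summarised before plotting.

## Synthetic fixtures: what they do and do not show

**Alignment simulator.** Emulates the structure of a well-chosen
diagnostic marker: a ~200-column alignment, six target sequences with
rare intraspecific substitutions (0.002/site), three non-target species
at 5% background divergence, one species carrying a 6-column deletion,
and a planted signature — a 6-column probe block plus two primer sites
with three diagnostic positions each. Exact recoverability is engineered
via a *sister species*: one non-target species is identical to the target
everywhere except at planted positions, so any window diagnostic against
*all* species must be diagnostic against the sister, which pins every
qualifying probe window to the planted block deterministically — no
probabilistic slack, hence zero-miss/zero-extra recovery tests across
seeds. Planted windows are excluded from random mutation (the real-world
analogue: the designer picked a conserved region on purpose). The
simulator is *not* a molecular-evolution model — no substitution-model
realism, no rate heterogeneity, no within-species phylogeny — so passing
recovery tests demonstrates algorithmic correctness on the assumed
structure, not performance on any particular real marker.

**Panel simulator.** Target specimens draw their diagnostic Cq from
N(18.7, 3.3²) truncated to (0, 39]; the control Cq is the diagnostic Cq
plus a duplex offset N(2.9, 0.8²) bounded by the 6-cycle fail threshold,
because within a specimen the two channels are strongly correlated
through template quantity — drawing the channels independently from
their marginal distributions would put ~24% of targets past the ΔCq QC
bound, which real validated duplex panels do not show. Both channel means
are preserved exactly (18.7 and 21.6); the control channel's marginal SD
consequently tracks the diagnostic SD (~3.4) rather than its separately
observed value (2.7) — a deliberate trade of one marginal moment for the
joint behaviour that the interpreter actually depends on. Non-targets
amplify only in the control channel, N(19.8, 3.7²). Per-channel dropout
(Bernoulli) emulates degraded DNA. One clean NTC row pair is appended.
All simulators use a single `numpy` generator with an explicit integer
seed and are bit-stable across runs.

## Problem sizes and verification

The shipped verification uses: exhaustive window/triple oracles on
alignments of ≤ 40 columns; scanner-vs-oracle equivalence on 100 random
alignments (≤ 40 columns × ≤ 12 records); designer recovery and
screen-consistency on 50 simulated 200-column alignments; panel
interpretation on 200-specimen simulated plates and a 1000-specimen
panel for distributional checks. These sizes exercise every code path
while keeping the whole suite around a minute of CPU.
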