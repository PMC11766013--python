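# diagpcr

Design and interpretation of species-diagnostic duplex real-time PCR
(TaqMan) assays from species-labelled multiple sequence alignments.

## The problem

Port inspectors and diagnostic labs frequently need to identify insect
larvae (or other morphologically cryptic life stages) to species within
hours. A hydrolysis-probe qPCR assay on a fast-evolving nuclear marker
such as ITS2 can do this without sequencing: a probe and primer pair are
placed on alignment regions that are conserved within the target species
but differ from every related non-target species, and each reaction is
duplexed with a universal 18S internal-control probe so that a negative
diagnostic signal can be distinguished from failed DNA extraction.

`diagpcr` covers the full desk workflow around such an assay:

1. **Signature discovery** — scan a species-labelled alignment for windows
   that are intraspecifically conserved and interspecifically diagnostic,
   indel-aware (a gap is a difference). A probe site must carry, for every
   non-target species, a run of ≥ 5 consecutive diagnostic columns; a
   primer site needs ≥ 3 diagnostic positions (one primer of the pair
   suffices).
2. **Assay assembly** — enumerate and rank forward/probe/reverse triples
   under amplicon-length, %GC and Tm constraints.
3. **Oligo thermodynamics** — length, %GC with IUPAC degenerate bases, and
   closed-form Tm. The reference Tm is the salt-adjusted formula
   `Tm = 100.5 + 41·GC/N − 820/N + 16.6·log10[Na+]` at [Na+] = 0.05 M; the
   basic model uses the Wallace rule `2(A+T) + 4(G+C)` below 14 nt and
   `64.9 + 41·(GC − 16.4)/N` otherwise.
4. **In-silico specificity** — a permissive mismatch screen (amplification
   predicted unless some oligo exceeds 3 mismatches) plus panel
   inclusivity `100·TP/(TP+FN)` and specificity `100·TN/(TN+FP)`.
5. **Run interpretation** — the duplex decision tree over (diagnostic Cq,
   control Cq) with ΔCq = Cq_control − Cq_diag quality control
   (warn > 4 cycles, fail > 6), no-template-control run validation, and
   triplicate-well aggregation.
6. **Standard curves** — OLS of Cq on log10(concentration), amplification
   efficiency `E = 10^(−1/slope) − 1`, and limit of detection.
7. **Synthetic fixtures** — seeded alignment and Cq-panel simulators with
   planted, exactly recoverable ground truth.

## Worked example

Compute the properties of two published oligos (a 20-mer forward primer
and a 30-mer probe carrying one degenerate M base):

```sh
$ diagpcr oligo-props \
    --oligo Cpom4F=CCCGCGTGTGTGTAATAAAT \
    --oligo CpomP4=TCATCATTGTACACGTATCGTGTTMCAGCT
name    sequence        length  gc_percent      tm_basic        tm_salt tm_salt_min     tm_salt_max
Cpom4F  CCCGCGTGTGTGTAATAAAT    20      45      49.7    56.4    56.4    56.4
CpomP4  TCATCATTGTACACGTATCGTGTTMCAGCT  30      43.3    59–60   68–69   68.0    69.3
```

The forward primer is 45% GC with a salt-adjusted Tm of 56.4 °C; the
probe's single M (A or C) makes its GC 43.3% under the count-ambiguous-
as-GC convention and spreads its Tm over the 68–69 °C interval.

Simulate an alignment with a planted diagnostic signature, design an
assay, and screen the whole panel against it:

```sh
$ diagpcr simulate alignment --seed 2 --out-dir fx
$ diagpcr screen --alignment fx/alignment.fasta --target Cydia_pomonella --out-dir out
{
  "true_positives": 6,
  "false_negatives": 0,
  "true_negatives": 10,
  "false_positives": 0,
  "inclusivity_percent": 100.0,
  "specificity_percent": 100.0
}
```

Every simulated target amplifies (zero mismatches against its own assay)
and every non-target record is blocked — the probe's ≥ 5-consecutive-
difference rule guarantees blocking even under the permissive 3-mismatch
screen.

Interpret a plate export (`well,specimen,channel,cq,ntc` with `ND` for no
amplification):

```sh
$ diagpcr simulate panel --seed 5 --out-dir fx
$ diagpcr interpret --plate fx/plate.csv --out-dir out
     specimen            call delta_cq    flags advice
   target_001 TARGET_POSITIVE     1.84
   target_002 TARGET_POSITIVE     2.99
   target_003 TARGET_POSITIVE     4.21 DCQ_WARN
...
nontarget_001      NOT_TARGET
```

`target_003`'s ΔCq of 4.21 cycles exceeds the 4-cycle warning bound but
not the 6-cycle fail bound, so it is called positive with a `DCQ_WARN`
flag — exactly the behaviour wanted for borderline duplex consistency.

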