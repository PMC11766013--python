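"""Designer tests, centred on an exhaustive triple oracle for a small
alignment: every (forward, probe, reverse) window triple is enumerated
directly from the raw sequences and filtered by the assay constraints,
independently of the designer's vectorised search."""

import math

import pytest

from diagpcr.alignment_io import make_alignment
from diagpcr.assay_designer import (
    AssayCandidate,
    DesignConstraints,
    design_assays,
    render_assay_report,
)
from diagpcr.errors import ParameterError, SpeciesLookupError
from diagpcr.iupac import expand

RELAXED = DesignConstraints(
    min_consecutive_probe_diffs=5,
    min_primer_diffs=3,
    amplicon_length=(20, 40),
    primer_length=(5, 8),
    probe_length=(6, 10),
    primer_tm=(-500.0, 500.0),
    probe_tm_offset=0.0,
    gc=(0.0, 100.0),
    degenerate_budget=0,
)


# -- independent oracle ------------------------------------------------------


def _tm_mid(n, gc_lo, gc_hi):
    def tm(gc):
        return 100.5 + 41.0 * gc / n - 820.0 / n + 16.6 * math.log10(0.05)

    return 0.5 * (tm(gc_lo) + tm(gc_hi))


def oracle_triples(aln, target, constraints):
    target_records = [r for r in aln.records if r.species == target]
    by_species = {}
    for r in aln.records:
        if r.species != target:
            by_species.setdefault(r.species, []).append(r)
    n = aln.n_columns

    def states(recs, c):
        return set().union(*(expand(r.sequence[c]) for r in recs))

    diag = {
        sp: [not (states(target_records, c) & states(recs, c)) for c in range(n)]
        for sp, recs in by_species.items()
    }

    def windows(length_range):
        out = []
        for s in range(n):
            for e in range(s + 1, n + 1):
                chars = []
                ok = True
                for c in range(s, e):
                    observed = {r.sequence[c] for r in target_records}
                    if len(observed) > 1:
                        ok = False
                        break
                    char = next(iter(observed))
                    if char != "-":
                        chars.append(char)
                if ok and length_range[0] <= len(chars) <= length_range[1]:
                    out.append((s, e, "".join(chars)))
        return out

    def max_run(sp, s, e):
        best = run = 0
        for c in range(s, e):
            run = run + 1 if diag[sp][c] else 0
            best = max(best, run)
        return best

    probes = [
        (s, e, seq)
        for s, e, seq in windows(constraints.probe_length)
        if all(
            max_run(sp, s, e) >= constraints.min_consecutive_probe_diffs
            for sp in by_species
        )
    ]
    primers = windows(constraints.primer_length)
    full = {
        (s, e)
        for s, e, _ in primers
        if all(
            sum(diag[sp][c] for c in range(s, e)) >= constraints.min_primer_diffs
            for sp in by_species
        )
    }

    def degapped(s, e):
        return sum(
            1
            for c in range(s, e)
            if {r.sequence[c] for r in target_records} != {"-"}
        )

    def tm_of(seq):
        gc = sum(ch in "GCS" for ch in seq)
        gc_hi = sum(bool(expand(ch) & {"G", "C"}) for ch in seq)
        gc_lo = sum(expand(ch) <= {"G", "C"} for ch in seq)
        return _tm_mid(len(seq), gc_lo, gc_hi)

    triples = set()
    for fs, fe, fseq in primers:
        for rs, re_, rseq in primers:
            if rs < fe or ((fs, fe) not in full and (rs, re_) not in full):
                continue
            amp = degapped(fs, re_)
            if not (constraints.amplicon_length[0] <= amp <= constraints.amplicon_length[1]):
                continue
            for ps, pe, pseq in probes:
                if ps < fe or pe > rs:
                    continue
                if tm_of(pseq) < max(tm_of(fseq), tm_of(rseq)) + constraints.probe_tm_offset:
                    continue
                triples.add(((fs, fe), (ps, pe), (rs, re_)))
    return triples


def spans(candidates):
    return {
        (
            (c.forward.start, c.forward.end),
            (c.probe.start, c.probe.end),
            (c.reverse.start, c.reverse.end),
        )
        for c in candidates
    }


# -- tests -------------------------------------------------------------------


class TestExhaustiveEquivalence:
    def test_toy_alignment_full_set_matches_oracle(self, toy_alignment):
        candidates = design_assays(
            toy_alignment, "Target_sp", RELAXED, max_candidates=None
        )
        assert spans(candidates) == oracle_triples(toy_alignment, "Target_sp", RELAXED)
        assert candidates  # the planted fixture is feasible

    def test_top_k_is_prefix_of_full_ranking(self, toy_alignment):
        full = design_assays(toy_alignment, "Target_sp", RELAXED, max_candidates=None)
        top = design_assays(toy_alignment, "Target_sp", RELAXED, max_candidates=7)
        assert spans(top) == spans(full[:7])

    def test_raising_probe_threshold_never_adds_candidates(self, toy_alignment):
        counts = []
        for k in (4, 5, 6, 7):
            constraints = DesignConstraints(
                **{
                    **RELAXED.__dict__,
                    "min_consecutive_probe_diffs": k,
                }
            )
            counts.append(
                len(design_assays(toy_alignment, "Target_sp", constraints, None))
            )
        assert counts == sorted(counts, reverse=True)


class TestDesignBehaviour:
    def test_planted_probe_block_covered_by_top_candidate(self, toy_alignment):
        top = design_assays(toy_alignment, "Target_sp", RELAXED)[0]
        assert top.probe.start < 22 and top.probe.end > 16

    def test_candidates_satisfy_their_own_invariants(self, toy_alignment):
        for cand in design_assays(toy_alignment, "Target_sp", RELAXED):
            assert cand.forward.end <= cand.probe.start
            assert cand.probe.end <= cand.reverse.start
            assert 20 <= cand.amplicon_length <= 40
            assert cand.probe_min_run >= 5
            # one primer must clear 3 worst-case mismatches vs every species
            assert any(
                all(cand.mismatch_summary[sp][i] >= 3 for sp in cand.mismatch_summary)
                for i in (0, 1)
            )

    def test_conserved_alignment_yields_no_assays(self, conserved_alignment):
        assert design_assays(conserved_alignment, "Target_sp", RELAXED) == []

    def test_infeasible_amplicon_interval(self, toy_alignment):
        # more degapped bases than the toy alignment has columns
        constraints = DesignConstraints(
            **{**RELAXED.__dict__, "amplicon_length": (41, 45)}
        )
        assert design_assays(toy_alignment, "Target_sp", constraints) == []

    def test_no_nontarget_species_refused(self):
        aln = make_alignment([("t1", "T", "ACGT" * 10), ("t2", "T", "ACGT" * 10)])
        with pytest.raises(SpeciesLookupError):
            design_assays(aln, "T", RELAXED)

    def test_deterministic_output(self, toy_alignment):
        first = design_assays(toy_alignment, "Target_sp", RELAXED)
        second = design_assays(toy_alignment, "Target_sp", RELAXED)
        assert render_assay_report(first).equals(render_assay_report(second))

    def test_reverse_primer_is_bottom_strand(self, toy_alignment):
        from diagpcr.oligo_thermo import reverse_complement
        from diagpcr.signature_scanner import window_oligo_sequence

        cand = design_assays(toy_alignment, "Target_sp", RELAXED)[0]
        top_strand = window_oligo_sequence(
            toy_alignment, "Target_sp", cand.reverse.start, cand.reverse.end
        )
        assert cand.reverse.sequence == reverse_complement(top_strand)

    def test_empty_interval_constraint_rejected(self):
        with pytest.raises(ParameterError):
            DesignConstraints(amplicon_length=(100, 60))


class TestReport:
    def test_amplicon_printed_on_forward_row_only(self, toy_alignment):
        candidates = design_assays(toy_alignment, "Target_sp", RELAXED, max_candidates=2)
        report = render_assay_report(candidates)
        assert list(report.columns) == [
            "oligo_name",
            "sequence",
            "amplicon_length",
            "oligo_length",
            "gc_percent",
            "tm_c",
        ]
        assert len(report) == 6
        fwd_rows = report[report["oligo_name"].str.endswith("F")]
        other_rows = report[~report["oligo_name"].str.endswith("F")]
        assert (fwd_rows["amplicon_length"] != "").all()
        assert (other_rows["amplicon_length"] == "").all()

    def test_empty_candidate_list_gives_header_only(self):
        report = render_assay_report([])
        assert report.empty and len(report.columns) == 6

    def test_degenerate_probe_tm_rendered_as_range(self):
        from diagpcr.oligo_thermo import tm_salt_adjusted, gc_percent
        from diagpcr.assay_designer import OligoCandidate

        seq = "TCATCATTGTACACGTATCGTGTTMCAGCT"
        oligo = OligoCandidate("probe", 0, 30, seq, gc_percent(seq), tm_salt_adjusted(seq))
        primer = OligoCandidate(
            "forward", 0, 18, "CGACGACGACAACGACAA",
            gc_percent("CGACGACGACAACGACAA"), tm_salt_adjusted("CGACGACGACAACGACAA"),
        )
        cand = AssayCandidate(
            forward=primer, reverse=primer, probe=oligo,
            amplicon_span=(0, 78), amplicon_length=78,
            probe_min_run=5, primer_total_diffs=3,
        )
        report = render_assay_report([cand])
        assert report.iloc[2]["tm_c"] == "68–69"
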