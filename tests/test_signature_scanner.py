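"""Scanner unit tests plus equivalence against a brute-force window oracle.

The oracle re-derives everything from the raw aligned sequences with plain
nested loops — no shared code with the scanner beyond the IUPAC tables —
and enumerates every (start, end) pair directly.
"""

import numpy as np
import pytest

from diagpcr.alignment_io import make_alignment
from diagpcr.errors import ParameterError
from diagpcr.iupac import expand
from diagpcr.signature_scanner import (
    find_primer_sites,
    find_probe_sites,
    profile_columns,
)


# -- independent oracle ------------------------------------------------------


def _column_states(records, col):
    return set().union(*(expand(r.sequence[col]) for r in records))


def brute_force_windows(aln, target, length_range, *, min_consecutive=None, min_diffs=None):
    """All (start, end, full_coverage) windows by direct enumeration.

    Probe mode (min_consecutive set): window qualifies iff every non-target
    species has a diagnostic run ≥ min_consecutive; only fully covering
    windows are returned. Primer mode (min_diffs set): returns windows
    covering ≥1 species, with the set of covered species.
    """
    target_records = [r for r in aln.records if r.species == target]
    by_species = {}
    for r in aln.records:
        if r.species != target:
            by_species.setdefault(r.species, []).append(r)
    n = aln.n_columns
    diag = {
        sp: [
            not (_column_states(target_records, c) & _column_states(recs, c))
            for c in range(n)
        ]
        for sp, recs in by_species.items()
    }
    out = []
    for start in range(n):
        for end in range(start + 1, n + 1):
            degapped = 0
            usable = True
            for c in range(start, end):
                observed = {r.sequence[c] for r in target_records}
                if len(observed) > 1:  # strict conservation, no budget
                    usable = False
                    break
                if observed != {"-"}:
                    degapped += 1
            if not usable or not (length_range[0] <= degapped <= length_range[1]):
                continue
            if min_consecutive is not None:
                ok = True
                for sp in by_species:
                    best = run = 0
                    for c in range(start, end):
                        run = run + 1 if diag[sp][c] else 0
                        best = max(best, run)
                    if best < min_consecutive:
                        ok = False
                        break
                if ok and by_species:
                    out.append((start, end))
            else:
                covered = {
                    sp
                    for sp in by_species
                    if sum(diag[sp][c] for c in range(start, end)) >= min_diffs
                }
                if covered:
                    out.append((start, end, frozenset(covered)))
    return out


def random_alignment(rng):
    """≤40 columns × ≤12 records over 2–4 species with gaps and ambiguity."""
    n_cols = int(rng.integers(8, 41))
    n_species = int(rng.integers(2, 5))
    rows = []
    alphabet = list("ACGT")
    for s in range(n_species):
        consensus = rng.choice(alphabet, size=n_cols)
        # occasional species-level gap stretch
        if rng.random() < 0.5:
            lo = int(rng.integers(0, n_cols))
            hi = min(n_cols, lo + int(rng.integers(1, 5)))
            consensus[lo:hi] = "-"
        for i in range(int(rng.integers(1, 4))):
            seq = consensus.copy()
            for c in range(n_cols):
                roll = rng.random()
                if seq[c] != "-" and roll < 0.08:
                    seq[c] = alphabet[int(rng.integers(4))]
                elif seq[c] != "-" and roll < 0.10:
                    seq[c] = "RYSWKM"[int(rng.integers(6))]
            rows.append((f"s{s}_{i}", f"species_{s}", "".join(seq)))
            if len(rows) >= 12:
                break
    return make_alignment(rows)


# -- unit behaviour ----------------------------------------------------------


class TestProfileColumns:
    def test_snv_column_is_diagnostic_only_vs_differing_species(self):
        aln = make_alignment(
            [("t1", "T", "A"), ("a1", "S1", "A"), ("b1", "S2", "G")]
        )
        (profile,) = profile_columns(aln, "T")
        assert profile.diagnostic_vs == frozenset({"S2"})
        assert profile.is_target_conserved

    def test_indel_column_is_diagnostic(self):
        aln = make_alignment([("t1", "T", "A"), ("a1", "S1", "-")])
        (profile,) = profile_columns(aln, "T")
        assert "S1" in profile.diagnostic_vs

    def test_intraspecific_variation_breaks_conservation(self):
        aln = make_alignment([("t1", "T", "A"), ("t2", "T", "G"), ("a1", "S1", "C")])
        (profile,) = profile_columns(aln, "T")
        assert not profile.is_target_conserved

    def test_degenerate_panel_base_widens_intersection(self):
        # R = {A,G} overlaps target {A}: conservatively not diagnostic
        aln = make_alignment([("t1", "T", "A"), ("a1", "S1", "R")])
        (profile,) = profile_columns(aln, "T")
        assert profile.diagnostic_vs == frozenset()


class TestWindows:
    def test_planted_block_found(self, toy_alignment):
        windows = find_probe_sites(toy_alignment, "Target_sp", length_range=(6, 10))
        assert windows
        assert all(w.start < 22 and w.end > 16 for w in windows)

    def test_conserved_alignment_yields_nothing(self, conserved_alignment):
        assert find_probe_sites(conserved_alignment, "Target_sp", length_range=(5, 10)) == []
        assert (
            find_primer_sites(conserved_alignment, "Target_sp", length_range=(5, 10))
            == []
        )

    def test_run_below_threshold_rejected(self):
        aln = make_alignment(
            [("t1", "T", "AAAAAAAAAA"), ("a1", "S", "AAACCCCAAA")]  # run of 4
        )
        assert find_probe_sites(aln, "T", min_consecutive=5, length_range=(5, 10)) == []
        assert find_probe_sites(aln, "T", min_consecutive=4, length_range=(5, 10))

    def test_scattered_primer_diffs_found(self, toy_alignment):
        windows = find_primer_sites(toy_alignment, "Target_sp", length_range=(10, 12))
        full = [w for w in windows if not w.partial]
        assert any(w.start <= 2 and w.end >= 9 for w in full)

    def test_two_diffs_insufficient(self):
        aln = make_alignment(
            [("t1", "T", "A" * 20), ("a1", "S", "C" + "A" * 9 + "C" + "A" * 9)]
        )
        windows = find_primer_sites(aln, "T", min_diffs=3, length_range=(15, 20))
        assert windows == []
        assert find_primer_sites(aln, "T", min_diffs=2, length_range=(15, 20))

    def test_inverted_length_range_rejected(self, toy_alignment):
        with pytest.raises(ParameterError):
            find_probe_sites(toy_alignment, "Target_sp", length_range=(10, 5))

    def test_windows_sorted_by_start(self, toy_alignment):
        windows = find_probe_sites(toy_alignment, "Target_sp", length_range=(6, 12))
        assert [(w.start, w.end) for w in windows] == sorted(
            (w.start, w.end) for w in windows
        )

    def test_degapped_length_excludes_target_gap_columns(self):
        aln = make_alignment(
            [("t1", "T", "AAAA--AAAA"), ("a1", "S", "CCCCCCCCCC")]
        )
        windows = find_probe_sites(aln, "T", min_consecutive=5, length_range=(8, 8))
        assert windows == [w for w in windows if w.degapped_length == 8]
        assert any(w.end - w.start == 10 for w in windows)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_probe_windows_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng)
        target = aln.records[0].species
        expected = brute_force_windows(aln, target, (4, 12), min_consecutive=3)
        got = [
            (w.start, w.end)
            for w in find_probe_sites(aln, target, min_consecutive=3, length_range=(4, 12))
        ]
        assert got == sorted(expected)

    @pytest.mark.parametrize("seed", range(30))
    def test_primer_windows_match_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        aln = random_alignment(rng)
        target = aln.records[0].species
        expected = brute_force_windows(aln, target, (4, 12), min_diffs=2)
        got = [
            (w.start, w.end, w.species_covered)
            for w in find_primer_sites(aln, target, min_diffs=2, length_range=(4, 12))
        ]
        assert got == sorted(expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_raising_thresholds_never_adds_windows(self, seed):
        rng = np.random.default_rng(2000 + seed)
        aln = random_alignment(rng)
        target = aln.records[0].species
        probe_sets = [
            {(w.start, w.end) for w in find_probe_sites(aln, target, k, (4, 12))}
            for k in (2, 3, 4, 5)
        ]
        for smaller, larger in zip(probe_sets[1:], probe_sets):
            assert smaller <= larger
        primer_sets = [
            {(w.start, w.end) for w in find_primer_sites(aln, target, k, (4, 12))}
            for k in (1, 2, 3, 4)
        ]
        for smaller, larger in zip(primer_sets[1:], primer_sets):
            assert smaller <= larger
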