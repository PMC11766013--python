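"""Shared fixtures: small hand-written alignments and panel builders."""

import pytest

from diagpcr.alignment_io import make_alignment


@pytest.fixture
def toy_alignment():
    """Four species, 40 columns, with a planted 6-column probe block
    (cols 16–22), 3 scattered primer diffs (cols 2, 5, 8) and an indel
    (cols 30–33 gapped in speciesB). Target rows are identical."""
    #          0         1         2         3
    #          0123456789012345678901234567890123456789
    target = "ACGTACGTACGTACGTAAAAAAGTACGTACGTACGTACGT"
    spA    = "ACTTAGGTTCGTACGTCCCCCCGTACGTACGTACGTACGT"  # diffs at 2,5,8 + block
    spB    = "ACTTAGGTTCGTACGTCCCCCCGTACGTAC----GTACGT"  # + indel 30..34
    return make_alignment(
        [
            ("t1", "Target_sp", target),
            ("t2", "Target_sp", target),
            ("a1", "SpeciesA", spA),
            ("a2", "SpeciesA", spA),
            ("b1", "SpeciesB", spB),
        ],
        target_species="Target_sp",
    )


@pytest.fixture
def conserved_alignment():
    """Two species, zero interspecific differences anywhere."""
    seq = "ACGTACGTACGTACGTACGT"
    return make_alignment(
        [
            ("t1", "Target_sp", seq),
            ("t2", "Target_sp", seq),
            ("x1", "Other_sp", seq),
        ],
        target_species="Target_sp",
    )
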