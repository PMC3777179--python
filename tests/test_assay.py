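"""Primer metrics and assay geometry validation."""

import numpy as np
import pytest

from pyrometh import (
    AssayDefinition,
    DegenerateSequence,
    GeometryError,
    NucleotideSequence,
    Primer,
    amplicon_length,
    bisulfite_convert,
    gc_content,
    melting_temperature,
    reverse_complement,
    validate_assay,
)


@pytest.mark.parametrize(
    "seq, pct",
    [
        ("GGGAGGAGTTAAGATGGT", 50.0),
        ("ATAAACCCCATACCTCAAA", 36.8),
        ("GGTTTATTTTATTAGGGAGTGTTA", 29.2),
        ("AAAAAAAAACTCCCTAACC", 31.6),
        ("AGGGAGTGTTAGATAGTGG", 47.4),
        ("AAAAAAAAAA", 0.0),
        ("G" * 9 + "A" * 7, 56.3),  # 56.25 rounds half away from zero
    ],
)
def test_gc_content(seq, pct):
    assert gc_content(seq) == pct


def test_gc_content_invariant_under_reverse_complement():
    p = NucleotideSequence("GGTTTATTTTATTAGGGAGTGTTA")
    assert gc_content(p.bases) == gc_content(reverse_complement(p).bases)


def test_gc_content_rejects_empty():
    with pytest.raises(ValueError):
        gc_content("")


@pytest.mark.parametrize(
    "seq, printed",
    [
        ("GGGAGGAGTTAAGATGGT", 60.2),
        ("ATAAACCCCATACCTCAAA", 60.9),
        ("GGTTTATTTTATTAGGGAGTGTTA", 61.9),
        ("AAAAAAAAACTCCCTAACC", 59.3),
    ],
)
def test_melting_temperature_near_design_report_values(seq, printed):
    # PCR-primer Tm values from a third-party design report; agreement is
    # advisory (parameterizations differ across software) hence +/- 3 C.
    assert abs(melting_temperature(seq) - printed) <= 3.0


def test_melting_temperature_deterministic_and_guards_short_input():
    s = "GGGAGGAGTTAAGATGGT"
    assert melting_temperature(s) == melting_temperature(str(s))
    with pytest.raises(ValueError):
        melting_temperature("ACGTAC")


def _primer(role, seq, start, end, name="p"):
    return Primer(name=name, role=role, sequence=seq, start=start, end=end)


def _assay(forward, reverse, sequencing, sta="TTYGTTTTTT", order="TCTGT",
           amplicon=None, name="a"):
    return AssayDefinition(
        name=name,
        reference_id="ref",
        forward=forward,
        reverse=reverse,
        sequencing=sequencing,
        sequence_to_analyze=DegenerateSequence(sta),
        dispensation_order=order,
        declared_amplicon_bp=amplicon,
    )


def test_primer_invariants():
    with pytest.raises(ValueError):
        _primer("forward", "ACGTACGTAY", 1, 10)  # Y forbidden
    with pytest.raises(ValueError):
        _primer("forward", "ACGTACGTA", 1, 9)  # too short
    with pytest.raises(ValueError):
        _primer("forward", "ACGTACGTAC", 1, 11)  # span != length
    p = _primer("reverse", "ATAAACCCCATACCTCAAA", 111, 93)
    assert p.window == (93, 111)  # printed 5'->3' coordinates normalized


def test_amplicon_length_table_coordinates():
    f1 = _primer("forward", "GGGAGGAGTTAAGATGGT", 3, 20)
    r1 = _primer("reverse", "ATAAACCCCATACCTCAAA", 111, 93)
    s1 = _primer("sequencing", "GGGAGGAGTTAAGATGGT", 3, 20)
    assert amplicon_length(_assay(f1, r1, s1)) == 109

    f2 = _primer("forward", "GGTTTATTTTATTAGGGAGTGTTA", 105, 128)
    r2 = _primer("reverse", "AAAAAAAAACTCCCTAACC", 231, 213)
    s2 = _primer("sequencing", "AGGGAGTGTTAGATAGTGG", 118, 136)
    assert amplicon_length(_assay(f2, r2, s2)) == 127


def test_amplicon_length_symmetry_and_same_window():
    f = _primer("forward", "A" * 12, 5, 16)
    r = _primer("reverse", "T" * 12, 16, 5)
    s = _primer("sequencing", "A" * 12, 5, 16)
    a = _assay(f, r, s)
    length = amplicon_length(a)
    assert length == 12  # identical windows: the primer length itself
    assert length >= len(f.sequence) and length >= len(r.sequence)


def test_amplicon_geometry_error_for_wrong_orientation():
    f = _primer("forward", "A" * 12, 50, 61)
    r = _primer("reverse", "T" * 12, 20, 9)  # entirely 5' of the forward primer
    s = _primer("sequencing", "A" * 12, 50, 61)
    with pytest.raises(GeometryError):
        amplicon_length(_assay(f, r, s))


def _assay_from_reference(ref: DegenerateSequence, f_len=12, s_gap=2, sta_len=10):
    """Carve a self-consistent assay out of a converted reference."""
    bases = ref.bases
    f_seq = bases[:f_len]
    s_start = f_len - s_gap
    s_seq = bases[s_start : s_start + f_len]
    sta_start = s_start + f_len
    sta = bases[sta_start : sta_start + sta_len]
    r_hi = len(bases)
    r_lo = r_hi - f_len + 1
    window = bases[r_lo - 1 : r_hi]
    r_seq = reverse_complement(NucleotideSequence(window)).bases
    f = _primer("forward", f_seq, 1, f_len, "F")
    s = _primer("sequencing", s_seq, s_start + 1, s_start + f_len, "S")
    r = _primer("reverse", r_seq, r_hi, r_lo, "R")
    return AssayDefinition(
        name="carved",
        reference_id=ref.source_id,
        forward=f,
        reverse=r,
        sequencing=s,
        sequence_to_analyze=DegenerateSequence(sta),
        dispensation_order="ACGT",
        declared_amplicon_bp=len(bases),
    )


@pytest.mark.parametrize("seed", range(5))
def test_validate_assay_passes_for_assay_carved_from_reference(seed):
    rng = np.random.default_rng(seed)
    # Y-free head and tail so primers never cover a CpG
    head = "".join(rng.choice(list("AGT"), 24))
    mid = "".join(rng.choice(list("ACGT"), 20))
    tail = "".join(rng.choice(list("AGT"), 14))
    ref = bisulfite_convert(NucleotideSequence(head + mid + tail, id="ref"))
    a = _assay_from_reference(ref)
    report = validate_assay(a, ref)
    assert report.passed, report.as_text()


def test_validate_assay_flags_mutated_primer_with_offset():
    ref = bisulfite_convert(
        NucleotideSequence("AGTAGTAGTAGTGATTACAGATTACAGGATTTAGGATTAGGTTAAGG", id="ref")
    )
    a = _assay_from_reference(ref)
    mutated = list(a.forward.sequence)
    mutated[4] = "A" if mutated[4] != "A" else "G"
    bad = AssayDefinition(
        name=a.name,
        reference_id=a.reference_id,
        forward=Primer(name="F", role="forward", sequence="".join(mutated),
                       start=a.forward.start, end=a.forward.end),
        reverse=a.reverse,
        sequencing=a.sequencing,
        sequence_to_analyze=a.sequence_to_analyze,
        dispensation_order=a.dispensation_order,
        declared_amplicon_bp=a.declared_amplicon_bp,
    )
    report = validate_assay(bad, ref)
    failures = {c.name for c in report.failures}
    assert "forward_primer_match" in failures
    msg = next(c.message for c in report.failures if c.name == "forward_primer_match")
    assert "offset 4" in msg


def test_validate_assay_without_reference_reports_unverified_content_checks(assays):
    for a in assays.values():
        report = validate_assay(a, ref=None)
        by_name = {c.name: c.status for c in report.checks}
        assert by_name["amplicon_length"] == "pass"
        assert by_name["forward_primer_match"] == "unverified"
        assert not report.failures
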