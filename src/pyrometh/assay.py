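"""Primer and assay geometry for bisulfite pyrosequencing.

An assay is a primer triple (forward PCR, reverse PCR, sequencing) on a
bisulfite-converted reference, the expected read-out downstream of the
sequencing primer (the "sequence to analyze", with Y at CpG sites), and
the nucleotide dispensation order used by the instrument.  Coordinates
are 1-based and inclusive at both ends; reverse primers are annotated
5'->3' as conventionally printed, i.e. the 5' coordinate first, which may
exceed the 3' coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

from Bio.SeqUtils import MeltingTemp as _mt

from .seqcore import (
    DegenerateSequence,
    NucleotideSequence,
    reverse_complement,
)


class GeometryError(ValueError):
    """Primer coordinates describe an impossible amplicon."""


class PrimerRole(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"
    SEQUENCING = "sequencing"


@dataclass(frozen=True)
class Primer:
    """A PCR or sequencing primer with its position on the converted reference.

    Primers for bisulfite assays are designed CpG-free so that they anneal
    regardless of methylation state; a Y in the sequence is therefore
    rejected outright.
    """

    name: str
    role: PrimerRole
    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", PrimerRole(self.role))
        if "Y" in self.sequence:
            raise ValueError(
                f"primer {self.name!r} contains Y; bisulfite primers must be CpG-free"
            )
        NucleotideSequence(bases=self.sequence, id=self.name)  # alphabet check
        if len(self.sequence) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt")
        span = abs(self.end - self.start) + 1
        if span != len(self.sequence):
            raise ValueError(
                f"primer {self.name!r}: coordinate span {span} != length "
                f"{len(self.sequence)}"
            )
        if self.start < 1 or self.end < 1:
            raise ValueError(f"primer {self.name!r}: coordinates are 1-based")

    @property
    def window(self) -> tuple[int, int]:
        """Normalized (leftmost, rightmost) 1-based inclusive coordinates."""
        return (min(self.start, self.end), max(self.start, self.end))


@dataclass(frozen=True)
class AssayDefinition:
    name: str
    reference_id: str
    forward: Primer
    reverse: Primer
    sequencing: Primer
    sequence_to_analyze: DegenerateSequence
    dispensation_order: str
    declared_amplicon_bp: Optional[int] = None

    def __post_init__(self) -> None:
        for p, role in (
            (self.forward, PrimerRole.FORWARD),
            (self.reverse, PrimerRole.REVERSE),
            (self.sequencing, PrimerRole.SEQUENCING),
        ):
            if p.role != role:
                raise ValueError(f"primer {p.name!r} has role {p.role}, expected {role}")
        if not self.dispensation_order:
            raise ValueError("dispensation_order must be non-empty")


def _primer_seq(p: Union[Primer, str]) -> str:
    return p.sequence if isinstance(p, Primer) else p


def gc_content(p: Union[Primer, str]) -> float:
    """G+C percentage, one decimal, rounded half away from zero."""
    s = _primer_seq(p)
    if not s:
        raise ValueError("empty primer sequence")
    pct = 100.0 * (s.count("G") + s.count("C")) / len(s)
    return math.floor(pct * 10.0 + 0.5) / 10.0


#: Nearest-neighbor Tm conditions: Breslauer et al. thermodynamics at
#: 100 mM monovalent salt and 200 nM primer, matching typical PCR-primer
#: design-report conditions.  Advisory only; quantification never uses Tm.
TM_CONDITIONS = {"Na": 100.0, "dnac1": 200.0, "dnac2": 0.0}


def melting_temperature(p: Union[Primer, str]) -> float:
    """Nearest-neighbor melting temperature in deg C, one decimal.

    Uses the Breslauer nearest-neighbor parameter set under the salt and
    primer concentrations in :data:`TM_CONDITIONS`.  Design software varies
    in parameter choice (sequencing primers in particular are often scored
    at lower effective stringency), so values are advisory and agreement
    with third-party reports is expected only to within a few deg C.
    """
    s = _primer_seq(p)
    if len(s) < 8:
        raise ValueError("sequence shorter than 8 nt: Tm estimate unreliable")
    tm = _mt.Tm_NN(s, nn_table=_mt.DNA_NN1, **TM_CONDITIONS)
    return round(tm, 1)


def amplicon_length(a: AssayDefinition) -> int:
    """PCR product length from primer coordinates.

    The amplicon runs from the leftmost coordinate touched by either PCR
    primer to the rightmost, inclusive.
    """
    f_lo, f_hi = a.forward.window
    r_lo, r_hi = a.reverse.window
    if r_hi < f_lo:
        raise GeometryError(
            f"assay {a.name!r}: reverse primer window {r_lo}-{r_hi} lies "
            f"entirely 5' of forward primer window {f_lo}-{f_hi}"
        )
    return max(f_hi, r_hi) - min(f_lo, r_lo) + 1


# --- validation ------------------------------------------------------------

@dataclass(frozen=True)
class Check:
    name: str
    status: str  # "pass" | "fail" | "unverified"
    message: str = ""


@dataclass(frozen=True)
class ValidationReport:
    assay: str
    checks: tuple[Check, ...] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return all(c.status == "pass" for c in self.checks)

    @property
    def failures(self) -> tuple[Check, ...]:
        return tuple(c for c in self.checks if c.status == "fail")

    def as_text(self) -> str:
        lines = [f"assay {self.assay}: {'PASS' if self.passed else 'FAIL'}"]
        for c in self.checks:
            lines.append(f"  [{c.status:10s}] {c.name}" + (f": {c.message}" if c.message else ""))
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "assay": self.assay,
            "passed": self.passed,
            "checks": [
                {"name": c.name, "status": c.status, "message": c.message}
                for c in self.checks
            ],
        }


def _window_bases(ref: DegenerateSequence, lo: int, hi: int) -> Optional[str]:
    if lo < 1 or hi > len(ref.bases):
        return None
    return ref.bases[lo - 1 : hi]


def _first_mismatch(a: str, b: str) -> int:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i
    return min(len(a), len(b))


def validate_assay(
    a: AssayDefinition, ref: Optional[DegenerateSequence] = None
) -> ValidationReport:
    """Check assay geometry and, given a converted reference, primer content.

    With a reference: forward and sequencing primers must equal the
    reference substring at their coordinates, the reverse primer must equal
    the reverse complement of its reference window, no primer window may
    overlap a CpG (Y), and the sequence-to-analyze must equal the reference
    read-out immediately 3' of the sequencing primer.  Without a reference
    those checks are reported as unverified.  The declared amplicon length
    is checked against the coordinates either way.
    """
    checks: list[Check] = []

    if a.declared_amplicon_bp is not None:
        try:
            computed = amplicon_length(a)
        except GeometryError as exc:
            checks.append(Check("amplicon_length", "fail", str(exc)))
        else:
            ok = computed == a.declared_amplicon_bp
            checks.append(
                Check(
                    "amplicon_length",
                    "pass" if ok else "fail",
                    f"computed {computed} bp, declared {a.declared_amplicon_bp} bp",
                )
            )

    if ref is None:
        for name in (
            "forward_primer_match",
            "reverse_primer_match",
            "sequencing_primer_match",
            "no_primer_over_cpg",
            "sequence_to_analyze_match",
        ):
            checks.append(Check(name, "unverified", "no reference supplied"))
        return ValidationReport(assay=a.name, checks=tuple(checks))

    for p, label in ((a.forward, "forward"), (a.sequencing, "sequencing")):
        lo, hi = p.window
        window = _window_bases(ref, lo, hi)
        if window is None:
            checks.append(
                Check(f"{label}_primer_match", "fail",
                      f"{p.name}: coordinates {lo}-{hi} outside reference")
            )
        elif window == p.sequence:
            checks.append(Check(f"{label}_primer_match", "pass"))
        else:
            off = _first_mismatch(p.sequence, window)
            checks.append(
                Check(
                    f"{label}_primer_match", "fail",
                    f"{p.name}: mismatch at offset {off} (reference position "
                    f"{lo + off}): primer {p.sequence[off]!r} vs reference "
                    f"{window[off]!r}",
                )
            )

    lo, hi = a.reverse.window
    window = _window_bases(ref, lo, hi)
    if window is None:
        checks.append(
            Check("reverse_primer_match", "fail",
                  f"{a.reverse.name}: coordinates {lo}-{hi} outside reference")
        )
    elif "Y" in window:
        checks.append(
            Check("reverse_primer_match", "fail",
                  f"{a.reverse.name}: reference window contains a CpG (Y)")
        )
    else:
        expected = reverse_complement(
            NucleotideSequence(bases=window, id="window")
        ).bases
        if expected == a.reverse.sequence:
            checks.append(Check("reverse_primer_match", "pass"))
        else:
            off = _first_mismatch(a.reverse.sequence, expected)
            checks.append(
                Check(
                    "reverse_primer_match", "fail",
                    f"{a.reverse.name}: mismatch at offset {off}: primer "
                    f"{a.reverse.sequence[off]!r} vs reverse-complemented "
                    f"reference {expected[off]!r}",
                )
            )

    overlap = []
    for p in (a.forward, a.reverse, a.sequencing):
        lo, hi = p.window
        window = _window_bases(ref, lo, hi)
        if window is not None and "Y" in window:
            overlap.append(f"{p.name} ({lo}-{hi})")
    checks.append(
        Check(
            "no_primer_over_cpg",
            "fail" if overlap else "pass",
            "; ".join(overlap),
        )
    )

    sta = a.sequence_to_analyze.bases
    s_lo = a.sequencing.window[1] + 1
    s_hi = s_lo + len(sta) - 1
    window = _window_bases(ref, s_lo, s_hi)
    if window is None:
        checks.append(
            Check("sequence_to_analyze_match", "fail",
                  f"read-out window {s_lo}-{s_hi} outside reference")
        )
    elif window == sta:
        checks.append(Check("sequence_to_analyze_match", "pass"))
    else:
        off = _first_mismatch(sta, window)
        checks.append(
            Check(
                "sequence_to_analyze_match", "fail",
                f"mismatch at offset {off} (reference position {s_lo + off}): "
                f"declared {sta[off]!r} vs reference {window[off]!r}",
            )
        )

    return ValidationReport(assay=a.name, checks=tuple(checks))
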