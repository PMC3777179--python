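"""Nucleotide sequences and in silico bisulfite conversion.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine, which in mammalian DNA occurs almost
exclusively in CpG context, is protected and still reads as C.  On the
converted top strand a CpG therefore becomes a degenerate Y/G dinucleotide
(Y = C or T, with the C fraction equal to the methylation level) and every
other C becomes T.  Conversion is modeled on the top strand only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PLAIN_ALPHABET = frozenset("ACGT")
DEGENERATE_ALPHABET = frozenset("ACGTY")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """Sequence contains characters outside the permitted alphabet."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A plain DNA sequence over {A, C, G, T}.

    Lowercase input and IUPAC ambiguity codes are rejected rather than
    silently normalized: upstream sources (GenBank records, primer lists)
    should be cleaned deliberately, not by guesswork.
    """

    bases: str
    id: str = "seq"

    def __post_init__(self) -> None:
        _check_alphabet(self.bases, PLAIN_ALPHABET, self.id)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class DegenerateSequence:
    """A bisulfite-converted template over {A, C, G, T, Y}.

    ``cpg_positions`` holds the 1-based positions of every Y, in order;
    each Y marks a CpG site whose methylation fraction is the quantity a
    pyrosequencing assay measures.
    """

    bases: str
    cpg_positions: tuple[int, ...] = field(default=None)  # type: ignore[assignment]
    source_id: str = "seq"

    def __post_init__(self) -> None:
        _check_alphabet(self.bases, DEGENERATE_ALPHABET, self.source_id)
        expected = tuple(i + 1 for i, b in enumerate(self.bases) if b == "Y")
        if self.cpg_positions is None:
            object.__setattr__(self, "cpg_positions", expected)
        elif tuple(self.cpg_positions) != expected:
            raise ValueError(
                f"cpg_positions {self.cpg_positions!r} do not enumerate the Y "
                f"positions {expected!r} of {self.source_id!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)


def _check_alphabet(bases: str, alphabet: frozenset[str], label: str) -> None:
    if not bases:
        raise AlphabetError(f"sequence {label!r} is empty")
    bad = set(bases) - alphabet
    if bad:
        raise AlphabetError(
            f"sequence {label!r} contains characters outside "
            f"{{{','.join(sorted(alphabet))}}}: {sorted(bad)}"
        )


def bisulfite_convert(
    seq: Union[NucleotideSequence, DegenerateSequence],
) -> DegenerateSequence:
    """In silico bisulfite conversion of the top strand: CG -> YG, other C -> T.

    A, G and T are untouched, so length and the positions of all non-C bases
    are preserved.  A terminal C (no base follows, so it cannot open a CpG)
    converts to T.  Re-converting an already converted sequence is the
    identity: Y is treated as opaque and no C survives a first pass outside
    CG context.
    """
    bases = seq.bases
    out = []
    n = len(bases)
    for i, b in enumerate(bases):
        if b == "C":
            out.append("Y" if i + 1 < n and bases[i + 1] == "G" else "T")
        else:
            out.append(b)
    label = seq.id if isinstance(seq, NucleotideSequence) else seq.source_id
    return DegenerateSequence(bases="".join(out), source_id=label)


def count_cpg_sites(seq: DegenerateSequence) -> int:
    """Number of CpG sites (Y symbols) in a converted template."""
    return len(seq.cpg_positions)


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Watson-Crick reverse complement of a plain sequence.

    Degenerate (Y-containing) input is rejected: assays are modeled on the
    converted forward strand only, and Y has no meaningful complement there.
    """
    if not isinstance(seq, NucleotideSequence):
        raise AlphabetError(
            "reverse_complement requires a plain A/C/G/T sequence; "
            "degenerate templates are modeled on the forward strand only"
        )
    return NucleotideSequence(
        bases=seq.bases.translate(_COMPLEMENT)[::-1], id=seq.id
    )


# --- FASTA I/O -------------------------------------------------------------

def read_fasta(path: Union[str, Path], degenerate: bool = False):
    """Read FASTA records as NucleotideSequence (or DegenerateSequence) objects."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    cls = DegenerateSequence if degenerate else NucleotideSequence
    out = []
    for rec in records:
        bases = str(rec.seq).upper()
        if degenerate:
            out.append(DegenerateSequence(bases=bases, source_id=rec.id))
        else:
            out.append(cls(bases=bases, id=rec.id))
    return out


def write_fasta(
    seqs: Iterable[Union[NucleotideSequence, DegenerateSequence]],
    path: Union[str, Path],
) -> None:
    """Write sequences as FASTA; Y symbols are retained in converted output."""
    records = []
    for s in seqs:
        label = s.id if isinstance(s, NucleotideSequence) else s.source_id
        records.append(SeqRecord(Seq(s.bases), id=label, description=""))
    SeqIO.write(records, str(path), "fasta")
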