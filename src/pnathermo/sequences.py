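"""PNA sequence handling and nearest-neighbor stack combinatorics.

Peptide nucleic acid (PNA) strands are written N-terminus to C-terminus over
the four canonical nucleobases.  A homoduplex pairs a strand with its
antiparallel Watson-Crick complement, so every duplex is fully described by a
single strand.  The nearest-neighbor decomposition views the duplex as the
``length - 1`` overlapping dinucleotide "stacks"; under the antiparallel
reversal-complement equivalence ``X1X2 == comp(X2)comp(X1)`` the 16
dinucleotides collapse into 10 symmetry-unique stack classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: The 10 canonical stack labels, in the fixed column order used everywhere.
CANONICAL_STACKS: tuple[str, ...] = (
    "AA", "AT", "TA", "AG", "GA", "AC", "CA", "GG", "GC", "CG",
)

#: Watson-Crick hydrogen bonds within each stack (two base pairs).
STACK_WC_HBONDS: dict[str, int] = {
    "AA": 4, "AT": 4, "TA": 4,
    "AG": 5, "GA": 5, "AC": 5, "CA": 5,
    "GG": 6, "GC": 6, "CG": 6,
}


@dataclass(frozen=True)
class StackClass:
    """One of the 10 symmetry-unique dinucleotide stacks of a homoduplex."""

    label: str
    wc_hbonds: int

    def __post_init__(self) -> None:
        if self.label not in CANONICAL_STACKS:
            raise ValueError(f"{self.label!r} is not a canonical stack label")
        if self.wc_hbonds != STACK_WC_HBONDS[self.label]:
            raise ValueError(
                f"stack {self.label} has {STACK_WC_HBONDS[self.label]} "
                f"Watson-Crick bonds, not {self.wc_hbonds}"
            )


@dataclass(frozen=True)
class PnaSequence:
    """A validated PNA strand, stored N-terminus to C-terminus."""

    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _validate_bases(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases


@dataclass(frozen=True)
class DuplexDescriptor:
    """Stack composition of the homoduplex formed by ``sequence``.

    ``stack_counts`` maps canonical stack labels to occurrence counts
    (the j_i of the nearest-neighbor sum); ``n_terminal_gc`` counts how many
    of the two terminal base pairs are G.C.
    """

    sequence: PnaSequence
    self_complementary: bool
    n_terminal_gc: int
    stack_counts: dict[str, int] = field(hash=False)

    @property
    def terminal_gc_indicator(self) -> int:
        """B of the nearest-neighbor sum: 1 only when both termini pair G.C."""
        return 1 if self.n_terminal_gc == 2 else 0


def _validate_bases(raw: str) -> str:
    text = raw.strip().upper()
    if len(text) < 2:
        raise ValueError(f"sequence must have length >= 2, got {text!r}")
    for pos, ch in enumerate(text, start=1):
        if ch not in _COMPLEMENT:
            raise ValueError(
                f"invalid base {ch!r} at position {pos} (allowed: A, C, G, T)"
            )
    return text


def validate_sequence(raw: str) -> PnaSequence:
    """Validate and normalize a raw sequence string (case-insensitive)."""
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("sequence must be non-empty text")
    return PnaSequence(raw)


def antiparallel_complement(s: PnaSequence | str) -> PnaSequence:
    """The Watson-Crick complement read in reversed (antiparallel) order."""
    seq = s if isinstance(s, PnaSequence) else validate_sequence(s)
    return PnaSequence("".join(_COMPLEMENT[b] for b in reversed(seq.bases)))


def is_self_complementary(s: PnaSequence | str) -> bool:
    """True iff the strand equals its own antiparallel complement.

    Odd-length strands can never be self-complementary (the central base
    would have to pair with itself) and simply return False.
    """
    seq = s if isinstance(s, PnaSequence) else validate_sequence(s)
    return antiparallel_complement(seq).bases == seq.bases


def canonical_stack(dinucleotide: str) -> StackClass:
    """Map a dinucleotide to its canonical stack class.

    ``X1X2`` and ``comp(X2)comp(X1)`` name the same physical stack read from
    the two strands of an antiparallel duplex; whichever of the two spellings
    appears in :data:`CANONICAL_STACKS` is the class label.
    """
    d = dinucleotide.strip().upper()
    if len(d) != 2:
        raise ValueError(f"expected two bases, got {dinucleotide!r}")
    for pos, ch in enumerate(d, start=1):
        if ch not in _COMPLEMENT:
            raise ValueError(
                f"invalid base {ch!r} at position {pos} (allowed: A, C, G, T)"
            )
    if d in STACK_WC_HBONDS:
        label = d
    else:
        label = _COMPLEMENT[d[1]] + _COMPLEMENT[d[0]]
    return StackClass(label, STACK_WC_HBONDS[label])


def describe_duplex(s: PnaSequence | str) -> DuplexDescriptor:
    """Enumerate and canonicalize the overlapping stacks of a homoduplex."""
    seq = s if isinstance(s, PnaSequence) else validate_sequence(s)
    counts: dict[str, int] = {}
    for i in range(len(seq) - 1):
        label = canonical_stack(seq.bases[i : i + 2]).label
        counts[label] = counts.get(label, 0) + 1
    n_gc = sum(1 for b in (seq.bases[0], seq.bases[-1]) if b in "GC")
    return DuplexDescriptor(
        sequence=seq,
        self_complementary=is_self_complementary(seq),
        n_terminal_gc=n_gc,
        stack_counts=counts,
    )


def read_sequences(path: str | Path) -> list[PnaSequence]:
    """Read sequences from plain text (one per line, ``#`` comments) or FASTA.

    FASTA headers (``>``) are treated as record separators; multi-line records
    are concatenated.  Returns sequences in file order.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    is_fasta = any(ln.lstrip().startswith(">") for ln in lines)
    if is_fasta:
        return list(_iter_fasta(lines))
    out = []
    for ln in lines:
        stripped = ln.split("#", 1)[0].strip()
        if stripped:
            out.append(validate_sequence(stripped))
    return out


def _iter_fasta(lines: Iterable[str]) -> Iterator[PnaSequence]:
    chunks: list[str] = []
    for ln in lines:
        ln = ln.strip()
        if ln.startswith(">"):
            if chunks:
                yield validate_sequence("".join(chunks))
                chunks = []
        elif ln:
            chunks.append(ln)
    if chunks:
        yield validate_sequence("".join(chunks))
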