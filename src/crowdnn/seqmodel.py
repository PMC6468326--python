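"""Self-complementary DNA sequences and canonical nearest-neighbor counting.

A self-complementary (palindromic) oligomer equals its own reverse
complement, so two identical strands hybridize into a duplex (2S ⇌ D).
Duplex stability in the nearest-neighbor (NN) model is additive over the
L−1 dinucleotide steps of the strand; a step read 5'→3' on one strand and
its reverse complement on the other strand describe the same stacked pair
of base pairs, so the 16 dinucleotides collapse to 10 canonical NN sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "NN_SETS",
    "DuplexSequence",
    "NNFrequencyVector",
    "reverse_complement",
    "is_self_complementary",
    "count_nn_steps",
    "read_sequences",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The 10 canonical NN sets, in the conventional table order. Each label
#: names the 5'→3' top-strand dinucleotide; e.g. "CA" is the dCA/dGT set.
NN_SETS: tuple[str, ...] = ("AA", "AT", "TA", "CA", "GT", "CT", "GA", "CG", "GC", "GG")


class InvalidAlphabetError(ValueError):
    """Sequence contains characters outside A/C/G/T."""


class NotSelfComplementaryError(ValueError):
    """Operation requires a self-complementary duplex sequence."""


def _validate(seq: str) -> str:
    s = seq.upper()
    if not s or set(s) - set("ACGT"):
        raise InvalidAlphabetError(
            f"sequence must be non-empty over A/C/G/T (got {seq!r}); "
            "U (RNA) is not accepted"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of a DNA string."""
    return _validate(seq).translate(_COMPLEMENT)[::-1]


def is_self_complementary(seq: str) -> bool:
    """True iff the strand equals its own reverse complement.

    Odd-length strands can never be self-complementary (the central base
    would have to pair with itself).
    """
    s = _validate(seq)
    return s == s.translate(_COMPLEMENT)[::-1]


def _canonical_step(step: str) -> str:
    """Map one of the 16 dinucleotide steps onto its canonical NN set."""
    return step if step in _CANONICAL else _CANONICAL_RC[step]


_CANONICAL = frozenset(NN_SETS)
# reverse complement of each non-canonical dinucleotide -> canonical label
_CANONICAL_RC: dict[str, str] = {
    step: step.translate(_COMPLEMENT)[::-1]
    for step in (a + b for a in "ACGT" for b in "ACGT")
    if step not in _CANONICAL
}
assert set(_CANONICAL_RC.values()) <= _CANONICAL


@dataclass(frozen=True)
class DuplexSequence:
    """A validated self-complementary DNA oligomer.

    Parameters
    ----------
    bases
        Strand sequence 5'→3' over A/C/G/T; uppercased on ingestion.
        Must equal its own reverse complement.
    name
        Free-text label (defaults to the sequence itself).
    """

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        s = _validate(self.bases)
        object.__setattr__(self, "bases", s)
        if len(s) < 2:
            raise ValueError("duplex sequence needs at least 2 bases")
        if not is_self_complementary(s):
            raise NotSelfComplementaryError(
                f"{s} is not self-complementary; only palindromic duplexes "
                "are supported"
            )
        if not self.name:
            object.__setattr__(self, "name", s)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def terminal_5prime_pair(self) -> str:
        """Terminal base pair written 5'-X·Y-3', e.g. 'T·A' for d(TGCA...)."""
        first = self.bases[0]
        return f"{first}·{first.translate(_COMPLEMENT)}"

    @property
    def initiation_class(self) -> str:
        """'AT' if the terminal pair is A·T or T·A, else 'GC'.

        Both termini of a self-complementary duplex carry the same pair
        type, so the first base alone decides the class.
        """
        return "AT" if self.bases[0] in "AT" else "GC"


@dataclass(frozen=True)
class NNFrequencyVector:
    """Counts of the 10 canonical NN sets for one duplex design."""

    counts: Mapping[str, int]
    initiation_class: str
    terminal_5prime_pair: str

    def __post_init__(self) -> None:
        if set(self.counts) - set(NN_SETS):
            raise ValueError(f"unknown NN set in {sorted(self.counts)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("NN counts must be non-negative")
        if self.initiation_class not in ("AT", "GC"):
            raise ValueError("initiation_class must be 'AT' or 'GC'")

    def __getitem__(self, nn_set: str) -> int:
        return self.counts.get(nn_set, 0)

    @property
    def total(self) -> int:
        """Number of NN steps; equals sequence length − 1."""
        return sum(self.counts.values())

    def as_dict(self) -> dict[str, int]:
        """All 10 sets, zero-filled, in canonical order."""
        return {s: self.counts.get(s, 0) for s in NN_SETS}


def count_nn_steps(seq: DuplexSequence | str) -> NNFrequencyVector:
    """Count the canonical NN sets present in a self-complementary duplex.

    Each of the L−1 dinucleotide steps is mapped onto its canonical set
    (a step and its reverse complement are the same set). The initiation
    class follows the terminal base pair.
    """
    if isinstance(seq, str):
        seq = DuplexSequence(seq)
    counts: dict[str, int] = {}
    b = seq.bases
    for i in range(len(b) - 1):
        key = _canonical_step(b[i : i + 2])
        counts[key] = counts.get(key, 0) + 1
    return NNFrequencyVector(
        counts=counts,
        initiation_class=seq.initiation_class,
        terminal_5prime_pair=seq.terminal_5prime_pair,
    )


def read_sequences(path: str | Path) -> Iterator[DuplexSequence]:
    """Read duplex sequences from FASTA or one-per-line plain text.

    Files whose first non-blank character is '>' are parsed as FASTA via
    Biopython; anything else is treated as one sequence per line, with an
    optional whitespace-separated name after the sequence.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            yield DuplexSequence(str(rec.seq), name=rec.id)
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            name = parts[1] if len(parts) > 1 else ""
            yield DuplexSequence(parts[0], name=name)
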