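"""Oligonucleotide handling and melting-temperature calculation.

The L-DNA sensor duplexes that drive adaptive cycling are designed so their
melting temperatures track those of the reaction's primers and target.  This
module provides the salt-adjusted Tm formula used for that design work
(the classic OligoCalc convention) and a two-state logistic melt model used by
the instrument simulator to turn temperature into single-stranded fraction.

L-DNA is the mirror-image stereoisomer of natural D-DNA: it hybridizes with
identical thermodynamics but is invisible to polymerases, so chirality is
carried as metadata only and never affects any computation here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "OligoSequence",
    "TmResult",
    "MeltModel",
    "gc_count",
    "salt_adjusted_tm",
    "ss_fraction",
    "read_fasta",
    "load_reference_oligos",
]

_VALID_BASES = frozenset("ACGT")

#: Length above which the long-oligo salt-adjusted formula applies.
LONG_FORMULA_MIN_LENGTH = 14


class SequenceError(ValueError):
    """Raised for invalid oligonucleotide sequences."""


@dataclass(frozen=True)
class OligoSequence:
    """A validated DNA oligonucleotide.

    Parameters
    ----------
    bases:
        Uppercase sequence over the alphabet ``ACGT`` (5'→3').
    name:
        Free-text identifier.
    label5, label3:
        Optional 5'/3' modification names (fluorophore / quencher); stripped
        from the sequence itself and carried purely as metadata.
    chirality:
        ``"D"`` (natural) or ``"L"`` (mirror-image sensor strand).  Metadata
        only: L-DNA hybridizes with identical thermodynamics.
    """

    bases: str
    name: str = ""
    label5: str | None = None
    label3: str | None = None
    chirality: str = "D"

    def __post_init__(self) -> None:
        if not self.bases:
            raise SequenceError("sequence must contain at least one base")
        for i, b in enumerate(self.bases):
            if b not in _VALID_BASES:
                raise SequenceError(
                    f"invalid base {b!r} at position {i + 1} "
                    f"(sequence must be uppercase ACGT)"
                )
        if self.chirality not in ("D", "L"):
            raise SequenceError(f"chirality must be 'D' or 'L', got {self.chirality!r}")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "OligoSequence":
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        rc = "".join(comp[b] for b in reversed(self.bases))
        return OligoSequence(
            rc, name=f"{self.name}_rc" if self.name else "", chirality=self.chirality
        )


@dataclass(frozen=True)
class TmResult:
    """Salt-adjusted melting temperature and the inputs that produced it."""

    tm_celsius: float
    gc_count: int
    length: int
    na_molar: float
    formula: str  # "salt_adjusted_long" | "salt_adjusted_short"

    @property
    def tm_display(self) -> float:
        """Tm rounded to one decimal, the conventional reporting precision."""
        return round(self.tm_celsius, 1)


def _as_oligo(seq: OligoSequence | str) -> OligoSequence:
    return seq if isinstance(seq, OligoSequence) else OligoSequence(str(seq))


def gc_count(seq: OligoSequence | str) -> int:
    """Number of G plus C bases in the sequence."""
    s = _as_oligo(seq)
    return sum(1 for b in s.bases if b in "GC")


def salt_adjusted_tm(seq: OligoSequence | str, na_molar: float = 0.05) -> TmResult:
    """Salt-adjusted melting temperature (°C) of an oligonucleotide.

    For oligos longer than 13 nt::

        Tm = 100.5 + 41·GC/N − 820/N + 16.6·log10([Na+])

    and for 13 nt or shorter the Wallace-rule variant::

        Tm = 2·(A+T) + 4·(G+C) − 16.6·log10(0.05) + 16.6·log10([Na+])

    Parameters
    ----------
    seq:
        Sequence or :class:`OligoSequence`.
    na_molar:
        Monovalent cation concentration in mol/L.  Defaults to 50 mM, a
        conventional approximation when the true master-mix salt content is
        proprietary.
    """
    if na_molar <= 0:
        raise ValueError(f"na_molar must be positive, got {na_molar}")
    s = _as_oligo(seq)
    n = len(s)
    gc = gc_count(s)
    salt_term = 16.6 * math.log10(na_molar)
    if n >= LONG_FORMULA_MIN_LENGTH:
        tm = 100.5 + 41.0 * gc / n - 820.0 / n + salt_term
        formula = "salt_adjusted_long"
    else:
        at = n - gc
        tm = 2.0 * at + 4.0 * gc - 16.6 * math.log10(0.05) + salt_term
        formula = "salt_adjusted_short"
    return TmResult(tm_celsius=tm, gc_count=gc, length=n, na_molar=na_molar, formula=formula)


@dataclass(frozen=True)
class MeltModel:
    """Two-state (duplex ⇌ single strands) logistic melt model.

    The single-stranded fraction is ``f_ss(T) = 1/(1 + exp(−(T − Tm)/w))``:
    0.5 at ``Tm``, approaching 0 well below and 1 well above, with ``w``
    setting the transition width in °C.
    """

    tm_celsius: float
    width_celsius: float = 2.5

    def __post_init__(self) -> None:
        if self.width_celsius <= 0:
            raise ValueError(f"width must be positive, got {self.width_celsius}")


def ss_fraction(t, model: MeltModel):
    """Single-stranded fraction at temperature ``t`` (°C); vectorized."""
    t = np.asarray(t, dtype=float)
    f = 1.0 / (1.0 + np.exp(-(t - model.tm_celsius) / model.width_celsius))
    return float(f) if f.ndim == 0 else f


def read_fasta(path: str | Path) -> list[OligoSequence]:
    """Read oligos from a FASTA file.

    Header tokens of the form ``key=value`` (``label5``, ``label3``,
    ``chirality``) are parsed into metadata; the first token is the name.
    """
    oligos = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = {}
        for tok in rec.description.split()[1:]:
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
        oligos.append(
            OligoSequence(
                bases=str(rec.seq).upper(),
                name=rec.id,
                label5=meta.get("label5"),
                label3=meta.get("label3"),
                chirality=meta.get("chirality", "D"),
            )
        )
    if not oligos:
        raise SequenceError(f"no sequences found in {path}")
    return oligos


def load_reference_oligos() -> dict[str, OligoSequence]:
    """The packaged reference oligo set (sensors, primers, probe, target)."""
    from importlib import resources

    with resources.as_file(
        resources.files("adaptivepcr").joinpath("data/table1_oligos.fasta")
    ) as p:
        return {o.name: o for o in read_fasta(p)}
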