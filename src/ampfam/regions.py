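"""Fixed-length region partition of a peptide sequence.

A sequence of length ``L`` is cut into six contiguous regions: four
N-terminal sub-regions ``n1..n4`` of ``d_N`` residues each, a C-terminal
``C`` of ``d_C`` residues, and whatever remains in the middle ``M``.  When
the sequence is too short for the nominal layout (``L < 4*d_N + d_C``) the
terminals shrink proportionally; see :func:`partition`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import Peptide

REGION_NAMES = ("n1", "n2", "n3", "n4", "M", "C")
FULL = "FULL"

MIN_LENGTH = 6  # one residue per region


@dataclass(frozen=True)
class RegionPartition:
    """Half-open, 0-based spans of the six regions of one sequence."""

    d_N: int
    d_C: int
    L: int
    spans: dict[str, tuple[int, int]]

    def span(self, region: str) -> tuple[int, int]:
        if region == FULL:
            return (0, self.L)
        try:
            return self.spans[region]
        except KeyError:
            raise KeyError(f"unknown region {region!r}") from None

    def width(self, region: str) -> int:
        a, b = self.span(region)
        return b - a


def _split_evenly(total: int, parts: int) -> list[int]:
    """Split ``total`` into ``parts`` integers, earlier parts get the extra."""
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def partition(sequence_length: int, d_N: int, d_C: int) -> RegionPartition:
    """Compute the n1..n4 / M / C spans for a sequence of given length.

    For ``L >= 4*d_N + d_C`` the layout is literal: each N sub-region takes
    ``d_N`` residues, C takes ``d_C``, M takes the remainder (possibly
    empty).  Shorter sequences keep the N:C proportions of the nominal
    layout: the N block gets ``floor(L*4*d_N/(4*d_N+d_C+1))`` residues
    (split as evenly as possible over n1..n4, earlier sub-regions first),
    C gets ``floor(L*d_C/(4*d_N+d_C+1))`` and M the rest, then minima are
    enforced (N block >= 4, C >= 1, M >= 1) by deterministically moving
    residues out of M, then C.  Every region is non-empty when ``L >= 6``.
    """
    L = int(sequence_length)
    if d_N < 1 or d_C < 1:
        raise ValueError("d_N and d_C must be >= 1")
    if L < MIN_LENGTH:
        raise ValueError(
            f"sequence length {L} < {MIN_LENGTH}: cannot form six regions"
        )

    nominal = 4 * d_N + d_C
    if L >= nominal:
        n_widths = [d_N] * 4
        c_width = d_C
        m_width = L - nominal
    else:
        denom = nominal + 1
        n_total = (L * 4 * d_N) // denom
        c_width = (L * d_C) // denom
        # enforce per-region minima deterministically
        n_total = max(n_total, 4)
        c_width = max(c_width, 1)
        m_width = L - n_total - c_width
        while m_width < 1:
            if c_width > 1:
                c_width -= 1
            elif n_total > 4:
                n_total -= 1
            else:  # unreachable for L >= 6
                raise ValueError(f"cannot partition length {L}")
            m_width = L - n_total - c_width
        n_widths = _split_evenly(n_total, 4)

    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, width in zip(REGION_NAMES, n_widths + [m_width, c_width]):
        spans[name] = (pos, pos + width)
        pos += width
    assert pos == L
    return RegionPartition(d_N=d_N, d_C=d_C, L=L, spans=spans)


def region_residues(
    peptide: Peptide | str, part: RegionPartition, region: str
) -> str:
    """Residues of ``peptide`` falling in the named region (or FULL)."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if len(seq) != part.L:
        raise ValueError(
            f"sequence length {len(seq)} does not match partition L={part.L}"
        )
    a, b = part.span(region)
    return seq[a:b]
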