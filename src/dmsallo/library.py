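"""Saturation-mutagenesis library design.

A full single-site scan of a 159-residue protein has 159 x 19 = 3021
missense variants.  Variants are identified by ``<wt><position><mut>``
names (e.g. ``D27N``) with 1-based residue numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genetics import AA20, DHFR_SEQ

_NAME_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")


@dataclass(frozen=True, order=True)
class VariantID:
    """One amino-acid substitution, optionally with its library codon."""

    position: int  # 1-based residue number
    wt: str
    mut: str
    codon: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("residue positions are 1-based")
        if self.wt == self.mut:
            raise ValueError(f"{self.wt}{self.position}{self.mut} is not a substitution")

    @property
    def name(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name

    @classmethod
    def from_name(cls, name: str, wt_protein: str | None = None) -> "VariantID":
        m = _NAME_RE.match(name)
        if not m:
            raise ValueError(f"malformed mutation name: {name!r}")
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
        if wt_protein is not None:
            if pos > len(wt_protein):
                raise ValueError(f"{name}: position beyond sequence end")
            if wt_protein[pos - 1] != wt:
                raise ValueError(
                    f"{name}: wild-type residue at {pos} is {wt_protein[pos - 1]}"
                )
        return cls(pos, wt, mut)


def enumerate_library(
    wt_protein: str = DHFR_SEQ, n_positions: int | None = None
) -> list[VariantID]:
    """Enumerate all 19 missense substitutions at every position.

    Parameters
    ----------
    wt_protein:
        Wild-type protein sequence (standard residues only).
    n_positions:
        Optional check that the sequence has the expected length.

    Returns
    -------
    list of :class:`VariantID`, ordered by ascending position and then
    alphabetically by mutant residue.  For a 159-residue scan this is
    exactly 3021 variants.
    """
    wt_protein = wt_protein.upper()
    if n_positions is not None and len(wt_protein) != n_positions:
        raise ValueError(
            f"sequence length {len(wt_protein)} != n_positions {n_positions}"
        )
    bad = sorted({aa for aa in wt_protein if aa not in AA20})
    if bad:
        raise ValueError(f"sequence contains non-standard residues: {''.join(bad)}")
    variants = []
    for i, wt in enumerate(wt_protein, start=1):
        for mut in AA20:
            if mut != wt:
                variants.append(VariantID(i, wt, mut))
    return variants
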