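"""Genetic-code utilities shared across the pipeline.

The saturation mutagenesis library studied here was built with NNS
degenerate codons (N = A/T/G/C, S = G/C), so every library codon has G
or C at the third position.  The 32 NNS codons cover all 20 amino acids
plus the amber stop (TAG).  Codon-level bookkeeping (Hamming distances,
NNS membership, translation) lives in this module.
"""

from __future__ import annotations

import itertools

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

#: The 20 standard amino acids, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Stop symbol used when pooling nonsense codons.
STOP = "*"

#: E. coli dihydrofolate reductase (folA), 159 residues.  This is the
#: DHFR moiety of the DL121 light-switchable chimera; the LOV2 domain is
#: inserted between residues 120 and 121 and is not part of the
#: mutagenized sequence.
DHFR_SEQ = (
    "MISLIAALAVDRVIGMENAMPWNLPADLAWFKRNTLNKPVIMGRHTWESIGRPLPGRKNI"
    "ILSSQPGTDDRVTWVKSVDEAIAACGDVPEIMVIGGGRVYEQFLPKAQKLYLTHIDAEVE"
    "GDTHFPDYEPDDWESVFSEFHDADAQNSHSYCFEILERR"
)

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)

#: The 32 codons compatible with NNS mutagenesis (third base G or C).
NNS_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c[2] in "GC")

_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = STOP


def translate_codon(codon: str) -> str:
    """Translate a single DNA codon; stop codons yield ``'*'``."""
    try:
        return CODON_TO_AA[codon.upper()]
    except KeyError:
        raise ValueError(f"not a valid DNA codon: {codon!r}") from None


def translate(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError("coding sequence length must be a multiple of 3")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


def hamming(codon_a: str, codon_b: str) -> int:
    """Nucleotide Hamming distance between two codons."""
    if len(codon_a) != len(codon_b):
        raise ValueError("codons must have equal length")
    return sum(a != b for a, b in zip(codon_a, codon_b))


def is_nns(codon: str) -> bool:
    return len(codon) == 3 and codon[2].upper() in "GC"


def nns_codons_for(aa: str) -> tuple[str, ...]:
    """All NNS codons encoding ``aa`` (alphabetical, deterministic)."""
    return tuple(c for c in NNS_CODONS if CODON_TO_AA[c] == aa)


def nns_codon_for(aa: str) -> str:
    """Canonical (first alphabetical) NNS codon for an amino acid."""
    codons = nns_codons_for(aa)
    if not codons:
        raise ValueError(f"no NNS codon encodes {aa!r}")
    return codons[0]


def reverse_translate(protein: str, prefer_nns: bool = True) -> str:
    """Deterministic reverse translation of a protein sequence.

    Used to build a synthetic reference coding sequence when the real
    plasmid sequence is not supplied.  With ``prefer_nns`` each codon is
    the canonical NNS codon, so wild-type codons sit inside the library
    codon space just like the real NNS-built reference construct.
    """
    codons = []
    for aa in protein:
        if aa not in AA20:
            raise ValueError(f"non-standard residue {aa!r}")
        if prefer_nns:
            codons.append(nns_codon_for(aa))
        else:
            codons.append(next(c for c in ALL_CODONS if CODON_TO_AA[c] == aa))
    return "".join(codons)


def codon_neighbors(codon: str, hd: int) -> tuple[str, ...]:
    """All codons at exactly Hamming distance ``hd`` from ``codon``."""
    return tuple(c for c in ALL_CODONS if hamming(c, codon) == hd)
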