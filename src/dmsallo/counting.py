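"""Codon-variant counting from merged amplicon reads.

Reads are assumed merged and in reference orientation.  A read is kept
only if every base of the mutagenized coding region meets the Phred
cutoff (Q >= 30 by default, matching the sequencing pipeline this
package reproduces).  Kept reads are classified as reference (no codon
differs), single-codon mutants (counted), or multi-codon mutants
(tallied but excluded from the variant table).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .genetics import is_nns, translate_codon


@dataclass(frozen=True)
class ReadFilterConfig:
    """Quality filtering and coordinate bookkeeping for one amplicon.

    ``coding_region`` is a 0-based half-open interval on the read
    covering the mutagenized codons; ``first_residue`` is the 1-based
    residue number of the first codon in that interval, so reported
    positions use protein numbering.
    """

    q_cutoff: int = 30
    coding_region: tuple[int, int] = (0, 477)
    first_residue: int = 1

    def __post_init__(self) -> None:
        if self.q_cutoff < 0:
            raise ValueError("q_cutoff must be >= 0")
        start, end = self.coding_region
        if end <= start or (end - start) % 3:
            raise ValueError("coding region length must be a positive multiple of 3")

    @property
    def n_codons(self) -> int:
        start, end = self.coding_region
        return (end - start) // 3


@dataclass
class CodonCountTable:
    """Per-sample codon-variant counts with filtering bookkeeping.

    ``counts`` maps (1-based residue position, codon) -> reads carrying
    exactly that single codon substitution.  ``n_wt`` counts reads that
    match the reference over the whole coding region.
    """

    counts: dict[tuple[int, str], float] = field(default_factory=dict)
    n_wt: float = 0.0
    n_discarded: int = 0  # failed the quality cutoff
    n_multi_mutant: int = 0  # >= 2 mutated codons
    n_rejected: int = 0  # wrong length / unparseable
    n_total: int = 0
    positions: tuple[int, ...] = ()
    sample: dict = field(default_factory=dict)  # condition/replicate/timepoint

    @property
    def n_kept(self) -> float:
        return self.n_wt + sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"position": pos, "codon": codon, "aa": translate_codon(codon), "count": c}
            for (pos, codon), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["position", "codon", "aa", "count"])

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# n_wt\t{self.n_wt}\n")
            fh.write(f"# n_discarded\t{self.n_discarded}\n")
            fh.write(f"# n_multi_mutant\t{self.n_multi_mutant}\n")
            fh.write(f"# n_rejected\t{self.n_rejected}\n")
            fh.write(f"# n_total\t{self.n_total}\n")
            frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CodonCountTable":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                key, value = line[1:].strip().split("\t")
                meta[key] = float(value)
                pos = fh.tell()
            frame = pd.read_csv(fh, sep="\t")
        table = cls(
            counts={
                (int(pos), str(codon)): float(c)
                for pos, codon, c in zip(
                    frame["position"], frame["codon"], frame["count"]
                )
            },
            n_wt=meta.get("n_wt", 0.0),
            n_discarded=int(meta.get("n_discarded", 0)),
            n_multi_mutant=int(meta.get("n_multi_mutant", 0)),
            n_rejected=int(meta.get("n_rejected", 0)),
            n_total=int(meta.get("n_total", 0)),
        )
        table.positions = tuple(sorted({p for p, _ in table.counts}))
        return table


def count_variants(
    reads: Iterable[SeqRecord] | str | Path,
    reference_cds: str,
    config: ReadFilterConfig = ReadFilterConfig(),
) -> CodonCountTable:
    """Count codon variants in merged amplicon reads.

    A read is discarded if any base of the coding region falls below the
    quality cutoff.  Kept reads matching the reference increment
    ``n_wt``; reads with exactly one mutated codon increment that
    (position, codon) entry; reads with two or more mutated codons are
    counted as multi-mutant and excluded.  Reads too short to span the
    coding region are rejected (counted, not fatal).
    """
    if isinstance(reads, (str, Path)):
        reads = SeqIO.parse(str(reads), "fastq")
    start, end = config.coding_region
    ref_region = reference_cds.upper()[start:end]
    if len(ref_region) != end - start:
        raise ValueError("reference shorter than the configured coding region")
    ref_codons = [ref_region[i : i + 3] for i in range(0, len(ref_region), 3)]

    table = CodonCountTable()
    for rec in reads:
        table.n_total += 1
        seq = str(rec.seq).upper()
        if len(seq) < end:
            table.n_rejected += 1
            continue
        quals = rec.letter_annotations.get("phred_quality")
        if quals is not None and min(quals[start:end]) < config.q_cutoff:
            table.n_discarded += 1
            continue
        region = seq[start:end]
        mutated = [
            (i, region[3 * i : 3 * i + 3])
            for i in range(config.n_codons)
            if region[3 * i : 3 * i + 3] != ref_codons[i]
        ]
        if not mutated:
            table.n_wt += 1
        elif len(mutated) == 1:
            i, codon = mutated[0]
            key = (config.first_residue + i, codon)
            table.counts[key] = table.counts.get(key, 0) + 1
        else:
            table.n_multi_mutant += 1
    table.positions = tuple(
        range(config.first_residue, config.first_residue + config.n_codons)
    )
    return table


def aggregate_codons_to_aa(
    table: CodonCountTable, require_nns: bool = True
) -> tuple[dict[tuple[int, str], float], float]:
    """Pool synonymous codons into amino-acid variant counts.

    Codons whose third base is not G/C cannot arise from NNS mutagenesis
    and are excluded as sequencing artifacts when ``require_nns``.
    Nonsense codons pool under the ``'*'`` variant.

    Returns ``(aa_counts, n_non_library)`` where ``aa_counts`` maps
    (position, amino acid) -> count.
    """
    aa_counts: dict[tuple[int, str], float] = {}
    n_non_library = 0.0
    for (pos, codon), c in table.counts.items():
        if require_nns and not is_nns(codon):
            n_non_library += c
            continue
        key = (pos, translate_codon(codon))
        aa_counts[key] = aa_counts.get(key, 0) + c
    return aa_counts, n_non_library
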