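"""Expected sequencing-noise subtraction for codon counts.

With mean run quality muQ, a source codon observed N times is expected
to spill

    N_errant = N * (10 ** (-muQ / 10)) ** HD

reads into each codon at nucleotide Hamming distance HD.  This is the
normative correction reproduced here; it intentionally omits the
binomial combinatorial factor and the (1 - p) survival term of the
exact per-base model (available as :func:`binomial_errant`), and it
treats the per-base error rate as the rate of each specific
substitution.  Expected flows into every observed codon (and the
reference allele) are computed from the raw table and subtracted
simultaneously; negative results are floored at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .genetics import hamming, codon_neighbors, nns_codon_for
from .counting import CodonCountTable


@dataclass(frozen=True)
class ErrorModelConfig:
    mean_q: float = 30.0
    max_hd: int = 3
    floor_at_zero: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.max_hd <= 3:
            raise ValueError("max_hd must be 1..3")
        if self.mean_q <= 0:
            raise ValueError("mean_q must be positive")

    @property
    def p(self) -> float:
        return 10.0 ** (-self.mean_q / 10.0)


def expected_errant(source_count: float, mean_q: float, hd: int) -> float:
    """Expected errant reads at Hamming distance ``hd`` from a source.

    ``source_count * (10 ** (-mean_q / 10)) ** hd`` — e.g. one million
    reads at muQ = 30 put 1000 expected miscalls into each single-base
    neighbour codon.
    """
    if source_count < 0:
        raise ValueError("source_count must be >= 0")
    if hd < 1:
        raise ValueError("hd must be >= 1")
    if mean_q <= 0:
        raise ValueError("mean_q must be positive")
    return source_count * (10.0 ** (-mean_q / 10.0)) ** hd


def binomial_errant(source_count: float, mean_q: float, hd: int) -> float:
    """Exact per-base binomial expectation, for comparison.

    Expected reads with exactly ``hd`` miscalled bases in a codon:
    ``N * C(3, hd) * p^hd * (1-p)^(3-hd)`` with p = 10^(-muQ/10).
    """
    if source_count < 0 or hd < 1 or hd > 3:
        raise ValueError("need source_count >= 0 and 1 <= hd <= 3")
    p = 10.0 ** (-mean_q / 10.0)
    return source_count * math.comb(3, hd) * p**hd * (1.0 - p) ** (3 - hd)


def correct_counts(
    table: CodonCountTable,
    config: ErrorModelConfig = ErrorModelConfig(),
    wt_codons: dict[int, str] | None = None,
) -> CodonCountTable:
    """Subtract expected sequencing-noise flows from a codon count table.

    For every observed codon at a position, the expected errant inflow
    from the reference codon and from every other observed codon at
    that position (Hamming distance <= ``max_hd``) is subtracted.  The
    reference count is reduced by its total expected outflow into the
    alternative codons of each position in the table (the same
    symmetric treatment the correction applies to mutants).  Because
    the reference correction is a constant factor across samples of a
    run, it cancels in the log-ratio normalization downstream.

    ``wt_codons`` maps 1-based position -> reference codon; if omitted
    the canonical NNS codon of the wild-type residue is assumed for
    positions present in ``table.positions`` paired with ``table.sample``
    metadata, and flows involving the reference are restricted to the
    positions listed in ``table.positions``.
    """
    if wt_codons is None:
        wt_codons = {}
    p = config.p
    positions = table.positions or tuple(sorted({pos for pos, _ in table.counts}))

    by_pos: dict[int, dict[str, float]] = {}
    for (pos, codon), c in table.counts.items():
        by_pos.setdefault(pos, {})[codon] = c

    new_counts: dict[tuple[int, str], float] = {}
    wt_outflow = 0.0
    wt_inflow = 0.0
    for pos in positions:
        observed = by_pos.get(pos, {})
        wt_codon = wt_codons.get(pos)
        if wt_codon is None and table.sample.get("wt_protein"):
            wt_codon = nns_codon_for(table.sample["wt_protein"][pos - 1])
        # expected flows out of the reference at this position
        for hd in range(1, config.max_hd + 1):
            if wt_codon is not None:
                wt_outflow += len(codon_neighbors(wt_codon, hd)) * table.n_wt * p**hd
        for codon, raw in observed.items():
            inflow = 0.0
            if wt_codon is not None and codon != wt_codon:
                hd = hamming(codon, wt_codon)
                if hd <= config.max_hd:
                    inflow += table.n_wt * p**hd
            for other, other_count in observed.items():
                if other == codon:
                    continue
                hd = hamming(codon, other)
                if hd <= config.max_hd:
                    inflow += other_count * p**hd
            corrected = raw - inflow
            if config.floor_at_zero:
                corrected = max(0.0, corrected)
            new_counts[(pos, codon)] = corrected
            if wt_codon is not None and codon != wt_codon:
                hd = hamming(codon, wt_codon)
                if hd <= config.max_hd:
                    wt_inflow += raw * p**hd

    new_wt = table.n_wt - wt_outflow - wt_inflow
    if config.floor_at_zero:
        new_wt = max(0.0, new_wt)
    return replace(
        table,
        counts=new_counts,
        n_wt=new_wt,
        positions=positions,
    )
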