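"""Synthetic turbidostat selection and amplicon sequencing.

The generator emulates the measurement process of a light-switchable
enzyme selection: a pooled library of single mutants competes in
exponential growth in triplicate vials under blue light ("lit") and in
the dark, samples are drawn at fixed hours and deep-sequenced, and each
sequenced base may be miscalled according to its Phred quality.  Every
variant carries a known true relative growth rate per condition, so
downstream estimators can be scored by parameter recovery.

Model
-----
For variant *a* with initial abundance ``x0_a`` and true relative growth
rate ``rgr_a`` (h^-1, relative to the unmutated reference, which grows
at rate 0 by definition), the expected population share at time *t* is

    p_a(t) = x0_a * exp(rgr_a * t) / sum_b x0_b * exp(rgr_b * t)

and a sample sequenced to ``depth`` reads is a multinomial draw from
``p(t)``.  Light-dependent (allosteric) variants carry an additive
offset in log-growth space: ``rgr_lit = rgr_dark + delta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import DHFR_SEQ, NUCLEOTIDES, nns_codons_for, reverse_translate
from .library import VariantID, enumerate_library

#: Sampling schedule of the selection assay (hours into selection).
DEFAULT_TIMEPOINTS_H = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)

CONDITIONS = ("lit", "dark")

#: Name used for the reference (unmutated) allele in count tables.
REFERENCE = "WT"


@dataclass(frozen=True)
class RgrMixture:
    """True relative-growth-rate distribution for the mutant library.

    A three-component mixture shaped like the observed fitness spectrum
    of an unoptimized enzyme chimera: a near-neutral class, a broad
    deleterious bulk centred at -0.084 h^-1, and a near-inactive class
    depleted so fast that it never yields three usable timepoints.
    """

    neutral_frac: float = 0.155
    neutral_sd: float = 0.01
    deleterious_mean: float = -0.084
    deleterious_sd: float = 0.04
    null_frac: float = 0.22
    null_rgr: float = -0.8

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        rgr = rng.normal(self.deleterious_mean, self.deleterious_sd, size=n)
        neutral = u < self.neutral_frac
        rgr[neutral] = rng.normal(0.0, self.neutral_sd, size=int(neutral.sum()))
        null = u > 1.0 - self.null_frac
        rgr[null] = self.null_rgr
        return rgr


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic selection experiment."""

    n_positions: int = 159
    wt_protein: str = DHFR_SEQ
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    n_replicates: int = 3
    depth: int = 1_000_000
    mean_q: float = 30.0
    rgr_distribution: RgrMixture = field(default_factory=RgrMixture)
    allosteric_fraction: float = 0.05
    allosteric_effect_scale: float = 0.03
    dropout_fraction: float = 0.075
    reference_weight: float = 0.05
    abundance_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        t = self.timepoints_h
        if not t or t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must start at 0 and strictly increase")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for name in ("allosteric_fraction", "dropout_fraction", "reference_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.wt_protein) != self.n_positions:
            raise ValueError("wt_protein length must equal n_positions")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth for a simulated library.

    ``frame`` is indexed by variant name with columns ``position``,
    ``wt``, ``mut``, ``codon``, ``rgr_dark``, ``rgr_lit``, ``delta`` and
    ``x0`` (initial abundance; 0 encodes library dropout).  The
    reference allele is implicit: rgr 0 in both conditions.
    """

    frame: pd.DataFrame
    reference_weight: float

    @property
    def variants(self) -> list[str]:
        return list(self.frame.index)

    def rgr(self, condition: str) -> pd.Series:
        return self.frame[f"rgr_{condition}"]

    def expected_shares(self, condition: str, t: float) -> pd.Series:
        """Closed-form expected population shares at time ``t``.

        Includes the reference allele under the name ``WT``; shares sum
        to 1.  This is the noise-free oracle used to validate both the
        sampler and the downstream slope estimators.
        """
        rgr = self.rgr(condition).to_numpy()
        x0 = self.frame["x0"].to_numpy()
        w = x0 * np.exp(rgr * t)
        ref = self.reference_weight_abs * math.exp(0.0)
        total = w.sum() + ref
        shares = pd.Series(w / total, index=self.frame.index)
        shares[REFERENCE] = ref / total
        return shares

    @property
    def reference_weight_abs(self) -> float:
        # reference abundance chosen so it is `reference_weight` of the
        # total initial population
        x0_sum = float(self.frame["x0"].sum())
        if self.reference_weight >= 1.0:
            raise ValueError("reference_weight must be < 1")
        return x0_sum * self.reference_weight / (1.0 - self.reference_weight)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="variant")

    @classmethod
    def from_tsv(cls, path, reference_weight: float = 0.05) -> "SimulationTruth":
        frame = pd.read_csv(path, sep="\t", index_col="variant")
        return cls(frame=frame, reference_weight=reference_weight)


def _truth_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 7_001]))


def _sample_rng(seed: int, condition: str, replicate: int, t_index: int) -> np.random.Generator:
    # one independent, reproducible stream per sequencing sample
    cond_code = CONDITIONS.index(condition)
    return np.random.default_rng(
        np.random.SeedSequence([seed, 11_003, cond_code, replicate, t_index])
    )


def make_truth(config: SimulationConfig) -> SimulationTruth:
    """Draw ground-truth growth rates, effects, codons and abundances."""
    rng = _truth_rng(config.seed)
    variants = enumerate_library(config.wt_protein, config.n_positions)
    n = len(variants)

    rgr_dark = config.rgr_distribution.sample(n, rng)
    delta = np.zeros(n)
    null_mask = rgr_dark <= config.rgr_distribution.null_rgr
    candidates = np.flatnonzero(~null_mask)
    n_allo = int(round(config.allosteric_fraction * n))
    n_allo = min(n_allo, candidates.size)
    if n_allo:
        chosen = rng.choice(candidates, size=n_allo, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_allo)
        delta[chosen] = signs * config.allosteric_effect_scale
    rgr_lit = rgr_dark + delta

    x0 = np.exp(rng.normal(0.0, config.abundance_log_sd, size=n))
    n_drop = int(round(config.dropout_fraction * n))
    if n_drop:
        x0[rng.choice(n, size=n_drop, replace=False)] = 0.0

    codons = [rng.choice(nns_codons_for(v.mut)) for v in variants]
    frame = pd.DataFrame(
        {
            "position": [v.position for v in variants],
            "wt": [v.wt for v in variants],
            "mut": [v.mut for v in variants],
            "codon": codons,
            "rgr_dark": rgr_dark,
            "rgr_lit": rgr_lit,
            "delta": delta,
            "x0": x0,
        },
        index=pd.Index([v.name for v in variants], name="variant"),
    )
    return SimulationTruth(frame=frame, reference_weight=config.reference_weight)


def simulate_counts(
    config: SimulationConfig, truth: SimulationTruth | None = None
) -> tuple[SimulationTruth, pd.DataFrame]:
    """Simulate sequencing count tables for every (condition, vial, time).

    Returns the ground truth and a long-format table with columns
    ``condition, replicate, timepoint_h, variant, count``; the reference
    allele appears as variant ``WT``.  Counts in each sample sum exactly
    to ``config.depth``.
    """
    if truth is None:
        truth = make_truth(config)
    names = truth.variants + [REFERENCE]
    rows = []
    for condition in CONDITIONS:
        rgr = np.concatenate([truth.rgr(condition).to_numpy(), [0.0]])
        x0 = np.concatenate([truth.frame["x0"].to_numpy(), [truth.reference_weight_abs]])
        if x0.sum() <= 0:
            raise ValueError("total initial abundance is zero")
        for replicate in range(1, config.n_replicates + 1):
            for t_index, t in enumerate(config.timepoints_h):
                w = x0 * np.exp(rgr * t)
                p = w / w.sum()
                rng = _sample_rng(config.seed, condition, replicate, t_index)
                counts = rng.multinomial(config.depth, p)
                rows.append(
                    pd.DataFrame(
                        {
                            "condition": condition,
                            "replicate": replicate,
                            "timepoint_h": t,
                            "variant": names,
                            "count": counts,
                        }
                    )
                )
    counts = pd.concat(rows, ignore_index=True)
    return truth, counts


def counts_to_wide(counts: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long count table to variants x (condition, replicate, t)."""
    wide = counts.pivot_table(
        index="variant",
        columns=["condition", "replicate", "timepoint_h"],
        values="count",
        aggfunc="sum",
        fill_value=0,
    )
    return wide.sort_index(axis=1)


def simulate_reads(
    sample_counts: pd.Series,
    reference_cds: str | None,
    codon_by_variant: dict[str, tuple[int, str]] | None = None,
    mean_q: float = 30.0,
    q_sd: float = 3.0,
    seed: int = 0,
    truth: SimulationTruth | None = None,
) -> list[SeqRecord]:
    """Generate pre-merged amplicon reads for one sequencing sample.

    Parameters
    ----------
    sample_counts:
        Variant-name -> read count for one sample (``WT`` = reference).
    reference_cds:
        Coding sequence of the unmutated amplicon; defaults to a
        deterministic NNS-codon reverse translation of the wild-type
        protein implied by ``truth``.
    codon_by_variant:
        Variant name -> (1-based residue position, library codon).
        Derived from ``truth`` when omitted.
    mean_q:
        Mean Phred quality of the run.  Per-base qualities are drawn
        from Normal(mean_q, q_sd), rounded and clipped to [2, 41]; each
        base is then miscalled with probability 10^(-q/10) consistent
        with its recorded quality.  ``math.inf`` disables errors.

    Returns Biopython ``SeqRecord`` objects with Sanger-scale
    ``phred_quality`` annotations, in deterministic order.
    """
    if codon_by_variant is None:
        if truth is None:
            raise ValueError("need codon_by_variant or truth")
        codon_by_variant = {
            name: (int(row.position), str(row.codon))
            for name, row in truth.frame.iterrows()
        }
    if reference_cds is None:
        if truth is None:
            raise ValueError("need reference_cds or truth")
        protein = "".join(
            truth.frame.sort_values("position").drop_duplicates("position")["wt"]
        )
        reference_cds = reverse_translate(protein)
    reference_cds = reference_cds.upper()
    length = len(reference_cds)
    if length % 3:
        raise ValueError("reference coding sequence length must be divisible by 3")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 21_007]))
    base_idx = {b: i for i, b in enumerate(NUCLEOTIDES)}
    ref_codes = np.array([base_idx[b] for b in reference_cds], dtype=np.int8)

    records: list[SeqRecord] = []
    read_no = 0
    for variant in sample_counts.index:
        n_reads = int(sample_counts[variant])
        if n_reads <= 0:
            continue
        codes = ref_codes.copy()
        if variant != REFERENCE:
            pos, codon = codon_by_variant[variant]
            start = (pos - 1) * 3
            if start + 3 > length:
                raise ValueError(f"variant {variant} outside reference")
            codes[start : start + 3] = [base_idx[b] for b in codon]
        if math.isinf(mean_q):
            quals = np.full((n_reads, length), 41, dtype=np.int16)
            miscall = np.zeros((n_reads, length), dtype=bool)
        else:
            quals = np.clip(
                np.rint(rng.normal(mean_q, q_sd, size=(n_reads, length))), 2, 41
            ).astype(np.int16)
            p_err = 10.0 ** (-quals / 10.0)
            miscall = rng.random((n_reads, length)) < p_err
        read_codes = np.broadcast_to(codes, (n_reads, length)).copy()
        if miscall.any():
            # substitute a uniformly chosen *different* base
            shift = rng.integers(1, 4, size=int(miscall.sum()))
            read_codes[miscall] = (read_codes[miscall] + shift) % 4
        for i in range(n_reads):
            seq = "".join(NUCLEOTIDES[c] for c in read_codes[i])
            rec = SeqRecord(Seq(seq), id=f"r{read_no}", description="")
            rec.letter_annotations["phred_quality"] = quals[i].tolist()
            records.append(rec)
            read_no += 1
    return records


def write_fastq(records: list[SeqRecord], path) -> None:
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fastq")


def read_fastq(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fastq"))
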