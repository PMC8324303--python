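"""End-to-end orchestration: simulate, fit, classify, report.

A single configuration (YAML or dict) drives the stages and one master
seed makes every output reproducible byte-for-byte.  Stage outputs are
plain TSV; the growth table follows the source-data layout of the
assay: mutation name, three lit replicate growth rates, lit mean and
sd, three dark replicate growth rates, dark mean and sd, with -999
marking variants that lacked three usable timepoints (null data) and
-1000 marking variants missing from the library at t = 0 (no data).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allostery as allostery_mod
from . import fitness as fitness_mod
from .simulate import (
    CONDITIONS,
    RgrMixture,
    SimulationConfig,
    simulate_counts,
)

_NAME_RE = re.compile(r"^[A-Z*]\d+[A-Z*]$")

_SENTINELS = {
    fitness_mod.NULL_DATA: fitness_mod.SENTINEL_NULL,
    fitness_mod.NO_DATA: fitness_mod.SENTINEL_NO_DATA,
}


def write_growth_table(growth: pd.DataFrame, path: str | Path) -> None:
    """Export a growth-rate table with sentinel encoding.

    Replicate, mean and sd columns of non-measured variants are encoded
    as -999 (null data) or -1000 (no data); measured values round-trip
    exactly through :func:`read_growth_table`.
    """
    cols = [
        c
        for cond in CONDITIONS
        for c in (
            [f"{cond}_{i}" for i in range(1, 4)] + [f"{cond}_mean", f"{cond}_sd"]
        )
    ]
    out = growth.reindex(columns=cols).copy()
    for status, sentinel in _SENTINELS.items():
        out.loc[growth["status"] == status, cols] = sentinel
    for name in out.index:
        if not _NAME_RE.match(str(name)):
            raise ValueError(f"malformed mutation name: {name!r}")
    out.to_csv(path, sep="\t", index_label="mutation", float_format="%.10g")


def read_growth_table(path: str | Path) -> pd.DataFrame:
    """Read a sentinel-encoded growth table back to the internal layout."""
    frame = pd.read_csv(path, sep="\t", index_col="mutation")
    for name in frame.index:
        if not _NAME_RE.match(str(name)):
            raise ValueError(f"malformed mutation name: {name!r}")
    first = frame.iloc[:, 0]
    status = pd.Series(fitness_mod.MEASURED, index=frame.index, dtype=object)
    status[first == fitness_mod.SENTINEL_NULL] = fitness_mod.NULL_DATA
    status[first == fitness_mod.SENTINEL_NO_DATA] = fitness_mod.NO_DATA
    frame[frame.isin(list(_SENTINELS.values()))] = np.nan
    frame["status"] = status
    frame.index.name = "variant"
    return frame


def _config_from_dict(section: dict) -> SimulationConfig:
    section = dict(section)
    if "rgr_distribution" in section and isinstance(section["rgr_distribution"], dict):
        section["rgr_distribution"] = RgrMixture(**section["rgr_distribution"])
    if "timepoints_h" in section:
        section["timepoints_h"] = tuple(float(t) for t in section["timepoints_h"])
    return SimulationConfig(**section)


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> dict:
    """Run simulation -> growth fitting -> allostery -> report.

    ``config`` has a ``simulation`` section (fields of
    :class:`SimulationConfig`) and an optional ``allostery`` section
    (``alpha``, ``gamma``, ``mode``).  Returns the run manifest, which
    is also written as ``manifest.json`` alongside the stage TSVs.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_config = _config_from_dict(cfg.get("simulation", {}))
    allo_cfg = cfg.get("allostery", {})

    truth, counts = simulate_counts(sim_config)
    truth.to_tsv(out / "truth.tsv")
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)

    growth = fitness_mod.estimate_growth_rates(
        counts, expected_variants=truth.variants
    )
    write_growth_table(growth, out / "growth.tsv")

    retained, excluded = fitness_mod.apply_low_growth_filter(growth)
    records, summary = allostery_mod.classify(
        retained,
        alpha=float(allo_cfg.get("alpha", 0.05)),
        gamma=float(allo_cfg.get("gamma", 0.05)),
        mode=str(allo_cfg.get("mode", "sgof")),
    )
    records.to_csv(out / "allostery.tsv", sep="\t", float_format="%.10g")

    status_counts = growth["status"].value_counts().to_dict()
    significant = records[
        records["class"].isin([allostery_mod.ENHANCING, allostery_mod.DISRUPTING])
    ].sort_values("dark_mean_proxy" if "dark_mean_proxy" in records else "delta")

    manifest = {
        "seed": sim_config.seed,
        "config": _jsonable(cfg),
        "library_size": len(truth.variants),
        "status_counts": {k: int(v) for k, v in sorted(status_counts.items())},
        "n_excluded_low_growth": int(len(excluded) - sum(
            v for k, v in status_counts.items() if k != fitness_mod.MEASURED
        )),
        "allostery_summary": summary,
        "input_checksums": {
            name: _sha256(out / name)
            for name in ("truth.tsv", "counts.tsv", "growth.tsv", "allostery.tsv")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    _write_report(out / "report.md", manifest, records, significant)
    return manifest


def _write_report(path: Path, manifest: dict, records: pd.DataFrame, significant: pd.DataFrame) -> None:
    lines = ["# Selection run report", ""]
    lines.append(f"Library size: {manifest['library_size']}")
    for status, n in manifest["status_counts"].items():
        lines.append(f"- {status}: {n}")
    lines.append(
        f"- excluded by low-growth cutoff: {manifest['n_excluded_low_growth']}"
    )
    s = manifest["allostery_summary"]
    lines.append("")
    lines.append(
        f"Allostery ({s['mode']}, threshold p <= {s['threshold']:.4g}): "
        f"{s['n_enhancing']} enhancing, {s['n_disrupting']} disrupting, "
        f"{s['n_not_significant']} not significant of {s['n_tested']} tested."
    )
    if len(significant):
        lines += ["", "| mutation | delta (1/h) | fold | p |", "| --- | --- | --- | --- |"]
        for name, row in significant.iterrows():
            lines.append(
                f"| {name} | {row['delta']:+.4f} | {row['fold']:.3f} | {row['p_value']:.3g} |"
            )
    path.write_text("\n".join(lines) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
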