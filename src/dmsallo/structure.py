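"""Structural annotation and enrichment statistics.

Residues of the enzyme are annotated with solvent accessibility
(rolling-probe surface area, 1.4 A probe), a surface flag (relative
accessibility strictly above 25%), sector and conservation membership
(supplied as input tables from coevolution analysis, not recomputed),
contact between a residue's peptide-bond atoms and any sector atom
(within 1.2x the sum of the atoms' Pauling radii), and the Calpha
distance to the effector-domain insertion site (residue 121 by
default).  Class-versus-annotation overlap is tested with two-sided
Fisher exact contingency tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from scipy import stats

#: Pauling van der Waals radii (Angstrom) by element.
PAULING_RADII: dict[str, float] = {
    "H": 1.2,
    "C": 1.7,
    "N": 1.5,
    "O": 1.4,
    "S": 1.85,
    "P": 1.9,
}

#: Theoretical maximum accessible surface areas (A^2) per residue type
#: (Gly-X-Gly based normalization table of Tien et al. 2013).
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

SURFACE_RSA_CUTOFF = 0.25
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SASA_POINTS = 960
INSERTION_SITE = 121

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def load_structure(path: str | Path, chain: str | None = None) -> struc.AtomArray:
    """Read a PDB file, keeping one model's protein atoms.

    Waters and heteroatoms are stripped before any surface computation,
    and hydrogens are dropped (areas are computed on heavy atoms).
    """
    pdb_file = pdb.PDBFile.read(str(path))
    array = pdb_file.get_structure(model=1)
    mask = struc.filter_amino_acids(array) & ~array.hetero
    mask &= array.element != "H"
    if chain is not None:
        mask &= array.chain_id == chain
    return array[mask]


def compute_sasa(
    structure: struc.AtomArray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
) -> pd.DataFrame:
    """Per-residue solvent-accessible surface area (A^2).

    Rolling-probe (Shrake-Rupley) surface with a deterministic sphere
    sampling of ``n_points`` points per atom.  Returns a DataFrame with
    columns ``res_id``, ``res_name``, ``area``.
    """
    atom_sasa = struc.sasa(
        structure,
        probe_radius=probe_radius,
        point_number=n_points,
        vdw_radii="Single",
    )
    atom_sasa = np.nan_to_num(atom_sasa)
    res_ids, names = [], []
    areas = []
    for res_id in np.unique(structure.res_id):
        m = structure.res_id == res_id
        res_ids.append(int(res_id))
        names.append(str(structure.res_name[m][0]))
        areas.append(float(atom_sasa[m].sum()))
    return pd.DataFrame({"res_id": res_ids, "res_name": names, "area": areas})


def relative_sasa(
    areas: pd.DataFrame,
    max_asa: dict[str, float] | None = None,
    cutoff: float = SURFACE_RSA_CUTOFF,
) -> pd.DataFrame:
    """Relative solvent accessibility and surface flags.

    RSA = area / max_area for the residue type; ``surface`` is strictly
    ``RSA > cutoff`` (a residue at exactly 25% is not surface).
    Unknown residue types get NaN RSA and no surface flag.
    """
    table = dict(MAX_ASA if max_asa is None else max_asa)
    out = areas.copy()
    out["rsa"] = [
        row.area / table[row.res_name] if row.res_name in table else np.nan
        for row in areas.itertuples()
    ]
    out["surface"] = out["rsa"] > cutoff
    return out


def sector_contact(
    structure: struc.AtomArray,
    sector_residues: set[int],
    scale: float = 1.2,
    backbone_atoms: tuple[str, ...] = ("N", "C", "O"),
    radii: dict[str, float] | None = None,
) -> dict[int, bool]:
    """Flag residues whose peptide-bond atoms touch any sector atom.

    Two atoms are in contact when their distance is within
    ``scale * (r1 + r2)`` of the elements' Pauling radii.  The
    peptide-bond atom set is the residue's own backbone N, C and O.
    Residues inside the sector are not flagged (contact is about the
    periphery).
    """
    radii = PAULING_RADII if radii is None else radii
    elem_r = np.array([radii[e] for e in structure.element])
    sector_mask = np.isin(structure.res_id, sorted(sector_residues))
    sector_coord = structure.coord[sector_mask]
    sector_r = elem_r[sector_mask]

    flags: dict[int, bool] = {}
    for res_id in np.unique(structure.res_id):
        rid = int(res_id)
        if rid in sector_residues:
            flags[rid] = False
            continue
        m = (structure.res_id == res_id) & np.isin(
            structure.atom_name, backbone_atoms
        )
        if not m.any() or len(sector_coord) == 0:
            flags[rid] = False
            continue
        d = np.linalg.norm(
            structure.coord[m][:, None, :] - sector_coord[None, :, :], axis=-1
        )
        limit = scale * (elem_r[m][:, None] + sector_r[None, :])
        flags[rid] = bool((d <= limit).any())
    return flags


def distance_to_anchor(
    structure: struc.AtomArray, anchor: int = INSERTION_SITE
) -> pd.Series:
    """Calpha-Calpha distance (A) of every residue to the anchor residue."""
    ca = structure[structure.atom_name == "CA"]
    res_ids = ca.res_id
    if anchor not in res_ids:
        raise ValueError(f"anchor residue {anchor} has no Calpha atom")
    anchor_xyz = ca.coord[res_ids == anchor][0]
    d = np.linalg.norm(ca.coord - anchor_xyz, axis=1)
    out = pd.Series(d, index=pd.Index(res_ids.astype(int), name="res_id"))
    return out[~out.index.duplicated()]


def distance_profile(
    positions_by_class: dict[str, list[int]],
    distances: pd.Series,
    bins: np.ndarray | list[float],
) -> pd.DataFrame:
    """Cumulative fraction of each mutation class within distance bins.

    ``distances`` maps residue -> distance to the insertion site; bins
    are upper edges in Angstrom.  Positions lacking a distance (e.g.
    missing Calpha) are excluded; an empty class yields NaN fractions.
    """
    bins = np.asarray(bins, dtype=float)
    data = {}
    for cls, positions in positions_by_class.items():
        dists = np.array(
            [distances[p] for p in positions if p in distances.index], dtype=float
        )
        if dists.size == 0:
            data[cls] = np.full(bins.shape, np.nan)
        else:
            data[cls] = np.array([(dists <= b).mean() for b in bins])
    return pd.DataFrame(data, index=pd.Index(bins, name="max_distance_A"))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap between a mutation class and a structural annotation."""

    in_class_in_annot: int
    in_class_out_annot: int
    out_class_in_annot: int
    out_class_out_annot: int
    odds_ratio: float
    p_value: float

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [
                [self.in_class_in_annot, self.in_class_out_annot],
                [self.out_class_in_annot, self.out_class_out_annot],
            ]
        )


def enrichment_test(
    class_set: set, annotation_set: set, universe: set
) -> ContingencyTable:
    """Two-sided Fisher exact test of class/annotation overlap.

    The p-value sums all hypergeometric tables (at the observed
    margins) whose probability does not exceed the observed table's.
    The odds ratio uses the Haldane 0.5 correction when any cell is
    zero.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not class_set <= universe or not annotation_set <= universe:
        raise ValueError("class and annotation sets must lie within the universe")
    a = len(class_set & annotation_set)
    b = len(class_set - annotation_set)
    c = len(annotation_set - class_set)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return ContingencyTable(a, b, c, d, float(odds), float(p))


def annotate_residues(
    structure: struc.AtomArray,
    sector_residues: set[int] | None = None,
    conserved_residues: set[int] | None = None,
    anchor: int = INSERTION_SITE,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
    max_asa: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Full per-residue annotation table.

    Columns: ``res_name``, ``area``, ``rsa``, ``surface``, ``sector``,
    ``conserved``, ``sector_contact``, ``dist_anchor_A`` indexed by
    residue number.
    """
    sector_residues = sector_residues or set()
    conserved_residues = conserved_residues or set()
    areas = compute_sasa(structure, probe_radius, n_points)
    table = relative_sasa(areas, max_asa).set_index("res_id")
    table["sector"] = [r in sector_residues for r in table.index]
    table["conserved"] = [r in conserved_residues for r in table.index]
    contact = sector_contact(structure, sector_residues)
    table["sector_contact"] = [
        bool(contact.get(r, False)) and bool(table.loc[r, "surface"])
        for r in table.index
    ]
    dist = distance_to_anchor(structure, anchor)
    table["dist_anchor_A"] = dist.reindex(table.index)
    table.index.name = "res_id"
    return table


def read_annotation_tsv(path: str | Path, flag_column: str = "flag") -> set[int]:
    """Read a residue flag table (columns ``res_id`` and ``flag``)."""
    frame = pd.read_csv(path, sep="\t")
    return set(frame.loc[frame[flag_column].astype(bool), "res_id"].astype(int))


def make_synthetic_chain(
    sequence: str = "ACDEFGHIKLMNPQRSTVWY",
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> struc.AtomArray:
    """Build a synthetic extended peptide backbone for testing.

    An idealized chain (N, CA, C, O, and CB for non-Gly) marching along
    the x axis at 3.8 A per residue.  This is a geometric stand-in used
    by the test-suite and examples, not a real protein structure.
    """
    n_res = len(sequence)
    atoms = []
    offsets = {
        "N": np.array([-0.8, 0.9, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([0.9, -0.9, 0.0]),
        "O": np.array([0.9, -2.1, 0.2]),
        "CB": np.array([-0.5, -0.8, 1.2]),
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    for i, aa in enumerate(sequence):
        res_name = _AA3[aa]
        base = np.array([3.8 * i, 1.2 * (i % 2), 0.0])
        names = ["N", "CA", "C", "O"] + ([] if aa == "G" else ["CB"])
        for name in names:
            xyz = base + offsets[name]
            if rng is not None and jitter > 0:
                xyz = xyz + rng.normal(0, jitter, 3)
            atoms.append((i + 1, res_name, name, elements[name], xyz))
    array = struc.AtomArray(len(atoms))
    array.coord = np.array([a[4] for a in atoms])
    array.chain_id[:] = "A"
    array.res_id = np.array([a[0] for a in atoms])
    array.res_name = np.array([a[1] for a in atoms])
    array.atom_name = np.array([a[2] for a in atoms])
    array.element = np.array([a[3] for a in atoms])
    array.hetero[:] = False
    return array
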