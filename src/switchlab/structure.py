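"""Structures, SASA, cross-link distance restraints and groove geometry.

BS3 (bis(sulfosuccinimidyl)suberate) cross-links lysine primary amines; on
proteins of known structure the Cα–Cα distance of cross-linked lysines is
below 28 Å for most links and up to 33 Å in flexible regions, which turns
an identified lysine–lysine cross-link into a distance restraint on a
structural model.  Cross-links quantified per SDS-PAGE band separate
intra- from inter-molecular contacts: a link absent from the monomer band
but present in covalent dimer/oligomer bands must span two protomers.

Solvent-accessible surface area is computed with the Shrake–Rupley
algorithm (quasi-uniform points on each atom's probe-expanded sphere,
counting those not occluded by any neighbour), used here to normalize PRE
broadening by how exposed each probe residue is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "VDW_RADII",
    "StructureModel",
    "RestraintLimits",
    "RestraintResult",
    "CrossLinkRecord",
    "GrooveGeometry",
    "parse_structure",
    "write_pdb",
    "sasa",
    "ca_distance",
    "classify_restraint",
    "check_restraints",
    "classify_xlinks",
    "reference_crosslink_table",
    "interface_residues",
    "peptide_fits_groove",
]

#: van der Waals radii (Å) for the elements that occur in protein models
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}


@dataclass
class StructureModel:
    """Flat atom table of a (possibly multi-chain) structure.

    Author chain ids and 1-based residue numbering are preserved.  CA-only
    models (e.g. ideal-helix fixtures or threading backbones) are
    first-class inputs.
    """

    chain: np.ndarray  # str
    resnum: np.ndarray  # int
    resname: np.ndarray  # str
    atom_name: np.ndarray  # str
    element: np.ndarray  # str
    coords: np.ndarray  # (n, 3) float, Å
    radii_table: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))

    def __post_init__(self):
        n = len(self.coords)
        self.chain = np.asarray(self.chain, dtype=object)
        self.resnum = np.asarray(self.resnum, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self):
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        seen = dict.fromkeys(self.chain.tolist())
        return list(seen)

    @property
    def is_ca_only(self) -> bool:
        return bool(np.all(self.atom_name == "CA"))

    def radii(self) -> np.ndarray:
        out = np.empty(len(self), dtype=float)
        for i, el in enumerate(self.element):
            key = str(el).upper()
            if key not in self.radii_table:
                raise ValueError(f"no van der Waals radius for element {el!r}")
            out[i] = self.radii_table[key]
        return out

    def ca_coord(self, chain: str, resnum: int) -> np.ndarray:
        mask = (self.chain == chain) & (self.resnum == resnum) & (self.atom_name == "CA")
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"no CA atom for residue {chain}/{resnum}")
        return self.coords[idx[0]]

    def has_residue(self, chain: str, resnum: int) -> bool:
        mask = (self.chain == chain) & (self.resnum == resnum) & (self.atom_name == "CA")
        return bool(mask.any())


def parse_structure(source) -> StructureModel:
    """Parse a PDB file (path or text) into a :class:`StructureModel`.

    Only the first model of multi-model files is used.  Alternate
    locations collapse to a single conformer per atom: highest occupancy
    wins, ties break by altloc letter order.  Raises on files with no ATOM
    records and on unparsable input.
    """
    import gemmi

    text = str(source)
    if "\n" in text or text.lstrip().startswith(("ATOM", "HETATM", "HEADER", "MODEL")):
        st = gemmi.read_pdb_string(text)
    else:
        st = gemmi.read_structure(text, format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError("structure contains no models")
    model = st[0]

    rows: dict[tuple, tuple] = {}
    order: list[tuple] = []
    for ch in model:
        for res in ch:
            for atom in res:
                key = (ch.name, res.seqid.num, atom.name)
                cand = (
                    atom.occ,
                    # invert altloc so that '' and 'A' beat 'B' on occupancy tie
                    -ord(atom.altloc or "A"),
                    res.name,
                    atom.element.name,
                    (atom.pos.x, atom.pos.y, atom.pos.z),
                )
                if key not in rows:
                    order.append(key)
                    rows[key] = cand
                elif cand[:2] > rows[key][:2]:
                    rows[key] = cand
    if not rows:
        raise ValueError("no ATOM/HETATM records found")

    chain, resnum, resname, atom_name, element, coords = [], [], [], [], [], []
    for key in order:
        ch_name, num, at_name = key
        _, _, res_name, el, xyz = rows[key]
        chain.append(ch_name)
        resnum.append(num)
        resname.append(res_name)
        atom_name.append(at_name)
        element.append(el if el else at_name[0])
        coords.append(xyz)
    return StructureModel(chain, resnum, resname, atom_name, element, np.array(coords))


def write_pdb(structure: StructureModel, path) -> None:
    """Write a minimal PDB file (ATOM records only, one conformer)."""
    lines = []
    for i in range(len(structure)):
        x, y, z = structure.coords[i]
        el = str(structure.element[i]).upper()
        name = str(structure.atom_name[i])
        # PDB columns: atom names of <4 chars start in column 14
        name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
        lines.append(
            f"ATOM  {i + 1:5d} {name_f} {str(structure.resname[i])[:3]:>3s} "
            f"{str(structure.chain[i])[:1]}{int(structure.resnum[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
        )
    lines.append("END")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- SASA


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-section spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    structure: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    points: np.ndarray | None = None,
):
    """Shrake–Rupley solvent-accessible surface area.

    For each atom, ``n_points`` quasi-uniform points are placed on its
    probe-expanded sphere; the exposed fraction (points inside no
    neighbour's expanded sphere) times 4π(r+probe)² is its SASA.  Returns
    ``(per_atom, per_residue)`` where per_atom is an array in Å² and
    per_residue a DataFrame (chain, resnum, resname, sasa_A2) summing all
    atoms of each residue.  ``points`` overrides the point set (used by
    the Monte-Carlo cross-check).
    """
    radii = structure.radii() + probe
    coords = structure.coords
    n = len(structure)
    if points is None:
        points = _sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    per_atom = np.zeros(n)
    for i in range(n):
        ri = radii[i]
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        surf = coords[i] + ri * points
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((surf[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * math.pi * ri * ri

    df = pd.DataFrame(
        {
            "chain": structure.chain,
            "resnum": structure.resnum,
            "resname": structure.resname,
            "sasa_A2": per_atom,
        }
    )
    per_residue = (
        df.groupby(["chain", "resnum", "resname"], sort=False)["sasa_A2"].sum().reset_index()
    )
    return per_atom, per_residue


# ---------------------------------------------------------------- restraints


@dataclass(frozen=True)
class RestraintLimits:
    """BS3 Cα–Cα reach: satisfied below 28 Å, marginal up to 33 Å."""

    satisfied_max: float = 28.0
    marginal_max: float = 33.0

    def __post_init__(self):
        if not 0 < self.satisfied_max < self.marginal_max:
            raise ValueError("require 0 < satisfied_max < marginal_max")


@dataclass(frozen=True)
class RestraintResult:
    pair: tuple[int, int]
    distance: float | None
    restraint_class: str  # satisfied | marginal | violated | unmappable
    assignment: str | None  # e.g. 'A-A' (intra) or 'A-B' (inter)


def ca_distance(structure: StructureModel, a: tuple[str, int], b: tuple[str, int]) -> float:
    """Euclidean Cα–Cα distance (Å) between two (chain, resnum) sites."""
    return float(np.linalg.norm(structure.ca_coord(*a) - structure.ca_coord(*b)))


def classify_restraint(distance: float, limits: RestraintLimits = RestraintLimits()) -> str:
    """Classify a Cα–Cα distance against the cross-linker's reach.

    < satisfied_max → 'satisfied'; in [satisfied_max, marginal_max]
    (closed interval) → 'marginal', attributable to local flexibility;
    beyond → 'violated'.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance < limits.satisfied_max:
        return "satisfied"
    if distance <= limits.marginal_max:
        return "marginal"
    return "violated"


def check_restraints(
    structure: StructureModel,
    pairs: list[tuple[int, int]],
    limits: RestraintLimits = RestraintLimits(),
    inter_chain: bool = False,
) -> list[RestraintResult]:
    """Evaluate lysine-pair cross-link restraints on a structural model.

    For each residue-number pair the minimum Cα–Cα distance over allowed
    chain assignments is classified.  With ``inter_chain`` False only
    same-chain assignments are considered; True additionally allows the
    two residues to sit on different chains (an oligomer model).  Pairs
    touching a residue absent from every chain are reported as
    'unmappable' rather than dropped.
    """
    chains = structure.chains
    if inter_chain and len(chains) < 2:
        raise ValueError("inter-chain evaluation requires >= 2 chains")
    results = []
    for res_a, res_b in pairs:
        best: tuple[float, str] | None = None
        for ca in chains:
            if not structure.has_residue(ca, res_a):
                continue
            for cb in chains:
                if ca != cb and not inter_chain:
                    continue
                if not structure.has_residue(cb, res_b):
                    continue
                d = ca_distance(structure, (ca, res_a), (cb, res_b))
                if best is None or d < best[0]:
                    best = (d, f"{ca}-{cb}")
        if best is None:
            results.append(RestraintResult((res_a, res_b), None, "unmappable", None))
        else:
            d, assign = best
            results.append(RestraintResult((res_a, res_b), d, classify_restraint(d, limits), assign))
    return results


# ---------------------------------------------------------------- cross-links


@dataclass(frozen=True)
class CrossLinkRecord:
    """One quantified lysine–lysine cross-link.

    ``bands`` maps SDS-PAGE band id (1 = monomer, higher ids = dimer and
    larger covalent oligomers) to (mean abundance %, sd %).
    """

    lys_a: int
    lys_b: int
    bands: tuple[tuple[int, tuple[float, float]], ...]
    condition: str = "with_peptides"

    def __init__(self, lys_a, lys_b, bands, condition="with_peptides"):
        object.__setattr__(self, "lys_a", int(lys_a))
        object.__setattr__(self, "lys_b", int(lys_b))
        if isinstance(bands, dict):
            bands = tuple(sorted(bands.items()))
        object.__setattr__(self, "bands", tuple(bands))
        object.__setattr__(self, "condition", condition)
        for _, (mean, sd) in self.bands:
            if not (0.0 <= mean <= 100.0) or sd < 0:
                raise ValueError("band abundances must be percentages in [0, 100]")

    @property
    def pair(self) -> tuple[int, int]:
        return tuple(sorted((self.lys_a, self.lys_b)))

    def band_mean(self, band: int) -> float:
        return dict(self.bands)[band][0]


def classify_xlinks(
    table: list[CrossLinkRecord],
    abundance_min: float = 1.0,
    band: int | None = None,
):
    """Split quantified cross-links into inter-molecular and abundant sets.

    Inter-molecular: zero mean abundance in the monomer band (band 1) and
    non-zero in at least one oligomer band — the link can only form across
    protomers.  Abundant: inter-molecular links whose mean abundance in
    ``band`` (default: the highest-order band present) reaches
    ``abundance_min`` percent.  Symmetric duplicates (a•b vs b•a) collapse;
    row order is irrelevant.  Returns (inter_set, abundant_set) of sorted
    residue-number pairs.
    """
    if not table:
        return set(), set()
    inter: dict[tuple[int, int], float] = {}
    for rec in table:
        bands = dict(rec.bands)
        if 1 not in bands:
            raise ValueError(f"cross-link {rec.pair}: no monomer band (band 1)")
        chosen = band if band is not None else max(bands)
        if chosen not in bands:
            raise ValueError(f"cross-link {rec.pair}: band {chosen} absent")
        oligomer_means = [m for b, (m, _) in bands.items() if b != 1]
        if bands[1][0] == 0.0 and any(m > 0 for m in oligomer_means):
            key = rec.pair
            inter[key] = max(inter.get(key, 0.0), bands[chosen][0])
    inter_set = set(inter)
    abundant = {p for p, m in inter.items() if m >= abundance_min}
    return inter_set, abundant


#: Published BS3 cross-link quantification of the hIRE1α core lumenal
#: domain: six lysine pairs, mean/sd % abundance per SDS-PAGE band
#: (band 1 = monomer, band 5 = largest covalent oligomer), with and
#: without bound peptide.
_XLINK_ROWS = {
    "with_peptides": [
        (53, 347, [(4.1, 0.4), (3.2, 1.9), (3.7, 1.0), (4.9, 1.0), (0.0, 0.0)]),
        (53, 349, [(1.4, 0.2), (1.0, 0.4), (1.4, 0.3), (1.5, 0.8), (0.0, 0.0)]),
        (53, 351, [(4.0, 1.1), (2.4, 2.4), (3.2, 0.8), (3.4, 0.3), (0.0, 0.0)]),
        (121, 121, [(3.7, 0.9), (2.9, 1.4), (1.5, 0.0), (0.8, 0.3), (0.0, 0.0)]),
        (351, 265, [(1.2, 0.1), (0.8, 0.6), (1.0, 0.5), (0.4, 0.3), (0.0, 0.0)]),
        (53, 265, [(0.5, 0.1), (0.4, 0.1), (0.2, 0.0), (0.2, 0.0), (0.0, 0.0)]),
    ],
    "without_peptides": [
        (53, 347, [(3.3, 0.3), (4.3, 1.9), (4.4, 2.1), (3.4, 2.5), (0.0, 0.0)]),
        (53, 349, [(1.6, 0.5), (1.4, 0.5), (1.6, 0.9), (1.6, 0.5), (0.0, 0.0)]),
        (53, 351, [(2.3, 0.4), (3.2, 1.0), (2.6, 1.7), (2.1, 2.3), (0.0, 0.0)]),
        (121, 121, [(2.6, 0.2), (2.1, 0.8), (2.1, 1.5), (0.3, 0.1), (0.0, 0.0)]),
        (351, 265, [(0.6, 0.3), (0.9, 0.2), (0.9, 0.4), (0.4, 0.3), (0.0, 0.0)]),
        (53, 265, [(0.3, 0.1), (0.4, 0.3), (0.3, 0.1), (0.1, 0.1), (0.0, 0.0)]),
    ],
}


def reference_crosslink_table(condition: str = "with_peptides") -> list[CrossLinkRecord]:
    """The published cross-link quantification table for the IRE1α cLD.

    Band ids run 5..1 with band 1 the monomer, matching the SDS-PAGE
    layout of the source quantification.
    """
    if condition not in _XLINK_ROWS:
        raise ValueError(f"condition must be one of {sorted(_XLINK_ROWS)}")
    out = []
    for lys_a, lys_b, vals in _XLINK_ROWS[condition]:
        bands = {band: ms for band, ms in zip((5, 4, 3, 2, 1), vals)}
        out.append(CrossLinkRecord(lys_a, lys_b, bands, condition))
    return out


def crosslink_table_to_csv(table: list[CrossLinkRecord], path) -> None:
    rows = []
    for rec in table:
        for band, (mean, sd) in rec.bands:
            rows.append(
                {
                    "lys_a": rec.lys_a,
                    "lys_b": rec.lys_b,
                    "band": band,
                    "condition": rec.condition,
                    "mean_pct": mean,
                    "sd_pct": sd,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def crosslink_table_from_csv(path) -> list[CrossLinkRecord]:
    df = pd.read_csv(path)
    out = []
    for (a, b, cond), sub in df.groupby(["lys_a", "lys_b", "condition"], sort=False):
        bands = {
            int(r.band): (float(r.mean_pct), float(r.sd_pct)) for r in sub.itertuples()
        }
        out.append(CrossLinkRecord(int(a), int(b), bands, str(cond)))
    return out


# ---------------------------------------------------------------- interface


def interface_residues(
    structure: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff: float | None = None,
):
    """Residues of each chain with any heavy atom within ``cutoff`` of the
    partner chain.

    Default cutoff is 5 Å for all-atom models; CA-only models use a
    widened 8 Å default since side chains are absent.  Returns
    ``{chain_a: set of resnums, chain_b: set}``.
    """
    for ch in (chain_a, chain_b):
        if ch not in structure.chains:
            raise ValueError(f"chain {ch!r} not in structure")
    if chain_a == chain_b:
        raise ValueError("need two distinct chains")
    if cutoff is None:
        cutoff = 8.0 if structure.is_ca_only else 5.0
    heavy = structure.element != "H"
    mask_a = (structure.chain == chain_a) & heavy
    mask_b = (structure.chain == chain_b) & heavy
    xa, xb = structure.coords[mask_a], structure.coords[mask_b]
    ra, rb = structure.resnum[mask_a], structure.resnum[mask_b]
    if xa.size == 0 or xb.size == 0:
        raise ValueError("one of the chains has no heavy atoms")
    pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), cutoff)
    res_a, res_b = set(), set()
    for i, js in enumerate(pairs):
        if js:
            res_a.add(int(ra[i]))
            res_b.update(int(rb[j]) for j in js)
    return {chain_a: res_a, chain_b: res_b}


# ---------------------------------------------------------------- groove


@dataclass(frozen=True)
class GrooveGeometry:
    """Extended-chain geometry of the MHC-like peptide-binding groove."""

    per_bond_length: float = 3.4  # Å per peptide bond, extended backbone
    groove_length: float = 39.0  # Å

    def __post_init__(self):
        if self.per_bond_length <= 0 or self.groove_length <= 0:
            raise ValueError("geometry lengths must be positive")


def peptide_fits_groove(n_res: int, geom: GrooveGeometry = GrooveGeometry()):
    """Does an n-residue extended peptide fit the binding groove?

    An n-mer has n-1 peptide bonds, so its extended length is
    (n-1) * per_bond_length; it fits when that is <= groove_length.
    Returns (length_A, fits).
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues for a peptide bond")
    length = (n_res - 1) * geom.per_bond_length
    return length, length <= geom.groove_length
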