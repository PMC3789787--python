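"""Per-residue structural features of substituted CBS positions.

Five physical characteristics are computed for each mutated residue from
a user-supplied structure of the (truncated) enzyme: minimum heavy-atom
distance to the heme group, minimum heavy-atom distance to the PLP
cofactor, relative solvent accessibility, membership in regular secondary
structure (helix or strand), and mean crystallographic B-factor.

Structures are read from PDB files via gemmi.  Hydrogens are ignored,
alternate locations are resolved to the highest-occupancy conformer, and
insertion codes are rejected.  File numbering is mapped to NP_000062
numbering by an explicit integer offset (or per-residue map) supplied by
the caller — deterministic and auditable, no alignment involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import gemmi
import numpy as np

from .data_model import VariantPanel

__all__ = [
    "StructureModel",
    "StructureFeatureSet",
    "FeatureTable",
    "load_structure",
    "min_distance",
    "solvent_accessibility",
    "residue_sasa",
    "secondary_structure",
    "bfactor",
    "feature_table",
    "VDW_RADII",
    "MAX_ACC",
]

#: van der Waals radii by element symbol (Angstrom); heavy atoms only
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "FE": 2.00, "ZN": 1.39, "MG": 1.73,
}

#: theoretical tripeptide maximum accessible areas (A^2) per residue type
#: (Tien et al. scale) used to normalize absolute SASA to relative
MAX_ACC: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: HETATM residue names recognized as each cofactor group
LIGAND_NAMES: dict[str, frozenset[str]] = {
    "heme": frozenset({"HEM"}),
    "plp": frozenset({"PLP", "LLP"}),
}

PROBE_RADIUS = 1.4   # water probe, Angstrom
N_SPHERE_POINTS = 960


class MissingEntityError(KeyError):
    pass


@dataclass(frozen=True)
class _Residue:
    chain: str
    seqid: int
    name: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray          # (n_atoms, 3)
    bfactors: np.ndarray        # (n_atoms,)


@dataclass
class StructureModel:
    """Heavy-atom model of a structure: protein residues plus cofactors.

    ``offset`` maps file numbering to NP_000062 numbering:
    NP position = file seqid + offset.  A per-residue mapping can be given
    instead for structures with non-uniform numbering.
    """

    residues: list[_Residue]
    ligands: dict[str, np.ndarray]              # ligand kind -> (n, 3) coords
    ligand_chains: dict[str, list[str]]         # parallel chain labels per atom
    helix_spans: list[tuple[str, int, int]]     # (chain, first, last) file numbering
    sheet_spans: list[tuple[str, int, int]]
    offset: int | Mapping[int, int] = 0

    def np_position(self, seqid: int) -> int:
        if isinstance(self.offset, int):
            return seqid + self.offset
        return self.offset[seqid]

    def residues_at(self, position: int) -> list[_Residue]:
        """All copies (chains) of the residue at an NP_000062 position."""
        out = []
        for res in self.residues:
            try:
                if self.np_position(res.seqid) == position:
                    out.append(res)
            except KeyError:
                continue
        return out

    def positions(self) -> set[int]:
        pos = set()
        for res in self.residues:
            try:
                pos.add(self.np_position(res.seqid))
            except KeyError:
                pass
        return pos

    def all_protein_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked heavy-atom coordinates and their vdW radii (protein +
        ligands), used as the occluder set for SASA."""
        coords = [r.coords for r in self.residues]
        radii = [
            np.array([_radius(e) for e in r.elements]) for r in self.residues
        ]
        for kind, lig in self.ligands.items():
            if len(lig):
                coords.append(lig)
                radii.append(np.full(len(lig), VDW_RADII["C"]))
        return np.vstack(coords), np.concatenate(radii)


def _radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise ValueError(f"no van der Waals radius configured for element {element!r}")


def load_structure(
    path: str | Path,
    offset: int | Mapping[int, int] = 0,
    ligand_names: Mapping[str, frozenset[str]] | None = None,
) -> StructureModel:
    """Read a PDB file into a heavy-atom :class:`StructureModel`."""
    ligand_names = dict(LIGAND_NAMES if ligand_names is None else ligand_names)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]

    residues: list[_Residue] = []
    ligands: dict[str, list[np.ndarray]] = {k: [] for k in ligand_names}
    ligand_chains: dict[str, list[str]] = {k: [] for k in ligand_names}
    name_to_kind = {n: k for k, names in ligand_names.items() for n in names}

    for chain in model:
        for res in chain:
            if res.seqid.icode not in (" ", "", "\x00"):
                raise ValueError(
                    f"insertion codes are not supported ({chain.name} {res.seqid})")
            kind = name_to_kind.get(res.name)
            heavy = [a for a in res if a.element.name.upper() != "H"]
            if not heavy:
                continue
            # resolve altlocs to the highest-occupancy conformer per atom name
            by_name: dict[str, gemmi.Atom] = {}
            for a in heavy:
                prev = by_name.get(a.name)
                if prev is None or a.occ > prev.occ:
                    by_name[a.name] = a
            atoms = list(by_name.values())
            if kind is not None:
                for a in atoms:
                    ligands[kind].append(np.array([a.pos.x, a.pos.y, a.pos.z]))
                    ligand_chains[kind].append(chain.name)
            elif res.name in MAX_ACC:
                residues.append(_Residue(
                    chain=chain.name,
                    seqid=res.seqid.num,
                    name=res.name,
                    atom_names=tuple(a.name for a in atoms),
                    elements=tuple(a.element.name for a in atoms),
                    coords=np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms]),
                    bfactors=np.array([a.b_iso for a in atoms]),
                ))

    helix_spans = [
        (h.start.chain_name, h.start.res_id.seqid.num, h.end.res_id.seqid.num)
        for h in st.helices
    ]
    sheet_spans = []
    for sheet in st.sheets:
        for strand in sheet.strands:
            sheet_spans.append((strand.start.chain_name,
                                strand.start.res_id.seqid.num,
                                strand.end.res_id.seqid.num))

    return StructureModel(
        residues=residues,
        ligands={k: (np.array(v) if v else np.empty((0, 3))) for k, v in ligands.items()},
        ligand_chains=ligand_chains,
        helix_spans=helix_spans,
        sheet_spans=sheet_spans,
        offset=offset,
    )


# ---------------------------------------------------------------------------
# the five features

def min_distance(
    model: StructureModel,
    position: int,
    ligand: Literal["heme", "plp"],
    scope: Literal["same_chain", "all_chains"] = "all_chains",
) -> float:
    """Minimum heavy-atom distance (A) from a residue to a cofactor group.

    With ``scope="all_chains"`` (default — the enzyme is oligomeric and a
    cofactor of a neighboring subunit may be nearest) every copy of the
    ligand is considered; ``same_chain`` restricts to the residue's chain.
    When the position occurs in several chains the smallest distance over
    copies is returned.
    """
    copies = model.residues_at(position)
    if not copies:
        raise MissingEntityError(f"residue {position} not present in the model")
    lig_coords = model.ligands.get(ligand)
    lig_chains = model.ligand_chains.get(ligand, [])
    if lig_coords is None or not len(lig_coords):
        raise MissingEntityError(f"no {ligand} group in the model")

    best = math.inf
    for res in copies:
        coords = lig_coords
        if scope == "same_chain":
            mask = np.array([c == res.chain for c in lig_chains])
            coords = lig_coords[mask]
            if not len(coords):
                continue
        d = np.linalg.norm(res.coords[:, None, :] - coords[None, :, :], axis=-1)
        best = min(best, float(d.min()))
    if not math.isfinite(best):
        raise MissingEntityError(
            f"no {ligand} group in the chain(s) of residue {position}")
    return best


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform unit-sphere point set (deterministic Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _local_frame(center: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Rotation matrix tied to the atom's neighborhood geometry.

    Orienting each atom's sample lattice in a frame built from its two
    nearest (non-collinear) neighbors makes the discretized area
    equivariant under rigid-body motion of the whole model, so SASA is
    invariant to numerical precision for generic geometries.
    """
    if not len(others):
        return np.eye(3)
    d = np.linalg.norm(others - center, axis=1)
    order = np.argsort(d, kind="stable")
    u = others[order[0]] - center
    u = u / np.linalg.norm(u)
    v = None
    for k in order[1:]:
        w = others[k] - center
        w = w - np.dot(w, u) * u
        norm = np.linalg.norm(w)
        if norm > 1e-6 * d[k]:
            v = w / norm
            break
    if v is None:
        # collinear neighborhood: fall back to an arbitrary perpendicular
        v = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(v) < 1e-6:
            v = np.cross(u, [0.0, 1.0, 0.0])
        v = v / np.linalg.norm(v)
    return np.column_stack([v, np.cross(u, v), u])


def _atom_sasa(coords: np.ndarray, radii: np.ndarray, targets: np.ndarray,
               probe: float, n_points: int) -> np.ndarray:
    """Rolling-probe accessible area of the ``targets`` atoms (indices into
    ``coords``): probe-expanded sphere sampling with neighbor occlusion."""
    pts = _sphere_points(n_points)
    out = np.empty(len(targets))
    expanded = radii + probe
    for j, idx in enumerate(targets):
        r = expanded[idx]
        d = np.linalg.norm(coords[idx] - coords, axis=1)
        neigh = np.nonzero((d < r + expanded) & (np.arange(len(coords)) != idx))[0]
        frame = _local_frame(coords[idx], coords[neigh])
        surface = coords[idx] + r * (pts @ frame.T)
        accessible = np.ones(n_points, dtype=bool)
        for k in neigh:
            accessible &= (np.linalg.norm(surface - coords[k], axis=1)
                           >= expanded[k])
            if not accessible.any():
                break
        out[j] = accessible.mean() * 4.0 * math.pi * r * r
    return out


def residue_sasa(model: StructureModel, position: int,
                 probe: float = PROBE_RADIUS,
                 n_points: int = N_SPHERE_POINTS) -> float:
    """Absolute solvent-accessible surface area (A^2) of a residue, in the
    context of the whole model; averaged over chain copies."""
    copies = model.residues_at(position)
    if not copies:
        raise MissingEntityError(f"residue {position} not present in the model")
    coords, radii = model.all_protein_coords()
    areas = []
    cursor = 0
    index_of: dict[int, int] = {id(r): 0 for r in model.residues}
    for r in model.residues:
        index_of[id(r)] = cursor
        cursor += len(r.coords)
    for res in copies:
        start = index_of[id(res)]
        targets = np.arange(start, start + len(res.coords))
        areas.append(float(_atom_sasa(coords, radii, targets, probe, n_points).sum()))
    return float(np.mean(areas))


def solvent_accessibility(model: StructureModel, position: int,
                          probe: float = PROBE_RADIUS,
                          n_points: int = N_SPHERE_POINTS) -> float:
    """Relative solvent accessibility in [0, 1]: absolute SASA divided by
    the residue type's tripeptide reference maximum."""
    copies = model.residues_at(position)
    if not copies:
        raise MissingEntityError(f"residue {position} not present in the model")
    area = residue_sasa(model, position, probe=probe, n_points=n_points)
    ref = MAX_ACC[copies[0].name]
    return float(min(1.0, max(0.0, area / ref)))


def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _backbone(res: _Residue) -> dict[str, np.ndarray] | None:
    out = {}
    for name in ("N", "CA", "C"):
        if name not in res.atom_names:
            return None
        out[name] = res.coords[res.atom_names.index(name)]
    return out


def _phi_psi_assignment(model: StructureModel, chain: str) -> dict[int, str]:
    """Fallback secondary-structure assignment from backbone dihedrals.

    Helix: phi in [-100, -30] and psi in [-80, -5];
    strand: phi in [-180, -80] and psi in [80, 180] or [-180, -170];
    either requires a run of >= 3 consecutive residues.
    """
    chain_res = sorted((r for r in model.residues if r.chain == chain),
                       key=lambda r: r.seqid)
    raw: dict[int, str] = {}
    for prev, cur, nxt in zip(chain_res, chain_res[1:], chain_res[2:]):
        if cur.seqid - prev.seqid != 1 or nxt.seqid - cur.seqid != 1:
            continue
        bb_p, bb_c, bb_n = _backbone(prev), _backbone(cur), _backbone(nxt)
        if bb_p is None or bb_c is None or bb_n is None:
            continue
        phi = _dihedral(bb_p["C"], bb_c["N"], bb_c["CA"], bb_c["C"])
        psi = _dihedral(bb_c["N"], bb_c["CA"], bb_c["C"], bb_n["N"])
        if -100 <= phi <= -30 and -80 <= psi <= -5:
            raw[cur.seqid] = "H"
        elif -180 <= phi <= -80 and (80 <= psi <= 180 or -180 <= psi <= -170):
            raw[cur.seqid] = "E"
    # keep only runs of >= 3
    assigned: dict[int, str] = {}
    seqids = sorted(raw)
    run: list[int] = []
    def flush(run: list[int]) -> None:
        if len(run) >= 3:
            for s in run:
                assigned[s] = raw[s]
    for s in seqids:
        if run and (s - run[-1] != 1 or raw[s] != raw[run[-1]]):
            flush(run)
            run = []
        run.append(s)
    flush(run)
    return assigned


def secondary_structure(model: StructureModel, position: int) -> bool | None:
    """True iff the residue lies in regular secondary structure.

    HELIX/SHEET records of the file are authoritative when present; with
    no records, assignment falls back to backbone-dihedral windows.
    Returns None when neither source is available.
    """
    copies = model.residues_at(position)
    if not copies:
        raise MissingEntityError(f"residue {position} not present in the model")
    if model.helix_spans or model.sheet_spans:
        for res in copies:
            for chain, lo, hi in model.helix_spans + model.sheet_spans:
                if chain == res.chain and lo <= res.seqid <= hi:
                    return True
        return False
    saw_backbone = False
    for res in copies:
        if _backbone(res) is None:
            continue
        saw_backbone = True
        if _phi_psi_assignment(model, res.chain).get(res.seqid):
            return True
    return False if saw_backbone else None


def bfactor(model: StructureModel, position: int) -> float | None:
    """Unweighted mean atomic B-factor of the residue (over chain copies)."""
    copies = model.residues_at(position)
    if not copies:
        raise MissingEntityError(f"residue {position} not present in the model")
    values = np.concatenate([r.bfactors for r in copies])
    if not len(values):
        return None
    return float(values.mean())


# ---------------------------------------------------------------------------
# feature table over a variant panel

@dataclass(frozen=True)
class StructureFeatureSet:
    """The five physical characteristics of one substituted residue."""

    position: int                    # NP_000062 numbering
    dist_heme: float | None
    dist_plp: float | None
    rsa: float | None
    in_regular_ss: bool | None
    mean_bfactor: float | None

    @property
    def mapped(self) -> bool:
        return self.dist_heme is not None or self.rsa is not None \
            or self.mean_bfactor is not None


@dataclass(frozen=True)
class FeatureTable:
    rows: tuple[StructureFeatureSet, ...]
    n_mapped: int
    n_unmapped_substitutions: int

    def as_dict(self) -> dict[int, StructureFeatureSet]:
        return {r.position: r for r in self.rows}


def feature_table(model: StructureModel, panel: VariantPanel,
                  scope: Literal["same_chain", "all_chains"] = "all_chains",
                  ) -> FeatureTable:
    """Compute the five features for every distinct mutated residue.

    Residues absent from the model are reported with all features absent.
    Bookkeeping counts the mapped residues and the substitutions falling
    outside the model.
    """
    positions = sorted({rec.substitution.position for rec in panel})
    modeled = model.positions()
    rows: list[StructureFeatureSet] = []
    for pos in positions:
        if pos not in modeled:
            rows.append(StructureFeatureSet(pos, None, None, None, None, None))
            continue
        rows.append(StructureFeatureSet(
            position=pos,
            dist_heme=min_distance(model, pos, "heme", scope) if len(model.ligands.get("heme", ())) else None,
            dist_plp=min_distance(model, pos, "plp", scope) if len(model.ligands.get("plp", ())) else None,
            rsa=solvent_accessibility(model, pos),
            in_regular_ss=secondary_structure(model, pos),
            mean_bfactor=bfactor(model, pos),
        ))
    n_mapped = sum(1 for r in rows if r.position in modeled)
    n_unmapped = sum(
        1 for rec in panel if rec.substitution.position not in modeled)
    return FeatureTable(rows=tuple(rows), n_mapped=n_mapped,
                        n_unmapped_substitutions=n_unmapped)
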