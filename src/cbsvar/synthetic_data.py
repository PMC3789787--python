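"""Generators for synthetic assay inputs.

No raw microplate curves or structure files are distributed with the
variant panel, so every pipeline stage is exercised on simulated inputs
that reproduce the statistical structure the analysis assumes:

* growth curves — lagged logistic trajectories read every 30 min for
  ~84 h from a starting OD595 of 0.01, with additive plate-reader noise
  and optional per-plate effects;
* variant panels — alleles drawn from the three phenotype categories
  with dose-dependent true relative rates, replicate curves, and a truth
  ledger for parameter-recovery scoring;
* structures — an ideal alpha-helical backbone with planted cofactor
  groups, written as a PDB file that re-reads losslessly.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .data_model import AssayCondition, Category
from .growth_kinetics import GrowthCurve

__all__ = [
    "CurveSimConfig",
    "PanelSimConfig",
    "SimulatedPanel",
    "simulate_curve",
    "simulate_panel",
    "simulate_structure",
    "helix_coordinates",
    "write_dihedral_backbone_pdb",
    "DEFAULT_RATE_EFFECTS",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class CurveSimConfig:
    """Study conditions of the microplate assay.

    Reads every 30 min for 84 h from OD595 0.01; additive Gaussian noise
    of 0.005 OD reflects plate-reader repeatability at low density.
    """

    start_od: float = 0.01
    carrying_capacity: float = 1.0
    lag: float = 4.0                 # h
    read_interval: float = 0.5       # h
    duration: float = 84.0           # h
    noise_sd: float = 0.005          # OD595, additive
    plate_gain: float = 1.0          # multiplicative reader gain per plate

    def __post_init__(self) -> None:
        for name in ("start_od", "carrying_capacity", "read_interval",
                     "duration", "plate_gain"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.duration < 10 * self.read_interval:
            raise ValueError("duration must cover >= 10 reads")


def logistic_od(t: np.ndarray, cfg: CurveSimConfig, rate: float) -> np.ndarray:
    """Noise-free lagged logistic trajectory.

    ``rate`` is the exponential-phase slope in log10 OD per hour; the
    logistic solution reduces to ``start_od * 10**(rate*(t-lag))`` far
    below carrying capacity.
    """
    k = cfg.carrying_capacity
    n0 = cfg.start_od
    rho = rate * LN10
    tt = np.maximum(np.asarray(t, dtype=float) - cfg.lag, 0.0)
    if rate == 0:
        return np.full_like(tt, n0)
    if math.isinf(k):
        return n0 * np.exp(rho * tt)
    return k / (1.0 + (k - n0) / n0 * np.exp(-rho * tt))


def logistic_log_slope(od: float, cfg: CurveSimConfig, rate: float) -> float:
    """Closed-form d(log10 OD)/dt of the logistic model at density ``od``."""
    k = cfg.carrying_capacity
    if math.isinf(k):
        return rate
    return rate * (1.0 - od / k)


def simulate_curve(cfg: CurveSimConfig, true_rate: float,
                   seed: int | np.random.Generator | None = 0,
                   *, well_id: str = "A1", strain_label: str = "major",
                   plate_id: str = "P1",
                   condition: AssayCondition | None = None) -> GrowthCurve:
    """One well's simulated OD595 time-series.

    The noise-free logistic trajectory is multiplied by the plate gain,
    i.i.d. Gaussian noise is added, and readings are floored at 0.  The
    endpoint read is the noise-free final value on the true density scale:
    resuspension recalibrates the well, so the endpoint read carries no
    reader gain, and dividing by it removes the gain from the kinetic
    trace.
    """
    if true_rate < 0:
        raise ValueError("true_rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if condition is None:
        condition = AssayCondition(pyridoxine=400.0)
    n_reads = int(cfg.duration / cfg.read_interval) + 1
    times = np.arange(n_reads) * cfg.read_interval
    clean = logistic_od(times, cfg, true_rate)
    measured = clean * cfg.plate_gain
    od = np.maximum(measured + rng.normal(0.0, cfg.noise_sd, size=n_reads), 0.0)
    return GrowthCurve(
        well_id=well_id, strain_label=strain_label, plate_id=plate_id,
        condition=condition, times=times, od=od,
        endpoint_od=float(clean[-1]),
    )


#: true mean relative rate per category and pyridoxine dose (ng/mL);
#: benign alleles track the major allele at every dose, sensitive alleles
#: decline monotonically as the dose is titrated down
DEFAULT_RATE_EFFECTS: dict[Category, dict[float, float]] = {
    Category.BENIGN: {400.0: 1.0, 4.0: 1.0, 2.0: 1.0, 1.0: 1.0},
    Category.SENSITIVE: {400.0: 0.8, 4.0: 0.7, 2.0: 0.45, 1.0: 0.35},
    Category.NONFUNCTIONAL: {400.0: 0.0, 4.0: 0.0, 2.0: 0.0, 1.0: 0.0},
}

#: the five feature names used in the category-association analysis
FEATURE_NAMES = ("dist_heme", "dist_plp", "rsa", "in_regular_ss", "mean_bfactor")


@dataclass(frozen=True)
class PanelSimConfig:
    """Synthetic variant-panel layout mirroring the real study design:
    ~1/3 nonfunctional, ~1/4 sensitive, rest benign; >= 3 replicate
    transformants per allele and dose."""

    n_alleles: int = 24
    category_proportions: tuple[float, float, float] = (19 / 58, 14 / 58, 25 / 58)
    rate_effects: dict[Category, dict[float, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RATE_EFFECTS.items()})
    allele_rate_sd: float = 0.05     # between-allele spread of true ratios
    n_replicates: int = 3
    doses: tuple[float, ...] = (400.0, 4.0, 2.0, 1.0)
    major_rate: float = 0.05         # major-allele log10 slope, /h
    feature_shift: dict[str, float] = field(default_factory=dict)
    plate_rate_effects: dict[str, float] = field(default_factory=dict)
    curve: CurveSimConfig = field(default_factory=CurveSimConfig)

    def __post_init__(self) -> None:
        p = self.category_proportions
        if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1) > 1e-9:
            raise ValueError("category_proportions must be a 3-vector summing to 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


@dataclass(frozen=True)
class SimulatedPanel:
    """Simulated raw data plus the truth ledger that generated it."""

    curves: list[GrowthCurve]                       # variant + major wells
    categories: dict[str, Category]                 # allele -> category
    true_ratios: dict[str, dict[float, float]]      # allele -> dose -> ratio
    features: dict[str, dict[str, float]]           # allele -> feature -> value
    plate_of: dict[str, str]                        # allele -> plate id


def simulate_panel(cfg: PanelSimConfig, seed: int | None = 0) -> SimulatedPanel:
    """Draw a full synthetic panel with replicate growth curves.

    Nonfunctional alleles emit flat (lag-only) curves; sensitive alleles'
    true ratios decline with decreasing pyridoxine; benign ratios sit at 1
    across doses.  Each allele is assigned to a plate that also carries
    major-allele reference wells; per-plate rate effects (if configured)
    multiply every true rate on the plate.  Synthetic structural features
    are drawn i.i.d. standard normal (occupancy fraction for the secondary-
    structure indicator), with any configured shift added for sensitive
    alleles to plant a category association.
    """
    rng = np.random.default_rng(seed)
    cats = (Category.NONFUNCTIONAL, Category.SENSITIVE, Category.BENIGN)
    n_per = np.floor(np.asarray(cfg.category_proportions) * cfg.n_alleles).astype(int)
    while n_per.sum() < cfg.n_alleles:
        n_per[int(rng.integers(3))] += 1

    plates = sorted(cfg.plate_rate_effects) or ["P1"]
    curves: list[GrowthCurve] = []
    categories: dict[str, Category] = {}
    true_ratios: dict[str, dict[float, float]] = {}
    features: dict[str, dict[str, float]] = {}
    plate_of: dict[str, str] = {}

    # reference wells: one major-allele replicate set per plate and dose
    for plate in plates:
        plate_mult = cfg.plate_rate_effects.get(plate, 1.0)
        for dose in cfg.doses:
            cond = AssayCondition(pyridoxine=dose)
            for rep in range(cfg.n_replicates):
                curves.append(simulate_curve(
                    cfg.curve, cfg.major_rate * plate_mult, rng,
                    well_id=f"{plate}-major-{dose:g}-{rep}",
                    strain_label="major", plate_id=plate, condition=cond))

    idx = 0
    for cat, count in zip(cats, n_per):
        for _ in range(count):
            allele = f"allele{idx:03d}"
            idx += 1
            plate = plates[idx % len(plates)]
            plate_mult = cfg.plate_rate_effects.get(plate, 1.0)
            categories[allele] = cat
            plate_of[allele] = plate
            offset = rng.normal(0.0, cfg.allele_rate_sd)
            ratios = {}
            for dose in cfg.doses:
                base = cfg.rate_effects[cat][dose]
                ratios[dose] = 0.0 if base == 0.0 else max(base + offset, 0.05)
            true_ratios[allele] = ratios
            cond_features = {
                f: float(rng.normal()) for f in FEATURE_NAMES if f != "in_regular_ss"
            }
            cond_features["in_regular_ss"] = float(rng.integers(2))
            if cat is Category.SENSITIVE:
                for f, shift in cfg.feature_shift.items():
                    cond_features[f] += shift
            features[allele] = cond_features
            for dose in cfg.doses:
                cond = AssayCondition(pyridoxine=dose)
                rate = cfg.major_rate * plate_mult * ratios[dose]
                for rep in range(cfg.n_replicates):
                    curves.append(simulate_curve(
                        cfg.curve, rate, rng,
                        well_id=f"{plate}-{allele}-{dose:g}-{rep}",
                        strain_label=allele, plate_id=plate, condition=cond))

    return SimulatedPanel(curves=curves, categories=categories,
                          true_ratios=true_ratios, features=features,
                          plate_of=plate_of)


# ---------------------------------------------------------------------------
# synthetic structures

HELIX_RISE = 1.5          # A per residue
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # A, C-alpha radius
SIDECHAIN_RADIUS = 3.8    # A, dummy side-chain (CB) radius


def helix_coordinates(n_residues: int, first_residue: int = 1
                      ) -> dict[int, dict[str, np.ndarray]]:
    """Idealized helical coordinates (rounded to PDB precision, 1e-3 A).

    Per residue: N, CA, C on the helical path plus a radially displaced
    dummy side-chain atom CB.  Rounding here makes the written PDB file a
    lossless representation of the model.
    """
    coords: dict[int, dict[str, np.ndarray]] = {}
    for j in range(n_residues):
        seqid = first_residue + j
        per = {}
        for name, offset, radius in (("N", -0.33, HELIX_RADIUS),
                                     ("CA", 0.0, HELIX_RADIUS),
                                     ("C", 0.33, HELIX_RADIUS),
                                     ("CB", 0.0, SIDECHAIN_RADIUS)):
            t = j + offset
            theta = math.radians(HELIX_TWIST) * t
            xyz = np.array([radius * math.cos(theta),
                            radius * math.sin(theta),
                            HELIX_RISE * t])
            per[name] = np.round(xyz, 3)
        coords[seqid] = per
    return coords


def _make_atom(name: str, element: str, xyz: np.ndarray,
               b_iso: float) -> gemmi.Atom:
    a = gemmi.Atom()
    a.name = name
    a.element = gemmi.Element(element)
    a.pos = gemmi.Position(*map(float, xyz))
    a.occ = 1.0
    a.b_iso = float(b_iso)
    return a


def simulate_structure(
    path,
    n_residues: int,
    ligand_positions: list[tuple[str, np.ndarray]] | None = None,
    bfactor_profile=20.0,
    seed: int | None = 0,
    first_residue: int = 1,
    write_helix_record: bool = True,
) -> None:
    """Write a synthetic helical structure as a PDB file.

    ``ligand_positions`` is a list of (kind, xyz) with kind "heme" or
    "plp"; each becomes a single-atom HETATM group (HEM/PLP).  The
    B-factor profile may be a constant, a per-residue sequence, or a
    callable of the residue index.  A ligand within 1 A of any protein
    atom is rejected as overlapping.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    coords = helix_coordinates(n_residues, first_residue)

    def bf(seqid: int) -> float:
        if callable(bfactor_profile):
            return float(bfactor_profile(seqid))
        if np.isscalar(bfactor_profile):
            return float(bfactor_profile)
        return float(bfactor_profile[seqid - first_residue])

    all_protein = np.array([xyz for per in coords.values() for xyz in per.values()])
    ligand_positions = ligand_positions or []
    for kind, xyz in ligand_positions:
        if np.linalg.norm(all_protein - np.asarray(xyz), axis=1).min() < 1.0:
            raise ValueError(f"{kind} ligand overlaps the backbone (< 1 A)")

    st = gemmi.Structure()
    st.name = "synthetic-helix"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for seqid, per in coords.items():
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(seqid, " ")
        b = bf(seqid)
        for name, xyz in per.items():
            res.add_atom(_make_atom(name, "N" if name == "N" else "C", xyz, b))
        chain.add_residue(res)
    lig_names = {"heme": ("HEM", "FE"), "plp": ("PLP", "P")}
    for i, (kind, xyz) in enumerate(ligand_positions):
        resname, element = lig_names[kind]
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(900 + i, " ")
        res.het_flag = "H"
        res.add_atom(_make_atom(element, element, np.round(np.asarray(xyz, float), 3), 30.0))
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)

    if write_helix_record:
        helix = gemmi.Helix()
        start = gemmi.AtomAddress()
        start.chain_name = "A"
        rid = gemmi.ResidueId()
        rid.name = "ALA"
        rid.seqid = gemmi.SeqId(first_residue, " ")
        start.res_id = rid
        end = gemmi.AtomAddress()
        end.chain_name = "A"
        rid2 = gemmi.ResidueId()
        rid2.name = "ALA"
        rid2.seqid = gemmi.SeqId(first_residue + n_residues - 1, " ")
        end.res_id = rid2
        helix.start = start
        helix.end = end
        helix.length = n_residues
        st.helices.append(helix)

    st.setup_entities()
    st.write_pdb(str(path))


# standard backbone internal coordinates (A / degrees)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Next atom position from internal coordinates (NeRF construction)."""
    ang = math.radians(angle)
    tor = math.radians(torsion - 180.0)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def write_dihedral_backbone_pdb(path, n_residues: int,
                                phi: float = -57.0, psi: float = -47.0,
                                omega: float = 180.0) -> None:
    """Poly-alanine backbone built from fixed (phi, psi) dihedrals.

    Written without HELIX/SHEET records so that reading it exercises the
    dihedral-window fallback of the secondary-structure assignment.
    """
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(_ANGLE["N-CA-C"])
    c = ca + _BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    atoms: list[tuple[int, str, np.ndarray]] = [(1, "N", n), (1, "CA", ca), (1, "C", c)]
    for i in range(2, n_residues + 1):
        n_next = _place(n, ca, c, _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        ca_next = _place(ca, c, n_next, _BOND["N-CA"], _ANGLE["C-N-CA"], omega)
        c_next = _place(c, n_next, ca_next, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        atoms += [(i, "N", n_next), (i, "CA", ca_next), (i, "C", c_next)]
        n, ca, c = n_next, ca_next, c_next

    st = gemmi.Structure()
    st.name = "dihedral-backbone"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for seqid in range(1, n_residues + 1):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(seqid, " ")
        for sid, name, xyz in atoms:
            if sid == seqid:
                res.add_atom(_make_atom(name, "N" if name == "N" else "C",
                                        np.round(xyz, 3), 15.0))
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
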