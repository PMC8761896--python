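"""Solvent-accessible surface area, interface burial, and hydrogen-bond /
salt-bridge detection with per-snapshot occupancy.

SASA uses a native Shrake-Rupley implementation with a deterministic golden
spiral sphere quadrature, so results are bit-reproducible at fixed
``n_points``.  The quadrature is expressed in a canonical frame derived from
the input coordinates (principal axes with a deterministic sign fix), which
makes the computed areas invariant under global rigid transforms of the
system rather than merely approximately so.

Buried ASA at an interface is reported as the total
``ASA(A) + ASA(B) - ASA(A+B)``; half of that is emitted alongside as the
interface area, for comparison with tools that report one side.  Hydrogen-bond criteria default to a
3.5 Angstrom heavy-atom donor-acceptor cutoff plus a 120 degree D-H...A angle
when hydrogens are present (crystal structures usually lack them; MD
snapshots have them); salt bridges use a 4.0 Angstrom cutoff between
opposite-charge side-chain atoms.  These are conventional values, not a
reproduction of any specific server's internals, and all are configurable.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InterfaceSpecError
from .structure_io import FabModel, ResidueID
from .tables import (
    NEGATIVE_ATOMS,
    POSITIVE_ATOMS,
    TABLES_VERSION,
    hbond_acceptor_atoms,
    hbond_donor_atoms,
)

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
DEFAULT_HBOND_DMAX = 3.5
DEFAULT_HBOND_DHA_MIN = 120.0
DEFAULT_SALTBRIDGE_DMAX = 4.0
COVALENT_H_CUTOFF = 1.3


# --- sphere quadrature ------------------------------------------------------


def golden_spiral_points(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere quadrature points."""
    i = np.arange(n_points)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _canonical_axes(coords: np.ndarray) -> np.ndarray:
    """Principal axes of the coordinate cloud with a deterministic sign fix.

    Returns a 3x3 matrix whose columns are the axes; degenerate inputs fall
    back to the identity.  Because the axes co-rotate with the molecule, the
    quadrature built on them is rigid-motion invariant.
    """
    if coords.shape[0] < 3:
        return np.eye(3)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    try:
        _vals, vecs = np.linalg.eigh(cov)
    except np.linalg.LinAlgError:
        return np.eye(3)
    vecs = vecs[:, ::-1]  # descending variance
    # sign fix must be equivariant (computed from the data, not the lab
    # frame), otherwise rotating the molecule could flip quadrature axes
    skew = np.empty(3)
    for j in range(3):
        proj = centered @ vecs[:, j]
        skew[j] = float((proj**3).sum())
        if abs(skew[j]) > 1e-8 and skew[j] < 0:
            vecs[:, j] = -vecs[:, j]
    if np.linalg.det(vecs) < 0:
        j = int(np.argmin(np.abs(skew)))
        vecs[:, j] = -vecs[:, j]
    return vecs


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    axes: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Angstrom^2.

    ``coords`` is (N, 3); ``radii`` the van der Waals radii (N,).  Each atom's
    expanded sphere (r + probe) is sampled at ``n_points`` quadrature points;
    the exposed fraction times the sphere area gives the ASA.  ``axes``
    optionally fixes the quadrature orientation (columns = frame vectors);
    by default the canonical axes of ``coords`` are used.  Burial comparisons
    between subsystems (e.g. buried ASA) must pass a shared ``axes`` so the
    quadrature is identical across calls.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    if radii.shape != (coords.shape[0],):
        raise ValueError("radii must match coords")
    if coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")

    if axes is None:
        axes = _canonical_axes(coords)
    unit = golden_spiral_points(n_points) @ np.asarray(axes, float).T
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_r = float(expanded.max())
    areas = np.empty(coords.shape[0])
    sphere_area = 4.0 * math.pi * expanded**2
    for i in range(coords.shape[0]):
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
            if j != i and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]
        ]
        if not neighbors:
            areas[i] = sphere_area[i]
            continue
        pts = coords[i] + expanded[i] * unit
        nb = np.array(neighbors, dtype=int)
        d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
        areas[i] = sphere_area[i] * (1.0 - buried.mean())
    return areas


@dataclasses.dataclass
class SasaResult:
    """Per-atom areas plus per-residue sums and the total, in Angstrom^2."""

    atom_area: np.ndarray
    residue_area: dict[ResidueID, float]
    total: float


def sasa(
    fab: FabModel,
    model_index: int = 0,
    domains: Sequence[str] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    axes: np.ndarray | None = None,
) -> SasaResult:
    """SASA of a model (optionally restricted to a set of domains)."""
    if domains is None:
        idx = np.arange(fab.structure.n_atoms)
    else:
        idx = fab.atom_indices(*domains)
    coords = fab.structure.coords[model_index][idx]
    radii = np.array([fab.structure.sites[i].vdw_radius for i in idx])
    areas = shrake_rupley(coords, radii, probe_radius, n_points, axes=axes)
    per_res: dict[ResidueID, float] = {}
    for a, i in enumerate(idx):
        rid = fab.structure.sites[i].residue
        per_res[rid] = per_res.get(rid, 0.0) + float(areas[a])
    return SasaResult(atom_area=areas, residue_area=per_res, total=float(areas.sum()))


# --- interfaces -------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class InterfaceSpec:
    """Two disjoint, non-empty domain-label sets defining an interface."""

    name: str
    side_a: tuple[str, ...]
    side_b: tuple[str, ...]

    def __post_init__(self):
        if not self.side_a or not self.side_b:
            raise InterfaceSpecError("both interface sides must be non-empty")
        if set(self.side_a) & set(self.side_b):
            raise InterfaceSpecError("interface sides must be disjoint")


VH_VL = InterfaceSpec("VH-VL", ("VH",), ("VL",))
ELBOW = InterfaceSpec("elbow", ("VH", "VL"), ("CH1", "CL"))


def _interface_sasa(fab, spec, model_index, probe_radius, n_points):
    # one quadrature orientation, derived from the union, shared by all three
    # calls: burial then cancels exactly for non-interacting sides and the
    # whole computation is rigid-motion invariant
    union = tuple(spec.side_a) + tuple(spec.side_b)
    idx = fab.atom_indices(*union)
    if len(idx) == 0:
        raise InterfaceSpecError(f"interface {spec.name}: no atoms resolved")
    axes = _canonical_axes(fab.structure.coords[model_index][idx])
    sasa_a = sasa(fab, model_index, spec.side_a, probe_radius, n_points, axes=axes)
    sasa_b = sasa(fab, model_index, spec.side_b, probe_radius, n_points, axes=axes)
    sasa_ab = sasa(fab, model_index, union, probe_radius, n_points, axes=axes)
    if len(sasa_a.atom_area) == 0 or len(sasa_b.atom_area) == 0:
        raise InterfaceSpecError(f"interface {spec.name}: a side resolves no atoms")
    return sasa_a, sasa_b, sasa_ab


def buried_asa(
    fab: FabModel,
    spec: InterfaceSpec = VH_VL,
    model_index: int = 0,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Total buried ASA ``ASA(A) + ASA(B) - ASA(A+B)`` in Angstrom^2."""
    sasa_a, sasa_b, sasa_ab = _interface_sasa(fab, spec, model_index, probe_radius, n_points)
    return sasa_a.total + sasa_b.total - sasa_ab.total


def interface_residues(
    fab: FabModel,
    spec: InterfaceSpec = VH_VL,
    model_index: int = 0,
    min_delta: float = 0.1,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> tuple[list[ResidueID], list[ResidueID]]:
    """Residues whose ASA drops by more than ``min_delta`` upon complexation."""
    sasa_a, sasa_b, sasa_ab = _interface_sasa(fab, spec, model_index, probe_radius, n_points)
    out = []
    for isolated in (sasa_a, sasa_b):
        side = [
            rid
            for rid, area in isolated.residue_area.items()
            if area - sasa_ab.residue_area.get(rid, 0.0) > min_delta
        ]
        out.append(side)
    return out[0], out[1]


# --- contacts ---------------------------------------------------------------


@dataclasses.dataclass
class Contact:
    """One polar contact across an interface.

    ``donor``/``acceptor`` are (ResidueID, atom_name) pairs; for salt bridges
    the donor is the positively charged atom.  ``angle`` is the D-H...A angle
    in degrees when a donor hydrogen was available, else None.  ``occupancy``
    is filled by :func:`contact_occupancy`.
    """

    kind: str
    donor: tuple[ResidueID, str]
    acceptor: tuple[ResidueID, str]
    distance: float
    angle: float | None = None
    occupancy: float | None = None

    @property
    def residue_pair(self) -> tuple[ResidueID, ResidueID]:
        return (self.donor[0], self.acceptor[0])

    @property
    def key(self):
        return (self.kind, self.donor, self.acceptor)


def _side_atoms(fab, domains, predicate):
    """(atom_index, site) pairs on one interface side passing a predicate."""
    out = []
    for i in fab.atom_indices(*domains):
        site = fab.structure.sites[i]
        if predicate(site):
            out.append((int(i), site))
    return out


def _pairs_within(coords_a, coords_b, cutoff):
    """Index pairs (ia, ib) with distance <= cutoff, via KD-tree query."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return []
    tree_b = cKDTree(coords_b)
    pairs = []
    for ia, hits in enumerate(cKDTree(coords_a).query_ball_tree(tree_b, cutoff)):
        pairs.extend((ia, ib) for ib in hits)
    return pairs


def _attached_hydrogens(fab, model_index, donor_index):
    """Hydrogen atom indices covalently attached to a donor heavy atom."""
    coords = fab.structure.coords[model_index]
    donor_site = fab.structure.sites[donor_index]
    out = []
    for i, site in enumerate(fab.structure.sites):
        if site.residue != donor_site.residue or site.element.upper() != "H":
            continue
        if np.linalg.norm(coords[i] - coords[donor_index]) <= COVALENT_H_CUTOFF:
            out.append(i)
    return out


def detect_hbonds(
    fab: FabModel,
    spec: InterfaceSpec = VH_VL,
    model_index: int = 0,
    d_heavy_max: float = DEFAULT_HBOND_DMAX,
    dha_min: float = DEFAULT_HBOND_DHA_MIN,
) -> list[Contact]:
    """Hydrogen bonds across an interface for one model.

    Donor-acceptor typing comes from the packaged residue tables.  When a
    donor carries a resolvable hydrogen the D-H...A angle criterion applies;
    donors without hydrogens are accepted on the heavy-atom distance alone
    (heavy-atom mode), so structures without hydrogens remain analyzable.
    """
    coords = fab.structure.coords[model_index]
    contacts = []
    for side_d, side_a in ((spec.side_a, spec.side_b), (spec.side_b, spec.side_a)):
        donors = _side_atoms(
            fab, side_d, lambda s: s.atom_name in hbond_donor_atoms(s.res_name)
        )
        acceptors = _side_atoms(
            fab, side_a, lambda s: s.atom_name in hbond_acceptor_atoms(s.res_name)
        )
        dc = np.array([coords[i] for i, _ in donors]).reshape(-1, 3)
        ac = np.array([coords[i] for i, _ in acceptors]).reshape(-1, 3)
        for id_, ia_ in _pairs_within(dc, ac, d_heavy_max):
            di, dsite = donors[id_]
            ai, asite = acceptors[ia_]
            dist = float(np.linalg.norm(coords[ai] - coords[di]))
            hydrogens = _attached_hydrogens(fab, model_index, di)
            angle = None
            if hydrogens:
                best = -1.0
                for hi in hydrogens:
                    hd = coords[di] - coords[hi]
                    ha = coords[ai] - coords[hi]
                    cosv = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                    best = max(best, math.degrees(math.acos(np.clip(cosv, -1, 1))))
                angle = best
                if angle < dha_min:
                    continue
            contacts.append(
                Contact(
                    kind="hbond",
                    donor=(dsite.residue, dsite.atom_name),
                    acceptor=(asite.residue, asite.atom_name),
                    distance=dist,
                    angle=angle,
                )
            )
    contacts.sort(key=lambda c: (c.donor[0].sort_key, c.donor[1], c.acceptor[0].sort_key, c.acceptor[1]))
    return contacts


def detect_saltbridges(
    fab: FabModel,
    spec: InterfaceSpec = VH_VL,
    model_index: int = 0,
    d_max: float = DEFAULT_SALTBRIDGE_DMAX,
) -> list[Contact]:
    """Opposite-charge atom pairs across an interface within ``d_max``."""
    coords = fab.structure.coords[model_index]
    contacts = []

    def charged(table):
        return lambda s: s.atom_name in table.get(s.res_name.upper(), ())

    for side_p, side_n in ((spec.side_a, spec.side_b), (spec.side_b, spec.side_a)):
        pos = _side_atoms(fab, side_p, charged(POSITIVE_ATOMS))
        neg = _side_atoms(fab, side_n, charged(NEGATIVE_ATOMS))
        pc = np.array([coords[i] for i, _ in pos]).reshape(-1, 3)
        nc = np.array([coords[i] for i, _ in neg]).reshape(-1, 3)
        for ip_, in_ in _pairs_within(pc, nc, d_max):
            pi, psite = pos[ip_]
            ni, nsite = neg[in_]
            contacts.append(
                Contact(
                    kind="saltbridge",
                    donor=(psite.residue, psite.atom_name),
                    acceptor=(nsite.residue, nsite.atom_name),
                    distance=float(np.linalg.norm(coords[ni] - coords[pi])),
                )
            )
    contacts.sort(key=lambda c: (c.donor[0].sort_key, c.donor[1], c.acceptor[0].sort_key, c.acceptor[1]))
    return contacts


def contact_occupancy(
    fab: FabModel,
    spec: InterfaceSpec = VH_VL,
    kinds: Sequence[str] = ("hbond", "saltbridge"),
    model_indices: Sequence[int] | None = None,
    d_heavy_max: float = DEFAULT_HBOND_DMAX,
    dha_min: float = DEFAULT_HBOND_DHA_MIN,
    d_salt_max: float = DEFAULT_SALTBRIDGE_DMAX,
) -> list[Contact]:
    """Contacts keyed by atom-pair identity with occupancy over models.

    Occupancy is the fraction of analyzed models in which the contact
    satisfies its criteria; pairs never observed are simply absent.
    """
    models = list(model_indices) if model_indices is not None else list(range(fab.structure.n_models))
    if not models:
        raise ValueError("no models to analyze")
    seen: dict[tuple, list[Contact]] = {}
    for m in models:
        found: list[Contact] = []
        if "hbond" in kinds:
            found.extend(detect_hbonds(fab, spec, m, d_heavy_max, dha_min))
        if "saltbridge" in kinds:
            found.extend(detect_saltbridges(fab, spec, m, d_salt_max))
        for c in found:
            seen.setdefault(c.key, []).append(c)
    out = []
    for key in sorted(seen, key=lambda k: (k[0], k[1][0].sort_key, k[1][1], k[2][0].sort_key, k[2][1])):
        group = seen[key]
        angles = [c.angle for c in group if c.angle is not None]
        out.append(
            Contact(
                kind=group[0].kind,
                donor=group[0].donor,
                acceptor=group[0].acceptor,
                distance=float(np.mean([c.distance for c in group])),
                angle=float(np.mean(angles)) if angles else None,
                occupancy=len(group) / len(models),
            )
        )
    return out


def group_contacts_by_residue(contacts: Sequence[Contact]) -> dict[tuple, dict]:
    """Aggregate atom-pair contacts to residue-pair granularity.

    Returns ``(donor_residue, acceptor_residue) -> {"kind", "n_atom_pairs",
    "max_occupancy"}``; both granularities are useful when counting interface
    networks.
    """
    grouped: dict[tuple, dict] = {}
    for c in contacts:
        key = (c.kind,) + tuple(str(r) for r in c.residue_pair)
        slot = grouped.setdefault(
            key, {"kind": c.kind, "n_atom_pairs": 0, "max_occupancy": None}
        )
        slot["n_atom_pairs"] += 1
        if c.occupancy is not None:
            prev = slot["max_occupancy"]
            slot["max_occupancy"] = c.occupancy if prev is None else max(prev, c.occupancy)
    return grouped


# --- report -----------------------------------------------------------------


@dataclasses.dataclass
class InterfaceReport:
    """Per-model burial plus contact inventory for one named interface."""

    spec: InterfaceSpec
    basa: np.ndarray                    # per model, Angstrom^2
    interface_area: np.ndarray          # bASA / 2, one-sided convention
    residues_side_a: list[ResidueID]
    residues_side_b: list[ResidueID]
    contacts: list[Contact]
    tables_version: str = TABLES_VERSION

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kind": c.kind,
                "side_a_atom": f"{c.donor[0]}:{c.donor[1]}",
                "side_b_atom": f"{c.acceptor[0]}:{c.acceptor[1]}",
                "mean_distance": c.distance,
                "occupancy": c.occupancy,
            }
            for c in self.contacts
        ]
        return pd.DataFrame(rows, columns=["kind", "side_a_atom", "side_b_atom", "mean_distance", "occupancy"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "interface": self.spec.name,
            "tables_version": self.tables_version,
            "basa_per_model": self.basa.tolist(),
            "interface_area_per_model": self.interface_area.tolist(),
            "residues_side_a": [str(r) for r in self.residues_side_a],
            "residues_side_b": [str(r) for r in self.residues_side_b],
            "contacts": [
                {
                    "kind": c.kind,
                    "donor": f"{c.donor[0]}:{c.donor[1]}",
                    "acceptor": f"{c.acceptor[0]}:{c.acceptor[1]}",
                    "mean_distance": c.distance,
                    "mean_angle": c.angle,
                    "occupancy": c.occupancy,
                }
                for c in self.contacts
            ],
            "residue_pairs": group_contacts_by_residue(self.contacts),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def interface_report(
    fab: FabModel,
    spec: InterfaceSpec = VH_VL,
    model_indices: Sequence[int] | None = None,
    min_delta: float = 0.1,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> InterfaceReport:
    """Full interface characterization over a set of models."""
    models = list(model_indices) if model_indices is not None else list(range(fab.structure.n_models))
    basa = np.array(
        [buried_asa(fab, spec, m, probe_radius, n_points) for m in models]
    )
    res_a, res_b = interface_residues(fab, spec, models[0], min_delta, probe_radius, n_points)
    contacts = contact_occupancy(fab, spec, model_indices=models)
    return InterfaceReport(
        spec=spec,
        basa=basa,
        interface_area=basa / 2.0,
        residues_side_a=res_a,
        residues_side_b=res_b,
        contacts=contacts,
    )
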