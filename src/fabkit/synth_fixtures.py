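"""Deterministic generator of idealized Fab-like assemblies and rigid-body
"trajectories" with known ground-truth geometry.

The toy domains are geometric idealizations — two antiparallel layers of
C-alpha positions with N/C/O backbone stubs — **not** physical proteins.  They
exist so that every geometric and statistical operation in the toolkit can be
exercised against exact, generator-known answers (applied twists, shifts and
elbow rotations), standing in for MD trajectory snapshots and for deposited
antibody structures.  Do not mistake the fixtures for structural models.

Geometry of the assembly (lab frame, before perturbations):

* the VH domain sits with its frame origin at ``(-s, 0, 0)``;
* VL is VH rotated 180 degrees about the lab y axis, origin at ``(+s, 0, 0)``;
* CH1/CL repeat the arrangement shifted down the z axis by ``h``;
* the VH->VL and CH1->CL pseudo-dyad axes are therefore parallel (both along
  y) and perpendicular to the module-connecting axis (z), which makes the
  reference elbow angle exactly 180 degrees;
* per-frame perturbations are rigid: an HL twist rotates VL about the axis
  through both variable-domain origins, a dc offset translates VL along that
  axis, and an elbow rotation turns the whole constant module about the
  module-connecting axis.

One pseudo-random stream is derived per purpose (residue names, each
perturbation program, per-frame jitter), so adding frames or enabling jitter
never changes earlier frames or the unperturbed placement.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np

from .structure_io import (
    AtomSite,
    DomainMap,
    DomainRange,
    ResidueID,
    Structure,
)
from .tables import STANDARD_AMINO_ACIDS, vdw_radius

REFERENCE_SEED = 712
REFERENCE_SIZE = 60

# backbone stub offsets relative to CA, in the canonical domain frame
_STUB_OFFSETS = {
    "N": np.array([-1.25, 0.45, 0.20]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.25, 0.40, -0.20]),
    "O": np.array([1.90, 1.50, -0.25]),
}
_STUB_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}

_RESNAME_BY_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a unit axis (Rodrigues)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


@dataclasses.dataclass
class ReferenceDomain:
    """Idealized beta-sandwich C-alpha layout with an embedded frame."""

    positions: list[tuple[int, str | None]]
    coords: np.ndarray  # (size, 3), coreset centroid at the origin
    coreset: list[tuple[int, str | None]]
    origin: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    seed: int
    version: str = "toy-reference-1"


def make_reference_domain(
    size: int = REFERENCE_SIZE,
    seed: int = REFERENCE_SEED,
    strand_len: int = 10,
    jitter: float = 0.3,
) -> ReferenceDomain:
    """Build the canonical idealized domain (deterministic per seed).

    Two antiparallel layers of strands (C-alpha spacing 3.8 A along x, strand
    spacing 4.8 A along z, layers at y = +-5 A) with a small frozen jitter so
    the shape has no exact symmetries.  The embedded frame origin is the
    coreset centroid; v1/v2 are fixed oblique orthonormal vectors.
    """
    if size < 20:
        raise ValueError("reference domain needs at least 20 residues")
    rng = np.random.default_rng([seed, 0])
    n_strands = math.ceil(size / strand_len)
    per_layer = math.ceil(n_strands / 2)
    coords = np.empty((size, 3))
    for i in range(size):
        strand, k = divmod(i, strand_len)
        layer, strand_in_layer = divmod(strand, per_layer)
        coords[i] = (
            (k - (strand_len - 1) / 2) * 3.8,
            -5.0 + 10.0 * layer,
            (strand_in_layer - (per_layer - 1) / 2) * 4.8,
        )
    coords += rng.normal(0.0, jitter, coords.shape)
    lo = round(0.2 * size)
    coreset_idx = list(range(lo, size - lo))
    coords -= coords[coreset_idx].mean(axis=0)
    v1 = np.array([1.0, 1.0, 2.0]) / math.sqrt(6.0)
    v2 = np.array([1.0, 1.0, -1.0]) / math.sqrt(3.0)
    positions = [(i + 1, None) for i in range(size)]
    return ReferenceDomain(
        positions=positions,
        coords=coords,
        coreset=[positions[i] for i in coreset_idx],
        origin=np.zeros(3),
        v1=v1,
        v2=v2,
        seed=seed,
    )


# --- perturbation programs --------------------------------------------------

Program = None | float | tuple | Sequence[float]


def resolve_program(program: Program, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Turn a perturbation program into one value per frame.

    ``None`` -> zeros; a float -> constant; ``("ramp", a, b)`` -> linear ramp
    from a to b inclusive; ``("gaussian", mu, sigma)`` -> i.i.d. draws; any
    sequence of length ``n_frames`` -> used verbatim.
    """
    if program is None:
        return np.zeros(n_frames)
    if isinstance(program, (int, float)):
        return np.full(n_frames, float(program))
    if isinstance(program, tuple) and len(program) == 3 and program[0] == "ramp":
        return np.linspace(float(program[1]), float(program[2]), n_frames)
    if isinstance(program, tuple) and len(program) == 3 and program[0] == "gaussian":
        return rng.normal(float(program[1]), float(program[2]), n_frames)
    values = np.asarray(program, dtype=float)
    if values.shape != (n_frames,):
        raise ValueError(
            f"explicit program must have length {n_frames}, got shape {values.shape}"
        )
    return values


@dataclasses.dataclass
class ToyFabSpec:
    """Parameters of the synthetic rigid-body Fab/trajectory generator."""

    domain_size: int = REFERENCE_SIZE
    n_frames: int = 1
    seed: int = 0
    fv_only: bool = False
    hl_twist: Program = None       # degrees, rotation of VL about the VH->VL axis
    dc_offset: Program = None      # Angstrom, translation of VL along that axis
    elbow_rot: Program = None      # degrees, rotation of the constant module
    jitter_sigma: float = 0.0      # Angstrom, isotropic per-atom Gaussian noise
    light_isotype: str = "kappa"
    contact_gap: float = 4.5       # closest heavy-atom gap across VH-VL, Angstrom

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """Generator-known per-frame geometry of a toy Fab trajectory.

    ``hl``/``dc``/``elbow`` are absolute values as the geometry module defines
    them; ``applied_*`` are the raw per-frame perturbations.  ``elbow`` is only
    recorded when no HL twist is applied (twisting VL tilts the variable-domain
    dyad axis, so the constant-module rotation alone no longer determines the
    elbow angle); it is ``None`` otherwise.
    """

    applied_hl: np.ndarray
    applied_dc: np.ndarray
    applied_elbow: np.ndarray
    hl: np.ndarray
    dc: np.ndarray
    elbow: np.ndarray | None
    domain_map: DomainMap
    coreset: list[tuple[int, str | None]]
    half_separation: float
    module_offset: float


def _signed_dihedral(p1, p2, p3, p4) -> float:
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    return math.degrees(math.atan2(y, x))


def _base_hl(reference: ReferenceDomain) -> float:
    """HL torsion of the unperturbed assembly, from construction constants."""
    ry = np.diag([-1.0, 1.0, -1.0])  # 180 deg about y
    h1 = reference.v1
    l1 = ry @ reference.v1
    o_h = np.array([-1.0, 0.0, 0.0])
    o_l = np.array([1.0, 0.0, 0.0])
    return _signed_dihedral(o_h + h1, o_h, o_l, o_l + l1)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap degrees into (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def make_toy_fab(spec: ToyFabSpec) -> tuple[Structure, DomainMap, GroundTruth]:
    """Build a multi-model toy Fab from a ToyFabSpec; see the module docstring."""
    ref = make_reference_domain(spec.domain_size)
    n = spec.domain_size

    # full-atom canonical domain: residues x (N, CA, C, O)
    atom_names = list(_STUB_OFFSETS)
    base = np.concatenate(
        [ref.coords[:, None, :] + np.stack([_STUB_OFFSETS[a] for a in atom_names])[None]],
    ).reshape(n * len(atom_names), 3)

    # placement: derived from the domain extent so the VH-VL faces are in
    # light contact and the V/C modules do not clash
    max_stub_x = max(abs(v[0]) for v in _STUB_OFFSETS.values())
    s = float(base[:, 0].max()) + spec.contact_gap / 2.0
    z_extent = float(base[:, 2].max() - base[:, 2].min())
    h = z_extent + 2 * max_stub_x + 5.0

    ry = np.diag([-1.0, 1.0, -1.0])  # 180 deg about y

    vh0 = base + np.array([-s, 0.0, 0.0])
    vl0 = vh0 @ ry.T
    domains0 = {"VH": vh0, "VL": vl0}
    if not spec.fv_only:
        ch10 = vh0 + np.array([0.0, 0.0, -h])
        p = np.array([0.0, 0.0, -h])
        cl0 = (ch10 - p) @ ry.T + p
        domains0["CH1"] = ch10
        domains0["CL"] = cl0

    # roster: chain H = VH (1..n) + CH1 (201..200+n); chain L likewise
    rng_names = np.random.default_rng([spec.seed, 5])
    sites: list[AtomSite] = []
    order: list[tuple[str, int]] = []  # (domain, canonical atom row)
    chain_of = {"VH": "H", "CH1": "H", "VL": "L", "CL": "L"}
    offset_of = {"VH": 0, "VL": 0, "CH1": 200, "CL": 200}
    domain_names = ["VH", "CH1", "VL", "CL"] if not spec.fv_only else ["VH", "VL"]
    letters = list(_RESNAME_BY_LETTER)
    for dom in domain_names:
        res_letters = rng_names.choice(letters, size=n)
        for i in range(n):
            rid = ResidueID(chain_of[dom], offset_of[dom] + i + 1, None)
            res_name = _RESNAME_BY_LETTER[str(res_letters[i])]
            for j, aname in enumerate(atom_names):
                sites.append(
                    AtomSite(
                        residue=rid,
                        res_name=res_name,
                        atom_name=aname,
                        element=_STUB_ELEMENTS[aname],
                        occupancy=1.0,
                        vdw_radius=vdw_radius(_STUB_ELEMENTS[aname]),
                    )
                )
                order.append((dom, i * len(atom_names) + j))

    # perturbation values per frame
    hl = resolve_program(spec.hl_twist, spec.n_frames, np.random.default_rng([spec.seed, 1]))
    dc = resolve_program(spec.dc_offset, spec.n_frames, np.random.default_rng([spec.seed, 2]))
    el = resolve_program(spec.elbow_rot, spec.n_frames, np.random.default_rng([spec.seed, 3]))
    if spec.fv_only and np.any(el != 0):
        raise ValueError("elbow_rot requires constant domains (fv_only=False)")

    n_atoms = len(sites)
    coords = np.empty((spec.n_frames, n_atoms, 3))
    x_axis = np.array([1.0, 0.0, 0.0])
    z_axis = np.array([0.0, 0.0, 1.0])
    c_pivot = np.array([0.0, 0.0, -h])
    for t in range(spec.n_frames):
        frame_domains = {k: v.copy() for k, v in domains0.items()}
        if hl[t] != 0.0:
            # axis through both variable-domain origins: the x axis
            frame_domains["VL"] = frame_domains["VL"] @ _rotation_about_axis(x_axis, hl[t]).T
        if dc[t] != 0.0:
            frame_domains["VL"] = frame_domains["VL"] + np.array([dc[t], 0.0, 0.0])
        if not spec.fv_only and el[t] != 0.0:
            rot = _rotation_about_axis(z_axis, el[t])
            for dom in ("CH1", "CL"):
                frame_domains[dom] = (frame_domains[dom] - c_pivot) @ rot.T + c_pivot
        frame = np.empty((n_atoms, 3))
        for a, (dom, row) in enumerate(order):
            frame[a] = frame_domains[dom][row]
        if spec.jitter_sigma > 0:
            rng_j = np.random.default_rng([spec.seed, 4, t])
            frame = frame + rng_j.normal(0.0, spec.jitter_sigma, frame.shape)
        coords[t] = frame

    structure = Structure(sites, coords, metadata={"source": "fabkit-toy", "format": "synthetic"})

    dmap_domains = {
        "VH": DomainRange("H", 1, n),
        "VL": DomainRange("L", 1, n),
    }
    if not spec.fv_only:
        dmap_domains["CH1"] = DomainRange("H", 201, 200 + n)
        dmap_domains["CL"] = DomainRange("L", 201, 200 + n)
    dmap = DomainMap(dmap_domains, light_isotype=spec.light_isotype)

    truth = GroundTruth(
        applied_hl=hl,
        applied_dc=dc,
        applied_elbow=el,
        hl=_wrap_angle(_base_hl(ref) + hl),
        dc=2.0 * s + dc,
        elbow=(180.0 - el) if not np.any(hl != 0) and not spec.fv_only else None,
        domain_map=dmap,
        coreset=list(ref.coreset),
        half_separation=s,
        module_offset=h,
    )
    return structure, dmap, truth


# --- minimal contact fixtures ----------------------------------------------


def make_contact_fixture(
    kind: str,
    distance: float,
    angle: float = 160.0,
    distances: Sequence[float] | None = None,
):
    """Minimal two-chain system realizing exactly one requested contact.

    ``kind`` is ``"hbond"`` (backbone N-H donor vs backbone O acceptor),
    ``"saltbridge"`` (GLU OE1 vs LYS NZ) or ``"none"`` (a carbon in donor
    position, which must never be detected).  ``distance`` is the heavy-atom
    donor-acceptor distance; ``angle`` the D-H...A angle for the hbond kind.
    If ``distances`` is given, a multi-model structure is produced with the
    acceptor side shifted so model ``i`` realizes ``distances[i]``.

    Both chains carry 20 padding residues so the system satisfies the Fab
    domain-size floor; padding sits far from the interface.
    """
    if kind not in ("hbond", "saltbridge", "none"):
        raise ValueError(f"invalid contact kind {kind!r}")
    n_pad = 20
    sites: list[AtomSite] = []
    xyz: list[np.ndarray] = []

    def add_atom(chain, resnum, res_name, atom_name, element, pos):
        sites.append(
            AtomSite(
                residue=ResidueID(chain, resnum, None),
                res_name=res_name,
                atom_name=atom_name,
                element=element,
                occupancy=1.0,
                vdw_radius=vdw_radius(element),
            )
        )
        xyz.append(np.asarray(pos, float))

    def add_padding(chain, sign):
        # residues 1..20 marching away from the interface along x
        for i in range(n_pad):
            x0 = sign * (30.0 + 5.0 * i)
            add_atom(chain, i + 1, "GLY", "N", "N", [x0 - 1.2, 0.5, 0.0])
            add_atom(chain, i + 1, "GLY", "CA", "C", [x0, 0.0, 0.0])
            add_atom(chain, i + 1, "GLY", "C", "C", [x0 + 1.2, 0.5, 0.0])
            add_atom(chain, i + 1, "GLY", "O", "O", [x0 + 1.9, 1.6, 0.0])

    add_padding("A", -1)
    add_padding("B", +1)

    d = float(distance)
    if kind == "hbond":
        # donor N at origin with its H placed so that angle(N-H-A) == angle
        theta = math.radians(angle)
        # triangle N-H-O: |NH| = 1.0, |NO| = d, angle at H = theta
        sin_o = math.sin(theta) * 1.0 / d
        ang_o = math.asin(min(1.0, sin_o))
        ang_n = math.pi - theta - ang_o
        h_pos = np.array([math.cos(ang_n), math.sin(ang_n), 0.0])
        add_atom("A", 21, "ALA", "N", "N", [0.0, 0.0, 0.0])
        add_atom("A", 21, "ALA", "H", "H", h_pos)
        add_atom("A", 21, "ALA", "CA", "C", [-1.5, -0.4, 0.0])
        add_atom("B", 21, "ALA", "O", "O", [d, 0.0, 0.0])
        add_atom("B", 21, "ALA", "C", "C", [d + 1.2, 0.6, 0.0])
        add_atom("B", 21, "ALA", "CA", "C", [d + 2.5, 0.0, 0.0])
        moving_from = len(xyz) - 3  # B-side contact atoms shift with distance
    elif kind == "saltbridge":
        add_atom("A", 21, "GLU", "CD", "C", [-1.3, 0.0, 0.0])
        add_atom("A", 21, "GLU", "OE1", "O", [0.0, 0.0, 0.0])
        add_atom("A", 21, "GLU", "OE2", "O", [-1.9, -1.1, 0.0])
        add_atom("A", 21, "GLU", "CA", "C", [-3.5, 0.8, 0.0])
        add_atom("B", 21, "LYS", "NZ", "N", [d, 0.0, 0.0])
        add_atom("B", 21, "LYS", "CE", "C", [d + 1.4, 0.5, 0.0])
        add_atom("B", 21, "LYS", "CA", "C", [d + 3.0, 0.0, 0.0])
        moving_from = len(xyz) - 3
    else:  # "none": carbon where the donor would be
        add_atom("A", 21, "ALA", "CA", "C", [0.0, 0.0, 0.0])
        add_atom("B", 21, "ALA", "O", "O", [d, 0.0, 0.0])
        add_atom("B", 21, "ALA", "C", "C", [d + 1.2, 0.6, 0.0])
        moving_from = len(xyz) - 2

    base = np.array(xyz)
    series = [d] if distances is None else [float(x) for x in distances]
    coords = np.empty((len(series), len(base), 3))
    for m, dm in enumerate(series):
        frame = base.copy()
        frame[moving_from:, 0] += dm - d
        coords[m] = frame

    structure = Structure(sites, coords, metadata={"source": "fabkit-contact", "format": "synthetic"})
    dmap = DomainMap(
        {"VH": DomainRange("A", 1, 21), "VL": DomainRange("B", 1, 21)},
        light_isotype="unspecified",
    )
    return structure, dmap
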