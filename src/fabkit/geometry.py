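"""Rigid-body superposition and the two headline conformation measures:
the six-parameter VH-VL orientation and the Fab elbow angle.

Angle conventions
-----------------
The VH-VL orientation follows the torsion/tilt/distance parameterization used
for antibody variable-domain pairing: each variable domain carries a frame
(origin ``o``, orthonormal vectors ``v1``, ``v2``) registered by superposing a
packaged reference coreset onto the observed C-alpha positions.  With
``C = o_L - o_H``:

* ``dc``  — |C| in Angstrom,
* ``HL``  — signed torsion of (o_H + H1, o_H, o_L, o_L + L1) in (-180, 180],
* ``HC1`` — angle(H1, C); ``HC2`` — angle(H2, C),
* ``LC1`` — angle(L1, -C); ``LC2`` — angle(L2, -C), all in [0, 180].

The elbow angle is the angle between the VH<->VL and CH1<->CL pseudo-twofold
axes.  Axes are sign-oriented with a fixed handedness rule (see
:func:`elbow_angle`) chosen so that the idealized straight assembly reads
180 degrees, and a triple-product test selects the reflex branch so values
above 180 degrees are representable.  All outputs are invariant under global
rigid transforms of the assembly.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import CoverageError, DegenerateGeometryError, InsufficientDataError
from .reference import default_reference
from .structure_io import FabModel, ResidueID
from .synth_fixtures import ReferenceDomain


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, applied as ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-9:
            raise ValueError("rotation must be orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: ``x -> self(other(x))``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def random(cls, rng: np.random.Generator) -> "RigidTransform":
        return cls(Rotation.random(rng=rng).as_matrix(), rng.uniform(-50, 50, 3))


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares proper superposition of ``mobile`` onto ``target``.

    Returns the transform and the post-fit (weighted) RMSD in Angstrom.  The
    reflection branch of the SVD solution is corrected so det(R) = +1.
    Degenerate (collinear or coincident) point sets raise
    :class:`DegenerateGeometryError`.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points to superpose")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be a non-negative N-vector")
        w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    tc = (w[:, None] * target).sum(axis=0)
    m0 = mobile - mc
    t0 = target - tc
    H = (m0 * w[:, None]).T @ t0
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 means the points are collinear/coincident: rotation not unique
    if S[1] <= max(1e-12 * max(S[0], 1.0), 1e-300):
        raise DegenerateGeometryError("point set is rank-deficient (collinear?)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = tc - R @ mc
    diff = m0 @ R.T - t0
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    return RigidTransform(R, t), rmsd


@dataclasses.dataclass(frozen=True)
class DomainFrame:
    """A domain-attached frame: origin plus two orthonormal unit vectors."""

    origin: np.ndarray
    v1: np.ndarray
    v2: np.ndarray

    def __post_init__(self):
        for v in (self.v1, self.v2):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("frame vectors must be unit length")
        if abs(float(np.dot(self.v1, self.v2))) > 1e-9:
            raise ValueError("frame vectors must be orthogonal")


PositionLike = tuple[int, str | None]


def _position_of(key) -> PositionLike:
    if isinstance(key, ResidueID):
        return key.position
    if isinstance(key, int):
        return (key, None)
    num, icode = key
    return (int(num), icode or None)


def fit_domain_frame(
    domain_calphas: Mapping,
    coreset: Sequence[PositionLike] | None = None,
    reference: ReferenceDomain | None = None,
    min_coverage: float = 0.8,
) -> DomainFrame:
    """Register the packaged reference onto observed C-alphas and return the
    transformed frame.

    ``domain_calphas`` maps residue identifiers (or bare Chothia positions) to
    coordinates.  Coreset positions missing from the observation are dropped
    pairwise; below ``min_coverage`` a :class:`CoverageError` is raised listing
    the missing positions.
    """
    ref = reference if reference is not None else default_reference()
    core = [_position_of(p) for p in (coreset if coreset is not None else ref.coreset)]
    ref_by_pos = {pos: ref.coords[i] for i, pos in enumerate(ref.positions)}
    obs_by_pos = {_position_of(k): np.asarray(v, float) for k, v in domain_calphas.items()}

    mobile, target, missing = [], [], []
    for pos in core:
        if pos in obs_by_pos and pos in ref_by_pos:
            mobile.append(ref_by_pos[pos])
            target.append(obs_by_pos[pos])
        else:
            missing.append(pos)
    coverage = len(mobile) / len(core) if core else 0.0
    if coverage < min_coverage:
        raise CoverageError(
            f"coreset coverage {coverage:.0%} below {min_coverage:.0%}; "
            f"missing positions: {missing}",
            missing=missing,
        )
    transform, _ = kabsch_superpose(np.array(mobile), np.array(target))
    R = transform.rotation
    return DomainFrame(
        origin=transform.apply(ref.origin),
        v1=R @ ref.v1,
        v2=R @ ref.v2,
    )


@dataclasses.dataclass(frozen=True)
class OrientationAngles:
    """Six VH-VL pairing parameters: one torsion, four tilts, one distance."""

    HL: float   # degrees, (-180, 180]
    HC1: float  # degrees, [0, 180]
    HC2: float
    LC1: float
    LC2: float
    dc: float   # Angstrom

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    FEATURES = ("HL", "HC1", "HC2", "LC1", "LC2", "dc")


def signed_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("dihedral undefined: collinear points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    return math.degrees(math.atan2(y, x))


def angle_between(a, b) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise DegenerateGeometryError("angle undefined for zero vector")
    return math.degrees(math.acos(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)))


def vhvl_orientation(
    fab: FabModel,
    model_index: int = 0,
    reference: ReferenceDomain | None = None,
) -> OrientationAngles:
    """Compute the six VH-VL orientation parameters for one model."""
    frame_h = fit_domain_frame(fab.calpha_map("VH", model_index), reference=reference)
    frame_l = fit_domain_frame(fab.calpha_map("VL", model_index), reference=reference)
    C = frame_l.origin - frame_h.origin
    dc = float(np.linalg.norm(C))
    if dc < 1e-9:
        raise DegenerateGeometryError("VH and VL frame origins coincide")
    return OrientationAngles(
        HL=signed_dihedral(
            frame_h.origin + frame_h.v1,
            frame_h.origin,
            frame_l.origin,
            frame_l.origin + frame_l.v1,
        ),
        HC1=angle_between(frame_h.v1, C),
        HC2=angle_between(frame_h.v2, C),
        LC1=angle_between(frame_l.v1, -C),
        LC2=angle_between(frame_l.v2, -C),
        dc=dc,
    )


@dataclasses.dataclass(frozen=True)
class DyadResult:
    """Pseudo-twofold axis between two homologous domains."""

    axis: np.ndarray       # unit vector (sign arbitrary at this level)
    angle: float           # rotation magnitude in degrees
    warning: bool          # True when the rotation is far from a twofold


def _paired_coords(calphas_a: Mapping, calphas_b: Mapping, pairing=None):
    a_by_pos = {_position_of(k): np.asarray(v, float) for k, v in calphas_a.items()}
    b_by_pos = {_position_of(k): np.asarray(v, float) for k, v in calphas_b.items()}
    if pairing is None:
        shared = [p for p in a_by_pos if p in b_by_pos]
        pairs = [(p, p) for p in shared]
    else:
        pairs = [(_position_of(pa), _position_of(pb)) for pa, pb in pairing]
        pairs = [(pa, pb) for pa, pb in pairs if pa in a_by_pos and pb in b_by_pos]
    if len(pairs) < 10:
        raise InsufficientDataError(
            f"pseudo-dyad needs >= 10 paired positions, got {len(pairs)}"
        )
    A = np.array([a_by_pos[pa] for pa, _ in pairs])
    B = np.array([b_by_pos[pb] for _, pb in pairs])
    return A, B


def pseudo_dyad(calphas_a: Mapping, calphas_b: Mapping, pairing=None) -> DyadResult:
    """Axis and magnitude of the rotation superposing domain A onto domain B.

    By default positions with identical (number, insertion-code) are paired;
    an explicit pairing table of (pos_a, pos_b) tuples overrides this.  For a
    true pseudo-twofold the magnitude is close to 180 degrees; below 90 the
    ``warning`` flag is set (the pairing is probably wrong).
    """
    A, B = _paired_coords(calphas_a, calphas_b, pairing)
    transform, _ = kabsch_superpose(A, B)
    rotvec = Rotation.from_matrix(transform.rotation).as_rotvec()
    angle = math.degrees(float(np.linalg.norm(rotvec)))
    if angle < 1e-9:
        axis = np.array([1.0, 0.0, 0.0])
    else:
        axis = rotvec / np.linalg.norm(rotvec)
    return DyadResult(axis=axis, angle=angle, warning=angle < 90.0)


def elbow_angle(
    fab: FabModel,
    model_index: int = 0,
    pairing_v=None,
    pairing_c=None,
) -> float:
    """Fab elbow angle in degrees, in (0, 360).

    Let ``v`` and ``c`` be the VH<->VL and CH1<->CL pseudo-dyad axes, ``u``
    the unit vector from the variable-module C-alpha centroid to the
    constant-module centroid, and ``r = u x (o_VL - o_VH)`` (domain centroids).
    Axes are sign-oriented so that ``v . r >= 0`` and ``c . (-r) >= 0``; then
    ``theta = arccos(v . c)`` and the reported value is ``theta`` when
    ``(v x c) . u >= 0`` and ``360 - theta`` otherwise.  The orientation rule
    makes the idealized straight assembly read exactly 180 degrees and keeps
    the value continuous through it.
    """
    for dom in ("VH", "VL", "CH1", "CL"):
        if dom not in fab.domains:
            raise InsufficientDataError(f"elbow angle requires domain {dom}")
    ca = {dom: fab.calpha_map(dom, model_index) for dom in ("VH", "VL", "CH1", "CL")}
    dyad_v = pseudo_dyad(ca["VH"], ca["VL"], pairing_v)
    dyad_c = pseudo_dyad(ca["CH1"], ca["CL"], pairing_c)

    def centroid(*doms):
        pts = np.concatenate([np.array(list(ca[d].values())) for d in doms])
        return pts.mean(axis=0)

    o_vh = centroid("VH")
    o_vl = centroid("VL")
    u = centroid("CH1", "CL") - centroid("VH", "VL")
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise DegenerateGeometryError("module centroids coincide")
    u = u / nu
    r = np.cross(u, o_vl - o_vh)
    nr = np.linalg.norm(r)
    if nr < 1e-9:
        raise DegenerateGeometryError(
            "VH->VL axis parallel to the module axis; elbow sign undefined"
        )
    r = r / nr
    v = dyad_v.axis if float(np.dot(dyad_v.axis, r)) >= 0 else -dyad_v.axis
    c = dyad_c.axis if float(np.dot(dyad_c.axis, -r)) >= 0 else -dyad_c.axis
    theta = math.degrees(math.acos(float(np.clip(np.dot(v, c), -1.0, 1.0))))
    if float(np.dot(np.cross(v, c), u)) >= 0:
        return theta
    return 360.0 - theta
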