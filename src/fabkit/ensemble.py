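"""Trajectory-level analytics over multi-model structures: alignment, RMSD
series, per-residue RMSF, coordinate PCA, and per-snapshot feature series.

Trajectory snapshots are the models of a multi-model structure.  The analysis
window is given as fractions of the trajectory, default ``(0.5, 1.0)`` —
conformational statistics are taken over the equilibrated second half of a run
by default, and the window is configurable per call.  A simple RMSD-plateau
diagnostic is provided for convergence screening; snapshots are never dropped
silently.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FabkitError, InsufficientDataError, RosterError
from .geometry import OrientationAngles, elbow_angle, kabsch_superpose, vhvl_orientation
from .interfaces import ELBOW, VH_VL, InterfaceSpec, buried_asa
from .structure_io import FabModel, ResidueID, Structure

DEFAULT_WINDOW = (0.5, 1.0)


def window_indices(n_models: int, window: tuple[float, float] = DEFAULT_WINDOW) -> list[int]:
    """Model indices selected by a (start_fraction, end_fraction) window."""
    start, end = window
    if not (0.0 <= start < end <= 1.0):
        raise ValueError("window must satisfy 0 <= start < end <= 1")
    return list(range(int(round(start * n_models)), int(round(end * n_models))))


def _selection_ca_indices(structure: Structure, selection: Iterable[ResidueID]) -> np.ndarray:
    idx = []
    missing = []
    for rid in selection:
        try:
            idx.append(structure.atom_index(rid, "CA"))
        except RosterError:
            missing.append(str(rid))
    if missing:
        raise RosterError(f"selection C-alphas missing from roster: {missing[:10]}")
    if len(idx) < 3:
        raise InsufficientDataError("selection must contain at least 3 residues")
    return np.array(sorted(idx), dtype=int)


def align_trajectory(
    structure: Structure,
    selection: Iterable[ResidueID],
    reference_model: int = 0,
) -> tuple[Structure, np.ndarray]:
    """Superpose every model onto a reference via Kabsch on selection C-alphas.

    Returns the aligned structure and the per-model post-fit RMSD series (the
    reference model's entry is 0 by construction).
    """
    ca = _selection_ca_indices(structure, selection)
    target = structure.coords[reference_model][ca]
    aligned = np.empty_like(structure.coords)
    rmsd = np.empty(structure.n_models)
    for m in range(structure.n_models):
        transform, r = kabsch_superpose(structure.coords[m][ca], target)
        aligned[m] = transform.apply(structure.coords[m])
        rmsd[m] = r
    return structure.with_coords(aligned), rmsd


@dataclasses.dataclass
class ConvergenceDiagnostic:
    """Sliding-window drift of the RMSD series (a screening aid, not a gate)."""

    drift: float          # |mean(last window) - mean(previous window)|, Angstrom
    threshold: float
    plateaued: bool


def rmsd_plateau(
    rmsd_series: np.ndarray, window_fraction: float = 0.25, threshold: float = 0.5
) -> ConvergenceDiagnostic:
    """Check whether the tail of an RMSD series has stopped drifting."""
    series = np.asarray(rmsd_series, float)
    w = max(2, int(len(series) * window_fraction))
    if len(series) < 2 * w:
        raise InsufficientDataError("series too short for the plateau diagnostic")
    drift = abs(float(series[-w:].mean() - series[-2 * w : -w].mean()))
    return ConvergenceDiagnostic(drift=drift, threshold=threshold, plateaued=drift < threshold)


def rmsf(
    aligned: Structure,
    selection: Iterable[ResidueID],
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> dict[ResidueID, float]:
    """Per-residue C-alpha root-mean-square fluctuation over the window.

    ``sqrt(mean_t |r_t - r_mean|^2)`` per residue, on an already aligned
    trajectory.
    """
    selection = list(selection)
    ca = _selection_ca_indices(aligned, selection)
    models = window_indices(aligned.n_models, window)
    if len(models) < 2:
        raise InsufficientDataError("RMSF needs at least 2 models in the window")
    X = aligned.coords[np.ix_(models, ca)]
    mean = X.mean(axis=0)
    sq = ((X - mean) ** 2).sum(axis=2).mean(axis=0)
    values = np.sqrt(sq)
    order = {aligned.sites[i].residue: k for k, i in enumerate(ca)}
    return {rid: float(values[order[rid]]) for rid in sorted(order, key=lambda r: r.sort_key)}


def rmsf_to_frame(profile: dict[ResidueID, float]) -> pd.DataFrame:
    rows = [
        {"chain": rid.chain_id, "resnum": rid.number, "icode": rid.insertion_code or "", "rmsf": v}
        for rid, v in profile.items()
    ]
    return pd.DataFrame(rows, columns=["chain", "resnum", "icode", "rmsf"])


@dataclasses.dataclass
class PcaResult:
    """Eigendecomposition of the 3N C-alpha coordinate covariance."""

    eigenvalues: np.ndarray        # Angstrom^2, descending
    components: np.ndarray         # (k, 3N), orthonormal rows
    projections: np.ndarray        # (n_window_models, k)
    variance_fractions: np.ndarray

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def pca(
    aligned: Structure,
    selection: Iterable[ResidueID],
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> PcaResult:
    """PCA of aligned C-alpha coordinates over the analysis window.

    The population covariance is used, so the eigenvalue sum equals the total
    coordinate variance of the windowed trajectory exactly.
    """
    ca = _selection_ca_indices(aligned, selection)
    models = window_indices(aligned.n_models, window)
    if len(models) < 3:
        raise InsufficientDataError("PCA needs at least 3 models in the window")
    X = aligned.coords[np.ix_(models, ca)].reshape(len(models), -1)
    Xc = X - X.mean(axis=0)
    _u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / len(models)
    total = float(eigenvalues.sum())
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return PcaResult(
        eigenvalues=eigenvalues,
        components=vt,
        projections=Xc @ vt.T,
        variance_fractions=fractions,
    )


# --- per-snapshot feature extraction ---------------------------------------


@dataclasses.dataclass
class FeatureSeries:
    """Ordered per-model values of one named feature."""

    name: str
    values: np.ndarray
    units: str
    window: tuple[float, float]
    model_indices: list[int]

    def __len__(self):
        return len(self.values)


_ANGLE_FEATURES = ("HL", "HC1", "HC2", "LC1", "LC2")


def _feature_units(name: str) -> str:
    if name in _ANGLE_FEATURES or name == "elbow":
        return "degrees"
    if name == "dc":
        return "Angstrom"
    if name.startswith("bASA:"):
        return "Angstrom^2"
    return ""


def _interface_for(tag: str) -> InterfaceSpec:
    if tag == "VH-VL":
        return VH_VL
    if tag == "elbow":
        return ELBOW
    raise ValueError(f"unknown interface tag {tag!r} (use 'VH-VL' or 'elbow')")


def feature_series_multi(
    fab: FabModel,
    features: Sequence[str],
    window: tuple[float, float] = DEFAULT_WINDOW,
    custom: dict[str, Callable[[FabModel, int], float]] | None = None,
) -> dict[str, FeatureSeries]:
    """Compute several per-snapshot features in one pass over the window.

    Feature names: the six orientation parameters (``HL``, ``HC1``, ``HC2``,
    ``LC1``, ``LC2``, ``dc``), ``elbow``, ``bASA:VH-VL`` / ``bASA:elbow``,
    or any key of ``custom`` mapping to a callable ``f(fab, model_index)``.
    Errors from underlying operations are re-raised with the model index
    attached.
    """
    custom = custom or {}
    models = window_indices(fab.structure.n_models, window)
    if not models:
        raise InsufficientDataError("analysis window selects no models")
    wants_orientation = any(f in OrientationAngles.FEATURES for f in features)
    out: dict[str, list[float]] = {f: [] for f in features}
    for m in models:
        try:
            angles = vhvl_orientation(fab, m) if wants_orientation else None
            for f in features:
                if f in OrientationAngles.FEATURES:
                    out[f].append(getattr(angles, f))
                elif f == "elbow":
                    out[f].append(elbow_angle(fab, m))
                elif f.startswith("bASA:"):
                    out[f].append(buried_asa(fab, _interface_for(f[5:]), m))
                elif f in custom:
                    out[f].append(float(custom[f](fab, m)))
                else:
                    raise ValueError(f"unknown feature {f!r}")
        except FabkitError as exc:
            raise type(exc)(f"model {m}: {exc}") from exc
    return {
        f: FeatureSeries(
            name=f,
            values=np.array(vals),
            units=_feature_units(f),
            window=window,
            model_indices=models,
        )
        for f, vals in out.items()
    }


def feature_series(
    fab: FabModel,
    feature: str,
    window: tuple[float, float] = DEFAULT_WINDOW,
    custom: dict[str, Callable[[FabModel, int], float]] | None = None,
) -> FeatureSeries:
    """Per-snapshot series of one feature (see :func:`feature_series_multi`)."""
    return feature_series_multi(fab, [feature], window, custom)[feature]


def series_to_frame(series: dict[str, FeatureSeries]) -> pd.DataFrame:
    """Tabulate feature series as one column per feature plus model_index."""
    if not series:
        raise ValueError("no series given")
    first = next(iter(series.values()))
    data = {"model_index": first.model_indices}
    for name, s in series.items():
        if s.model_indices != first.model_indices:
            raise ValueError("series cover different windows")
        data[name] = s.values
    return pd.DataFrame(data)
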