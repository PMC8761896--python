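"""Non-redundant structure-set construction and interface position profiling.

A batch of Fab structures is annotated (orientation, elbow, interface burial,
contact counts, interface positions), de-duplicated by exact variable-domain
sequence identity, and profiled: for each Chothia position, the fraction of
structures in which that position is an interface residue.  Gene origin and
somatic-hypermutation level are accepted as pass-through metadata columns —
they are never computed here.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FabkitError, InsufficientDataError
from .geometry import OrientationAngles, elbow_angle, vhvl_orientation
from .interfaces import ELBOW, VH_VL, detect_hbonds, detect_saltbridges, interface_residues
from .structure_io import FabModel, extract_sequence

PositionLike = tuple[int, str | None]


@dataclasses.dataclass
class AnnotationRecord:
    """Per-structure feature annotation (fields are None when not computable)."""

    identifier: str
    vh_sequence: str
    vl_sequence: str
    vh_positions: list[PositionLike]
    vl_positions: list[PositionLike]
    light_isotype: str = "unspecified"
    orientation: OrientationAngles | None = None
    elbow: float | None = None
    basa_vhvl: float | None = None
    basa_elbow: float | None = None
    n_hbonds_vhvl: int | None = None
    n_saltbridges_elbow: int | None = None
    interface_positions_vh: list[PositionLike] | None = None
    interface_positions_vl: list[PositionLike] | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def residue_at(self, side: str, position: PositionLike) -> str | None:
        """One-letter residue at a Chothia position, or None if absent."""
        positions = self.vh_positions if side == "VH" else self.vl_positions
        seq = self.vh_sequence if side == "VH" else self.vl_sequence
        key = (int(position[0]), position[1] or None)
        for i, pos in enumerate(positions):
            if pos == key:
                return seq[i]
        return None


def annotate_structure(
    fab: FabModel,
    identifier: str,
    min_delta: float = 0.1,
    n_points: int = 960,
    metadata: Mapping | None = None,
) -> AnnotationRecord:
    """Single-model (model 0) feature annotation of one Fab.

    Elbow-related fields stay None for Fv-only inputs; per-field computation
    errors are recorded as None rather than aborting a batch.
    """
    record = AnnotationRecord(
        identifier=identifier,
        vh_sequence=extract_sequence(fab, "VH"),
        vl_sequence=extract_sequence(fab, "VL"),
        vh_positions=[rid.position for rid in fab.domain_residues("VH")],
        vl_positions=[rid.position for rid in fab.domain_residues("VL")],
        light_isotype=fab.domain_map.light_isotype,
        metadata=dict(metadata or {}),
    )
    if not record.vh_sequence or not record.vl_sequence:
        raise InsufficientDataError(f"{identifier}: empty variable-domain sequence")

    def attempt(label, fn):
        try:
            return fn()
        except FabkitError as exc:
            warnings.warn(f"{identifier}: {label} not computed ({exc})", stacklevel=3)
            return None

    record.orientation = attempt("orientation", lambda: vhvl_orientation(fab, 0))
    record.basa_vhvl = attempt(
        "bASA(VH-VL)", lambda: _basa(fab, VH_VL, n_points)
    )
    record.n_hbonds_vhvl = attempt(
        "hbonds(VH-VL)", lambda: len(detect_hbonds(fab, VH_VL, 0))
    )
    vhvl_res = attempt(
        "interface residues",
        lambda: interface_residues(fab, VH_VL, 0, min_delta, n_points=n_points),
    )
    if vhvl_res is not None:
        record.interface_positions_vh = [r.position for r in vhvl_res[0]]
        record.interface_positions_vl = [r.position for r in vhvl_res[1]]
    if fab.domain_map.has_constant_domains:
        record.elbow = attempt("elbow angle", lambda: elbow_angle(fab, 0))
        record.basa_elbow = attempt("bASA(elbow)", lambda: _basa(fab, ELBOW, n_points))
        record.n_saltbridges_elbow = attempt(
            "saltbridges(elbow)", lambda: len(detect_saltbridges(fab, ELBOW, 0))
        )
    return record


def _basa(fab, spec, n_points):
    from .interfaces import buried_asa

    return buried_asa(fab, spec, 0, n_points=n_points)


# --- deduplication -----------------------------------------------------------


def dedup_by_sequence(
    records: Iterable[AnnotationRecord],
) -> tuple[list[AnnotationRecord], dict[str, list[str]]]:
    """Collapse records with identical concatenated VH+VL sequences.

    Grouping is by exact case-normalized string identity.  The representative
    of each cluster is the record with the lexicographically smallest
    identifier, the unique list is sorted by representative identifier, and
    the cluster map lists every member per representative.  Records without
    sequences are skipped with a warning.
    """
    clusters: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        if not rec.vh_sequence or not rec.vl_sequence:
            warnings.warn(f"{rec.identifier}: missing sequence, skipped in dedup")
            continue
        key = (rec.vh_sequence + rec.vl_sequence).upper()
        clusters.setdefault(key, []).append(rec)
    unique: list[AnnotationRecord] = []
    cluster_map: dict[str, list[str]] = {}
    for members in clusters.values():
        members = sorted(members, key=lambda r: r.identifier)
        unique.append(members[0])
        cluster_map[members[0].identifier] = [r.identifier for r in members]
    unique.sort(key=lambda r: r.identifier)
    return unique, cluster_map


# --- interface position profiling -------------------------------------------


@dataclasses.dataclass
class PositionFrequencyProfile:
    """Per-position interface frequency over a record set."""

    side: str
    frequencies: dict[PositionLike, float]   # every observed position
    reported: dict[PositionLike, float]      # only those >= min_report
    n_records: int
    min_report: float
    delta_threshold_note: str = "interface membership: ASA drop > min_delta (see interfaces module)"

    def to_frame(self, reported_only: bool = True) -> pd.DataFrame:
        src = self.reported if reported_only else self.frequencies
        rows = [
            {
                "position": f"{num}{icode or ''}",
                "frequency": freq,
                "count": int(round(freq * self.n_records)),
            }
            for (num, icode), freq in sorted(src.items(), key=lambda kv: (kv[0][0], kv[0][1] or ""))
        ]
        return pd.DataFrame(rows, columns=["position", "frequency", "count"])


def position_frequencies(
    records: Sequence[AnnotationRecord],
    side: str = "VH",
    min_report: float = 0.01,
) -> PositionFrequencyProfile:
    """Fraction of records in which each Chothia position is at the interface.

    Positions below ``min_report`` are omitted from the reported table but
    retained in the raw frequencies.  Records lacking interface annotation
    for the side are excluded from the denominator.
    """
    if side not in ("VH", "VL"):
        raise ValueError("side must be 'VH' or 'VL'")
    attr = "interface_positions_vh" if side == "VH" else "interface_positions_vl"
    annotated = [r for r in records if getattr(r, attr) is not None]
    if not annotated:
        raise InsufficientDataError("no records with interface annotation")
    counts: dict[PositionLike, int] = {}
    for rec in annotated:
        for pos in getattr(rec, attr):
            key = (int(pos[0]), pos[1] or None)
            counts[key] = counts.get(key, 0) + 1
    n = len(annotated)
    frequencies = {pos: c / n for pos, c in counts.items()}
    reported = {pos: f for pos, f in frequencies.items() if f >= min_report}
    return PositionFrequencyProfile(
        side=side,
        frequencies=frequencies,
        reported=reported,
        n_records=n,
        min_report=min_report,
    )


# --- stratification ----------------------------------------------------------


def has_position_pair(
    vh: tuple[PositionLike | int, str],
    vl: tuple[PositionLike | int, str],
) -> Callable[[AnnotationRecord], str]:
    """Predicate factory: does a record carry given residues at two positions?

    ``vh``/``vl`` are (Chothia position, one-letter amino acid); e.g.
    ``has_position_pair((39, "Q"), (38, "Q"))`` labels records by whether the
    heavy chain has Gln at 39 and the light chain Gln at 38.  Records missing
    either position map to "unspecified".
    """

    def as_pos(p) -> PositionLike:
        return (p, None) if isinstance(p, int) else (int(p[0]), p[1] or None)

    vh_pos, vh_aa = as_pos(vh[0]), vh[1].upper()
    vl_pos, vl_aa = as_pos(vl[0]), vl[1].upper()

    def classify(record: AnnotationRecord) -> str:
        a = record.residue_at("VH", vh_pos)
        b = record.residue_at("VL", vl_pos)
        if a is None or b is None:
            return "unspecified"
        return "present" if (a.upper() == vh_aa and b.upper() == vl_aa) else "absent"

    return classify


def stratify(
    records: Sequence[AnnotationRecord],
    key: str | Callable[[AnnotationRecord], str] = "light_isotype",
) -> dict[str, list[AnnotationRecord]]:
    """Partition records by light-chain isotype or by an arbitrary labeller.

    Unknown/missing labels land in the "unspecified" bucket.  The partitions
    feed directly into :mod:`fabkit.stats_compare` via
    :func:`records_to_series`.
    """
    if isinstance(key, str):
        if key != "light_isotype":
            raise ValueError("string keys: only 'light_isotype' is built in")
        labeller = lambda r: r.light_isotype or "unspecified"  # noqa: E731
    else:
        labeller = key
    partitions: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        label = labeller(rec) or "unspecified"
        partitions.setdefault(label, []).append(rec)
    return partitions


def records_to_series(
    records: Sequence[AnnotationRecord],
    features: Sequence[str] = OrientationAngles.FEATURES + ("elbow",),
) -> dict[str, np.ndarray]:
    """Extract numeric feature arrays from annotated records.

    Records lacking a value for a feature are skipped for that feature, so
    array lengths can differ between features.
    """
    out: dict[str, list[float]] = {f: [] for f in features}
    for rec in records:
        for f in features:
            if f in OrientationAngles.FEATURES:
                if rec.orientation is not None:
                    out[f].append(getattr(rec.orientation, f))
            elif f == "elbow":
                if rec.elbow is not None:
                    out[f].append(rec.elbow)
            elif f == "bASA:VH-VL":
                if rec.basa_vhvl is not None:
                    out[f].append(rec.basa_vhvl)
            elif f == "bASA:elbow":
                if rec.basa_elbow is not None:
                    out[f].append(rec.basa_elbow)
            else:
                raise ValueError(f"unknown feature {f!r}")
    return {f: np.array(v) for f, v in out.items()}


# --- tabular I/O --------------------------------------------------------------


def _positions_to_str(positions) -> str:
    if positions is None:
        return ""
    return ",".join(f"{num}{icode or ''}" for num, icode in positions)


def _positions_from_str(text: str):
    if not isinstance(text, str) or not text:
        return None
    out = []
    for token in text.split(","):
        num = "".join(ch for ch in token if ch.isdigit() or ch == "-")
        icode = token[len(num):] or None
        out.append((int(num), icode))
    return out


def records_to_frame(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """One row per record; nulls as empty cells; metadata as extra columns."""
    rows = []
    for r in records:
        row = {
            "identifier": r.identifier,
            "vh_sequence": r.vh_sequence,
            "vl_sequence": r.vl_sequence,
            "vh_positions": _positions_to_str(r.vh_positions),
            "vl_positions": _positions_to_str(r.vl_positions),
            "light_isotype": r.light_isotype,
            "elbow": r.elbow,
            "basa_vhvl": r.basa_vhvl,
            "basa_elbow": r.basa_elbow,
            "n_hbonds_vhvl": r.n_hbonds_vhvl,
            "n_saltbridges_elbow": r.n_saltbridges_elbow,
            "interface_positions_vh": _positions_to_str(r.interface_positions_vh),
            "interface_positions_vl": _positions_to_str(r.interface_positions_vl),
        }
        for name in OrientationAngles.FEATURES:
            row[name] = getattr(r.orientation, name) if r.orientation else None
        row.update(r.metadata)
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(records: Sequence[AnnotationRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_dataset(path) -> list[AnnotationRecord]:
    """Read a dataset TSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    known = {
        "identifier", "vh_sequence", "vl_sequence", "vh_positions", "vl_positions",
        "light_isotype", "elbow", "basa_vhvl", "basa_elbow", "n_hbonds_vhvl",
        "n_saltbridges_elbow", "interface_positions_vh", "interface_positions_vl",
    } | set(OrientationAngles.FEATURES)
    records = []
    for _, row in df.iterrows():
        orient = None
        if all(pd.notna(row.get(f)) for f in OrientationAngles.FEATURES):
            orient = OrientationAngles(**{f: float(row[f]) for f in OrientationAngles.FEATURES})
        records.append(
            AnnotationRecord(
                identifier=str(row["identifier"]),
                vh_sequence=str(row["vh_sequence"]),
                vl_sequence=str(row["vl_sequence"]),
                vh_positions=_positions_from_str(row.get("vh_positions", "")) or [],
                vl_positions=_positions_from_str(row.get("vl_positions", "")) or [],
                light_isotype=str(row.get("light_isotype", "unspecified")),
                orientation=orient,
                elbow=float(row["elbow"]) if pd.notna(row.get("elbow")) else None,
                basa_vhvl=float(row["basa_vhvl"]) if pd.notna(row.get("basa_vhvl")) else None,
                basa_elbow=float(row["basa_elbow"]) if pd.notna(row.get("basa_elbow")) else None,
                n_hbonds_vhvl=int(row["n_hbonds_vhvl"]) if pd.notna(row.get("n_hbonds_vhvl")) else None,
                n_saltbridges_elbow=int(row["n_saltbridges_elbow"])
                if pd.notna(row.get("n_saltbridges_elbow"))
                else None,
                interface_positions_vh=_positions_from_str(row.get("interface_positions_vh", "")),
                interface_positions_vl=_positions_from_str(row.get("interface_positions_vl", "")),
                metadata={k: row[k] for k in df.columns if k not in known},
            )
        )
    return records


def records_from_fasta_pairs(
    vh_fasta: Mapping[str, str], vl_fasta: Mapping[str, str]
) -> list[AnnotationRecord]:
    """Sequence-only records from paired FASTA dicts (for dedup workflows)."""
    shared = sorted(set(vh_fasta) & set(vl_fasta))
    return [
        AnnotationRecord(
            identifier=name,
            vh_sequence=vh_fasta[name],
            vl_sequence=vl_fasta[name],
            vh_positions=[(i + 1, None) for i in range(len(vh_fasta[name]))],
            vl_positions=[(i + 1, None) for i in range(len(vl_fasta[name]))],
        )
        for name in shared
    ]
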