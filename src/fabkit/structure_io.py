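"""Structure reading/writing and the four-domain Fab data model.

Coordinates are Angstrom throughout.  PDB is the canonical dialect (multi-model
via MODEL/ENDMDL); mmCIF is read through the same interface.  Residue numbering
is taken verbatim from the file — Chothia numbering with insertion codes is
assumed for antibody chains and the toolkit never renumbers.

The in-memory model keeps one shared atom roster (:class:`AtomSite` list) and a
``(n_models, n_atoms, 3)`` coordinate array, which is the natural layout for
trajectory snapshots stored as multi-model files.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .errors import (
    DomainResolutionError,
    FormatError,
    MissingChainError,
    RosterError,
)
from .tables import vdw_radius

DOMAIN_NAMES = ("VH", "VL", "CH1", "CL")
VARIABLE_DOMAINS = ("VH", "VL")


@dataclasses.dataclass(frozen=True, order=True)
class ResidueID:
    """Chain + Chothia position + optional insertion code (e.g. 103a)."""

    chain_id: str
    number: int
    insertion_code: str | None = None

    @property
    def sort_key(self):
        return (self.chain_id, self.number, self.insertion_code or "")

    @property
    def position(self) -> tuple[int, str | None]:
        """Position without the chain — the key used by coreset/pairing tables."""
        return (self.number, self.insertion_code)

    def __str__(self):
        return f"{self.chain_id}{self.number}{self.insertion_code or ''}"


@dataclasses.dataclass(frozen=True)
class AtomSite:
    """One atom of the shared roster (coordinates live in Structure.coords)."""

    residue: ResidueID
    res_name: str
    atom_name: str
    element: str
    occupancy: float
    vdw_radius: float
    hetero: bool = False

    @property
    def key(self):
        return (self.residue, self.atom_name)


class Structure:
    """Multi-model atomic coordinates over a single shared atom roster."""

    def __init__(self, sites: list[AtomSite], coords: np.ndarray, metadata=None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if coords.shape[1] != len(sites):
            raise ValueError("coords second axis must match number of sites")
        if coords.shape[0] < 1:
            raise ValueError("a Structure needs at least one model")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.sites = list(sites)
        self.coords = coords
        self.metadata = dict(metadata or {})
        self._index = {s.key: i for i, s in enumerate(self.sites)}
        if len(self._index) != len(self.sites):
            raise RosterError("duplicate (residue, atom_name) in atom roster")

    # -- basic introspection -------------------------------------------------
    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def model_coords(self, model_index: int) -> np.ndarray:
        return self.coords[model_index]

    def atom_index(self, residue: ResidueID, atom_name: str) -> int:
        try:
            return self._index[(residue, atom_name)]
        except KeyError:
            raise RosterError(f"atom {residue}:{atom_name} not in roster") from None

    def residues(self, chain_id: str | None = None) -> list[ResidueID]:
        """Unique residues in roster order, optionally limited to one chain."""
        seen: dict[ResidueID, None] = {}
        for s in self.sites:
            if chain_id is None or s.residue.chain_id == chain_id:
                seen.setdefault(s.residue, None)
        return list(seen)

    def chain_ids(self) -> list[str]:
        out: dict[str, None] = {}
        for s in self.sites:
            out.setdefault(s.residue.chain_id, None)
        return list(out)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.sites, coords, self.metadata)


# --- reading ----------------------------------------------------------------

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by file order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of the winners
    winners = set(id(a) for a in best.values())
    return [a for a in residue if id(a) in winners]


def read_structure(
    path: str | Path,
    format: str = "auto",
    include_hetero: bool = False,
    include_waters: bool = False,
) -> Structure:
    """Read a single- or multi-model PDB/mmCIF file.

    Waters and hetero compounds are excluded by default; altlocs are resolved
    to the highest-occupancy conformer (ties: first in file).  All models must
    share an identical atom roster or a :class:`RosterError` is raised.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}")
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")

    sites: list[AtomSite] = []
    rosters: list[list[tuple]] = []
    model_coords: list[list[list[float]]] = []
    for model in st:
        roster: list[tuple] = []
        xyz: list[list[float]] = []
        for chain in model:
            for residue in chain:
                is_water = residue.is_water()
                is_het = residue.het_flag == "H" and not is_water
                if is_water and not include_waters:
                    continue
                if is_het and not include_hetero:
                    continue
                rid = ResidueID(
                    chain.name,
                    residue.seqid.num,
                    (residue.seqid.icode.strip().lower() or None),
                )
                for atom in _resolve_altlocs(residue):
                    roster.append((rid, residue.name, atom.name))
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    if len(rosters) == 0:
                        sites.append(
                            AtomSite(
                                residue=rid,
                                res_name=residue.name,
                                atom_name=atom.name,
                                element=atom.element.name,
                                occupancy=float(atom.occ),
                                vdw_radius=vdw_radius(atom.element.name),
                                hetero=is_het or is_water,
                            )
                        )
        rosters.append(roster)
        model_coords.append(xyz)

    ref = rosters[0]
    for i, roster in enumerate(rosters[1:], start=2):
        if roster != ref:
            a, b = set(ref), set(roster)
            offending = sorted(
                f"{rid}:{atom}" for rid, _res, atom in (a ^ b)
            )
            raise RosterError(
                f"{path}: model {i} atom roster differs from model 1; "
                f"offending atoms: {', '.join(offending[:20])}"
            )
    coords = np.array(model_coords, dtype=float)
    return Structure(sites, coords, metadata={"source": str(path), "format": format})


# --- writing ----------------------------------------------------------------


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a (multi-model) PDB file; models become MODEL/ENDMDL blocks."""
    st = gemmi.Structure()
    st.name = "fabkit"
    for m in range(structure.n_models):
        model = gemmi.Model(m + 1)
        chains: dict[str, gemmi.Chain] = {}
        cur_res_key = None
        cur_res = None
        for i, site in enumerate(structure.sites):
            cid = site.residue.chain_id
            if cid not in chains:
                chains[cid] = gemmi.Chain(cid)
                model.add_chain(chains[cid])
                cur_res_key = None
            key = (cid, site.residue.number, site.residue.insertion_code)
            if key != cur_res_key:
                res = gemmi.Residue()
                res.name = site.res_name
                res.seqid = gemmi.SeqId(
                    site.residue.number, (site.residue.insertion_code or " ").upper()
                )
                res.het_flag = "H" if site.hetero else "A"
                # gemmi copies residues on add; fetch the live reference back
                chain = model[cid]
                chain.add_residue(res)
                cur_res = chain[len(chain) - 1]
                cur_res_key = key
            atom = gemmi.Atom()
            atom.name = site.atom_name
            atom.element = gemmi.Element(site.element)
            atom.occ = site.occupancy
            atom.b_iso = 0.0
            x, y, z = structure.coords[m, i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            cur_res.add_atom(atom)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# --- domain map -------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class DomainRange:
    chain_id: str
    start: int
    end: int  # inclusive Chothia numbers

    def contains(self, rid: ResidueID) -> bool:
        # 103a lies inside [103, 104): any icode on an in-range number counts
        return rid.chain_id == self.chain_id and self.start <= rid.number <= self.end


@dataclasses.dataclass
class DomainMap:
    """Chain + inclusive Chothia residue range per domain (VH/VL required)."""

    domains: dict[str, DomainRange]
    light_isotype: str = "unspecified"

    def __post_init__(self):
        for required in VARIABLE_DOMAINS:
            if required not in self.domains:
                raise ValueError(f"domain map must define {required}")
        for name in self.domains:
            if name not in DOMAIN_NAMES:
                raise ValueError(f"unknown domain name {name!r}")
        if self.light_isotype not in ("kappa", "lambda", "unspecified"):
            raise ValueError(f"bad light_isotype {self.light_isotype!r}")
        by_chain: dict[str, list[DomainRange]] = {}
        for rng in self.domains.values():
            by_chain.setdefault(rng.chain_id, []).append(rng)
        for chain, ranges in by_chain.items():
            ranges = sorted(ranges, key=lambda r: r.start)
            for a, b in zip(ranges, ranges[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping domain ranges on chain {chain}")

    @property
    def has_constant_domains(self) -> bool:
        return "CH1" in self.domains and "CL" in self.domains

    # YAML round trip -- layout:
    # domains: {VH: {chain: H, range: [1, 113]}, ...}
    # light_isotype: kappa
    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        domains = {
            name: DomainRange(str(spec["chain"]), int(spec["range"][0]), int(spec["range"][1]))
            for name, spec in raw["domains"].items()
        }
        return cls(domains, raw.get("light_isotype", "unspecified"))

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "domains": {
                name: {"chain": rng.chain_id, "range": [rng.start, rng.end]}
                for name, rng in sorted(self.domains.items())
            },
            "light_isotype": self.light_isotype,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


class FabModel:
    """A Structure partitioned into VH/VL(/CH1/CL) domain views."""

    MIN_CALPHAS = 20

    def __init__(self, structure: Structure, domain_map: DomainMap):
        self.structure = structure
        self.domain_map = domain_map
        self._atom_indices: dict[str, np.ndarray] = {}
        self._calpha: dict[str, list[tuple[ResidueID, int]]] = {}
        chains = set(structure.chain_ids())
        for name, rng in domain_map.domains.items():
            if rng.chain_id not in chains:
                raise MissingChainError(
                    f"domain {name}: chain {rng.chain_id!r} not present "
                    f"(chains: {sorted(chains)})"
                )
            idx = [
                i for i, s in enumerate(structure.sites) if rng.contains(s.residue)
            ]
            self._atom_indices[name] = np.array(idx, dtype=int)
            ca = [
                (structure.sites[i].residue, i)
                for i in idx
                if structure.sites[i].atom_name == "CA"
            ]
            ca.sort(key=lambda pair: pair[0].sort_key)
            self._calpha[name] = ca
            if len(ca) < self.MIN_CALPHAS:
                raise DomainResolutionError(
                    f"domain {name} resolves only {len(ca)} C-alpha atoms "
                    f"(minimum {self.MIN_CALPHAS})"
                )

    @property
    def domains(self) -> list[str]:
        return list(self._atom_indices)

    def atom_indices(self, *domain_names: str) -> np.ndarray:
        parts = []
        for name in domain_names:
            if name not in self._atom_indices:
                raise KeyError(f"domain {name} not resolved")
            parts.append(self._atom_indices[name])
        return np.concatenate(parts) if parts else np.array([], dtype=int)

    def calpha_map(self, domain: str, model_index: int = 0) -> dict[ResidueID, np.ndarray]:
        """Ordered ResidueID -> C-alpha coordinate map for one model."""
        coords = self.structure.coords[model_index]
        return {rid: coords[i] for rid, i in self._calpha[domain]}

    def domain_residues(self, domain: str) -> list[ResidueID]:
        return [rid for rid, _ in self._calpha[domain]]


def apply_domain_map(structure: Structure, domain_map: DomainMap) -> FabModel:
    """Partition a structure into Fab domains according to the map."""
    return FabModel(structure, domain_map)


# --- sequences --------------------------------------------------------------


def _one_letter(res_name: str) -> str:
    info = gemmi.find_tabulated_residue(res_name.upper())
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def extract_sequence(fab: FabModel, domain: str) -> str:
    """One-letter sequence of a domain in residue order; unknowns become X."""
    seq = []
    res_names = {}
    for s in fab.structure.sites:
        res_names[s.residue] = s.res_name
    for rid in fab.domain_residues(domain):
        seq.append(_one_letter(res_names[rid]))
    return "".join(seq)


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (identifier -> sequence) records as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    items = records.items() if isinstance(records, Mapping) else records
    seqio_write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in items],
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an (identifier -> sequence) dict."""
    from Bio.SeqIO import parse as seqio_parse

    return {rec.id: str(rec.seq) for rec in seqio_parse(str(path), "fasta")}
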