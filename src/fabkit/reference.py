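"""Packaged registration reference for domain-frame fitting.

The reference is the canonical idealized domain from
:mod:`fabkit.synth_fixtures`, frozen into ``data/reference_domain.json`` so the
frame convention is versioned with the package.  Absolute orientation-angle
values depend on this convention; differences between variants are the
meaningful output.  Users analysing real Chothia-numbered structures should
supply their own reference (coreset coordinates + embedded frame) through the
``reference=`` arguments of the geometry functions.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

from .synth_fixtures import ReferenceDomain


def _positions_from_json(raw) -> list[tuple[int, str | None]]:
    return [(int(num), icode if icode else None) for num, icode in raw]


@lru_cache(maxsize=1)
def default_reference() -> ReferenceDomain:
    """Load the packaged reference domain (cached)."""
    path = resources.files("fabkit.data").joinpath("reference_domain.json")
    raw = json.loads(path.read_text())
    return ReferenceDomain(
        positions=_positions_from_json(raw["positions"]),
        coords=np.asarray(raw["coords"], dtype=float),
        coreset=_positions_from_json(raw["coreset"]),
        origin=np.asarray(raw["origin"], dtype=float),
        v1=np.asarray(raw["v1"], dtype=float),
        v2=np.asarray(raw["v2"], dtype=float),
        seed=int(raw["seed"]),
        version=str(raw["version"]),
    )


def dump_reference(ref: ReferenceDomain, path) -> None:
    """Serialize a reference domain to JSON (used to build the packaged file)."""
    raw = {
        "version": ref.version,
        "seed": ref.seed,
        "positions": [[num, icode or ""] for num, icode in ref.positions],
        "coreset": [[num, icode or ""] for num, icode in ref.coreset],
        "origin": ref.origin.tolist(),
        "v1": ref.v1.tolist(),
        "v2": ref.v2.tolist(),
        "coords": [[float(x) for x in row] for row in ref.coords],
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1)
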