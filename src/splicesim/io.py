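"""File formats: lattice container, trajectory tables, run manifests.

Lattices round-trip through an HDF5 container (uint8 site array plus
spacing, site-type name table, config echo, placed objects and gene
positions).  Trajectories and experiment summaries are tab-separated
text with ``#``-prefixed metadata headers.  Every CLI invocation writes
a JSON run manifest (config echo, code version, seeds, file digests,
wall time) so outputs can be regenerated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .geometry import (
    ConeShell,
    GeometryConfig,
    LatticeSpec,
    SiteLattice,
    SiteType,
    Sphere,
    SphericalShell,
    Spherocylinder,
    construction_report,
)
from .traj import Trajectory

_FORMAT_VERSION = 1
_PRIMITIVES = {
    "Sphere": Sphere,
    "SphericalShell": SphericalShell,
    "Spherocylinder": Spherocylinder,
    "ConeShell": ConeShell,
}


def _placed_to_json(placed) -> str:
    rows = []
    for kind, obj, st in placed:
        if dataclasses.is_dataclass(obj):
            params = dataclasses.asdict(obj)
        else:
            params = {"value": obj}
        rows.append({"kind": kind, "params": params, "site_type": int(st)})
    return json.dumps(rows)


def _placed_from_json(text: str):
    placed = []
    for row in json.loads(text):
        cls = _PRIMITIVES.get(row["kind"])
        if cls is not None:
            params = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in row["params"].items()
            }
            obj = cls(**params)
        else:
            obj = row["params"].get("value")
        placed.append((row["kind"], obj, SiteType(row["site_type"])))
    return placed


def write_lattice(lattice: SiteLattice, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sites", data=lattice.sites, compression="gzip",
                         compression_opts=4)
        f.create_dataset("gene_positions", data=lattice.gene_positions)
        f.create_dataset("gene_coords", data=lattice.gene_coords)
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["edge_length_um"] = lattice.spec.edge_length
        f.attrs["spacing_um"] = lattice.spec.spacing
        f.attrs["seed"] = lattice.seed
        f.attrs["npc_count"] = lattice.npc_count
        f.attrs["site_type_names"] = json.dumps(
            {int(st): st.name.lower() for st in SiteType}
        )
        f.attrs["placed_objects"] = _placed_to_json(lattice.placed_objects)
        if lattice.config is not None:
            f.attrs["config"] = json.dumps(dataclasses.asdict(lattice.config))


def read_lattice(path) -> SiteLattice:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported lattice format version "
                f"{f.attrs.get('format_version')!r} in {path}"
            )
        sites = f["sites"][...]
        known = {int(st) for st in SiteType}
        present = set(np.unique(sites).tolist())
        bad = present - known
        if bad:
            raise ValueError(f"unknown site-type code(s) {sorted(bad)} in {path}")
        names = json.loads(f.attrs["site_type_names"])
        for code, name in names.items():
            if SiteType(int(code)).name.lower() != name:
                raise ValueError(
                    f"site-type table mismatch for code {code}: {name!r}"
                )
        spec = LatticeSpec(float(f.attrs["edge_length_um"]),
                           float(f.attrs["spacing_um"]))
        lattice = SiteLattice(
            spec=spec,
            sites=sites,
            placed_objects=_placed_from_json(f.attrs["placed_objects"]),
            gene_positions=f["gene_positions"][...],
            gene_coords=f["gene_coords"][...],
            seed=int(f.attrs["seed"]),
            npc_count=int(f.attrs["npc_count"]),
        )
        if "config" in f.attrs:
            lattice.config = GeometryConfig(**json.loads(f.attrs["config"]))
    return lattice


def write_report(lattice: SiteLattice, path) -> None:
    """Human-readable construction report (TSV)."""
    rows = construction_report(lattice)
    with open(path, "w") as f:
        f.write("site_type\tsite_count\tvolume_um3\tfraction\n")
        for r in rows:
            f.write(
                f"{r['site_type']}\t{r['site_count']}\t"
                f"{r['volume_um3']:.6g}\t{r['fraction']:.6g}\n"
            )


def write_trajectory(trajectory: Trajectory, path, replicate: int = 0) -> None:
    """Tab-separated long format with a ``#`` metadata header."""
    with open(path, "w") as f:
        for k, v in trajectory.metadata.items():
            if isinstance(v, (str, int, float, bool)):
                f.write(f"# {k}: {v}\n")
        f.write("time\tcompartment\tspecies\tcount\treplicate\n")
        nt, nc, ns = trajectory.counts.shape
        for it in range(nt):
            t = trajectory.times[it]
            for ic in range(nc):
                for isp in range(ns):
                    c = trajectory.counts[it, ic, isp]
                    if c == 0:
                        continue
                    f.write(
                        f"{t:.6g}\t{trajectory.compartment_names[ic]}\t"
                        f"{trajectory.species_names[isp]}\t{c}\t{replicate}\n"
                    )


def read_trajectory_frame(path) -> pd.DataFrame:
    """Parse a trajectory TSV back into a tidy DataFrame."""
    return pd.read_csv(path, sep="\t", comment="#")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, config: dict, seeds,
                   inputs: list, outputs: list, t_start: float) -> None:
    manifest = {
        "command": command,
        "code_version": __version__,
        "config": config,
        "seeds": list(seeds),
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": {str(p): file_digest(p) for p in outputs},
        "wall_time_s": round(time.time() - t_start, 3),
    }
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2)
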