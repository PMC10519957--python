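"""Plain-text trajectory I/O.

* Topology geometry goes to PDB (ATOM records with a CRYST1 box record);
  annotations that PDB cannot carry (charges, Lennard-Jones parameters,
  hydrogen-bond roles, bonds, species) go to a JSON sidecar.
* Frames go to extended XYZ: the comment line carries the orthorhombic
  lattice and the frame time, e.g.
  ``Lattice="40.0 0 0 0 40.0 0 0 0 40.0" Time=12.5``.
  Coordinates are written with 3 decimals, so a round trip reproduces them
  to 1e-3 A; metadata round-trips exactly at the printed precision.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .core import Bond, Topology, Trajectory

__all__ = [
    "TrajectoryParseError",
    "write_pdb",
    "read_pdb",
    "topology_to_json",
    "topology_from_json",
    "write_extxyz",
    "read_extxyz",
    "write_trajectory",
    "read_trajectory",
]


class TrajectoryParseError(ValueError):
    """Malformed trajectory or topology file; carries the offending line."""

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


def write_pdb(
    topology: Topology, coords: np.ndarray, box, path: str | Path
) -> None:
    """Write one frame as PDB with a CRYST1 record.

    Molecule ids map to residue sequence numbers (modulo PDB's 4-digit
    field) and species to residue names (DRG/OLI/ION/SOL).
    """
    resnames = {"drug": "DRG", "oligomer": "OLI", "ion": "ION", "solvent": "SOL"}
    bx, by, bz = (float(v) for v in box)
    with open(path, "w") as handle:
        handle.write(
            f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for i in range(topology.n_atoms):
            mol = int(topology.molecule_ids[i])
            species = topology.molecule_species[mol]
            name = topology.names[i][:4]
            x, y, z = coords[i]
            # standard ATOM columns: serial 7-11, name 13-16, resName 18-20,
            # chain 22, resSeq 23-26, xyz 31-54, element 77-78
            handle.write(
                f"ATOM  {(i + 1) % 100000:5d} {name:<4s} {resnames.get(species, 'UNK'):<3s} "
                f"A{(mol % 9999) + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {topology.elements[i]:>2s}\n"
            )
        handle.write("END\n")


def read_pdb(path: str | Path):
    """Read coordinates, box and basic labels back from a PDB file.

    Returns ``(elements, molecule_ids, coords, box)``; annotation-carrying
    topologies are reconstructed via the JSON sidecar instead.
    """
    elements: list[str] = []
    molecule_ids: list[int] = []
    coords: list[list[float]] = []
    box = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record == "CRYST1":
                try:
                    box = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
                except ValueError:
                    raise TrajectoryParseError(path, lineno, "malformed CRYST1 record")
            elif record in ("ATOM", "HETATM"):
                try:
                    coords.append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                    molecule_ids.append(int(line[22:26]) - 1)
                    elements.append(line[76:78].strip() or line[12:16].strip()[0])
                except (ValueError, IndexError):
                    raise TrajectoryParseError(path, lineno, "malformed ATOM record")
    if box is None:
        raise TrajectoryParseError(path, 0, "missing CRYST1 box record")
    if not coords:
        raise TrajectoryParseError(path, 0, "no ATOM records found")
    return elements, np.array(molecule_ids), np.array(coords), np.array(box)


def topology_to_json(topology: Topology, path: str | Path) -> None:
    payload = {
        "elements": topology.elements,
        "names": topology.names,
        "masses": topology.masses.tolist(),
        "molecule_ids": topology.molecule_ids.tolist(),
        "charges": topology.charges.tolist(),
        "lj_sigma": topology.lj_sigma.tolist(),
        "lj_epsilon": topology.lj_epsilon.tolist(),
        "molecule_species": {str(k): v for k, v in topology.molecule_species.items()},
        "donor_flags": topology.donor_flags.astype(int).tolist(),
        "acceptor_flags": topology.acceptor_flags.astype(int).tolist(),
        "hydrogen_donor_index": topology.hydrogen_donor_index.tolist(),
        "bonds": [[b.i, b.j, b.r0, b.k] for b in topology.bonds],
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1, sort_keys=True)
        handle.write("\n")


def topology_from_json(path: str | Path) -> Topology:
    with open(path) as handle:
        payload = json.load(handle)
    return Topology(
        elements=payload["elements"],
        names=payload["names"],
        masses=np.array(payload["masses"]),
        molecule_ids=np.array(payload["molecule_ids"]),
        charges=np.array(payload["charges"]),
        lj_sigma=np.array(payload["lj_sigma"]),
        lj_epsilon=np.array(payload["lj_epsilon"]),
        molecule_species={int(k): v for k, v in payload["molecule_species"].items()},
        donor_flags=np.array(payload["donor_flags"], dtype=bool),
        acceptor_flags=np.array(payload["acceptor_flags"], dtype=bool),
        hydrogen_donor_index=np.array(payload["hydrogen_donor_index"]),
        bonds=[Bond(int(i), int(j), float(r0), float(k)) for i, j, r0, k in payload["bonds"]],
    )


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([-+0-9.eE]+)")


def write_extxyz(traj: Trajectory, path: str | Path) -> None:
    """Write all frames as extended XYZ."""
    top = traj.topology
    with open(path, "w") as handle:
        for f in range(traj.n_frames):
            bx, by, bz = traj.boxes[f]
            handle.write(f"{top.n_atoms}\n")
            handle.write(
                f'Lattice="{bx:.6f} 0.0 0.0 0.0 {by:.6f} 0.0 0.0 0.0 {bz:.6f}" '
                f"Properties=species:S:1:pos:R:3 Time={traj.times[f]:.6f}\n"
            )
            for i in range(top.n_atoms):
                x, y, z = traj.coords[f, i]
                handle.write(f"{top.elements[i]:<2s} {x:12.3f} {y:12.3f} {z:12.3f}\n")


def read_extxyz(path: str | Path, topology: Topology) -> Trajectory:
    """Read an extended-XYZ frame stack against a known topology."""
    times: list[float] = []
    boxes: list[list[float]] = []
    frames: list[np.ndarray] = []
    with open(path) as handle:
        lines = handle.readlines()
    lineno = 0
    frame_no = 0
    n = len(lines)
    while lineno < n:
        header = lines[lineno].strip()
        if not header:
            lineno += 1
            continue
        frame_no += 1
        try:
            n_atoms = int(header)
        except ValueError:
            raise TrajectoryParseError(
                path, lineno + 1, f"expected atom count, got {header!r}"
            )
        if n_atoms != topology.n_atoms:
            raise TrajectoryParseError(
                path,
                lineno + 1,
                f"frame {frame_no} has {n_atoms} atoms, topology has "
                f"{topology.n_atoms}",
            )
        if lineno + 1 >= n:
            raise TrajectoryParseError(path, lineno + 2, "missing comment line")
        comment = lines[lineno + 1]
        lattice = _LATTICE_RE.search(comment)
        if lattice is None:
            raise TrajectoryParseError(
                path, lineno + 2, "missing Lattice box record in comment line"
            )
        cell = [float(v) for v in lattice.group(1).split()]
        if len(cell) != 9 or any(
            abs(cell[k]) > 1e-9 for k in (1, 2, 3, 5, 6, 7)
        ):
            raise TrajectoryParseError(
                path, lineno + 2, "only orthorhombic lattices are supported"
            )
        time_match = _TIME_RE.search(comment)
        times.append(float(time_match.group(1)) if time_match else float(len(times)))
        boxes.append([cell[0], cell[4], cell[8]])
        xyz = np.empty((n_atoms, 3))
        for i in range(n_atoms):
            row = lineno + 2 + i
            if row >= n:
                raise TrajectoryParseError(
                    path, row + 1, f"frame {frame_no} truncated"
                )
            parts = lines[row].split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    path, row + 1, f"frame {frame_no}: malformed atom line"
                )
            try:
                xyz[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise TrajectoryParseError(
                    path, row + 1, f"frame {frame_no}: non-numeric coordinate"
                )
        frames.append(xyz)
        lineno += 2 + n_atoms
    if not frames:
        raise TrajectoryParseError(path, 0, "no frames found")
    return Trajectory(
        topology=topology,
        times=np.array(times),
        boxes=np.array(boxes),
        coords=np.array(frames),
    )


def write_trajectory(
    traj: Trajectory,
    pdb_path: str | Path,
    xyz_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write topology (PDB + JSON sidecar) and frames (extended XYZ)."""
    write_pdb(traj.topology, traj.coords[0], traj.boxes[0], pdb_path)
    if json_path is not None:
        topology_to_json(traj.topology, json_path)
    write_extxyz(traj, xyz_path)


def read_trajectory(
    xyz_path: str | Path, json_path: str | Path
) -> Trajectory:
    """Read a trajectory from the JSON topology sidecar and extended XYZ."""
    topology = topology_from_json(json_path)
    return read_extxyz(xyz_path, topology)
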