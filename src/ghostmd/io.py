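"""Extended-XYZ and HDF5 input/output.

The extended-XYZ dialect used here is the common one: per-frame header line
with the atom count, then a comment line of key=value pairs including
Lattice="ax ay az bx by bz cx cy cz" and a Properties= descriptor for the
per-atom columns (species:S:1:pos:R:3[:vel:R:3][:forces:R:3][:mol:I:1]).
Floats are written with %.17g so a write→read→write cycle is bit-identical.
"""

from __future__ import annotations

import re
import shlex
from dataclasses import dataclass, field

import numpy as np

from .system import Configuration, GhostMDError

_FMT = "%.17g"


@dataclass
class XYZFrame:
    """One parsed extended-XYZ frame."""

    species: np.ndarray
    positions: np.ndarray
    cell: np.ndarray
    info: dict = field(default_factory=dict)        # scalar comment-line keys
    arrays: dict = field(default_factory=dict)      # extra per-atom columns


def _format_comment(cell, info, columns) -> str:
    lat = " ".join(_FMT % x for x in
                   [cell[0], 0, 0, 0, cell[1], 0, 0, 0, cell[2]])
    props = ":".join(columns)
    parts = [f'Lattice="{lat}"', f"Properties={props}"]
    for k, v in info.items():
        if isinstance(v, float):
            parts.append(f"{k}={_FMT % v}")
        elif isinstance(v, bool):
            parts.append(f"{k}={'T' if v else 'F'}")
        else:
            parts.append(f"{k}={v}")
    return " ".join(parts)


def write_extxyz(path, frames: list[XYZFrame], mode: str = "w") -> None:
    """Write frames; per-atom arrays beyond positions come from frame.arrays
    (keys 'vel', 'forces', 'mol' are recognized on read)."""
    with open(path, mode) as fh:
        for fr in frames:
            n = len(fr.species)
            cols = ["species:S:1", "pos:R:3"]
            extra = []
            for key, width, kind in (("vel", 3, "R"), ("forces", 3, "R"),
                                     ("mol", 1, "I")):
                if key in fr.arrays:
                    cols.append(f"{key}:{kind}:{width}")
                    extra.append((key, width, kind))
            fh.write(f"{n}\n")
            fh.write(_format_comment(fr.cell, fr.info, cols) + "\n")
            for i in range(n):
                fields = [fr.species[i]]
                fields += [_FMT % x for x in fr.positions[i]]
                for key, width, kind in extra:
                    v = np.atleast_1d(fr.arrays[key][i])
                    if kind == "I":
                        fields += [str(int(x)) for x in v]
                    else:
                        fields += [_FMT % x for x in v]
                fh.write(" ".join(fields) + "\n")


def _parse_comment(line: str, lineno: int):
    try:
        tokens = shlex.split(line)
    except ValueError as exc:
        raise GhostMDError(f"malformed comment line {lineno}: {exc}")
    info = {}
    for tok in tokens:
        if "=" not in tok:
            continue
        k, v = tok.split("=", 1)
        info[k] = v
    if "Lattice" not in info:
        raise GhostMDError(f"missing Lattice on comment line {lineno}")
    lat = np.array([float(x) for x in info.pop("Lattice").split()])
    if lat.size != 9:
        raise GhostMDError(f"Lattice must have 9 entries (line {lineno})")
    lat = lat.reshape(3, 3)
    if np.any(np.abs(lat - np.diag(np.diag(lat))) > 1e-12):
        raise GhostMDError(f"only orthorhombic cells supported (line {lineno})")
    cell = np.diag(lat).copy()
    props = info.pop("Properties", "species:S:1:pos:R:3")
    fields = props.split(":")
    columns = [(fields[i], fields[i + 1], int(fields[i + 2]))
               for i in range(0, len(fields), 3)]
    # typed scalar info values
    parsed = {}
    for k, v in info.items():
        if v in ("T", "F"):
            parsed[k] = v == "T"
            continue
        try:
            parsed[k] = int(v)
        except ValueError:
            try:
                parsed[k] = float(v)
            except ValueError:
                parsed[k] = v
    return cell, columns, parsed


def read_extxyz(path) -> list[XYZFrame]:
    """Parse all frames; errors carry the offending line number."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise GhostMDError(f"expected atom count on line {i + 1}, "
                               f"got {lines[i].strip()!r}")
        if i + 1 >= len(lines):
            raise GhostMDError(f"truncated file: missing comment line {i + 2}")
        cell, columns, info = _parse_comment(lines[i + 1], i + 2)
        if i + 1 + n >= len(lines):
            raise GhostMDError(
                f"truncated file: frame starting at line {i + 1} declares "
                f"{n} atoms but the file ends at line {len(lines)}")
        species = []
        data = {name: [] for name, _, w in columns if name != "species"}
        for a in range(n):
            ln = i + 2 + a
            toks = lines[ln].split()
            want = sum(w for _, _, w in columns)
            if len(toks) != want:
                raise GhostMDError(
                    f"line {ln + 1}: expected {want} fields, got {len(toks)}")
            ptr = 0
            for name, kind, w in columns:
                chunk = toks[ptr:ptr + w]
                ptr += w
                if name == "species":
                    species.append(chunk[0])
                elif kind == "I":
                    data[name].append([int(x) for x in chunk])
                else:
                    data[name].append([float(x) for x in chunk])
        arrays = {}
        pos = np.array(data.pop("pos"))
        for name, vals in data.items():
            arr = np.array(vals)
            arrays[name] = arr[:, 0] if arr.shape[1] == 1 else arr
        frames.append(XYZFrame(np.array(species, dtype="U2"), pos, cell,
                               info, arrays))
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# dataset adapters
# ---------------------------------------------------------------------------

def write_dataset_extxyz(path, dataset) -> None:
    frames = []
    for s in dataset.samples:
        c = s.configuration
        frames.append(XYZFrame(
            c.species, c.positions, c.cell,
            info=dict(energy=float(s.energy), has_ghost=bool(s.has_ghost)),
            arrays=dict(forces=s.forces, mol=c.molecule_index)))
    write_extxyz(path, frames)


def read_dataset_extxyz(path):
    from .toy import Dataset, LabeledSample
    frames = read_extxyz(path)
    samples = []
    for fr in frames:
        if "forces" not in fr.arrays or "energy" not in fr.info:
            raise GhostMDError("dataset frames need forces columns and an "
                               "energy= comment key")
        mol = fr.arrays.get("mol")
        if mol is None:
            mol = np.repeat(np.arange(len(fr.species) // 3), 3)
        cfg = Configuration(fr.species, fr.positions, fr.cell,
                            np.asarray(mol, dtype=int))
        samples.append(LabeledSample(cfg, float(fr.info["energy"]),
                                     np.asarray(fr.arrays["forces"], float),
                                     bool(fr.info.get("has_ghost", False))))
    has_ghost = samples[0].has_ghost if samples else False
    return Dataset(samples, has_ghost=has_ghost)


def write_dataset_hdf5(path, dataset) -> None:
    import h5py
    import json
    c0 = dataset.samples[0].configuration
    with h5py.File(path, "w") as f:
        f.attrs["has_ghost"] = dataset.has_ghost
        f.attrs["metadata"] = json.dumps(dataset.metadata, default=float)
        f.create_dataset("species", data=np.array(c0.species, dtype="S2"))
        f.create_dataset("molecule_index", data=c0.molecule_index)
        f.create_dataset("cell", data=c0.cell)
        f.create_dataset("positions", data=np.stack(
            [s.configuration.positions for s in dataset.samples]))
        f.create_dataset("energies", data=dataset.energies)
        f.create_dataset("forces", data=dataset.forces)
        if dataset.frame_labels is not None:
            f.create_dataset("frame_labels",
                             data=np.array(dataset.frame_labels, dtype="S32"))


def read_dataset_hdf5(path):
    import h5py
    import json
    from .toy import Dataset, LabeledSample
    with h5py.File(path, "r") as f:
        species = np.array(f["species"]).astype("U2")
        mol = np.array(f["molecule_index"])
        cell = np.array(f["cell"])
        P = np.array(f["positions"])
        E = np.array(f["energies"])
        F = np.array(f["forces"])
        has_ghost = bool(f.attrs["has_ghost"])
        meta = json.loads(f.attrs["metadata"])
        labels = ([x.decode() for x in f["frame_labels"]]
                  if "frame_labels" in f else None)
    samples = [LabeledSample(Configuration(species, P[i], cell, mol),
                             float(E[i]), F[i], has_ghost)
               for i in range(len(E))]
    return Dataset(samples, has_ghost, meta, labels)


# ---------------------------------------------------------------------------
# trajectory adapters
# ---------------------------------------------------------------------------

def write_trajectory_extxyz(path, traj) -> None:
    frames = []
    for i in range(traj.n_frames):
        arrays = dict(mol=traj.molecule_index)
        if traj.velocities is not None:
            arrays["vel"] = traj.velocities[i]
        frames.append(XYZFrame(traj.species, traj.positions[i], traj.cell,
                               info=dict(time=float(traj.times[i])),
                               arrays=arrays))
    write_extxyz(path, frames)


def read_trajectory_extxyz(path):
    from .dynamics import Trajectory
    from .units import ATOMIC_MASSES
    frames = read_extxyz(path)
    if not frames:
        raise GhostMDError("empty trajectory file")
    times = np.array([fr.info.get("time", float(i))
                      for i, fr in enumerate(frames)])
    pos = np.stack([fr.positions for fr in frames])
    vel = None
    if all("vel" in fr.arrays for fr in frames):
        vel = np.stack([fr.arrays["vel"] for fr in frames])
    f0 = frames[0]
    mol = f0.arrays.get("mol")
    if mol is None:
        mol = np.repeat(np.arange(len(f0.species) // 3), 3)
    masses = np.array([ATOMIC_MASSES[s] for s in f0.species])
    return Trajectory(times, pos, f0.cell, f0.species,
                      np.asarray(mol, dtype=int), velocities=vel,
                      metadata=dict(masses=masses))


def write_trajectory_hdf5(path, traj) -> None:
    import h5py
    import json
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("positions", data=traj.positions)
        f.create_dataset("species", data=np.array(traj.species, dtype="S2"))
        f.create_dataset("molecule_index", data=traj.molecule_index)
        f.create_dataset("cell", data=traj.cell)
        if traj.velocities is not None:
            f.create_dataset("velocities", data=traj.velocities)
        if traj.bead_positions is not None:
            f.create_dataset("bead_positions", data=traj.bead_positions)
        meta = {k: v for k, v in traj.metadata.items() if k != "masses"}
        f.attrs["metadata"] = json.dumps(meta, default=float)
        if "masses" in traj.metadata:
            f.create_dataset("masses", data=np.asarray(traj.metadata["masses"]))


def read_trajectory_hdf5(path):
    import h5py
    import json
    from .dynamics import Trajectory
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["metadata"])
        if "masses" in f:
            meta["masses"] = np.array(f["masses"])
        return Trajectory(
            np.array(f["times"]), np.array(f["positions"]),
            np.array(f["cell"]), np.array(f["species"]).astype("U2"),
            np.array(f["molecule_index"]),
            velocities=np.array(f["velocities"]) if "velocities" in f else None,
            bead_positions=(np.array(f["bead_positions"])
                            if "bead_positions" in f else None),
            metadata=meta)
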