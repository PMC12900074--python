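"""Multi-conformation structure I/O and Ballesteros–Weinstein residue mapping.

A :class:`ConformationEnsemble` is an ordered stack of snapshots (frames) of one
receptor, all sharing the same atoms in the same order — the natural container
for frames extracted from a molecular-dynamics trajectory.  The canonical
interchange format is multi-model PDB (one MODEL per frame); a directory of
single-model PDB files is also accepted.

Ballesteros–Weinstein (BW) generic numbers (e.g. ``3x50``) address structurally
equivalent residues across Class A GPCRs.  The mapping from author residue
numbering to BW labels is supplied explicitly as a TSV with columns
``chain``, ``residue_seq``, ``bw_label`` rather than inferred from a sequence
alignment, keeping the dependency surface small and the mapping auditable.

Coordinates are in Å throughout.
"""
from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

_BW_PATTERN = re.compile(r"^\d+x\d+$")

STATE_TAGS = ("active", "inactive", "unknown")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame (author residue numbering, Å coordinates)."""

    atom_name: str
    element: str
    residue_seq: int
    chain: str
    coord: np.ndarray

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Frame:
    """A single snapshot: per-atom metadata arrays plus an (n_atoms, 3) coordinate block."""

    frame_id: int
    atom_name: np.ndarray
    element: np.ndarray
    residue_seq: np.ndarray
    chain: np.ndarray
    res_name: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atom_name), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinate in frame %d" % self.frame_id)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def is_heavy(self) -> np.ndarray:
        return np.char.upper(self.element.astype(str)) != "H"

    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(str(self.atom_name[i]), str(self.element[i]),
                       int(self.residue_seq[i]), str(self.chain[i]), self.coords[i])
            for i in range(self.n_atoms)
        ]

    def residue_atoms(self, chain: str, residue_seq: int, heavy_only: bool = True) -> np.ndarray:
        """Coordinates of one residue's atoms (heavy atoms by default)."""
        mask = (self.chain == chain) & (self.residue_seq == residue_seq)
        if heavy_only:
            mask &= self.is_heavy
        if not mask.any():
            raise KeyError(f"no atoms for residue {chain}:{residue_seq}")
        return self.coords[mask]


@dataclass
class ConformationEnsemble:
    """Ordered frames sharing one atom table, tagged with an activation state."""

    frames: list[Frame]
    state_tag: str = "unknown"
    source: str = ""

    def __post_init__(self):
        if self.state_tag not in STATE_TAGS:
            raise ValueError(f"state_tag must be one of {STATE_TAGS}")
        if not self.frames:
            raise ValueError("ensemble must contain at least one frame")
        ref = self.frames[0]
        for fr in self.frames[1:]:
            if fr.n_atoms != ref.n_atoms:
                raise ValueError(
                    f"frame {fr.frame_id} has {fr.n_atoms} atoms, "
                    f"expected {ref.n_atoms} (frame {ref.frame_id})"
                )
            if not (np.array_equal(fr.atom_name, ref.atom_name)
                    and np.array_equal(fr.residue_seq, ref.residue_seq)
                    and np.array_equal(fr.chain, ref.chain)):
                raise ValueError(f"frame {fr.frame_id} atom ordering differs from frame {ref.frame_id}")
        ids = [fr.frame_id for fr in self.frames]
        if len(set(ids)) != len(ids):
            raise ValueError("frame_ids must be unique")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def coords_stack(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.stack([fr.coords for fr in self.frames])

    def subset(self, frame_indices) -> "ConformationEnsemble":
        return ConformationEnsemble(
            frames=[self.frames[i] for i in frame_indices],
            state_tag=self.state_tag, source=self.source,
        )


class BWMap:
    """Bijective map between (chain, residue_seq) and BW generic labels."""

    def __init__(self, rows: list[tuple[str, int, str]]):
        self._to_bw: dict[tuple[str, int], str] = {}
        self._from_bw: dict[str, tuple[str, int]] = {}
        for chain, seq, label in rows:
            key = (str(chain), int(seq))
            if not _BW_PATTERN.match(label):
                raise ValueError(f"malformed BW label {label!r} for residue {key}")
            if key in self._to_bw:
                raise ValueError(f"duplicate residue {key} in BW map")
            if label in self._from_bw:
                raise ValueError(f"duplicate BW label {label!r} in BW map")
            self._to_bw[key] = label
            self._from_bw[label] = key

    def __len__(self) -> int:
        return len(self._from_bw)

    def __contains__(self, label: str) -> bool:
        return label in self._from_bw

    def residue(self, bw_label: str) -> tuple[str, int]:
        try:
            return self._from_bw[bw_label]
        except KeyError:
            raise KeyError(f"BW label {bw_label!r} not in map") from None

    def label(self, chain: str, residue_seq: int) -> str:
        return self._to_bw[(str(chain), int(residue_seq))]

    def labels(self) -> list[str]:
        return list(self._from_bw)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _frame_from_atom_array(arr, frame_id: int) -> Frame:
    return Frame(
        frame_id=frame_id,
        atom_name=np.asarray(arr.atom_name),
        element=np.asarray(arr.element),
        residue_seq=np.asarray(arr.res_id, dtype=int),
        chain=np.asarray(arr.chain_id),
        res_name=np.asarray(arr.res_name),
        coords=np.asarray(arr.coord, dtype=float),
    )


def _validate_model_atom_counts(text: str, path) -> None:
    """Per-MODEL ATOM/HETATM counts must agree; name the offending frame."""
    counts, current, in_model, any_model = [], 0, False, False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model, any_model, current = True, True, 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM") and (in_model or not any_model):
            current += 1
    if len(counts) > 1:
        ref = counts[0]
        for i, c in enumerate(counts[1:], start=2):
            if c != ref:
                raise ValueError(
                    f"{path}: model {i} has {c} atoms, expected {ref} (model 1)"
                )


def read_ensemble(path, fmt: str = "auto", state_tag: str = "unknown",
                  altloc: str = "occupancy") -> ConformationEnsemble:
    """Read a conformational ensemble from a multi-model PDB or a frame directory.

    Parameters
    ----------
    path
        A PDB file (MODEL/ENDMDL delimits frames) or a directory of per-frame
        PDB files read in sorted name order.
    fmt
        ``"pdb"``, ``"dir"`` or ``"auto"`` (decide from the path).
    state_tag
        Activation-state tag to attach (``active`` / ``inactive`` / ``unknown``).
    altloc
        Alternate-location policy passed to biotite; the default keeps the
        highest-occupancy location (ties resolve to the first encountered).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "dir" if path.is_dir() else "pdb"
    if fmt == "dir":
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".pdb", ".ent"))
        if not files:
            raise FileNotFoundError(f"no PDB files in directory {path}")
        frames = []
        for i, f in enumerate(files):
            sub = read_ensemble(f, fmt="pdb", state_tag=state_tag, altloc=altloc)
            if len(sub) != 1:
                raise ValueError(f"{f}: expected single-model file in frame directory")
            fr = sub.frames[0]
            fr.frame_id = i
            frames.append(fr)
        return ConformationEnsemble(frames, state_tag=state_tag, source=str(path))

    text = path.read_text()
    _validate_model_atom_counts(text, path)
    try:
        pdb = PDBFile.read(io.StringIO(text))
        n_models = pdb.get_model_count()
        frames = []
        for m in range(1, n_models + 1):
            arr = pdb.get_structure(model=m, altloc=altloc)
            frames.append(_frame_from_atom_array(arr, frame_id=m - 1))
    except ValueError as exc:
        raise ValueError(f"{path}: unparsable PDB record ({exc})") from exc
    return ConformationEnsemble(frames, state_tag=state_tag, source=str(path))


def write_ensemble(ensemble: ConformationEnsemble, path) -> None:
    """Write a multi-model PDB (coordinates on the standard 3-decimal grid)."""
    n = ensemble.n_atoms
    ref = ensemble.frames[0]
    arr = struc.AtomArrayStack(len(ensemble), n)
    arr.coord = ensemble.coords_stack()
    arr.atom_name = ref.atom_name
    arr.element = ref.element
    arr.res_id = ref.residue_seq
    arr.chain_id = ref.chain
    arr.res_name = ref.res_name
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def load_bw_map(path) -> BWMap:
    """Load a BW mapping TSV with columns chain, residue_seq, bw_label."""
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "bw_label": str})
    required = {"chain", "residue_seq", "bw_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"BW map must have columns {sorted(required)}, got {list(df.columns)}")
    if df.empty:
        logger.warning("BW map %s is empty", path)
    rows = []
    for idx, row in df.iterrows():
        label = str(row["bw_label"]).strip()
        if not _BW_PATTERN.match(label):
            raise ValueError(f"row {idx}: malformed BW label {label!r}")
        rows.append((str(row["chain"]).strip(), int(row["residue_seq"]), label))
    return BWMap(rows)


# ---------------------------------------------------------------------------
# coordinate extraction
# ---------------------------------------------------------------------------

def _ca_indices(frame: Frame) -> np.ndarray:
    """Indices of Cα atoms, validated to one per residue."""
    is_ca = frame.atom_name == "CA"
    idx = np.flatnonzero(is_ca)
    residues = list(zip(frame.chain, frame.residue_seq))
    seen: dict[tuple, int] = {}
    for i in idx:
        key = (frame.chain[i], int(frame.residue_seq[i]))
        seen[key] = seen.get(key, 0) + 1
    for key in dict.fromkeys(residues):
        n = seen.get(key, 0)
        if n == 0:
            raise ValueError(f"residue {key[0]}:{key[1]} has no CA atom")
        if n > 1:
            raise ValueError(f"residue {key[0]}:{key[1]} has {n} CA atoms")
    return idx


def ca_matrix(ensemble: ConformationEnsemble) -> np.ndarray:
    """Flattened Cα coordinate matrix, one row per frame, shape (n, 3N)."""
    idx = _ca_indices(ensemble.frames[0])
    return ensemble.coords_stack()[:, idx, :].reshape(len(ensemble), -1)


def ca_coords(frame: Frame) -> np.ndarray:
    """(N, 3) Cα coordinates of one frame in residue order."""
    return frame.coords[_ca_indices(frame)]


def ca_distance_map(frame: Frame, set_a: list[str], set_b: list[str], bw_map: BWMap) -> np.ndarray:
    """Cα–Cα distance matrix (Å) between two BW-labelled residue sets.

    Entry (i, j) is the Euclidean distance between the Cα of ``set_a[i]`` and
    ``set_b[j]``.  Symmetric when the two sets coincide; used for interhelical
    contact maps (e.g. TM5 vs TM6 packing).
    """
    def _ca_of(label: str) -> np.ndarray:
        chain, seq = bw_map.residue(label)
        mask = (frame.chain == chain) & (frame.residue_seq == seq) & (frame.atom_name == "CA")
        hit = np.flatnonzero(mask)
        if hit.size != 1:
            raise KeyError(f"residue {chain}:{seq} ({label}) has {hit.size} CA atoms")
        return frame.coords[hit[0]]

    a = np.array([_ca_of(l) for l in set_a])
    b = np.array([_ca_of(l) for l in set_b])
    diff = a[:, None, :] - b[None, :, :]
    return np.linalg.norm(diff, axis=-1)
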