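"""Trajectory analytics: Kabsch superposition, RMSD series, windowed Cα RMSF,
and region-level flexibility comparison between two variants.

RMSD over a trajectory is a global-stability proxy; per-residue RMSF over a
trailing window (default the final 40% of frames, generalizing "the last 8 ns
of 20 ns") is a local-flexibility proxy.  Comparing the RMSF profiles of a
wild type and a mutant region-by-region classifies each region as rigidified,
flexibilized, or unchanged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError


@dataclass
class Trajectory:
    """Frames of coordinates with constant atom order.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``resids`` and ``names``
    label each atom with its residue number and atom name.
    """

    coords: np.ndarray
    resids: np.ndarray
    names: list[str]
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("trajectory coordinates must be finite")
        if self.coords.shape[1] != len(self.resids) or len(self.resids) != len(self.names):
            raise ValidationError("atom labels must match the coordinate atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, atom_name: str | None = "CA") -> np.ndarray:
        """Indices of atoms with the given name (all atoms when None)."""
        if atom_name is None:
            return np.arange(self.n_atoms)
        idx = np.array([i for i, n in enumerate(self.names) if n == atom_name])
        if idx.size == 0:
            raise ValidationError(f"no atoms named {atom_name!r} in trajectory")
        return idx


def read_trajectory(path: str | Path, format: str = "auto") -> Trajectory:
    """Read a multi-model PDB or a multi-frame XYZ file.

    XYZ carries no residue information, so atoms are numbered sequentially and
    the element symbol doubles as the atom name.
    """
    path = Path(path)
    text = path.read_text()
    if format == "auto":
        format = "xyz" if path.suffix.lower() == ".xyz" else "multi-model-pdb"
    if format == "multi-model-pdb":
        return _read_multimodel_pdb(text)
    if format == "xyz":
        return _read_xyz(text)
    raise ValidationError(f"unknown trajectory format: {format!r}")


def _read_multimodel_pdb(text: str) -> Trajectory:
    frames: list[list[list[float]]] = []
    labels_per_frame: list[list[tuple[int, str]]] = []
    current: list[list[float]] | None = None
    labels: list[tuple[int, str]] | None = None
    saw_model = "MODEL" in text
    if not saw_model:
        current, labels = [], []
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            current, labels = [], []
        elif rec == "ENDMDL":
            if current is None:
                raise ParseError("ENDMDL without MODEL")
            frames.append(current)
            labels_per_frame.append(labels)
            current = labels = None
        elif rec in ("ATOM", "HETATM") and current is not None:
            current.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            labels.append((int(line[22:26]), line[12:16].strip()))
    if not saw_model and current:
        frames.append(current)
        labels_per_frame.append(labels)
    if not frames:
        raise ParseError("no frames found in multi-model PDB")
    ref = labels_per_frame[0]
    for i, lab in enumerate(labels_per_frame):
        if lab != ref:
            raise ParseError(f"frame {i + 1}: atom count/order differs from frame 1")
    return Trajectory(
        coords=np.array(frames),
        resids=np.array([r for r, _ in ref]),
        names=[n for _, n in ref],
    )


def _read_xyz(text: str) -> Trajectory:
    lines = text.splitlines()
    frames = []
    labels = []
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"frame {frame_no}: expected atom count, got {lines[i]!r}")
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ParseError(f"frame {frame_no}: truncated ({len(body)} of {n} atoms)")
        coords = []
        names = []
        for row in body:
            parts = row.split()
            names.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        frames.append(coords)
        if not labels:
            labels = names
        elif names != labels:
            raise ParseError(f"frame {frame_no}: atom order differs from frame 1")
        i += 2 + n
    if not frames:
        raise ParseError("no frames found in XYZ file")
    return Trajectory(
        coords=np.array(frames),
        resids=np.arange(1, len(labels) + 1),
        names=labels,
    )


def write_xyz(traj: Trajectory) -> str:
    out = io.StringIO()
    for f in range(traj.n_frames):
        out.write(f"{traj.n_atoms}\nframe {f + 1}\n")
        for name, (x, y, z) in zip(traj.names, traj.coords[f]):
            out.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")
    return out.getvalue()


def write_multimodel_pdb(traj: Trajectory, res_name: str = "GLY") -> str:
    lines = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL {f + 1:8d}")
        for i, (name, rid, (x, y, z)) in enumerate(
            zip(traj.names, traj.resids, traj.coords[f]), start=1
        ):
            pname = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {i:5d} {pname:<4s} {res_name:>3s} A{rid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    The rotation is computed on the selected atoms (all by default) and applied
    to the full frame.  Returns ``(rotation, translation, aligned_frame)`` with
    ``aligned = mobile @ rotation.T + translation`` and ``det(rotation) = +1``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if sel.size < 3:
        raise ValidationError("superposition needs at least 3 selected atoms")
    m = mobile[sel]
    r = reference[sel]
    mc = m.mean(axis=0)
    rc = r.mean(axis=0)
    # a collinear mobile selection leaves the rotation about its axis free
    spread = np.linalg.svd(m - mc, compute_uv=False)
    if spread[1] <= 1e-8 * max(spread[0], 1e-30):
        raise ValidationError("selected atoms are collinear; superposition undefined")
    h = (m - mc).T @ (r - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    aligned = mobile @ rot.T + trans
    return rot, trans, aligned


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | str = "first",
    selection: np.ndarray | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) of the selected atoms against a reference frame.

    ``reference`` is the first frame by default or a supplied (n_atoms, 3)
    array.  With ``superpose=False`` frames are compared in place (useful for
    closed-form checks on pinned fixtures).
    """
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValidationError("empty atom selection")
    ref = traj.coords[0] if isinstance(reference, str) else np.asarray(reference, float)
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        frame = traj.coords[t]
        if superpose:
            _, _, frame = kabsch_superpose(frame, ref, sel)
        out[t] = _rmsd(frame[sel], ref[sel])
    return out


def rmsf_profile(
    traj: Trajectory,
    selection_name: str | None = "CA",
    window: float = 0.4,
    reference: str = "mean",
    superpose: bool = True,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> pd.Series:
    """Per-residue RMSF (Å) over the trailing ``window`` fraction of frames.

    Frames in the window are superposed either onto an iteratively refined
    mean structure (``reference="mean"``, the common convention) or onto the
    window's first frame (``reference="first"``).  Returns a Series indexed by
    residue number.
    """
    if not 0 < window <= 1:
        raise ValidationError("window must be in (0, 1]")
    sel = traj.select(selection_name)
    n_win = max(int(round(window * traj.n_frames)), 1)
    frames = traj.coords[traj.n_frames - n_win :, sel, :].copy()
    if len(frames) < 2:
        raise ValidationError(
            f"trailing window holds {len(frames)} frame(s); at least 2 required"
        )
    if superpose:
        if reference == "first":
            ref = frames[0]
            for t in range(len(frames)):
                _, _, frames[t] = kabsch_superpose(frames[t], ref)
        elif reference == "mean":
            mean = frames.mean(axis=0)
            for _ in range(max_iter):
                for t in range(len(frames)):
                    _, _, frames[t] = kabsch_superpose(frames[t], mean)
                new_mean = frames.mean(axis=0)
                shift = np.abs(new_mean - mean).max()
                mean = new_mean
                if shift < tol:
                    break
        else:
            raise ValidationError(f"unknown RMSF reference mode: {reference!r}")
    mean = frames.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))
    return pd.Series(rmsf, index=traj.resids[sel], name="rmsf")


@dataclass
class Region:
    label: str
    start: int
    end: int  # 1-based inclusive residue range

    def residues(self) -> range:
        return range(self.start, self.end + 1)


def read_regions_tsv(text: str) -> list[Region]:
    """Parse BED-like region TSV: label, start_residue, end_residue (1-based, inclusive)."""
    regions = []
    for line in text.strip().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"bad region line: {line!r}")
        regions.append(Region(parts[0], int(parts[1]), int(parts[2])))
    return regions


@dataclass
class RegionComparison:
    region: Region
    mean_a: float
    mean_b: float
    delta: float  # mean_b - mean_a
    classification: str  # rigidified | flexibilized | unchanged


@dataclass
class FlexReport:
    comparisons: list[RegionComparison] = field(default_factory=list)
    min_delta: float = 0.05

    def count(self, classification: str) -> int:
        return sum(1 for c in self.comparisons if c.classification == classification)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [c.region.label for c in self.comparisons],
                "start": [c.region.start for c in self.comparisons],
                "end": [c.region.end for c in self.comparisons],
                "mean_rmsf_a": [c.mean_a for c in self.comparisons],
                "mean_rmsf_b": [c.mean_b for c in self.comparisons],
                "delta": [c.delta for c in self.comparisons],
                "classification": [c.classification for c in self.comparisons],
            }
        )


def compare_flexibility(
    rmsf_a: pd.Series,
    rmsf_b: pd.Series,
    regions: list[Region],
    min_delta: float = 0.05,
) -> FlexReport:
    """Classify each region by the change in mean RMSF from variant a to b.

    ``rigidified`` when mean RMSF drops by more than ``min_delta`` Å in b,
    ``flexibilized`` when it rises by more than ``min_delta``, else
    ``unchanged``.
    """
    report = FlexReport(min_delta=min_delta)
    for region in regions:
        resids = list(region.residues())
        for series, tag in ((rmsf_a, "a"), (rmsf_b, "b")):
            missing = [r for r in resids if r not in series.index]
            if missing:
                raise ValidationError(
                    f"region {region.label!r}: residues {missing[:5]} missing from profile {tag}"
                )
        mean_a = float(rmsf_a.loc[resids].mean())
        mean_b = float(rmsf_b.loc[resids].mean())
        delta = mean_b - mean_a
        if delta < -min_delta:
            cls = "rigidified"
        elif delta > min_delta:
            cls = "flexibilized"
        else:
            cls = "unchanged"
        report.comparisons.append(RegionComparison(region, mean_a, mean_b, delta, cls))
    return report


def average_profiles(profiles: list[pd.Series]) -> pd.Series:
    """Average RMSF profiles from replicate trajectories (indexes must agree)."""
    if not profiles:
        raise ValidationError("no profiles to average")
    base = profiles[0].index
    for p in profiles[1:]:
        if not p.index.equals(base):
            raise ValidationError("replicate profiles cover different residues")
    return pd.concat(profiles, axis=1).mean(axis=1).rename("rmsf")
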