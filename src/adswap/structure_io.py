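"""PDB chain reading, backbone torsions, and SSE vectorization.

A protein chain is reduced to its backbone geometry: per-residue N/Cα/C
coordinates, IUPAC φ/ψ torsions, and the helix/strand segments announced by the
file's HELIX/SHEET records.  Each secondary structural element (SSE) is
abstracted as a least-squares line through its Cα atoms — a unit direction
oriented N→C, a centroid, and the length of the Cα cloud projected onto the
line.  These vectors are the raw material of the angle-distance image.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "ProteinChain",
    "SSEVector",
    "read_chain",
    "chain_from_gemmi",
    "extract_sses",
    "vectorize_segment",
    "backbone_torsions",
    "torsion",
    "angle_diff",
    "vector_angle",
]

SeqId = tuple[int, str]


@dataclass
class Residue:
    seq_id: SeqId                 # author residue number + insertion code
    aa: str                       # one-letter code ('X' when unknown)
    ca: np.ndarray                # Cα coordinate, Å
    n: np.ndarray | None = None
    c: np.ndarray | None = None
    phi: float | None = None      # degrees in (-180, 180]; None at termini/breaks
    psi: float | None = None


@dataclass
class SSEVector:
    index: int                    # ordinal along the sequence
    kind: str                     # "helix" | "strand"
    span: tuple[SeqId, SeqId]     # first/last residue seq_ids
    first_pos: int                # positional indices into the chain
    last_pos: int
    n_x: int                      # residue count
    direction: np.ndarray         # unit vector, N→C oriented
    centroid: np.ndarray          # Cα mean, Å
    length: float                 # L_x: projection span of first/last Cα, Å

    @property
    def vector(self) -> np.ndarray:
        """Direction scaled by L_x."""
        return self.direction * self.length


class ProteinChain:
    """Ordered backbone of one chain; residues sorted by author numbering."""

    def __init__(self, chain_id: str, residues: list[Residue],
                 sse_records: list[tuple[str, SeqId, SeqId]] | None = None):
        self.id = chain_id
        self.residues = residues
        self.sse_records = sse_records or []
        self.ca = np.array([r.ca for r in residues], dtype=float).reshape(len(residues), 3)
        self._pos = {r.seq_id: i for i, r in enumerate(residues)}

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def position(self, seq_id: SeqId) -> int | None:
        return self._pos.get(seq_id)

    def seq_ids(self) -> list[SeqId]:
        return [r.seq_id for r in self.residues]


# ---------------------------------------------------------------------------
# geometry helpers

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def vector_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    c = float(np.clip(np.dot(_unit(a), _unit(b)), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def torsion(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Dihedral p1-p2-p3-p4 in degrees, wrapped to (-180, 180]."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def angle_diff(a: float, b: float) -> float:
    """Minimal periodic |a - b| for angles in degrees; always <= 180."""
    d = abs(a - b) % 360.0
    return 360.0 - d if d > 180.0 else d


# ---------------------------------------------------------------------------
# reading

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}


def _pick_atom(res: gemmi.Residue, name: str) -> np.ndarray | None:
    best = None
    for atom in res:
        if atom.name == name and (best is None or atom.occ > best.occ):
            best = atom
    if best is None:
        return None
    return np.array([best.pos.x, best.pos.y, best.pos.z], dtype=float)


def chain_from_gemmi(structure: gemmi.Structure, chain_id: str) -> ProteinChain:
    """Convert the first model's chain of a gemmi structure to a ProteinChain."""
    model = structure[0]
    names = [c.name for c in model]
    if chain_id not in names:
        raise ValueError(
            f"chain {chain_id!r} not found in {structure.name!r}; "
            f"available chains: {', '.join(sorted(set(names)))}")
    residues: list[Residue] = []
    for chain in model:
        if chain.name != chain_id:
            continue
        for res in chain:
            if res.het_flag == "H" and res.name not in _AA3TO1:
                continue
            if res.name == "HOH":
                continue
            ca = _pick_atom(res, "CA")
            if ca is None:
                continue
            residues.append(Residue(
                seq_id=(res.seqid.num, (res.seqid.icode or " ").strip()),
                aa=_AA3TO1.get(res.name, "X"),
                ca=ca,
                n=_pick_atom(res, "N"),
                c=_pick_atom(res, "C"),
            ))
    if not residues:
        raise ValueError(f"chain {chain_id!r} contains no Cα atoms")
    residues.sort(key=lambda r: (r.seq_id[0], r.seq_id[1]))

    records: list[tuple[str, SeqId, SeqId]] = []
    for h in structure.helices:
        if h.start.chain_name == chain_id:
            records.append(("helix",
                            (h.start.res_id.seqid.num, (h.start.res_id.seqid.icode or " ").strip()),
                            (h.end.res_id.seqid.num, (h.end.res_id.seqid.icode or " ").strip())))
    for sheet in structure.sheets:
        for s in sheet.strands:
            if s.start.chain_name == chain_id:
                records.append(("strand",
                                (s.start.res_id.seqid.num, (s.start.res_id.seqid.icode or " ").strip()),
                                (s.end.res_id.seqid.num, (s.end.res_id.seqid.icode or " ").strip())))

    out = ProteinChain(f"{structure.name}{chain_id}", residues, records)
    backbone_torsions(out)
    return out


def read_chain(path: str | Path, chain_id: str) -> ProteinChain:
    """Read one chain of a PDB-format file (first model, highest-occupancy
    alternate locations, hetero/water excluded)."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.name = Path(path).stem
    return chain_from_gemmi(st, chain_id)


# ---------------------------------------------------------------------------
# torsions

def backbone_torsions(chain: ProteinChain,
                      break_cutoff: float = 2.5) -> list[tuple[float | None, float | None]]:
    """Fill and return per-residue (φ, ψ) in degrees.

    φ(i) needs C(i-1), N(i), Cα(i), C(i); ψ(i) needs N(i), Cα(i), C(i), N(i+1).
    Torsions across a chain break (C–N distance > ``break_cutoff``) and at the
    termini are None.
    """
    res = chain.residues
    for i, r in enumerate(res):
        r.phi = None
        r.psi = None
        if r.n is None or r.c is None:
            continue
        if i > 0:
            prev = res[i - 1]
            if prev.c is not None and np.linalg.norm(r.n - prev.c) <= break_cutoff:
                r.phi = torsion(prev.c, r.n, r.ca, r.c)
        if i + 1 < len(res):
            nxt = res[i + 1]
            if nxt.n is not None and np.linalg.norm(nxt.n - r.c) <= break_cutoff:
                r.psi = torsion(r.n, r.ca, r.c, nxt.n)
    return [(r.phi, r.psi) for r in res]


# ---------------------------------------------------------------------------
# SSE extraction and vectorization

def vectorize_segment(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares 3D line through a Cα cloud.

    Returns (unit direction oriented N→C, centroid, L = span of the first/last
    point projections onto the line).  Raises on degenerate input.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need at least 3 coordinates")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    if np.allclose(centered, 0.0):
        raise ValueError("degenerate segment: all points identical")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    # orient N→C
    if np.dot(direction, coords[-1] - coords[0]) < 0:
        direction = -direction
    proj = centered @ direction
    length = float(proj[-1] - proj[0])
    if length < 0:  # can only happen for pathological clouds; keep |span|
        length = -length
    return direction, centroid, length


# φ/ψ basins of the computed (record-less) assignment
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)


def _torsion_labels(chain: ProteinChain) -> list[str]:
    labels = []
    for r in chain.residues:
        lab = "-"
        if r.phi is not None and r.psi is not None:
            if _HELIX_PHI[0] <= r.phi <= _HELIX_PHI[1] and _HELIX_PSI[0] <= r.psi <= _HELIX_PSI[1]:
                lab = "helix"
            elif r.phi < -80.0 and (r.psi > 90.0 or r.psi < -150.0):
                lab = "strand"
        labels.append(lab)
    return labels


def extract_sses(chain: ProteinChain, source: str = "records",
                 min_len: int = 3) -> list[SSEVector]:
    """Ordered, non-overlapping helix/strand vectors of a chain.

    ``source="records"`` uses the file's HELIX/SHEET announcements (the
    default); ``source="geometry"`` is a torsion-basin fallback for record-less
    files.  Segments shorter than ``min_len`` residues are dropped.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")

    spans: list[tuple[str, int, int]] = []  # (kind, first_pos, last_pos)
    if source == "records":
        for kind, start, end in chain.sse_records:
            positions = [i for i, r in enumerate(chain.residues)
                         if (start[0], start[1]) <= (r.seq_id[0], r.seq_id[1]) <= (end[0], end[1])]
            if len(positions) >= min_len:
                spans.append((kind, positions[0], positions[-1]))
    elif source == "geometry":
        labels = _torsion_labels(chain)
        i = 0
        while i < len(labels):
            if labels[i] in ("helix", "strand"):
                j = i
                while j + 1 < len(labels) and labels[j + 1] == labels[i]:
                    j += 1
                if j - i + 1 >= min_len:
                    spans.append((labels[i], i, j))
                i = j + 1
            else:
                i += 1
    else:
        raise ValueError(f"unknown SSE source {source!r}")

    spans.sort(key=lambda s: s[1])
    sses: list[SSEVector] = []
    prev_end = -1
    for kind, first, last in spans:
        if first <= prev_end:
            warnings.warn(f"overlapping SSE record {kind} at positions {first}-{last} dropped")
            continue
        coords = chain.ca[first:last + 1]
        try:
            direction, centroid, length = vectorize_segment(coords)
        except ValueError:
            continue
        sses.append(SSEVector(
            index=len(sses), kind=kind,
            span=(chain.residues[first].seq_id, chain.residues[last].seq_id),
            first_pos=first, last_pos=last, n_x=last - first + 1,
            direction=direction, centroid=centroid, length=length))
        prev_end = last
    return sses
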