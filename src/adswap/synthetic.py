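"""Parameterized synthetic closed/open structure pairs.

The generator emulates the geometry this method cares about: a chain of two
(or three) domains built from ideal helix/strand torsions, connected by loops,
with a domain-swapped "open" conformer produced by rigidly rotating one domain
about an axis through a hinge Cα.  Negative controls are noise-perturbed
copies with no domain rotation.  Everything is seeded; identical spec + seed
reproduce bit-identical coordinates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .structure_io import ProteinChain, Residue, backbone_torsions, chain_from_gemmi, vectorize_segment

__all__ = [
    "FixtureSpec",
    "make_closed_form",
    "make_open_form",
    "make_common_homolog",
    "write_pdb",
    "to_gemmi",
    "build_backbone",
    "rotation_matrix",
]

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_OMEGA = 180.0

TORSIONS = {"helix": (-57.0, -47.0), "strand": (-120.0, 125.0)}

# loop φ/ψ basins sampled by the compactness-greedy loop builder
_LOOP_BASINS = [(-60.0, -30.0), (-90.0, 0.0), (55.0, 45.0),
                (-140.0, 150.0), (-75.0, 140.0), (-100.0, 120.0)]

Layout = tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class FixtureSpec:
    """Blueprint of a two-domain chain and its open conformer."""
    sse_layout: tuple[Layout, ...] = (
        (("helix", 12), ("strand", 7), ("strand", 5), ("helix", 9)),
        (("strand", 6), ("helix", 11), ("strand", 4)),
    )
    loop_len: int = 4             # residues between SSEs of one domain
    linker_len: int = 6           # residues between domains (houses the hinge)
    ds_type: str = "C"            # where the swapped domain sits: N | C | middle
    swap_rotation: float = 120.0  # degrees of the planted domain rotation
    noise_sigma: float = 0.0      # Å, Gaussian coordinate noise
    seed: int = 0

    def domain_lengths(self) -> list[int]:
        return [sum(n for _, n in d) + self.loop_len * (len(d) - 1)
                for d in self.sse_layout]

    def total_length(self) -> int:
        d = self.domain_lengths()
        return sum(d) + self.linker_len * (len(d) - 1)

    def hinge_positions(self) -> list[int]:
        """0-based pivot residue position(s) of the planted hinge(s)."""
        d = self.domain_lengths()
        pivots = []
        offset = 0
        for length in d[:-1]:
            offset += length
            pivots.append(offset + self.linker_len // 2)
            offset += self.linker_len
        return pivots

    def swapped_positions(self) -> tuple[int, int]:
        """Positional range (inclusive) of the rotated segment in the open form."""
        piv = self.hinge_positions()
        n = self.total_length()
        if self.ds_type == "C":
            return piv[-1] + 1, n - 1
        if self.ds_type == "N":
            return 0, piv[0] - 1
        if self.ds_type == "middle":
            if len(piv) < 2:
                raise ValueError("middle swap needs three domains in sse_layout")
            return piv[0] + 1, piv[1] - 1
        raise ValueError(f"unknown ds_type {self.ds_type!r}")

    def sse_spans(self) -> list[tuple[str, int, int]]:
        """(kind, first_pos, last_pos) of every laid-out SSE."""
        spans = []
        pos = 0
        for di, domain in enumerate(self.sse_layout):
            if di > 0:
                pos += self.linker_len
            for si, (kind, n) in enumerate(domain):
                if si > 0:
                    pos += self.loop_len
                spans.append((kind, pos, pos + n - 1))
                pos += n
        return spans


# ---------------------------------------------------------------------------
# backbone construction

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d so that |cd|=bond, ∠bcd=angle and torsion(a,b,c,d)=torsion."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(theta),
                  bond * np.sin(theta) * np.cos(chi),
                  -bond * np.sin(theta) * np.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi: list[tuple[float, float]]) -> np.ndarray:
    """Backbone N/Cα/C coordinates from per-residue (φ, ψ), ω fixed at 180°.

    φ of the first residue is unused (undefined at the N terminus).  Returns an
    array of shape (n_residues, 3 atoms, 3).
    """
    n = len(phi_psi)
    atoms = np.zeros((n, 3, 3))
    atoms[0, 0] = (0.0, 0.0, 0.0)
    atoms[0, 1] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _A_N_CA_C)
    atoms[0, 2] = atoms[0, 1] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(n - 1):
        psi = phi_psi[i][1]
        phi_next = phi_psi[i + 1][0]
        atoms[i + 1, 0] = _nerf(atoms[i, 0], atoms[i, 1], atoms[i, 2], _B_C_N, _A_CA_C_N, psi)
        atoms[i + 1, 1] = _nerf(atoms[i, 1], atoms[i, 2], atoms[i + 1, 0], _B_N_CA, _A_C_N_CA, _OMEGA)
        atoms[i + 1, 2] = _nerf(atoms[i, 2], atoms[i + 1, 0], atoms[i + 1, 1], _B_CA_C, _A_N_CA_C, phi_next)
    return atoms


def _segment_torsions(spec: FixtureSpec, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Per-residue (φ, ψ): ideal SSE basins, loops chosen greedily for compactness."""
    torsions: list[tuple[float, float]] = []
    pending_loops: list[tuple[int, int]] = []  # (start index, length) of undecided loops

    def grow_loop(length: int) -> None:
        """Append `length` loop residues, trying a few torsion draws and keeping
        the one that leaves the chain most compact and clash-free."""
        base = list(torsions)
        best = None
        for _ in range(6):
            cand = [tuple(_LOOP_BASINS[rng.integers(len(_LOOP_BASINS))]) for _ in range(length)]
            trial = base + cand
            atoms = build_backbone(trial + [TORSIONS["helix"]] * 3)  # probe a short lookahead
            ca = atoms[:, 1, :]
            rg = float(np.sqrt(((ca - ca.mean(0)) ** 2).sum(1).mean()))
            d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            for k in range(len(ca) - 1):
                d[k, k + 1] = d[k + 1, k] = np.inf
            clash = float((d < 2.5).sum())
            score = rg + 10.0 * clash
            if best is None or score < best[0]:
                best = (score, cand)
        torsions.extend(best[1])

    first_domain = True
    for domain in spec.sse_layout:
        if not first_domain:
            grow_loop(spec.linker_len)
        first_domain = False
        first_sse = True
        for kind, n in domain:
            if not first_sse:
                grow_loop(spec.loop_len)
            first_sse = False
            torsions.extend([TORSIONS[kind]] * n)
    return torsions


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


# ---------------------------------------------------------------------------
# chains

def _chain_from_atoms(name: str, atoms: np.ndarray,
                      spec: FixtureSpec) -> ProteinChain:
    residues = [Residue(seq_id=(i + 1, ""), aa="A",
                        ca=atoms[i, 1].copy(), n=atoms[i, 0].copy(), c=atoms[i, 2].copy())
                for i in range(atoms.shape[0])]
    records = [(kind, (first + 1, ""), (last + 1, ""))
               for kind, first, last in spec.sse_spans()]
    chain = ProteinChain(name, residues, records)
    backbone_torsions(chain)
    return chain


def _atoms_of(chain: ProteinChain) -> np.ndarray:
    atoms = np.zeros((len(chain), 3, 3))
    for i, r in enumerate(chain.residues):
        atoms[i, 0], atoms[i, 1], atoms[i, 2] = r.n, r.ca, r.c
    return atoms


def make_closed_form(spec: FixtureSpec, path=None) -> ProteinChain:
    """Build the closed (monomer-like) conformer; optionally write it as PDB
    with HELIX/SHEET records consistent with the generated coordinates."""
    rng = np.random.default_rng(spec.seed)
    torsions = _segment_torsions(spec, rng)
    atoms = build_backbone(torsions)
    if spec.noise_sigma > 0:
        atoms = atoms + rng.normal(0.0, spec.noise_sigma, atoms.shape)
    chain = _chain_from_atoms("closed", atoms, spec)
    if path is not None:
        write_pdb(chain, path)
    return chain


def make_open_form(closed: ProteinChain, spec: FixtureSpec, path=None) -> ProteinChain:
    """Rotate the swapped segment of the closed form rigidly about an axis
    through the hinge Cα, then apply fresh coordinate noise.

    The axis is drawn perpendicular to the swapped segment's elongation axis so
    the planted rotation is recoverable from the domain's representative
    vectors.  Axes causing steric collapse (<1 Å contacts) are redrawn.
    """
    rng = np.random.default_rng(spec.seed + 1)
    atoms = _atoms_of(closed)
    if spec.swap_rotation == 0.0 and spec.noise_sigma == 0.0:
        chain = _chain_from_atoms("open", atoms, spec)
        if path is not None:
            write_pdb(chain, path)
        return chain

    first, last = spec.swapped_positions()
    pivots = spec.hinge_positions()
    pivot_pos = pivots[0] if spec.ds_type in ("N", "middle") else pivots[-1]
    if spec.ds_type == "N":
        pivot_pos = pivots[0]
    pivot = atoms[pivot_pos, 1]

    seg_ca = atoms[first:last + 1, 1]
    if seg_ca.shape[0] >= 3:
        rep_dir, _, _ = vectorize_segment(seg_ca)
    else:
        rep_dir = seg_ca[-1] - pivot
        rep_dir /= np.linalg.norm(rep_dir)
    # aim the axis perpendicular to the hinge-to-domain-center direction too
    c0 = 0.5 * (seg_ca[len(seg_ca) // 2] + seg_ca[-1 if spec.ds_type != "N" else 0])
    u = c0 - pivot
    u = rep_dir if np.linalg.norm(u) < 1e-6 else u / np.linalg.norm(u)

    # axis perpendicular to both representative directions of the domain, so
    # the planted rotation is read back by either vectorization method; when u
    # and the fitted line nearly coincide, any axis perpendicular to u works
    base_axis = np.cross(u, rep_dir)
    if np.linalg.norm(base_axis) < 1e-6:
        probe = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        base_axis = np.cross(u, probe)
    base_axis /= np.linalg.norm(base_axis)
    best = None
    for axis in (base_axis, -base_axis):
        rot = rotation_matrix(axis, spec.swap_rotation)
        cand = atoms.copy()
        seg = cand[first:last + 1].reshape(-1, 3)
        cand[first:last + 1] = ((seg - pivot) @ rot.T + pivot).reshape(-1, 3, 3)
        fixed_ca = np.concatenate([cand[:first, 1], cand[last + 1:, 1]]) \
            if first > 0 or last + 1 < cand.shape[0] else np.zeros((0, 3))
        if fixed_ca.shape[0]:
            dmin = float(np.min(np.linalg.norm(
                cand[first:last + 1, 1][:, None] - fixed_ca[None], axis=-1)))
        else:
            dmin = np.inf
        if best is None or dmin > best[0]:
            best = (dmin, cand)
        if dmin >= 1.0:
            break
    if best[0] < 1.0:
        warnings.warn("swap rotation leaves close contacts "
                      f"(min Cα-Cα {best[0]:.2f} Å); keeping the better axis")
    atoms = best[1]
    if spec.noise_sigma > 0:
        atoms = atoms + rng.normal(0.0, spec.noise_sigma, atoms.shape)
    chain = _chain_from_atoms("open", atoms, spec)
    if path is not None:
        write_pdb(chain, path)
    return chain


def make_common_homolog(chain: ProteinChain, noise_sigma: float, seed: int) -> ProteinChain:
    """Noise-perturbed copy with no domain rotation — a common structural
    homolog control that must not register as domain-swapped."""
    if noise_sigma >= 2.0:
        raise ValueError("noise_sigma must stay below 2 Å for a meaningful homolog")
    rng = np.random.default_rng(seed)
    residues = []
    for r in chain.residues:
        def jiggle(x):
            return None if x is None else x + rng.normal(0.0, noise_sigma, 3)
        residues.append(Residue(seq_id=r.seq_id, aa=r.aa, ca=jiggle(r.ca),
                                n=jiggle(r.n), c=jiggle(r.c)))
    out = ProteinChain(chain.id + "_hom", residues, list(chain.sse_records))
    backbone_torsions(out)
    return out


# ---------------------------------------------------------------------------
# PDB round-trip

def to_gemmi(chain: ProteinChain, chain_name: str = "A") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = chain.id or "model"
    model = gemmi.Model("1")
    gchain = gemmi.Chain(chain_name)
    for r in chain.residues:
        gr = gemmi.Residue()
        gr.name = "ALA"
        gr.seqid = gemmi.SeqId(r.seq_id[0], r.seq_id[1] or " ")
        for name, el, pos in (("N", "N", r.n), ("CA", "C", r.ca), ("C", "C", r.c)):
            if pos is None:
                continue
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(el)
            a.pos = gemmi.Position(*[float(x) for x in pos])
            a.occ = 1.0
            gr.add_atom(a)
        gchain.add_residue(gr)
    model.add_chain(gchain)
    st.add_model(model)
    for kind, start, end in chain.sse_records:
        if kind == "helix":
            h = gemmi.Helix()
            h.start = gemmi.AtomAddress(chain_name, gemmi.SeqId(start[0], start[1] or " "), "ALA", "")
            h.end = gemmi.AtomAddress(chain_name, gemmi.SeqId(end[0], end[1] or " "), "ALA", "")
            h.pdb_helix_class = 1
            h.length = end[0] - start[0] + 1
            st.helices.append(h)
        else:
            sheet = gemmi.Sheet(f"S{len(st.sheets) + 1}")
            s = gemmi.Sheet.Strand()
            s.start = gemmi.AtomAddress(chain_name, gemmi.SeqId(start[0], start[1] or " "), "ALA", "")
            s.end = gemmi.AtomAddress(chain_name, gemmi.SeqId(end[0], end[1] or " "), "ALA", "")
            s.sense = 0
            sheet.strands.append(s)
            st.sheets.append(sheet)
    st.setup_entities()
    return st


def write_pdb(chain: ProteinChain, path, chain_name: str = "A") -> None:
    st = to_gemmi(chain, chain_name)
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())
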