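"""Backbone phi/psi torsion analysis of peptide conformers.

The orientation of a peptide backbone is described by the dihedral angles
phi_k = C(k-1)-N(k)-CA(k)-C(k) and psi_k = N(k)-CA(k)-C(k)-N(k+1), using
the IUPAC sign convention with angles in (-180, 180].  For a C-terminally
amidated peptide the amide nitrogen serves as N(k+1) of the last residue,
so an amidated pentapeptide has exactly four full (phi, psi) pairs; the
table rows are numbered 1..n-1 from a declared start terminus, row k
holding the angles of residue k+1.

The module also provides circular angle arithmetic and a simple
helix-resemblance score: the RMS circular distance of all (phi, psi)
pairs from the canonical alpha-helix point (-57, -47).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GeometryRecord

#: canonical alpha-helix backbone angles (deg)
ALPHA_HELIX_PHI_PSI = (-57.0, -47.0)


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    w = deg - 360.0 * np.round(np.asarray(deg) / 360.0)
    w = np.where(w <= -180.0, w + 360.0, w)
    return float(w) if np.ndim(deg) == 0 else w


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (deg) of four points, IUPAC convention.

    With b1 = p2-p1, b2 = p3-p2, b3 = p4-p3 and the plane normals
    n1 = b1 x b2, n2 = b2 x b3, the angle is
    atan2((n1 x n2) . b2_hat, n1 . n2), wrapped to (-180, 180].
    Collinear consecutive bonds make the angle undefined and raise.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    b2_len = np.linalg.norm(b2)
    if b2_len == 0.0:
        raise ValueError("degenerate dihedral: central bond has zero length")
    scale = max(np.linalg.norm(b1), 1.0) * max(np.linalg.norm(b3), 1.0) * b2_len
    if np.linalg.norm(n1) < 1e-10 * scale or np.linalg.norm(n2) < 1e-10 * scale:
        raise ValueError("degenerate dihedral: three consecutive points are collinear")
    y = np.dot(np.cross(n1, n2), b2 / b2_len)
    x = np.dot(n1, n2)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


@dataclass
class BackboneMap:
    """Indices of the backbone chain N1, CA1, C1, N2, CA2, C2, ...

    ``atom_indices`` has length 3n for n residues; ``amide_n_index``
    optionally points at the C-terminal amide nitrogen, which completes the
    final psi.  ``source`` records whether the map came from PDB atom names
    or was supplied explicitly (XYZ files carry no atom-name metadata, so
    element lists alone cannot identify a backbone).
    """

    atom_indices: list[int]
    amide_n_index: int | None = None
    source: str = "explicit_indices"

    def __post_init__(self) -> None:
        if len(self.atom_indices) % 3 != 0 or len(self.atom_indices) < 6:
            raise ValueError("backbone map needs 3 atoms per residue and >= 2 residues")

    @property
    def n_residues(self) -> int:
        return len(self.atom_indices) // 3


def backbone_map_from_pdb(geom: GeometryRecord) -> BackboneMap:
    """Derive the backbone map from PDB-style N/CA/C atom names.

    A trailing residue containing only a nitrogen (names N, NT or NH2) is
    interpreted as the C-terminal amide group.
    """
    if geom.atom_names is None or geom.residue_index is None:
        raise ValueError("geometry lacks atom names / residue numbers; supply an explicit map")
    by_residue: dict[int, dict[str, int]] = {}
    for i, (name, resid) in enumerate(zip(geom.atom_names, geom.residue_index)):
        by_residue.setdefault(resid, {})[name.upper()] = i
    indices: list[int] = []
    amide = None
    residues = sorted(by_residue)
    for pos, resid in enumerate(residues):
        atoms = by_residue[resid]
        if all(k in atoms for k in ("N", "CA", "C")):
            indices.extend([atoms["N"], atoms["CA"], atoms["C"]])
        elif pos == len(residues) - 1:
            for key in ("N", "NT", "NH2"):
                if key in atoms:
                    amide = atoms[key]
                    break
            if amide is None:
                raise ValueError(f"residue {resid} has no backbone N/CA/C atoms")
        else:
            raise ValueError(f"residue {resid} is missing backbone N/CA/C atoms")
    return BackboneMap(indices, amide, source="pdb_names")


@dataclass
class BackboneTorsionTable:
    """Per-row (phi, psi) in degrees; rows numbered 1..n from the start terminus."""

    phi_deg: np.ndarray
    psi_deg: np.ndarray

    def __post_init__(self) -> None:
        self.phi_deg = np.atleast_1d(np.asarray(self.phi_deg, dtype=float))
        self.psi_deg = np.atleast_1d(np.asarray(self.psi_deg, dtype=float))
        if self.phi_deg.shape != self.psi_deg.shape:
            raise ValueError("phi and psi arrays must have equal length")
        if self.phi_deg.size == 0:
            raise ValueError("torsion table must be non-empty")

    def __len__(self) -> int:
        return int(self.phi_deg.size)

    def as_pairs(self) -> list[tuple[float, float]]:
        return [(float(p), float(s)) for p, s in zip(self.phi_deg, self.psi_deg)]


def backbone_torsions(
    geom: GeometryRecord, backbone_map: BackboneMap, start_terminus: str = "N"
) -> BackboneTorsionTable:
    """Compute the (phi, psi) table of a peptide backbone.

    Row k holds residue k+1's angles counting from ``start_terminus``
    ("N", the default, matches numbering from the first residue of the
    chain; "C" reverses the row order).  Without an amide nitrogen the
    last residue's psi is undefined and the final row is dropped.
    """
    coords = geom.coords_angstrom
    n = backbone_map.n_residues
    if n < 2:
        raise ValueError("at least 2 residues are required for torsion analysis")
    if max(backbone_map.atom_indices) >= len(geom) or (
        backbone_map.amide_n_index is not None and backbone_map.amide_n_index >= len(geom)
    ):
        raise ValueError("backbone map refers to atoms outside the geometry")

    def atom(res: int, kind: int) -> np.ndarray:  # kind: 0=N, 1=CA, 2=C
        return coords[backbone_map.atom_indices[3 * (res - 1) + kind]]

    phis, psis = [], []
    for k in range(2, n + 1):
        phi = dihedral(atom(k - 1, 2), atom(k, 0), atom(k, 1), atom(k, 2))
        if k < n:
            psi = dihedral(atom(k, 0), atom(k, 1), atom(k, 2), atom(k + 1, 0))
        elif backbone_map.amide_n_index is not None:
            psi = dihedral(
                atom(k, 0), atom(k, 1), atom(k, 2), coords[backbone_map.amide_n_index]
            )
        else:
            break  # free C-terminus: last psi undefined, drop the row
        phis.append(phi)
        psis.append(psi)
    if not phis:
        raise ValueError("no complete (phi, psi) pair could be computed")
    if start_terminus.upper() == "C":
        phis, psis = phis[::-1], psis[::-1]
    elif start_terminus.upper() != "N":
        raise ValueError("start_terminus must be 'N' or 'C'")
    return BackboneTorsionTable(np.array(phis), np.array(psis))


def circular_difference(a_deg: float, b_deg: float) -> float:
    """Shortest angular distance |a - b| on the circle, in [0, 180]."""
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 360.0
    out = np.minimum(d, 360.0 - d)
    return float(out) if np.ndim(out) == 0 else out


def helix_deviation(table: BackboneTorsionTable) -> float:
    """RMS circular distance of all (phi, psi) pairs from the alpha-helix point.

    0 means an ideal (-57, -47) helix; values grow toward 180 as the
    backbone departs from helical geometry.
    """
    phi0, psi0 = ALPHA_HELIX_PHI_PSI
    d_phi = circular_difference(table.phi_deg, phi0)
    d_psi = circular_difference(table.psi_deg, psi0)
    return float(np.sqrt(np.mean(np.concatenate([np.atleast_1d(d_phi) ** 2, np.atleast_1d(d_psi) ** 2]))))
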