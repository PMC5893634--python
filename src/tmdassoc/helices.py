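"""Toy two-helix coordinate ensembles with integrin-style residue labels.

These ensembles stand in for the αIIbβ3 transmembrane dimer when exercising
structural observables without MD: two ideal α-helices (1.5 Å rise, 100°
twist per residue) carrying the residues the clasp analyses name — the
GXXXG outer-clasp glycines (α-chain G972/G976 vs β-chain V700/I704), the
inner-clasp aromatics (F992/F993 vs W715), the membrane-proximal charges
(R995/R997 vs D723/E726), the snorkeling lysine K716 — plus an optional
pseudo-lipid plane of head-group oxygens.  Side chains are single placement
points (ring centroids, terminal N/O atoms), which is sufficient for every
observable defined through distances or angles between named atoms.

Frame ``f`` places the two helices so that the distance between the
mass-weighted COMs of their Cα atoms equals ``separation_series[f]``
exactly; the atom table is identical across frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .structures import StructureEnsemble, _element_mass

__all__ = ["HelixGeometry", "generate_helix_dimer_ensemble"]

# residue-name overrides on an otherwise poly-ALA helix
_CHAIN_A_NAMES = {971: "VAL", 972: "GLY", 973: "VAL", 976: "GLY",
                  992: "PHE", 993: "PHE", 995: "ARG", 996: "PRO",
                  997: "ARG", 1015: "VAL"}
_CHAIN_B_NAMES = {698: "LEU", 700: "VAL", 704: "ILE", 715: "TRP",
                  716: "LYS", 718: "ASP", 723: "ASP", 726: "GLU", 747: "ILE"}

# pseudo-sidechain placement: atom name -> (element, radial Å, tangential Å)
_SIDECHAINS = {
    "PHE": [("RC", "C", 3.4, 0.0)],
    "TRP": [("RC", "C", 3.9, 0.0)],
    "ARG": [("NH1", "N", 5.0, 0.5), ("NH2", "N", 5.0, -0.5)],
    "LYS": [("NZ", "N", 4.9, 0.0)],
    "ASP": [("OD1", "O", 2.9, 0.5), ("OD2", "O", 2.9, -0.5)],
    "GLU": [("OE1", "O", 3.9, 0.5), ("OE2", "O", 3.9, -0.5)],
}


@dataclass(frozen=True)
class HelixGeometry:
    """Ideal α-helix construction parameters (Å / degrees)."""

    rise: float = 1.5
    twist_deg: float = 100.0
    ca_radius: float = 2.3
    chain_a_range: tuple = (966, 1015)
    chain_b_range: tuple = (694, 747)
    lipid_spacing: float = 2.0
    lipid_margin: float = 8.0
    lipid_offset: float = 3.0


def _build_helix(res_range, names, geom: HelixGeometry, flip: bool):
    """One ideal helix along +z; returns (records, coords)."""
    start, stop = res_range
    records, coords = [], []
    twist = np.deg2rad(geom.twist_deg)
    for i, res_id in enumerate(range(start, stop + 1)):
        res_name = names.get(res_id, "ALA")
        theta = i * twist + (np.pi if flip else 0.0)
        z = i * geom.rise
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        tang = np.array([-np.sin(theta), np.cos(theta), 0.0])
        ca = geom.ca_radius * u + np.array([0.0, 0.0, z])
        n = 1.6 * np.array([np.cos(theta - 0.5), np.sin(theta - 0.5), 0.0]) + [0, 0, z - 0.9]
        c = 1.7 * np.array([np.cos(theta + 0.5), np.sin(theta + 0.5), 0.0]) + [0, 0, z + 0.7]
        o = c + np.array([0.0, 0.0, 1.23])
        for atom_name, element, xyz in (("N", "N", n), ("CA", "C", ca),
                                        ("C", "C", c), ("O", "O", o)):
            records.append((res_id, res_name, atom_name, element))
            coords.append(xyz)
        for atom_name, element, radial, tangential in _SIDECHAINS.get(res_name, ()):
            records.append((res_id, res_name, atom_name, element))
            coords.append(ca + (radial - geom.ca_radius) * u + tangential * tang)
    return records, np.array(coords)


def generate_helix_dimer_ensemble(separation_series, geometry: HelixGeometry | None = None,
                                  seed: int = 0, jitter: float = 0.0,
                                  include_lipids: bool = True) -> StructureEnsemble:
    """Build the toy dimer ensemble, one frame per requested separation (Å).

    ``jitter`` adds isotropic Gaussian noise (Å) to helix atoms of every
    frame (reproducible via ``seed``); the frame-defining Cα-COM separation
    is restored exactly afterwards.  The pseudo-lipid oxygen plane (chain
    ``L``, residue ``LIP``, atom ``O``) sits ``geometry.lipid_offset`` Å
    below the snorkeling lysine's NZ and never moves.
    """
    separations = np.asarray(list(separation_series), dtype=float)
    if separations.size == 0:
        raise ValidationError("separation series must be non-empty")
    if np.any(separations <= 0):
        raise ValidationError("separations must be positive")
    geom = geometry or HelixGeometry()

    rec_a, xyz_a = _build_helix(geom.chain_a_range, _CHAIN_A_NAMES, geom, flip=False)
    rec_b, xyz_b = _build_helix(geom.chain_b_range, _CHAIN_B_NAMES, geom, flip=True)

    def center_on_ca(records, xyz):
        ca_mask = np.array([r[2] == "CA" for r in records])
        return xyz - xyz[ca_mask].mean(axis=0)

    xyz_a = center_on_ca(rec_a, xyz_a)
    xyz_b = center_on_ca(rec_b, xyz_b)

    rows = ([("A",) + r for r in rec_a] + [("B",) + r for r in rec_b])
    helix_xyz = np.vstack([xyz_a, xyz_b])
    n_helix = helix_xyz.shape[0]
    is_b = np.array([row[0] == "B" for row in rows])
    ca_mask = np.array([row[3] == "CA" for row in rows])

    lipid_xyz = np.empty((0, 3))
    if include_lipids:
        nz_rows = [i for i, row in enumerate(rows)
                   if row[0] == "B" and row[1] == 716 and row[3] == "NZ"]
        anchor = helix_xyz[nz_rows[0]] if nz_rows else helix_xyz.min(axis=0)
        z_plane = anchor[2] - geom.lipid_offset
        half = max(separations.max(), 10.0) / 2 + geom.lipid_margin
        pos = np.arange(0.0, half + geom.lipid_spacing, geom.lipid_spacing)
        ticks = np.concatenate([-pos[:0:-1], pos])  # symmetric, includes 0
        gx, gy = np.meshgrid(anchor[0] + ticks, anchor[1] + ticks)
        lipid_xyz = np.column_stack([gx.ravel(), gy.ravel(),
                                     np.full(gx.size, z_plane)])
        rows += [("L", j + 1, "LIP", "O", "O") for j in range(lipid_xyz.shape[0])]

    rng = np.random.default_rng(seed)
    frames = np.empty((separations.size, len(rows), 3))
    for f, sep in enumerate(separations):
        xyz = helix_xyz.copy()
        if jitter > 0:
            xyz += rng.normal(0.0, jitter, xyz.shape)
        # place chain B so the Cα-COM separation is exact even under jitter
        com_a = xyz[ca_mask & ~is_b].mean(axis=0)
        com_b = xyz[ca_mask & is_b].mean(axis=0)
        xyz[is_b] += com_a + np.array([sep, 0.0, 0.0]) - com_b
        frames[f, :n_helix] = xyz
        if lipid_xyz.size:
            frames[f, n_helix:] = lipid_xyz

    # rows for helices are (chain, res_id, res_name, atom_name, element);
    # lipid rows already carry the same 5 fields
    atoms = pd.DataFrame(rows, columns=["chain_id", "res_id", "res_name",
                                        "atom_name", "element"])
    atoms["mass"] = [_element_mass(el, nm)
                     for el, nm in zip(atoms["element"], atoms["atom_name"])]
    return StructureEnsemble(frames, atoms)
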