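"""Structural observables on helix-dimer ensembles.

Implements the clasp geometry of the integrin TMD analyses: the inter-helix
COM distance (the PMF reaction coordinate), the outer-clasp distance d_OMC
(Cα COMs of the GXXXG motif vs its β-chain partner), the inner-clasp
distance d_IMC (minimum of the two Phe-ring/Trp-ring centroid distances),
hydrogen-bond and salt-bridge occupancies, the lysine snorkeling distance,
native/non-native contact counts, RMSD/RMSF after mass-weighted Kabsch
superposition, the helix-packing θ angles entering the configurational
restriction factor, and principal-component histogram-overlap convergence.

Cutoff comparisons are inclusive (≤) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import SelectionError, ValidationError
from .structures import AtomSelection, StructureEnsemble

__all__ = [
    "ObservableSeries", "ContactReport", "com_distance", "d_omc", "d_imc",
    "hbond_occupancy", "salt_bridge_occupancy", "snorkeling_occupancy",
    "contacts", "rmsd", "rmsf", "superpose", "theta_angles",
    "pc_overlap_convergence", "reference_distances",
]

_PHE_RING = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
_TRP_RING = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")


@dataclass
class ObservableSeries:
    """A per-frame scalar observable."""

    name: str
    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.times, self.name: self.values})


def _series(name, values, units=""):
    return ObservableSeries(name, np.arange(len(values), dtype=float),
                            np.asarray(values, dtype=float), units)


def com_distance(ensemble: StructureEnsemble, sel_a: AtomSelection,
                 sel_b: AtomSelection, name: str = "d_com") -> ObservableSeries:
    """Per-frame distance between the mass-weighted COMs of two selections (Å)."""
    com_a = ensemble.com(ensemble.select(sel_a))
    com_b = ensemble.com(ensemble.select(sel_b))
    return _series(name, np.linalg.norm(com_a - com_b, axis=1), "Å")


def d_omc(ensemble: StructureEnsemble, chain_alpha: str = "A", chain_beta: str = "B",
          alpha_res=(972, 976), beta_res=(700, 704)) -> ObservableSeries:
    """Outer-membrane-clasp distance: COM of GXXXG-motif Cα atoms
    (α-chain residues 972–976) vs COM of the Cα atoms of β-chain 700–704."""
    sel_a = AtomSelection.range(chain_alpha, *alpha_res, atom_names=("CA",))
    sel_b = AtomSelection.range(chain_beta, *beta_res, atom_names=("CA",))
    return com_distance(ensemble, sel_a, sel_b, name="d_OMC")


def _ring_centroid(ensemble, chain, res_id):
    """Aromatic ring centroid (unweighted mean of ring heavy atoms);
    falls back to a single pre-placed centroid pseudo-atom named RC."""
    atoms = ensemble.atoms
    mask = (atoms["chain_id"] == chain) & (atoms["res_id"] == res_id)
    res = atoms.loc[mask]
    if res.empty:
        raise SelectionError(f"residue {chain}:{res_id} not found")
    ring_names = _TRP_RING if res["res_name"].iloc[0] == "TRP" else _PHE_RING
    idx = res.index[res["atom_name"].isin(ring_names)].to_numpy()
    if idx.size == 0:
        idx = res.index[res["atom_name"] == "RC"].to_numpy()
    if idx.size == 0:
        raise SelectionError(f"no ring atoms (or RC pseudo-atom) on {chain}:{res_id}")
    return ensemble.coords[:, idx, :].mean(axis=1)


def d_imc(ensemble: StructureEnsemble, chain_alpha: str = "A", chain_beta: str = "B",
          phe_res=(992, 993), trp_res: int = 715) -> ObservableSeries:
    """Inner-membrane-clasp distance: the smaller of the two distances from
    the ring centroids of F992 / F993 to the ring centroid of W715."""
    trp = _ring_centroid(ensemble, chain_beta, trp_res)
    dists = [np.linalg.norm(_ring_centroid(ensemble, chain_alpha, r) - trp, axis=1)
             for r in phe_res]
    return _series("d_IMC", np.min(dists, axis=0), "Å")


def hbond_occupancy(ensemble: StructureEnsemble, donor: AtomSelection,
                    acceptor: AtomSelection, hydrogen: AtomSelection | None = None,
                    d_max: float = 3.5, angle_min: float = 120.0) -> float:
    """Fraction of frames with a donor–acceptor hydrogen bond.

    Criteria: donor–acceptor distance ≤ ``d_max`` Å and donor–H–acceptor
    angle ≥ ``angle_min`` degrees.  When no hydrogen selection is supplied
    (heavy-atom-only models) the angle criterion is dropped with a warning.
    """
    di = ensemble.select(donor)
    ai = ensemble.select(acceptor)
    if set(di) & set(ai):
        raise ValidationError("donor and acceptor selections overlap")
    d_xyz = ensemble.coords[:, di[0], :]
    a_xyz = ensemble.coords[:, ai[0], :]
    dist_ok = np.linalg.norm(d_xyz - a_xyz, axis=1) <= d_max
    if hydrogen is None:
        warnings.warn("no hydrogen given; hydrogen-bond criterion is distance-only")
        return float(np.mean(dist_ok))
    h_xyz = ensemble.coords[:, ensemble.select(hydrogen)[0], :]
    v1 = d_xyz - h_xyz
    v2 = a_xyz - h_xyz
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(np.mean(dist_ok & (angles >= angle_min)))


def _min_group_distance(ensemble, idx_a, idx_b):
    return np.array([cdist(ensemble.coords[f, idx_a], ensemble.coords[f, idx_b]).min()
                     for f in range(ensemble.n_frames)])


def salt_bridge_occupancy(ensemble: StructureEnsemble, group_a: AtomSelection,
                          group_b: AtomSelection, cutoff: float = 4.0) -> float:
    """Fraction of frames whose minimal inter-group atom distance is ≤ cutoff (Å).

    Standard usage pairs the guanidinium nitrogens (Nη1/Nη2 of R995 or R997)
    against carboxylate oxygens (Oδ of D723 or Oε of E726)."""
    idx_a = ensemble.select(group_a)
    idx_b = ensemble.select(group_b)
    return float(np.mean(_min_group_distance(ensemble, idx_a, idx_b) <= cutoff))


def snorkeling_occupancy(ensemble: StructureEnsemble,
                         nz_atom: AtomSelection | None = None,
                         lipid_o: AtomSelection | None = None,
                         cutoff: float = 4.0):
    """Lysine snorkeling toward the lipid head groups.

    Returns ``(occupancy, d_snorkeling)`` where d_snorkeling is the per-frame
    minimal distance between the lysine terminal nitrogen (default: K716 NZ)
    and the head-group oxygens of the lower leaflet (default: chain L 'O'
    pseudo-lipid atoms)."""
    nz_atom = nz_atom or AtomSelection(chain="B", res_ids=(716,), atom_names=("NZ",),
                                       label="K716 NZ")
    lipid_o = lipid_o or AtomSelection(chain="L", atom_names=("O",), label="lipid O plane")
    idx_nz = ensemble.select(nz_atom)
    idx_o = ensemble.select(lipid_o)
    d = _min_group_distance(ensemble, idx_nz, idx_o)
    series = _series("d_snorkeling", d, "Å")
    return float(np.mean(d <= cutoff)), series


@dataclass
class ContactReport:
    """Native / non-native inter-chain contacts relative to a reference frame."""

    native: np.ndarray          # per-frame counts
    non_native: np.ndarray      # per-frame counts
    per_residue: pd.DataFrame   # mean native / non-native counts per α-chain residue
    reference_frame: int
    cutoff: float
    granularity: str


def _contact_pairs(coords_a, coords_b, cutoff):
    """Set of (i, j) atom-index pairs within cutoff (inclusive)."""
    d = cdist(coords_a, coords_b)
    ii, jj = np.nonzero(d <= cutoff)
    return set(zip(ii.tolist(), jj.tolist()))


def contacts(ensemble: StructureEnsemble, chain_a: AtomSelection, chain_b: AtomSelection,
             cutoff: float = 7.0, reference_frame: int = 0,
             granularity: str = "residue") -> ContactReport:
    """Inter-chain contact analysis.

    A contact exists when two atoms (``granularity="atom"``) or any atom
    pair of two residues (``granularity="residue"``) are within ``cutoff`` Å
    (inclusive).  Contacts present in ``reference_frame`` are *native*;
    contacts formed in other frames but absent from the reference are
    *non-native*.
    """
    if granularity not in ("atom", "residue"):
        raise ValidationError(f"granularity must be 'atom' or 'residue', got {granularity!r}")
    idx_a = ensemble.select(chain_a)
    idx_b = ensemble.select(chain_b)
    if set(idx_a) & set(idx_b):
        raise ValidationError("chain selections overlap")

    if granularity == "residue":
        # map atoms to (chain, res) groups
        at = ensemble.atoms
        key_a = list(zip(at["chain_id"].iloc[idx_a], at["res_id"].iloc[idx_a]))
        key_b = list(zip(at["chain_id"].iloc[idx_b], at["res_id"].iloc[idx_b]))
        ids_a = pd.factorize(pd.Series(key_a))[0]
        ids_b = pd.factorize(pd.Series(key_b))[0]
    else:
        ids_a = np.arange(len(idx_a))
        ids_b = np.arange(len(idx_b))

    def frame_contacts(f):
        pairs = _contact_pairs(ensemble.coords[f, idx_a], ensemble.coords[f, idx_b], cutoff)
        return {(ids_a[i], ids_b[j]) for i, j in pairs}

    ref = frame_contacts(reference_frame)
    native = np.zeros(ensemble.n_frames, dtype=int)
    non_native = np.zeros(ensemble.n_frames, dtype=int)
    # per-α-residue tallies averaged over frames
    res_a = ensemble.atoms["res_id"].iloc[idx_a].to_numpy()
    if granularity == "residue":
        uniq_keys = pd.Series(list(zip(ensemble.atoms["chain_id"].iloc[idx_a],
                                       ensemble.atoms["res_id"].iloc[idx_a]))).unique()
        group_res = np.array([k[1] for k in uniq_keys])
    else:
        group_res = res_a
    tally_nat = {}
    tally_non = {}
    for f in range(ensemble.n_frames):
        cset = frame_contacts(f)
        nat = cset & ref
        non = cset - ref
        native[f] = len(nat)
        non_native[f] = len(non)
        for group, count in ((nat, tally_nat), (non, tally_non)):
            for i, _ in group:
                rid = int(group_res[i])
                count[rid] = count.get(rid, 0) + 1
    res_ids = sorted(set(tally_nat) | set(tally_non) | set(int(r) for r in group_res))
    per_residue = pd.DataFrame({
        "res_id": res_ids,
        "native_mean": [tally_nat.get(r, 0) / ensemble.n_frames for r in res_ids],
        "non_native_mean": [tally_non.get(r, 0) / ensemble.n_frames for r in res_ids],
    })
    return ContactReport(native, non_native, per_residue, reference_frame, cutoff, granularity)


# -- superposition -----------------------------------------------------------

def _kabsch(mobile, reference, weights):
    """Optimal rotation R, translation t minimising weighted RMSD; applies to
    row-vector coordinates as x @ R.T + t."""
    wsum = weights.sum()
    mu_m = (mobile * weights[:, None]).sum(0) / wsum
    mu_r = (reference * weights[:, None]).sum(0) / wsum
    a = (mobile - mu_m) * weights[:, None]
    h = a.T @ (reference - mu_r)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, mu_r - (rot @ mu_m)


def superpose(ensemble: StructureEnsemble, fit_sel: AtomSelection,
              reference_frame: int = 0) -> StructureEnsemble:
    """Mass-weighted Kabsch superposition of every frame onto the reference
    frame, fitting on ``fit_sel``; returns a transformed copy."""
    fit_idx = ensemble.select(fit_sel)
    if fit_idx.size < 3:
        raise ValidationError("superposition needs at least 3 fit atoms")
    w = ensemble.masses[fit_idx]
    ref = ensemble.coords[reference_frame, fit_idx]
    out = ensemble.coords.copy()
    for f in range(ensemble.n_frames):
        rot, t = _kabsch(ensemble.coords[f, fit_idx], ref, w)
        out[f] = ensemble.coords[f] @ rot.T + t
    return StructureEnsemble(out, ensemble.atoms)


def rmsd(ensemble: StructureEnsemble, fit_sel: AtomSelection,
         report_sel: AtomSelection | None = None) -> ObservableSeries:
    """Per-frame mass-weighted RMSD to frame 0 after Kabsch superposition.

    Fitting and reporting default to the same selection, the convention used
    for the membrane-embedded helix-core analyses."""
    report_sel = report_sel or fit_sel
    sup = superpose(ensemble, fit_sel)
    idx = sup.select(report_sel)
    w = sup.masses[idx]
    diff = sup.coords[:, idx, :] - sup.coords[0, idx, :]
    ms = (w[None, :] * (diff ** 2).sum(axis=2)).sum(axis=1) / w.sum()
    return _series("rmsd", np.sqrt(ms), "Å")


def rmsf(ensemble: StructureEnsemble, sel: AtomSelection,
         fit_sel: AtomSelection | None = None) -> pd.DataFrame:
    """Per-residue Cα root mean square fluctuation about the mean structure.

    The ensemble is first superposed (on ``fit_sel``, default = ``sel``).
    Returns a DataFrame with columns chain_id, res_id, rmsf.
    """
    if ensemble.n_frames < 2:
        raise ValidationError("RMSF undefined for a single frame")
    fit_sel = fit_sel or sel
    sup = superpose(ensemble, fit_sel)
    idx = sup.select(sel)
    at = sup.atoms.iloc[idx]
    ca = at["atom_name"] == "CA"
    idx = idx[ca.to_numpy()]
    at = at.loc[ca]
    xyz = sup.coords[:, idx, :]
    fluct = np.sqrt(((xyz - xyz.mean(axis=0)) ** 2).sum(axis=2).mean(axis=0))
    return pd.DataFrame({"chain_id": at["chain_id"].to_numpy(),
                         "res_id": at["res_id"].to_numpy(),
                         "rmsf": fluct})


def _angle_at(origin, p1, p2):
    v1 = p1 - origin
    v2 = p2 - origin
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValidationError("coincident COMs give a zero-length vector")
    return np.arccos(np.clip(np.einsum("ij,ij->i", v1, v2) / (n1 * n2), -1.0, 1.0))


def theta_angles(ensemble: StructureEnsemble,
                 helix1_sel: AtomSelection | None = None,
                 helix2_sel: AtomSelection | None = None,
                 ref_a_sel: AtomSelection | None = None,
                 ref_b_sel: AtomSelection | None = None):
    """Helix-packing angles (radians, in [0, π]) entering the configurational
    restriction factor: θ_a is the angle at the COM of helix 1 between the
    COM of helix 2 and the COM of the reference triplet (default residues
    971–973); θ_b is defined analogously from helix 2 using residues 698–700.
    """
    helix1_sel = helix1_sel or AtomSelection(chain="A", atom_names=("CA",), label="helix A Cα")
    helix2_sel = helix2_sel or AtomSelection(chain="B", atom_names=("CA",), label="helix B Cα")
    ref_a_sel = ref_a_sel or AtomSelection.range("A", 971, 973, atom_names=("CA",))
    ref_b_sel = ref_b_sel or AtomSelection.range("B", 698, 700, atom_names=("CA",))
    com1 = ensemble.com(ensemble.select(helix1_sel))
    com2 = ensemble.com(ensemble.select(helix2_sel))
    ref_a = ensemble.com(ensemble.select(ref_a_sel))
    ref_b = ensemble.com(ensemble.select(ref_b_sel))
    theta_a = _angle_at(com1, com2, ref_a)
    theta_b = _angle_at(com2, com1, ref_b)
    return (_series("theta_a", theta_a, "rad"), _series("theta_b", theta_b, "rad"))


def pc_overlap_convergence(traj_a: StructureEnsemble, traj_b: StructureEnsemble,
                           n_components: int = 3, n_timepoints: int = 5,
                           n_bins: int = 50, fit_sel: AtomSelection | None = None
                           ) -> np.ndarray:
    """Convergence of internal motions between two trajectories.

    Both trajectories are superposed on the Cα atoms of the first frame of
    ``traj_a``; PCA is done on the pooled coordinates, both trajectories are
    projected, and for growing prefixes (fractions 1/n ... 1) the overlap of
    the two normalised projection histograms (sum of bin-wise minima; 1 =
    identical sampling) is returned as an array of shape
    ``(n_timepoints, n_components)``.
    """
    if not traj_a.atoms[["chain_id", "res_id", "atom_name"]].equals(
            traj_b.atoms[["chain_id", "res_id", "atom_name"]]):
        raise ValidationError("trajectories must share the atom table")
    if min(traj_a.n_frames, traj_b.n_frames) < n_components:
        raise ValidationError("fewer frames than requested components")
    fit_sel = fit_sel or AtomSelection(atom_names=("CA",), label="Cα")
    idx = traj_a.select(fit_sel)
    w = traj_a.masses[idx]
    ref = traj_a.coords[0, idx]

    def flat(traj):
        out = np.empty((traj.n_frames, idx.size * 3))
        for f in range(traj.n_frames):
            rot, t = _kabsch(traj.coords[f, idx], ref, w)
            out[f] = (traj.coords[f, idx] @ rot.T + t).ravel()
        return out

    xa, xb = flat(traj_a), flat(traj_b)
    pooled = np.vstack([xa, xb])
    mean = pooled.mean(axis=0)
    _, _, vt = np.linalg.svd(pooled - mean, full_matrices=False)
    pcs = vt[:n_components]
    proj_a = (xa - mean) @ pcs.T
    proj_b = (xb - mean) @ pcs.T

    out = np.empty((n_timepoints, n_components))
    for t in range(1, n_timepoints + 1):
        na = max(1, int(round(t / n_timepoints * len(proj_a))))
        nb = max(1, int(round(t / n_timepoints * len(proj_b))))
        for c in range(n_components):
            lo = min(proj_a[:, c].min(), proj_b[:, c].min())
            hi = max(proj_a[:, c].max(), proj_b[:, c].max())
            edges = np.linspace(lo, hi, n_bins + 1)
            ha, _ = np.histogram(proj_a[:na, c], bins=edges)
            hb, _ = np.histogram(proj_b[:nb, c], bins=edges)
            out[t - 1, c] = np.minimum(ha / ha.sum(), hb / hb.sum()).sum()
    return out


def reference_distances(ensemble: StructureEnsemble, chain_alpha: str = "A",
                        chain_beta: str = "B", frame: int = 0) -> dict:
    """The four single-structure reference distances of the αIIbβ3 TMD
    analyses, evaluated on one frame (default: model 1) and as ensemble
    means: the inter-helix COM distance over the membrane-embedded Cα
    ranges 996–1015 / 718–747, d_OMC, d_IMC, and the K716 NZ – F992 O
    distance.  Intended for accession-based checks on 2K9J-style files."""
    sel_a = AtomSelection.range(chain_alpha, 996, 1015, atom_names=("CA",))
    sel_b = AtomSelection.range(chain_beta, 718, 747, atom_names=("CA",))
    nz = AtomSelection(chain=chain_beta, res_ids=(716,), atom_names=("NZ",), label="K716 NZ")
    f992o = AtomSelection(chain=chain_alpha, res_ids=(992,), atom_names=("O",), label="F992 O")
    d_nz = np.linalg.norm(ensemble.coords[:, ensemble.select(nz)[0], :]
                          - ensemble.coords[:, ensemble.select(f992o)[0], :], axis=1)
    out = {}
    for key, series in (("d_com_com", com_distance(ensemble, sel_a, sel_b)),
                        ("d_omc", d_omc(ensemble, chain_alpha, chain_beta)),
                        ("d_imc", d_imc(ensemble, chain_alpha, chain_beta)),
                        ("d_k716nz_f992o", _series("d_nz_o", d_nz, "Å"))):
        out[key] = float(series.values[frame])
        out[key + "_ensemble_mean"] = float(series.values.mean())
    return out
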