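"""Synthetic fixtures: toy folds, decoy ladders, shift tables and corpora.

Everything downstream — NOESY simulation, potential contacts, CS/DS/RPF,
TM-score labels and SPANR training — is exercised on data generated here,
with no downloads.  Folds are idealized backbones (3.8 Å consecutive Cα
spacing) with backbone N/C, a placed amide H and one pseudo side-chain
hydrogen per residue; decoys perturb a fold on a controlled ladder so
that the TM-score decreases with the perturbation level; shift tables
draw from amide/side-chain distributions typical of protein ¹H/¹⁵N
spectra.  The synthetic PAE is generated from the TM label — it exists
only to exercise the PAE feature path and is explicitly non-physical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import DatasetEntry, mismatch_augment
from .contacts import ContactSet, ToleranceParams, find_potential_contacts, sufficiency_check
from .noesy import NoesySimParams, simulate_noesy
from .pae import PaeMatrix, pae_features
from .rpf import RpfParams, rpf_scores
from .scores import ScoringParams, contact_score, distance_score
from .shifts_io import PeakList, ShiftEntry, ShiftTable
from .structmodel import Atom, ProteinStructure, place_amide_hydrogens
from .tmscore import tm_score

__all__ = [
    "SynthParams",
    "CorpusEntry",
    "make_fold",
    "make_decoy",
    "make_shift_table",
    "make_pae",
    "score_pair",
    "make_corpus",
    "augment_corpus",
]

#: residue types cycled through synthetic sequences (no PRO/GLY: every
#: residue carries an amide H and the pseudo side-chain H)
_RESIDUE_CYCLE = ("ALA", "VAL", "LEU", "SER", "THR", "PHE", "LYS", "GLU")


@dataclass
class SynthParams:
    """Study conditions for the synthetic corpus.

    n_resi : residues per fold (≥ 10); 60 gives chains long enough for a
        meaningful long-range contact network and a TM-score scale (d0 ≈
        2.6 Å) comparable to small real proteins.
    topology : helix | hairpin | mixed.
    decoy_levels : Å, the perturbation ladder decoys are drawn from;
        spans near-native (0.5 Å) through misfolded (8 Å plus a hinge
        rotation) so TM labels cover both classes.
    corpus_size : number of corpus members.
    """

    n_resi: int = 60
    topology: str = "mixed"
    decoy_levels: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)
    shift_seed: int = 0
    geom_seed: int = 0
    corpus_size: int = 50

    def __post_init__(self):
        if self.n_resi < 10:
            raise ValueError("n_resi must be at least 10")
        if any(l < 0 for l in self.decoy_levels):
            raise ValueError("decoy levels must be non-negative")
        if self.topology not in ("helix", "hairpin", "mixed"):
            raise ValueError("topology must be helix, hairpin or mixed")


# ------------------------------------------------------------------- folds

def _helix_ca(n: int, phase: float = 0.0) -> np.ndarray:
    """Ideal α-helical Cα trace: 1.5 Å rise, 100°/residue, radius chosen
    for an exact 3.8 Å consecutive Cα spacing (≈ 2.28 Å)."""
    k = np.arange(n)
    radius = math.sqrt(3.8 ** 2 - 1.5 ** 2) / (2.0 * math.sin(math.radians(50.0)))
    theta = np.deg2rad(100.0) * k + phase
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                            1.5 * k])


def _hairpin_ca(n: int, sep: float = 5.0) -> np.ndarray:
    """Two antiparallel extended strands (3.4 Å rise, ±0.85 Å zigzag)
    joined by a one-residue turn; consecutive spacing 3.8 Å throughout."""
    m1 = (n - 1) // 2
    m2 = n - m1 - 1
    pts = []
    for k in range(m1):
        pts.append([0.85 * (-1) ** k, 0.0, 3.4 * k])
    z_top = 3.4 * (m1 - 1)
    x_a = pts[-1][0]
    x_b = 0.85 * (-1) ** 0
    apex_xy = ((x_a + x_b) / 2.0, sep / 2.0)
    h_sq = 3.8 ** 2 - (sep / 2.0) ** 2 - ((x_b - x_a) / 2.0) ** 2
    apex_z = z_top + math.sqrt(max(h_sq, 0.25))
    pts.append([apex_xy[0], apex_xy[1], apex_z])
    for k in range(m2):
        pts.append([0.85 * (-1) ** k, sep, z_top - 3.4 * k])
    return np.array(pts)


def _mixed_ca(n: int, phase: float = 0.0) -> np.ndarray:
    """Half helix, a short connector, then an extended strand packed back
    alongside the helix — helix/sheet tertiary contacts."""
    m1 = n // 2
    helix = _helix_ca(m1, phase)
    end = helix[-1]
    # strand runs back down at y = 6 Å from the helix axis; connector of
    # c residues spaced exactly 3.8 Å bridges helix end to strand start
    lateral = np.array([0.0, 6.0, end[2]]) - end
    lateral[2] = 0.0
    lat = np.linalg.norm(lateral)
    c = max(1, math.ceil(lat / 3.8))
    total = 3.8 * (c + 1)
    dz = math.sqrt(max(total ** 2 - lat ** 2, 1.0))
    start = end + lateral + np.array([0.0, 0.0, dz])
    pts = list(helix)
    for k in range(1, c + 1):
        pts.append(end + (start - end) * k / (c + 1))
    m2 = n - m1 - c
    for k in range(m2):
        pts.append(start + np.array([0.0, 0.0, -3.8 * k]))
    return np.array(pts)


def make_fold(params: SynthParams) -> ProteinStructure:
    """Build an idealized protonated fold, deterministic per ``geom_seed``.

    The Cα trace follows the requested topology; each residue then gets a
    backbone N and C in a local frame, a pseudo side-chain hydrogen
    ``HB`` at 1.5 Å from Cα, and (via :func:`place_amide_hydrogens`) an
    amide H.  A small seeded jitter (0.02 Å) makes folds from different
    seeds distinct without breaking the ideal geometry.
    """
    rng = np.random.default_rng(params.geom_seed)
    n = params.n_resi
    phase = float(rng.uniform(0, 2 * np.pi))
    if params.topology == "helix":
        ca = _helix_ca(n, phase)
    elif params.topology == "hairpin":
        ca = _hairpin_ca(n, sep=float(rng.uniform(4.8, 5.3)))
    else:
        ca = _mixed_ca(n, phase)
    ca = ca + rng.normal(0.0, 0.02, size=ca.shape)

    atoms: list[Atom] = []
    ref = np.array([0.0, 0.0, 1.0])
    for idx in range(n):
        i = idx + 1
        resname = _RESIDUE_CYCLE[idx % len(_RESIDUE_CYCLE)]
        p = ca[idx]
        u = ca[idx + 1] - p if idx < n - 1 else p - ca[idx - 1]
        u = u / np.linalg.norm(u)
        perp = ref - np.dot(ref, u) * u
        if np.linalg.norm(perp) < 1e-6:
            perp = np.array([1.0, 0.0, 0.0]) - u[0] * u
        perp = perp / np.linalg.norm(perp)
        n_dir = -(u + 0.8 * perp)
        c_dir = u - 0.8 * perp
        hb_dir = np.cross(u, perp)
        atoms.append(Atom(i, resname, "N", "N",
                          p + 1.46 * n_dir / np.linalg.norm(n_dir)))
        atoms.append(Atom(i, resname, "CA", "C", p))
        atoms.append(Atom(i, resname, "C", "C",
                          p + 1.52 * c_dir / np.linalg.norm(c_dir)))
        atoms.append(Atom(i, resname, "HB", "H",
                          p + 1.5 * hb_dir / np.linalg.norm(hb_dir)))
    return place_amide_hydrogens(ProteinStructure(atoms))


# ------------------------------------------------------------------- decoys

def make_decoy(structure: ProteinStructure, level: float,
               seed: int) -> ProteinStructure:
    """Perturb a fold on the decoy ladder.

    Per-residue Gaussian displacement of scale *level* (Å, applied rigidly
    to all atoms of the residue so local geometry is preserved), and for
    ``level > 2`` additionally a random rigid rotation of the chain's
    second half about a hinge at the middle residue's Cα — emulating the
    correlated, fold-breaking errors of genuinely wrong predictions.
    Level 0 returns an identical copy.
    """
    if level < 0:
        raise ValueError("level must be non-negative")
    out = structure.copy()
    if level == 0:
        return out
    rng = np.random.default_rng(seed)
    indices = out.residue_indices
    disp = {i: rng.normal(0.0, level, size=3) for i in indices}
    rotation = None
    hinge = None
    second_half: set[int] = set()
    if level > 2:
        mid = indices[len(indices) // 2]
        hinge = out.atom(mid, "CA").position.copy()
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(np.pi / 3, np.pi)
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rotation = (np.eye(3) + np.sin(angle) * k
                    + (1 - np.cos(angle)) * (k @ k))
        second_half = {i for i in indices if i > mid}
    for atom in out.atoms:
        pos = atom.position
        if rotation is not None and atom.residue_index in second_half:
            pos = hinge + rotation @ (pos - hinge)
        atom.position = pos + disp[atom.residue_index]
    return out


# ------------------------------------------------------------------- shifts

def make_shift_table(structure: ProteinStructure, seed: int,
                     ambiguity: float = 0.0) -> ShiftTable:
    """Assign every hydrogen and backbone amide N a plausible shift.

    Amide HN ~ N(8.3, 0.5) ppm, amide N ~ N(119, 4) ppm, side-chain
    hydrogens ~ N(2.0, σ) ppm with σ = 1.0/(1 + ambiguity): raising
    *ambiguity* compresses the side-chain shift range so candidate lists
    overlap more, stressing the Δshift matching.
    """
    rng = np.random.default_rng(seed)
    sigma_side = 1.0 / (1.0 + max(0.0, ambiguity))
    table = ShiftTable()
    for atom in sorted(structure.atoms,
                       key=lambda a: (a.residue_index, a.atom_name)):
        if atom.atom_name == "N":
            shift = float(rng.normal(119.0, 4.0))
            table.add(ShiftEntry(atom.residue_index, atom.residue_name,
                                 "N", "N", shift), warn_duplicate=False)
        elif atom.is_hydrogen:
            if atom.atom_name == "H":
                shift = float(rng.normal(8.3, 0.5))
            else:
                shift = float(rng.normal(2.0, sigma_side))
            table.add(ShiftEntry(atom.residue_index, atom.residue_name,
                                 atom.atom_name, "H", shift),
                      warn_duplicate=False)
    return table


# --------------------------------------------------------------------- PAE

def make_pae(n_resi: int, tm: float, seed: int) -> PaeMatrix:
    """Synthetic PAE whose long-range mean grows with (1 − TM) plus noise.

    Generated from the label, not from any structure pair: it exists so
    the PAE feature path is exercised, and is documented as non-physical.
    """
    rng = np.random.default_rng(seed)
    idx = np.arange(n_resi)
    sep = np.abs(idx[:, None] - idx[None, :])
    base = np.where(sep < 5,
                    rng.normal(1.0, 0.3, size=sep.shape),
                    rng.normal(2.0 + 25.0 * (1.0 - tm), 1.5, size=sep.shape))
    m = np.clip((base + base.T) / 2.0, 0.2, 31.75)
    np.fill_diagonal(m, 0.2)
    return PaeMatrix(m)


# ------------------------------------------------------------------- corpus

@dataclass
class CorpusEntry:
    """One synthetic corpus member with all intermediate objects retained."""

    entry_id: str
    truth: ProteinStructure
    decoy: ProteinStructure
    shifts: ShiftTable
    peaks: PeakList
    contacts: ContactSet
    level: float
    tm: float
    sufficiency_pass: bool
    coverage: float
    features: DatasetEntry


def score_pair(contacts: ContactSet, proposed: ProteinStructure,
               scoring: ScoringParams | None = None,
               rpf: RpfParams | None = None) -> dict[str, float | None]:
    """CS, DS and RPF of one proposed structure against one contact set."""
    cs = contact_score(contacts, proposed, scoring).cs
    ds = distance_score(contacts, proposed, scoring).ds
    r = rpf_scores(contacts, proposed, rpf)
    return {"cs": cs, "ds": ds, "recall": r.recall,
            "precision": r.precision, "f": r.f_measure}


def make_corpus(params: SynthParams,
                scoring: ScoringParams | None = None,
                rpf: RpfParams | None = None,
                tol: ToleranceParams | None = None) -> list[CorpusEntry]:
    """Generate a fully labeled synthetic corpus.

    Per member: a truth fold (alternating hairpin/mixed topology for
    structural variety), a shift table, zero-jitter simulated NOESY peaks
    from the truth, a decoy at a level drawn from the ladder, CS/DS/RPF of
    the decoy against the truth's peaks, the TM(truth, decoy) label and a
    synthetic PAE.  Fully reproducible from the two seeds in *params*.
    """
    if params.corpus_size < 10:
        raise ValueError("corpus_size must be at least 10")
    scoring = scoring or ScoringParams()
    master = np.random.default_rng(
        np.random.SeedSequence([params.geom_seed, params.shift_seed, 2318]))
    topologies = (("hairpin", "mixed") if params.topology == "mixed"
                  else (params.topology,))
    corpus: list[CorpusEntry] = []
    for k in range(params.corpus_size):
        seeds = master.integers(0, 2 ** 31 - 1, size=5)
        topo = topologies[k % len(topologies)]
        member = replace(params, topology=topo, geom_seed=int(seeds[0]),
                         shift_seed=int(seeds[1]))
        truth = make_fold(member)
        shifts = make_shift_table(truth, int(seeds[1]))
        peaks = simulate_noesy(truth, shifts, NoesySimParams(seed=int(seeds[2])))
        contacts = find_potential_contacts(peaks, shifts, tol,
                                           n_resi=params.n_resi)
        passed, coverage = sufficiency_check(contacts)
        level = float(params.decoy_levels[
            int(master.integers(0, len(params.decoy_levels)))])
        decoy = make_decoy(truth, level, int(seeds[3]))
        tm = tm_score(truth, decoy).tm
        sc = score_pair(contacts, decoy, scoring, rpf)
        pae = make_pae(params.n_resi, tm, int(seeds[4]))
        mean_pae, lr_pae = pae_features(pae, scoring.min_sep)
        entry_id = f"synth{k:04d}"
        features = DatasetEntry(entry_id=entry_id, tm=tm,
                                mean_pae=mean_pae,
                                long_range_mean_pae=lr_pae, **sc)
        corpus.append(CorpusEntry(entry_id, truth, decoy, shifts, peaks,
                                  contacts, level, tm, passed, coverage,
                                  features))
    return corpus


def augment_corpus(corpus: list[CorpusEntry], seed: int,
                   scoring: ScoringParams | None = None,
                   rpf: RpfParams | None = None) -> list[DatasetEntry]:
    """Mismatch-augment a corpus, rescoring every structure-dependent
    feature (CS, DS, RPF and the TM label) against the donor's prediction.

    Mismatched entries carry no PAE features.  Returns 2·len(corpus)
    :class:`~spanr.classify.DatasetEntry` rows.
    """
    by_id = {c.entry_id: c for c in corpus}

    def rescore(entry: DatasetEntry, donor: DatasetEntry) -> DatasetEntry:
        own = by_id[entry.entry_id]
        don = by_id[donor.entry_id]
        sc = score_pair(own.contacts, don.decoy, scoring, rpf)
        tm = tm_score(own.truth, don.decoy).tm
        return DatasetEntry(entry_id=f"{entry.entry_id}|mm", tm=tm, **sc)

    return mismatch_augment([c.features for c in corpus], seed, rescore=rescore)
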