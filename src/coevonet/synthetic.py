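"""Desk-scale synthetic proteins with planted co-evolution.

The generator emulates the statistical premise of covariance-based
contact prediction: residue pairs that are close in the structure
co-vary across homologs.  For each protein it

1. samples a compact self-avoiding 3-D walk of pseudo-residues (bond
   3.8 A, clash radius 3.5 A, a centripetal bias keeps the chain
   globular) and derives the contact map from the resulting C-beta
   geometry with the same code used for real coordinates;
2. picks `n_contact_pairs` contacting column pairs with separation >= 6
   and evolves N-1 homologs from a random query: positions mutate
   independently at `mutation_rate`, gaps open at a small fixed rate,
   and each planted pair is jointly resampled with probability
   `coupling` through a pair-specific symbol permutation (one column's
   symbol determines the other's), which is exactly the pairwise
   frequency coupling the covariance features detect;
3. appends `noise_fraction * N` uniform-random sequences (identity with
   the query ~ 1/21 — the rows a weighting network should suppress);
4. assigns 3-state secondary structure by a geometric rule on the walk
   (tight backbone turns -> helix, extended stretches paired with a
   nearby extended stretch -> sheet, runs shorter than 3 -> coil) and
   ASA by a distance-to-centroid proxy scaled to [0, 200] A^2.

Everything is deterministic in the seed, and suites can be written to
standard formats (FASTA MSAs, minimal PDB, label TSV, JSON manifest).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .labels import LabelBundle, ResidueCoords, ResidueLabels, contacts_from_coordinates
from .msa import ALPHABET, GAP_CODE, Alignment, EncodedAlignment, decode

BOND_LENGTH = 3.8  # Angstrom, consecutive C-alpha
CLASH_RADIUS = 3.5
CB_OFFSET = 1.5
GAP_OPEN_RATE = 0.03  # per-position gap probability in evolved homologs
MAX_ASA_PROXY = 200.0


@dataclass
class SyntheticSpec:
    """The stated world of the synthetic suite.

    Defaults are the desk-scale conditions the package is exercised at:
    200 proteins of length 30 with 50 evolved sequences each, strong
    coupling (0.9) at 12 planted contact pairs, half again as many
    pure-noise sequences, and a 0.3 per-position mutation rate (homolog
    identity ~70-75%, a realistic mid-range MSA).
    """

    n_proteins: int = 200
    length: int = 30
    depth: int = 50
    n_contact_pairs: int = 12
    coupling: float = 0.9
    noise_fraction: float = 0.5
    mutation_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise_fraction must lie in [0, 1)")


@dataclass
class SyntheticProtein:
    identifier: str
    alignment: Alignment
    enc: EncodedAlignment
    coords: ResidueCoords
    contact_map: np.ndarray
    residue_labels: ResidueLabels
    planted_pairs: list[tuple[int, int]]
    noise_mask: np.ndarray  # True for appended pure-noise rows

    @property
    def labels(self) -> LabelBundle:
        return LabelBundle(
            contact_map=self.contact_map,
            ss3=self.residue_labels.ss3,
            asa=self.residue_labels.asa,
        )


# ------------------------------------------------------------------ geometry


def _segment_persistence(L: int, rng: np.random.Generator) -> np.ndarray:
    """Per-residue direction persistence: the chain alternates turny
    (helix-like) and extended (strand-like) segments of 4-8 residues,
    which gives the runs the secondary-structure proxy labels."""
    alpha = np.empty(L)
    i = 0
    turny = bool(rng.integers(0, 2))
    while i < L:
        seg = int(rng.integers(4, 9))
        alpha[i : i + seg] = 0.12 if turny else 0.92
        turny = not turny
        i += seg
    return alpha


def _self_avoiding_walk(L: int, rng: np.random.Generator, max_restarts: int = 200):
    """Compact self-avoiding chain of L points; raises if infeasible."""
    for _ in range(max_restarts):
        pos = np.zeros((L, 3))
        direction = _unit(rng.normal(size=3))
        alpha = _segment_persistence(L, rng)
        ok = True
        for i in range(1, L):
            placed = False
            for _attempt in range(60):
                centroid = pos[:i].mean(axis=0)
                pull = centroid - pos[i - 1]
                norm = np.linalg.norm(pull)
                pull = pull / norm if norm > 1e-9 else np.zeros(3)
                a = alpha[i]
                step = _unit(
                    a * direction + (1.0 - a) * rng.normal(size=3) + 0.45 * pull
                )
                cand = pos[i - 1] + BOND_LENGTH * step
                if i < 2 or np.min(np.linalg.norm(pos[: i - 1] - cand, axis=1)) > CLASH_RADIUS:
                    pos[i] = cand
                    direction = step
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return pos
    raise RuntimeError(
        f"could not build a self-avoiding walk of length {L}; try a smaller length"
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _coords_from_walk(ca: np.ndarray, restypes: list[str]) -> ResidueCoords:
    """Place C-beta 1.5 A off the backbone, pointing away from the local
    chain direction (glycine rows still get one; the contact code ignores it)."""
    L = ca.shape[0]
    cb = np.empty_like(ca)
    for i in range(L):
        prev_p = ca[max(i - 1, 0)]
        next_p = ca[min(i + 1, L - 1)]
        away = ca[i] - 0.5 * (prev_p + next_p)
        norm = np.linalg.norm(away)
        away = away / norm if norm > 1e-9 else _unit(np.ones(3))
        cb[i] = ca[i] + CB_OFFSET * away
    return ResidueCoords(restypes=restypes, ca=ca, cb=cb)


def _secondary_structure_from_walk(ca: np.ndarray) -> np.ndarray:
    """Geometric 3-state proxy on the realized chain: residues whose
    i-1..i+1 span is tight (< 6.5 A) are helix-like; extended residues
    (span > 7.0 A) with an extended nonlocal partner within 9 A are
    sheet-like; runs shorter than 3 revert to coil.  Thresholds are
    calibrated to the walk's own span distribution."""
    from .labels import COIL, HELIX, SHEET

    L = ca.shape[0]
    span = np.full(L, np.nan)
    for i in range(1, L - 1):
        span[i] = np.linalg.norm(ca[i + 1] - ca[i - 1])
    raw = np.full(L, COIL, dtype=np.int8)
    extended = np.zeros(L, dtype=bool)
    for i in range(L):
        if np.isfinite(span[i]) and span[i] < 6.5:
            raw[i] = HELIX
        elif np.isfinite(span[i]) and span[i] > 7.0:
            extended[i] = True
    dists = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    for i in np.flatnonzero(extended):
        partners = np.flatnonzero(extended & (np.abs(np.arange(L) - i) >= 4) & (dists[i] < 9.0))
        if len(partners):
            raw[i] = SHEET
    # suppress runs shorter than 3
    out = raw.copy()
    i = 0
    while i < L:
        j = i
        while j < L and raw[j] == raw[i]:
            j += 1
        if raw[i] != COIL and (j - i) < 3:
            out[i:j] = COIL
        i = j
    return out


def _asa_from_walk(ca: np.ndarray) -> np.ndarray:
    """Burial proxy: distance to the centroid, scaled to [0, 200] A^2."""
    d = np.linalg.norm(ca - ca.mean(axis=0), axis=1)
    lo, hi = d.min(), d.max()
    return MAX_ASA_PROXY * (d - lo) / max(hi - lo, 1e-9)


# ----------------------------------------------------------------- evolution


def _evolve_homolog(query, rng, spec, pair_tables):
    seq = query.copy()
    mutate = rng.random(len(seq)) < spec.mutation_rate
    seq[mutate] = rng.integers(0, 20, size=int(mutate.sum()))
    gaps = rng.random(len(seq)) < GAP_OPEN_RATE
    seq[gaps] = GAP_CODE
    for (i, j), table in pair_tables.items():
        if rng.random() < spec.coupling:
            a = rng.integers(0, 20)
            seq[i] = a
            seq[j] = table[a]
    return seq


def generate_protein(spec: SyntheticSpec, seed: int, identifier: str = "synth0000"):
    """One synthetic protein: alignment, geometry, labels, noise bookkeeping."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED)))
    L = spec.length
    ca = _self_avoiding_walk(L, rng)
    query = rng.integers(0, 20, size=L).astype(np.int8)
    restypes = [ALPHABET[c] for c in query]
    coords = _coords_from_walk(ca, restypes)
    contact_map = contacts_from_coordinates(coords)

    ii, jj = np.where(np.triu(np.nan_to_num(contact_map) == 1.0, k=6))
    candidates = list(zip(ii.tolist(), jj.tolist()))
    rng.shuffle(candidates)
    planted = sorted(candidates[: spec.n_contact_pairs])
    pair_tables = {
        (i, j): rng.permutation(20) for (i, j) in planted
    }  # one symbol-pairing rule per planted pair

    rows = [query]
    for _ in range(spec.depth - 1):
        rows.append(_evolve_homolog(query, rng, spec, pair_tables))
    n_noise = int(round(spec.noise_fraction * spec.depth))
    for _ in range(n_noise):
        rows.append(rng.integers(0, 21, size=L).astype(np.int8))  # uniform over 21 symbols
    codes = np.stack([np.asarray(r, dtype=np.int8) for r in rows])
    noise_mask = np.zeros(len(rows), dtype=bool)
    noise_mask[spec.depth :] = True
    identifiers = [f"{identifier}_query"]
    identifiers += [f"{identifier}_homolog{k:04d}" for k in range(1, spec.depth)]
    identifiers += [f"{identifier}_noise{k:04d}" for k in range(n_noise)]
    enc = EncodedAlignment(codes=codes, identifiers=identifiers)

    residue_labels = ResidueLabels(
        ss3=_secondary_structure_from_walk(ca), asa=_asa_from_walk(ca)
    )
    return SyntheticProtein(
        identifier=identifier,
        alignment=decode(enc),
        enc=enc,
        coords=coords,
        contact_map=contact_map,
        residue_labels=residue_labels,
        planted_pairs=planted,
        noise_mask=noise_mask,
    )


# -------------------------------------------------------------------- suites


@dataclass
class SyntheticSuite:
    spec: SyntheticSpec
    proteins: list[SyntheticProtein]
    folds: list[list[int]]  # disjoint index sets

    def fold_split(self, held_out: int):
        """(train, validation) protein lists for one fold."""
        val = [self.proteins[i] for i in self.folds[held_out]]
        train = [
            self.proteins[i]
            for f, fold in enumerate(self.folds)
            if f != held_out
            for i in fold
        ]
        return train, val

    @property
    def manifest(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "n_folds": len(self.folds),
            "folds": [[self.proteins[i].identifier for i in fold] for fold in self.folds],
        }


def make_suite(spec: SyntheticSpec, n_folds: int = 5) -> SyntheticSuite:
    """Generate `spec.n_proteins` proteins, split into disjoint folds.

    Per-protein seeds derive from (spec.seed, index), so regeneration
    from the manifest is bit-identical.
    """
    proteins = [
        generate_protein(spec, seed=_protein_seed(spec.seed, i), identifier=f"synth{i:04d}")
        for i in range(spec.n_proteins)
    ]
    folds = [list(range(f, spec.n_proteins, n_folds)) for f in range(n_folds)]
    return SyntheticSuite(spec=spec, proteins=proteins, folds=folds)


def _protein_seed(base_seed: int, index: int) -> int:
    mix = np.random.SeedSequence((int(base_seed), int(index)))
    return int(mix.generate_state(1, np.uint32)[0])


# ------------------------------------------------------------------- writers


def write_pdb(coords: ResidueCoords, path) -> None:
    """Minimal single-chain PDB with C-alpha and C-beta ATOM records."""
    with open(path, "w") as fh:
        serial = 1
        for i, aa in enumerate(coords.restypes):
            res3 = _ONE_TO_THREE.get(aa, "UNK")
            for name, xyz in (("CA", coords.ca[i]), ("CB", coords.cb[i])):
                if np.any(np.isnan(xyz)):
                    continue
                if name == "CB" and aa == "G":
                    continue  # glycine has no C-beta
                fh.write(
                    f"ATOM  {serial:5d}  {name:<3s} {res3:>3s} A{i + 1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"           C\n"
                )
                serial += 1
        fh.write("END\n")


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def write_suite(suite: SyntheticSuite, out_dir) -> Path:
    """Write FASTA MSAs, PDB coordinates, label TSVs and the manifest."""
    from .labels import write_label_tsv
    from .msa import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for protein in suite.proteins:
        stem = out_dir / protein.identifier
        write_fasta(protein.alignment, stem.with_suffix(".fasta"))
        write_pdb(protein.coords, stem.with_suffix(".pdb"))
        write_label_tsv(
            stem.with_suffix(".labels.tsv"),
            protein.coords.restypes,
            protein.residue_labels,
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(suite.manifest, fh, indent=2)
    return out_dir
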