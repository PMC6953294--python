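"""Training/evaluation labels: contact maps, secondary structure, ASA.

Conventions
-----------
* Contact maps are (L, L) float arrays with 1.0 (contact), 0.0 (no
  contact) and NaN (masked / missing coordinate).  A contact is a residue
  pair whose representative atoms (C-beta; C-alpha for glycine) lie
  strictly within 8 Angstrom.
* 3-state secondary structure is an integer array: 0 helix, 1 sheet,
  2 coil, -1 masked.
* ASA is absolute area in Angstrom^2 (NaN masked); the relative,
  3-state form (B/M/E at 10%/40% of a residue-type maximum) is used only
  when comparing predictions, never for the regression itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

CONTACT_DISTANCE = 8.0  # Angstrom, strict '<'

HELIX, SHEET, COIL, SS_MASKED = 0, 1, 2, -1
SS3_CHARS = "HEC"

_SS8_TO_SS3 = {
    "H": HELIX, "G": HELIX, "I": HELIX,
    "E": SHEET, "B": SHEET,
    "T": COIL, "S": COIL, " ": COIL, "-": COIL, "C": COIL, "P": COIL,
}

# Theoretical maximum ASA per residue (Tien et al. 2013), Angstrom^2,
# used to convert absolute ASA to relative solvent accessibility.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

RSA_BURIED, RSA_EXPOSED = 0.10, 0.40  # B below 10%, E above 40%, M between


@dataclass
class ResidueCoords:
    """Per-residue representative-atom coordinates for one chain.

    `ca` and `cb` are (L, 3) arrays with NaN rows where the atom is
    missing; `restypes` holds one-letter residue codes.
    """

    restypes: list[str]
    ca: np.ndarray
    cb: np.ndarray

    def __post_init__(self):
        self.ca = np.asarray(self.ca, dtype=float)
        self.cb = np.asarray(self.cb, dtype=float)
        L = len(self.restypes)
        if self.ca.shape != (L, 3) or self.cb.shape != (L, 3):
            raise ValueError("ca/cb must be (L, 3) arrays matching restypes")

    @property
    def length(self) -> int:
        return len(self.restypes)

    def representative_atoms(self) -> np.ndarray:
        """C-beta coordinates, C-alpha for glycine; NaN where missing."""
        rep = self.cb.copy()
        for i, aa in enumerate(self.restypes):
            if aa == "G":
                rep[i] = self.ca[i]
        return rep


@dataclass
class ResidueLabels:
    """Per-residue 3-state secondary structure and absolute ASA."""

    ss3: np.ndarray
    asa: np.ndarray

    def __post_init__(self):
        self.ss3 = np.asarray(self.ss3, dtype=np.int8)
        self.asa = np.asarray(self.asa, dtype=float)
        if self.ss3.shape != self.asa.shape:
            raise ValueError("ss3 and asa must share length")

    @property
    def length(self) -> int:
        return self.ss3.shape[0]

    @property
    def ss3_coverage(self) -> float:
        return float(np.mean(self.ss3 != SS_MASKED))

    def meets_coverage(self, minimum: float = 0.8) -> bool:
        """Dataset filter: keep proteins with SS assigned for >=80% of residues."""
        return self.ss3_coverage >= minimum


@dataclass
class LabelBundle:
    """Everything the losses need for one protein; fields may be None."""

    contact_map: np.ndarray | None
    ss3: np.ndarray | None = None
    asa: np.ndarray | None = None


def contacts_from_coordinates(coords: ResidueCoords) -> np.ndarray:
    """Symmetric (L, L) contact map from representative-atom distances.

    A pair is a contact iff the distance is strictly below 8 A.  Any pair
    involving a residue whose representative atom is missing is NaN
    (missing coordinates are data, not errors).  The diagonal is 0.
    """
    rep = coords.representative_atoms()
    missing = np.isnan(rep).any(axis=1)
    diff = rep[:, None, :] - rep[None, :, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN rows propagate
        dist = np.sqrt((diff**2).sum(axis=-1))
    cmap = (dist < CONTACT_DISTANCE).astype(float)
    np.fill_diagonal(cmap, 0.0)
    cmap[missing, :] = np.nan
    cmap[:, missing] = np.nan
    return cmap


def read_pdb_coordinates(path, chain_id: str | None = None) -> ResidueCoords:
    """ATOM records of the first model, one chain, in file order."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("protein", str(path))
    model = next(iter(structure))
    if chain_id is None:
        chain = next(iter(model))
    else:
        chain = model[chain_id]
    restypes, ca, cb = [], [], []
    for residue in chain:
        if residue.id[0] != " ":  # skip heteroatoms/waters
            continue
        try:
            one = seq1(residue.get_resname())
        except Exception:
            one = "X"
        restypes.append(one if one in MAX_ASA else "X")
        ca.append(residue["CA"].get_coord() if "CA" in residue else [np.nan] * 3)
        cb.append(residue["CB"].get_coord() if "CB" in residue else [np.nan] * 3)
    if not restypes:
        raise ValueError(f"no standard residues found in {path}")
    return ResidueCoords(restypes=restypes, ca=np.array(ca, float), cb=np.array(cb, float))


def parse_dssp(path):
    """Parse a DSSP output file into (restypes, ss8, asa).

    Returns one-letter residue codes, 8-state codes (' ' for blank) and
    absolute ASA; chain-break records ('!') yield a masked position
    (restype 'X', ss8 '!', ASA NaN).
    """
    restypes: list[str] = []
    ss8: list[str] = []
    asa: list[float] = []
    in_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not in_data:
                if line.startswith("  #  RESIDUE"):
                    in_data = True
                continue
            if len(line.rstrip("\n")) < 38:
                raise ValueError(f"{path}: malformed DSSP data line {lineno}")
            aa = line[13]
            if aa == "!":
                restypes.append("X")
                ss8.append("!")
                asa.append(np.nan)
                continue
            try:
                acc = float(line[34:38])
            except ValueError as err:
                raise ValueError(f"{path}: bad ACC field on line {lineno}") from err
            restypes.append(aa.upper() if aa.isupper() else "C")  # lowercase = SS-bonded Cys
            ss8.append(line[16])
            asa.append(acc)
    if not in_data:
        raise ValueError(f"{path}: no DSSP data header found")
    return restypes, ss8, np.array(asa, float)


def ss8_to_ss3(code: str) -> int:
    """DSSP 8-state to 3-state: H/G/I helix, E/B sheet, rest coil."""
    if code == "!":
        return SS_MASKED
    try:
        return _SS8_TO_SS3[code]
    except KeyError:
        raise ValueError(f"unknown DSSP secondary-structure code: {code!r}") from None


def dssp_to_residue_labels(ss8_codes, asa) -> ResidueLabels:
    ss3 = np.array([ss8_to_ss3(c) for c in ss8_codes], dtype=np.int8)
    asa = np.asarray(asa, float).copy()
    asa[ss3 == SS_MASKED] = np.nan
    return ResidueLabels(ss3=ss3, asa=asa)


def relative_asa(asa: float, restype: str) -> float:
    try:
        return asa / MAX_ASA[restype]
    except KeyError:
        raise ValueError(f"unknown residue type {restype!r}") from None


def asa_to_three_state(asa: float, restype: str) -> str:
    """Absolute ASA to B/M/E at 10% / 40% relative accessibility.

    Boundary values fall in M (closed middle interval).
    """
    rel = relative_asa(asa, restype)
    if rel < RSA_BURIED:
        return "B"
    if rel <= RSA_EXPOSED:
        return "M"
    return "E"


def asa_to_three_state_array(asa: np.ndarray, restypes) -> np.ndarray:
    """Vectorized B/M/E conversion; NaN ASA yields '-' (masked)."""
    out = np.full(len(restypes), "-", dtype="<U1")
    for i, (a, r) in enumerate(zip(np.asarray(asa, float), restypes)):
        if np.isfinite(a):
            out[i] = asa_to_three_state(a, r)
    return out


def masked_fraction(contact_map: np.ndarray) -> float:
    return float(np.mean(np.isnan(contact_map)))


def write_label_tsv(path, restypes, labels: ResidueLabels) -> None:
    """Per-protein label table: index, residue, 3-state SS char, ASA."""
    with open(path, "w") as fh:
        fh.write("resi\taa\tss3\tasa\n")
        for i, (aa, s, a) in enumerate(zip(restypes, labels.ss3, labels.asa)):
            ss_char = SS3_CHARS[s] if s != SS_MASKED else "-"
            asa_str = "nan" if not np.isfinite(a) else f"{a:.2f}"
            fh.write(f"{i}\t{aa}\t{ss_char}\t{asa_str}\n")


def read_label_tsv(path):
    """Inverse of :func:`write_label_tsv`: returns (restypes, ResidueLabels)."""
    restypes, ss3, asa = [], [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("resi"):
            raise ValueError(f"{path}: unexpected label TSV header")
        for line in fh:
            _, aa, ss_char, asa_str = line.rstrip("\n").split("\t")
            restypes.append(aa)
            ss3.append(SS3_CHARS.index(ss_char) if ss_char in SS3_CHARS else SS_MASKED)
            asa.append(float(asa_str))
    return restypes, ResidueLabels(ss3=np.array(ss3, np.int8), asa=np.array(asa, float))
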