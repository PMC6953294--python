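"""Multiple sequence alignment I/O, encoding, sampling and cropping.

Owns the 21-symbol alphabet (20 amino acids in alphabetical one-letter
order plus the gap) and the column convention used everywhere else: the
first record of an alignment is the query/target sequence, it contains no
gaps, and columns are indexed 0-based relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP  # codes 0..19 amino acids, 20 gap
GAP_CODE = 20
N_SYMBOLS = 21

# Non-standard residue letters are collapsed onto the gap code so the
# 21-letter alphabet stays closed (B/Z ambiguous, X unknown, U/O rare, J=I/L).
_NONSTANDARD = "BZXUOJ"

_CODE_OF = {aa: i for i, aa in enumerate(ALPHABET)}
_CODE_OF.update({aa: GAP_CODE for aa in _NONSTANDARD})
_CODE_OF["."] = GAP_CODE

_ENCODE_TABLE = np.full(128, -1, dtype=np.int16)
for _ch, _code in _CODE_OF.items():
    _ENCODE_TABLE[ord(_ch)] = _code
    _ENCODE_TABLE[ord(_ch.lower())] = _code


class AlignmentFormatError(ValueError):
    """Raised when an input file violates the alignment contract."""


@dataclass
class Alignment:
    """An MSA of N same-length sequences; row 0 is the gap-free query."""

    sequences: list[str]
    identifiers: list[str]
    query_index: int = 0

    def __post_init__(self):
        if len(self.sequences) < 1:
            raise AlignmentFormatError("alignment must contain at least one sequence")
        if len(self.identifiers) != len(self.sequences):
            raise AlignmentFormatError("identifiers and sequences differ in number")
        L = len(self.sequences[0])
        for ident, seq in zip(self.identifiers, self.sequences):
            if len(seq) != L:
                raise AlignmentFormatError(
                    f"record '{ident}' has length {len(seq)}, expected {L}"
                )
        if GAP in self.sequences[self.query_index]:
            raise AlignmentFormatError("query sequence must not contain gaps")

    @property
    def depth(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def query(self) -> str:
        return self.sequences[self.query_index]


@dataclass
class EncodedAlignment:
    """Integer-coded MSA: (N, L) grid of codes in [0, 20], query at row 0."""

    codes: np.ndarray
    identifiers: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (N, L) array")
        if self.codes.min() < 0 or self.codes.max() > GAP_CODE:
            raise ValueError("codes must lie in [0, 20]")
        if np.any(self.codes[0] == GAP_CODE):
            raise ValueError("query row must not contain the gap code")
        if not self.identifiers:
            self.identifiers = [f"seq{i}" for i in range(self.codes.shape[0])]

    @property
    def depth(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]


def read_alignment(path, fmt: str | None = None) -> Alignment:
    """Read a FASTA or A3M alignment; the first record is the query.

    A3M lowercase characters mark insertions relative to the query and are
    deleted, as are '.' characters, so every row comes out at query length.
    Non-standard residue letters map to the gap code at encoding time.
    """
    path = Path(path)
    if fmt is None:
        fmt = "a3m" if path.suffix.lower() == ".a3m" else "fasta"
    if fmt not in ("fasta", "a3m"):
        raise ValueError(f"unknown alignment format: {fmt}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    identifiers, sequences = [], []
    for rec in records:
        seq = str(rec.seq).replace(".", "")
        if fmt == "a3m":
            seq = "".join(ch for ch in seq if not ch.islower())
        identifiers.append(rec.id)
        sequences.append(seq.upper())
    L = len(sequences[0])
    for ident, seq in zip(identifiers, sequences):
        if len(seq) != L:
            raise AlignmentFormatError(
                f"record '{ident}' has length {len(seq)} after normalization, "
                f"expected query length {L}"
            )
    return Alignment(sequences=sequences, identifiers=identifiers)


def write_fasta(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for ident, seq in zip(alignment.identifiers, alignment.sequences):
            fh.write(f">{ident}\n{seq}\n")


def encode(alignment: Alignment) -> EncodedAlignment:
    """Map characters to integer codes (0-19 amino acids, 20 gap/unknown)."""
    rows = np.frombuffer(
        "".join(alignment.sequences).encode("ascii"), dtype=np.uint8
    ).reshape(alignment.depth, alignment.length)
    codes = _ENCODE_TABLE[rows]
    if codes.min() < 0:
        bad = chr(rows.ravel()[np.argmin(codes)])
        raise AlignmentFormatError(f"unencodable character {bad!r} in alignment")
    return EncodedAlignment(codes=codes.astype(np.int8), identifiers=list(alignment.identifiers))


def decode(enc: EncodedAlignment) -> Alignment:
    lut = np.array(list(ALPHABET))
    seqs = ["".join(lut[row]) for row in enc.codes]
    return Alignment(sequences=seqs, identifiers=list(enc.identifiers))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_sequences(
    enc: EncodedAlignment, max_depth: int = 30000, seed=0
) -> EncodedAlignment:
    """Cap alignment depth by uniform sampling without replacement.

    The query row is always retained at index 0 (it defines the columns and
    the identity-with-target feature).  Under the cap the input is returned
    unchanged.  Training-time only; prediction uses the full alignment.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if enc.depth <= max_depth:
        return enc
    rng = _as_rng(seed)
    others = rng.choice(np.arange(1, enc.depth), size=max_depth - 1, replace=False)
    others.sort()
    keep = np.concatenate([[0], others])
    return EncodedAlignment(
        codes=enc.codes[keep],
        identifiers=[enc.identifiers[i] for i in keep],
    )


def crop_window(enc: EncodedAlignment, labels, max_len: int = 200, seed=0):
    """Crop a contiguous window of at most `max_len` columns, consistently
    across all sequences and all labels (contact map on both axes).

    `labels` is any object with `contact_map` (L, L), `ss3` (L,) and `asa`
    (L,) attributes (see :class:`coevonet.labels.LabelBundle`); attributes
    that are None are passed through.  Training-time only.
    """
    L = enc.length
    for name in ("contact_map", "ss3", "asa"):
        arr = getattr(labels, name)
        if arr is not None and arr.shape[0] != L:
            raise ValueError(f"label '{name}' has length {arr.shape[0]}, alignment has {L}")
    if L <= max_len:
        return enc, labels
    rng = _as_rng(seed)
    start = int(rng.integers(0, L - max_len + 1))
    stop = start + max_len
    cropped_enc = EncodedAlignment(
        codes=enc.codes[:, start:stop], identifiers=list(enc.identifiers)
    )
    cropped = labels.__class__(
        contact_map=None
        if labels.contact_map is None
        else labels.contact_map[start:stop, start:stop],
        ss3=None if labels.ss3 is None else labels.ss3[start:stop],
        asa=None if labels.asa is None else labels.asa[start:stop],
    )
    return cropped_enc, cropped
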