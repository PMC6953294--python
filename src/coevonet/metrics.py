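"""CASP-style evaluation of contact, secondary-structure and ASA predictions.

Contacts are scored as precision TP / (TP + FP) of the top L/k
highest-probability pairs (k in {10, 5, 2, 1}, ceil rounding) within a
sequence-separation bin: short 6 <= |i-j| <= 11, medium 12 <= |i-j| <= 23,
long |i-j| >= 24.  Pairs with separation <= 5 are never evaluated, masked
pairs are excluded from numerator and denominator, and metrics with an
empty denominator are reported as None (absent), not 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .labels import COIL, HELIX, SHEET, SS3_CHARS, SS_MASKED, asa_to_three_state_array

MIN_SEPARATION = 6  # |i-j| <= 5 is never evaluated
TOP_K_VALUES = (10, 5, 2, 1)
CONTACT_TYPES = ("HH", "HS", "SS")


@dataclass(frozen=True)
class RangeBin:
    name: str
    lo: int
    hi: int  # inclusive; use a large value for unbounded

    def contains(self, separation) -> np.ndarray:
        return (separation >= self.lo) & (separation <= self.hi)


SHORT = RangeBin("short", 6, 11)
MEDIUM = RangeBin("medium", 12, 23)
LONG = RangeBin("long", 24, 10**9)
ALL_RANGES = RangeBin("all", MIN_SEPARATION, 10**9)  # the three bins mixed
RANGE_BINS = {"short": SHORT, "medium": MEDIUM, "long": LONG, "all": ALL_RANGES}


def _as_bin(bin_like) -> RangeBin:
    if bin_like is None:
        return ALL_RANGES
    if isinstance(bin_like, RangeBin):
        return bin_like
    return RANGE_BINS[bin_like]


def _ranked_pairs(p: np.ndarray, mask_ij: tuple[np.ndarray, np.ndarray]):
    """Candidate pairs sorted by probability desc; ties break to smaller
    separation, then lexicographic (i, j) — deterministic."""
    ii, jj = mask_ij
    sep = jj - ii
    order = np.lexsort((jj, ii, sep, -p[ii, jj]))
    return ii[order], jj[order]


def _candidate_pairs(p, y, rng_bin: RangeBin):
    L = p.shape[0]
    ii, jj = np.triu_indices(L, k=1)
    sep = jj - ii
    keep = rng_bin.contains(sep) & np.isfinite(y[ii, jj])
    return ii[keep], jj[keep]


def top_lk_precision(p: np.ndarray, y: np.ndarray, rng_bin="long", k: int = 5):
    """Precision of the ceil(L/k) top-probability pairs in a separation bin.

    Returns None when the bin holds no unmasked candidate pairs.  If the
    bin holds fewer than ceil(L/k) candidates, all of them are scored
    (see :func:`top_lk_report` for the truncation flag).
    """
    return top_lk_report(p, y, rng_bin, k)["precision"]


def top_lk_report(p: np.ndarray, y: np.ndarray, rng_bin="long", k: int = 5) -> dict:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape or p.shape[0] != p.shape[1]:
        raise ValueError("p and y must be equal square matrices")
    L = p.shape[0]
    rng_bin = _as_bin(rng_bin)
    ii, jj = _candidate_pairs(p, y, rng_bin)
    n_wanted = math.ceil(L / k)
    if len(ii) == 0:
        return {"precision": None, "n_selected": 0, "n_wanted": n_wanted,
                "truncated": True}
    ri, rj = _ranked_pairs(p, (ii, jj))
    n_sel = min(n_wanted, len(ri))
    sel_true = y[ri[:n_sel], rj[:n_sel]]
    return {
        "precision": float(sel_true.mean()),
        "n_selected": int(n_sel),
        "n_wanted": n_wanted,
        "truncated": n_sel < n_wanted,
    }


def contact_recall(p: np.ndarray, y: np.ndarray, rng_bin="long", k: int = 5):
    """TP / (TP + FN): recall of the same top-L/k selection."""
    y = np.asarray(y, dtype=float)
    rng_bin = _as_bin(rng_bin)
    ii, jj = _candidate_pairs(p, y, rng_bin)
    n_true = float(y[ii, jj].sum())
    if n_true == 0:
        return None
    L = p.shape[0]
    ri, rj = _ranked_pairs(p, (ii, jj))
    n_sel = min(math.ceil(L / k), len(ri))
    return float(y[ri[:n_sel], rj[:n_sel]].sum() / n_true)


# ----------------------------------------------------------- residue metrics


def ss_metrics(ss3_true: np.ndarray, ss3_pred) -> dict:
    """Accuracy and per-class recall/precision of 3-state SS prediction.

    `ss3_pred` may be class codes or an (L, 3) probability matrix
    (argmax is taken).  Masked residues (-1 in truth) are excluded;
    undefined ratios are None.
    """
    ss3_true = np.asarray(ss3_true)
    ss3_pred = np.asarray(ss3_pred)
    if ss3_pred.ndim == 2:
        ss3_pred = ss3_pred.argmax(axis=1)
    keep = ss3_true != SS_MASKED
    t, q = ss3_true[keep], ss3_pred[keep]
    report = {"accuracy": float(np.mean(t == q)) if len(t) else None, "per_class": {}}
    for cls, char in zip((HELIX, SHEET, COIL), SS3_CHARS):
        tp = float(np.sum((t == cls) & (q == cls)))
        n_true = float(np.sum(t == cls))
        n_pred = float(np.sum(q == cls))
        report["per_class"][char] = {
            "recall": tp / n_true if n_true else None,
            "precision": tp / n_pred if n_pred else None,
        }
    return report


def asa_three_state_accuracy(asa_true, asa_pred, restypes):
    """Accuracy after converting both sides to B/M/E relative-ASA states."""
    asa_true = np.asarray(asa_true, float)
    asa_pred = np.asarray(asa_pred, float)
    keep = np.isfinite(asa_true)
    if not keep.any():
        return None
    restypes = [r for r, k in zip(restypes, keep) if k]
    true_states = asa_to_three_state_array(asa_true[keep], restypes)
    pred_states = asa_to_three_state_array(asa_pred[keep], restypes)
    return float(np.mean(true_states == pred_states))


# ------------------------------------------------------------- contact types


def contact_type_metrics(
    p: np.ndarray, y: np.ndarray, ss3_true: np.ndarray, selection=None
) -> dict:
    """Recall and precision of HH / HS / SS contacts.

    A pair's type comes from the true secondary structure of its two
    residues; only pairs whose residues are both helix or sheet are
    typed (HS is unordered).  By default the prediction set is the union
    of the top-L selections of the short, medium and long bins
    (configurable via `selection`, a list of (i, j) pairs).
    """
    y = np.asarray(y, dtype=float)
    ss3_true = np.asarray(ss3_true)
    L = p.shape[0]
    if selection is None:
        selected = set()
        for rng_bin in (SHORT, MEDIUM, LONG):
            ii, jj = _candidate_pairs(p, y, rng_bin)
            if len(ii) == 0:
                continue
            ri, rj = _ranked_pairs(p, (ii, jj))
            selected.update(zip(ri[:L].tolist(), rj[:L].tolist()))
    else:
        selected = {(min(i, j), max(i, j)) for i, j in selection}

    def pair_type(i, j):
        a, b = ss3_true[i], ss3_true[j]
        if a not in (HELIX, SHEET) or b not in (HELIX, SHEET):
            return None
        if a == HELIX and b == HELIX:
            return "HH"
        if a == SHEET and b == SHEET:
            return "SS"
        return "HS"

    tp = {t: 0 for t in CONTACT_TYPES}
    n_sel = {t: 0 for t in CONTACT_TYPES}
    n_true = {t: 0 for t in CONTACT_TYPES}
    ii, jj = _candidate_pairs(p, y, ALL_RANGES)
    for i, j in zip(ii.tolist(), jj.tolist()):
        t = pair_type(i, j)
        if t is None:
            continue
        is_contact = y[i, j] == 1.0
        in_sel = (i, j) in selected
        if is_contact:
            n_true[t] += 1
        if in_sel:
            n_sel[t] += 1
            if is_contact:
                tp[t] += 1
    return {
        t: {
            "recall": tp[t] / n_true[t] if n_true[t] else None,
            "precision": tp[t] / n_sel[t] if n_sel[t] else None,
        }
        for t in CONTACT_TYPES
    }


# ------------------------------------------------------------------ RR export


def select_top_contacts(p: np.ndarray, max_count: int | None = None):
    """Rank all pairs with separation >= 6 by probability (ranges mixed)
    and keep up to `max_count` (default 2L) — the tertiary-structure
    pipeline's contact selection."""
    p = np.asarray(p, dtype=float)
    L = p.shape[0]
    if max_count is None:
        max_count = 2 * L
    ii, jj = np.triu_indices(L, k=MIN_SEPARATION)
    ri, rj = _ranked_pairs(p, (ii, jj))
    ri, rj = ri[:max_count], rj[:max_count]
    return [(int(i), int(j), float(p[i, j])) for i, j in zip(ri, rj)]


def write_casp_rr(pairs, sequence: str, target: str = "T0000") -> str:
    """CASP RR text: header, sequence, then '<i> <j> 0 8 <prob>' lines
    with 1-based i < j."""
    lines = ["PFRMAT RR", f"TARGET {target}", "MODEL 1"]
    for start in range(0, len(sequence), 50):
        lines.append(sequence[start : start + 50])
    for i, j, prob in pairs:
        a, b = (i, j) if i < j else (j, i)
        lines.append(f"{a + 1} {b + 1} 0 8 {prob:g}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_casp_rr(text: str):
    """Inverse of :func:`write_casp_rr`: returns (sequence, pairs)."""
    sequence_parts, pairs = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line in ("END",) or line.split()[0] in ("PFRMAT", "TARGET", "MODEL"):
            continue
        fields = line.split()
        if len(fields) == 5:
            i, j = int(fields[0]) - 1, int(fields[1]) - 1
            pairs.append((i, j, float(fields[4])))
        else:
            sequence_parts.append(line)
    return "".join(sequence_parts), pairs


# ------------------------------------------------------------------- reports


def contact_report(p: np.ndarray, y: np.ndarray) -> dict:
    """Precision for every bin x k in {10, 5, 2, 1} (None where undefined)."""
    return {
        name: {f"L/{k}": top_lk_precision(p, y, rng_bin, k) for k in TOP_K_VALUES}
        for name, rng_bin in RANGE_BINS.items()
    }


def full_report(bundle, labels, restypes=None) -> dict:
    """MetricReport for one protein from a PredictionBundle and labels."""
    report = {"contact": contact_report(bundle.contact_prob, labels.contact_map)}
    if bundle.ss_prob is not None and labels.ss3 is not None:
        report["ss"] = ss_metrics(labels.ss3, bundle.ss_prob)
        report["contact_types"] = contact_type_metrics(
            bundle.contact_prob, labels.contact_map, labels.ss3
        )
    if bundle.asa_pred is not None and labels.asa is not None and restypes is not None:
        report["asa_three_state_accuracy"] = asa_three_state_accuracy(
            labels.asa, bundle.asa_pred, restypes
        )
    return report
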