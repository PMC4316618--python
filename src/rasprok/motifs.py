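"""G1-G5 motif extraction, conservation profiling, mechanism classification.

Motif windows are defined once on a reference protein (1-based residue
ranges) and projected onto every sequence of a multiple alignment through
the reference's alignment columns.  The catalytic-mechanism caller then
applies ordered sequence rules distinguishing the intrinsic-arginine type
(arginine adjacent to the G2 threonine plus a TxPGQ switch II), the
threonine/GTPGQ type shared by the remaining MglA groups, and the two
eukaryote-like Ras types with and without the catalytic glutamine of the
DxxG(Q) motif.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .synthetic_data import AA, MOTIF_NAMES

__all__ = [
    "MotifCoordinateMap",
    "MotifSet",
    "ConservationProfile",
    "MechanismCall",
    "project_motifs",
    "profile",
    "call_mechanism",
    "detect_insertion",
]

MECHANISMS = (
    "INTRINSIC_ARG",
    "G2THR_GTPGQ",
    "RAS_LIKE_Q",
    "RAS_LIKE_NO_Q",
    "UNCALLED",
)

#: residue classes used for ambiguity-class consensus letters
RESIDUE_CLASSES = ("ILVM", "FYW", "KR", "DE", "ST", "NQ", "AG")


@dataclass(frozen=True)
class MotifCoordinateMap:
    """Reference-anchored motif geometry.

    All coordinates are 1-based inclusive residue positions on the
    ungapped reference sequence.  ``g2_thr_offset`` is the 0-based offset
    of the conserved G2 threonine within the G2 window;
    ``base_g1_g2_spacing`` is the insertion-free G1-to-G2 spacing used as
    the baseline when measuring the bacterial-MglA insertion.
    """

    reference_id: str
    core_range: tuple[int, int]
    motif_windows: dict[str, tuple[int, int]]
    g2_thr_offset: int = 1
    base_g1_g2_spacing: int = 24

    def __post_init__(self):
        lo, hi = self.core_range
        prev_end = None
        for m in MOTIF_NAMES:
            if m not in self.motif_windows:
                raise ValueError(f"missing window for {m}")
            a, b = self.motif_windows[m]
            if a > b:
                raise ValueError(f"window {m} reversed")
            if not (lo <= a and b <= hi):
                raise ValueError(f"window {m} outside core range")
            if prev_end is not None and a <= prev_end:
                raise ValueError(f"window {m} overlaps or disorders previous")
            prev_end = b

    @classmethod
    def from_dict(cls, d: Mapping) -> "MotifCoordinateMap":
        return cls(
            reference_id=d["reference_id"],
            core_range=tuple(d["core_range"]),
            motif_windows={k: tuple(v) for k, v in d["motif_windows"].items()},
            g2_thr_offset=d.get("g2_thr_offset", 1),
            base_g1_g2_spacing=d.get("base_g1_g2_spacing", 24),
        )


@dataclass
class MotifSet:
    """Per-protein G1-G5 windows (absent windows are None, never "")."""

    protein_id: str
    windows: dict[str, str | None]
    #: ungapped residues between the end of G1 and the start of G2
    g1_g2_spacing: int | None = None
    insertion_present: bool = False
    insertion_length: int = 0


def _reference_columns(ref_row: str) -> list[int]:
    """Column index (0-based) of each ungapped reference position."""
    return [i for i, c in enumerate(ref_row) if c not in "-."]


def project_motifs(
    alignment: Mapping[str, str], cmap: MotifCoordinateMap, gap_fraction: float = 0.5
) -> dict[str, MotifSet]:
    """Project the reference motif windows through alignment columns.

    For each sequence, a motif window is the ungapped residues it carries
    in the reference window's columns; a window with more than
    `gap_fraction` gap characters is recorded as absent.  Inserting
    all-gap columns into the alignment cannot change the result.
    """
    if cmap.reference_id not in alignment:
        raise ValueError(f"reference {cmap.reference_id!r} missing from alignment")
    ref_row = alignment[cmap.reference_id]
    ref_cols = _reference_columns(ref_row)
    need = max(b for _, b in cmap.motif_windows.values())
    if need > len(ref_cols):
        raise ValueError("coordinate map extends past reference length")
    window_cols = {
        m: ref_cols[a - 1 : b] for m, (a, b) in cmap.motif_windows.items()
    }
    g1_end_col = ref_cols[cmap.motif_windows["G1"][1] - 1]
    g2_start_col = ref_cols[cmap.motif_windows["G2"][0] - 1]

    out: dict[str, MotifSet] = {}
    for sid, row in alignment.items():
        windows: dict[str, str | None] = {}
        for m, cols in window_cols.items():
            chars = [row[c] for c in cols]
            gaps = sum(1 for c in chars if c in "-.")
            if cols and gaps / len(cols) > gap_fraction:
                windows[m] = None
            else:
                s = "".join(c for c in chars if c not in "-.")
                windows[m] = s if s else None
        spacing = None
        if windows.get("G1") is not None and windows.get("G2") is not None:
            between = row[g1_end_col + 1 : g2_start_col]
            spacing = sum(1 for c in between if c not in "-.")
        out[sid] = MotifSet(protein_id=sid, windows=windows, g1_g2_spacing=spacing)
    return out


@dataclass
class ConservationProfile:
    """Per-column residue frequencies of one motif across a family."""

    motif: str
    length: int
    frequencies: np.ndarray  # (length, 20), rows sum to 1
    consensus: str
    information_content: np.ndarray  # bits per column, in [0, log2 20]
    n_windows: int

    def to_rows(self) -> list[dict]:
        rows = []
        for i in range(self.length):
            row = {"column": i + 1, "information_bits": float(self.information_content[i])}
            row.update({aa: float(self.frequencies[i, k]) for k, aa in enumerate(AA)})
            rows.append(row)
        return rows


def profile(
    motif_sets: Sequence[MotifSet],
    motif: str,
    single_threshold: float = 0.5,
    class_threshold: float = 0.8,
) -> ConservationProfile:
    """Column frequencies and consensus of one motif over present windows.

    The consensus letter is the residue reaching `single_threshold`,
    else a bracketed residue class whose joint frequency reaches
    `class_threshold`, else ``x``.  Windows whose length differs from the
    modal length are ignored (no indel handling inside motifs).
    """
    present = [m.windows.get(motif) for m in motif_sets]
    present = [w for w in present if w]
    if not present:
        raise ValueError(f"no present windows for {motif}")
    modal_len = Counter(len(w) for w in present).most_common(1)[0][0]
    used = [w for w in present if len(w) == modal_len]
    freqs = np.zeros((modal_len, 20))
    index = {aa: k for k, aa in enumerate(AA)}
    for w in used:
        for i, c in enumerate(w):
            if c in index:
                freqs[i, index[c]] += 1
    freqs /= freqs.sum(axis=1, keepdims=True)
    max_bits = math.log2(20)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(freqs > 0, freqs * np.log2(freqs), 0.0), axis=1)
    info = np.clip(max_bits - h, 0.0, max_bits)
    letters = []
    for i in range(modal_len):
        k = int(np.argmax(freqs[i]))
        if freqs[i, k] >= single_threshold:
            letters.append(AA[k])
            continue
        best_cls = None
        for cls in RESIDUE_CLASSES:
            joint = sum(freqs[i, index[c]] for c in cls)
            if joint >= class_threshold:
                best_cls = cls
                break
        letters.append(f"[{best_cls}]" if best_cls else "x")
    return ConservationProfile(
        motif=motif,
        length=modal_len,
        frequencies=freqs,
        consensus="".join(letters),
        information_content=info,
        n_windows=len(used),
    )


@dataclass(frozen=True)
class MechanismCall:
    protein_id: str
    call: str  # one of MECHANISMS
    evidence: tuple[str, ...]


_G3_TXPGQ = re.compile(r"^T.PGQ$")
_G3_GT__Q = re.compile(r"^GT..Q$")
_G3_D__GQ = re.compile(r"^D..GQ$")
_G3_D__G = re.compile(r"^D..G")

_G4_ANNOT = (
    (re.compile(r"^[NT]K.D$"), "G4 [NT]KxD"),
    (re.compile(r"^N.FD$"), "G4 NxFD"),
)
_G5_ANNOT = (
    (re.compile(r"^SA[KL]$"), "G5 SA[KL]"),
    (re.compile(r"^DAR$"), "G5 DAR"),
)


def call_mechanism(m: MotifSet, g2_thr_offset: int = 1) -> MechanismCall:
    """Ordered rule-based catalytic-mechanism call from G2/G3 windows.

    1. arginine adjacent to the G2 threonine and a TxPGQ switch II
       -> INTRINSIC_ARG (the Group-1 MglA type);
    2. GTPGQ-like switch II (G,T leading, terminal Q) with a threonine in
       place of that arginine -> G2THR_GTPGQ (MglA Groups 2-5 type);
    3. DxxGQ -> RAS_LIKE_Q (eukaryote-like, catalytic glutamine present);
    4. DxxG without Q at the +4 position -> RAS_LIKE_NO_Q;
    otherwise UNCALLED.  G4/G5 matches are recorded as evidence only.
    """
    g2 = m.windows.get("G2")
    g3 = m.windows.get("G3")
    t = g2_thr_offset
    evidence: list[str] = []
    call = "UNCALLED"

    g2_thr = bool(g2) and len(g2) > t and g2[t] == "T"
    g2_arg_adj = g2_thr and len(g2) > t + 1 and g2[t + 1] == "R"
    g2_thr_adj = g2_thr and len(g2) > t + 1 and g2[t + 1] == "T"

    if g3 and g2_arg_adj and _G3_TXPGQ.match(g3):
        call = "INTRINSIC_ARG"
        evidence += ["G2 arginine adjacent to threonine", f"G3 {g3} (TxPGQ)"]
    elif g3 and g2_thr_adj and _G3_GT__Q.match(g3):
        call = "G2THR_GTPGQ"
        evidence += ["G2 threonine in place of arginine", f"G3 {g3} (GTxxQ)"]
    elif g3 and _G3_D__GQ.match(g3):
        call = "RAS_LIKE_Q"
        evidence.append(f"G3 {g3} (DxxGQ)")
    elif g3 and _G3_D__G.match(g3) and (len(g3) < 5 or g3[4] != "Q"):
        call = "RAS_LIKE_NO_Q"
        evidence.append(f"G3 {g3} (DxxG, no Q)")

    for window, annots in (("G4", _G4_ANNOT), ("G5", _G5_ANNOT)):
        w = m.windows.get(window)
        if w:
            for pat, label in annots:
                if pat.match(w):
                    evidence.append(label)
    return MechanismCall(protein_id=m.protein_id, call=call, evidence=tuple(evidence))


def detect_insertion(
    m: MotifSet, reference_spacing: int, min_insertion: int = 5
) -> MotifSet:
    """Flag a G1-G2 insertion when the observed ungapped spacing exceeds
    the (insertion-free) reference spacing by at least `min_insertion`.

    Returns the MotifSet with insertion fields filled in; sequences with
    an absent G1 or G2 are left unflagged.
    """
    if m.g1_g2_spacing is None:
        m.insertion_present = False
        m.insertion_length = 0
        return m
    length = m.g1_g2_spacing - reference_spacing
    m.insertion_length = length
    m.insertion_present = length >= min_insertion
    return m
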