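"""Charge-patterning and disorder statistics for protein sequence regions.

This module quantifies the *form* of intrinsic disorder encoded in a
polypeptide sequence, following the polyampholyte framework of Das & Pappu:

* fractions of charged residues (FCR) and net charge per residue (NCPR),
* the kappa statistic measuring segregation of opposite charges along the
  chain (0 = perfectly mixed, 1 = fully blocky),
* the diagram-of-states conformational classification derived from
  (f+, f-),
* windowed Kyte-Doolittle hydropathy,
* spacing statistics of residue classes (arginine, aromatics, ...) that
  report on the sticker patterning relevant to phase separation,
* a heuristic count of arginines left unpaired by acidic residues, and
* global pairwise identity/similarity between two regions.

Charge conventions: R and K are positive, D and E negative; histidine is
treated as neutral at pH 7.4 and terminal charges are ignored (regions are
internal fragments of a membrane protein).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "ProteinRegion",
    "ChargeFractions",
    "SequenceMetrics",
    "SpacingDistribution",
    "read_fasta_region",
    "packaged_region",
    "charge_fractions",
    "kappa",
    "windowed_hydropathy",
    "classify_diagram_of_states",
    "residue_spacing",
    "unpaired_arginine_count",
    "pairwise_identity",
    "sequence_metrics",
    "metrics_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

POSITIVE = frozenset("RK")
NEGATIVE = frozenset("DE")
AROMATIC = frozenset("FYW")

#: Kyte & Doolittle (1982) hydropathy values.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

KAPPA_WINDOWS = (5, 6)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRegion:
    """A named subsequence with 1-based inclusive residue numbering."""

    name: str
    sequence: str
    start: int = 1
    end: int = 0

    def __post_init__(self):
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"length {len(self.sequence)} inconsistent with "
                f"boundaries {self.start}-{self.end}"
            )
        bad = [
            (i + self.start, c)
            for i, c in enumerate(self.sequence)
            if c not in AMINO_ACIDS
        ]
        if bad:
            raise ValueError(
                "non-canonical residue letters at positions: "
                + ", ".join(f"{p}({c})" for p, c in bad[:10])
            )

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class ChargeFractions:
    """Charge composition of a region: f+, f-, FCR and NCPR."""

    f_plus: float
    f_minus: float

    @property
    def fcr(self) -> float:
        return self.f_plus + self.f_minus

    @property
    def ncpr(self) -> float:
        return self.f_plus - self.f_minus


@dataclass(frozen=True)
class SpacingDistribution:
    """Separations between consecutive occurrences of a residue class.

    ``gaps[i]`` is the position difference between occurrence ``i+1`` and
    occurrence ``i``; an empty list (fewer than two occurrences) leaves
    ``mean``/``sd`` as NaN.
    """

    residue_class: str
    positions: tuple[int, ...]
    gaps: tuple[int, ...]

    @property
    def defined(self) -> bool:
        return len(self.gaps) > 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.gaps)) if self.gaps else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.gaps)) if self.gaps else float("nan")


@dataclass(frozen=True)
class SequenceMetrics:
    """Bundle of per-region disorder statistics (one Table row)."""

    region: ProteinRegion
    charges: ChargeFractions
    kappa: float  # NaN when undefined (<2 charged residues)
    hydropathy: float
    conformational_class: str


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------

def read_fasta_region(
    path,
    start: int,
    end: int,
    name: str | None = None,
    record_id: str | None = None,
    record_start: int = 1,
) -> ProteinRegion:
    """Extract an inclusive residue range from a FASTA record.

    Parameters
    ----------
    path : path-like
        Single- or multi-record FASTA file.
    start, end : int
        1-based inclusive residue numbers *in the parent protein*.
    record_id : str, optional
        Which record to use in a multi-record file (default: first).
    record_start : int
        Residue number of the first letter of the record; lets a FASTA file
        hold an already-excised fragment while keeping parent numbering.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if record_id is None:
        record = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"record {record_id!r} not found in {path}")
        record = matches[0]
    seq = str(record.seq).upper()
    lo = start - record_start
    hi = end - record_start + 1
    if start > end or lo < 0 or hi > len(seq):
        raise IndexError(
            f"boundaries {start}-{end} outside record "
            f"{record.id} ({record_start}-{record_start + len(seq) - 1})"
        )
    return ProteinRegion(
        name=name or f"{record.id}_{start}-{end}",
        sequence=seq[lo:hi],
        start=start,
        end=end,
    )


def packaged_region(name: str) -> ProteinRegion:
    """Load one of the packaged synthetic surrogate CTD2 regions.

    ``name`` is ``"CTD2A"`` or ``"CTD2B"``. The packaged FASTA files are
    *synthetic surrogates*: sequences generated to match the published
    composition, charge-patterning and residue-spacing statistics of the rat
    GluN2A/GluN2B CTD2 subdomains, not the UniProt records themselves (see
    the file headers).
    """
    files = {
        "CTD2A": ("ctd2a_synthetic.fasta", 1243, 1464),
        "CTD2B": ("ctd2b_synthetic.fasta", 1250, 1482),
    }
    try:
        fname, start, end = files[name.upper()]
    except KeyError:
        raise KeyError(f"unknown packaged region {name!r}; choose from {sorted(files)}")
    ref = resources.files("idrctd.data") / fname
    with resources.as_file(ref) as path:
        return read_fasta_region(path, start, end, name=name.upper(), record_start=start)


# ---------------------------------------------------------------------------
# charge composition
# ---------------------------------------------------------------------------

def _charge_array(sequence: str) -> np.ndarray:
    q = np.zeros(len(sequence), dtype=np.int8)
    for i, c in enumerate(sequence):
        if c in POSITIVE:
            q[i] = 1
        elif c in NEGATIVE:
            q[i] = -1
    return q


def charge_fractions(region: ProteinRegion | str) -> ChargeFractions:
    """f+, f- (and thus FCR/NCPR) of a region; H counted neutral."""
    seq = region.sequence if isinstance(region, ProteinRegion) else region
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    npos = sum(c in POSITIVE for c in seq)
    nneg = sum(c in NEGATIVE for c in seq)
    return ChargeFractions(f_plus=npos / n, f_minus=nneg / n)


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------

def _sigma(f_plus: np.ndarray, f_minus: np.ndarray) -> np.ndarray:
    """Charge asymmetry sigma = (f+ - f-)^2 / (f+ + f-), 0 where uncharged."""
    tot = f_plus + f_minus
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(tot > 0, (f_plus - f_minus) ** 2 / np.where(tot > 0, tot, 1), 0.0)
    return s


def charge_delta(charges: Sequence[int], window: int) -> float:
    """Mean squared deviation of windowed sigma from whole-sequence sigma.

    ``charges`` is a vector over residues with values +1/-1/0. Windows slide
    by one residue.
    """
    q = np.asarray(charges, dtype=float)
    n = q.size
    if window < 1 or window > n:
        raise ValueError(f"window {window} does not fit sequence of length {n}")
    pos = (q > 0).astype(float)
    neg = (q < 0).astype(float)
    kern = np.ones(window)
    fp = np.convolve(pos, kern, mode="valid") / window
    fm = np.convolve(neg, kern, mode="valid") / window
    sig_seq = _sigma(np.array([pos.mean()]), np.array([neg.mean()]))[0]
    return float(np.mean((_sigma(fp, fm) - sig_seq) ** 2))


@lru_cache(maxsize=512)
def _delta_max(n_pos: int, n_neg: int, n_neutral: int, window: int) -> float:
    """Maximal delta over maximally segregated test arrangements.

    Evaluates delta over two deterministic layout families and returns the
    maximum:

    1. two contiguous charge blocks with the neutral residues distributed
       around and between them,

           [0]*a  [+]*n_pos  [0]*m  [-]*n_neg  [0]*b

    2. "wrapped" layouts where one charge species is split into blocks at
       the two chain ends with the other species centred and all neutrals
       internal,

           [x]*c  [0]*a  [y]*n_y  [0]*b  [x]*(n_x - c)

    Exchanging + and - leaves sigma (hence delta) unchanged, so family 1
    needs one orientation only; family 2 runs over both choices of the
    split species. This search stands in for the exponential exact
    permutation search; on short sequences it is verified against
    exhaustive enumeration in the test-suite.
    """
    best = 0.0
    for a in range(n_neutral + 1):
        for b in range(n_neutral - a + 1):
            m = n_neutral - a - b
            q = [0] * a + [1] * n_pos + [0] * m + [-1] * n_neg + [0] * b
            best = max(best, charge_delta(tuple(q), window))
    for n_x, n_y, s_x, s_y in ((n_pos, n_neg, 1, -1), (n_neg, n_pos, -1, 1)):
        for c in range(n_x + 1):
            for a in range(n_neutral + 1):
                b = n_neutral - a
                q = [s_x] * c + [0] * a + [s_y] * n_y + [0] * b + [s_x] * (n_x - c)
                best = max(best, charge_delta(tuple(q), window))
    return best


def kappa(region: ProteinRegion | str, windows: tuple[int, ...] = KAPPA_WINDOWS) -> float:
    """Das-Pappu charge-segregation statistic in [0, 1].

    Returns NaN when the region carries fewer than two charged residues
    (the statistic is undefined); raises if the sequence is shorter than a
    blob window.
    """
    seq = region.sequence if isinstance(region, ProteinRegion) else region
    q = _charge_array(seq)
    n_pos = int(np.sum(q > 0))
    n_neg = int(np.sum(q < 0))
    if n_pos + n_neg < 2:
        return float("nan")
    if len(seq) < max(windows):
        raise ValueError(
            f"sequence of length {len(seq)} shorter than blob window {max(windows)}"
        )
    ratios = []
    for g in windows:
        dmax = _delta_max(n_pos, n_neg, len(seq) - n_pos - n_neg, g)
        if dmax == 0.0:
            return float("nan")
        ratios.append(charge_delta(tuple(q), g) / dmax)
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# hydropathy
# ---------------------------------------------------------------------------

def windowed_hydropathy(region: ProteinRegion | str, window: int = 5) -> float:
    """Mean rescaled Kyte-Doolittle hydropathy over sliding windows.

    Per-residue values are shifted from [-4.5, +4.5] onto [0, 9], averaged
    within each sliding window of ``window`` residues, and the window means
    are averaged. Poly-Ile scores 9 (most hydrophobic), poly-Arg scores 0.
    """
    seq = region.sequence if isinstance(region, ProteinRegion) else region
    if window < 1 or window > len(seq):
        raise ValueError(f"window {window} invalid for length {len(seq)}")
    vals = np.array([KYTE_DOOLITTLE[c] + 4.5 for c in seq])
    win_means = np.convolve(vals, np.ones(window) / window, mode="valid")
    return float(win_means.mean())


# ---------------------------------------------------------------------------
# diagram of states
# ---------------------------------------------------------------------------

WEAK_POLYAMPHOLYTE = "weak polyampholyte"
INTERMEDIATE_POLYAMPHOLYTE = "intermediate polyampholyte"
STRONG_POLYAMPHOLYTE = "strong polyampholyte"
POSITIVE_POLYELECTROLYTE = "positive polyelectrolyte"
NEGATIVE_POLYELECTROLYTE = "negative polyelectrolyte"


def classify_diagram_of_states(charges: ChargeFractions) -> str:
    """Das-Pappu diagram-of-states region from (f+, f-).

    Boundaries belong to the more-charged class (checked from the
    polyelectrolyte corner down), making the classification total and
    deterministic on the (f+, f-) simplex.
    """
    fp, fm = charges.f_plus, charges.f_minus
    if fp > 0.35 and fm > 0.35:
        return STRONG_POLYAMPHOLYTE
    if fm > 0.35:
        return NEGATIVE_POLYELECTROLYTE
    if fp > 0.35:
        return POSITIVE_POLYELECTROLYTE
    if charges.fcr > 0.35:
        return STRONG_POLYAMPHOLYTE
    if charges.fcr >= 0.25:
        return INTERMEDIATE_POLYAMPHOLYTE
    return WEAK_POLYAMPHOLYTE


# ---------------------------------------------------------------------------
# residue patterning
# ---------------------------------------------------------------------------

def residue_spacing(region: ProteinRegion | str, residue_class: Iterable[str]) -> SpacingDistribution:
    """Separations between consecutive occurrences of a residue class.

    ``residue_class`` pools one or more letters (e.g. ``"R"`` or ``"FY"``).
    """
    letters = frozenset(residue_class)
    if not letters:
        raise ValueError("residue_class must not be empty")
    seq = region.sequence if isinstance(region, ProteinRegion) else region
    positions = tuple(i + 1 for i, c in enumerate(seq) if c in letters)
    gaps = tuple(int(b - a) for a, b in zip(positions, positions[1:]))
    return SpacingDistribution(
        residue_class="".join(sorted(letters)), positions=positions, gaps=gaps
    )


def unpaired_arginine_count(region: ProteinRegion | str) -> int:
    """Arginines left after acidic residues pair first with lysines.

    Heuristic composition arithmetic: acidic residues (D+E) neutralise
    lysines first; any acidic excess then pairs against arginines; the
    remainder is returned. Exposed as a replaceable convention, not a
    physical model.
    """
    seq = region.sequence if isinstance(region, ProteinRegion) else region
    n_r = seq.count("R")
    n_k = seq.count("K")
    n_acid = seq.count("D") + seq.count("E")
    return max(0, n_r - max(0, n_acid - n_k))


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

def pairwise_identity(a: ProteinRegion | str, b: ProteinRegion | str) -> tuple[float, float]:
    """Global-alignment identity and similarity fractions.

    BLOSUM62 scoring with affine gaps (open 10, extend 0.5). Identity is
    identical pairs / alignment columns (gap columns included); similarity
    additionally counts substitutions with a positive BLOSUM62 score.
    """
    sa = a.sequence if isinstance(a, ProteinRegion) else a
    sb = b.sequence if isinstance(b, ProteinRegion) else b
    if not sa or not sb:
        raise ValueError("both sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(sa, sb)[0]
    row_a, row_b = aln[0], aln[1]
    matrix = aligner.substitution_matrix
    n_cols = len(row_a)
    ident = 0
    simil = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            ident += 1
            simil += 1
        elif matrix[ca, cb] > 0:
            simil += 1
    return ident / n_cols, simil / n_cols


# ---------------------------------------------------------------------------
# per-region summary
# ---------------------------------------------------------------------------

def sequence_metrics(region: ProteinRegion, window: int = 5) -> SequenceMetrics:
    """All Table-style statistics for one region."""
    ch = charge_fractions(region)
    return SequenceMetrics(
        region=region,
        charges=ch,
        kappa=kappa(region),
        hydropathy=windowed_hydropathy(region, window=window),
        conformational_class=classify_diagram_of_states(ch),
    )


def metrics_table(metrics: Iterable[SequenceMetrics]):
    """Per-region metrics as a pandas DataFrame mirroring the report layout."""
    import pandas as pd

    rows = []
    for m in metrics:
        rows.append(
            {
                "Protein": m.region.name,
                "Sequence": f"{m.region.start}-{m.region.end}",
                "Kappa": round(m.kappa, 3),
                "FCR": round(m.charges.fcr, 3),
                "NCPR": round(m.charges.ncpr, 3),
                "Hydropathy": round(m.hydropathy, 1),
                "Class": m.conformational_class,
            }
        )
    return pd.DataFrame(rows)
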