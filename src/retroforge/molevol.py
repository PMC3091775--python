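"""LPB Ka/Ks estimation, rate calibration, ages and origination rates.

The estimator follows the Li (1993) / Pamilo-Bianchi (1993) refinement of
the Li-Wu-Luo method: every codon position is classified as nondegenerate
(0-fold), twofold or fourfold degenerate from the genetic code (threefold
sites are treated as twofold), transitional and transversional differences
are tallied per degeneracy class, Kimura two-parameter corrections are
applied per class, and the synonymous and nonsynonymous distances combine
the class distances as

    Ks = (L2*A2 + L4*A4) / (L2 + L4) + B4
    Ka = A0 + (L0*B0 + L2*B2) / (L0 + L2)

where Ai and Bi are the transitional and transversional K2P distances of
class i and Li the (pair-averaged) site counts.

Ages follow from the molecular clock Ks = 2*r*T, with the synonymous rate r
calibrated from ortholog pairs at a known divergence time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SaturationError",
    "SiteCounts",
    "KaKsResult",
    "RateCalibration",
    "count_sites",
    "kaks_lpb",
    "calibrate_rate",
    "estimate_age",
    "origination_rate",
    "ks_histogram",
]

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Raised when divergence exceeds the K2P correction's validity range."""


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def _degeneracy_class(codon: str, position: int) -> int:
    """Degeneracy class (0, 2 or 4) of one codon position.

    The class is the number of nucleotides at the position that preserve the
    amino acid: 4 synonymous choices -> fourfold, 2 or 3 -> twofold, 1 ->
    nondegenerate.  Computed from the code table, so the arginine/leucine
    first-position irregularities fall out of each codon's own row.
    """
    aa = GENETIC_CODE[codon]
    n_same = 0
    for nt in "ACGT":
        alt = codon[:position] + nt + codon[position + 1:]
        if GENETIC_CODE[alt] == aa:
            n_same += 1
    if n_same == 4:
        return 4
    if n_same >= 2:
        return 2
    return 0


# cache: degeneracy of every sense codon at each position
_DEGENERACY: dict[str, tuple[int, int, int]] = {
    codon: tuple(_degeneracy_class(codon, k) for k in range(3))
    for codon, aa in GENETIC_CODE.items()
    if aa != "*"
}

_CLASS_INDEX = {0: 0, 2: 1, 4: 2}


@dataclass
class SiteCounts:
    """Per-class site and difference counts of one codon-aligned pair.

    ``L`` holds the pair-averaged numbers of nondegenerate, twofold and
    fourfold sites; ``ts`` and ``tv`` the transitional and transversional
    difference counts attributed to each class.
    """

    L: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ts: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tv: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_codons: int = 0

    @property
    def L0(self) -> float:
        return float(self.L[0])

    @property
    def L2(self) -> float:
        return float(self.L[1])

    @property
    def L4(self) -> float:
        return float(self.L[2])


@dataclass
class KaKsResult:
    """LPB distances of one pair: rates, site counts and per-class terms."""

    ka: float
    ks: float
    ratio: float | None
    sites: SiteCounts
    P: np.ndarray  # transition proportions per class
    Q: np.ndarray  # transversion proportions per class
    A: np.ndarray  # transitional K2P distances per class
    B: np.ndarray  # transversional K2P distances per class


def _clean_codon_columns(seq_a: str, seq_b: str) -> list[tuple[str, str]]:
    """Split an aligned pair into codon columns, dropping gapped/ambiguous ones."""
    seq_a = seq_a.upper().replace("U", "T")
    seq_b = seq_b.upper().replace("U", "T")
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("aligned length must be a multiple of 3")
    keep = []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue  # gap or ambiguity column: excluded from site counting
        keep.append((ca, cb))
    return keep


def count_sites(seq_a: str, seq_b: str) -> SiteCounts:
    """Classify sites and tally per-class differences for an aligned CDS pair.

    Site classes are averaged over the two sequences.  Each differing
    position contributes one transition or transversion; when the two codons
    assign the position to different classes the count is split half-half.
    Internal stop codons are an input error (they invalidate the degeneracy
    classification downstream).
    """
    pairs = _clean_codon_columns(seq_a, seq_b)
    counts = SiteCounts()
    # terminal stop codons are tolerated only at the final column
    for idx, (ca, cb) in enumerate(pairs):
        last = idx == len(pairs) - 1
        for name, codon in (("first", ca), ("second", cb)):
            if GENETIC_CODE[codon] == "*":
                if last:
                    break
                raise ValueError(
                    f"internal stop codon {codon} at codon {idx} of {name} sequence"
                )
        else:
            counts.n_codons += 1
            deg_a = _DEGENERACY[ca]
            deg_b = _DEGENERACY[cb]
            for k in range(3):
                ia, ib = _CLASS_INDEX[deg_a[k]], _CLASS_INDEX[deg_b[k]]
                counts.L[ia] += 0.5
                counts.L[ib] += 0.5
                if ca[k] != cb[k]:
                    dest = counts.ts if is_transition(ca[k], cb[k]) else counts.tv
                    dest[ia] += 0.5
                    dest[ib] += 0.5
            continue
        break  # terminal stop reached
    return counts


def _k2p_class_distances(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a_arg = 1.0 - 2.0 * P - Q
    b_arg = 1.0 - 2.0 * Q
    if np.any(a_arg <= 0.0) or np.any(b_arg <= 0.0):
        raise SaturationError(
            f"divergence saturated (1-2P-Q={a_arg}, 1-2Q={b_arg}); "
            "K2P correction undefined"
        )
    A = 0.5 * np.log(1.0 / a_arg) - 0.25 * np.log(1.0 / b_arg)
    B = 0.5 * np.log(1.0 / b_arg)
    return A, B


def kaks_lpb(seq_a: str, seq_b: str) -> KaKsResult:
    """LPB Ka, Ks and Ka/Ks for a codon-aligned pair of coding sequences.

    Accepts aligned sequences (``-`` gaps allowed; gapped or ambiguous codon
    columns are excluded).  Raises :class:`SaturationError` when a class is
    too diverged for the K2P correction.
    """
    sites = count_sites(seq_a, seq_b)
    L = sites.L.copy()
    with np.errstate(invalid="ignore"):
        P = np.where(L > 0, sites.ts / np.where(L > 0, L, 1.0), 0.0)
        Q = np.where(L > 0, sites.tv / np.where(L > 0, L, 1.0), 0.0)
    A, B = _k2p_class_distances(P, Q)
    L0, L2, L4 = L
    syn_sites = L2 + L4
    nonsyn_sites = L0 + L2
    ks = (L2 * A[1] + L4 * A[2]) / syn_sites + B[2] if syn_sites > 0 else 0.0
    ka = A[0] + ((L0 * B[0] + L2 * B[1]) / nonsyn_sites if nonsyn_sites > 0 else 0.0)
    ks = float(max(ks, 0.0))
    ka = float(max(ka, 0.0))
    ratio = ka / ks if ks > 0 else None
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, sites=sites, P=P, Q=Q, A=A, B=B)


@dataclass
class RateCalibration:
    """Synonymous rate calibrated from ortholog Ks at a known split time."""

    r: float  # substitutions per silent site per year
    T: float  # divergence time used, years
    ortholog_ks: list[float]
    n_pairs: int
    n_saturated: int = 0


def calibrate_rate(ortholog_ks, T: float, use_median: bool = False) -> RateCalibration:
    """Calibrate the synonymous substitution rate r from ortholog Ks values.

    Under the clock each ortholog pair accumulates Ks = 2*r*T, so
    r = mean(Ks) / (2*T).  Saturated (non-finite) values are excluded with
    a count kept on the result.  ``use_median`` swaps the mean for the
    median.
    """
    if T <= 0:
        raise ValueError("divergence time must be positive")
    values = [float(k) for k in ortholog_ks]
    finite = [k for k in values if math.isfinite(k) and k >= 0]
    if not finite:
        raise ValueError("no usable ortholog Ks values")
    center = float(np.median(finite)) if use_median else float(np.mean(finite))
    return RateCalibration(
        r=center / (2.0 * T),
        T=float(T),
        ortholog_ks=finite,
        n_pairs=len(finite),
        n_saturated=len(values) - len(finite),
    )


def estimate_age(ks: float, r: float) -> float:
    """Age in years of a duplication with synonymous divergence ``ks``: T = Ks/(2r)."""
    if r <= 0:
        raise ValueError("rate must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * r)


def origination_rate(ages, window_years: float) -> float:
    """Origination rate, new genes per million years within ``window_years``."""
    if window_years <= 0:
        raise ValueError("window must be positive")
    n = sum(1 for a in ages if a <= window_years)
    return n / (window_years / 1.0e6)


def ratio_to(rate: float, reference_rate: float) -> float:
    """Fold difference of an origination rate over a reference lineage's rate."""
    if reference_rate <= 0:
        raise ValueError("reference rate must be positive")
    return rate / reference_rate


def ks_histogram(ks_values, max_ks: float = 1.5, bin_width: float = 0.1):
    """Histogram of Ks over [0, max_ks]; values above max_ks are excluded.

    Returns ``(edges, counts, excluded)`` where ``excluded`` is the list of
    out-of-range values.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(list(ks_values), dtype=float)
    in_range = values[(values >= 0) & (values <= max_ks)]
    excluded = values[(values < 0) | (values > max_ks)]
    n_bins = int(math.ceil(max_ks / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(in_range, bins=edges)
    return edges, counts, excluded.tolist()
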