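"""Theoretical isotope patterns from elemental compositions.

``predict_pattern`` aggregates the isotopologue distribution into unit-nucleon
bins by iterated convolution of per-element distributions — exact up to float
rounding, and fast enough to run over a whole glycopeptide database.
``pattern_oracle`` recomputes the same distribution by explicit enumeration of
isotopologue multinomials; it is deliberately independent of the convolution
path and is only feasible for small formulas, which is what makes it a useful
cross-check.

Patterns are binned at unit nucleon resolution (high-resolution instruments at
Rs >= 30,000 resolve isotope peaks of multiply charged precursors but not fine
structure); each bin's m/z is the probability-weighted centroid of the fine
masses it aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np

from .chem import ELEMENT_ISOTOPES, PROTON_MASS, Formula

__all__ = ["IsotopePattern", "predict_pattern", "pattern_oracle"]

DEFAULT_PRUNE = 1e-4
MAX_PEAKS = 12


@dataclass(frozen=True)
class IsotopePattern:
    """Isotope peaks as (m/z, relative intensity) with base peak = 1.

    ``monoisotopic_index`` locates the all-lightest-isotopes peak within
    ``mz``; for large glycopeptides the base peak sits 1-3 nucleons above it.
    """

    mz: np.ndarray
    rel_intensity: np.ndarray
    charge: int
    monoisotopic_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(
            self, "rel_intensity", np.asarray(self.rel_intensity, dtype=float)
        )
        if len(self.mz) != len(self.rel_intensity):
            raise ValueError("mz and rel_intensity length mismatch")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def base_index(self) -> int:
        return int(np.argmax(self.rel_intensity))

    def top_peaks(self, n: int = 3) -> list[tuple[float, float]]:
        """The n most intense peaks, ordered by descending intensity."""
        order = np.argsort(self.rel_intensity)[::-1][:n]
        return [(float(self.mz[i]), float(self.rel_intensity[i])) for i in order]

    def to_list(self) -> list[list[float]]:
        return [[round(float(m), 5), round(float(r), 6)]
                for m, r in zip(self.mz, self.rel_intensity)]


def _pair_convolve(p1, s1, p2, s2):
    """Convolve two (probability, mass-moment) bin distributions.

    ``s`` carries sum(prob * mass) per bin, so centroids propagate exactly:
    s_k = sum_{i+j=k} p1_i p2_j (m1_i + m2_j) = conv(p1,s2) + conv(s1,p2).
    """
    return np.convolve(p1, p2), np.convolve(p1, s2) + np.convolve(s1, p2)


def _element_distribution(element: str, n: int):
    """n-fold self-convolution of one element's isotope distribution."""
    isotopes = ELEMENT_ISOTOPES[element]
    mono = isotopes[0][0]
    # offsets in whole nucleons from the lightest isotope
    size = max(int(round(m - mono)) for m, _ in isotopes) + 1
    p = np.zeros(size)
    s = np.zeros(size)
    for m, a in isotopes:
        k = int(round(m - mono))
        p[k] += a
        s[k] += a * m
    # binary exponentiation
    rp, rs = np.array([1.0]), np.array([0.0])
    bp, bs = p, s
    while n:
        if n & 1:
            rp, rs = _pair_convolve(rp, rs, bp, bs)
        n >>= 1
        if n:
            bp, bs = _pair_convolve(bp, bs, bp, bs)
    return rp, rs


def _neutral_distribution(f: Formula):
    p, s = np.array([1.0]), np.array([0.0])
    for el, n in sorted(f.items()):
        if n == 0:
            continue
        ep, es = _element_distribution(el, n)
        p, s = _pair_convolve(p, s, ep, es)
    return p, s


def _finalize(p: np.ndarray, s: np.ndarray, charge: int,
              prune: float, max_peaks: int) -> IsotopePattern:
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = np.where(p > 0, s / np.where(p > 0, p, 1.0), 0.0)
    rel = p / p.max()
    keep = np.flatnonzero(rel >= prune)
    if len(keep) > max_peaks:
        # retain the max_peaks most intense bins, keeping m/z order
        order = keep[np.argsort(rel[keep])[::-1][:max_peaks]]
        keep = np.sort(order)
    mz = (centroid[keep] + charge * PROTON_MASS) / charge
    monoiso = int(np.searchsorted(keep, 0)) if 0 in keep else -1
    return IsotopePattern(
        mz=mz, rel_intensity=rel[keep] / rel[keep].max(),
        charge=charge, monoisotopic_index=monoiso,
    )


def predict_pattern(f: Formula, charge: int = 1, prune: float = DEFAULT_PRUNE,
                    max_peaks: int = MAX_PEAKS) -> IsotopePattern:
    """Theoretical isotope pattern of formula ``f`` at the given charge.

    Bins with relative intensity below ``prune`` (fraction of the base peak)
    are dropped; at most ``max_peaks`` peaks are kept.
    """
    if not (0 < prune <= 0.1):
        raise ValueError("prune must be in (0, 0.1]")
    if f.n_atoms == 0:
        raise ValueError("empty formula")
    p, s = _neutral_distribution(f)
    return _finalize(p, s, charge, prune, max_peaks)


ORACLE_MAX_ATOMS = 60


def _partitions(n: int, k: int):
    """All ways to split n atoms among k isotope slots."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _partitions(n - first, k - 1):
            yield (first,) + rest


def pattern_oracle(f: Formula, charge: int = 1, prune: float = DEFAULT_PRUNE,
                   max_peaks: int = MAX_PEAKS,
                   state_floor: float = 1e-13) -> IsotopePattern:
    """Exact pattern by exhaustive isotopologue enumeration (small formulas).

    Enumerates every multinomial split of each element's atoms over its
    isotopes, multiplies probabilities across elements, and bins by total
    nucleon offset exactly as ``predict_pattern`` does.  Per-element splits
    with probability below ``state_floor`` are skipped; their total
    contribution is orders of magnitude below the intensities being compared.
    Refuses formulas with more than 60 atoms, where enumeration stops being
    practical.
    """
    if f.n_atoms > ORACLE_MAX_ATOMS:
        raise ValueError(f"formula too large for enumeration ({f.n_atoms} atoms)")
    if f.n_atoms == 0:
        raise ValueError("empty formula")

    per_element = []  # list of lists of (offset, prob, mass) per element
    for el, n in sorted(f.items()):
        if n == 0:
            continue
        isotopes = ELEMENT_ISOTOPES[el]
        mono = isotopes[0][0]
        states = []
        for split in _partitions(n, len(isotopes)):
            logp = math.lgamma(n + 1)
            mass = 0.0
            offset = 0
            for cnt, (im, ab) in zip(split, isotopes):
                logp -= math.lgamma(cnt + 1)
                logp += cnt * math.log(ab) if cnt else 0.0
                mass += cnt * im
                offset += cnt * int(round(im - mono))
            prob = math.exp(logp)
            if prob >= state_floor:
                states.append((offset, prob, mass))
        per_element.append(states)

    max_offset = sum(max(st[0] for st in states) for states in per_element)
    p = np.zeros(max_offset + 1)
    s = np.zeros(max_offset + 1)
    for combo in product(*per_element):
        offset = sum(c[0] for c in combo)
        prob = math.prod(c[1] for c in combo)
        mass = sum(c[2] for c in combo)
        p[offset] += prob
        s[offset] += prob * mass
    return _finalize(p, s, charge, prune, max_peaks)
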