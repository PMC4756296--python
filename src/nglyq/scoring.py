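"""Scores for the three-stage glycopeptide identification cascade.

* M-score: oxonium-ion triage of HCD spectra (weighted relative intensities
  of 15 diagnostic glycan fragment ions below 700 Da).
* S-score: similarity of an observed precursor isotope envelope to the
  theoretical pattern, weighting mass accuracy : relative intensity at 9:1.
* CID/HCD match scores: fraction of spectrum ion current explained by
  theoretical Y/B/b/y fragments, combined 7:3 into the Y-score.
* Decoy construction (glycan class swap + peptide reversal) and the
  decoy-based FDR / q-value estimate.

Scale conventions: M-score is unbounded below ~a few; S-, match- and Y-scores
live on [0, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .chem import (
    GLYCAN_RESIDUE_MASSES,
    PROTON_MASS,
    AA_RESIDUE_MASSES,
    CARBAMIDOMETHYL,
    GlycanComposition,
    Glycopeptide,
    PeptideBackbone,
    peptide_mass,
)
from .isotopes import IsotopePattern
from .spectra import Ms2Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "OxoniumIon", "DEFAULT_OXONIUM_TABLE", "FragmentSet",
    "m_score", "fit_mscore_threshold", "s_score", "generate_fragments",
    "match_score", "y_score", "make_decoy", "estimate_fdr",
]


@dataclass(frozen=True)
class OxoniumIon:
    mz: float
    weight: float  # C: theoretical frequency of appearance in HCD spectra
    label: str


#: 15 diagnostic oxonium ions; weights favor the HexNAc fragment series
#: (m/z 204/186/168/144/138/126) that dominates glycopeptide HCD spectra.
DEFAULT_OXONIUM_TABLE: tuple[OxoniumIon, ...] = (
    OxoniumIon(126.055, 0.8, "HexNAc-CH6O3"),
    OxoniumIon(138.055, 1.0, "HexNAc-CH8O3"),
    OxoniumIon(144.066, 0.8, "HexNAc-C2H4O2"),
    OxoniumIon(163.060, 0.6, "Hex"),
    OxoniumIon(168.066, 0.9, "HexNAc-2H2O"),
    OxoniumIon(186.076, 0.9, "HexNAc-H2O"),
    OxoniumIon(204.087, 1.0, "HexNAc"),
    OxoniumIon(274.092, 0.8, "NeuAc-H2O"),
    OxoniumIon(292.103, 0.8, "NeuAc"),
    OxoniumIon(325.113, 0.5, "Hex2"),
    OxoniumIon(366.140, 0.9, "HexHexNAc"),
    OxoniumIon(454.156, 0.5, "NeuAcHex"),
    OxoniumIon(512.197, 0.5, "Hex2HexNAc"),
    OxoniumIon(657.235, 0.6, "NeuAcHexHexNAc"),
    OxoniumIon(673.230, 0.5, "NeuAcHex2HexNAc-H2O"),
)

OXONIUM_REGION_DA = 700.0


def m_score(hcd: Ms2Spectrum, table: tuple[OxoniumIon, ...] = DEFAULT_OXONIUM_TABLE,
            tol_ppm: float = 20.0) -> float:
    """Oxonium-ion score of an HCD spectrum.

    For each table ion matched within ``tol_ppm``,
    O_i = C_i * (I_i / I_max(<700 Da)) / (|mass error, Da| + 1.0) and
    M = sum(O_i).  At zero mass error O_i is the weighted relative intensity
    of the matched peak.  Returns 0 for empty spectra or when no peak lies
    below 700 Da.
    """
    if tol_ppm > 20:
        raise ValueError("oxonium match tolerance must be <= 20 ppm")
    if len(hcd) == 0:
        logger.debug("empty spectrum %s", hcd.scan_id)
        return 0.0
    sub = hcd.peaks_mz < OXONIUM_REGION_DA
    if not sub.any():
        return 0.0
    i_max = float(hcd.peaks_intensity[sub].max())
    if i_max <= 0:
        return 0.0
    score = 0.0
    for ion in table:
        tol = ion.mz * tol_ppm * 1e-6
        lo = int(np.searchsorted(hcd.peaks_mz, ion.mz - tol))
        hi = int(np.searchsorted(hcd.peaks_mz, ion.mz + tol))
        if hi <= lo:
            continue
        j = lo + int(np.argmax(hcd.peaks_intensity[lo:hi]))
        err = abs(float(hcd.peaks_mz[j]) - ion.mz)
        score += ion.weight * (float(hcd.peaks_intensity[j]) / i_max) / (err + 1.0)
    return score


def fit_mscore_threshold(scores, floor: float = 0.5) -> float:
    """Data-driven M-score cutoff: mu + 3*sigma of the dominant null mode.

    A Gaussian is fitted to the histogram of scores below the 90th percentile
    (the null mode; genuine glycopeptide spectra form a sparse right tail).
    Degenerate score sets fall back to ``floor``.
    """
    scores = np.asarray(list(scores), dtype=float)
    if len(scores) < 100:
        raise ValueError("need >= 100 scores to fit a threshold")
    low = scores[scores <= np.percentile(scores, 90)]
    if low.std() < 1e-12:
        logger.warning("degenerate M-score distribution; using floor %.2f", floor)
        return floor
    counts, edges = np.histogram(low, bins=40)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, sig):
        return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    try:
        p0 = (counts.max(), float(low.mean()), float(low.std()) + 1e-9)
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
        mu, sig = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        mu, sig = float(low.mean()), float(low.std())
    return max(mu + 3.0 * sig, floor)


def s_score(observed: np.ndarray, theoretical: IsotopePattern,
            tol_ppm: float = 200.0, observed_mz: np.ndarray | None = None,
            min_rel: float = 0.05) -> float:
    """Isotope-envelope similarity score on [0, 100].

    Over theoretical peaks with relative intensity >= ``min_rel``, each peak j
    contributes w_j * (0.9 * m_j + 0.1 * t_j) where m_j = max(0, 1 -
    |mass error, ppm| / tol_ppm), t_j = max(0, 1 - |observed - theoretical
    relative intensity|), and w_j is proportional to theoretical intensity
    (mass accuracy : intensity at 9:1).  A theoretical peak with no observed
    partner contributes zero; an all-zero envelope scores 0.

    ``observed`` holds intensities at the isotope slots aligned with the
    theoretical peaks (slot k = k nucleons above the monoisotopic peak);
    ``observed_mz`` optionally carries the measured m/z per slot for the mass
    term (slots without it are assigned zero mass error when intensity is
    present, since alignment already bounded the error).
    """
    observed = np.asarray(observed, dtype=float)
    if observed.sum() <= 0:
        return 0.0
    theo_rel = theoretical.rel_intensity
    theo_mz = theoretical.mz
    mono = theoretical.monoisotopic_index
    # theoretical peaks above min_rel whose slot (nucleons above the
    # monoisotopic peak) falls inside the extracted envelope; slots never
    # extracted are not evidence either way
    keep = np.flatnonzero(theo_rel >= min_rel)
    keep = keep[(keep - mono >= 0) & (keep - mono < len(observed))]
    if len(keep) == 0:
        return 0.0
    obs_base = observed.max()
    weights = theo_rel[keep]
    weights = weights / weights.sum()
    total = 0.0
    for w, j in zip(weights, keep):
        slot = j - mono
        if observed[slot] <= 0:
            continue  # m_j = t_j = 0
        if observed_mz is not None and np.isfinite(observed_mz[slot]):
            err_ppm = abs(observed_mz[slot] - theo_mz[j]) / theo_mz[j] * 1e6
        else:
            err_ppm = 0.0
        m_term = max(0.0, 1.0 - err_ppm / tol_ppm)
        t_term = max(0.0, 1.0 - abs(observed[slot] / obs_base - theo_rel[j]))
        total += w * (0.9 * m_term + 0.1 * t_term)
    return 100.0 * total


# --- fragment generation ---------------------------------------------------


@dataclass
class FragmentSet:
    """Theoretical fragment m/z values with unique labels."""

    mz: np.ndarray
    labels: list[str]

    def __post_init__(self):
        order = np.argsort(self.mz, kind="stable")
        self.mz = np.asarray(self.mz, dtype=float)[order]
        self.labels = [self.labels[i] for i in order]
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate fragment labels")

    def __len__(self) -> int:
        return len(self.mz)


def glycan_ladder(g: GlycanComposition) -> set[tuple[int, int, int, int]]:
    """Biosynthetically ordered sub-compositions reachable by outer-in loss.

    From the full composition, one residue is removed at a time: NeuAc and Fuc
    at any step; Hex only once NeuAc and Fuc are gone or while Hex > 3 (antenna
    hexoses under remaining decorations); HexNAc last, after all other classes.
    The bare peptide state (0,0,0,0) is always reachable.
    """
    start = g.as_tuple()
    seen = {start}
    stack = [start]
    while stack:
        h, n, f, s = stack.pop()
        nxt = []
        if s > 0:
            nxt.append((h, n, f, s - 1))
        if f > 0:
            nxt.append((h, n, f - 1, s))
        if h > 0 and ((s == 0 and f == 0) or h > 3):
            nxt.append((h - 1, n, f, s))
        if n > 0 and h == 0 and s == 0 and f == 0:
            nxt.append((h, n - 1, f, s))
        for state in nxt:
            if state not in seen:
                seen.add(state)
                stack.append(state)
    return seen


def _sub_mass(state: tuple[int, int, int, int]) -> float:
    h, n, f, s = state
    return (h * GLYCAN_RESIDUE_MASSES["hex"] + n * GLYCAN_RESIDUE_MASSES["hexnac"]
            + f * GLYCAN_RESIDUE_MASSES["fuc"] + s * GLYCAN_RESIDUE_MASSES["neuac"])


def _code(state: tuple[int, int, int, int]) -> str:
    return GlycanComposition(*state).code


def generate_fragments(gp: Glycopeptide, precursor_charge: int, mode: str,
                       oxonium_table: tuple[OxoniumIon, ...] = DEFAULT_OXONIUM_TABLE,
                       ) -> FragmentSet:
    """Theoretical fragments of a glycopeptide for one fragmentation mode.

    CID: Y-ions (peptide + partial glycan) at charges 1..precursor_charge-1
    and singly charged B-ions (glycan-only, non-reducing end).  HCD: Y-ions at
    +1 only, singly charged b/y ions of the bare peptide, and oxonium ions.
    """
    if mode not in ("CID", "HCD"):
        raise ValueError(f"mode must be CID or HCD, got {mode!r}")
    pep_mass = peptide_mass(gp.backbone.sequence)
    ladder = sorted(glycan_ladder(gp.glycan))
    mzs: list[float] = []
    labels: list[str] = []

    y_charges = (range(1, max(precursor_charge, 2))
                 if mode == "CID" else (1,))
    for state in ladder:
        for z in y_charges:
            mzs.append((pep_mass + _sub_mass(state) + z * PROTON_MASS) / z)
            labels.append(f"Y_{_code(state)}^{z}+")

    if mode == "CID":
        for state in ladder:
            if sum(state) == 0:
                continue
            mzs.append(_sub_mass(state) + PROTON_MASS)
            labels.append(f"B_{_code(state)}")
    else:
        seq = gp.backbone.sequence
        cam = CARBAMIDOMETHYL.mass
        prefix = 0.0
        for i, aa in enumerate(seq[:-1], start=1):
            prefix += AA_RESIDUE_MASSES[aa] + (cam if aa == "C" else 0.0)
            mzs.append(prefix + PROTON_MASS)  # b ion
            labels.append(f"b{i}")
            suffix = pep_mass - prefix
            mzs.append(suffix + PROTON_MASS)  # y ion (suffix includes water)
            labels.append(f"y{len(seq) - i}")
        for ion in oxonium_table:
            mzs.append(ion.mz)
            labels.append(f"oxonium_{ion.label}")

    return FragmentSet(np.array(mzs), labels)


def match_score(spectrum: Ms2Spectrum, frags: FragmentSet,
                tol_ppm: float = 20.0, denoise_top: int = 200) -> float:
    """Fraction of retained ion current explained by theoretical fragments.

    The ``denoise_top`` most intense peaks are retained; score =
    100 * sum(matched peak intensities) / sum(retained peak intensities).
    Each spectrum peak matches at most one theoretical fragment (the nearest
    within tolerance; ties broken toward lower m/z).
    """
    if len(spectrum) == 0:
        return 0.0
    mz = spectrum.peaks_mz
    inten = spectrum.peaks_intensity
    if len(mz) > denoise_top:
        keep = np.sort(np.argsort(inten)[::-1][:denoise_top])
        mz, inten = mz[keep], inten[keep]
    total = float(inten.sum())
    if total <= 0:
        return 0.0
    fmz = frags.mz
    # nearest theoretical fragment per peak
    idx = np.searchsorted(fmz, mz)
    left = np.clip(idx - 1, 0, len(fmz) - 1)
    right = np.clip(idx, 0, len(fmz) - 1)
    d_left = np.abs(mz - fmz[left])
    d_right = np.abs(mz - fmz[right])
    nearest = np.where(d_left <= d_right, left, right)  # tie -> lower m/z
    dist = np.minimum(d_left, d_right)
    matched = dist <= mz * tol_ppm * 1e-6
    return 100.0 * float(inten[matched].sum()) / total


def y_score(cid_match: float | None, hcd_match: float | None) -> float:
    """Combined fragment-match score: 0.7 * CID + 0.3 * HCD.

    If one mode is absent, the other is used with weight 1.
    """
    if cid_match is None and hcd_match is None:
        raise ValueError("at least one of CID/HCD match required")
    if cid_match is None:
        logger.debug("CID absent; Y-score from HCD alone")
        return float(hcd_match)
    if hcd_match is None:
        logger.debug("HCD absent; Y-score from CID alone")
        return float(cid_match)
    return 0.7 * float(cid_match) + 0.3 * float(hcd_match)


def make_decoy(gp: Glycopeptide) -> Glycopeptide:
    """Decoy glycopeptide: swap Hex<->HexNAc and Fuc<->NeuAc counts, reverse
    the peptide sequence (glycosite mirrored).

    The glycan swap is an involution; at its fixed points (hex = hexnac and
    fuc = neuac) the decoy still differs through the reversed peptide.
    """
    g = gp.glycan
    decoy_glycan = GlycanComposition(g.hexnac, g.hex, g.neuac, g.fuc)
    seq = gp.backbone.sequence[::-1]
    site = len(seq) - gp.backbone.glycosite + 1
    try:
        backbone = PeptideBackbone(seq, site, gp.backbone.protein_id + "_decoy",
                                   gp.backbone.missed_cleavages)
    except ValueError:
        # the mirrored Asn rarely lands in a sequon; decoys do not need one
        backbone = _UncheckedBackbone(seq, site,
                                      gp.backbone.protein_id + "_decoy",
                                      gp.backbone.missed_cleavages)
    return Glycopeptide(backbone, decoy_glycan)


@dataclass(frozen=True)
class _UncheckedBackbone(PeptideBackbone):
    """Backbone without the sequon invariant — reversed decoy sequences only."""

    def __post_init__(self):  # skip sequon validation, keep residue check
        from .chem import _check_sequence

        _check_sequence(self.sequence)


def estimate_fdr(target_scores, decoy_scores, fdr: float = 0.01
                 ) -> tuple[np.ndarray, float]:
    """Decoy-based q-values for target scores and the score threshold at
    ``fdr``.

    FDR(t) = #{decoy >= t} / max(1, #{target >= t}); the q-value of a score s
    is min over thresholds t <= s of FDR(t); the returned threshold is the
    smallest target score whose FDR is <= ``fdr`` (the minimum target score
    when no decoy outscores any target).
    """
    targets = np.asarray(list(target_scores), dtype=float)
    decoys = np.asarray(list(decoy_scores), dtype=float)
    if len(targets) == 0:
        return np.array([]), float("inf")
    if len(decoys) == 0:
        logger.warning("no decoy scores; FDR is 0 everywhere")
        return np.zeros(len(targets)), float(targets.min())
    order = np.argsort(targets)[::-1]  # descending
    sorted_t = targets[order]
    sorted_decoys = np.sort(decoys)
    n_above_t = np.arange(1, len(sorted_t) + 1)
    n_above_d = len(decoys) - np.searchsorted(sorted_decoys, sorted_t,
                                              side="left")
    fdr_at = n_above_d / np.maximum(1, n_above_t)
    # q(s) = min over thresholds t <= s of FDR(t): reverse cumulative minimum
    q_sorted = np.minimum.accumulate(fdr_at[::-1])[::-1]
    q = np.empty(len(targets))
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    passing = sorted_t[q_sorted <= fdr]
    threshold = float(passing.min()) if len(passing) else float("inf")
    return q, threshold
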