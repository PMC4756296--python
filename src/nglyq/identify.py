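"""The three-stage identification cascade.

Stage 1 (M-score) triages HCD spectra by oxonium-ion content.  Stage 2
(S-score) matches each surviving precursor's observed MS1 isotope envelope
against database glycopeptides within a ppm window.  Stage 3 scores CID and
HCD fragment matches for surviving candidates and their decoys, combines them
into the Y-score, and filters at a decoy-estimated FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem import NEUTRON_SPACING, Glycopeptide, neutral_mass_from_mz
from .config import RunConfig
from .db import GlycopeptideDb, GlycopeptideRecord
from .scoring import (
    DEFAULT_OXONIUM_TABLE,
    estimate_fdr,
    fit_mscore_threshold,
    generate_fragments,
    m_score,
    make_decoy,
    match_score,
    s_score,
    y_score,
)
from .spectra import MsRun, extract_envelope

logger = logging.getLogger(__name__)

__all__ = ["GlycoPSM", "identify", "write_psm_report", "read_psm_report"]


@dataclass
class GlycoPSM:
    """One candidate <-> spectrum match with all cascade scores."""

    hcd_scan: str
    cid_scan: str | None
    glycopeptide: Glycopeptide
    charge: int
    rt: float
    m_score: float
    s_score: float
    cid_match: float | None
    hcd_match: float | None
    y_score: float
    is_decoy: bool = False
    q_value: float = 1.0
    flags: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str, int]:
        return self.glycopeptide.key


@dataclass
class StageCounts:
    """Per-stage retention bookkeeping (the run report's column structure)."""

    total_hcd: int = 0
    m_selected: int = 0
    m_threshold: float = 0.0
    s_selected: int = 0
    y_identified: int = 0
    y_threshold: float = 0.0
    unique_glycopeptides: int = 0
    unique_proteins: int = 0


def _candidate_records(db: GlycopeptideDb, precursor_mz: float, charge: int,
                       cfg: RunConfig) -> list[GlycopeptideRecord]:
    """DB records within the precursor ppm window, with +-k isotope-offset
    recovery for mispicked monoisotopic peaks."""
    out: list[GlycopeptideRecord] = []
    seen: set[int] = set()
    neutral = neutral_mass_from_mz(precursor_mz, charge)
    for k in range(-cfg.isotope_offset_recovery,
                   cfg.isotope_offset_recovery + 1):
        for rec in db.lookup(neutral - k * NEUTRON_SPACING, cfg.precursor_ppm):
            if id(rec) not in seen:
                seen.add(id(rec))
                out.append(rec)
    return out


def identify(run: MsRun, db: GlycopeptideDb, cfg: RunConfig | None = None,
             oxonium_table=DEFAULT_OXONIUM_TABLE,
             ) -> tuple[list[GlycoPSM], StageCounts]:
    """Run the full cascade on one LC-MS/MS run.

    Returns accepted PSMs (sorted by q-value, then Y-score descending) and
    the per-stage retention counts.  A run without MS1 scans skips the
    S-score stage (flagged on every PSM); spectra without a linked CID scan
    are scored from HCD alone.
    """
    cfg = cfg or RunConfig()
    if len(db) == 0:
        raise ValueError("empty glycopeptide database")
    counts = StageCounts()
    hcd_spectra = run.hcd_spectra()
    counts.total_hcd = len(hcd_spectra)
    if not hcd_spectra:
        return [], counts

    # --- stage 1: M-score triage ------------------------------------------
    m_scores = np.array(
        [m_score(s, oxonium_table, cfg.oxonium_ppm) for s in hcd_spectra]
    )
    if len(m_scores) >= 100:
        m_thresh = fit_mscore_threshold(m_scores, floor=cfg.m_score_floor)
    else:
        m_thresh = cfg.m_score_floor
    counts.m_threshold = m_thresh
    stage1 = [(s, m) for s, m in zip(hcd_spectra, m_scores) if m >= m_thresh]
    counts.m_selected = len(stage1)
    logger.info("stage 1: %d / %d HCD spectra with M >= %.2f",
                len(stage1), len(hcd_spectra), m_thresh)

    no_ms1 = len(run.ms1) == 0
    if no_ms1:
        logger.warning("run has no MS1 scans: S-score stage skipped; "
                       "identifications rely on fragment evidence only")

    # --- stage 2: S-score precursor matching ------------------------------
    stage2: list[tuple] = []  # (spectrum, m, record, charge, s)
    for spectrum, m in stage1:
        charges = ((spectrum.precursor_charge,)
                   if spectrum.precursor_charge else cfg.charges)
        for charge in charges:
            for rec in _candidate_records(db, spectrum.precursor_mz,
                                          charge, cfg):
                if no_ms1:
                    stage2.append((spectrum, m, rec, charge, float("nan")))
                    continue
                theo = rec.pattern_for_charge(charge)
                mono_mz = theo.mz[theo.monoisotopic_index]
                env, env_mz, ok = extract_envelope(
                    run, mono_mz, charge, spectrum.rt, cfg.envelope_ppm
                )
                s = s_score(env, theo, cfg.s_score_tol_ppm, env_mz) if ok else 0.0
                if s >= cfg.s_score_min:
                    stage2.append((spectrum, m, rec, charge, s))
    counts.s_selected = len({s.scan_id for s, *_ in stage2})
    logger.info("stage 2: %d spectra carry candidates with S >= %.1f",
                counts.s_selected, cfg.s_score_min)

    # --- stage 3: Y-score + decoy FDR -------------------------------------
    best_target: dict[str, GlycoPSM] = {}
    best_decoy: dict[str, GlycoPSM] = {}
    for spectrum, m, rec, charge, s in stage2:
        cid_id = run.pairs.get(spectrum.scan_id)
        cid_spec = run.spectrum(cid_id) if cid_id else None
        for gp, is_decoy in ((rec.glycopeptide, False),
                             (make_decoy(rec.glycopeptide), True)):
            hcd_frags = generate_fragments(gp, charge, "HCD", oxonium_table)
            hcd_m = match_score(spectrum, hcd_frags, cfg.fragment_ppm,
                                cfg.denoise_top)
            cid_m = None
            if cid_spec is not None:
                cid_frags = generate_fragments(gp, charge, "CID")
                cid_m = match_score(cid_spec, cid_frags, cfg.fragment_ppm,
                                    cfg.denoise_top)
            psm = GlycoPSM(
                hcd_scan=spectrum.scan_id, cid_scan=cid_id,
                glycopeptide=gp, charge=charge, rt=spectrum.rt,
                m_score=m, s_score=s, cid_match=cid_m, hcd_match=hcd_m,
                y_score=y_score(cid_m, hcd_m), is_decoy=is_decoy,
                flags=(["no_ms1"] if no_ms1 else [])
                + ([] if cid_spec is not None else ["hcd_only"]),
            )
            pool = best_decoy if is_decoy else best_target
            prev = pool.get(spectrum.scan_id)
            if prev is None or psm.y_score > prev.y_score:
                pool[spectrum.scan_id] = psm

    targets = list(best_target.values())
    decoys = list(best_decoy.values())
    if not targets:
        return [], counts
    q, threshold = estimate_fdr([p.y_score for p in targets],
                                [p.y_score for p in decoys], cfg.fdr)
    for psm, qv in zip(targets, q):
        psm.q_value = float(qv)
    accepted = [p for p in targets if p.q_value <= cfg.fdr]
    accepted.sort(key=lambda p: (p.q_value, -p.y_score))
    counts.y_identified = len(accepted)
    counts.y_threshold = threshold
    counts.unique_glycopeptides = len({p.key for p in accepted})
    counts.unique_proteins = len(
        {p.glycopeptide.backbone.protein_id for p in accepted}
    )
    logger.info(
        "stage 3: %d PSMs at FDR <= %.2g (Y >= %.1f); %d unique glycopeptides,"
        " %d proteins", counts.y_identified, cfg.fdr, threshold,
        counts.unique_glycopeptides, counts.unique_proteins,
    )
    return accepted, counts


PSM_COLUMNS = ("hcd_scan", "cid_scan", "protein", "peptide", "glycosite",
               "glycan", "charge", "rt", "m_score", "s_score", "cid_match",
               "hcd_match", "y_score", "q_value", "decoy", "flags")


def write_psm_report(psms: list[GlycoPSM], path, cfg: RunConfig | None = None
                     ) -> None:
    """Tab-separated PSM report with a '#'-prefixed JSON config header."""
    cfg = cfg or RunConfig()
    with open(path, "w") as fh:
        fh.write(cfg.header_line() + "\n")
        fh.write("\t".join(PSM_COLUMNS) + "\n")
        for p in psms:
            gp = p.glycopeptide
            fh.write("\t".join(str(x) for x in (
                p.hcd_scan, p.cid_scan or "", gp.backbone.protein_id,
                gp.backbone.sequence, gp.backbone.glycosite, gp.glycan.code,
                p.charge, f"{p.rt:.3f}", f"{p.m_score:.3f}",
                f"{p.s_score:.2f}",
                "" if p.cid_match is None else f"{p.cid_match:.2f}",
                "" if p.hcd_match is None else f"{p.hcd_match:.2f}",
                f"{p.y_score:.2f}", f"{p.q_value:.4f}",
                int(p.is_decoy), ";".join(p.flags),
            )) + "\n")


def read_psm_report(path) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
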