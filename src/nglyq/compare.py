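"""Cross-run comparison: master-list assembly, match-between-runs, charge
merging, global normalization, replicate aggregation with CV filtering,
protein roll-up and volcano statistics.

The master quantitation table is a pandas DataFrame keyed by
(peptide, glycan, glycosite) with one abundance column per run plus provenance
(direct vs match-between-runs).  Protein abundance is the sum of its
site-specific glycopeptide abundances; because a fold change on one glycoform
can be diluted by constant glycoforms of the same protein, differential
signals are tested at both levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .db import GlycopeptideRecord
from .quant import QuantResult, tiq3
from .spectra import MsRun

logger = logging.getLogger(__name__)

__all__ = [
    "MasterRow", "match_between_runs", "aggregate_replicates",
    "merge_charges", "normalize_global", "rollup_and_volcano",
    "build_master_table", "compare_groups",
]


@dataclass
class MasterRow:
    """Reference entry of the compiled cross-run glycopeptide list."""

    record: GlycopeptideRecord
    charge: int
    rt_ref: float


def match_between_runs(run: MsRun, master_row: MasterRow,
                       cfg: RunConfig | None = None) -> QuantResult | None:
    """Transfer a quantitation into a run where the species was not
    identified.

    Scans within the retention-time window of the reference are searched for
    an envelope matching the reference isotope pattern; the species is
    quantified by 3TIQ (method "MBR-3TIQ") only when a qualifying scan
    (S >= gate) exists, otherwise None.
    """
    cfg = cfg or RunConfig()
    mbr_cfg = cfg.replace(tiq_rt_window_min=cfg.mbr_rt_window_min)
    result = tiq3(run, master_row.record, master_row.charge,
                  master_row.rt_ref, mbr_cfg, method="MBR-3TIQ")
    if result.abundance <= 0 or "no_qualifying_scan" in result.flags:
        return None
    return result


def aggregate_replicates(abundances, min_obs: int = 2,
                         cv_cutoff: float = 0.30
                         ) -> tuple[float, float] | None:
    """Mean abundance across replicates, or None when excluded.

    Requires >= ``min_obs`` observations (missing values are None/NaN); the
    species is excluded when the sample CV (sd/mean, ddof=1) is >= the cutoff.
    Returns (mean, cv) when kept.
    """
    vals = np.array([a for a in abundances
                     if a is not None and not math.isnan(a) and a > 0])
    if len(vals) < min_obs:
        return None
    mean = float(vals.mean())
    cv = float(vals.std(ddof=1) / mean) if mean > 0 else float("inf")
    if cv >= cv_cutoff:
        logger.debug("excluded by CV %.1f%% >= %.0f%%", cv * 100,
                     cv_cutoff * 100)
        return None
    return mean, cv


def merge_charges(table: pd.DataFrame, run_columns: list[str]) -> pd.DataFrame:
    """Combine rows of the same (peptide, glycan, glycosite) observed at
    different charges: abundances summed per run (absent = 0), contributing
    charges recorded."""
    def _agg(group: pd.DataFrame) -> pd.Series:
        out = {col: group[col].fillna(0.0).sum() for col in run_columns}
        out["charges"] = ",".join(str(c) for c in sorted(group["charge"]))
        for col in group.columns:
            if col not in out and col not in ("charge",):
                out[col] = group[col].iloc[0]
        return pd.Series(out)

    merged = (table.groupby(["peptide", "glycan", "glycosite"], sort=True)
              .apply(_agg, include_groups=False).reset_index())
    return merged


def normalize_global(table: pd.DataFrame, run_columns: list[str]
                     ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Scale each run so its total abundance equals the across-run median
    total; all-zero runs are excluded with a warning."""
    totals = {c: float(table[c].fillna(0.0).sum()) for c in run_columns}
    usable = [c for c, t in totals.items() if t > 0]
    if len(usable) < len(run_columns):
        logger.warning("runs with zero total abundance excluded: %s",
                       sorted(set(run_columns) - set(usable)))
    if not usable:
        return table, {}
    median_total = float(np.median([totals[c] for c in usable]))
    out = table.copy()
    factors = {}
    for c in usable:
        factors[c] = median_total / totals[c]
        out[c] = out[c] * factors[c]
    logger.info("normalization factors: %s",
                {c: round(f, 4) for c, f in factors.items()})
    return out, factors


def _welch_log2(a: np.ndarray, b: np.ndarray) -> float:
    """Welch's t-test p-value on log2 abundances."""
    la, lb = np.log2(a), np.log2(b)
    if la.std(ddof=1) == 0 and lb.std(ddof=1) == 0:
        return 1.0 if np.isclose(la.mean(), lb.mean()) else 0.0
    return float(stats.ttest_ind(lb, la, equal_var=False).pvalue)


def rollup_and_volcano(table: pd.DataFrame, group_a: list[str],
                       group_b: list[str], fc_log2: float = 1.0
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Glycopeptide- and protein-level fold changes with p-values.

    Fold change is mean(B)/mean(A) per species (direction convention:
    case/control); the p-value is Welch's t-test on log2 abundances of the
    replicate runs.  Rows with |log2 FC| >= ``fc_log2`` are flagged.  Protein
    abundance per run is the sum of that protein's glycopeptide abundances.
    Requires >= 2 replicate runs per group; zero denominators yield infinite
    fold change, flagged.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 replicate runs")

    def _volcano(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        rows = []
        for _, row in df.iterrows():
            a = row[group_a].to_numpy(dtype=float)
            b = row[group_b].to_numpy(dtype=float)
            a = np.where(np.isnan(a), 0.0, a)
            b = np.where(np.isnan(b), 0.0, b)
            mean_a, mean_b = a.mean(), b.mean()
            if mean_a > 0 and mean_b > 0:
                log2fc = math.log2(mean_b / mean_a)
                p = _welch_log2(np.clip(a, 1e-12, None),
                                np.clip(b, 1e-12, None))
                infinite = False
            else:
                log2fc = math.inf if mean_b > mean_a else -math.inf
                p = float("nan")
                infinite = True
            rows.append({**{k: row[k] for k in keys},
                         "mean_a": mean_a, "mean_b": mean_b,
                         "log2_fc": log2fc, "p_value": p,
                         "flagged": abs(log2fc) >= fc_log2,
                         "infinite_fc": infinite})
        return pd.DataFrame(rows)

    pep_level = _volcano(table, ["peptide", "glycan", "glycosite", "protein"])

    prot = (table.groupby("protein")[group_a + group_b].sum(min_count=1)
            .fillna(0.0).reset_index())
    prot_level = _volcano(prot, ["protein"])
    return pep_level, prot_level


def build_master_table(
    runs: dict[str, MsRun],
    identifications: dict[str, list],
    records: dict[tuple[str, str, int], GlycopeptideRecord],
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Quantify every identified glycopeptide in every run.

    ``identifications`` maps run name -> accepted PSMs.  Species identified in
    a run are quantified directly (3TIQ at the PSM's retention time); species
    on the master list but missing from a run are recovered by
    match-between-runs where the envelope and retention-time gates allow.
    Direct quantitation always takes precedence over MBR.  One row per
    (peptide, glycan, glycosite, charge); columns per run hold abundances,
    method columns record provenance.
    """
    cfg = cfg or RunConfig()
    # master list: (key, charge) -> reference rt (first seen), record
    master: dict[tuple, MasterRow] = {}
    direct: dict[tuple, dict[str, float]] = {}
    for run_name, psms in identifications.items():
        for psm in psms:
            mkey = (psm.key, psm.charge)
            if mkey not in master:
                master[mkey] = MasterRow(records[psm.key], psm.charge, psm.rt)

    rows = []
    run_names = list(runs)
    for (key, charge), mrow in sorted(master.items(),
                                      key=lambda kv: (kv[0][0], kv[0][1])):
        row: dict = {
            "peptide": key[0], "glycan": key[1], "glycosite": key[2],
            "protein": mrow.record.glycopeptide.backbone.protein_id,
            "charge": charge,
        }
        identified_in = {
            rn: next((p for p in identifications.get(rn, [])
                      if p.key == key and p.charge == charge), None)
            for rn in run_names
        }
        for rn in run_names:
            psm = identified_in[rn]
            if psm is not None:
                res = tiq3(runs[rn], mrow.record, charge, psm.rt, cfg)
                row[rn] = res.abundance if res.abundance > 0 else np.nan
                row[f"{rn}__method"] = res.method
            else:
                res = match_between_runs(runs[rn], mrow, cfg)
                if res is not None:
                    row[rn] = res.abundance
                    row[f"{rn}__method"] = "MBR-3TIQ"
                else:
                    row[rn] = np.nan
                    row[f"{rn}__method"] = "absent"
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(master: pd.DataFrame, group_a: list[str],
                   group_b: list[str], cfg: RunConfig | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full comparison: charge merge, global normalization, CV-gated replicate
    means per group, volcano at both glycopeptide and protein level.

    Returns (processed per-replicate table, glycopeptide-level volcano,
    protein-level volcano).  Species whose replicate means fail the CV gate or
    the >= 2-observation rule in either group are dropped before testing.
    """
    cfg = cfg or RunConfig()
    run_cols = list(group_a) + list(group_b)
    merged = merge_charges(master, run_cols)
    normalized, _ = normalize_global(merged, run_cols)

    keep = []
    for _, row in normalized.iterrows():
        ok = True
        for cols in (group_a, group_b):
            agg = aggregate_replicates([row[c] for c in cols],
                                       cv_cutoff=cfg.cv_cutoff)
            if agg is None:
                ok = False
        keep.append(ok)
    filtered = normalized[np.array(keep, dtype=bool)].reset_index(drop=True)
    logger.info("replicate aggregation kept %d / %d species",
                len(filtered), len(normalized))
    pep_level, prot_level = rollup_and_volcano(
        filtered, list(group_a), list(group_b), cfg.fold_change_log2
    )
    return filtered, pep_level, prot_level
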