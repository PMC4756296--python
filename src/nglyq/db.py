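"""Glycopeptide database construction: in-silico tryptic digestion, sequon
detection, cross product with a glycan library, masses and isotope patterns.

A database row is one (peptide backbone, glycosite, glycan) combination with
its neutral mass, elemental formula and theoretical isotope pattern; the table
is indexed by neutral mass for ppm-window lookup.  Records are unique by
(peptide sequence, glycosite, glycan): a peptide with two sequons yields one
record per site, each carrying the whole glycan (multiply-glycosylated
peptides are not enumerated).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyteomics import fasta as _fasta

from .chem import (
    GlycanComposition,
    Glycopeptide,
    PeptideBackbone,
    parse_glycan_code,
)
from .isotopes import IsotopePattern, predict_pattern

logger = logging.getLogger(__name__)

__all__ = ["TrypticPeptide", "GlycopeptideRecord", "GlycopeptideDb",
           "digest", "find_sequons", "build_db"]

DEFAULT_CHARGES = (2, 3, 4)


@dataclass(frozen=True)
class TrypticPeptide:
    sequence: str
    start: int  # 1-based position in the protein
    missed_cleavages: int


def digest(protein_sequence: str, max_missed: int = 2) -> list[TrypticPeptide]:
    """Tryptic peptides (cleave after K/R, not before P) with 0..max_missed
    internal missed cleavages and 1-based protein coordinates."""
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    if max_missed > 3:
        raise ValueError("max_missed must be <= 3")
    seq = protein_sequence.strip().upper()
    # cut points: index i means a cut between seq[i-1] and seq[i]
    cuts = [0]
    for i in range(len(seq) - 1):
        if seq[i] in "KR" and seq[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(seq))
    peptides = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(cuts))):
            peptides.append(
                TrypticPeptide(seq[cuts[a]:cuts[b]], cuts[a] + 1, b - a - 1)
            )
    return peptides


def find_sequons(peptide: str) -> list[int]:
    """1-based positions of Asn in N-X(S/T) sequons (X != P) within a peptide."""
    out = []
    for i in range(len(peptide) - 2):
        if peptide[i] == "N" and peptide[i + 1] != "P" and peptide[i + 2] in "ST":
            out.append(i + 1)
    return out


@dataclass(frozen=True)
class GlycopeptideRecord:
    """One database row: a glycopeptide plus its theoretical isotope pattern."""

    glycopeptide: Glycopeptide
    pattern: IsotopePattern = field(compare=False)  # neutral (charge-agnostic bins)
    peptide_start: int = 0

    @property
    def neutral_mass(self) -> float:
        return self.glycopeptide.neutral_mass

    def pattern_for_charge(self, charge: int) -> IsotopePattern:
        """The isotope pattern re-expressed as m/z at the given charge."""
        from .chem import PROTON_MASS

        neutral = self.pattern.mz  # stored at charge 1
        masses = neutral - PROTON_MASS  # back to neutral bin centroids
        return IsotopePattern(
            mz=(masses + charge * PROTON_MASS) / charge,
            rel_intensity=self.pattern.rel_intensity,
            charge=charge,
            monoisotopic_index=self.pattern.monoisotopic_index,
        )


class GlycopeptideDb:
    """Searchable glycopeptide table, mass-indexed.

    ``records`` is sorted by neutral mass; :meth:`lookup` returns all records
    within a ppm window of a query mass by binary search.
    """

    def __init__(self, records: list[GlycopeptideRecord],
                 meta: dict | None = None):
        self.records = sorted(records, key=lambda r: r.neutral_mass)
        self._masses = np.array([r.neutral_mass for r in self.records])
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, neutral_mass: float, ppm: float = 10.0
               ) -> list[GlycopeptideRecord]:
        tol = neutral_mass * ppm * 1e-6
        lo = int(np.searchsorted(self._masses, neutral_mass - tol, side="left"))
        hi = int(np.searchsorted(self._masses, neutral_mass + tol, side="right"))
        return self.records[lo:hi]

    # --- serialization: '#'-prefixed JSON header + TSV body ----------------

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(self.meta, sort_keys=True) + "\n")
            fh.write("protein_id\tpeptide\tglycosite\tmissed\tglycan\t"
                     "neutral_mass\tformula\tpattern\n")
            for r in self.records:
                gp = r.glycopeptide
                fh.write(
                    f"{gp.backbone.protein_id}\t{gp.backbone.sequence}\t"
                    f"{gp.backbone.glycosite}\t{gp.backbone.missed_cleavages}\t"
                    f"{gp.glycan.code}\t{gp.neutral_mass:.5f}\t{gp.formula}\t"
                    f"{json.dumps(r.pattern.to_list())}\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "GlycopeptideDb":
        records = []
        meta: dict = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                meta = json.loads(first[1:])
                fh.readline()  # column header
            for line in fh:
                (pid, pep, site, missed, code, _mass, _formula,
                 pattern_json) = line.rstrip("\n").split("\t")
                backbone = PeptideBackbone(pep, int(site), pid, int(missed))
                gp = Glycopeptide(backbone, parse_glycan_code(code))
                peaks = json.loads(pattern_json)
                pattern = IsotopePattern(
                    mz=[p[0] for p in peaks],
                    rel_intensity=[p[1] for p in peaks],
                    charge=1,
                )
                records.append(GlycopeptideRecord(gp, pattern))
        return cls(records, meta)


def _read_fasta(path: str | Path) -> list[tuple[str, str]]:
    out = []
    n_bad = 0
    for header, seq in _fasta.read(str(path)):
        pid = header.split()[0]
        try:
            seq = "".join(seq.split()).upper()
            if not seq:
                raise ValueError("empty sequence")
            out.append((pid, seq))
        except ValueError as exc:  # report and continue
            n_bad += 1
            logger.warning("skipping FASTA record %s: %s", pid, exc)
    if n_bad:
        logger.warning("%d FASTA records skipped", n_bad)
    return out


def build_db(
    proteome: str | Path | list[tuple[str, str]],
    glycans: list[GlycanComposition],
    charges: tuple[int, ...] = DEFAULT_CHARGES,
    max_missed: int = 2,
    prune: float = 1e-4,
) -> GlycopeptideDb:
    """Build the glycopeptide database from a proteome and a glycan library.

    ``proteome`` is a FASTA path or a list of (protein_id, sequence) pairs.
    One record is emitted per unique (peptide sequence, glycosite) pair per
    glycan; the record count is therefore always divisible by the library
    size.  Each record stores one neutral isotope pattern, re-chargeable on
    demand for any precursor charge.
    """
    if not glycans:
        raise ValueError("glycan library is empty")
    if isinstance(proteome, (str, Path)):
        proteome = _read_fasta(proteome)

    backbones: dict[tuple[str, int], PeptideBackbone] = {}
    starts: dict[tuple[str, int], int] = {}
    for pid, seq in proteome:
        skipped = 0
        for pep in digest(seq, max_missed):
            for site in find_sequons(pep.sequence):
                key = (pep.sequence, site)
                if key in backbones:
                    continue
                try:
                    backbones[key] = PeptideBackbone(
                        pep.sequence, site, pid, pep.missed_cleavages
                    )
                    starts[key] = pep.start
                except ValueError:
                    skipped += 1
        if skipped:
            logger.warning("%s: %d peptides with non-standard residues skipped",
                           pid, skipped)

    if not backbones:
        logger.warning("no sequon-bearing peptides found; database is empty")

    records = []
    for key, backbone in backbones.items():
        for glycan in glycans:
            gp = Glycopeptide(backbone, glycan)
            pattern = predict_pattern(gp.formula, charge=1, prune=prune)
            records.append(GlycopeptideRecord(gp, pattern, starts[key]))

    meta = {
        "n_backbones": len(backbones),
        "n_glycans": len(glycans),
        "charges": list(charges),
        "max_missed": max_missed,
        "prune": prune,
    }
    logger.info("built DB: %d backbones x %d glycans = %d records",
                len(backbones), len(glycans), len(records))
    return GlycopeptideDb(records, meta)
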