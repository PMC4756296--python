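"""Seedable simulator of glycopeptide LC-MS/MS runs with ground truth.

Emulates the data regime the pipeline targets: high-resolution MS1 scans
carrying each planted species' theoretical isotope envelope under a Gaussian
elution profile with Poisson count noise and ppm mass jitter; paired HCD
(oxonium + singly charged Y + peptide b/y) and CID (multi-charge Y + B)
MS2 spectra near each elution apex; and noise-only MS2 spectra that exercise
the triage and FDR stages.  Identical seeds give identical runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import GlycanComposition, Glycopeptide, PeptideBackbone
from .db import GlycopeptideDb, GlycopeptideRecord
from .isotopes import predict_pattern
from .scoring import generate_fragments
from .spectra import Ms1Scan, Ms2Spectrum, MsRun, pair_scans

__all__ = ["SimSpecies", "SimConfig", "simulate_run", "simulate_two_group",
           "pick_species", "interference_pair"]


@dataclass(frozen=True)
class SimSpecies:
    record: GlycopeptideRecord
    charge: int
    abundance: float  # apex height of the base isotope channel (counts)
    rt: float  # elution apex, minutes


@dataclass
class SimConfig:
    species: list[SimSpecies]
    run_length: float = 10.0  # minutes
    ms1_interval: float = 0.05  # minutes between MS1 scans
    elution_sigma: float = 0.1  # minutes
    ppm_jitter: float = 2.0  # 1-sigma mass error, MS1 and MS2
    ms1_noise_peaks: int = 20  # random peaks per MS1 scan
    ms1_noise_mean: float = 500.0
    ms2_noise_peaks: int = 100  # random peaks per MS2 spectrum
    ms2_noise_mean: float = 2000.0
    n_noise_ms2: int = 0  # additional noise-only HCD spectra
    # relative fragmentation efficiency per ion class
    efficiency: dict = field(default_factory=lambda: {
        "oxonium": 1.0, "Y_hcd": 0.5, "by": 0.35, "Y_cid": 1.0, "B": 0.7,
    })
    ms2_base_intensity: float = 2.0e5
    poisson: bool = True  # False: noiseless expected counts in MS1
    seed: int = 0

    def validate(self) -> None:
        if not self.species:
            raise ValueError("no species configured")
        if self.ms1_interval <= 0 or self.run_length <= 0:
            raise ValueError("run_length and ms1_interval must be positive")
        for sp in self.species:
            if not (0 <= sp.rt <= self.run_length):
                raise ValueError(f"species rt {sp.rt} outside the run")
            if sp.abundance <= 0:
                raise ValueError("species abundance must be positive")


def _jitter(rng: np.random.Generator, mz: np.ndarray, ppm: float) -> np.ndarray:
    return mz * (1.0 + rng.normal(0.0, ppm * 1e-6, size=np.shape(mz)))


def _noise_peaks(rng: np.random.Generator, n: int, mean: float,
                 lo: float = 100.0, hi: float = 2000.0):
    mz = rng.uniform(lo, hi, n)
    intensity = rng.exponential(mean, n)
    return mz, intensity


def _ms2_for_species(sp: SimSpecies, cfg: SimConfig, rng: np.random.Generator,
                     rt: float, idx: int) -> tuple[Ms2Spectrum, Ms2Spectrum]:
    gp = sp.record.glycopeptide
    base = cfg.ms2_base_intensity
    eff = cfg.efficiency

    def build(mode: str) -> Ms2Spectrum:
        frags = generate_fragments(gp, sp.charge, mode)
        mzs, intens = [], []
        for mz, label in zip(frags.mz, frags.labels):
            if label.startswith("oxonium"):
                scale = eff["oxonium"]
            elif label.startswith("Y_"):
                scale = eff["Y_hcd"] if mode == "HCD" else eff["Y_cid"]
            elif label.startswith("B_"):
                scale = eff["B"]
            else:
                scale = eff["by"]
            # per-fragment lognormal variation keeps spectra non-uniform
            inten = base * scale * rng.lognormal(-0.5, 0.5)
            mzs.append(mz)
            intens.append(inten)
        nmz, nint = _noise_peaks(rng, cfg.ms2_noise_peaks, cfg.ms2_noise_mean)
        all_mz = _jitter(rng, np.array(mzs), cfg.ppm_jitter)
        all_mz = np.concatenate([all_mz, nmz])
        all_int = np.concatenate([np.array(intens), nint])
        theo = sp.record.pattern_for_charge(sp.charge)
        return Ms2Spectrum(
            all_mz, all_int,
            precursor_mz=float(theo.mz[theo.monoisotopic_index]),
            precursor_charge=sp.charge, rt=rt, mode=mode,
            scan_id=f"{mode}_{idx}_{gp.backbone.sequence}_{gp.glycan.code}",
        )

    return build("HCD"), build("CID")


def simulate_run(cfg: SimConfig) -> tuple[MsRun, pd.DataFrame]:
    """Simulate one LC-MS/MS run; returns the run and its ground truth.

    The truth table lists every planted species with its peptide, glycan,
    site, charge, apex abundance and retention time.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rts = np.arange(0.0, cfg.run_length + 1e-9, cfg.ms1_interval)

    ms1: list[Ms1Scan] = []
    for rt in rts:
        mzs, intens = [], []
        for sp in cfg.species:
            z = (rt - sp.rt) / cfg.elution_sigma
            if abs(z) > 5:
                continue
            profile = float(np.exp(-0.5 * z * z))
            theo = sp.record.pattern_for_charge(sp.charge)
            expected = sp.abundance * profile * theo.rel_intensity
            counts = (rng.poisson(expected).astype(float)
                      if cfg.poisson else expected.copy())
            keep = counts > 0
            if keep.any():
                mzs.append(_jitter(rng, theo.mz[keep], cfg.ppm_jitter))
                intens.append(counts[keep])
        nmz, nint = _noise_peaks(rng, cfg.ms1_noise_peaks, cfg.ms1_noise_mean,
                                 400.0, 2000.0)
        mzs.append(nmz)
        intens.append(nint)
        ms1.append(Ms1Scan(float(rt), np.concatenate(mzs),
                           np.concatenate(intens)))

    ms2: list[Ms2Spectrum] = []
    for i, sp in enumerate(cfg.species):
        # MS2 triggered on the MS1 cycle nearest the apex
        rt = float(rts[np.argmin(np.abs(rts - sp.rt))]) + cfg.ms1_interval / 2
        hcd, cid = _ms2_for_species(sp, cfg, rng, rt, i)
        ms2.extend([hcd, cid])
    for j in range(cfg.n_noise_ms2):
        nmz, nint = _noise_peaks(rng, cfg.ms2_noise_peaks, cfg.ms2_noise_mean)
        ms2.append(Ms2Spectrum(
            nmz, nint, precursor_mz=float(rng.uniform(800, 1600)),
            precursor_charge=int(rng.integers(2, 5)),
            rt=float(rng.uniform(0, cfg.run_length)),
            mode="HCD", scan_id=f"noise_{j}",
        ))

    run = MsRun(ms1=ms1, ms2=ms2, name=f"sim_seed{cfg.seed}")
    pair_scans(run)
    truth = pd.DataFrame([
        {
            "peptide": sp.record.glycopeptide.backbone.sequence,
            "glycan": sp.record.glycopeptide.glycan.code,
            "glycosite": sp.record.glycopeptide.backbone.glycosite,
            "protein": sp.record.glycopeptide.backbone.protein_id,
            "charge": sp.charge,
            "abundance": sp.abundance,
            "rt": sp.rt,
        }
        for sp in cfg.species
    ])
    return run, truth


def simulate_two_group(
    cfg: SimConfig,
    fold_changes: dict[tuple[str, str, int], float],
    replicates: int = 3,
    replicate_sigma: float = 0.15,
) -> tuple[dict[str, MsRun], dict[str, pd.DataFrame], list[str], list[str]]:
    """Triplicate two-group design: group B abundances = group A x fold
    change, with lognormal replicate noise of the given sigma (natural log).

    ``fold_changes`` maps (peptide, glycan, glycosite) to the B/A ratio;
    unlisted species have fold change 1.  Returns (runs by name, truths by
    name, group A names, group B names).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    runs: dict[str, MsRun] = {}
    truths: dict[str, pd.DataFrame] = {}
    group_a, group_b = [], []
    for group, names in (("A", group_a), ("B", group_b)):
        for rep in range(replicates):
            species = []
            for sp in cfg.species:
                gp = sp.record.glycopeptide
                key = (gp.backbone.sequence, gp.glycan.code,
                       gp.backbone.glycosite)
                fold = fold_changes.get(key, 1.0) if group == "B" else 1.0
                noise = (rng.lognormal(0.0, replicate_sigma)
                         if replicate_sigma > 0 else 1.0)
                species.append(replace(sp, abundance=sp.abundance * fold * noise))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            name = f"{group}{rep + 1}"
            run, truth = simulate_run(replace(cfg, species=species,
                                              seed=sub_seed))
            run.name = name
            runs[name] = run
            truths[name] = truth
            names.append(name)
    return runs, truths, group_a, group_b


def pick_species(db: GlycopeptideDb, n: int, seed: int = 0,
                 run_length: float = 10.0,
                 abundance_range: tuple[float, float] = (2e5, 2e6),
                 charges: tuple[int, ...] = (2, 3, 4),
                 single_site: bool = True,
                 mass_range: tuple[float, float] | None = None
                 ) -> list[SimSpecies]:
    """Draw n distinct database records as planted species with log-uniform
    abundances and retention times spread across the run.

    By default only single-sequon backbones are planted: with deglycosylated
    b/y ions, glycosites of a multi-sequon peptide are indistinguishable, so
    multi-sequon records belong in the search space but not in the ground
    truth.  ``mass_range`` restricts planting to a neutral-mass window
    (species of one size regime share envelope shapes, as in a standard-
    glycoprotein experiment).
    """
    from .db import find_sequons

    rng = np.random.default_rng(seed)
    pool = np.arange(len(db.records))
    if single_site:
        pool = np.array([
            i for i in pool
            if len(find_sequons(db.records[i].glycopeptide.backbone.sequence)) == 1
        ])
    if mass_range is not None:
        pool = np.array([
            i for i in pool
            if mass_range[0] <= db.records[i].neutral_mass <= mass_range[1]
        ])
    idx = pool[rng.choice(len(pool), size=min(n, len(pool)), replace=False)]
    lo, hi = np.log(abundance_range[0]), np.log(abundance_range[1])
    species = []
    rts = np.linspace(0.08, 0.92, len(idx)) * run_length
    for i, (rec_i, rt) in enumerate(zip(idx, rts)):
        rec = db.records[int(rec_i)]
        species.append(SimSpecies(
            record=rec,
            charge=int(rng.choice(charges)),
            abundance=float(np.exp(rng.uniform(lo, hi))),
            rt=float(rt),
        ))
    return species


def interference_pair(sequence: str = "CANLVPVPITNATLDQITGK",
                      glycosite: int = 11, protein_id: str = "AGP1_SYNTH",
                      rt: float = 5.0, abundance: float = 1.0e6,
                      charge: int = 4,
                      rt_offset: float = 0.3) -> list[SimSpecies]:
    """The co-elution interference scenario: two glycoforms of one backbone
    whose monoisotopic peak (Hex6HexNAc5Fuc2NeuAc2) sits 3-4 ppm from the
    other's (Hex6HexNAc5NeuAc3) second isotope at z = 4.

    The glycoforms elute close together (``rt_offset`` apart, default three
    elution sigmas) so their chromatographic tails overlap: the overlap scans
    carry merged envelopes that the pattern gate must reject, while a plain
    XIC integrates the contamination.
    """
    backbone = PeptideBackbone(sequence, glycosite, protein_id)
    species = []
    for code, dr in (("6503", 0.0), ("6522", rt_offset)):
        gp = Glycopeptide(backbone, GlycanComposition(*(int(c) for c in code)))
        pattern = predict_pattern(gp.formula, charge=1)
        rec = GlycopeptideRecord(gp, pattern)
        species.append(SimSpecies(rec, charge, abundance, rt + dr))
    return species
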