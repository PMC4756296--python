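"""Reading, writing and slicing LC-MS/MS runs.

Supported formats: MGF for MS2 (standard TITLE/RTINSECONDS/PEPMASS/CHARGE
keys, parsed with pyteomics), a minimal mzML reader (centroided spectra,
float peak arrays, optional zlib), and a simple MS1-TSV dialect for survey
scans: ``scan_rt <tab> mz <tab> intensity``, one peak per row, retention
times in minutes.  HCD and CID scans of the same precursor are paired by
precursor m/z and retention time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyteomics import mgf as _mgf

from .chem import NEUTRON_SPACING

logger = logging.getLogger(__name__)

__all__ = ["Peak", "Ms1Scan", "Ms2Spectrum", "MsRun",
           "read_run", "write_run", "extract_envelope", "xic"]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float


@dataclass
class Ms1Scan:
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


@dataclass
class Ms2Spectrum:
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    precursor_mz: float
    precursor_charge: int | None
    rt: float  # minutes
    mode: str  # "HCD" or "CID"
    scan_id: str

    def __post_init__(self):
        self.peaks_mz = np.asarray(self.peaks_mz, dtype=float)
        self.peaks_intensity = np.asarray(self.peaks_intensity, dtype=float)
        order = np.argsort(self.peaks_mz, kind="stable")
        self.peaks_mz = self.peaks_mz[order]
        self.peaks_intensity = self.peaks_intensity[order]

    def __len__(self) -> int:
        return len(self.peaks_mz)


@dataclass
class MsRun:
    """Ordered MS1 scans plus MS2 spectra with an HCD<->CID pairing map."""

    ms1: list[Ms1Scan] = field(default_factory=list)
    ms2: list[Ms2Spectrum] = field(default_factory=list)
    pairs: dict[str, str] = field(default_factory=dict)  # HCD scan_id -> CID
    name: str = ""

    def __post_init__(self):
        self.ms1.sort(key=lambda s: s.rt)

    @property
    def ms1_rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.ms1])

    def spectrum(self, scan_id: str) -> Ms2Spectrum:
        for s in self.ms2:
            if s.scan_id == scan_id:
                return s
        raise KeyError(scan_id)

    def hcd_spectra(self) -> list[Ms2Spectrum]:
        return [s for s in self.ms2 if s.mode == "HCD"]

    def nearest_ms1(self, rt: float, max_gap: float = 1.0) -> Ms1Scan | None:
        if not self.ms1:
            return None
        rts = self.ms1_rts
        i = int(np.argmin(np.abs(rts - rt)))
        if abs(rts[i] - rt) > max_gap:
            return None
        return self.ms1[i]


def pair_scans(run: MsRun, ppm: float = 10.0, rt_tol: float = 0.1) -> None:
    """Link each HCD scan to the closest CID scan sharing its precursor."""
    run.pairs.clear()
    cids = [s for s in run.ms2 if s.mode == "CID"]
    for hcd in run.ms2:
        if hcd.mode != "HCD":
            continue
        best, best_drt = None, rt_tol
        for cid in cids:
            if abs(cid.precursor_mz - hcd.precursor_mz) \
                    > hcd.precursor_mz * ppm * 1e-6:
                continue
            drt = abs(cid.rt - hcd.rt)
            if drt <= best_drt:
                best, best_drt = cid, drt
        if best is not None:
            run.pairs[hcd.scan_id] = best.scan_id


def _parse_mgf(path: str | Path) -> list[Ms2Spectrum]:
    spectra = []
    n_bad = 0
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            try:
                params = entry["params"]
                title = str(params.get("title", ""))
                rt = params.get("rtinseconds")
                rt = float(rt) / 60.0 if rt is not None else 0.0
                pepmass = params["pepmass"]
                pmz = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
                charge = params.get("charge")
                charge = int(charge[0]) if charge else None
                mode = "CID" if "CID" in title.upper() else "HCD"
                spectra.append(Ms2Spectrum(
                    entry["m/z array"], entry["intensity array"],
                    pmz, charge, rt, mode, title or f"scan{len(spectra)}",
                ))
            except (KeyError, ValueError, TypeError) as exc:
                n_bad += 1
                logger.warning("skipping malformed MGF entry: %s", exc)
    if n_bad:
        logger.warning("%d malformed MGF entries skipped", n_bad)
    return spectra


def _parse_ms1_tsv(path: str | Path) -> list[Ms1Scan]:
    by_rt: dict[float, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line[0].isalpha():
                continue
            rt_s, mz_s, i_s = line.split("\t")
            by_rt.setdefault(float(rt_s), []).append((float(mz_s), float(i_s)))
    return [
        Ms1Scan(rt, np.array([p[0] for p in pk]), np.array([p[1] for p in pk]))
        for rt, pk in sorted(by_rt.items())
    ]


def _mzml_binary(array_el, ns: str) -> "np.ndarray":
    """Decode one <binaryDataArray>: 32/64-bit float, zlib or none."""
    import base64
    import zlib

    accessions = {cv.get("accession") for cv in
                  array_el.findall(f"{ns}cvParam")}
    binary = array_el.find(f"{ns}binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_mzml(path: str | Path) -> tuple[list[Ms1Scan], list[Ms2Spectrum]]:
    """Minimal mzML reader: centroided spectra, float peak arrays, optional
    zlib compression — the subset converted instrument files use."""
    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    ms1, ms2 = [], []
    tree = etree.parse(str(path))
    for sp in tree.iter(f"{ns}spectrum"):
        cv = {c.get("accession"): c.get("value")
              for c in sp.findall(f"{ns}cvParam")}
        level = int(cv.get("MS:1000511", "1"))
        rt = 0.0
        scan = sp.find(f"{ns}scanList/{ns}scan")
        if scan is not None:
            for c in scan.findall(f"{ns}cvParam"):
                if c.get("accession") == "MS:1000016":
                    rt = float(c.get("value"))
                    if c.get("unitName", "minute") == "second":
                        rt /= 60.0
        arrays = {}
        for arr in sp.findall(f"{ns}binaryDataArrayList/{ns}binaryDataArray"):
            acc = {c.get("accession") for c in arr.findall(f"{ns}cvParam")}
            if "MS:1000514" in acc:
                arrays["mz"] = _mzml_binary(arr, ns)
            elif "MS:1000515" in acc:
                arrays["intensity"] = _mzml_binary(arr, ns)
        if "mz" not in arrays or "intensity" not in arrays:
            logger.warning("spectrum %s lacks peak arrays; skipped",
                           sp.get("id"))
            continue
        if level == 1:
            ms1.append(Ms1Scan(rt, arrays["mz"], arrays["intensity"]))
            continue
        pmz, charge = 0.0, None
        ion = sp.find(f"{ns}precursorList/{ns}precursor/"
                      f"{ns}selectedIonList/{ns}selectedIon")
        if ion is not None:
            for c in ion.findall(f"{ns}cvParam"):
                if c.get("accession") == "MS:1000744":
                    pmz = float(c.get("value"))
                elif c.get("accession") == "MS:1000041":
                    charge = int(c.get("value"))
        ident = sp.get("id", "")
        filt = (cv.get("MS:1000512") or "") + ident
        mode = "CID" if "CID" in filt.upper() else "HCD"
        ms2.append(Ms2Spectrum(arrays["mz"], arrays["intensity"], pmz,
                               charge, rt, mode, ident))
    return ms1, ms2


def read_run(path: str | Path, ms1_path: str | Path | None = None,
             fmt: str | None = None, pair_ppm: float = 10.0,
             pair_rt_tol: float = 0.1) -> MsRun:
    """Load a run from mzML, or from MGF (MS2) plus optional MS1-TSV.

    HCD/CID pairs are linked when precursor m/z agrees within ``pair_ppm``
    and retention time within ``pair_rt_tol`` minutes.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mzml" if path.suffix.lower() == ".mzml" else "mgf"
    if fmt == "mzml":
        ms1, ms2 = _parse_mzml(path)
    elif fmt == "mgf":
        ms2 = _parse_mgf(path)
        ms1 = _parse_ms1_tsv(ms1_path) if ms1_path else []
    else:
        raise ValueError(f"unknown format {fmt!r}")
    run = MsRun(ms1=ms1, ms2=ms2, name=path.stem)
    pair_scans(run, pair_ppm, pair_rt_tol)
    if not run.pairs and any(s.mode == "CID" for s in run.ms2):
        logger.info("no HCD/CID pairs linked")
    return run


def write_run(run: MsRun, mgf_path: str | Path,
              ms1_path: str | Path | None = None) -> None:
    """Write MS2 spectra as MGF and MS1 scans as the TSV dialect."""
    entries = []
    for s in run.ms2:
        params = {
            "title": s.scan_id,
            "pepmass": s.precursor_mz,
            "rtinseconds": s.rt * 60.0,
        }
        if s.precursor_charge:
            params["charge"] = s.precursor_charge
        entries.append({
            "m/z array": s.peaks_mz,
            "intensity array": s.peaks_intensity,
            "params": params,
        })
    _mgf.write(entries, str(mgf_path), file_mode="w")
    if ms1_path is not None:
        with open(ms1_path, "w") as fh:
            fh.write("rt\tmz\tintensity\n")
            for scan in run.ms1:
                for mz, inten in zip(scan.mz, scan.intensity):
                    fh.write(f"{scan.rt:.4f}\t{mz:.5f}\t{inten:.4f}\n")


def envelope_from_scan(scan: Ms1Scan, mz0: float, charge: int,
                       window_ppm: float = 10.0, n_iso: int = 8) -> np.ndarray:
    """Intensities at mz0 + k*1.00336/charge, k = 0..n_iso-1, from one scan.

    Peaks inside each isotope slot's ppm window are summed: species a few ppm
    apart are not resolved at the instrument resolutions this targets, so
    their intensities merge, as they would in a centroided spectrum.  A slot
    with no peak contributes zero.
    """
    out = np.zeros(n_iso)
    for k in range(n_iso):
        target = mz0 + k * NEUTRON_SPACING / charge
        tol = target * window_ppm * 1e-6
        lo = int(np.searchsorted(scan.mz, target - tol))
        hi = int(np.searchsorted(scan.mz, target + tol))
        if hi > lo:
            out[k] = scan.intensity[lo:hi].sum()
    return out


def envelope_mz_from_scan(scan: Ms1Scan, mz0: float, charge: int,
                          window_ppm: float = 10.0, n_iso: int = 8
                          ) -> np.ndarray:
    """Observed m/z per isotope slot (NaN where missing); companion of
    :func:`envelope_from_scan`.  The slot m/z is the intensity-weighted
    centroid of the peaks in the window, mirroring the summed intensities."""
    out = np.full(n_iso, np.nan)
    for k in range(n_iso):
        target = mz0 + k * NEUTRON_SPACING / charge
        tol = target * window_ppm * 1e-6
        lo = int(np.searchsorted(scan.mz, target - tol))
        hi = int(np.searchsorted(scan.mz, target + tol))
        if hi > lo:
            weights = scan.intensity[lo:hi]
            total = weights.sum()
            out[k] = (float((scan.mz[lo:hi] * weights).sum() / total)
                      if total > 0 else float(scan.mz[lo:hi].mean()))
    return out


def extract_envelope(run: MsRun, mz: float, charge: int, rt: float,
                     window_ppm: float = 10.0, n_iso: int = 8
                     ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Observed isotope envelope near ``rt``.

    Returns (intensities, observed m/z per slot, ok flag); the flag is False
    when no MS1 scan lies within 1 minute (envelope all zero).
    """
    if window_ppm > 20:
        raise ValueError("envelope window must be <= 20 ppm")
    scan = run.nearest_ms1(rt)
    if scan is None:
        return np.zeros(n_iso), np.full(n_iso, np.nan), False
    intensities = envelope_from_scan(scan, mz, charge, window_ppm, n_iso)
    mzs = envelope_mz_from_scan(scan, mz, charge, window_ppm, n_iso)
    return intensities, mzs, True


def xic(run: MsRun, mz: float, window_ppm: float = 10.0,
        rt_range: tuple[float, float] | None = None
        ) -> tuple[np.ndarray, np.ndarray, float]:
    """Extracted ion chromatogram and its trapezoidal area.

    Per MS1 scan, intensities of all peaks within the ppm window of ``mz``
    are summed; the area is the trapezoid-rule integral over retention time.
    """
    tol = mz * window_ppm * 1e-6
    rts, vals = [], []
    for scan in run.ms1:
        if rt_range is not None and not (rt_range[0] <= scan.rt <= rt_range[1]):
            continue
        lo = int(np.searchsorted(scan.mz, mz - tol))
        hi = int(np.searchsorted(scan.mz, mz + tol))
        rts.append(scan.rt)
        vals.append(float(scan.intensity[lo:hi].sum()))
    rts = np.array(rts)
    vals = np.array(vals)
    area = float(np.trapezoid(vals, rts)) if len(rts) > 1 else 0.0
    return rts, vals, area
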