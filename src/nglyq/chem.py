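"""Monoisotopic mass and elemental-formula arithmetic for glycopeptides.

All masses are computed from a single pinned table of isotope masses and
abundances (IUPAC/CODATA values to the precision instruments resolve), so
database builds are bit-reproducible.  Peptides carry fixed
carbamidomethylation on every cysteine; glycans are compositions of the four
classes Hex / HexNAc / Fuc / NeuAc, written in the field's 4-digit code
("5402" = 5 Hex, 4 HexNAc, 0 Fuc, 2 NeuAc).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ELEMENT_ISOTOPES",
    "PROTON_MASS",
    "WATER",
    "CARBAMIDOMETHYL",
    "Formula",
    "GlycanComposition",
    "PeptideBackbone",
    "Glycopeptide",
    "parse_glycan_code",
    "glycan_mass",
    "glycan_formula",
    "peptide_formula",
    "peptide_mass",
    "glycopeptide_mz",
    "neutral_mass_from_mz",
]

#: isotope table: element -> list of (exact mass, abundance), lightest first.
#: Values pinned (IUPAC 2013 / NIST); the monoisotopic mass is the first entry.
ELEMENT_ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "H": [(1.0078250319, 0.999885), (2.0141017779, 0.000115)],
    "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
    "O": [(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)],
    "S": [(31.97207069, 0.9499), (32.9714585, 0.0075), (33.96786683, 0.0425),
          (35.96708088, 0.0001)],
}

PROTON_MASS = 1.007276
#: average spacing of successive isotope peaks, Da (13C-dominated)
NEUTRON_SPACING = 1.00336


def monoisotopic_element_mass(element: str) -> float:
    try:
        return ELEMENT_ISOTOPES[element][0][0]
    except KeyError:
        raise ValueError(f"unknown element {element!r}") from None


class Formula(dict):
    """Elemental composition: mapping element symbol -> atom count.

    Addition is supported with ``+`` and is commutative/associative; counts
    never go negative.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for el, n in list(self.items()):
            if el not in ELEMENT_ISOTOPES:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n == 0:
                del self[el]  # zero counts don't affect identity

    def __add__(self, other: "Formula") -> "Formula":
        out = Formula(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return out

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self.items()})

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(monoisotopic_element_mass(el) * n for el, n in self.items())

    @property
    def n_atoms(self) -> int:
        return sum(self.values())

    def __str__(self) -> str:
        return "".join(
            f"{el}{self[el]}" for el in ("C", "H", "N", "O", "S") if self.get(el)
        )

    @classmethod
    def parse(cls, text: str) -> "Formula":
        out: dict[str, int] = {}
        for el, n in re.findall(r"([A-Z][a-z]?)(\d*)", text):
            if el:
                out[el] = out.get(el, 0) + (int(n) if n else 1)
        return cls(out)


WATER = Formula({"H": 2, "O": 1})
#: carbamidomethyl adduct on Cys (iodoacetamide alkylation), +57.02146 Da
CARBAMIDOMETHYL = Formula({"C": 2, "H": 3, "N": 1, "O": 1})

#: residue (not free amino acid) formulas for the 20 standard residues
AA_RESIDUE_FORMULAS: dict[str, Formula] = {
    "G": Formula({"C": 2, "H": 3, "N": 1, "O": 1}),
    "A": Formula({"C": 3, "H": 5, "N": 1, "O": 1}),
    "S": Formula({"C": 3, "H": 5, "N": 1, "O": 2}),
    "P": Formula({"C": 5, "H": 7, "N": 1, "O": 1}),
    "V": Formula({"C": 5, "H": 9, "N": 1, "O": 1}),
    "T": Formula({"C": 4, "H": 7, "N": 1, "O": 2}),
    "C": Formula({"C": 3, "H": 5, "N": 1, "O": 1, "S": 1}),
    "L": Formula({"C": 6, "H": 11, "N": 1, "O": 1}),
    "I": Formula({"C": 6, "H": 11, "N": 1, "O": 1}),
    "N": Formula({"C": 4, "H": 6, "N": 2, "O": 2}),
    "D": Formula({"C": 4, "H": 5, "N": 1, "O": 3}),
    "Q": Formula({"C": 5, "H": 8, "N": 2, "O": 2}),
    "K": Formula({"C": 6, "H": 12, "N": 2, "O": 1}),
    "E": Formula({"C": 5, "H": 7, "N": 1, "O": 3}),
    "M": Formula({"C": 5, "H": 9, "N": 1, "O": 1, "S": 1}),
    "H": Formula({"C": 6, "H": 7, "N": 3, "O": 1}),
    "F": Formula({"C": 9, "H": 9, "N": 1, "O": 1}),
    "R": Formula({"C": 6, "H": 12, "N": 4, "O": 1}),
    "Y": Formula({"C": 9, "H": 9, "N": 1, "O": 2}),
    "W": Formula({"C": 11, "H": 10, "N": 2, "O": 1}),
}

#: per-residue monoisotopic masses derived once from the pinned element table
AA_RESIDUE_MASSES: dict[str, float] = {
    aa: f.mass for aa, f in AA_RESIDUE_FORMULAS.items()
}

#: monosaccharide residue formulas (as incorporated, i.e. minus water)
GLYCAN_RESIDUE_FORMULAS: dict[str, Formula] = {
    "hex": Formula({"C": 6, "H": 10, "O": 5}),
    "hexnac": Formula({"C": 8, "H": 13, "N": 1, "O": 5}),
    "fuc": Formula({"C": 6, "H": 10, "O": 4}),
    "neuac": Formula({"C": 11, "H": 17, "N": 1, "O": 8}),
}

GLYCAN_RESIDUE_MASSES: dict[str, float] = {
    k: f.mass for k, f in GLYCAN_RESIDUE_FORMULAS.items()
}


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of Hex / HexNAc / Fuc / NeuAc — glycan composition, no topology."""

    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self):
        for name in ("hex", "hexnac", "fuc", "neuac"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} count")

    @property
    def code(self) -> str:
        """Canonical 4-digit code; delimited dialect when any count > 9."""
        counts = (self.hex, self.hexnac, self.fuc, self.neuac)
        if all(c <= 9 for c in counts):
            return "".join(str(c) for c in counts)
        return "-".join(str(c) for c in counts)

    @property
    def total(self) -> int:
        return self.hex + self.hexnac + self.fuc + self.neuac

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.hex, self.hexnac, self.fuc, self.neuac)

    @property
    def mass(self) -> float:
        return glycan_mass(self)

    @property
    def formula(self) -> Formula:
        return glycan_formula(self)

    def __str__(self) -> str:
        return self.code


def parse_glycan_code(code: str) -> GlycanComposition:
    """Parse a 4-digit glycan code ("5402") or its delimited dialect ("6-5-0-12").

    Counts are in Hex, HexNAc, Fuc, NeuAc order.  The delimited dialect exists
    because polylactosamine series can exceed 9 in the Hex/HexNAc slots.
    """
    code = code.strip()
    if re.fullmatch(r"\d{4}", code):
        counts = [int(c) for c in code]
    else:
        tokens = re.split(r"[-_/., ]+", code)
        if len(tokens) != 4:
            raise ValueError(
                f"glycan code {code!r}: expected 4 digits or 4 delimited counts"
            )
        counts = []
        for tok in tokens:
            if not tok.isdigit():
                raise ValueError(f"glycan code {code!r}: bad token {tok!r}")
            counts.append(int(tok))
    return GlycanComposition(*counts)


def glycan_mass(g: GlycanComposition) -> float:
    """Monoisotopic mass added by the glycan (sum of residue masses, Da)."""
    return (
        g.hex * GLYCAN_RESIDUE_MASSES["hex"]
        + g.hexnac * GLYCAN_RESIDUE_MASSES["hexnac"]
        + g.fuc * GLYCAN_RESIDUE_MASSES["fuc"]
        + g.neuac * GLYCAN_RESIDUE_MASSES["neuac"]
    )


def glycan_formula(g: GlycanComposition) -> Formula:
    return (
        g.hex * GLYCAN_RESIDUE_FORMULAS["hex"]
        + g.hexnac * GLYCAN_RESIDUE_FORMULAS["hexnac"]
        + g.fuc * GLYCAN_RESIDUE_FORMULAS["fuc"]
        + g.neuac * GLYCAN_RESIDUE_FORMULAS["neuac"]
    )


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for i, aa in enumerate(sequence):
        if aa not in AA_RESIDUE_FORMULAS:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")


def peptide_formula(sequence: str) -> Formula:
    """Elemental formula of a peptide incl. water and carbamidomethyl-Cys."""
    _check_sequence(sequence)
    out = Formula(WATER)
    for aa in sequence:
        out = out + AA_RESIDUE_FORMULAS[aa]
    n_cys = sequence.count("C")
    if n_cys:
        out = out + n_cys * CARBAMIDOMETHYL
    return out


def peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic peptide mass (water + CAM-Cys included), Da."""
    _check_sequence(sequence)
    m = WATER.mass + sum(AA_RESIDUE_MASSES[aa] for aa in sequence)
    return m + sequence.count("C") * CARBAMIDOMETHYL.mass


_SEQUON = re.compile(r"N[^P](?=[ST])")


@dataclass(frozen=True)
class PeptideBackbone:
    """A tryptic peptide carrying one glycosylated Asn.

    ``glycosite`` is the 1-based position of the Asn within the peptide; it
    must sit in an N-X(S/T) sequon with X != P.
    """

    sequence: str
    glycosite: int
    protein_id: str = ""
    missed_cleavages: int = 0

    def __post_init__(self):
        _check_sequence(self.sequence)
        i = self.glycosite
        s = self.sequence
        if not (1 <= i <= len(s)) or s[i - 1] != "N":
            raise ValueError(f"glycosite {i} is not an Asn in {s}")
        if i + 1 >= len(s) or s[i] == "P" or s[i + 1] not in "ST":
            raise ValueError(f"Asn at {i} in {s} is not in an N-X(S/T) sequon")


@dataclass(frozen=True)
class Glycopeptide:
    """Peptide backbone + glycan composition; masses derived on construction."""

    backbone: PeptideBackbone
    glycan: GlycanComposition
    neutral_mass: float = field(init=False, compare=False)
    formula: Formula = field(init=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "neutral_mass",
            peptide_mass(self.backbone.sequence) + glycan_mass(self.glycan),
        )
        object.__setattr__(
            self, "formula",
            peptide_formula(self.backbone.sequence) + glycan_formula(self.glycan),
        )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.backbone.sequence, self.glycan.code, self.backbone.glycosite)

    def mz(self, charge: int) -> float:
        return glycopeptide_mz(self, charge)

    def __str__(self) -> str:
        return f"{self.backbone.sequence}_{self.glycan.code}"


def glycopeptide_mz(gp: Glycopeptide, charge: int) -> float:
    """m/z of the [M + charge*H]^charge+ ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (gp.neutral_mass + charge * PROTON_MASS) / charge


def neutral_mass_from_mz(mz: float, charge: int) -> float:
    return mz * charge - charge * PROTON_MASS


def ppm(a: float, b: float) -> float:
    """Relative difference of a vs b in parts per million."""
    return (a - b) / b * 1e6
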