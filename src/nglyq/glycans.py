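"""N-glycan composition library: packaged default plus TSV load/save.

The packaged default library (``data/glycan_library_synthetic.tsv``) is a
synthetic stand-in generated by :func:`generate_default_compositions`: 331
biosynthetically plausible N-glycan compositions (high-mannose, hybrid and
complex types under antenna/sialylation/fucosylation constraints) plus 20
penta/hexa polylactosamine compositions, 351 in total.  It reproduces the size
and composition classes of published serum N-glycan libraries; it is not a
copy of any published list.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .chem import GlycanComposition, glycan_mass

__all__ = [
    "generate_default_compositions",
    "default_glycan_library",
    "load_glycan_library",
    "save_glycan_library",
]

DEFAULT_LIBRARY_RESOURCE = "glycan_library_synthetic.tsv"
_MAIN_SET_SIZE = 331


def generate_default_compositions() -> list[GlycanComposition]:
    """Deterministic rule-based enumeration of the default 351 compositions.

    Main set (331): HexNAc n = 2..6 with antenna count a = n - 2; Hex from the
    Man3 core up to a + 5; NeuAc <= a; Fuc <= 1 (n = 2), <= 2 (n = 3), <= 3
    (n >= 4).  The enumeration slightly overshoots and the heaviest entries
    are dropped to fix the size.  Polylactosamine set (20): penta (Hex8HexNAc7)
    and hexa (Hex9HexNAc8) LacNAc-extended compositions with Fuc 0..4 and
    NeuAc 0..1.
    """
    main: list[GlycanComposition] = []
    for n in range(2, 7):
        a = n - 2
        max_f = 1 if n == 2 else (2 if n == 3 else 3)
        max_h = 9 if n == 2 else a + 5
        for h in range(3, max_h + 1):
            for f in range(0, max_f + 1):
                for s in range(0, a + 1):
                    main.append(GlycanComposition(h, n, f, s))
    main.sort(key=lambda g: (glycan_mass(g), g.as_tuple()))
    main = main[:_MAIN_SET_SIZE]

    polylac = [
        GlycanComposition(h, n, f, s)
        for (h, n) in ((8, 7), (9, 8))
        for f in range(5)
        for s in range(2)
    ]
    out = main + polylac
    assert len(out) == len(set(out)) == 351
    return out


def load_glycan_library(path: str | Path) -> list[GlycanComposition]:
    """Read a TSV glycan library with columns hex, hexnac, fuc, neuac."""
    glycans: list[GlycanComposition] = []
    seen = set()
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and not fields[0].isdigit():
                header = fields
                continue
            if len(fields) < 4:
                raise ValueError(f"glycan library row has <4 columns: {line!r}")
            g = GlycanComposition(*(int(x) for x in fields[:4]))
            if g not in seen:
                seen.add(g)
                glycans.append(g)
    if not glycans:
        raise ValueError(f"empty glycan library: {path}")
    return glycans


def save_glycan_library(glycans: list[GlycanComposition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("hex\thexnac\tfuc\tneuac\tcode\tmass\n")
        for g in glycans:
            fh.write(
                f"{g.hex}\t{g.hexnac}\t{g.fuc}\t{g.neuac}\t{g.code}"
                f"\t{glycan_mass(g):.5f}\n"
            )


def default_glycan_library() -> list[GlycanComposition]:
    """The packaged 351-composition default library."""
    ref = resources.files("nglyq").joinpath("data", DEFAULT_LIBRARY_RESOURCE)
    with resources.as_file(ref) as path:
        return load_glycan_library(path)
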