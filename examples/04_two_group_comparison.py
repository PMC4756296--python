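"""Two-group comparison with match-between-runs and volcano statistics.

Simulates a triplicate case/control design where 3 of 30 glycopeptides are
planted at a 4-fold abundance change.  Each run is identified independently,
abundances are transferred to runs that missed a species (S >= 98 within
5 min), charges merged, runs globally normalized, replicate means taken with
a CV < 30% gate, and fold changes tested at the glycopeptide level.
"""

from importlib import resources

from nglyq import (
    SimConfig,
    build_db,
    build_master_table,
    compare_groups,
    default_glycan_library,
    identify,
    pick_species,
    simulate_two_group,
)

fasta = resources.files("nglyq").joinpath("data", "agp_synthetic.fasta")
with resources.as_file(fasta) as path:
    db = build_db(str(path), default_glycan_library())

species = pick_species(db, 30, seed=11)
keys = [(sp.record.glycopeptide.backbone.sequence,
         sp.record.glycopeptide.glycan.code,
         sp.record.glycopeptide.backbone.glycosite) for sp in species]
fold_map = {k: 4.0 for k in keys[:3]}

base = SimConfig(species=species, n_noise_ms2=30, seed=11)
runs, _, group_a, group_b = simulate_two_group(base, fold_map)
records = {k: sp.record for k, sp in zip(keys, species)}
idents = {name: identify(run, db)[0] for name, run in runs.items()}

master = build_master_table(runs, idents, records)
kept, pep_level, prot_level = compare_groups(master, group_a, group_b)

print(f"species on master list:   {len(master)}")
print(f"kept after CV filtering:  {len(kept)}")
print(f"flagged (|log2 FC| >= 1): {int(pep_level.flagged.sum())}")
print("\nplanted 4-fold species:")
for _, row in pep_level[pep_level.flagged].iterrows():
    mark = "planted" if (row.peptide, row.glycan,
                         row.glycosite) in fold_map else "FALSE"
    print(f"  {row.peptide[:20]:22s} {row.glycan}  "
          f"log2FC {row.log2_fc:+.2f}  p {row.p_value:.2g}  [{mark}]")
print("\nGlobal normalization pulls fold changes slightly toward the")
print("background (a compositional effect of normalizing on totals), but")
print("4-fold species remain well past the 2-fold line.")
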