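"""Generate a synthetic cross-species phenotype study bundle.

Builds the complete input set of an ontology-alignment study from one seed:
shared entity/quality support trees, two species phenotype ontologies with
EQ definitions and partially shared labels, model and disease annotation
corpora, an orthology map and planted gene-disease associations.
"""

from pathlib import Path

from phenobridge import generate_bundle, small_preset, write_bundle

cfg = small_preset(seed=42)
bundle = generate_bundle(cfg)

outdir = write_bundle(bundle, Path("scratch") / "example_bundle")
print(f"bundle written to {outdir}/")
print(f"  species 1 concepts : {len(bundle.species.o1)}")
print(f"  species 2 concepts : {len(bundle.species.o2)}")
print(f"  EQ definitions     : {len(bundle.species.defs1)} / {len(bundle.species.defs2)}")
print(f"  mouse models       : {len(bundle.models)} (one gene each)")
print(f"  diseases           : {len(bundle.diseases)}")
print(f"  planted true pairs : {len(bundle.gold)}")
# Every concept carries a (quality, entity) grounding; with the small preset
# all definitions and labels are shared, so both alignment routes can in
# principle recover every cross-species counterpart.
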