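"""Compare the two methods' mappings concept by concept.

For every concept mapped by both routes, the two target sets fall into
exactly one of five categories: identical, one a proper subset of the
other (either way), partially overlapping, or disjoint.
"""

from phenobridge import compare_mappings, generate_bundle, paper_shaped_preset
from phenobridge.comparison import write_overlap_table
from phenobridge.pipeline import build_all_mappings

bundle = generate_bundle(paper_shaped_preset(seed=1))
mappings = build_all_mappings(bundle)

tables = []
for direction in ("1to2", "2to1"):
    table, records = compare_mappings(
        mappings[("lexical", direction)], mappings[("formal", direction)]
    )
    tables.append(table)

print(write_overlap_table(tables))
# Counts per category sum to the number of doubly-mapped concepts per
# direction; most concepts fall into "exact" or one of the subset
# categories because both routes propagate through the same taxonomy.
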