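"""Curate a small alignment with the three-stage input filter.

Uses the bundled twelve-block demonstration alignment in which each
curation rule (minimum length, normalized score, border overlap,
complete containment) removes a known set of blocks.
"""

import json
import tempfile
from pathlib import Path

from supercoord import apply_filters, normalized_score, read_maf
from supercoord.synthetic import curation_demo_maf

path = Path(tempfile.mkdtemp()) / "demo.maf"
path.write_text(curation_demo_maf())

msa = read_maf(path)
print(f"input: {len(msa)} blocks, {msa.nucleotides} nt")
for block in msa.blocks:
    print(f"  {block.id}: {block.columns} columns, "
          f"normalized score {normalized_score(block):.0f}")

filtered, report = apply_filters(msa)
print(f"\nretained: {[b.id for b in filtered.blocks]}")
print(json.dumps(report.to_dict(), indent=2))

# Stage 1 removes the 10-column block, stage 2 the block scoring below
# -30 per column pair (the gap-extension limit; exactly -30 survives),
# stage 3 both members of the 30-nt overlap and of the containment pair.
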