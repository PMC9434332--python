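"""Light mode: list every collection peak in one gene's promoter.

Instead of testing a whole gene list, this inspects a single gene: which
TF tracks have a binding peak in its upstream region, and where exactly.
"""

from ciscross import build_promoters, ciscross_light
from ciscross.simulate import FixtureSpec, PlantedSignal, build_fixture

spec = FixtureSpec(seed=42, planted=(PlantedSignal("TF000_col", 0.5, 0.05),))
fx = build_fixture(spec)
promoters = build_promoters(fx.annotation, spec.promoter_length)

gene = fx.foreground[0]
table = ciscross_light(gene, promoters, fx.collection)

prom = promoters.promoters[gene]
print(f"Gene {gene}: promoter {prom.chrom}:{prom.start}-{prom.end} ({prom.strand})")
print(table.to_string(index=False) if len(table) else "(no peaks in this promoter)")
print(f"\n{len(table)} peak(s) found; each row names the TF track and the genomic")
print("coordinates of its peak inside this gene's upstream region — the gene's")
print("candidate direct regulators.")
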