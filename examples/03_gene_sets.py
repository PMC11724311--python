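"""Work with the packaged marker gene sets and resolve them to a matrix.

Loads the default heart registry (13 mitochondrial, 30 nuclear-enriched,
23 CM-nuclear, 8 CM-cytoplasmic genes plus 11 non-CM cell-type sets),
resolves it against a toy gene universe and shows how absent symbols are
reported without failing the run.
"""

import warnings

import qclus

registry = qclus.default_registry("heart")
for name, gs in registry.sets.items():
    print(f"{name:22s} role={gs.role:17s} {len(gs):3d} genes  e.g. {', '.join(gs.genes[:3])}")

# Resolve against a universe missing one mitochondrial symbol: the set still
# resolves (12 of 13 genes) and a warning names the absentee.
universe = [g for gs in registry.sets.values() for g in gs.genes if g != "MT-CYB"]
with warnings.catch_warnings(record=True) as caught:
    warnings.simplefilter("always")
    resolved = qclus.resolve(registry, universe)
print(f"\nmitochondrial set resolved to {len(resolved['mitochondrial'])} indices")
print(f"warning raised: {caught[0].message}")
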