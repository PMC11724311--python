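"""Named marker gene sets parameterizing the cell-type-specific QC metrics.

A :class:`GeneSetRegistry` bundles the marker lists a tissue needs: the
mitochondrially encoded genes (contamination tracker), a nuclear-enriched
set of MALAT1-correlated genes, cardiomyocyte (CM) nuclear and cytoplasmic
marker sets for heart, and one marker set per non-CM cell type. Registries
are loaded from YAML configs; defaults for heart and brain ship with the
package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

ROLES = frozenset(
    {"mitochondrial", "nuclear_enriched", "cm_nuclear", "cm_cytoplasmic", "celltype_marker"}
)

#: Roles that may appear at most once in a registry.
_SINGLETON_ROLES = frozenset({"mitochondrial", "nuclear_enriched", "cm_nuclear", "cm_cytoplasmic"})


class GeneSetError(ValueError):
    """Raised for invalid gene-set configuration or unresolvable sets."""


@dataclass(frozen=True)
class GeneSet:
    """An ordered, duplicate-free list of gene symbols with a QC role."""

    name: str
    genes: tuple[str, ...]
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise GeneSetError(
                f"gene set {self.name!r}: unknown role {self.role!r} "
                f"(expected one of {sorted(ROLES)})"
            )
        if not self.genes:
            raise GeneSetError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise GeneSetError(f"gene set {self.name!r} has duplicate symbols: {dupes}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetRegistry:
    """Mapping of set name -> :class:`GeneSet` for one tissue."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    tissue: str = "unspecified"

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def by_role(self, role: str) -> list[GeneSet]:
        """All sets carrying ``role``, in declaration order."""
        if role not in ROLES:
            raise GeneSetError(f"unknown role {role!r}")
        return [s for s in self.sets.values() if s.role == role]

    def single(self, role: str) -> GeneSet:
        """The unique set with ``role``; raises if absent or ambiguous."""
        hits = self.by_role(role)
        if len(hits) != 1:
            raise GeneSetError(
                f"registry for tissue {self.tissue!r} has {len(hits)} sets with "
                f"role {role!r}; expected exactly one"
            )
        return hits[0]

    @property
    def celltype_sets(self) -> list[GeneSet]:
        return self.by_role("celltype_marker")


def _build_registry(doc: Mapping) -> GeneSetRegistry:
    if not isinstance(doc, Mapping) or "sets" not in doc:
        raise GeneSetError("config document must contain a 'sets' mapping")
    tissue = str(doc.get("tissue", "unspecified"))
    raw_sets = doc["sets"]
    if not raw_sets:
        raise GeneSetError("config declares zero gene sets")
    registry = GeneSetRegistry(tissue=tissue)
    seen_roles: dict[str, str] = {}
    for name, spec in raw_sets.items():
        if name in registry.sets:
            raise GeneSetError(f"duplicate set name {name!r}")
        if not isinstance(spec, Mapping) or "role" not in spec or "genes" not in spec:
            raise GeneSetError(f"set {name!r} must declare 'role' and 'genes'")
        genes = spec["genes"]
        if genes is None:
            raise GeneSetError(f"gene set {name!r} is empty")
        gs = GeneSet(name=name, genes=tuple(str(g) for g in genes), role=str(spec["role"]))
        if gs.role in _SINGLETON_ROLES and gs.role in seen_roles:
            raise GeneSetError(
                f"duplicate set name for role {gs.role!r}: {seen_roles[gs.role]!r} "
                f"and {name!r} both claim it"
            )
        seen_roles[gs.role] = name
        registry.sets[name] = gs
    if not registry.celltype_sets:
        raise GeneSetError(
            f"config for tissue {tissue!r} declares no celltype_marker set; at least one is required"
        )
    return registry


def load_registry(source: str | Path | Mapping) -> GeneSetRegistry:
    """Load a :class:`GeneSetRegistry` from a YAML path or a parsed mapping.

    The document declares ``tissue`` and a ``sets`` mapping of
    ``name -> {role, genes}``. Duplicate names, empty sets, unknown roles and
    configs without any cell-type marker set are rejected with a message
    naming the offending set.
    """
    if isinstance(source, Mapping):
        return _build_registry(source)
    with open(source, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _build_registry(doc)


def default_registry(tissue: str = "heart") -> GeneSetRegistry:
    """The packaged default registry for ``tissue`` (``heart`` or ``brain``)."""
    ref = resources.files("qclus").joinpath("data", f"{tissue}.yaml")
    if not ref.is_file():
        raise GeneSetError(f"no packaged gene-set config for tissue {tissue!r}")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _build_registry(doc)


def resolve(
    registry: GeneSetRegistry, gene_universe: Sequence[str]
) -> dict[str, list[int]]:
    """Map each set to column indices of its symbols in ``gene_universe``.

    Symbols absent from the universe produce a warning listing them; a set
    resolving to zero genes is an error (a fraction over an empty set is
    undefined). Resolution preserves set order and is idempotent.
    """
    if len(gene_universe) == 0:
        raise GeneSetError("gene universe is empty")
    index = {g: i for i, g in enumerate(gene_universe)}
    resolved: dict[str, list[int]] = {}
    for name, gs in registry.sets.items():
        hits = [index[g] for g in gs.genes if g in index]
        missing = [g for g in gs.genes if g not in index]
        if missing:
            warnings.warn(
                f"gene set {name!r}: {len(missing)} symbol(s) absent from the "
                f"gene universe: {', '.join(missing)}",
                UserWarning,
                stacklevel=2,
            )
        if not hits:
            raise GeneSetError(
                f"gene set {name!r} resolves to zero genes in this universe"
            )
        resolved[name] = hits
    return resolved
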