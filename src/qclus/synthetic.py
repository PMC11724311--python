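"""Synthetic droplet populations with planted ground truth.

The generator emulates the contamination structure of a single-nuclei
heart experiment: an ambient RNA pool dominated by cytoplasm-enriched
cardiomyocyte transcripts and mitochondrial reads; empty droplets sampling
only ambient RNA with a low unspliced probability; nuclei sampling a
mixture ``w * ambient + (1 - w) * celltype profile`` whose nuclear-origin
reads are mostly unspliced; contaminated nuclei with large ``w``; and
doublets as sums of two independent nuclei. Mitochondrial reads come only
from the ambient pool. Per-droplet depth is Poisson, gene choice
multinomial, splice status per-read categorical.

Fixtures are structural, not realistic: they reproduce the qualitative
metric geometry the filter exploits, not real library-size or expression
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genesets import GeneSet, GeneSetRegistry
from .io import DropletMatrix

CLASSES = ("empty", "contaminated_nucleus", "cm_nucleus", "noncm_nucleus", "doublet")


def make_gene_universe(
    n_celltypes: int = 11,
    genes_per_set: int = 20,
    n_background: int = 700,
    include_cm: bool | None = None,
) -> tuple[np.ndarray, GeneSetRegistry]:
    """Build a disjoint synthetic gene universe and its registry.

    Fixed-role sets mirror the real registry sizes (13 mitochondrial, 30
    nuclear-enriched, 23 CM-nuclear, 8 CM-cytoplasmic) plus ``n_celltypes``
    non-CM marker sets of ``genes_per_set`` genes and ``n_background``
    unassigned genes. ``include_cm`` defaults to True; passing
    ``n_celltypes=0`` is shorthand for a brain-like universe — CM sets are
    dropped and three generic cell-type sets are created instead.
    """
    if include_cm is None:
        include_cm = n_celltypes > 0
    if n_celltypes == 0:
        n_celltypes, include_cm = 3, False
    genes: list[str] = []
    registry = GeneSetRegistry(tissue="heart" if include_cm else "brain")

    def add_set(name: str, role: str, size: int, prefix: str) -> None:
        symbols = tuple(f"{prefix}{i:03d}" for i in range(size))
        genes.extend(symbols)
        registry.sets[name] = GeneSet(name=name, genes=symbols, role=role)

    add_set("mitochondrial", "mitochondrial", 13, "sMT-")
    add_set("nuclear_enriched", "nuclear_enriched", 30, "sNUC-")
    if include_cm:
        add_set("cm_nuclear", "cm_nuclear", 23, "sCMN-")
        add_set("cm_cytoplasmic", "cm_cytoplasmic", 8, "sCMC-")
    for t in range(n_celltypes):
        add_set(f"celltype_{t}", "celltype_marker", genes_per_set, f"sCT{t:02d}-")
    genes.extend(f"sBG-{i:04d}" for i in range(n_background))
    return np.array(genes, dtype=object), registry


@dataclass
class SyntheticParams:
    """Generation parameters; defaults plant the four-cluster heart structure."""

    n_droplets: int = 5000
    proportions: dict[str, float] = field(
        default_factory=lambda: {
            "empty": 0.30,
            "contaminated_nucleus": 0.12,
            "cm_nucleus": 0.18,
            "noncm_nucleus": 0.32,
            "doublet": 0.08,
        }
    )
    n_celltypes: int = 11
    genes_per_set: int = 20
    n_background: int = 700
    empty_depth: float = 1200.0
    nucleus_depth: float = 4000.0
    #: ambient pool composition by role (cytoplasmic CM + mito dominated)
    ambient_role_weights: dict[str, float] = field(
        default_factory=lambda: {
            "cm_cytoplasmic": 0.45,
            "mitochondrial": 0.18,
            "background": 0.35,
            "nuclear_enriched": 0.02,
        }
    )
    w_clean: tuple[float, float] = (0.05, 0.25)
    w_contaminated: tuple[float, float] = (0.50, 0.70)
    #: P(unspliced), P(ambiguous) per read, by read origin
    splice_ambient: tuple[float, float] = (0.08, 0.05)
    splice_nucleus: tuple[float, float] = (0.75, 0.05)
    #: Dirichlet concentration for per-nucleus biological expression
    #: variability around the cell-type profile; None disables overdispersion
    profile_concentration: float | None = 300.0

    def validate(self) -> None:
        total = sum(self.proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.proportions.values()):
            raise ValueError("class proportions must be non-negative")
        unknown = set(self.proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown droplet classes: {sorted(unknown)}")


def clean_params(**overrides) -> SyntheticParams:
    """A contamination-free population: no empties or doublets, w near zero."""
    p = SyntheticParams(
        proportions={
            "empty": 0.0,
            "contaminated_nucleus": 0.0,
            "cm_nucleus": 0.35,
            "noncm_nucleus": 0.65,
            "doublet": 0.0,
        },
        w_clean=(0.0, 0.05),
    )
    return replace(p, **overrides)


@dataclass
class SyntheticTruth:
    """Ground-truth labels and the parameters that generated them."""

    labels: pd.DataFrame  # barcode, class, celltype, ambient_weight, depth
    params: SyntheticParams
    seed: int

    def mask(self, cls: str) -> np.ndarray:
        return (self.labels["class"] == cls).to_numpy()


def _role_profile(
    registry: GeneSetRegistry,
    resolved: Mapping[str, list[int]],
    n_genes: int,
    role_weights: Mapping[str, float],
    rng: np.random.Generator,
    extra_sets: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Probability vector over genes from per-role weights, Dirichlet within role."""
    p = np.zeros(n_genes)
    bg_idx = None
    assigned = np.zeros(n_genes, dtype=bool)
    for name, idx in resolved.items():
        assigned[idx] = True
    bg_idx = np.flatnonzero(~assigned)

    def spread(indices, weight):
        if weight <= 0 or len(indices) == 0:
            return
        p[np.asarray(indices)] += weight * rng.dirichlet(np.full(len(indices), 5.0))

    for role, weight in role_weights.items():
        if role == "background":
            spread(bg_idx, weight)
        else:
            for gs in registry.by_role(role):
                spread(resolved[gs.name], weight)
    if extra_sets:
        for name, weight in extra_sets.items():
            spread(resolved[name], weight)
    total = p.sum()
    if total <= 0:
        raise ValueError("profile weights resolve to an empty distribution")
    return p / total


def generate_population(
    params: SyntheticParams | None = None, seed: int = 0
) -> tuple[DropletMatrix, SyntheticTruth, GeneSetRegistry]:
    """Generate a droplet population with splicing layers and ground truth.

    Deterministic for a given ``(params, seed)``. Returns the matrix (with
    spliced/unspliced/ambiguous layers), the truth table and the registry
    resolved against the synthetic gene universe.
    """
    if params is None:
        params = SyntheticParams()
    params.validate()
    rng = np.random.default_rng(seed)
    genes, registry = make_gene_universe(
        params.n_celltypes, params.genes_per_set, params.n_background
    )
    from .genesets import resolve

    resolved = resolve(registry, genes)
    G = len(genes)

    ambient_p = _role_profile(registry, resolved, G, params.ambient_role_weights, rng)
    celltype_names = [s.name for s in registry.celltype_sets]
    noncm_profiles = {
        name: _role_profile(
            registry,
            resolved,
            G,
            {"nuclear_enriched": 0.35, "background": 0.20},
            rng,
            extra_sets={name: 0.45},
        )
        for name in celltype_names
    }
    if registry.by_role("cm_nuclear"):
        cm_profile = _role_profile(
            registry,
            resolved,
            G,
            {"nuclear_enriched": 0.35, "background": 0.20},
            rng,
            extra_sets={"cm_nuclear": 0.30, "cm_cytoplasmic": 0.15},
        )
    else:
        cm_profile = None

    classes = list(params.proportions)
    probs = np.array([params.proportions[c] for c in classes])
    if cm_profile is None and params.proportions.get("cm_nucleus", 0) > 0:
        raise ValueError("cm_nucleus class requested but the universe has no CM sets")
    draw = rng.choice(len(classes), size=params.n_droplets, p=probs)
    labels = [classes[i] for i in draw]

    # relative frequencies of nucleus types, for doublet partner sampling
    nuc_classes = [c for c in ("cm_nucleus", "noncm_nucleus") if params.proportions.get(c, 0) > 0]
    nuc_probs = np.array([params.proportions[c] for c in nuc_classes])
    nuc_probs = nuc_probs / nuc_probs.sum() if nuc_probs.sum() > 0 else None

    counts = np.zeros((params.n_droplets, G), dtype=np.int32)
    spliced = np.zeros_like(counts)
    unspliced = np.zeros_like(counts)
    ambiguous = np.zeros_like(counts)
    truth_rows = []

    def sample_nucleus(cls: str):
        """One nucleus: (ambient counts, nuclear counts, w, celltype name)."""
        if cls == "cm_nucleus":
            profile, ct = cm_profile, "cm"
        else:
            ct = celltype_names[rng.integers(len(celltype_names))]
            profile = noncm_profiles[ct]
        if params.profile_concentration is not None:
            # per-nucleus biological variability: Dirichlet around the profile,
            # restricted to its support (gives overdispersed, not pure
            # multinomial, counts — without it simulated doublet sums are
            # artificially tight and the doublet scorer degenerates)
            nz = profile > 0
            jittered = np.zeros_like(profile)
            jittered[nz] = rng.dirichlet(profile[nz] * params.profile_concentration)
            profile = jittered
        w = rng.uniform(*(params.w_contaminated if cls == "contaminated_nucleus" else params.w_clean))
        depth = rng.poisson(params.nucleus_depth)
        n_amb = rng.binomial(depth, w)
        amb = rng.multinomial(n_amb, ambient_p)
        nuc = rng.multinomial(depth - n_amb, profile)
        return amb, nuc, w, ct

    def splice_split(vec: np.ndarray, p_u: float, p_a: float):
        u = rng.binomial(vec, p_u)
        rest = vec - u
        a = rng.binomial(rest, p_a / (1 - p_u)) if p_u < 1 else np.zeros_like(rest)
        s = rest - a
        return s, u, a

    for i, cls in enumerate(labels):
        if cls == "empty":
            depth = rng.poisson(params.empty_depth)
            amb = rng.multinomial(depth, ambient_p)
            nuc = np.zeros(G, dtype=np.int64)
            w, ct = 1.0, ""
        elif cls == "doublet":
            partners = [nuc_classes[j] for j in rng.choice(len(nuc_classes), size=2, p=nuc_probs)]
            amb1, nuc1, w1, ct1 = sample_nucleus(partners[0])
            amb2, nuc2, w2, ct2 = sample_nucleus(partners[1])
            amb, nuc = amb1 + amb2, nuc1 + nuc2
            w, ct = (w1 + w2) / 2, f"{ct1}+{ct2}"
        else:
            amb, nuc, w, ct = sample_nucleus(cls)
        s_a, u_a, a_a = splice_split(amb, *params.splice_ambient)
        s_n, u_n, a_n = splice_split(nuc, *params.splice_nucleus)
        counts[i] = amb + nuc
        spliced[i] = s_a + s_n
        unspliced[i] = u_a + u_n
        ambiguous[i] = a_a + a_n
        truth_rows.append((cls, ct, w))

    barcodes = np.array([f"BC{i:06d}" for i in range(params.n_droplets)], dtype=object)
    matrix = DropletMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=barcodes,
        genes=genes,
        layers={
            "spliced": sp.csr_matrix(spliced),
            "unspliced": sp.csr_matrix(unspliced),
            "ambiguous": sp.csr_matrix(ambiguous),
        },
        splicing_available=np.ones(params.n_droplets, dtype=bool),
    )
    truth = SyntheticTruth(
        labels=pd.DataFrame(
            {
                "barcode": barcodes,
                "class": [r[0] for r in truth_rows],
                "celltype": [r[1] for r in truth_rows],
                "ambient_weight": [r[2] for r in truth_rows],
                "depth": np.asarray(counts.sum(axis=1)).ravel(),
            }
        ),
        params=params,
        seed=seed,
    )
    return matrix, truth, registry


def synthetic_pipeline_config(seed: int = 0, tissue: str = "heart", **overrides):
    """Pipeline config scaled to the synthetic gene universe (~1000 genes).

    The real-data detected-genes bounds assume a genome-scale universe;
    synthetic populations carry ~1000 genes, so the floor drops to 100 and
    the ceiling is lifted.
    """
    from .pipeline import PipelineConfig

    base = dict(min_genes=100, max_genes=10**9, seed=seed)
    base.update(overrides)
    return PipelineConfig.for_tissue(tissue, **base)
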