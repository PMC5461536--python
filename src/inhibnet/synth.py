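"""Synthetic world generator for the whole prediction pipeline.

Generates every input the pipeline consumes — protein catalog with classes
and families, annotated true inhibitions, tissue expression, ortholog
presence profiles, localization annotations, and PPI edges — with planted,
dial-controlled signal, so every downstream stage is testable without any
database download.

Expression model
----------------
Log10 expression of gene *g* in sample *s* is a per-gene tissue baseline
plus Gaussian noise.  Housekeeping genes have a flat baseline across
tissues; tissue-specific genes are high in one or two designated tissues
and near the detection floor elsewhere (the two archetypes real tissue
atlases show).  A configurable fraction of the true inhibitions is
*planted*: the genes of a planted pair are set to housekeeping baselines
and share a per-sample latent factor,

    noise_g(s) = sqrt(rho) * z(s) + sqrt(1 - rho) * eps_g(s),

so the population correlation of their log values is exactly ``planted_rho``.
Planted pairs sharing a gene are merged into connected components that share
one factor (a gene cannot carry two independent 0.9-loadings), so every
within-component pair attains the planted correlation.

Reproducibility: every sub-generator derives its own substream from the
single config seed with a fixed component key, so standalone calls and the
orchestrated :func:`generate_world` produce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import CatalyticClass, CompatibilityRule, PairKey, ProteinRecord, Role
from .coexpression import ExpressionMatrix
from .localization import LocalizationRecord, default_compartment_model
from .phylo import OrthologTable
from .ppi import EdgeList

CLASS_ORDER = (
    CatalyticClass.ASPARTIC,
    CatalyticClass.CYSTEINE,
    CatalyticClass.METALLO,
    CatalyticClass.SERINE,
    CatalyticClass.THREONINE,
)

# two protease families per catalytic class, named in MEROPS style
PROTEASE_FAMILIES = {
    CatalyticClass.ASPARTIC: ("A1", "A2"),
    CatalyticClass.CYSTEINE: ("C1", "C14"),
    CatalyticClass.METALLO: ("M10", "M12"),
    CatalyticClass.SERINE: ("S1", "S8"),
    CatalyticClass.THREONINE: ("T1", "T2"),
}


def round_half_up(x: float) -> int:
    """Deterministic rounding for count knobs (0.5 always rounds up)."""
    return int(math.floor(x + 0.5))


def default_inhibitor_families(
    classes: Sequence[CatalyticClass],
) -> list[tuple[str, frozenset[CatalyticClass]]]:
    """Six inhibitor families with class commitments echoing real biology.

    Serpin-like (I4) and Kunitz-like (I2) families target serine proteases,
    cystatin-like (I25, I29) target cysteine proteases, TIMP-like (I35)
    target metalloproteases, and a macroglobulin-like family (I39) traps
    proteases of every class.  Families whose committed classes are absent
    from the configured class roster are dropped.
    """
    avail = set(classes)
    raw = [
        ("I4", frozenset({CatalyticClass.SERINE})),
        ("I25", frozenset({CatalyticClass.CYSTEINE})),
        ("I35", frozenset({CatalyticClass.METALLO})),
        ("I2", frozenset({CatalyticClass.SERINE})),
        ("I29", frozenset({CatalyticClass.CYSTEINE})),
        ("I39", frozenset(avail)),
    ]
    out = []
    for fam, compat in raw:
        kept = frozenset(compat & avail)
        if kept:
            out.append((fam, kept))
    return out


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_protease_classes: int = 5
    proteases_per_class: int = 20
    inhibitor_families: tuple[tuple[str, frozenset[CatalyticClass]], ...] | None = None
    inhibitors_per_family: int = 5
    n_true_inhibitions: int = 60
    frac_coexpressed_truth: float = 0.5
    planted_rho: float = 0.9
    n_tissues: int = 20
    samples_per_tissue: int = 10
    frac_tissue_specific_genes: float = 0.5
    expression_noise_sd: float = 0.5
    n_species: int = 162
    phylo_flip_rate: float = 0.1
    localization_missing_rate: float = 0.6
    ppi_recall: float = 0.27
    ppi_spurious_edges: int = 200

    def __post_init__(self) -> None:
        for name in (
            "frac_coexpressed_truth",
            "frac_tissue_specific_genes",
            "phylo_flip_rate",
            "localization_missing_rate",
            "ppi_recall",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 < self.planted_rho < 1.0:
            raise ValueError("planted_rho must be in (-1, 1)")
        for name in (
            "n_protease_classes",
            "proteases_per_class",
            "inhibitors_per_family",
            "n_true_inhibitions",
            "n_tissues",
            "samples_per_tissue",
            "n_species",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.expression_noise_sd <= 0:
            raise ValueError("expression_noise_sd must be positive")
        if not 1 <= self.n_protease_classes <= len(CLASS_ORDER):
            raise ValueError(
                f"n_protease_classes must be in 1..{len(CLASS_ORDER)}"
            )

    @property
    def classes(self) -> tuple[CatalyticClass, ...]:
        return CLASS_ORDER[: self.n_protease_classes]

    @property
    def families(self) -> list[tuple[str, frozenset[CatalyticClass]]]:
        if self.inhibitor_families is not None:
            return [(f, frozenset(c)) for f, c in self.inhibitor_families]
        return default_inhibitor_families(self.classes)


@dataclass
class SynthWorld:
    catalog: list[ProteinRecord]
    rules: list[CompatibilityRule]
    true_inhibitions: list[PairKey]
    planted_pairs: list[PairKey]
    expression: ExpressionMatrix | None = None
    ortholog_table: OrthologTable | None = None
    localization: list[LocalizationRecord] = field(default_factory=list)
    ppi_edges: EdgeList | None = None
    gene_tissues: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def inhibitors(self) -> list[ProteinRecord]:
        return [r for r in self.catalog if r.role is Role.INHIBITOR]

    @property
    def proteases(self) -> list[ProteinRecord]:
        return [r for r in self.catalog if r.role is Role.PROTEASE]


def _rng(config: SynthConfig, component: int) -> np.random.Generator:
    # fixed component keys keep standalone sub-generator calls reproducible
    return np.random.default_rng([component, config.seed])


def _planted_components(pairs: Sequence[PairKey]) -> list[set[str]]:
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, set[str]] = {}
    for x in parent:
        comps.setdefault(find(x), set()).add(x)
    return list(comps.values())


def build_catalog(
    config: SynthConfig,
) -> tuple[list[ProteinRecord], list[CompatibilityRule]]:
    """Deterministic class/family-structured catalog plus compatibility rules."""
    catalog: list[ProteinRecord] = []
    for cls in config.classes:
        fams = PROTEASE_FAMILIES[cls]
        for i in range(config.proteases_per_class):
            catalog.append(
                ProteinRecord(
                    id=f"P_{cls.value}_{i + 1:02d}",
                    role=Role.PROTEASE,
                    catalytic_class=cls,
                    family=fams[i % len(fams)],
                    # a few catalytically dead homologs stay in the space
                    active=(i % 7 != 6),
                )
            )
    rules = []
    for fam, compat in config.families:
        rules.append(CompatibilityRule(fam, frozenset(compat)))
        for i in range(config.inhibitors_per_family):
            catalog.append(
                ProteinRecord(
                    id=f"I_{fam}_{i + 1:02d}",
                    role=Role.INHIBITOR,
                    catalytic_class=CatalyticClass.NONE,
                    family=fam,
                )
            )
    return catalog, rules


def generate_world(config: SynthConfig) -> SynthWorld:
    """Generate a complete synthetic world (catalog through PPI edges)."""
    catalog, rules = build_catalog(config)
    rng = _rng(config, 1)

    compat = {r.inhibitor_family: r.compatible_protease_classes for r in rules}
    inhibitors = [r for r in catalog if r.role is Role.INHIBITOR]
    proteases = [r for r in catalog if r.role is Role.PROTEASE]
    compatible_pairs = [
        PairKey(i.id, p.id)
        for i in inhibitors
        for p in proteases
        if p.catalytic_class in compat[i.family]
    ]
    if config.n_true_inhibitions > len(compatible_pairs):
        raise ValueError(
            f"n_true_inhibitions={config.n_true_inhibitions} exceeds the "
            f"{len(compatible_pairs)} class-compatible inhibitor/protease pairs"
        )
    pick = rng.choice(len(compatible_pairs), size=config.n_true_inhibitions, replace=False)
    true_inhibitions = [compatible_pairs[k] for k in sorted(pick)]

    n_planted = round_half_up(config.frac_coexpressed_truth * config.n_true_inhibitions)
    planted_idx = rng.choice(len(true_inhibitions), size=n_planted, replace=False)
    planted_pairs = [true_inhibitions[k] for k in sorted(planted_idx)]

    world = SynthWorld(
        catalog=catalog,
        rules=rules,
        true_inhibitions=true_inhibitions,
        planted_pairs=planted_pairs,
    )
    world.expression = generate_expression(world, config)
    world.ortholog_table = generate_phylo(world, config)
    world.localization = generate_localization(world, config)
    world.ppi_edges = generate_ppi(world, config)
    return world


def generate_expression(world: SynthWorld, config: SynthConfig) -> ExpressionMatrix:
    """Tissue expression with planted log-scale correlation for flagged pairs."""
    if config.n_tissues * config.samples_per_tissue < 3:
        raise ValueError("need at least 3 samples overall")
    rng = _rng(config, 2)
    genes = [r.id for r in world.catalog]
    tissues = [f"T{t + 1:02d}" for t in range(config.n_tissues)]
    samples = [f"{t}_s{j + 1:02d}" for t in tissues for j in range(config.samples_per_tissue)]
    tissue_of = pd.Series({s: s.split("_s")[0] for s in samples})

    comps = _planted_components(world.planted_pairs)
    comp_of: dict[str, int] = {}
    for ci, members in enumerate(comps):
        for g in members:
            comp_of[g] = ci

    # per-gene archetype: planted genes are housekeeping by construction
    is_ts = {}
    gene_tissues: dict[str, tuple[str, ...]] = {}
    baseline = np.empty((len(genes), config.n_tissues))
    for gi, g in enumerate(genes):
        if g in comp_of:
            is_ts[g] = False
        else:
            is_ts[g] = bool(rng.random() < config.frac_tissue_specific_genes)
        if is_ts[g]:
            k = 1 + int(rng.random() < 0.3)  # one or two home tissues
            home = rng.choice(config.n_tissues, size=k, replace=False)
            gene_tissues[g] = tuple(tissues[h] for h in sorted(home))
            high = rng.uniform(1.0, 2.0)
            baseline[gi, :] = -2.0
            baseline[gi, sorted(home)] = high
        else:
            gene_tissues[g] = ()
            baseline[gi, :] = rng.uniform(0.5, 1.5)

    n_samples = len(samples)
    rho = config.planted_rho
    z = rng.standard_normal((len(comps), n_samples))
    eps = rng.standard_normal((len(genes), n_samples))
    noise = np.empty_like(eps)
    sign = 1.0 if rho >= 0 else -1.0
    a = math.sqrt(abs(rho))
    b = math.sqrt(1.0 - abs(rho))
    for gi, g in enumerate(genes):
        if g in comp_of:
            # negative rho: inhibitor-side genes load with opposite sign
            load = a if (sign > 0 or not g.startswith("I_")) else -a
            noise[gi] = load * z[comp_of[g]] + b * eps[gi]
        else:
            noise[gi] = eps[gi]

    tissue_idx = np.array([tissues.index(tissue_of[s]) for s in samples])
    log10_vals = baseline[:, tissue_idx] + config.expression_noise_sd * noise
    values = pd.DataFrame(10.0 ** log10_vals, index=genes, columns=samples)
    world.gene_tissues = gene_tissues
    return ExpressionMatrix(values, tissue_of)


def generate_phylo(world: SynthWorld, config: SynthConfig) -> OrthologTable:
    """Ortholog presence profiles: true pairs share a profile up to bit flips."""
    rng = _rng(config, 3)
    genes = [r.id for r in world.catalog]
    species = [f"sp{k + 1:03d}" for k in range(config.n_species)]
    comps = _planted_components(world.true_inhibitions)
    comp_of: dict[str, int] = {}
    for ci, members in enumerate(comps):
        for g in members:
            comp_of[g] = ci
    base = rng.random((len(comps), config.n_species)) < 0.5
    present = np.empty((len(genes), config.n_species), dtype=bool)
    for gi, g in enumerate(genes):
        if g in comp_of:
            flips = rng.random(config.n_species) < config.phylo_flip_rate
            present[gi] = base[comp_of[g]] ^ flips
        else:
            present[gi] = rng.random(config.n_species) < 0.5
    inpara = np.where(present, rng.uniform(0.3, 1.0, present.shape), 0.0)
    bits = np.where(present, rng.uniform(50.0, 500.0, present.shape), 0.0)
    return OrthologTable(
        inparalog_score=pd.DataFrame(inpara, index=genes, columns=species),
        bit_score=pd.DataFrame(bits, index=genes, columns=species),
    )


def generate_localization(
    world: SynthWorld, config: SynthConfig
) -> list[LocalizationRecord]:
    """Patchy annotations: an exact round of the catalog stays unannotated."""
    rng = _rng(config, 4)
    model = default_compartment_model()
    terms = sorted(model.vocabulary - {model.root})
    genes = [r.id for r in world.catalog]
    n_missing = round_half_up(config.localization_missing_rate * len(genes))
    missing_idx = set(rng.choice(len(genes), size=n_missing, replace=False).tolist())
    evidence = {
        "locdb": ("primary", "secondary"),
        "hpa": ("High", "Medium", "Supportive"),
        "go": ("EXP", "IDA", "TAS"),
    }
    sources = sorted(evidence)
    records: list[LocalizationRecord] = []
    for gi, g in enumerate(genes):
        if gi in missing_idx:
            continue
        n_terms = 1 + int(rng.random() < 0.3)
        picked = rng.choice(len(terms), size=n_terms, replace=False)
        for ti in sorted(picked):
            src = sources[int(rng.integers(len(sources)))]
            ev = evidence[src][int(rng.integers(len(evidence[src])))]
            records.append(LocalizationRecord(g, terms[ti], src, ev))
    return records


def generate_ppi(world: SynthWorld, config: SynthConfig) -> EdgeList:
    """PPI edges covering an exact fraction of true inhibitions plus noise."""
    rng = _rng(config, 5)
    n_true_edges = round_half_up(config.ppi_recall * len(world.true_inhibitions))
    pick = rng.choice(len(world.true_inhibitions), size=n_true_edges, replace=False)
    edges = [tuple(world.true_inhibitions[k]) for k in sorted(pick)]
    genes = [r.id for r in world.catalog]
    true_set = {frozenset(p) for p in world.true_inhibitions}
    n_avail = len(genes) * (len(genes) - 1) // 2 - len(true_set)
    if config.ppi_spurious_edges > n_avail:
        raise ValueError(
            f"ppi_spurious_edges={config.ppi_spurious_edges} exceeds the "
            f"{n_avail} non-true unordered pairs available"
        )
    have = {frozenset(e) for e in edges}
    while len(edges) < n_true_edges + config.ppi_spurious_edges:
        a, b = rng.choice(len(genes), size=2, replace=False)
        key = frozenset((genes[a], genes[b]))
        if key in true_set or key in have:
            continue
        have.add(key)
        edges.append((genes[a], genes[b]))
    scores = {e: float(s) for e, s in zip(edges, rng.uniform(0.5, 1.0, len(edges)))}
    return EdgeList.from_pairs(edges, source_tag="synthetic_ppi", scores=scores)


def with_params(config: SynthConfig, **kwargs) -> SynthConfig:
    """Convenience copy-with-overrides for seed batches and signal dials."""
    return replace(config, **kwargs)
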