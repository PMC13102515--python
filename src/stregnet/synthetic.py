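"""Synthetic spatial transcriptomics data with known regulatory ground truth.

The generator emulates the statistical structure the screening pipeline
assumes: a spot lattice partitioned into tissue domains; negative-binomial
UMI counts whose means follow domain-specific module activities; TF genes
whose spatial profiles track their module (never their targets directly —
the analysis must rediscover the link); promoters with exact-consensus
family binding sites planted in true targets and uniform-random background
elsewhere; and a paired control/knockdown expression + metabolite
experiment for the downstream validation analog.

Counts are drawn as ``NB(mean = lib_s * base_g * activity[module(g),
domain(s)], size = dispersion)`` with a log-normal per-spot library factor
normalized to unit expectation, so ``base_g * activity`` is the expected
count itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneAnnotation, PromoterSet, SpotGeometry
from .motifs import BASES, PWM, MotifLibrary, reverse_complement

__all__ = [
    "TissueSpec",
    "SyntheticTruth",
    "simulate_tissue",
    "simulate_promoters",
    "simulate_knockdown",
    "default_screen_spec",
    "homogeneous_spec",
    "default_module_activity",
    "truth_to_json",
    "truth_from_json",
]

_DECOY_FAMILIES = ["MYB", "bHLH", "ERF", "WRKY", "C2H2", "GRAS", "bZIP"]


@dataclass
class TissueSpec:
    """Parameters of one synthetic tissue section.

    ``module_activity`` is a (modules x domains) matrix of fold
    activations; when None, a default harmonic layout is used in which
    every module's peak-to-trough contrast across domains is at least 4x
    while adjacent modules stay below the default network correlation
    threshold.  ``base_mean`` is either a per-gene array of expected
    counts or a scalar median for a log-normal draw across genes.
    """

    grid_width: int = 50
    grid_height: int = 30
    n_domains: int = 3
    domain_layout: str = "bands"  # or "voronoi"
    n_genes: int = 600
    n_modules: int = 9
    module_activity: np.ndarray | None = None
    base_mean: float | np.ndarray = 5.0
    base_mean_sigma: float = 0.6
    nb_dispersion: float = 2.0
    libsize_sigma: float = 0.25
    n_tfs: int = 30
    tf_module_map: dict[str, int] | None = None
    tf_family_map: dict[str, str] | None = None
    target_map: dict[str, set[str]] | None = None
    pathway_tags: dict[str, set[str]] | None = None
    promoter_len: int = 500
    motif_width: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_width <= 0 or self.grid_height <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_modules < 1:
            raise ValueError("need at least one module")
        if self.n_modules > self.n_genes:
            raise ValueError("more modules than genes")
        if self.n_tfs > self.n_genes:
            raise ValueError("more TFs than genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.domain_layout not in ("bands", "voronoi"):
            raise ValueError(f"unknown domain layout {self.domain_layout!r}")
        if self.module_activity is not None:
            act = np.asarray(self.module_activity, dtype=float)
            if act.shape != (self.n_modules, self.n_domains):
                raise ValueError("module_activity must be n_modules x n_domains")
            if np.any(act < 0):
                raise ValueError("module_activity entries must be >= 0")
            self.module_activity = act

    @property
    def n_spots(self) -> int:
        return self.grid_width * self.grid_height

    def resolved_activity(self) -> np.ndarray:
        if self.module_activity is not None:
            return self.module_activity
        return default_module_activity(self.n_modules, self.n_domains)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    domain_of: dict[str, int]
    module_of: dict[str, int]
    true_edges: set[tuple[str, str, int]]  # (tf, target, sign)
    planted_sites: list[tuple[str, int, str, str]]  # (gene, pos, strand, family)
    metabolite_loadings: dict[str, tuple[list[str], list[float], int]]
    tf_family_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for _, _, sign in self.true_edges:
            if sign not in (+1, -1):
                raise ValueError("edge signs must be +1 or -1")

    def domain_labels(self, barcodes: list[str]) -> np.ndarray:
        return np.array([self.domain_of[b] for b in barcodes])

    def module_labels(self, gene_ids: list[str]) -> np.ndarray:
        return np.array([self.module_of[g] for g in gene_ids])


def default_module_activity(n_modules: int, n_domains: int) -> np.ndarray:
    """Harmonic module-activity layout.

    ``activity[m, d] = 1 + cos(2*pi*m/M - 2*pi*d/D)`` places the M module
    profiles at evenly spaced phases over the D domains: every module
    peaks somewhere, the worst-case peak-to-trough contrast is exactly 4x
    (for D = 3), and the correlation between standardized profiles of
    modules m and m' is cos(2*pi*(m-m')/M), so adjacent modules are
    distinct.  A single domain degenerates to all-ones.
    """
    if n_domains == 1:
        return np.ones((n_modules, 1))
    m = np.arange(n_modules)[:, None]
    d = np.arange(n_domains)[None, :]
    return 1.0 + np.cos(2 * np.pi * m / n_modules - 2 * np.pi * d / n_domains)


def homogeneous_spec(
    n_spots: int = 1000, n_genes: int = 2000, seed: int = 0, **overrides
) -> TissueSpec:
    """One-domain tissue with a single flat module: the replicate analog.

    Spot-to-spot variation comes only from library size and NB noise, so
    any two disjoint spot sets are biological replicates of one another.
    """
    width = int(np.ceil(np.sqrt(n_spots)))
    height = int(np.ceil(n_spots / width))
    if width * height != n_spots:
        # keep the spot count exact by using a 1 x n strip when not rectangular
        width, height = n_spots, 1
    params = dict(
        grid_width=width,
        grid_height=height,
        n_domains=1,
        n_genes=n_genes,
        n_modules=1,
        n_tfs=0,
        seed=seed,
    )
    params.update(overrides)
    return TissueSpec(**params)


def default_screen_spec(seed: int = 0, **overrides) -> TissueSpec:
    """The default regulator-screen tissue: 3 band domains, 9 modules.

    One planted dual-pathway TF (family TCP, module 4) regulates four
    structural genes in its own module, two tagged as a catechin-synthesis
    set and two as a theanine-hydrolysis set.  Decoys probe both arms of
    the dual criterion: two same-family TFs sit in a spatially
    anti-correlated module (binding evidence without coexpression), and
    two other-family TFs share module 4 (coexpression without binding
    evidence).  Remaining TFs are spread across the other modules.
    """
    params: dict = dict(seed=seed)
    params.update(overrides)
    spec = TissueSpec(**params)

    reg = "tf000"
    gene_ids = _gene_ids(spec)
    struct_module = {g: i % spec.n_modules for i, g in enumerate(gene_ids[: spec.n_genes - spec.n_tfs])}
    # four structural targets in the regulator's module
    module4_genes = [g for g, m in struct_module.items() if m == 4]
    targets = module4_genes[:4]
    if len(targets) < 4:
        raise ValueError("spec too small for the default screen layout")

    tf_ids = gene_ids[spec.n_genes - spec.n_tfs :]
    tf_module: dict[str, int] = {}
    tf_family: dict[str, str] = {}
    tf_module[reg] = 4
    tf_family[reg] = "TCP"
    # same-family, anti-correlated module (phase ~160 degrees away)
    for tf in tf_ids[1:3]:
        tf_module[tf] = 0
        tf_family[tf] = "TCP"
    # co-modular, other-family decoys
    for tf, fam in zip(tf_ids[3:5], ("MYB", "bHLH")):
        tf_module[tf] = 4
        tf_family[tf] = fam
    # background TFs spread over the remaining modules
    other_modules = [m for m in range(spec.n_modules) if m != 4]
    for i, tf in enumerate(tf_ids[5:]):
        tf_module[tf] = other_modules[i % len(other_modules)]
        tf_family[tf] = _DECOY_FAMILIES[i % len(_DECOY_FAMILIES)]

    pathway = {
        targets[0]: {"catechin_synthesis"},
        targets[1]: {"catechin_synthesis"},
        targets[2]: {"theanine_hydrolysis"},
        targets[3]: {"theanine_hydrolysis"},
    }
    spec.tf_module_map = tf_module
    spec.tf_family_map = tf_family
    spec.target_map = {reg: set(targets)}
    spec.pathway_tags = pathway
    return spec


def _gene_ids(spec: TissueSpec) -> list[str]:
    n_struct = spec.n_genes - spec.n_tfs
    return [f"g{i:04d}" for i in range(n_struct)] + [f"tf{i:03d}" for i in range(spec.n_tfs)]


def _domain_labels(spec: TissueSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-spot domain over the full grid (row-major y, then x)."""
    xs, ys = np.meshgrid(np.arange(spec.grid_width), np.arange(spec.grid_height))
    xs, ys = xs.ravel(), ys.ravel()
    if spec.n_domains == 1:
        return np.zeros(xs.size, dtype=int)
    if spec.domain_layout == "bands":
        return (xs * spec.n_domains) // spec.grid_width
    centers = np.column_stack(
        [
            rng.uniform(0, spec.grid_width, spec.n_domains),
            rng.uniform(0, spec.grid_height, spec.n_domains),
        ]
    )
    pts = np.column_stack([xs, ys]).astype(float)
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def simulate_tissue(
    spec: TissueSpec,
) -> tuple[CountMatrix, SpotGeometry, GeneAnnotation, SyntheticTruth]:
    """Draw one spatial count dataset from the spec.

    Deterministic at a fixed spec seed.  TF genes are generated exactly
    like structural genes of their mapped module — their coupling to their
    targets exists only through the shared module activity, which is the
    link the downstream screen must rediscover.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = _gene_ids(spec)
    n_struct = spec.n_genes - spec.n_tfs
    tf_ids = gene_ids[n_struct:]

    tf_module = dict(spec.tf_module_map or {})
    for i, tf in enumerate(tf_ids):
        tf_module.setdefault(tf, i % spec.n_modules)
    tf_family = dict(spec.tf_family_map or {})
    for i, tf in enumerate(tf_ids):
        tf_family.setdefault(tf, _DECOY_FAMILIES[i % len(_DECOY_FAMILIES)])
    bad_tf = set(tf_module) - set(tf_ids)
    if bad_tf:
        raise ValueError(f"tf_module_map names unknown TFs: {sorted(bad_tf)}")

    module_of = {g: i % spec.n_modules for i, g in enumerate(gene_ids[:n_struct])}
    module_of.update({tf: tf_module[tf] for tf in tf_ids})

    target_map = spec.target_map or {}
    for tf, targets in target_map.items():
        if tf not in tf_ids:
            raise ValueError(f"target_map key {tf!r} is not a TF gene")
        missing = set(targets) - set(gene_ids)
        if missing:
            raise ValueError(f"target genes do not exist: {sorted(missing)}")

    # spot lattice and domains
    xs, ys = np.meshgrid(np.arange(spec.grid_width), np.arange(spec.grid_height))
    xs, ys = xs.ravel(), ys.ravel()
    domains = _domain_labels(spec, rng)
    barcodes = [f"s{x:03d}x{y:03d}" for x, y in zip(xs, ys)]
    geometry = SpotGeometry(
        pd.DataFrame(
            {"x": xs, "y": ys, "in_tissue": True}, index=pd.Index(barcodes, name="barcode")
        )
    )

    # per-gene baseline means
    if np.ndim(spec.base_mean) == 0:
        base = float(spec.base_mean) * rng.lognormal(
            mean=0.0, sigma=spec.base_mean_sigma, size=spec.n_genes
        )
    else:
        base = np.asarray(spec.base_mean, dtype=float)
        if base.shape != (spec.n_genes,):
            raise ValueError("base_mean array must have one entry per gene")

    activity = spec.resolved_activity()
    gene_modules = np.array([module_of[g] for g in gene_ids])
    # library factor normalized to unit expectation
    lib = rng.lognormal(
        mean=-0.5 * spec.libsize_sigma**2, sigma=spec.libsize_sigma, size=len(barcodes)
    )
    mean = lib[:, None] * base[None, :] * activity[gene_modules][:, domains].T
    r = spec.nb_dispersion
    p = np.where(mean > 0, r / (r + mean), 1.0)
    counts = rng.negative_binomial(r, p)

    matrix = CountMatrix(counts, barcodes, gene_ids)

    symbols = {g: g for g in gene_ids}
    pathway_tags = spec.pathway_tags or {}
    annot = pd.DataFrame(
        {
            "symbol": [symbols[g] for g in gene_ids],
            "is_tf": [g in set(tf_ids) for g in gene_ids],
            "tf_family": [tf_family.get(g, "") for g in gene_ids],
            "pathway_tags": [frozenset(pathway_tags.get(g, ())) for g in gene_ids],
            "term_ids": [frozenset({f"M{module_of[g]}"}) for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    annotation = GeneAnnotation(annot)

    true_edges = {
        (tf, target, +1) for tf, targets in target_map.items() for target in targets
    }
    metabolites = _default_metabolites(pathway_tags)
    truth = SyntheticTruth(
        domain_of=dict(zip(barcodes, domains.tolist())),
        module_of=module_of,
        true_edges=true_edges,
        planted_sites=[],
        metabolite_loadings=metabolites,
        tf_family_of=tf_family,
    )
    return matrix, geometry, annotation, truth


def _default_metabolites(
    pathway_tags: dict[str, set[str]],
) -> dict[str, tuple[list[str], list[float], int]]:
    """Catechins load positively on the synthesis set; theanine loads
    negatively on its hydrolysis set (more hydrolase, less theanine)."""
    by_tag: dict[str, list[str]] = {}
    for gene, tags in pathway_tags.items():
        for tag in tags:
            by_tag.setdefault(tag, []).append(gene)
    out: dict[str, tuple[list[str], list[float], int]] = {}
    if "catechin_synthesis" in by_tag:
        genes = sorted(by_tag["catechin_synthesis"])
        out["catechins"] = (genes, [1.0] * len(genes), +1)
    if "theanine_hydrolysis" in by_tag:
        genes = sorted(by_tag["theanine_hydrolysis"])
        out["theanine"] = (genes, [1.0] * len(genes), -1)
    return out


def simulate_promoters(
    truth: SyntheticTruth, spec: TissueSpec, seed: int | None = None
) -> tuple[PromoterSet, MotifLibrary]:
    """Uniform-random promoters with exact consensus sites in true targets.

    One motif per TF family (random consensus, 0.91/0.03 column
    probabilities, so the consensus scores a relative 1.0).  For every
    true edge one exact-consensus instance of the TF's family motif is
    planted at a random non-overlapping offset and strand in the target
    promoter.  Non-target promoters get no deliberate planting; chance
    hits in the uniform background are allowed — they are exactly what
    the dual network criterion must reject.
    """
    if spec.promoter_len < spec.motif_width:
        raise ValueError("promoter_len must be >= motif_width")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    families = sorted(set(truth.tf_family_of.values()))
    library: dict[str, PWM] = {}
    for fam in families:
        consensus_idx = rng.integers(0, 4, size=spec.motif_width)
        probs = np.full((4, spec.motif_width), 0.03)
        probs[consensus_idx, np.arange(spec.motif_width)] = 0.91
        library[fam] = PWM(fam, probs)

    gene_ids = sorted(truth.module_of)
    seqs = {
        g: "".join(BASES[i] for i in rng.integers(0, 4, size=spec.promoter_len))
        for g in gene_ids
    }

    planted: list[tuple[str, int, str, str]] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for tf, target, _sign in sorted(truth.true_edges):
        fam = truth.tf_family_of[tf]
        consensus = library[fam].consensus
        w = len(consensus)
        for _ in range(1000):
            pos = int(rng.integers(0, spec.promoter_len - w + 1))
            if all(
                pos + w <= a or pos >= b for a, b in occupied.get(target, [])
            ):
                break
        else:
            raise ValueError(f"could not place a site in promoter of {target}")
        strand = "+" if rng.random() < 0.5 else "-"
        site = consensus if strand == "+" else reverse_complement(consensus)
        seq = seqs[target]
        seqs[target] = seq[:pos] + site + seq[pos + w :]
        occupied.setdefault(target, []).append((pos, pos + w))
        planted.append((target, pos, strand, fam))

    truth.planted_sites = planted
    return PromoterSet(seqs), MotifLibrary(library)


def simulate_knockdown(
    truth: SyntheticTruth,
    spec: TissueSpec,
    n_reps: int = 6,
    delta: float = 0.3,
    beta: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    tf_mean: float = 10.0,
    target_mean: float = 10.0,
) -> pd.DataFrame:
    """Paired control/knockdown expression + metabolite table.

    Control replicates draw TF expression ~ N(tf_mean, noise_sd); the
    knockdown condition scales the TF mean by ``delta``.  Each target's
    mean shifts by ``sign * beta * (TF deviation from its control mean)``,
    and each metabolite is its signed weighted sum of pathway-gene
    expression plus noise.  Rows are replicates with a ``condition``
    column (``control`` / ``knockdown``).
    """
    if n_reps < 2:
        raise ValueError("need n_reps >= 2")
    if not 0 < delta < 1:
        raise ValueError("delta must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    tfs = sorted({tf for tf, _, _ in truth.true_edges})
    edges_by_target: dict[str, list[tuple[str, int]]] = {}
    for tf, target, sign in truth.true_edges:
        edges_by_target.setdefault(target, []).append((tf, sign))
    targets = sorted(edges_by_target)

    conditions = ["control"] * n_reps + ["knockdown"] * n_reps
    data: dict[str, np.ndarray] = {}
    tf_values: dict[str, np.ndarray] = {}
    for tf in tfs:
        mu = np.where(np.array(conditions) == "control", tf_mean, tf_mean * delta)
        tf_values[tf] = mu + rng.normal(0.0, noise_sd, size=2 * n_reps)
        data[tf] = tf_values[tf]
    for target in targets:
        expr = np.full(2 * n_reps, target_mean, dtype=float)
        for tf, sign in edges_by_target[target]:
            expr = expr + sign * beta * (tf_values[tf] - tf_mean)
        data[target] = expr + rng.normal(0.0, noise_sd, size=2 * n_reps)
    for met, (genes, weights, sign) in sorted(truth.metabolite_loadings.items()):
        total = np.zeros(2 * n_reps)
        for gene, w in zip(genes, weights):
            if gene not in data:
                raise ValueError(f"metabolite {met!r} loads on unmeasured gene {gene!r}")
            total = total + w * data[gene]
        data[met] = sign * total + rng.normal(0.0, noise_sd, size=2 * n_reps)

    table = pd.DataFrame({"condition": conditions, **data})
    table.index.name = "replicate"
    return table


# ---------------------------------------------------------------------------
# truth (de)serialization


def truth_to_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "domain_of": truth.domain_of,
        "module_of": truth.module_of,
        "true_edges": sorted([tf, tg, sign] for tf, tg, sign in truth.true_edges),
        "planted_sites": [list(site) for site in truth.planted_sites],
        "metabolite_loadings": {
            met: {"genes": genes, "weights": weights, "sign": sign}
            for met, (genes, weights, sign) in truth.metabolite_loadings.items()
        },
        "tf_family_of": truth.tf_family_of,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def truth_from_json(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        domain_of=payload["domain_of"],
        module_of=payload["module_of"],
        true_edges={(tf, tg, int(sign)) for tf, tg, sign in payload["true_edges"]},
        planted_sites=[tuple(site) for site in payload["planted_sites"]],
        metabolite_loadings={
            met: (d["genes"], d["weights"], int(d["sign"]))
            for met, d in payload["metabolite_loadings"].items()
        },
        tf_family_of=payload.get("tf_family_of", {}),
    )
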