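"""Synthetic directed gene networks with planted drivers + matched omics.

The generator emulates the *shape* of a pan-cancer driver-gene study at
desk scale, not TCGA marginals: a directed two-block
preferential-attachment graph in which planted driver genes are both more
densely interconnected (within-driver multiplier ρ) and more regulatory
(out-degree boost ρ), plus a paired tumor/normal omics cohort whose driver
columns are shifted by an effect size δ (in units of the per-feature
noise scale):

* mutation — Bernoulli indicators, driver rate shifted by δ·sd;
* methylation — Beta-distributed betas, tumor−normal mean shift for drivers;
* expression — log-normal, drivers get a δ-scaled log2 fold-change;
* SYS table — Gaussian/Bernoulli columns with δ-scaled driver shifts.

At δ=0 and ρ=1 drivers are exchangeable with every other gene, so the
full pipeline must score at chance. A separate generator plants the driver
signal *only* in edge orientation (identical undirected skeleton for all
genes), isolating the value of the phase encoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import GeneGraph, LabelSet
from .omics_features import SYS_COLUMNS, OmicsCohort

__all__ = [
    "SimSpec",
    "simulate_graph",
    "simulate_direction_graph",
    "simulate_cohort",
    "simulate_benchmark",
    "make_benchmark",
    "load_benchmark",
]


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic benchmark.

    Defaults are the desk-scale benchmark: 400 genes, 40 planted drivers,
    120 labeled negatives, 4 cancer types × 30 tumor/normal pairs, strong
    planted signal (δ=2 feature separation, ρ=2 driver connectivity).
    """

    n_genes: int = 400
    n_drivers: int = 40
    n_nondrivers: int = 120
    n_cancer_types: int = 4
    samples_per_type: int = 30
    mean_out_degree: float = 6.0
    rho: float = 2.0          # within-driver density and out-degree multiplier
    reciprocal_fraction: float = 0.3
    delta: float = 2.0        # driver feature shift in noise-sd units
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.rho < 1:
            raise ValueError("rho must be >= 1")
        if self.n_drivers + self.n_nondrivers > self.n_genes:
            raise ValueError("labeled genes exceed n_genes")
        if self.samples_per_type < 2:
            raise ValueError("samples_per_type must be >= 2")
        if self.delta < 0 or self.noise_sd <= 0:
            raise ValueError("delta must be >= 0 and noise_sd > 0")

    def replace(self, **kw) -> "SimSpec":
        return replace(self, **kw)


def gene_names(spec: SimSpec) -> tuple[str, ...]:
    width = len(str(spec.n_genes - 1))
    return tuple(f"G{i:0{width}d}" for i in range(spec.n_genes))


def planted_sets(spec: SimSpec) -> tuple[frozenset[str], frozenset[str]]:
    """(drivers, labeled negatives); deterministic given the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    names = gene_names(spec)
    order = rng.permutation(spec.n_genes)
    drivers = frozenset(names[i] for i in order[: spec.n_drivers])
    negatives = frozenset(
        names[i] for i in order[spec.n_drivers: spec.n_drivers + spec.n_nondrivers]
    )
    return drivers, negatives


def simulate_graph(spec: SimSpec) -> GeneGraph:
    """Directed two-block preferential-attachment graph.

    Every node emits ~Poisson(mean_out_degree) edges (drivers: ×ρ), each
    aimed at a target drawn with probability ∝ (in-degree + 1), with
    driver→driver attachments further up-weighted by ρ. A fraction of the
    edges is made reciprocal, emulating the undirected PPI component.
    """
    rng = np.random.default_rng(spec.seed + 1)
    names = gene_names(spec)
    drivers, _ = planted_sets(spec)
    is_driver = np.array([g in drivers for g in names])
    n = spec.n_genes
    in_deg = np.ones(n)
    edges: set[tuple[int, int]] = set()
    for u in rng.permutation(n):
        rate = spec.mean_out_degree * (spec.rho if is_driver[u] else 1.0)
        k = rng.poisson(rate)
        if k == 0:
            continue
        w = in_deg.copy()
        if is_driver[u]:
            w[is_driver] *= spec.rho
        w[u] = 0.0
        p = w / w.sum()
        targets = rng.choice(n, size=k, p=p)
        for v in np.unique(targets):
            edges.add((u, int(v)))
            in_deg[v] += 1
    edge_list = sorted(edges)
    flip = rng.random(len(edge_list)) < spec.reciprocal_fraction
    for (u, v), rec in zip(edge_list, flip):
        if rec:
            edges.add((v, u))
    built = {
        (names[u], names[v]): (1.0, frozenset(["SIM"]))
        for u, v in edges
    }
    return GeneGraph.from_symbol_edges(built, extra_nodes=set(names))


def simulate_direction_graph(spec: SimSpec) -> GeneGraph:
    """Driver signal planted ONLY in edge orientation.

    An Erdős–Rényi undirected skeleton (class-blind) is generated, then
    every edge receives exactly one direction: edges incident to a driver
    point away from the driver with probability 0.9; all other edges are
    oriented uniformly. Degrees and the symmetrized adjacency are therefore
    exchangeable across classes — only the phase encoding can separate them.
    """
    rng = np.random.default_rng(spec.seed + 2)
    names = gene_names(spec)
    drivers, _ = planted_sets(spec)
    is_driver = np.array([g in drivers for g in names])
    n = spec.n_genes
    p = spec.mean_out_degree * 2.0 / (n - 1)
    iu = np.triu_indices(n, k=1)
    keep = rng.random(len(iu[0])) < p
    us, vs = iu[0][keep], iu[1][keep]
    edges: dict[tuple[str, str], tuple[float, frozenset[str]]] = {}
    tag = frozenset(["SIM"])
    for u, v in zip(us, vs):
        du, dv = is_driver[u], is_driver[v]
        if du and not dv:
            src, dst = (u, v) if rng.random() < 0.9 else (v, u)
        elif dv and not du:
            src, dst = (v, u) if rng.random() < 0.9 else (u, v)
        else:
            src, dst = (u, v) if rng.random() < 0.5 else (v, u)
        edges[(names[src], names[dst])] = (1.0, tag)
    return GeneGraph.from_symbol_edges(edges, extra_nodes=set(names))


def simulate_cohort(spec: SimSpec, driver_set: frozenset[str]
                    ) -> tuple[OmicsCohort, pd.DataFrame]:
    """Paired tumor/normal omics + SYS table with δ-scaled driver shifts."""
    names = gene_names(spec)
    unknown = set(driver_set) - set(names)
    if unknown:
        raise ValueError(f"driver set contains unknown genes: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(spec.seed + 3)
    is_driver = np.array([g in driver_set for g in names])
    n, m = spec.n_genes, spec.samples_per_type
    cohort = OmicsCohort()
    base_mut = 0.05
    mut_shift = spec.delta * np.sqrt(base_mut * (1 - base_mut)) * 0.5
    meth_shift = min(0.08 * spec.delta, 0.4)
    log2fc = 0.5 * spec.delta
    for t in range(spec.n_cancer_types):
        c = f"C{t:02d}"
        samples = [f"{c}_S{s:02d}" for s in range(m)]
        p_mut = np.where(is_driver, min(base_mut + mut_shift, 0.95), base_mut)
        cohort.mutation[c] = pd.DataFrame(
            (rng.random((n, m)) < p_mut[:, None]).astype(float),
            index=names, columns=samples,
        )
        mean_norm = rng.uniform(0.3, 0.7, size=n)
        a, b = _beta_params_vec(mean_norm)
        beta_n = rng.beta(a[:, None], b[:, None], size=(n, m))
        mean_tum = np.clip(mean_norm + np.where(is_driver, meth_shift, 0.0),
                           0.02, 0.98)
        at, bt = _beta_params_vec(mean_tum)
        beta_t = rng.beta(at[:, None], bt[:, None], size=(n, m))
        cohort.methylation_normal[c] = pd.DataFrame(
            beta_n, index=names, columns=samples)
        cohort.methylation_tumor[c] = pd.DataFrame(
            beta_t, index=names, columns=samples)
        mu = rng.normal(2.0, 1.0, size=n)
        sd = 0.5 * spec.noise_sd
        expr_n = np.exp(mu[:, None] + rng.normal(0, sd, size=(n, m)))
        shift = np.where(is_driver, log2fc * np.log(2.0), 0.0)
        expr_t = np.exp(mu[:, None] + shift[:, None]
                        + rng.normal(0, sd, size=(n, m)))
        cohort.expression_normal[c] = pd.DataFrame(
            expr_n, index=names, columns=samples)
        cohort.expression_tumor[c] = pd.DataFrame(
            expr_t, index=names, columns=samples)

    shift = 0.5 * spec.delta
    sys = pd.DataFrame(index=list(names))
    bern = {"ohnolog": 0.2, "essential_flag": 0.3, "hub_flag": 0.2}
    for col in SYS_COLUMNS:
        if col in bern:
            p0 = bern[col]
            p1 = min(p0 + 0.15 * spec.delta, 0.95)
            pv = np.where(is_driver, p1, p0)
            sys[col] = (rng.random(n) < pv).astype(float)
        else:
            base = rng.normal(0.0, spec.noise_sd, size=n)
            sys[col] = base + np.where(is_driver, shift * spec.noise_sd, 0.0)
    return cohort, sys


def _beta_params_vec(mean: np.ndarray, concentration: float = 20.0):
    mean = np.clip(mean, 0.02, 0.98)
    return mean * concentration, (1.0 - mean) * concentration


def simulate_benchmark(spec: SimSpec, direction_only: bool = False
                       ) -> tuple[GeneGraph, OmicsCohort, pd.DataFrame, LabelSet]:
    """In-memory benchmark: graph, cohort, SYS table and labels."""
    drivers, negatives = planted_sets(spec)
    graph = (simulate_direction_graph(spec) if direction_only
             else simulate_graph(spec))
    cohort, sys = simulate_cohort(spec, drivers)
    labels = LabelSet(
        positives=drivers, negatives=negatives,
        unknown=frozenset(set(graph.nodes) - drivers - negatives),
    )
    return graph, cohort, sys, labels


def make_benchmark(spec: SimSpec, outdir) -> dict:
    """Write a CLI-consumable bundle and return its manifest.

    The directed edges are split across two pseudo-sources (so integration
    dedup/merging is exercised) and an undirected pseudo-PPI source with
    uniform(0,1) confidence scores is added (so score thresholds are
    exercised). Cohort matrices are one TSV per (cancer type, channel).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, cohort, sys, labels = simulate_benchmark(spec)
    rng = np.random.default_rng(spec.seed + 4)

    split = rng.random(graph.n_edges) < 0.5
    with open(outdir / "regnet_a.tsv", "w") as fa, \
         open(outdir / "regnet_b.tsv", "w") as fb:
        for take_a, (u, v, _, _) in zip(split, graph.edges):
            (fa if take_a else fb).write(f"{graph.nodes[u]}\t{graph.nodes[v]}\n")

    n_ppi = max(graph.n_edges // 2, 1)
    nodes = list(graph.nodes)
    with open(outdir / "ppi.tsv", "w") as fp:
        for _ in range(n_ppi):
            u, v = rng.choice(len(nodes), size=2, replace=False)
            fp.write(f"{nodes[u]}\t{nodes[v]}\t{rng.random():.6f}\n")

    for c in cohort.cancer_types:
        for channel, table in (
            ("mutation", cohort.mutation[c]),
            ("methylation_tumor", cohort.methylation_tumor[c]),
            ("methylation_normal", cohort.methylation_normal[c]),
            ("expression_tumor", cohort.expression_tumor[c]),
            ("expression_normal", cohort.expression_normal[c]),
        ):
            table.to_csv(outdir / f"{channel}_{c}.tsv", sep="\t")
    sys.to_csv(outdir / "sys_features.tsv", sep="\t")
    (outdir / "positives.txt").write_text(
        "\n".join(sorted(labels.positives)) + "\n")
    (outdir / "negatives.txt").write_text(
        "\n".join(sorted(labels.negatives)) + "\n")
    manifest = {
        "n_genes": spec.n_genes,
        "cancer_types": list(cohort.cancer_types),
        "drivers": sorted(labels.positives),
        "negatives": sorted(labels.negatives),
        "sources": [
            {"name": "REGNET_A", "kind": "directed", "path": "regnet_a.tsv"},
            {"name": "REGNET_B", "kind": "directed", "path": "regnet_b.tsv"},
            {"name": "PPI", "kind": "undirected", "path": "ppi.tsv",
             "score_column": 2, "min_score": 0.85},
        ],
        "seed": spec.seed,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_benchmark(outdir) -> tuple[GeneGraph, OmicsCohort, pd.DataFrame, LabelSet]:
    """Load a bundle written by :func:`make_benchmark` through the regular
    ingestion path (integration + label reading)."""
    from .core_io import read_labels
    from .network_integration import SourceSpec, integrate

    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    sources = [
        SourceSpec(
            name=s["name"], path=str(outdir / s["path"]), kind=s["kind"],
            score_column=s.get("score_column"), min_score=s.get("min_score"),
        )
        for s in manifest["sources"]
    ]
    graph = integrate(sources)
    cohort = OmicsCohort()
    for c in manifest["cancer_types"]:
        for channel, store in (
            ("mutation", cohort.mutation),
            ("methylation_tumor", cohort.methylation_tumor),
            ("methylation_normal", cohort.methylation_normal),
            ("expression_tumor", cohort.expression_tumor),
            ("expression_normal", cohort.expression_normal),
        ):
            store[c] = pd.read_csv(outdir / f"{channel}_{c}.tsv",
                                   sep="\t", index_col=0)
    sys = pd.read_csv(outdir / "sys_features.tsv", sep="\t", index_col=0)
    labels = read_labels(outdir / "positives.txt", outdir / "negatives.txt",
                         graph)
    return graph, cohort, sys, labels
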