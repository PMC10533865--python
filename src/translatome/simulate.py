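"""Synthetic fixture generators with planted ground truth.

Every generator is a pure function of its parameters and seed and mimics
the statistical shape of one of the study's four assay types: NB
polysome-profiling counts over input/monosome/polysome fractions with
antagonistically planted translational shifts, Poisson UMI nucleus
matrices with planted cluster markers, annotation tables and risk gene
sets with a tunable enrichment factor, and qPCR Ct tables constructed so
the triple-differenced statistic inverts the planted log2 ratios exactly
at zero noise. A bundle writer emits the full on-disk fixture set plus a
ground_truth.json.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as tio
from .datatypes import AnnotationTable, CountTable, CtTable, GeneSetCollection, NucleusMatrix
from .errors import SpecError

PHASE_PREFIX = {"early": "E", "mid": "M", "late": "L"}


@dataclass
class SimulationSpec:
    """Parameters for the fraction-count generator."""

    n_features: int = 2000
    n_replicates: int = 3
    planted_derepressed: set[str] = field(default_factory=set)
    planted_repressed: set[str] = field(default_factory=set)
    planted_input_shifted: set[str] = field(default_factory=set)
    effect_log2fc: float = 2.0
    dispersion: float = 0.05
    library_size_mean: int = 200_000
    library_sigma: float = 0.15  # sd of log library-size factors
    mean_sigma: float = 1.0     # sd of log feature means
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise SpecError("dispersion must be > 0")
        if self.n_replicates < 2:
            raise SpecError("n_replicates must be >= 2")
        if self.effect_log2fc <= 0:
            raise SpecError("effect_log2fc must be > 0")
        sets = [set(self.planted_derepressed), set(self.planted_repressed),
                set(self.planted_input_shifted)]
        total = sum(len(s) for s in sets)
        if len(set.union(*sets)) != total:
            raise SpecError("planted feature sets must be pairwise disjoint")
        ids = set(self.feature_ids)
        for s in sets:
            if not s <= ids:
                raise SpecError("planted set contains unknown feature ids")

    @property
    def feature_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_features)]


def default_planted_spec(
    n_features: int = 2000,
    n_planted: int = 100,
    n_input_shifted: int = 100,
    seed: int = 0,
    **kwargs,
) -> SimulationSpec:
    """Convenience spec with the first features planted derepressed,
    then repressed, then input-shifted."""
    ids = [f"G{i:05d}" for i in range(n_features)]
    return SimulationSpec(
        n_features=n_features,
        planted_derepressed=set(ids[:n_planted]),
        planted_repressed=set(ids[n_planted:2 * n_planted]),
        planted_input_shifted=set(ids[2 * n_planted:2 * n_planted + n_input_shifted]),
        seed=seed,
        **kwargs,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean mu, variance mu + alpha mu^2) via the gamma-Poisson mixture
    parameterization numpy exposes."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_fraction_counts(spec: SimulationSpec, design=("early", "mid")) -> CountTable:
    """Generate input/monosome/polysome counts for two conditions.

    ``design`` is a pair of condition labels: two phases (early/mid/late)
    or two genotypes (WT/cKO). Feature means are log-normal across
    features; each sample carries a log-normal library-size factor;
    planted derepressed features gain ``effect_log2fc`` on polysome means
    and lose it on monosome means in the second condition (repressed
    features the reverse); input-shifted features move their input means
    by the effect with a random sign.
    """
    cond1, cond2 = design
    if {cond1, cond2} <= set(PHASE_PREFIX):
        kind = "phases"
    elif {cond1, cond2} <= {"WT", "cKO"}:
        kind = "genotypes"
    else:
        raise SpecError(f"design must be two phases or two genotypes, got {design}")

    rng = np.random.default_rng(spec.seed)
    ids = spec.feature_ids
    mean_expr = spec.library_size_mean / spec.n_features
    base = mean_expr * np.exp(
        rng.normal(0.0, spec.mean_sigma, spec.n_features) - spec.mean_sigma**2 / 2
    )
    shift = 2.0 ** spec.effect_log2fc
    dere = np.asarray([f in spec.planted_derepressed for f in ids])
    repr_ = np.asarray([f in spec.planted_repressed for f in ids])
    inp_sh = np.asarray([f in spec.planted_input_shifted for f in ids])
    input_sign = rng.choice([-1.0, 1.0], size=spec.n_features)

    # per-fraction mean multipliers in the second condition
    mult = {
        ("input", cond1): np.ones(spec.n_features),
        ("monosome", cond1): np.ones(spec.n_features),
        ("polysome", cond1): np.ones(spec.n_features),
        ("input", cond2): np.where(inp_sh, shift**input_sign, 1.0),
        ("monosome", cond2): np.where(dere, 1 / shift, np.where(repr_, shift, 1.0)),
        ("polysome", cond2): np.where(dere, shift, np.where(repr_, 1 / shift, 1.0)),
    }

    columns, meta_rows = {}, []
    for cond in design:
        for fraction in ("input", "monosome", "polysome"):
            for rep in range(1, spec.n_replicates + 1):
                lib = float(np.exp(rng.normal(0.0, spec.library_sigma)))
                mu = base * mult[(fraction, cond)] * lib
                name = f"{cond}_{fraction}_r{rep}"
                columns[name] = _nb_draw(rng, mu, spec.dispersion)
                meta_rows.append(
                    {
                        "sample_id": name,
                        "fraction": fraction,
                        "phase": cond if kind == "phases" else "na",
                        "genotype": cond if kind == "genotypes" else "na",
                        "antibody": "na",
                        "replicate": rep,
                    }
                )
    counts = pd.DataFrame(columns, index=ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountTable(counts, meta)


def simulate_nucleus_matrix(
    n_clusters: int,
    nuclei_per_cluster: int,
    markers_per_cluster: int,
    marker_fold: float,
    baseline_rate: float,
    seed: int,
    n_genes: int = 500,
    phase: str = "mid",
    rate_sigma: float = 0.5,
) -> tuple[NucleusMatrix, dict[str, list[str]]]:
    """Poisson UMI matrix with planted cluster markers.

    Each gene has a log-normal baseline rate (median ``baseline_rate``);
    a cluster's designated markers have their rate multiplied by
    ``marker_fold`` inside that cluster. Returns the matrix and the
    ground-truth cluster -> marker genes mapping.
    """
    if min(n_clusters, nuclei_per_cluster, markers_per_cluster) <= 0:
        raise SpecError("all size parameters must be positive")
    if marker_fold < 1:
        raise SpecError("marker_fold must be >= 1")
    if markers_per_cluster * n_clusters > n_genes:
        raise SpecError("markers_per_cluster x n_clusters exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"SG{i:04d}" for i in range(n_genes)]
    prefix = PHASE_PREFIX.get(phase, "C")
    clusters = [f"{prefix}{i}" for i in range(n_clusters)]
    perm = rng.permutation(n_genes)
    truth = {
        clusters[c]: sorted(genes[perm[c * markers_per_cluster + j]]
                            for j in range(markers_per_cluster))
        for c in range(n_clusters)
    }
    rates = baseline_rate * np.exp(rng.normal(0.0, rate_sigma, n_genes))
    n_nuclei = n_clusters * nuclei_per_cluster
    labels = np.repeat(clusters, nuclei_per_cluster)
    rate_matrix = np.tile(rates[:, None], (1, n_nuclei))
    gene_index = {g: i for i, g in enumerate(genes)}
    for c, cluster in enumerate(clusters):
        cols = slice(c * nuclei_per_cluster, (c + 1) * nuclei_per_cluster)
        for g in truth[cluster]:
            rate_matrix[gene_index[g], cols] *= marker_fold
    counts = sp.csr_matrix(rng.poisson(rate_matrix))
    barcodes = [f"BC{i:05d}" for i in range(n_nuclei)]
    matrix = NucleusMatrix(genes, barcodes, counts, labels, phase=phase)
    return matrix, truth


def simulate_annotations(
    gene_ids: list[str],
    frac_rbp: float,
    frac_synaptic: float,
    enriched_cluster_markers: set[str],
    target_set_size: int,
    enrichment_factor: float,
    seed: int,
    frac_scored: float = 1.0,
    planted_top_rbp: str | None = None,
) -> tuple[AnnotationTable, GeneSetCollection, dict]:
    """Annotation table + risk gene set with planted structure.

    A ``frac_rbp`` subset gets positive RBP scores, a ``frac_synaptic``
    subset gets >=1 GO term name containing 'synapt', and the risk set of
    ``target_set_size`` genes is drawn with weight ``enrichment_factor``
    on ``enriched_cluster_markers`` and weight 1 elsewhere.
    ``planted_top_rbp`` forces one gene to be the top-scoring synaptic
    RBP candidate.
    """
    if target_set_size > len(gene_ids):
        raise SpecError("target_set_size exceeds the number of genes")
    rng = np.random.default_rng(seed)
    genes = list(gene_ids)
    n = len(genes)
    rbp_genes = set(rng.choice(genes, size=int(round(frac_rbp * n)), replace=False))
    synaptic_genes = set(rng.choice(genes, size=int(round(frac_synaptic * n)), replace=False))
    synaptic_pool = [
        "synapse assembly",
        "modification of synaptic structure",
        "presynaptic active zone organization",
        "chemical synaptic transmission",
    ]
    other_pool = [
        "mitochondrial respiratory chain complex I",
        "cytoplasmic translation",
        "RNA splicing",
        "axon guidance",
    ]
    records = []
    max_score = 0.0
    for g in genes:
        score = float(rng.gamma(2.0, 15.0)) if g in rbp_genes else float("nan")
        if not np.isnan(score):
            max_score = max(max_score, score)
        terms = list(rng.choice(other_pool, size=2, replace=False))
        if g in synaptic_genes:
            terms.append(str(rng.choice(synaptic_pool)))
        records.append({"symbol": g, "rbp_score": score, "go_terms": terms})
    table = pd.DataFrame(records).set_index("symbol")
    scored = set(rng.choice(genes, size=int(round(frac_scored * n)), replace=False))
    table["risk_score_present"] = [g in scored for g in table.index]
    if planted_top_rbp is not None:
        if planted_top_rbp not in table.index:
            raise SpecError(f"planted_top_rbp {planted_top_rbp!r} not among gene_ids")
        table.at[planted_top_rbp, "rbp_score"] = max_score + 50.0
        table.at[planted_top_rbp, "go_terms"] = ["synapse assembly", "axon guidance"]
        rbp_genes.add(planted_top_rbp)
        synaptic_genes.add(planted_top_rbp)
    weights = np.asarray(
        [enrichment_factor if g in enriched_cluster_markers else 1.0 for g in genes]
    )
    target = rng.choice(genes, size=target_set_size, replace=False, p=weights / weights.sum())
    collection = GeneSetCollection(
        sets={"RISK": sorted(target)},
        descriptions={"RISK": "synthetic risk gene set"},
    )
    truth = {
        "rbp_genes": sorted(rbp_genes),
        "synaptic_genes": sorted(synaptic_genes),
        "risk_set": sorted(target),
        "scored_genes": sorted(scored),
        "planted_top_rbp": planted_top_rbp,
        "enrichment_factor": enrichment_factor,
    }
    return AnnotationTable(table), collection, truth


def simulate_ct_table(
    true_log2_ratios: dict[str, float],
    noise_sd: float,
    n_bio: int,
    n_tech: int,
    seed: int,
    reference_gene: str = "ACTB",
    base_ct: float = 25.0,
    ref_ct: float = 20.0,
) -> CtTable:
    """qPCR Ct table whose expected cKO ΔΔΔCt equals -true_log2_ratio.

    WT samples have equal target Ct in both fractions; cKO samples have
    their polysome Ct lowered by the planted ratio (one Ct unit = one
    2-fold change). Gaussian noise with sd ``noise_sd`` on every
    technical replicate.
    """
    if n_tech < 1:
        raise SpecError("n_tech must be >= 1")
    if n_bio < 1:
        raise SpecError("n_bio must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in ("WT", "cKO"):
        for b in range(1, n_bio + 1):
            sample = f"{genotype}{b}"
            for fraction in ("monosome", "polysome"):
                for tech in range(1, n_tech + 1):
                    rows.append({
                        "gene": reference_gene, "sample_id": sample, "fraction": fraction,
                        "genotype": genotype, "antibody": "na", "tech_replicate": tech,
                        "ct": ref_ct + noise_sd * rng.standard_normal(),
                    })
                for gene, ratio in true_log2_ratios.items():
                    mean = base_ct
                    if genotype == "cKO" and fraction == "polysome":
                        mean = base_ct - ratio
                    for tech in range(1, n_tech + 1):
                        rows.append({
                            "gene": gene, "sample_id": sample, "fraction": fraction,
                            "genotype": genotype, "antibody": "na", "tech_replicate": tech,
                            "ct": mean + noise_sd * rng.standard_normal(),
                        })
    return CtTable(pd.DataFrame(rows))


def simulate_rip_counts(
    n_features: int,
    planted_targets: set[str],
    effect_log2fc: float,
    dispersion: float,
    n_replicates: int,
    seed: int,
    mean_expression: float = 100.0,
    mean_sigma: float = 1.0,
    library_sigma: float = 0.15,
) -> CountTable:
    """RIP-vs-IgG count table with planted enriched features.

    Planted features have their RIP-sample means multiplied by
    2**effect_log2fc; all features share the IgG baseline.
    """
    ids = [f"R{i:05d}" for i in range(n_features)]
    if not set(planted_targets) <= set(ids):
        raise SpecError("planted_targets contains unknown feature ids")
    rng = np.random.default_rng(seed)
    base = mean_expression * np.exp(
        rng.normal(0.0, mean_sigma, n_features) - mean_sigma**2 / 2
    )
    enriched = np.asarray([f in planted_targets for f in ids])
    shift = np.where(enriched, 2.0 ** effect_log2fc, 1.0)
    columns, meta_rows = {}, []
    for antibody in ("IgG", "RIP"):
        for rep in range(1, n_replicates + 1):
            lib = float(np.exp(rng.normal(0.0, library_sigma)))
            mu = base * (shift if antibody == "RIP" else 1.0) * lib
            name = f"{antibody}_r{rep}"
            columns[name] = _nb_draw(rng, mu, dispersion)
            meta_rows.append({
                "sample_id": name, "fraction": "na", "phase": "na",
                "genotype": "na", "antibody": antibody, "replicate": rep,
            })
    counts = pd.DataFrame(columns, index=ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountTable(counts, meta)


def write_fixture_bundle(out_dir, seed: int) -> dict:
    """Write a complete fixture set for the CLI chain; returns ground truth.

    Emits: fraction counts + metadata TSVs (early vs mid phases), an MTX
    nucleus bundle, a risk-set GMT, an annotation TSV, a polysome/monosome
    Ct CSV, RIP counts + metadata TSVs, and ground_truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed) % (2**31)

    spec = default_planted_spec(
        n_features=2000, n_planted=100, n_input_shifted=100,
        effect_log2fc=2.0, dispersion=0.05, seed=rng_seed,
    )
    table = simulate_fraction_counts(spec, design=("early", "mid"))
    tio.write_count_table(table, out / "fraction_counts.tsv", out / "fraction_meta.tsv")

    matrix, marker_truth = simulate_nucleus_matrix(
        n_clusters=6, nuclei_per_cluster=100, markers_per_cluster=5,
        marker_fold=8.0, baseline_rate=0.2, seed=rng_seed + 1,
        n_genes=500, phase="mid",
    )
    tio.write_nucleus_matrix(matrix, out / "nuclei")

    sp_clusters = ["M0", "M1"]
    neuronal_clusters = ["M2", "M3", "M4"]
    enriched = {g for c in sp_clusters for g in marker_truth[c]}
    planted_rbp = marker_truth[sp_clusters[0]][0]
    annotations, gene_sets, ann_truth = simulate_annotations(
        matrix.gene_ids, frac_rbp=0.2, frac_synaptic=0.3,
        enriched_cluster_markers=enriched, target_set_size=40,
        enrichment_factor=10.0, seed=rng_seed + 2,
        planted_top_rbp=planted_rbp,
    )
    tio.write_annotations(annotations, out / "annotations.tsv")
    tio.write_gene_sets(gene_sets, out / "gene_sets.gmt")

    ratios = {"SYN2": 1.0, "SV2A": 1.5, "GABRA3": 0.5, "EIF4A2": 2.0, "NES": 0.0}
    ct = simulate_ct_table(ratios, noise_sd=0.2, n_bio=4, n_tech=3, seed=rng_seed + 3)
    tio.write_ct_table(ct, out / "ct_table.csv")

    rip_ids = [f"R{i:05d}" for i in range(1000)]
    rip_targets = set(rip_ids[:50])
    rip = simulate_rip_counts(
        n_features=1000, planted_targets=rip_targets, effect_log2fc=3.0,
        dispersion=0.05, n_replicates=3, seed=rng_seed + 4,
    )
    tio.write_count_table(rip, out / "rip_counts.tsv", out / "rip_meta.tsv")

    truth = {
        "seed": rng_seed,
        "fraction_design": ["early", "mid"],
        "planted_derepressed": sorted(spec.planted_derepressed),
        "planted_repressed": sorted(spec.planted_repressed),
        "planted_input_shifted": sorted(spec.planted_input_shifted),
        "cluster_markers": marker_truth,
        "sp_clusters": sp_clusters,
        "neuronal_clusters": neuronal_clusters,
        "annotations": ann_truth,
        "ct_true_log2_ratios": ratios,
        "ct_reference_gene": "ACTB",
        "rip_planted_targets": sorted(rip_targets),
    }
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
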