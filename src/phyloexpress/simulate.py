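"""Synthetic multi-species 3'TagSeq-like datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomial transcript counts with per-sample library-size
factors, per-orthogroup baselines, species baseline effects, a shared
treatment log2 fold change per orthogroup, and species x treatment interaction
deviations optionally drawn with phylogenetic (Brownian, lambda-scaled)
covariance across species. Orthogroup copy number varies per species
(zero-truncated geometric for core orthogroups; absences allowed otherwise)
and the orthogroup-level mean is split across its transcripts by symmetric
Dirichlet weights. GO terms are assigned at random, with an optional bias of a
designated term block toward truly DE transcripts.

Defaults are the study conditions: 14 species, 158 samples split as evenly as
possible over the 28 species x treatment cells, interaction variance exceeding
the shared-treatment variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json
import math

import numpy as np
import pandas as pd

from .io import (
    GOAnnotation,
    OrthogroupMap,
    SampleMetadata,
    SpeciesTree,
    TranscriptCountMatrix,
    read_newick,
    write_counts,
    write_go,
    write_metadata,
    write_newick,
    write_orthogroups,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_dataset",
    "write_dataset",
]

LN2 = math.log(2.0)


@dataclass
class SimulationConfig:
    """Knobs of the generative model. All effect scales are standard deviations.

    Log-fold-change scales (``treatment_lfc_sd``, ``interaction_sd``, ``de_lfc``)
    are in log2 units; baseline and species effects are on the natural-log scale
    of expected counts.
    """

    n_species: int = 14
    n_orthogroups: int = 2000
    # None -> allocate target_total_samples as evenly as possible over the
    # 2 * n_species cells; an int forces that many samples per cell.
    samples_per_species_per_treatment: int | None = None
    target_total_samples: int = 158
    core_fraction: float = 0.85
    copy_number_mean: float = 1.5  # zero-truncated geometric mean per species
    baseline_log_mean: float = 4.6  # ln scale, exp(4.6) ~ 100 counts
    baseline_log_sd: float = 1.2
    species_effect_sd: float = 1.0  # ln scale
    treatment_lfc_sd: float = 0.25  # shared treatment lfc scale (log2)
    interaction_sd: float = 0.5  # species x treatment deviation scale (log2)
    lambda_true: float = 0.5  # phylogenetic weight of interaction covariance
    nb_dispersion: float = 0.3  # alpha in Var = mu + alpha mu^2
    size_factor_log_sd: float = 0.4
    n_go_terms: int = 300
    go_annotation_rate: float = 0.7
    go_terms_per_transcript: float = 3.0
    go_de_bias: float = 1.0  # >1 biases a 10% term block onto DE transcripts
    de_fraction: float | None = None  # spike mode: fraction of OGs at |lfc|=de_lfc
    de_lfc: float = 2.0
    dirichlet_concentration: float = 1.0
    center_interactions: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_orthogroups < 1:
            raise ValueError("n_orthogroups must be >= 1")
        for name in (
            "baseline_log_sd",
            "species_effect_sd",
            "treatment_lfc_sd",
            "interaction_sd",
            "size_factor_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.copy_number_mean < 1:
            raise ValueError("copy_number_mean must be >= 1")
        if not 0.0 < self.core_fraction <= 1.0:
            raise ValueError("core_fraction must lie in (0, 1]")


@dataclass
class GroundTruth:
    """What the generator knows and the analysis tries to recover."""

    shared_lfc: pd.Series  # per orthogroup, log2
    interaction: pd.DataFrame  # orthogroup x species, log2
    species_effects: pd.DataFrame  # orthogroup x species, ln
    baseline_log: pd.Series  # per orthogroup, ln
    lambda_true: float
    size_factors: pd.Series  # per sample (geometric mean not forced to 1)
    copy_numbers: pd.DataFrame  # orthogroup x species
    core_orthogroups: frozenset
    de_orthogroups: frozenset  # spike mode only; empty otherwise
    de_transcripts: dict  # species -> frozenset of transcript ids

    def species_lfc(self) -> pd.DataFrame:
        """Total per-species log2 fold change: shared + interaction."""
        return self.interaction.add(self.shared_lfc, axis=0)


@dataclass
class SimulatedDataset:
    counts: dict  # species -> TranscriptCountMatrix
    metadata: SampleMetadata
    og_map: OrthogroupMap
    go: GOAnnotation
    tree: SpeciesTree
    truth: GroundTruth
    config: SimulationConfig

    @property
    def species_ids(self):
        return list(self.counts)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(n_species: int, seed: int | np.random.Generator = 0) -> SpeciesTree:
    """Ultrametric Yule (pure-birth) tree with strictly positive branch lengths.

    Lineages split at unit rate; after the final split all tips are extended by
    one extra exponential waiting time so no branch has length zero.
    Deterministic given the seed.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    class _Node:
        __slots__ = ("start", "split", "children", "label")

        def __init__(self, start):
            self.start, self.split, self.children, self.label = start, None, None, None

    root = _Node(0.0)
    root.split = 0.0
    a, b = _Node(0.0), _Node(0.0)
    root.children = [a, b]
    active, t = [a, b], 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active[i]
        node.split = t
        kids = [_Node(t), _Node(t)]
        node.children = kids
        active[i] = kids[0]
        active.append(kids[1])
    t_final = t + rng.exponential(1.0 / n_species)
    order = rng.permutation(n_species)
    for node, k in zip(active, order):
        node.label = f"sp{k + 1:02d}"

    def newick(node):
        if node.children is None:
            return f"{node.label}:{t_final - node.start:.10f}"
        inner = ",".join(newick(c) for c in node.children)
        end = node.split
        return f"({inner}):{end - node.start:.10f}"

    inner = ",".join(newick(c) for c in root.children)
    return read_newick(f"({inner});")


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------


def _allocate_samples(config: SimulationConfig, species: list) -> dict:
    """(species, treatment) -> sample count, as even as possible."""
    cells = [(sp, tr) for sp in species for tr in ("PBS", "alum")]
    if config.samples_per_species_per_treatment is not None:
        n = config.samples_per_species_per_treatment
        if n < 2:
            raise ValueError("need >= 2 samples per species per treatment")
        return {cell: n for cell in cells}
    total = config.target_total_samples
    base, extra = divmod(total, len(cells))
    if base < 2:
        raise ValueError("target_total_samples too small for the design")
    return {cell: base + (1 if i < extra else 0) for i, cell in enumerate(cells)}


def _zt_geometric(rng, mean: float, size) -> np.ndarray:
    """Zero-truncated geometric (support 1,2,...) with the given mean."""
    return rng.geometric(1.0 / mean, size=size)


def _lambda_correlation(tree: SpeciesTree, species: list, lam: float) -> np.ndarray:
    from .phylo_signal import tree_to_covariance

    C = tree_to_covariance(tree).correlation.loc[species, species].to_numpy()
    S = len(species)
    return lam * C + (1.0 - lam) * np.eye(S)


def simulate_dataset(
    config: SimulationConfig, tree: SpeciesTree | None = None
) -> SimulatedDataset:
    """Draw a full multi-species dataset plus its ground truth.

    Counts are NB with Var = mu + alpha mu^2 where
    mu(t, j) = s_j * w_t * exp(b_g + u_{g,s(j)} + x_j * ln2 * (beta_g + delta_{g,s(j)}))
    for transcript t of orthogroup g, sample j with treatment indicator x_j,
    and Dirichlet transcript weights w summing to 1 within (g, species).
    Bit-identical on re-run with the same config and tree.
    """
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = simulate_tree(config.n_species, rng)
    species = sorted(tree.leaf_labels)
    if len(species) != config.n_species:
        raise ValueError(
            f"tree has {len(species)} leaves but config.n_species={config.n_species}"
        )
    S, G = len(species), config.n_orthogroups
    ogs = [f"OG{k:07d}" for k in range(1, G + 1)]

    # --- design -------------------------------------------------------------
    alloc = _allocate_samples(config, species)
    meta_rows, sample_species, sample_treat = [], {}, {}
    for sp in species:
        for tr in ("PBS", "alum"):
            for k in range(alloc[(sp, tr)]):
                sid = f"{sp}_{tr}_{k + 1}"
                score = (
                    int(rng.integers(0, 2)) if tr == "PBS" else int(rng.integers(1, 4))
                )
                meta_rows.append((sid, sp, tr, score))
                sample_species[sid] = sp
                sample_treat[sid] = tr
    metadata = SampleMetadata(
        pd.DataFrame(
            meta_rows, columns=["sample_id", "species_id", "treatment", "fibrosis_score"]
        )
    )
    all_samples = [r[0] for r in meta_rows]
    size_factors = pd.Series(
        np.exp(rng.normal(0.0, config.size_factor_log_sd, len(all_samples))),
        index=all_samples,
        name="size_factor",
    )

    # --- orthogroup structure -------------------------------------------------
    n_core = max(1, int(round(config.core_fraction * G)))
    core_mask = np.zeros(G, dtype=bool)
    core_mask[rng.choice(G, size=n_core, replace=False)] = True
    copy_numbers = _zt_geometric(rng, config.copy_number_mean, (G, S))
    for g in np.flatnonzero(~core_mask):
        n_absent = 1 + int(rng.integers(0, S - 1))
        absent = rng.choice(S, size=n_absent, replace=False)
        copy_numbers[g, absent] = 0
    cn = pd.DataFrame(copy_numbers, index=ogs, columns=species)

    # --- effects ---------------------------------------------------------------
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, G)
    species_eff = rng.normal(0.0, config.species_effect_sd, (G, S))
    de_ogs = frozenset()
    if config.de_fraction is not None:
        n_de = int(round(config.de_fraction * G))
        idx = rng.choice(G, size=n_de, replace=False)
        beta = np.zeros(G)
        beta[idx] = rng.choice([-1.0, 1.0], size=n_de) * config.de_lfc
        de_ogs = frozenset(ogs[i] for i in idx)
    else:
        beta = rng.normal(0.0, config.treatment_lfc_sd, G)
    Clam = _lambda_correlation(tree, species, config.lambda_true)
    L = np.linalg.cholesky(Clam + 1e-12 * np.eye(S))
    delta = config.interaction_sd * (rng.standard_normal((G, S)) @ L.T)
    if config.center_interactions and config.interaction_sd > 0:
        delta = delta - delta.mean(axis=1, keepdims=True)

    # --- transcripts, counts, GO ---------------------------------------------
    members = {og: {} for og in ogs}
    counts, de_transcripts, go_rows = {}, {}, []
    block = max(1, config.n_go_terms // 10)  # DE-biased term block
    term_ids = np.arange(config.n_go_terms)
    base_w = np.ones(config.n_go_terms)
    bias_w = base_w.copy()
    bias_w[:block] *= config.go_de_bias
    x_is_de_og = np.zeros(G, dtype=bool)
    if de_ogs:
        x_is_de_og = np.array([og in de_ogs for og in ogs])

    sf_arr = size_factors
    for s_idx, sp in enumerate(species):
        samples = [sid for sid in all_samples if sample_species[sid] == sp]
        x = np.array([1.0 if sample_treat[sid] == "alum" else 0.0 for sid in samples])
        s_j = sf_arr.loc[samples].to_numpy()

        tx_names, tx_base, tx_lfc, tx_de = [], [], [], []
        serial = 0
        for g in range(G):
            k = copy_numbers[g, s_idx]
            if k == 0:
                continue
            w = rng.dirichlet(np.full(k, config.dirichlet_concentration))
            names = tuple(f"{sp}_t{serial + i + 1:05d}" for i in range(k))
            serial += k
            members[ogs[g]][sp] = names
            tx_names.extend(names)
            base = w * math.exp(baseline[g] + species_eff[g, s_idx])
            tx_base.extend(base)
            lfc = LN2 * (beta[g] + delta[g, s_idx])
            tx_lfc.extend([lfc] * k)
            tx_de.extend([bool(x_is_de_og[g])] * k)
        tx_base = np.asarray(tx_base)
        tx_lfc = np.asarray(tx_lfc)
        mu = tx_base[:, None] * np.exp(np.outer(tx_lfc, x)) * s_j[None, :]
        shape = 1.0 / config.nb_dispersion
        lam_mat = rng.gamma(shape, mu * config.nb_dispersion)
        y = rng.poisson(lam_mat)
        counts[sp] = TranscriptCountMatrix(
            sp, pd.DataFrame(y.astype(np.int64), index=tx_names, columns=samples)
        )
        de_transcripts[sp] = frozenset(
            name for name, flag in zip(tx_names, tx_de) if flag
        )
        annotated = rng.random(len(tx_names)) < config.go_annotation_rate
        n_terms = rng.poisson(max(config.go_terms_per_transcript - 1.0, 0.0),
                              len(tx_names)) + 1
        for name, is_on, nt, is_de in zip(tx_names, annotated, n_terms, tx_de):
            if not is_on:
                go_rows.append((name, sp, frozenset()))
                continue
            w = bias_w if (is_de and config.go_de_bias != 1.0) else base_w
            p = w / w.sum()
            nt = min(nt, config.n_go_terms)
            chosen = rng.choice(term_ids, size=nt, replace=False, p=p)
            go_rows.append(
                (name, sp, frozenset(f"GO:{t + 1:07d}" for t in chosen))
            )

    og_map = OrthogroupMap(species, members)
    go = GOAnnotation(
        pd.DataFrame(go_rows, columns=["transcript_id", "species_id", "go_terms"])
    )
    truth = GroundTruth(
        shared_lfc=pd.Series(beta, index=ogs, name="shared_lfc"),
        interaction=pd.DataFrame(delta, index=ogs, columns=species),
        species_effects=pd.DataFrame(species_eff, index=ogs, columns=species),
        baseline_log=pd.Series(baseline, index=ogs, name="baseline_log"),
        lambda_true=config.lambda_true,
        size_factors=size_factors,
        copy_numbers=cn,
        core_orthogroups=frozenset(cn.index[(cn >= 1).all(axis=1)]),
        de_orthogroups=de_ogs,
        de_transcripts=de_transcripts,
    )
    return SimulatedDataset(counts, metadata, og_map, go, tree, truth, config)


def write_dataset(ds: SimulatedDataset, outdir) -> dict:
    """Write the dataset in exactly the formats the io module reads.

    Returns a manifest of written paths. Ground truth goes to a JSON/TSV sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sp, tcm in ds.counts.items():
        p = outdir / f"counts_{sp}.tsv"
        write_counts(tcm, p)
        paths[f"counts_{sp}"] = str(p)
    write_metadata(ds.metadata, outdir / "metadata.tsv")
    paths["metadata"] = str(outdir / "metadata.tsv")
    write_orthogroups(ds.og_map, outdir / "orthogroups.tsv")
    paths["orthogroups"] = str(outdir / "orthogroups.tsv")
    write_go(ds.go, outdir / "go_annotation.tsv")
    paths["go"] = str(outdir / "go_annotation.tsv")
    write_newick(ds.tree, outdir / "species_tree.nwk")
    paths["tree"] = str(outdir / "species_tree.nwk")

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    ds.truth.shared_lfc.to_csv(truth_dir / "shared_lfc.tsv", sep="\t")
    ds.truth.interaction.to_csv(truth_dir / "interaction_lfc.tsv", sep="\t")
    ds.truth.size_factors.to_csv(truth_dir / "size_factors.tsv", sep="\t")
    ds.truth.copy_numbers.to_csv(truth_dir / "copy_numbers.tsv", sep="\t")
    scalars = {
        "lambda_true": ds.truth.lambda_true,
        "de_orthogroups": sorted(ds.truth.de_orthogroups),
        "core_orthogroups": sorted(ds.truth.core_orthogroups),
        "config": asdict(ds.config),
    }
    (truth_dir / "truth.json").write_text(json.dumps(scalars, indent=1))
    paths["truth"] = str(truth_dir)
    return paths
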